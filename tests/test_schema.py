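import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from treestrat.errors import CohortError, SchemaError
from treestrat.schema import (
    VariableSpec,
    Cutpoint,
    default_specs,
    discretize,
    impute_missing,
    load_cohort,
)


@pytest.fixture(scope="module")
def specs():
    return default_specs()


def spec_of(specs, name):
    return next(s for s in specs if s.name == name)


class TestVariableSpec:
    def test_default_specs_cover_the_full_design(self, specs):
        assert len(specs) == 34
        roles = {}
        for s in specs:
            roles[s.role] = roles.get(s.role, 0) + 1
        assert roles == {"outcome": 1, "putative_risk": 17, "confounder": 16}

    def test_invalid_specs_are_rejected(self):
        with pytest.raises(SchemaError):
            VariableSpec("x", "outcome", "categorical", ("a", "b"), "a")  # not 0/1
        with pytest.raises(SchemaError):
            VariableSpec("x", "putative_risk", "categorical", ("a", "b"), "c")
        with pytest.raises(SchemaError):
            VariableSpec(
                "x", "putative_risk", "continuous", ("a", "b", "c"), "a",
                cutpoints=(Cutpoint(2.0), Cutpoint(1.0)),
            )

    @pytest.mark.parametrize(
        "var,value,expected",
        [
            ("scr", 116, "<=116"),
            ("scr", 116.01, ">116"),
            ("car", 0.278, ">=0.278"),
            ("car", 0.2779, "<0.278"),
            ("glu", 10.0, "<=10"),
            ("glu", 10.01, ">10"),
            ("bmi", 24.0, ">=24"),
            ("bmi", 18.5, "18.5-24"),
            ("bmi", 18.49, "<18.5"),
            ("age", 75, ">=75"),
            ("age", 74.9, "65-74"),
            ("alb", 36, ">=36"),
            ("alb", 35.9, "<36"),
            ("surgery_duration", 120, "<=120"),
            ("surgery_duration", 121, ">120"),
        ],
    )
    def test_interval_boundaries_follow_the_printed_groups(self, specs, var, value, expected):
        assert spec_of(specs, var).interval_label(value) == expected

    @given(st.floats(min_value=0, max_value=500, allow_nan=False))
    @settings(deadline=None, max_examples=100)
    def test_every_value_maps_to_exactly_one_declared_level(self, value):
        spec = spec_of(default_specs(), "bmi")
        assert spec.interval_label(value) in spec.levels


def _write(tmp_path, text, name="cohort.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


SMALL = (
    "scr,alb,sepsis\n"
    "100,30,0\n"
    "150,40,1\n"
    "90,35,0\n"
)


@pytest.fixture
def small_specs():
    full = default_specs()
    return [s for s in full if s.name in ("scr", "alb", "sepsis")]


class TestLoadCohort:
    def test_loads_all_rows_and_columns(self, tmp_path, small_specs):
        raw = load_cohort(_write(tmp_path, SMALL), small_specs)
        assert len(raw) == 3
        assert list(raw.columns) == ["scr", "alb", "sepsis"]

    def test_missing_column_is_a_schema_error_naming_it(self, tmp_path, small_specs):
        path = _write(tmp_path, "scr,sepsis\n100,0\n")
        with pytest.raises(SchemaError, match="alb"):
            load_cohort(path, small_specs)

    def test_empty_cell_is_flagged_not_dropped(self, tmp_path, small_specs):
        path = _write(tmp_path, "scr,alb,sepsis\n100,30,0\n,40,1\n")
        raw = load_cohort(path, small_specs)
        assert len(raw) == 2
        assert int(raw.isna().sum().sum()) == 1

    def test_unparseable_numeric_reports_the_line(self, tmp_path, small_specs):
        path = _write(tmp_path, "scr,alb,sepsis\n100,30,0\noops,40,1\n")
        with pytest.raises(CohortError, match=r"line.*3"):
            load_cohort(path, small_specs)

    def test_tab_delimited_input_is_autodetected(self, tmp_path, small_specs):
        raw = load_cohort(_write(tmp_path, SMALL.replace(",", "\t")), small_specs)
        assert len(raw) == 3


class TestImpute:
    def test_continuous_missing_gets_the_mean(self, small_specs):
        raw = pd.DataFrame({"scr": [1.0, 2.0, np.nan], "alb": [30.0, 40.0, 35.0],
                            "sepsis": ["0", "1", "0"]})
        out = impute_missing(raw, small_specs)
        assert out["scr"].tolist() == [1.0, 2.0, 1.5]

    def test_categorical_missing_gets_the_mode(self, specs):
        raw = pd.DataFrame({"sex": ["male", "male", "female", np.nan]})
        out = impute_missing(raw, [spec_of(specs, "sex")])
        assert out["sex"].tolist()[-1] == "male"

    def test_mode_tie_breaks_to_lexicographically_smallest(self, specs):
        raw = pd.DataFrame({"sex": ["male", "female", np.nan]})
        out = impute_missing(raw, [spec_of(specs, "sex")])
        assert out["sex"].tolist()[-1] == "female"

    def test_no_missing_is_identity(self, small_specs):
        raw = pd.DataFrame({"scr": [1.0, 2.0], "alb": [30.0, 40.0], "sepsis": ["0", "1"]})
        assert impute_missing(raw, small_specs).equals(raw)

    def test_fully_missing_column_is_an_error(self, small_specs):
        raw = pd.DataFrame({"scr": [np.nan, np.nan], "alb": [30.0, 40.0],
                            "sepsis": ["0", "1"]})
        with pytest.raises(CohortError, match="scr"):
            impute_missing(raw, small_specs)


class TestDiscretize:
    def test_maps_values_and_validates(self, small_specs):
        raw = pd.DataFrame({"scr": [100.0, 150.0], "alb": [30.0, 40.0],
                            "sepsis": ["0", "1"]})
        cohort = discretize(raw, small_specs)
        assert cohort.data["scr"].tolist() == ["<=116", ">116"]
        assert cohort.data["alb"].tolist() == ["<36", ">=36"]

    def test_negative_duration_is_a_domain_error(self, specs):
        use = [s for s in specs if s.name in ("surgery_duration", "sepsis")]
        raw = pd.DataFrame({"surgery_duration": [-5.0], "sepsis": ["0"]})
        with pytest.raises(CohortError, match="domain"):
            discretize(raw, use)

    def test_idempotent_on_already_clean_categorical_table(self, small_specs):
        raw = pd.DataFrame({"scr": [100.0, 150.0], "alb": [30.0, 40.0],
                            "sepsis": ["0", "1"]})
        once = discretize(raw, small_specs)
        twice = discretize(impute_missing(once.data, small_specs), small_specs)
        assert twice.data.equals(once.data)

    def test_level_counts_partition_the_cohort(self, small_specs, rng):
        n = 200
        raw = pd.DataFrame({
            "scr": rng.uniform(50, 200, n),
            "alb": rng.uniform(20, 50, n),
            "sepsis": [str(v) for v in rng.integers(0, 2, n)],
        })
        cohort = discretize(raw, small_specs)
        for var in ("scr", "alb"):
            assert cohort.data[var].value_counts().sum() == n

    def test_round_trip_through_csv_is_cell_identical(self, tmp_path, small_specs):
        raw = pd.DataFrame({"scr": [100.0, 150.0, 90.0], "alb": [30.0, 40.0, 36.0],
                            "sepsis": ["0", "1", "0"]})
        cohort = discretize(raw, small_specs)
        path = tmp_path / "out.csv"
        cohort.write(path)
        back = discretize(load_cohort(path, small_specs), small_specs)
        assert back.data.equals(cohort.data)

    def test_comorbidity_count_is_derived_when_absent(self, specs):
        flags = ["diabetes", "coronary_disease", "cerebrovascular_disease",
                 "malignant_tumor", "hepatic_failure", "pneumonia",
                 "acute_kidney_injury"]
        use = [s for s in specs if s.name in flags + ["n_comorbidities", "sepsis"]]
        raw = pd.DataFrame({f: ["no", "yes", "yes"] for f in flags})
        raw["diabetes"] = ["no", "yes", "yes"]
        raw.loc[0, :] = "no"
        raw["sepsis"] = ["0", "1", "0"]
        cohort = discretize(raw, use)
        counts = cohort.data["n_comorbidities"].tolist()
        assert counts[0] == "0" and counts[1] == ">=3" and counts[2] == ">=3"
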