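"""Logistic-regression sensitivity analysis.

Per-exposure adjusted odds ratios controlling for the tree-selected
confounders, with likelihood-ratio screening of first-order confounder
interactions and forward-stepwise exploration of the putative risk factors.

The fitter is iteratively reweighted least squares (Newton scoring) with
step-halving, so the log-likelihood is non-decreasing across iterations;
convergence is declared when the largest absolute coefficient change drops
below 1e-8 (at most 100 iterations). Wald intervals throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .effects import EffectEstimate, Z95
from .errors import CohortError, EstimationError
from .schema import CohortTable


def _safe_exp(x: float) -> float:
    """exp without overflow: a Wald bound past exp(700) is effectively infinite."""
    return math.inf if x > 700 else math.exp(x)


MAX_ITER = 100
COEF_TOL = 1e-8
SEPARATION_COEF = 15.0  # |log-odds| beyond this flags quasi-separation


@dataclass
class LogisticFit:
    """A maximum-likelihood logistic fit."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)
    diagnostic: str | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.coef)

    def odds_ratio(self, term: str) -> tuple[float, float, float]:
        i = self.terms.index(term)
        point = _safe_exp(self.coef[i])
        lo = _safe_exp(self.coef[i] - Z95 * self.se[i])
        hi = _safe_exp(self.coef[i] + Z95 * self.se[i])
        return point, lo, hi


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # stable log(1+exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(y: np.ndarray, X: np.ndarray, terms: list[str]) -> LogisticFit:
    """IRLS fit of a logistic model; ``X`` includes any intercept column.

    The design must have full column rank and the outcome both classes.
    Divergent coefficients (separation) are returned flagged non-converged
    rather than raising.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise CohortError("design matrix and outcome length mismatch")
    if y.sum() == 0 or y.sum() == len(y):
        raise EstimationError("outcome must have both classes")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError("design matrix is rank deficient after level coding")

    beta = np.zeros(X.shape[1])
    eta = X @ beta
    ll = _loglik(y, eta)
    trace = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        step = beta_new - beta
        # step-halving keeps the likelihood monotone
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = _loglik(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta_prev = beta
        beta = beta + factor * step
        eta = X @ beta
        ll = _loglik(y, eta)
        trace.append(ll)
        if np.max(np.abs(beta - beta_prev)) < COEF_TOL:
            converged = True
            break

    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    diagnostic = None
    if np.max(np.abs(beta)) > SEPARATION_COEF:
        converged = False
        diagnostic = "possible separation: coefficient diverging"
    elif not converged:
        diagnostic = f"no convergence in {MAX_ITER} iterations"
    return LogisticFit(list(terms), beta, se, ll, converged, n_iter, trace, diagnostic)


def build_design(cohort: CohortTable, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; terms are variable names or ``a:b``
    interactions, each expanded to non-reference level dummies."""
    cols: list[np.ndarray] = [np.ones(cohort.n_subjects)]
    names: list[str] = ["(intercept)"]

    def dummies(var: str) -> list[tuple[str, np.ndarray]]:
        spec = cohort.specs[var]
        col = cohort.data[var].astype(str).to_numpy()
        return [
            (f"{var}={lv}", (col == lv).astype(float))
            for lv in spec.levels
            if lv != spec.reference
        ]

    for term in terms:
        if ":" in term:
            left, right = term.split(":", 1)
            for ln, lc in dummies(left):
                for rn, rc in dummies(right):
                    cols.append(lc * rc)
                    names.append(f"{ln}:{rn}")
        else:
            for n, c in dummies(term):
                cols.append(c)
                names.append(n)
    return np.column_stack(cols), names


def fit_model(cohort: CohortTable, terms: list[str]) -> LogisticFit:
    X, names = build_design(cohort, terms)
    return fit_logistic(cohort.outcome, X, names)


def screen_interactions(cohort: CohortTable, confounders: list[str],
                        alpha: float = 0.05) -> list[dict]:
    """Likelihood-ratio test of each pairwise confounder interaction added to
    the main-effects model; flagged when p < ``alpha``, reported untestable
    when the augmented design is rank deficient."""
    results = []
    if len(confounders) < 2:
        return results
    base = fit_model(cohort, confounders)
    for a, b in itertools.combinations(confounders, 2):
        try:
            aug = fit_model(cohort, confounders + [f"{a}:{b}"])
        except EstimationError:
            results.append({"pair": (a, b), "p_value": None, "flagged": False,
                            "untestable": True})
            continue
        df = len(aug.coef) - len(base.coef)
        lr = 2.0 * (aug.loglik - base.loglik)
        p = float(stats.chi2.sf(max(lr, 0.0), df))
        results.append({"pair": (a, b), "p_value": p, "flagged": p < alpha,
                        "untestable": False})
    return results


def adjusted_or_lr(cohort: CohortTable, exposure: str, confounders: list[str],
                   interactions: list[tuple[str, str]] | None = None,
                   ) -> list[EffectEstimate]:
    """Exposure odds ratios adjusted for confounder main effects plus any
    flagged confounder interactions; one estimate per non-reference level."""
    if exposure in confounders:
        raise CohortError(f"{exposure}: exposure cannot be in the confounder set")
    terms = [exposure] + list(confounders)
    for a, b in interactions or []:
        terms.append(f"{a}:{b}")
    fit = fit_model(cohort, terms)
    spec = cohort.specs[exposure]
    out = []
    for lv in spec.ordered_display_levels:
        if lv == spec.reference:
            continue
        point, lo, hi = fit.odds_ratio(f"{exposure}={lv}")
        est = EffectEstimate(
            exposure=exposure, exposed_level=lv, point=point,
            ci_low=lo, ci_high=hi, measure="odds-ratio", method="LR",
            model="+".join(confounders) if confounders else "unadjusted",
            flags=[] if fit.converged else ["non-converged"],
        )
        out.append(est)
    return out


@dataclass
class StepwiseTrace:
    """Forward-selection record: terms added in order, with the AIC path."""

    selected: list[str]
    aic_path: list[float]
    details: list[dict] = field(default_factory=list)


def forward_stepwise(cohort: CohortTable, candidates: list[str],
                     confounders: list[str]) -> StepwiseTrace:
    """Forward selection by AIC starting from the confounder-only model.

    At each step every remaining candidate is tried; the one lowering AIC the
    most is added; selection stops when no addition lowers AIC.
    """
    current: list[str] = []
    base = fit_model(cohort, confounders) if confounders else fit_model(cohort, [])
    aic = base.aic
    trace = StepwiseTrace(selected=[], aic_path=[aic])
    remaining = list(candidates)
    while remaining:
        best_term, best_aic = None, aic
        for term in remaining:
            try:
                fit = fit_model(cohort, confounders + current + [term])
            except EstimationError:
                continue
            if fit.aic < best_aic - 1e-9:
                best_term, best_aic = term, fit.aic
        if best_term is None:
            break
        current.append(best_term)
        remaining.remove(best_term)
        aic = best_aic
        trace.selected.append(best_term)
        trace.aic_path.append(aic)
        trace.details.append({"added": best_term, "aic": aic})
    return trace
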