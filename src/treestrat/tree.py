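"""Recursive-partitioning stratifier over confounder indicators.

Stage one of the analysis: a binary regression tree is grown on the 0/1
outcome using *confounders only* — the split chosen at each node is the binary
indicator that maximizes the between-group sum of squares (equivalently,
minimizes the within-group SSE of the 0/1 outcome). The full tree is then
pruned by weakest-link cost-complexity pruning, with the complexity parameter
chosen by stratified k-fold cross-validation, and candidate trees built from
nested confounder sets are compared by AIC. Leaves of the selected tree define
the strata used downstream for Mantel-Haenszel pooling.

No surrogate splits and no in-tree missing-value handling: imputation happens
upstream in the schema module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .effects import TwoByTwo, EffectEstimate, crude_rr
from .errors import CohortError, EstimationError
from .schema import CohortTable, CONFOUNDER

DEFAULT_MIN_SPLIT = 20  # smallest node still eligible for splitting
DEFAULT_MIN_LEAF = 7  # round(min_split / 3)
DEFAULT_SEED = 20150901
_GAIN_TOL = 1e-12


class Node:
    """One tree node; a leaf when ``feature`` is None."""

    __slots__ = ("feature", "left", "right", "n", "events", "node_id")

    def __init__(self, n: int, events: int):
        self.feature: int | None = None
        self.left: "Node | None" = None
        self.right: "Node | None" = None
        self.n = int(n)
        self.events = int(events)
        self.node_id: int = -1

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def incidence(self) -> float:
        return self.events / self.n

    @property
    def sse(self) -> float:
        """Within-node sum of squares of the 0/1 outcome."""
        return self.events - self.events**2 / self.n

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def internal_nodes(self) -> list["Node"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()

    def subtree_sse(self) -> float:
        return sum(leaf.sse for leaf in self.leaves())

    def collapse(self) -> None:
        self.feature = None
        self.left = None
        self.right = None

    def clone(self) -> "Node":
        new = Node(self.n, self.events)
        new.feature = self.feature
        new.node_id = self.node_id
        if not self.is_leaf:
            new.left = self.left.clone()
            new.right = self.right.clone()
        return new


@dataclass
class StratificationTree:
    """A fitted (possibly pruned) partition of the cohort by confounders."""

    root: Node
    feature_names: list[str]
    confounders: list[str] = field(default_factory=list)
    model_id: str | None = None
    alpha: float = 0.0
    cv_metric: str | None = None
    cv_results: list[tuple[float, float]] = field(default_factory=list)

    def clone(self) -> "StratificationTree":
        return StratificationTree(
            root=self.root.clone(),
            feature_names=list(self.feature_names),
            confounders=list(self.confounders),
            model_id=self.model_id,
            alpha=self.alpha,
            cv_metric=self.cv_metric,
            cv_results=list(self.cv_results),
        )

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    @property
    def aic(self) -> float:
        return tree_aic(self)

    def assign_ids(self) -> None:
        counter = 0

        def visit(node: Node) -> None:
            nonlocal counter
            node.node_id = counter
            counter += 1
            if not node.is_leaf:
                visit(node.left)
                visit(node.right)

        visit(self.root)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Leaf incidence per row of the indicator matrix."""
        leaf = self.apply(X)
        incid = {n.node_id: n.incidence for n in self.root.leaves()}
        return np.array([incid[i] for i in leaf])

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node id per row."""
        X = np.asarray(X, dtype=bool)
        out = np.empty(len(X), dtype=int)

        def route(node: Node, idx: np.ndarray) -> None:
            if node.is_leaf:
                out[idx] = node.node_id
                return
            mask = X[idx, node.feature]
            route(node.right, idx[mask])
            route(node.left, idx[~mask])

        route(self.root, np.arange(len(X)))
        return out

    # ---- serialization ----
    def to_dict(self) -> dict:
        def node_dict(node: Node) -> dict:
            d = {"n": node.n, "events": node.events, "incidence": node.incidence}
            if not node.is_leaf:
                d["split"] = self.feature_names[node.feature]
                d["absent"] = node_dict(node.left)
                d["present"] = node_dict(node.right)
            return d

        return {
            "model_id": self.model_id,
            "confounders": self.confounders,
            "feature_names": self.feature_names,
            "alpha": self.alpha,
            "n_leaves": self.n_leaves,
            "aic": self.aic,
            "root": node_dict(self.root),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "StratificationTree":
        names = list(doc["feature_names"])

        def build(d: dict) -> Node:
            node = Node(d["n"], d["events"])
            if "split" in d:
                node.feature = names.index(d["split"])
                node.left = build(d["absent"])
                node.right = build(d["present"])
            return node

        tree = cls(
            root=build(doc["root"]),
            feature_names=names,
            confounders=list(doc.get("confounders", [])),
            model_id=doc.get("model_id"),
            alpha=float(doc.get("alpha", 0.0)),
        )
        tree.assign_ids()
        return tree

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def render_text(self) -> str:
        lines: list[str] = []

        def visit(node: Node, prefix: str, tag: str) -> None:
            desc = (
                f"leaf"
                if node.is_leaf
                else f"split on {self.feature_names[node.feature]}"
            )
            lines.append(
                f"{prefix}{tag}{desc}: n={node.n}, events={node.events}, "
                f"incidence={node.incidence:.4f}"
            )
            if not node.is_leaf:
                visit(node.left, prefix + "  ", "[absent] ")
                visit(node.right, prefix + "  ", "[present] ")

        visit(self.root, "", "")
        return "\n".join(lines)

    def to_dot(self) -> str:
        self.assign_ids()
        lines = ["digraph stratification_tree {", "  node [shape=box];"]

        def visit(node: Node) -> None:
            label = f"n={node.n}\\nevents={node.events}\\nincidence={node.incidence:.3f}"
            if not node.is_leaf:
                label = f"{self.feature_names[node.feature]}\\n{label}"
            lines.append(f'  n{node.node_id} [label="{label}"];')
            if not node.is_leaf:
                lines.append(f'  n{node.node_id} -> n{node.left.node_id} [label="absent"];')
                lines.append(f'  n{node.node_id} -> n{node.right.node_id} [label="present"];')
                visit(node.left)
                visit(node.right)

        visit(self.root)
        lines.append("}")
        return "\n".join(lines)


@dataclass
class CandidateModel:
    """One nested confounder set with its fitted tree and AIC."""

    model_id: str
    confounders: list[str]
    tree: StratificationTree
    aic: float


def encode_confounders(cohort: CohortTable, confounders: list[str] | None = None
                       ) -> tuple[np.ndarray, list[str]]:
    """One-vs-rest binary indicators for the non-reference levels.

    A binary confounder becomes a single indicator; a K-level one becomes K-1
    indicators named ``var=level``.
    """
    if confounders is None:
        confounders = [s.name for s in cohort.specs.values() if s.role == CONFOUNDER]
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in confounders:
        spec = cohort.specs[name]
        col = cohort.data[name].astype(str).to_numpy()
        unseen = set(col) - set(spec.levels)
        if unseen:
            raise CohortError(f"{name}: level(s) unseen by encoding: {sorted(unseen)}")
        for level in spec.levels:
            if level == spec.reference:
                continue
            cols.append(col == level)
            names.append(f"{name}={level}")
    X = np.column_stack(cols) if cols else np.empty((cohort.n_subjects, 0), dtype=bool)
    return X, names


def grow_tree(X: np.ndarray, y: np.ndarray, feature_names: list[str],
              min_split: int = DEFAULT_MIN_SPLIT, min_leaf: int = DEFAULT_MIN_LEAF,
              ) -> StratificationTree:
    """Greedy top-down growth maximizing the between-group sum of squares.

    Splitting stops when a node is smaller than ``min_split``, when no split
    reduces the within-group SSE, or when a child would fall below
    ``min_leaf``. A constant outcome yields a single-leaf tree.
    """
    X = np.asarray(X, dtype=bool)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise CohortError("indicator matrix and outcome length mismatch")

    def build(idx: np.ndarray) -> Node:
        n = len(idx)
        events = int(y[idx].sum())
        node = Node(n, events)
        if n < min_split or events == 0 or events == n or X.shape[1] == 0:
            return node
        j, mask = _best_split(X, y, idx, min_leaf)
        if j is None:
            return node
        node.feature = j
        node.right = build(idx[mask])
        node.left = build(idx[~mask])
        return node

    tree = StratificationTree(root=build(np.arange(len(y))),
                              feature_names=list(feature_names))
    tree.assign_ids()
    return tree


def _best_split(X: np.ndarray, y: np.ndarray, idx: np.ndarray, min_leaf: int
                ) -> tuple[int | None, np.ndarray | None]:
    Xs = X[idx]
    ys = y[idx]
    n = len(idx)
    e = ys.sum()
    n1 = Xs.sum(axis=0).astype(float)
    s1 = ys @ Xs
    n0 = n - n1
    s0 = e - s1
    valid = (n1 >= min_leaf) & (n0 >= min_leaf)
    with np.errstate(divide="ignore", invalid="ignore"):
        child_sse = (s1 - s1**2 / n1) + (s0 - s0**2 / n0)
    parent_sse = e - e**2 / n
    gain = np.where(valid, parent_sse - child_sse, -np.inf)
    j = int(np.argmax(gain))  # ties: lowest feature index, deterministic
    if not np.isfinite(gain[j]) or gain[j] <= _GAIN_TOL:
        return None, None
    return j, Xs[:, j]


def cost_complexity_path(tree: StratificationTree) -> list[tuple[float, StratificationTree]]:
    """Weakest-link pruning sequence: non-decreasing alphas, nested subtrees,
    ending at the root-only tree."""
    work = tree.clone()
    path: list[tuple[float, StratificationTree]] = [(0.0, work.clone())]
    alpha_prev = 0.0
    while not work.root.is_leaf:
        stats: dict[int, tuple[float, int]] = {}  # id(node) -> (subtree SSE, leaves)

        def post(node: Node) -> tuple[float, int]:
            if node.is_leaf:
                return node.sse, 1
            sl, ll = post(node.left)
            sr, lr = post(node.right)
            stats[id(node)] = (sl + sr, ll + lr)
            return sl + sr, ll + lr

        post(work.root)
        internals = work.root.internal_nodes()
        gs = [
            (node.sse - stats[id(node)][0]) / (stats[id(node)][1] - 1)
            for node in internals
        ]
        gmin = min(gs)
        alpha = max(gmin, alpha_prev)
        # collapse every weakest link; internal_nodes() is preorder, so parents
        # collapse before their descendants are visited
        for node, g in zip(internals, gs):
            if node.feature is not None and g <= gmin + _GAIN_TOL:
                node.collapse()
        snapshot = work.clone()
        snapshot.alpha = alpha
        if path and math.isclose(path[-1][0], alpha, abs_tol=_GAIN_TOL):
            path[-1] = (alpha, snapshot)
        else:
            path.append((alpha, snapshot))
        alpha_prev = alpha
    for _, t in path:
        t.assign_ids()
    return path


def _subtree_at(path: list[tuple[float, StratificationTree]], alpha: float) -> StratificationTree:
    """The most-pruned subtree whose path alpha does not exceed ``alpha``."""
    chosen = path[0][1]
    for a, t in path:
        if a <= alpha + _GAIN_TOL:
            chosen = t
        else:
            break
    return chosen


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Fold label per subject, preserving outcome prevalence per fold."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


def _score(y: np.ndarray, p: np.ndarray, metric: str) -> float:
    if metric == "mse":
        return -float(np.mean((y - p) ** 2))
    if metric == "deviance":
        eps = 1e-10
        pc = np.clip(p, eps, 1 - eps)
        return float(np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
    if metric == "accuracy":
        return float(np.mean((p > 0.5) == y))
    raise CohortError(f"unknown CV metric {metric!r}")


def cv_prune(X: np.ndarray, y: np.ndarray, feature_names: list[str],
             folds: int = 10, seed: int = DEFAULT_SEED, metric: str = "mse",
             min_split: int = DEFAULT_MIN_SPLIT, min_leaf: int = DEFAULT_MIN_LEAF,
             ) -> StratificationTree:
    """Grow, then select the pruning level by stratified k-fold cross-validation.

    The candidate alphas are interval representatives of the full-data pruning
    path (geometric midpoints); each is scored on held-out folds and the alpha
    with the highest mean test score wins, ties going to the largest alpha
    (simplest tree). The returned tree is the full-data tree pruned at the
    winning alpha.
    """
    X = np.asarray(X, dtype=bool)
    y = np.asarray(y, dtype=float)
    if folds < 2:
        raise CohortError("folds must be >= 2")
    if y.sum() == 0 or y.sum() == len(y):
        raise EstimationError("outcome must have both classes for cross-validation")

    full = grow_tree(X, y, feature_names, min_split, min_leaf)
    path = cost_complexity_path(full)
    alphas = [a for a, _ in path]
    candidates: list[float] = []
    for k in range(len(alphas) - 1):
        lo, hi = alphas[k], alphas[k + 1]
        candidates.append(math.sqrt(lo * hi) if lo > 0 else hi / 2)
    candidates.append(alphas[-1])

    fold_of = _stratified_folds(y.astype(int), folds, seed)
    for f in range(folds):
        test = fold_of == f
        if y[test].sum() == 0 or y[~test].sum() == 0:
            raise EstimationError(
                "a cross-validation fold lacks both outcome classes; use fewer folds"
            )

    scores = np.zeros((folds, len(candidates)))
    for f in range(folds):
        train = fold_of != f
        sub = grow_tree(X[train], y[train], feature_names, min_split, min_leaf)
        sub_path = cost_complexity_path(sub)
        for k, alpha in enumerate(candidates):
            pruned = _subtree_at(sub_path, alpha)
            p = pruned.predict(X[~train])
            scores[f, k] = _score(y[~train], p, metric)

    mean_scores = scores.mean(axis=0)
    best = mean_scores.max()
    best_alpha = max(
        alpha for alpha, s in zip(candidates, mean_scores) if s >= best - _GAIN_TOL
    )
    selected = _subtree_at(path, best_alpha).clone()
    selected.feature_names = list(feature_names)
    selected.alpha = best_alpha
    selected.cv_metric = metric
    selected.cv_results = list(zip(candidates, mean_scores))
    selected.assign_ids()
    return selected


def tree_aic(tree: StratificationTree) -> float:
    """AIC = binomial deviance over leaves + 2 x (number of leaves).

    Pure leaves (incidence 0 or 1) are clamped to 1/(2n) from the boundary so
    the likelihood stays finite.
    """
    dev = 0.0
    leaves = tree.root.leaves()
    for leaf in leaves:
        p = leaf.incidence
        eps = 1.0 / (2 * leaf.n)
        p = min(max(p, eps), 1 - eps)
        e, n = leaf.events, leaf.n
        dev += -2.0 * (e * math.log(p) + (n - e) * math.log(1 - p))
    return dev + 2.0 * len(leaves)


def select_model(candidates: list[CandidateModel]) -> CandidateModel:
    """Lowest AIC wins; ties go to the smaller confounder set."""
    if not candidates:
        raise EstimationError("no candidate models to select from")
    return min(candidates, key=lambda c: (c.aic, len(c.confounders)))


def assign_strata(tree: StratificationTree, cohort: CohortTable) -> np.ndarray:
    """Leaf id per subject; leaves partition the cohort."""
    X, names = encode_confounders(cohort, tree.confounders or None)
    if names != tree.feature_names:
        raise CohortError("cohort encoding does not match the fitted tree's features")
    return tree.apply(X)


def pairwise_node_effects(tree: StratificationTree) -> list[EffectEstimate]:
    """Crude risk ratio at each internal node: indicator-present child vs its
    sibling, with a Katz log CI (0.5 continuity increment when a child has
    zero events)."""
    tree.assign_ids()
    out = []
    for node in tree.root.internal_nodes():
        right, left = node.right, node.left
        if right.n == 0 or left.n == 0:
            raise EstimationError("internal node with an empty child")
        t = TwoByTwo(
            a=right.events, b=right.n - right.events,
            c=left.events, d=left.n - left.events,
        )
        est = crude_rr(
            t,
            exposure=tree.feature_names[node.feature],
            exposed_level="present",
        )
        est.model = f"node{node.node_id}"
        out.append(est)
    return out


def fit_candidate_models(
    cohort: CohortTable,
    model_defs: dict[str, list[str]],
    folds: int = 10,
    seed: int = DEFAULT_SEED,
    metric: str = "mse",
    min_split: int = DEFAULT_MIN_SPLIT,
    min_leaf: int = DEFAULT_MIN_LEAF,
) -> list[CandidateModel]:
    """Fit one cross-validated tree per nested confounder set."""
    cohort.require_estimable()
    out = []
    for model_id, confounders in model_defs.items():
        X, names = encode_confounders(cohort, confounders)
        tree = cv_prune(X, cohort.outcome, names, folds=folds, seed=seed,
                        metric=metric, min_split=min_split, min_leaf=min_leaf)
        tree.confounders = list(confounders)
        tree.model_id = model_id
        out.append(CandidateModel(model_id, list(confounders), tree, tree.aic))
    return out


def default_model_defs(cohort: CohortTable) -> dict[str, list[str]]:
    """Nested confounder sets: demographics; + comorbidities; + management."""
    groups = {"model1": ["demographic"],
              "model2": ["demographic", "comorbidity"],
              "model3": ["demographic", "comorbidity", "management"]}
    defs = {}
    for model_id, wanted in groups.items():
        defs[model_id] = [
            s.name for s in cohort.specs.values()
            if s.role == CONFOUNDER and s.group in wanted
        ]
    return defs
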