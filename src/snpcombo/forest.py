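"""Random-forest OOB scoring and backward-elimination variable selection.

The selection procedure is the classic backward elimination over random
forests: fit one large forest, rank variables once by unscaled permutation
importance (mean decrease in OOB accuracy), then repeatedly drop the least
important fraction of variables and refit a smaller forest, tracking the
out-of-bag error of every step. The chosen SNP combination is the smallest
variable set whose OOB error is within ``se_rule_c`` standard errors of
the minimum over the elimination history (``se_rule_c = 0`` gives the
plain minimum-error set with fewest variables).

Individual trees come from scikit-learn (Gini splitting, ``mtry``
candidate features per split); bootstrap bags, OOB votes, OOB error and
OOB permutation importance are computed here from per-tree bag
assignments, which is the contract the elimination procedure depends on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from ._util import MISSING, derive_seed
from .io import GenotypeMatrix
from .subsets import SNPSubset

__all__ = [
    "RFParams",
    "ForestFit",
    "SelectionResult",
    "RandomForestSelector",
    "fit_forest",
    "backward_elimination",
    "evaluate_subsets",
    "drop_schedule",
    "impute_mode",
]


@dataclass
class RFParams:
    """Forest and elimination parameters.

    ``mtry = max(1, round(mtry_factor * sqrt(p)))`` candidate variables
    per split. ``ntree`` trees in the initial (importance-ranking)
    forest, ``ntree_iterat`` in every refit during elimination;
    ``vars_drop_frac`` of the surviving variables are dropped per step.
    ``se_rule_c`` is the standard-error constant of the selection rule.
    """

    mtry_factor: float = 1.0
    ntree: int = 5_000
    ntree_iterat: int = 2_000
    vars_drop_frac: float = 0.2
    se_rule_c: float = 1.0
    importance: str = "permutation"  # or "gini"
    recompute_importance: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1 or self.ntree_iterat < 1:
            raise ValueError("tree counts must be >= 1")
        if not 0 < self.vars_drop_frac < 1:
            raise ValueError("vars_drop_frac must be in (0, 1)")
        if self.mtry_factor <= 0:
            raise ValueError("mtry_factor must be positive")
        if self.importance not in ("permutation", "gini"):
            raise ValueError("importance must be 'permutation' or 'gini'")

    def mtry(self, p: int) -> int:
        return max(1, int(round(self.mtry_factor * math.sqrt(p))))


@dataclass
class ForestFit:
    """A fitted forest's OOB summary.

    ``oob_error`` is the misclassification fraction among samples with at
    least one OOB vote; ``importance`` is the unscaled mean decrease in
    OOB accuracy under within-OOB permutation (or Gini importance when
    configured); ``n_oob_uncovered`` counts samples that were in-bag for
    every tree.
    """

    oob_error: float
    oob_se: float
    importance: np.ndarray | None
    n_oob_uncovered: int
    n_samples: int
    n_vars: int
    params: RFParams


@dataclass
class SelectionResult:
    """Backward-elimination history and the selected SNP combination."""

    history: pd.DataFrame  # columns: n_vars, oob_error, oob_se
    selected: list[str]
    selected_error: float
    se_rule_c: float
    var_names: list[str]
    initial_importance: np.ndarray | None = None
    #: per-history-entry variable sets (same order as ``history`` rows)
    entry_vars: list[list[str]] | None = None

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def summary(self) -> str:
        lines = [
            "Backward-elimination variable selection",
            "=" * 47,
            f"{'n_vars':>8} {'OOB error':>12} {'OOB SE':>10}",
        ]
        for row in self.history.itertuples(index=False):
            lines.append(
                f"{int(row.n_vars):>8} {row.oob_error:>12.6f} "
                f"{row.oob_se:>10.6f}"
            )
        lines += [
            "-" * 47,
            f"selected combination: {self.n_selected} variables "
            f"(OOB error {self.selected_error:.6f}, "
            f"SE rule c = {self.se_rule_c:g})",
        ]
        return "\n".join(lines)


def impute_mode(X: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-SNP most frequent genotype."""
    X = np.asarray(X)
    out = X.astype(np.float32, copy=True)
    for j in range(X.shape[1]):
        col = X[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if len(obs) == 0:
            out[:, j] = 0
            continue
        vals, counts = np.unique(obs, return_counts=True)
        out[miss, j] = vals[np.argmax(counts)]
    return out


def _tree_classes(tree, leaf_values: np.ndarray) -> np.ndarray:
    if leaf_values.ndim == 3:
        leaf_values = leaf_values[:, 0, :]
    cls_idx = leaf_values.argmax(axis=1)
    return tree.classes_.take(cls_idx).astype(np.int8)


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    params: RFParams | None = None,
    *,
    seed: int | None = None,
    compute_importance: bool = True,
    ntree: int | None = None,
) -> ForestFit:
    """Fit a bootstrap forest and return its OOB error and importance.

    ``X`` must be free of missing values (see :func:`impute_mode`); both
    classes must be present in ``y``. Deterministic given the seed.
    """
    params = params or RFParams()
    X = np.ascontiguousarray(X, dtype=np.float32)
    y = np.asarray(y).astype(np.int8).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    ntree = ntree if ntree is not None else params.ntree
    mtry = params.mtry(p)
    rng = np.random.default_rng(params.seed if seed is None else seed)

    votes = np.zeros((n, 2), dtype=np.int32)
    imp_sum = np.zeros(p)
    want_perm = compute_importance and params.importance == "permutation"
    want_gini = compute_importance and params.importance == "gini"

    for _ in range(ntree):
        idx = rng.integers(0, n, size=n)
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X[idx], y[idx], check_input=False)
        tt = tree.tree_

        oob_idx = np.flatnonzero(oob)
        if len(oob_idx) == 0:
            if want_gini:
                imp_sum += tree.feature_importances_
            continue
        Xo = np.ascontiguousarray(X[oob_idx])
        pred = _tree_classes(tree, tt.predict(Xo))
        votes[oob_idx, pred] += 1

        if want_gini:
            imp_sum += tree.feature_importances_
        elif want_perm:
            yo = y[oob_idx]
            base_acc = float((pred == yo).mean())
            used = np.unique(tt.feature[tt.feature >= 0])
            perm = rng.permutation(len(oob_idx))
            for f in used:
                saved = Xo[:, f].copy()
                Xo[:, f] = saved[perm]
                acc = float(
                    (_tree_classes(tree, tt.predict(Xo)) == yo).mean()
                )
                Xo[:, f] = saved
                imp_sum[f] += base_acc - acc

    covered = votes.sum(axis=1) > 0
    n_cov = int(covered.sum())
    if n_cov == 0:
        raise RuntimeError("no sample received an OOB vote; increase ntree")
    oob_pred = votes.argmax(axis=1)
    err = float((oob_pred[covered] != y[covered]).mean())
    se = math.sqrt(err * (1.0 - err) / n_cov)
    return ForestFit(
        oob_error=err,
        oob_se=se,
        importance=imp_sum / ntree if compute_importance else None,
        n_oob_uncovered=n - n_cov,
        n_samples=n,
        n_vars=p,
        params=params,
    )


def drop_schedule(p: int, vars_drop_frac: float) -> list[int]:
    """Variable counts visited by the elimination, starting at p.

    Each step keeps ``floor(current * (1 - frac))`` variables (dropping at
    least one) and stops once 2 variables are reached.
    """
    sizes = [p]
    cur = p
    while cur > 2:
        nxt = int(math.floor(cur * (1.0 - vars_drop_frac)))
        nxt = min(cur - 1, max(2, nxt))
        sizes.append(nxt)
        cur = nxt
    return sizes


class RandomForestSelector:
    """Backward-elimination variable selection over random forests.

    A model-like object: construct from a variables matrix and binary
    labels, call :meth:`fit`, and receive a :class:`SelectionResult`
    carrying the elimination history, the selected variable set and its
    OOB error.

    Parameters
    ----------
    X
        ``(n_samples, n_vars)`` dosage matrix; missing sentinels are
        mode-imputed per variable.
    y
        Binary labels (0 = control, 1 = case).
    params
        :class:`RFParams`; ``params.seed`` drives all randomness unless
        ``seed`` overrides it.
    var_names
        Optional variable (SNP) identifiers; defaults to ``V0..``.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        params: RFParams | None = None,
        var_names: list[str] | None = None,
    ) -> None:
        self.params = params or RFParams()
        self.X = impute_mode(np.asarray(X))
        self.y = np.asarray(y).astype(np.int8).ravel()
        p = self.X.shape[1]
        self.var_names = (
            list(var_names) if var_names is not None
            else [f"V{i}" for i in range(p)]
        )
        if len(self.var_names) != p:
            raise ValueError("var_names length mismatch")

    @classmethod
    def from_genotypes(
        cls, g: GenotypeMatrix, y: np.ndarray, params: RFParams | None = None
    ) -> "RandomForestSelector":
        return cls(g.dosages, y, params,
                   var_names=[str(s) for s in g.snp_map["snp"]])

    def fit(self, seed: int | None = None) -> SelectionResult:
        params = self.params
        seed = params.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        p = self.X.shape[1]
        names = np.asarray(self.var_names)

        first = fit_forest(
            self.X, self.y, params,
            seed=int(rng.integers(2**31 - 1)),
            compute_importance=True,
        )
        ranking = np.argsort(-first.importance, kind="stable")
        history = [(p, first.oob_error, first.oob_se)]
        entries = [names[ranking]]

        current = ranking
        for size in drop_schedule(p, params.vars_drop_frac)[1:]:
            if params.recompute_importance and len(current) < p:
                refit = fit_forest(
                    self.X[:, current], self.y, params,
                    seed=int(rng.integers(2**31 - 1)),
                    compute_importance=True, ntree=params.ntree_iterat,
                )
                current = current[np.argsort(-refit.importance,
                                             kind="stable")]
            current = current[:size]
            fit = fit_forest(
                self.X[:, current], self.y, params,
                seed=int(rng.integers(2**31 - 1)),
                compute_importance=False, ntree=params.ntree_iterat,
            )
            history.append((size, fit.oob_error, fit.oob_se))
            entries.append(names[current])

        hist = pd.DataFrame(history, columns=["n_vars", "oob_error", "oob_se"])
        sel_idx = _select_entry(hist, params.se_rule_c)
        return SelectionResult(
            history=hist,
            selected=list(entries[sel_idx]),
            selected_error=float(hist["oob_error"].iloc[sel_idx]),
            se_rule_c=params.se_rule_c,
            var_names=self.var_names,
            initial_importance=first.importance,
            entry_vars=[list(e) for e in entries],
        )


def _select_entry(hist: pd.DataFrame, se_rule_c: float) -> int:
    err = hist["oob_error"].to_numpy()
    se = hist["oob_se"].to_numpy()
    nv = hist["n_vars"].to_numpy()
    best = np.flatnonzero(err == err.min())
    best_at = best[np.argmin(nv[best])]
    threshold = err.min() + se_rule_c * se[best_at]
    ok = np.flatnonzero(err <= threshold)
    return int(ok[np.argmin(nv[ok])])


def backward_elimination(
    X: np.ndarray,
    y: np.ndarray,
    params: RFParams | None = None,
    var_names: list[str] | None = None,
    seed: int | None = None,
) -> SelectionResult:
    """Functional wrapper around :class:`RandomForestSelector`."""
    return RandomForestSelector(X, y, params, var_names).fit(seed=seed)


def evaluate_subsets(
    subsets: list[SNPSubset],
    g: GenotypeMatrix,
    y: np.ndarray,
    params: RFParams | None = None,
) -> pd.DataFrame:
    """Score every candidate SNP subset with and without selection.

    Per subset, fits a full forest (error without selection) and runs
    backward elimination (error with selection); per-subset seeds are
    derived deterministically from ``params.seed`` and the subset label.
    Empty subsets yield flagged rows with NaN errors. Returns a grid with
    columns ``label, criterion, parameter, n_snps, error_full,
    n_selected, error_selected, empty``.
    """
    if not subsets:
        raise ValueError("no subsets to evaluate")
    params = params or RFParams()
    rows = []
    for sub in subsets:
        if sub.empty:
            rows.append((sub.label, sub.criterion, sub.parameter, 0,
                         np.nan, 0, np.nan, True))
            continue
        sub_g = g.subset_snps(sub.snps)
        X = impute_mode(sub_g.dosages)
        sub_seed = derive_seed(params.seed, sub.label)
        full = fit_forest(X, y, params, seed=sub_seed,
                          compute_importance=False)
        sel = backward_elimination(
            X, y, params, var_names=sub.snps, seed=sub_seed + 1
        )
        rows.append(
            (sub.label, sub.criterion, sub.parameter, sub.size,
             full.oob_error, sel.n_selected, sel.selected_error, False)
        )
    return pd.DataFrame(
        rows,
        columns=["label", "criterion", "parameter", "n_snps", "error_full",
                 "n_selected", "error_selected", "empty"],
    )


def optimal_subset(grid: pd.DataFrame) -> pd.Series:
    """Row of the optimal subset: minimum error with selection; ties go
    to fewer selected SNPs, then the smaller subset."""
    g = grid.loc[~grid["empty"]].copy()
    if g.empty:
        raise ValueError("all subsets empty")
    g = g.sort_values(["error_selected", "n_selected", "n_snps"],
                      kind="mergesort")
    return g.iloc[0]
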