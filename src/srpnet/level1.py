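"""First-level feature screening: two filter and two embedded methods.

Each feature is scored four ways — chi-square test against the risk
label (discrete features), Pearson correlation with the ordinal-coded
label, Lasso coefficient magnitude, and elastic-net coefficient
magnitude — and each method keeps its significant set.  The union of
the four kept sets, in original column order, is the candidate set
handed to the exhaustive second-level subset search.

The Lasso / elastic-net objectives are the squared-error forms

    (1/2n) sum_i (y_i - t0 - sum_j x_ij t_j)^2 + penalty,

fit on labels coded as ordinal integers rescaled to [0, 1]; a feature is
kept when its coefficient is non-zero.  Penalty strength defaults to
k-fold cross-validated choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV, Lasso, LassoCV

from .data import FeatureTable, LabelVector

METHODS = ("chi2", "pearson", "lasso", "enet")


@dataclass
class MethodScore:
    """Per-feature statistics and kept flags for one selection method."""

    method: str
    feature_names: list[str]
    statistic: np.ndarray  # chi2 value, |rho| signed rho, or coefficient
    kept: np.ndarray  # bool per feature
    p_values: np.ndarray | None = None  # chi2 only

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.kept = np.asarray(self.kept, dtype=bool)
        if self.p_values is not None:
            self.p_values = np.asarray(self.p_values, dtype=float)

    @property
    def kept_names(self) -> list[str]:
        return [n for n, k in zip(self.feature_names, self.kept) if k]

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "feature_names": self.feature_names,
            "statistic": self.statistic.tolist(),
            "kept": self.kept.tolist(),
        }
        if self.p_values is not None:
            out["p_values"] = self.p_values.tolist()
        return out


@dataclass
class SelectionReport:
    """The four method scores plus their union, the candidate feature set."""

    scores: dict[str, MethodScore]
    candidate_set: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scores": {m: s.to_dict() for m, s in self.scores.items()},
            "candidate_set": self.candidate_set,
        }


def _label_codes_01(labels: LabelVector) -> np.ndarray:
    """Ordinal label codes rescaled to [0, 1] for the regression selectors."""
    y = labels.codes.astype(float)
    lo, hi = y.min(), y.max()
    if hi == lo:
        raise ValueError("labels are constant; nothing to regress on")
    return (y - lo) / (hi - lo)


def chi_square_scores(
    table: FeatureTable, labels: LabelVector, alpha: float = 0.05
) -> MethodScore:
    """Chi-square test of independence between each discrete feature and the label.

    The statistic is sum((A - E)^2 / E) over the feature-by-label
    contingency table with df = (r-1)(c-1); no continuity correction is
    applied.  Empty rows/columns of the contingency table are dropped
    before computing expectations.  Continuous columns are skipped with a
    warning (statistic 0, p-value 1).  A feature is kept when p <= alpha.
    """
    n = table.n_subjects
    stat = np.zeros(table.d_features)
    pval = np.ones(table.d_features)
    kept = np.zeros(table.d_features, dtype=bool)
    skipped = []
    for j, (name, kind) in enumerate(zip(table.feature_names, table.feature_kinds)):
        if kind == "continuous":
            skipped.append(name)
            continue
        x = table.values[:, j]
        rows, ri = np.unique(x, return_inverse=True)
        cols, ci = np.unique(labels.codes, return_inverse=True)
        obs = np.zeros((rows.size, cols.size))
        np.add.at(obs, (ri, ci), 1.0)
        obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
        if obs.shape[0] < 2 or obs.shape[1] < 2:
            # degenerate: feature (or label slice) constant -> no association
            continue
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        chi2 = float(((obs - expected) ** 2 / expected).sum())
        df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
        stat[j] = chi2
        pval[j] = float(stats.chi2.sf(chi2, df))
        kept[j] = pval[j] <= alpha
    if skipped:
        warnings.warn(
            f"chi-square: skipped continuous column(s) {skipped}", UserWarning, stacklevel=2
        )
    if n == 0:
        raise ValueError("empty table")
    return MethodScore(
        method="chi2",
        feature_names=list(table.feature_names),
        statistic=stat,
        kept=kept,
        p_values=pval,
    )


def pearson_scores(
    table: FeatureTable, labels: LabelVector, tau: float = 0.1
) -> MethodScore:
    """Pearson correlation of each feature with the ordinal label codes.

    Kept when |rho| >= tau.  Constant columns have undefined correlation;
    they score 0 and are dropped with a warning.
    """
    y = labels.codes.astype(float)
    ys = y - y.mean()
    ynorm = np.sqrt((ys**2).sum())
    if ynorm == 0:
        raise ValueError("labels are constant; correlation undefined")
    rho = np.zeros(table.d_features)
    constant = []
    for j in range(table.d_features):
        x = table.values[:, j]
        xs = x - x.mean()
        xnorm = np.sqrt((xs**2).sum())
        if xnorm == 0:
            constant.append(table.feature_names[j])
            continue
        rho[j] = float((xs @ ys) / (xnorm * ynorm))
    if constant:
        warnings.warn(
            f"pearson: constant column(s) {constant} scored 0", UserWarning, stacklevel=2
        )
    kept = np.abs(rho) >= tau
    return MethodScore(
        method="pearson", feature_names=list(table.feature_names), statistic=rho, kept=kept
    )


def _check_converged(model, max_iter: int) -> None:
    n_iter = getattr(model, "n_iter_", None)
    if n_iter is not None and np.max(np.atleast_1d(n_iter)) >= max_iter:
        raise RuntimeError(
            f"coordinate descent did not converge within {max_iter} iterations"
        )


def lasso_select(
    table: FeatureTable,
    labels: LabelVector,
    lam: float | None = None,
    *,
    cv: int = 5,
    max_iter: int = 50_000,
    seed: int = 0,
) -> MethodScore:
    """L1-penalized squared-error selection; kept iff the coefficient is non-zero.

    ``lam`` is the penalty strength; when ``None`` it is chosen by
    ``cv``-fold cross-validated squared error.
    """
    if not table.normalized:
        raise ValueError("lasso_select expects a normalized table")
    X = table.values
    y = _label_codes_01(labels)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        if lam is None:
            model = LassoCV(cv=cv, max_iter=max_iter, random_state=seed).fit(X, y)
        else:
            model = Lasso(alpha=lam, max_iter=max_iter).fit(X, y)
    _check_converged(model, max_iter)
    coef = np.asarray(model.coef_, dtype=float)
    return MethodScore(
        method="lasso",
        feature_names=list(table.feature_names),
        statistic=coef,
        kept=np.abs(coef) > 0,
    )


def enet_select(
    table: FeatureTable,
    labels: LabelVector,
    lam: float | None = None,
    mix: float = 0.5,
    *,
    cv: int = 5,
    max_iter: int = 50_000,
    seed: int = 0,
    ridge_tol: float = 1e-8,
) -> MethodScore:
    """Elastic-net selection: penalty lam * [mix*L1 + (1-mix)*L2].

    ``mix`` is the L1 proportion (1 reduces to the Lasso, 0 to ridge;
    default 0.5).  Kept iff |coefficient| > 0, except at mix = 0 where
    exact zeros are non-generic and ``ridge_tol`` is used instead.
    """
    if not table.normalized:
        raise ValueError("enet_select expects a normalized table")
    if not 0.0 <= mix <= 1.0:
        raise ValueError("mix must lie in [0, 1]")
    X = table.values
    y = _label_codes_01(labels)
    # sklearn's l1_ratio=0 path is ill-behaved in CV mode; bound it away from 0
    l1_ratio = max(mix, 1e-6) if lam is None else mix
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        if lam is None:
            model = ElasticNetCV(
                l1_ratio=l1_ratio, cv=cv, max_iter=max_iter, random_state=seed
            ).fit(X, y)
        else:
            model = ElasticNet(alpha=lam, l1_ratio=l1_ratio, max_iter=max_iter).fit(X, y)
    _check_converged(model, max_iter)
    coef = np.asarray(model.coef_, dtype=float)
    tol = ridge_tol if mix == 0.0 else 0.0
    return MethodScore(
        method="enet",
        feature_names=list(table.feature_names),
        statistic=coef,
        kept=np.abs(coef) > tol,
    )


def union_candidates(
    scores: list[MethodScore], table: FeatureTable
) -> SelectionReport:
    """Union of the kept sets, ordered as in the input table.

    Raises when the union is empty (all four thresholds too strict).
    """
    by_method: dict[str, MethodScore] = {}
    kept_union: set[str] = set()
    for s in scores:
        if s.feature_names != list(table.feature_names):
            raise ValueError(
                f"method {s.method!r} was scored on different columns than the table"
            )
        by_method[s.method] = s
        kept_union.update(s.kept_names)
    if not kept_union:
        raise ValueError(
            "no method kept any feature; relax alpha/tau or the penalty strength"
        )
    candidate = [n for n in table.feature_names if n in kept_union]
    return SelectionReport(scores=by_method, candidate_set=candidate)


def select_level1(
    table: FeatureTable,
    labels: LabelVector,
    *,
    alpha: float = 0.05,
    tau: float = 0.1,
    lam: float | None = None,
    mix: float = 0.5,
    seed: int = 0,
) -> SelectionReport:
    """Run all four methods and return the candidate-set report."""
    scores = [
        chi_square_scores(table, labels, alpha=alpha),
        pearson_scores(table, labels, tau=tau),
        lasso_select(table, labels, lam=lam, seed=seed),
        enet_select(table, labels, lam=lam, mix=mix, seed=seed),
    ]
    return union_candidates(scores, table)
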