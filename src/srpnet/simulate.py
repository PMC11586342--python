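"""Synthetic screening cohorts with planted ground truth.

Cohorts emulate the structure of large stroke-screening registries: a
mix of binary, ordinal and continuous features; heavy class imbalance
across five risk categories (low / medium / high risk, TIA, stroke);
a handful of genuinely informative risk factors; redundant features
that are noisy copies of informative parents; and pure-noise columns.

Labels are drawn from a multinomial logit on a latent risk score
``s = sum_j w_j z_j`` over the standardized informative features, with
category slopes increasing in risk level and intercepts tuned so the
marginal category proportions hit their targets.  With
``separable=True`` labels are instead assigned deterministically by
quantile bands of ``s``, giving linearly separable categories.

The generative distributions here are test fixtures with known planted
truth, not claims about any real registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import FeatureTable, LabelVector

#: category counts of the emulated screening registry (low, medium, high, TIA, stroke)
CSDC_CATEGORY_COUNTS = (612_819, 124_103, 85_155, 23_305, 16_862)
CSDC_CATEGORY_NAMES = ("low", "medium", "high", "TIA", "stroke")


@dataclass
class FeatureDef:
    """One synthetic feature column.

    ``kind``: binary | ordinal | continuous.  Distribution parameters:
    ``prevalence`` (binary), ``n_levels`` (ordinal, equal-probability
    levels), ``mean``/``sd`` (continuous).
    """

    name: str
    kind: str
    prevalence: float = 0.5
    n_levels: int = 3
    mean: float = 0.0
    sd: float = 1.0


@dataclass
class InformativeDef(FeatureDef):
    """Informative feature: contributes ``weight`` to the latent risk score."""

    weight: float = 1.0


@dataclass
class RedundantDef:
    """Continuous noisy copy of an informative parent at a target correlation."""

    name: str
    parent: str
    correlation: float = 0.9


@dataclass
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n_subjects: int
    proportions: tuple[float, ...]
    category_names: tuple[str, ...]
    informative: list[InformativeDef]
    redundant: list[RedundantDef]
    noise: list[FeatureDef]
    feature_order: list[str] | None = None  # column order; default: informative, redundant, noise
    slope_scale: float = 1.0  # slope of category K-1 on the risk score
    separable: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        if len(self.proportions) != len(self.category_names):
            raise ValueError("proportions and category_names disagree")
        inf_names = {f.name for f in self.informative}
        for r in self.redundant:
            if r.parent not in inf_names:
                raise ValueError(f"redundant feature {r.name!r}: parent {r.parent!r} not informative")
        all_names = (
            [f.name for f in self.informative]
            + [r.name for r in self.redundant]
            + [f.name for f in self.noise]
        )
        if len(set(all_names)) != len(all_names):
            raise ValueError("duplicate feature names in cohort spec")
        if self.feature_order is not None and sorted(self.feature_order) != sorted(all_names):
            raise ValueError("feature_order must be a permutation of all feature names")

    @property
    def n_features(self) -> int:
        return len(self.informative) + len(self.redundant) + len(self.noise)


@dataclass
class PlantedTruth:
    """The ground-truth partition behind a synthetic cohort (the test oracle)."""

    informative: list[str]
    redundant: dict[str, str]  # name -> parent
    noise: list[str]
    weights: dict[str, float] = field(default_factory=dict)
    intercepts: np.ndarray | None = None
    slopes: np.ndarray | None = None


def _draw_feature(f: FeatureDef, z: np.ndarray) -> np.ndarray:
    """Map a standard-normal latent to the observed feature values."""
    if f.kind == "continuous":
        return f.mean + f.sd * z
    if f.kind == "binary":
        return (z > stats.norm.ppf(1.0 - f.prevalence)).astype(float)
    if f.kind == "ordinal":
        cuts = stats.norm.ppf(np.arange(1, f.n_levels) / f.n_levels)
        return np.searchsorted(cuts, z).astype(float)
    raise ValueError(f"unknown feature kind {f.kind!r}")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _tune_intercepts(
    s: np.ndarray, slopes: np.ndarray, targets: np.ndarray,
    max_iter: int = 500, tol: float = 5e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate-wise search for intercepts hitting the target marginals.

    Iteratively shifts each intercept by log(target / achieved), which is
    the exact one-category fix when the others are held; converges
    geometrically for these well-behaved targets.
    """
    b = np.log(targets)  # slope-free starting point
    pilot = s if s.size <= 100_000 else s[:100_000]
    for _ in range(max_iter):
        logits = b[None, :] + pilot[:, None] * slopes[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        achieved = p.mean(axis=0)
        if np.abs(achieved - targets).max() < tol:
            return b - b[0], achieved
        b = b + np.log(targets / achieved)
    raise RuntimeError(
        f"intercept search did not reach the target proportions {targets.tolist()}; "
        f"achieved {achieved.tolist()}"
    )


def generate_cohort(spec: CohortSpec) -> tuple[FeatureTable, LabelVector, PlantedTruth]:
    """Draw one cohort; fully deterministic for a fixed spec (including seed).

    Returns the unnormalized feature table, the label vector, and the
    planted truth.  Redundant columns are continuous noisy copies of
    their standardized parents at the spec's target correlation.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    k = len(spec.proportions)

    columns: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    score = np.zeros(n)
    weights: dict[str, float] = {}
    for f in spec.informative:
        x = _draw_feature(f, rng.standard_normal(n))
        columns[f.name] = x
        kinds[f.name] = f.kind
        weights[f.name] = f.weight
        score += f.weight * _standardize(x)
    for r in spec.redundant:
        parent = _standardize(columns[r.parent])
        if not 0 < r.correlation <= 1:
            raise ValueError(f"redundant {r.name!r}: correlation must lie in (0, 1]")
        noise_sd = np.sqrt(max(1.0 / r.correlation**2 - 1.0, 0.0))
        columns[r.name] = parent + noise_sd * rng.standard_normal(n)
        kinds[r.name] = "continuous"
    for f in spec.noise:
        columns[f.name] = _draw_feature(f, rng.standard_normal(n))
        kinds[f.name] = f.kind

    targets = np.asarray(spec.proportions, dtype=float)
    slopes = spec.slope_scale * np.arange(k) / max(k - 1, 1)
    if spec.separable:
        # deterministic quantile bands of the risk score
        qs = np.cumsum(targets)[:-1]
        cuts = np.quantile(score, qs)
        codes = np.searchsorted(cuts, score).astype(int)
        intercepts = None
    else:
        intercepts, _ = _tune_intercepts(score, slopes, targets)
        logits = intercepts[None, :] + score[:, None] * slopes[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(n)
        codes = (p.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(int)
        codes = np.minimum(codes, k - 1)

    order = spec.feature_order or list(columns)
    table = FeatureTable(
        values=np.column_stack([columns[name] for name in order]),
        feature_names=list(order),
        feature_kinds=[kinds[name] for name in order],
        normalized=False,
    )
    labels = LabelVector(codes=codes, category_names=list(spec.category_names))
    truth = PlantedTruth(
        informative=[f.name for f in spec.informative],
        redundant={r.name: r.parent for r in spec.redundant},
        noise=[f.name for f in spec.noise],
        weights=weights,
        intercepts=intercepts,
        slopes=slopes,
    )
    return table, labels, truth


def csdc_proportions() -> tuple[float, ...]:
    total = sum(CSDC_CATEGORY_COUNTS)
    return tuple(c / total for c in CSDC_CATEGORY_COUNTS)


def default_csdc_spec(n_subjects: int = 5_000, seed: int = 0) -> CohortSpec:
    """26-feature cohort spec emulating the screening registry's structure.

    Six informative binary risk factors (hypertension, stroke history,
    atrial fibrillation, elevated LDL-C, diabetes, smoking) at their
    registry prevalences; four redundant continuous copies; sixteen noise
    features spanning the remaining registry columns; five risk
    categories at the registry's imbalanced proportions.
    """
    informative = [
        InformativeDef("HYP", "binary", prevalence=182_800 / 862_244),
        InformativeDef("HS", "binary", prevalence=16_862 / 862_244),
        InformativeDef("AF", "binary", prevalence=23_445 / 862_244),
        InformativeDef("LDL-C", "binary", prevalence=270_313 / 862_244),
        InformativeDef("Diabetes", "binary", prevalence=49_674 / 862_244),
        InformativeDef("Smoking", "binary", prevalence=155_982 / 862_244),
    ]
    redundant = [
        RedundantDef("AG", parent="HS", correlation=0.9),
        RedundantDef("Gender", parent="HYP", correlation=0.9),
        RedundantDef("Occupation", parent="Smoking", correlation=0.9),
        RedundantDef("LE", parent="Diabetes", correlation=0.9),
    ]
    noise = [
        FeatureDef("EG", "binary", prevalence=2_716 / 862_244),
        FeatureDef("ES", "ordinal", n_levels=5),
        FeatureDef("FHS/HYP/CHD", "binary", prevalence=60_320 / 862_244),
        FeatureDef("PHT", "continuous", mean=26.83, sd=2.08),
        FeatureDef("PLT", "continuous", mean=-0.09, sd=3.32),
        FeatureDef("Overweight", "binary", prevalence=148_834 / 862_244),
        FeatureDef("NM", "ordinal", n_levels=3),
        FeatureDef("MS", "binary", prevalence=783_723 / 862_244),
        FeatureDef("MO", "binary", prevalence=3_537 / 862_244),
        FeatureDef("PGDP", "continuous", mean=39.12, sd=15.88),
        FeatureDef("PLO", "continuous", mean=112.94, sd=6.61),
        FeatureDef("PLA", "continuous", mean=35.18, sd=2.96),
        FeatureDef("PP", "continuous", mean=721.27, sd=202.66),
        FeatureDef("PHH", "continuous", mean=78.60, sd=4.67),
        FeatureDef("PLH", "continuous", mean=55.36, sd=12.80),
        FeatureDef("Category", "binary", prevalence=384_272 / 862_244),
    ]
    # registry column order
    feature_order = [
        "AG", "Gender", "EG", "Occupation", "ES", "FHS/HYP/CHD", "HS", "HYP",
        "AF", "LDL-C", "PHT", "PLT", "Smoking", "Diabetes", "LE", "Overweight",
        "NM", "MS", "MO", "PGDP", "PLO", "PLA", "PP", "PHH", "PLH", "Category",
    ]
    return CohortSpec(
        n_subjects=n_subjects,
        proportions=csdc_proportions(),
        category_names=CSDC_CATEGORY_NAMES,
        informative=informative,
        redundant=redundant,
        noise=noise,
        feature_order=feature_order,
        slope_scale=2.0,
        seed=seed,
    )


def separable_spec(n_subjects: int = 2_000, n_noise: int = 2, seed: int = 0) -> CohortSpec:
    """Linearly separable five-category cohort for optimizer sanity checks.

    Six continuous informative features; labels are deterministic quantile
    bands of the linear risk score, so a linear decision rule achieves
    perfect micro precision.
    """
    informative = [
        InformativeDef(f"risk{i}", "continuous", weight=1.0) for i in range(1, 7)
    ]
    noise = [FeatureDef(f"noise{i}", "continuous") for i in range(1, n_noise + 1)]
    return CohortSpec(
        n_subjects=n_subjects,
        proportions=csdc_proportions(),
        category_names=CSDC_CATEGORY_NAMES,
        informative=informative,
        redundant=[],
        noise=noise,
        separable=True,
        seed=seed,
    )
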