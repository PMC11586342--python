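"""End-to-end pipeline: preprocess -> level-1 -> level-2 -> train -> evaluate.

Each stage writes its artifact into the run directory so stages can be
re-used individually; a manifest records the configuration, the global
seed, and content hashes of every artifact.  A single global seed fans
out to fixed per-stage seeds so each stage is independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .data import (
    FeatureSchema,
    FeatureTable,
    LabelVector,
    minmax_normalize,
    read_cohort,
)
from .fusion import FusionClassifier, FusionConfig
from .level1 import select_level1
from .level2 import greedy_forward_search, search_optimal

logger = logging.getLogger("srpnet")

_STAGES = ("preprocess", "select1", "select2", "train", "evaluate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Fixed derivation of a per-stage seed from the global one (< 2**31)."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    cohort_path: str
    schema_path: str
    output_dir: str
    seed: int = 0
    # level-1 thresholds
    alpha: float = 0.05
    tau: float = 0.1
    lam: float | None = None
    mix: float = 0.5
    # level-2 search
    cv: int = 5
    n_max: int = 20
    profile: str = "default"
    subsample: int | None = 20_000
    n_jobs: int = 1
    # network
    fusion: FusionConfig = field(default_factory=FusionConfig)

    def validate(self) -> None:
        for attr in ("cohort_path", "schema_path"):
            p = Path(getattr(self, attr))
            if not p.exists():
                raise FileNotFoundError(f"{attr} does not exist: {p}")

    def to_dict(self) -> dict:
        out = asdict(self)
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Artifacts: normalization.json, selection_report.json,
    subset_search.json, checkpoint.npz (+ .json sidecar),
    eval_report.json, and manifest.json.  Any stage failure halts with
    the stage name; artifacts of completed stages are kept.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "preprocess"
    timings: dict[str, float] = {}
    try:
        t0 = time.perf_counter()
        schema = FeatureSchema.from_yaml(config.schema_path)
        table, labels = read_cohort(config.cohort_path, schema)
        table, norm_stats = minmax_normalize(table)
        norm_stats.to_json(out / "normalization.json")
        artifacts["normalization"] = out / "normalization.json"
        timings[stage] = time.perf_counter() - t0

        stage = "select1"
        t0 = time.perf_counter()
        report = select_level1(
            table,
            labels,
            alpha=config.alpha,
            tau=config.tau,
            lam=config.lam,
            mix=config.mix,
            seed=stage_seed(config.seed, stage),
        )
        (out / "selection_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        artifacts["selection_report"] = out / "selection_report.json"
        logger.info("level-1 candidate set: %s", report.candidate_set)
        timings[stage] = time.perf_counter() - t0

        stage = "select2"
        t0 = time.perf_counter()
        if len(report.candidate_set) > config.n_max:
            search = greedy_forward_search(
                report.candidate_set,
                table,
                labels,
                seed=stage_seed(config.seed, stage),
                cv=config.cv,
                profile=config.profile,
                subsample=config.subsample,
            )
        else:
            search = search_optimal(
                report,
                table,
                labels,
                seed=stage_seed(config.seed, stage),
                cv=config.cv,
                n_max=config.n_max,
                profile=config.profile,
                subsample=config.subsample,
                n_jobs=config.n_jobs,
            )
        (out / "subset_search.json").write_text(json.dumps(search.to_dict(), indent=2))
        artifacts["subset_search"] = out / "subset_search.json"
        # best-score-vs-size curve (the subset-size performance profile)
        curve = search.score_curve()
        (out / "score_curve.csv").write_text(
            "subset_size,best_mean_micro_precision\n"
            + "\n".join(f"{k},{v:.6f}" for k, v in curve)
        )
        artifacts["score_curve"] = out / "score_curve.csv"
        logger.info("level-2 optimal subset: %s", list(search.overall_best.subset))
        timings[stage] = time.perf_counter() - t0

        stage = "train"
        t0 = time.perf_counter()
        selected = table.select(search.overall_best.subset)
        fcfg = FusionConfig(
            **{**asdict(config.fusion), "seed": stage_seed(config.seed, stage),
               "n_categories": labels.n_categories}
        )
        results = FusionClassifier(selected, labels, fcfg).fit()
        results.save(out / "checkpoint.npz")
        artifacts["checkpoint"] = out / "checkpoint.npz"
        timings[stage] = time.perf_counter() - t0

        stage = "evaluate"
        t0 = time.perf_counter()
        report_eval = results.evaluate()
        report_eval.to_json(out / "eval_report.json")
        artifacts["eval_report"] = out / "eval_report.json"
        report_eval.confusion_matrix.to_csv(out / "confusion_matrix.csv")
        artifacts["confusion_matrix"] = out / "confusion_matrix.csv"
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_seconds": timings,
        "artifact_hashes": {k: _sha256(p) for k, p in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
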