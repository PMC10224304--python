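"""End-to-end orchestration: cohort -> clustering -> agreement -> profiling -> lasso.

Runs the full analysis with a single seed, writing every stage's outputs
(CSV/JSON) plus a manifest (config hash, seed, package version) that allows
an exact rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import DEFAULT_MERGES, agreement_report, crosstab
from .cluster import (
    METHOD_ORDER,
    canonical_relabel,
    pca_decompose,
    select_clustering,
)
from .mixedlasso import lasso_analysis
from .prep import BiomarkerMatrix, log_transform, standardize
from .profiling import profile_report
from .synthetic import (
    BIOMARKERS,
    COHORT_COLUMNS,
    GROUPS,
    GeneratorConfig,
    default_config,
    generate_cohort,
)

logger = logging.getLogger("raasid")


@dataclass
class PipelineConfig:
    """Settings of one full analysis run.

    Exactly one of ``input_csv`` (a cohort table on disk) or ``generator``
    (synthesize the cohort) must be provided; ``seed`` flows to every
    stochastic stage.
    """

    input_csv: str | None = None
    generator: GeneratorConfig | None = None
    methods: tuple[str, ...] = METHOD_ORDER
    k_min: int = 2
    k_max: int = 6
    merges: dict = field(default_factory=lambda: dict(DEFAULT_MERGES))
    cv_folds: int = 8
    lambda_grid_size: int = 50
    seed: int = 0
    output_dir: str = "raasid_output"

    def validate(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ValueError(
                "provide exactly one of input_csv or a generator config"
            )
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV with the documented column order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cohort = pd.read_csv(path)
    if cohort.empty:
        raise ValueError(f"{path} contains no subjects")
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing column(s) {missing!r}")
    bad_groups = sorted(set(cohort["group"]) - set(GROUPS))
    if bad_groups:
        raise ValueError(f"unknown treatment label(s) {bad_groups!r}")
    if cohort["id"].duplicated().any():
        dup = cohort.loc[cohort["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate subject id {dup!r}")
    for bm in BIOMARKERS:
        if (cohort[bm] <= 0).any():
            row = int(np.argmax(cohort[bm].to_numpy() <= 0))
            raise ValueError(
                f"non-positive {bm} at row {row} (id {cohort['id'].iloc[row]!r})"
            )
    return cohort[list(COHORT_COLUMNS)]


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort[list(COHORT_COLUMNS)].to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every analysis stage and return the in-memory report bundle.

    Stages: log-transform and standardize the biomarker panel; silhouette-
    based method/k selection with canonical relabeling; cluster-vs-treatment
    agreement grid; clinical profiling; one penalized mixed-model fit per
    biomarker. Raises with a stage-named message on failure.
    """
    config.validate()
    if config.input_csv is not None:
        cohort = read_cohort_csv(config.input_csv)
    else:
        cohort = generate_cohort(config.generator)

    bundle: dict = {"cohort": cohort, "config": config}
    try:
        raw = BiomarkerMatrix(cohort[list(BIOMARKERS)].to_numpy(dtype=float))
        logm = log_transform(raw)
        std = standardize(logm)
    except ValueError as exc:
        raise RuntimeError(f"biomarker_prep stage failed: {exc}") from exc

    try:
        selection = select_clustering(
            std.values,
            methods=config.methods,
            k_range=range(config.k_min, config.k_max + 1),
            seed=config.seed,
        )
        solution = canonical_relabel(selection.best_solution, logm.values)
        pca = pca_decompose(std.values)
    except ValueError as exc:
        raise RuntimeError(f"cluster_engine stage failed: {exc}") from exc
    bundle.update(selection=selection, solution=solution, pca=pca)

    try:
        table = crosstab(solution.labels, cohort["group"].to_numpy())
        agreement = agreement_report(table, merges=config.merges)
    except ValueError as exc:
        raise RuntimeError(f"agreement_eval stage failed: {exc}") from exc
    bundle.update(contingency=table, agreement=agreement)

    try:
        profile = profile_report(cohort, solution.labels)
    except ValueError as exc:
        raise RuntimeError(f"cluster_profiling stage failed: {exc}") from exc
    bundle["profile"] = profile

    lasso: dict = {}
    for bm in BIOMARKERS:
        try:
            lasso[bm] = lasso_analysis(
                cohort,
                solution.labels,
                bm,
                n_folds=config.cv_folds,
                grid_size=config.lambda_grid_size,
                seed=config.seed,
            )
        except ValueError as exc:
            raise RuntimeError(
                f"penalized_mixed_lasso stage failed for {bm}: {exc}"
            ) from exc
    bundle["lasso"] = lasso
    return bundle


def _config_digest(config: PipelineConfig) -> str:
    raw = dataclasses.asdict(config)
    if raw.get("generator") is not None:
        gen = raw["generator"]
        gen["biomarker_profiles"] = {
            g: np.asarray(v).tolist() for g, v in gen["biomarker_profiles"].items()
        }
        gen["biomarker_cov"] = np.asarray(gen["biomarker_cov"]).tolist()
    blob = json.dumps(raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_reports(bundle: dict, out_dir: str | Path) -> Path:
    """Write all stage outputs and the run manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config: PipelineConfig = bundle["config"]

    write_cohort_csv(bundle["cohort"], out / "cohort.csv")
    labels = pd.DataFrame(
        {"id": bundle["cohort"]["id"], "cluster": bundle["solution"].labels}
    )
    labels.to_csv(out / "cluster_labels.csv", index=False)
    bundle["selection"].grid.to_csv(out / "selection_grid.csv", index=False)
    pca = bundle["pca"]
    with open(out / "pca.json", "w") as fh:
        json.dump(
            {
                "variance_fractions": pca.variance_fractions.tolist(),
                "loadings": pca.loadings.tolist(),
            },
            fh,
            indent=2,
        )
    bundle["contingency"].counts.to_csv(out / "contingency.csv")
    bundle["agreement"].to_csv(out / "agreement.csv", index=False)
    bundle["profile"]["table"].to_csv(out / "profile.csv", index=False)
    bundle["profile"]["pairwise"].to_csv(out / "profile_pairwise.csv", index=False)
    for bm, res in bundle["lasso"].items():
        res["inference"].to_csv(out / f"lasso_{bm}.csv", index=False)
        curve = res["cv"]
        pd.DataFrame(
            {
                "lambda": curve.lambdas,
                "mean_mse": curve.mean_mse,
                "se_mse": curve.se_mse,
            }
        ).to_csv(out / f"cv_curve_{bm}.csv", index=False)
    manifest = {
        "package": "raasid",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_digest(config),
        "selected_method": bundle["selection"].best_method,
        "selected_k": bundle["selection"].best_k,
        "lambda_min": {
            bm: bundle["lasso"][bm]["cv"].lambda_min for bm in bundle["lasso"]
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("reports written to %s", out)
    return out


def run_default_synthetic(seed: int = 0, **overrides) -> dict:
    """Convenience: run the whole pipeline on a default synthetic cohort."""
    config = PipelineConfig(
        generator=default_config(seed=seed), seed=seed, **overrides
    )
    return run_pipeline(config)
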