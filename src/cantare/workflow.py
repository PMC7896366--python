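"""End-to-end orchestration: pairwise sweep -> network -> models -> figures.

One :func:`run_all` call executes the whole workflow from either a dataset
directory on disk or a synthetic-cohort spec, persists every intermediate
artifact (top-table CSV, network JSON, model report, cumulative-fit
figure), and writes a manifest recording the parameters, the counts at
each filter stage, and per-model convergence. For a fixed configuration
and seed the manifest is byte-stable across reruns.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field

from cantare import cumulative, dataset_io, models as nm, network as nt, pairwise
from cantare.simulate import SyntheticSpec, simulate

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Parameters of one reproducible workflow run."""

    #: directory of ome CSVs + metadata.csv, or None to simulate
    data_dir: str | None = None
    #: synthetic spec used when data_dir is None
    synthetic: SyntheticSpec | None = None
    mode: str = "interaction"
    per_pair_cap: int = 35
    alpha: float = 0.05
    dffits_max: float = 4.0
    prevalence_min_frac: float = 0.10
    prevalence_omes: list[str] = Field(default_factory=lambda: ["mb"])
    seed_ome: str = "mb"
    order: int = 2
    min_nodes: int = 4
    covariates: list[str] = Field(default_factory=lambda: ["age", "calprotectin"])
    force_keep: list[str] = Field(default_factory=list)
    out_dir: str = "cantare_run"

    def model_post_init(self, _ctx) -> None:
        if self.mode not in {"interaction", "correlation"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.order < 1 or self.min_nodes < 1 or self.per_pair_cap < 1:
            raise ValueError("order, min_nodes and per_pair_cap must be >= 1")
        if not 0 < self.alpha <= 1 or not 0 <= self.prevalence_min_frac <= 1:
            raise ValueError("alpha/prevalence out of range")


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n"
    )


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    On a stage failure the manifest records the failure point and the
    artifacts of completed stages are retained; the manifest's
    ``failed_stage`` is None on full success.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": json.loads(config.model_dump_json()),
        "counts": {},
        "models": [],
        "failed_stage": None,
        "error": None,
    }
    stage = "load"
    try:
        if config.data_dir is not None:
            dataset = dataset_io.read_dataset_dir(config.data_dir)
        elif config.synthetic is not None:
            dataset, _truth = simulate(config.synthetic)
        else:
            raise ValueError("config needs data_dir or a synthetic spec")
        manifest["counts"]["samples"] = dataset.n_samples
        manifest["counts"]["analytes"] = {
            ome: mat.shape[1] for ome, mat in dataset.omes.items()
        }

        stage = "pairwise"
        fits = pairwise.run_all_pairs(dataset, mode=config.mode)
        excluded: set[str] = set()
        for ome in config.prevalence_omes:
            kept = set(
                pairwise.prevalence_filter(dataset, ome, config.prevalence_min_frac)
            )
            excluded |= set(dataset.omes[ome].columns) - kept
        top = pairwise.build_top_table(
            fits,
            per_pair_cap=config.per_pair_cap,
            alpha=config.alpha,
            dffits_max=config.dffits_max,
            excluded_analytes=sorted(excluded),
        )
        manifest["counts"]["pairwise_attempted"] = len(fits)
        manifest["counts"]["pairwise_invalid"] = top.exclusions["invalid"]
        manifest["counts"]["pairwise_p_undefined"] = top.exclusions["p_undefined"]
        manifest["counts"]["pairwise_prevalence_removed"] = top.exclusions["prevalence"]
        manifest["counts"]["pairwise_dffits_removed"] = top.exclusions["dffits"]
        manifest["counts"]["pairwise_retained"] = top.exclusions["retained"]
        manifest["counts"]["top_table_entries"] = len(top)
        pairwise.top_table_frame(top).to_csv(out_dir / "toptable.csv", index=False)

        stage = "network"
        net = nt.build_network(top)
        manifest["counts"]["vnet_nodes"] = net.n_nodes
        manifest["counts"]["vnet_edges"] = net.n_edges
        manifest["counts"]["vnet_duplicate_pairs_dropped"] = getattr(
            net, "duplicates_dropped", 0
        )
        dataset_io.write_network_json(net, out_dir / "vnet.json")

        stage = "neighborhoods"
        hoods = nt.enumerate_seed_neighborhoods(
            net, seed_ome=config.seed_ome, order=config.order,
            min_nodes=config.min_nodes,
        )
        manifest["counts"]["neighborhoods"] = len(hoods)

        stage = "models"
        fitted = nm.run_neighborhood_models(
            dataset,
            hoods,
            covariates=tuple(config.covariates),
            force_keep=tuple(config.force_keep),
        )
        unique = nm.dedupe_models(fitted)
        converged = [m for m in unique if m.converged]
        manifest["counts"]["models_fitted"] = len(fitted)
        manifest["counts"]["models_converged"] = sum(m.converged for m in fitted)
        manifest["counts"]["models_unique"] = len(converged)
        manifest["models"] = [
            {
                "seed": m.seed,
                "seeds": m.seeds or [m.seed],
                "n_reduced": len(m.reduced_predictors),
                "auc": None if not np.isfinite(m.auc) else round(float(m.auc), 10),
                "converged": m.converged,
                "note": m.note,
            }
            for m in unique
        ]
        nm.model_report(unique).to_csv(out_dir / "models.csv", index=False)

        stage = "cumulative_fit"
        if converged:
            best = max(converged, key=lambda m: (m.auc, m.seed))
            frame = dataset.predictor_frame(
                [p for p in best.reduced_predictors if p in dataset.registry],
                [p for p in best.reduced_predictors if p not in dataset.registry],
            )
            refit = nm.fit_logistic(frame, dataset.group)
            contrib = cumulative.fit_matrix(refit, frame)
            order = [e.predictor for e in nm.effect_sizes(refit, frame)]
            matrix = cumulative.cumulative_fit(contrib, order, dataset.group)
            matrix.log_odds.to_csv(out_dir / "cumfit_logodds.csv")
            matrix.probability.to_csv(out_dir / "cumfit_probability.csv")
            cumulative.plot_cumulative(
                matrix, out_dir / "cumfit_best_model.svg",
                title=f"cumulative fit: seed {best.seed} (AUC {best.auc:.3f})",
            )
            manifest["counts"]["figures"] = 1
        else:
            manifest["counts"]["figures"] = 0
    except Exception as exc:  # record the failure point, keep prior artifacts
        logger.exception("stage %r failed", stage)
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
    _write_manifest(manifest, out_dir)
    return manifest
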