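"""End-to-end orchestration: simulate or ingest, then normalize, diversity,
enterotypes, maturation, differential abundance, AMR trends and qPCR
models, from one configuration with a machine-readable report.

All stage randomness derives from the global seed via stage-name hashing,
so any stage can be rerun in isolation and reproduce its output.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import zlib
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from enterochron.io import (
    read_count_table,
    read_metadata,
    read_amr_table,
    read_qpcr_table,
    assemble_dataset,
    write_metadata,
    CountTable,
)
from enterochron.simulate import CohortConfig, simulate_cohort, write_simulation
from enterochron.metrics import css_normalize, alpha_diversity, bray_curtis, beta_dispersion
from enterochron.permanova import permanova
from enterochron.dmm import select_k, assign_enterotypes, trajectories
from enterochron.maturation import first_appearance_ranks, consensus_order, maturation_scores
from enterochron.lmm import differential_abundance_scan
from enterochron.amr import SplineTrendAR1, standardize_gene_copies, qpcr_age_models
from enterochron.simulate import NO_GROWTH, AMR_PANEL

logger = logging.getLogger("enterochron")

_pkg_version = "0.1.0"

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stage-name hashing)."""
    return int((int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1))


@dataclasses.dataclass
class PipelineConfig:
    """Pipeline inputs and per-stage parameter blocks.

    Exactly one of ``inputs`` (paths to counts/metadata/amr/qpcr TSVs) or
    ``simulation`` (CohortConfig keyword arguments) must be given.
    """

    outdir: str | Path
    seed: int = 0
    inputs: Mapping[str, str] | None = None
    simulation: Mapping[str, Any] | None = None
    normalization: Mapping[str, Any] = dataclasses.field(
        default_factory=lambda: {"quantile": 0.5, "scale_constant": 1000.0}
    )
    dmm: Mapping[str, Any] = dataclasses.field(
        default_factory=lambda: {"kmax": 7, "n_restarts": 5}
    )
    permanova: Mapping[str, Any] = dataclasses.field(
        default_factory=lambda: {"n_permutations": 10000}
    )
    maturation: Mapping[str, Any] = dataclasses.field(
        default_factory=lambda: {"ra_threshold": 0.005, "n_permutations": 10000}
    )
    da: Mapping[str, Any] = dataclasses.field(
        default_factory=lambda: {"min_mean_ra": 0.0001, "alpha_p": 0.05, "alpha_q": 0.25}
    )
    amr: Mapping[str, Any] = dataclasses.field(
        default_factory=lambda: {"n_knots": 9, "degree": 3, "penalty_order": 2}
    )

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of 'inputs' and 'simulation' must be configured"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


@dataclasses.dataclass
class ReportBundle:
    """Manifest of stage outputs plus run metadata."""

    outdir: str
    seed: int
    version: str
    started: str
    finished: str | None = None
    stages: dict[str, dict] = dataclasses.field(default_factory=dict)

    def record(self, stage: str, status: str, files: list[str] | None = None,
               error: str | None = None) -> None:
        self.stages[stage] = {
            "status": status,
            "files": files or [],
            **({"error": error} if error else {}),
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages in dependency order; a stage failure halts its
    downstream stages and is recorded in the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = ReportBundle(
        outdir=str(outdir),
        seed=config.seed,
        version=_pkg_version,
        started=datetime.datetime.now().isoformat(timespec="seconds"),
    )

    # -- ingest / simulate -------------------------------------------------
    try:
        if config.simulation is not None:
            sim_cfg = CohortConfig(
                **{**dict(config.simulation), "seed": stage_seed(config.seed, "simulate")}
            )
            sim = simulate_cohort(sim_cfg)
            paths = write_simulation(sim, outdir / "sim")
            dataset = sim.dataset()
            report.record("simulate", "ok", list(paths.values()))
        else:
            inputs = dict(config.inputs)
            counts = read_count_table(inputs["counts"])
            metadata = read_metadata(inputs["metadata"])
            amr = read_amr_table(inputs["amr"]) if "amr" in inputs else None
            qpcr = read_qpcr_table(inputs["qpcr"]) if "qpcr" in inputs else None
            dataset = assemble_dataset(counts, metadata, amr=amr, qpcr=qpcr)
            report.record("ingest", "ok", list(inputs.values()))
    except Exception as exc:  # noqa: BLE001 - report and stop
        report.record("ingest", "failed", error=str(exc))
        report.finished = datetime.datetime.now().isoformat(timespec="seconds")
        report.write(outdir / "report.json")
        return report

    meta_df = dataset.metadata_frame()
    counts = dataset.counts

    def _run(stage: str, fn):
        try:
            files = fn()
            report.record(stage, "ok", files)
            logger.info("stage %s: ok", stage)
        except Exception as exc:  # noqa: BLE001
            logger.exception("stage %s failed", stage)
            report.record(stage, "failed", error=str(exc))

    # -- normalization + diversity ----------------------------------------
    state: dict[str, Any] = {}

    def diversity_stage() -> list[str]:
        norm = css_normalize(counts, **config.normalization)
        state["norm"] = norm
        alpha = alpha_diversity(counts)
        bc = bray_curtis(norm)
        state["bc"] = bc
        groups = meta_df.set_index("sample_id")["age_weeks"].astype(str).to_dict()
        disp = beta_dispersion(bc, {s: groups[s] for s in bc.index})
        f1 = outdir / "alpha.tsv"
        f2 = outdir / "bray_curtis.tsv"
        f3 = outdir / "beta_dispersion.tsv"
        alpha.to_csv(f1, sep="\t", index=False)
        bc.to_csv(f2, sep="\t")
        disp.to_csv(f3, sep="\t", index=False)
        return [str(f1), str(f2), str(f3)]

    _run("diversity", diversity_stage)

    def permanova_stage() -> list[str]:
        bc = state["bc"]
        design = meta_df.set_index("sample_id").loc[list(bc.index)]
        res = permanova(
            bc,
            design.reset_index(),
            terms=["age_weeks", "cohort"],
            strata="pig_id",
            seed=stage_seed(config.seed, "permanova"),
            **config.permanova,
        )
        f = outdir / "permanova.tsv"
        res.table.to_csv(f, sep="\t", index=False)
        return [str(f)]

    if "bc" in state:
        _run("permanova", permanova_stage)

    def enterotype_stage() -> list[str]:
        kmax = int(config.dmm.get("kmax", 7))
        fits, best = select_k(
            counts,
            k_range=range(1, kmax + 1),
            n_restarts=int(config.dmm.get("n_restarts", 5)),
            seed=stage_seed(config.seed, "enterotype"),
        )
        state["dmm"] = fits[best]
        scores = pd.DataFrame(
            {
                "K": list(fits),
                "laplace": [fits[k].laplace() for k in fits],
                "log_likelihood": [fits[k].log_likelihood for k in fits],
                "selected": [k == best for k in fits],
            }
        )
        assign = assign_enterotypes(fits[best])
        state["assignments"] = assign
        traj = trajectories(assign, meta_df)
        f1 = outdir / "model_scores.tsv"
        f2 = outdir / "assignments.tsv"
        f3 = outdir / "trajectories.tsv"
        scores.to_csv(f1, sep="\t", index=False)
        assign.to_csv(f2, sep="\t", index=False)
        traj.per_pig.to_csv(f3, sep="\t", index=False)
        return [str(f1), str(f2), str(f3)]

    _run("enterotype", enterotype_stage)

    def maturation_stage() -> list[str]:
        ranks = first_appearance_ranks(
            counts, meta_df, ra_threshold=config.maturation["ra_threshold"]
        )
        cons = consensus_order(
            ranks,
            n_permutations=int(config.maturation["n_permutations"]),
            seed=stage_seed(config.seed, "maturation"),
        )
        scores = maturation_scores(
            cons, counts, meta_df, ra_threshold=config.maturation["ra_threshold"]
        )
        f = outdir / "maturation.tsv"
        scores.to_csv(f, sep="\t", index=False)
        (outdir / "maturation_consensus.tsv").write_text(
            "genus\tmedian_rank\n"
            + "\n".join(f"{g}\t{cons.median_ranks[g]}" for g in cons.order)
            + f"\n# kendalls_w={cons.kendalls_w}\tp={cons.permutation_p}\n"
        )
        return [str(f), str(outdir / "maturation_consensus.tsv")]

    _run("maturation", maturation_stage)

    def da_stage() -> list[str]:
        da = differential_abundance_scan(state["norm"], meta_df, **config.da)
        f = outdir / "differential_abundance.tsv"
        da.to_csv(f, sep="\t", index=False)
        return [str(f)]

    if "norm" in state:
        _run("differential_abundance", da_stage)

    def amr_stage() -> list[str]:
        if dataset.amr is None:
            return []
        amr = dataset.amr.merge(meta_df, on="sample_id")
        rows = []
        for (bact, dclass), sub in amr.groupby(["bacterium", "drug_class"]):
            if (bact, dclass) in NO_GROWTH or sub["log10_cfu_per_g"].notna().sum() < 20:
                continue
            # classes with several drugs contribute one AR(1) series per
            # pig x drug (independent plates), not one per pig
            series = (sub["pig_id"].astype(str) + "|" + sub["drug"].astype(str))
            fit = SplineTrendAR1(
                sub["log10_cfu_per_g"].to_numpy(float),
                sub["age_weeks"].to_numpy(float),
                cohort=sub["cohort"].to_numpy(),
                pig=series.to_numpy(),
                **config.amr,
            ).fit()
            for w in fit.significance_windows():
                rows.append(
                    {
                        "bacterium": bact,
                        "drug_class": dclass,
                        "start_week": w.start,
                        "end_week": w.end,
                        "direction": w.direction,
                        "phi": fit.phi,
                        "edf": fit.edf,
                    }
                )
        f = outdir / "amr_windows.tsv"
        pd.DataFrame(rows).to_csv(f, sep="\t", index=False)
        return [str(f)]

    _run("amr_trends", amr_stage)

    def qpcr_stage() -> list[str]:
        if dataset.qpcr is None:
            return []
        std = standardize_gene_copies(dataset.qpcr)
        fits = qpcr_age_models(dataset.qpcr, meta_df)
        f1 = outdir / "qpcr_standardized.tsv"
        std.to_csv(f1, sep="\t", index=False)
        f2 = outdir / "qpcr_models.txt"
        with open(f2, "w") as fh:
            for (gene, outcome), fit in fits.items():
                fh.write(f"== {gene} ({outcome}) ==\n{fit.summary()}\n\n")
        return [str(f1), str(f2)]

    _run("qpcr", qpcr_stage)

    report.finished = datetime.datetime.now().isoformat(timespec="seconds")
    report.write(outdir / "report.json")
    return report
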