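"""Pipeline orchestration: benchmark reports and MD analysis bundles.

Each run takes a :class:`RunConfig`, writes its outputs under a run
directory with fixed file names, and drops the fully resolved config next
to them (``resolved_config.yaml``) so any run is reproducible from its own
artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import md_analysis, screening
from .curation import CuratedActiveSet, curate, load_active_table
from .errors import JoinError
from .screening import RankedLibrary
from .trajectory import load_trajectory

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_benchmark", "run_mdreport"]

DEFAULT_EF_FRACTIONS = (0.005, 0.01, 0.05, 0.10)


@dataclass
class RunConfig:
    """Serializable parameters of one pipeline run."""

    outdir: str = "run"
    # benchmark stage
    actives_csv: Optional[str] = None
    score_tables: list[str] = field(default_factory=list)
    kd_cutoff: float = 100.0
    proc_floor: Optional[float] = None
    ef_fractions: tuple[float, ...] = DEFAULT_EF_FRACTIONS
    higher_is_better: Optional[bool] = None
    # md stage
    trajectories: list[str] = field(default_factory=list)
    rmsd_selection: str = "protein and name CA"
    rmsf_selection: str = "protein"
    pca_selection: str = "protein and name CA"
    distance_pairs: list[tuple[str, str]] = field(default_factory=list)
    hbond_donors: Optional[str] = None
    hbond_acceptors: Optional[str] = None
    hbond_distance_cut: float = 3.5
    hbond_angle_cut: float = 30.0
    fel_bins: int = 50
    temperature: float = 300.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _prepare_outdir(config: RunConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.write(outdir / "resolved_config.yaml")
    return outdir


def run_benchmark(
    config: RunConfig, actives: Optional[CuratedActiveSet] = None
) -> dict:
    """Evaluate one or more score tables against the curated active set.

    Per table: pROC-AUC, ROC-AUC, EF at the configured fractions, and the
    chemotype table CSV.  Writes ``metrics.json``, ``chemotype_<name>.csv``
    and the curated set; returns the metrics dict.
    """
    t0 = time.time()
    outdir = _prepare_outdir(config)
    if actives is None:
        if config.actives_csv is None:
            raise ValueError("run_benchmark needs actives (csv path or object)")
        actives = curate(load_active_table(config.actives_csv), config.kd_cutoff)
    actives.write_csv(outdir / "curated_actives.csv")

    known_ids = {r.id for r in actives.records}
    metrics: dict = {"tables": {}}
    for table_path in config.score_tables:
        name = Path(table_path).stem
        lib = RankedLibrary.from_csv(table_path, config.higher_is_better)
        unknown = [
            e.id
            for e in lib.entries.itertuples(index=False)
            if e.label == screening.ACTIVE and e.id not in known_ids
        ]
        if unknown:
            raise JoinError(
                f"score table {name!r} has active ids absent from the "
                f"curated set: {unknown}"
            )
        proc = screening.proc_auc(lib, config.proc_floor)
        table_metrics = {
            "n_actives": lib.n_actives,
            "n_decoys": lib.n_decoys,
            "proc_auc": proc.auc,
            "proc_floor": proc.floor,
            "roc_auc": screening.roc_auc(lib),
            "ef": {},
        }
        for fraction in config.ef_fractions:
            ef = screening.enrichment_factor(lib, fraction)
            table_metrics["ef"][f"{fraction:g}"] = {
                "ef": ef.ef,
                "n_subset": ef.n_subset,
                "bioactives_subset": ef.bioactives_subset,
            }
        chemotype = screening.chemotype_table(lib, actives)
        chemotype.to_csv(outdir / f"chemotype_{name}.csv", index=False)
        summary = screening.cluster_fitness_summary(chemotype)
        summary.to_csv(outdir / f"cluster_fitness_{name}.csv", index=False)
        metrics["tables"][name] = table_metrics

    metrics["elapsed_s"] = time.time() - t0
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1))
    logger.info("benchmark: %d table(s) in %.2fs", len(config.score_tables), metrics["elapsed_s"])
    return metrics


def run_mdreport(config: RunConfig) -> dict:
    """Run the trajectory-analysis battery on each configured trajectory.

    Per trajectory: RMSD/RoG series, per-residue RMSF, optional H-bond
    counts and COM/minimum distance series for each selection pair, PCA
    and the PC1/PC2 free-energy landscape.  Series go to CSV; a summary
    comparison table covers all trajectories.
    """
    t0 = time.time()
    outdir = _prepare_outdir(config)
    if not config.trajectories:
        raise ValueError("run_mdreport needs at least one trajectory")
    summary_rows = []
    for traj_path in config.trajectories:
        name = Path(traj_path).name
        traj = load_trajectory(traj_path)
        series = pd.DataFrame({"time_ps": traj.times})
        series["rmsd_A"] = md_analysis.rmsd_series(traj, sel=config.rmsd_selection)
        series["rog_A"] = md_analysis.rog_series(traj, sel=config.rmsd_selection)
        if config.hbond_donors and config.hbond_acceptors:
            series["hbonds"] = md_analysis.hbond_count_series(
                traj,
                config.hbond_donors,
                config.hbond_acceptors,
                d_cut=config.hbond_distance_cut,
                angle_cut=config.hbond_angle_cut,
            )
        for sel_a, sel_b in config.distance_pairs:
            tag = f"{sel_a}|{sel_b}".replace(" ", "_")
            series[f"com_nm[{tag}]"] = md_analysis.com_distance_series(traj, sel_a, sel_b)
            series[f"min_nm[{tag}]"] = md_analysis.min_distance_series(traj, sel_a, sel_b)
        series.to_csv(outdir / f"series_{name}.csv", index=False)

        residue_rmsf = md_analysis.rmsf(traj, sel=config.rmsf_selection)
        residue_rmsf.to_csv(outdir / f"rmsf_{name}.csv")

        result = md_analysis.pca(traj, sel=config.pca_selection)
        fel = md_analysis.free_energy_landscape(
            result.projections[:, 0],
            result.projections[:, 1],
            bins=config.fel_bins,
            temperature=config.temperature,
        )
        fel.write_csv(outdir / f"fel_{name}.csv")
        np.savetxt(
            outdir / f"eigenvalues_{name}.csv",
            result.eigenvalues,
            header="eigenvalue_A2",
            comments="",
            delimiter=",",
        )
        summary_rows.append(
            {
                "trajectory": name,
                "n_frames": traj.n_frames,
                "n_atoms": traj.n_atoms,
                "rmsd_mean_A": float(series["rmsd_A"].mean()),
                "rmsd_max_A": float(series["rmsd_A"].max()),
                "rog_mean_A": float(series["rog_A"].mean()),
                "rmsf_mean_A": float(residue_rmsf.mean()),
                "pc1_variance_A2": float(result.eigenvalues[0]),
                "pc2_variance_A2": float(result.eigenvalues[1])
                if len(result.eigenvalues) > 1
                else 0.0,
                "fel_kt_kcal_mol": fel.kt,
            }
        )
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "md_summary.csv", index=False)
    elapsed = time.time() - t0
    logger.info("mdreport: %d trajectories in %.2fs", len(config.trajectories), elapsed)
    return {"summary": summary, "elapsed_s": elapsed}
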