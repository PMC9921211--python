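"""Score-list performance metrics for virtual-screening benchmarks.

Given a score-ordered library of known actives and decoys, this module
computes the standard retrospective-screening quantities:

* *fitness* — the negated docking score, so that larger is better,
* the ROC curve (true-positive rate of actives vs false-positive rate of
  decoys down the ranked list) and its trapezoidal AUC,
* the pROC-AUC, ``(1/n) Σ_i −log10(D_i)`` where ``D_i`` is the fraction of
  decoys ranked above the i-th active — a log-scaled ROC area that rewards
  early enrichment (random expectation 1/ln 10 ≈ 0.434),
* enrichment factors, ``EF(f) = (Bioactives_subset/N_subset) /
  (Bioactives_total/N_total)`` for a top fraction ``f`` of the library,
* the chemotype table joining docking ranks to cluster labels, bioactivity
  ranks, LOA and TOD of the curated actives (the machine-readable form of a
  pROC-chemotype plot), and per-cluster five-number fitness summaries.

``D_i`` is clamped below at a configurable floor (default: one-decoy
resolution, 1/n_decoys) so a perfectly ranked library has a finite pROC-AUC
of log10(n_decoys).  The subset size at fraction ``f`` is ``ceil(f·N)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curation import CuratedActiveSet
from .errors import ConfigurationError, EmptyClassError, FormatError, JoinError

__all__ = [
    "RankedLibrary",
    "ProcResult",
    "EnrichmentResult",
    "fitness",
    "roc_points",
    "roc_auc",
    "proc_auc",
    "enrichment_factor",
    "chemotype_table",
    "cluster_fitness_summary",
]

ACTIVE = "active"
DECOY = "decoy"


def fitness(score: float) -> float:
    """Negated docking score (PLANTS-style scores are lower-is-better)."""
    if not math.isfinite(score):
        raise ValueError(f"score must be finite, got {score!r}")
    return -score


@dataclass
class RankedLibrary:
    """A labeled compound library ordered best score first.

    ``entries`` carries columns id, label ('active'/'decoy'), score, fitness
    and optionally cluster.  ``lower_is_better`` records the score direction
    used to rank; ties keep input order (stable sort).
    """

    entries: pd.DataFrame
    lower_is_better: bool = True

    def __post_init__(self):
        required = {"id", "label", "score"}
        missing = required - set(self.entries.columns)
        if missing:
            raise FormatError(f"ranked library missing columns: {sorted(missing)}")
        bad = set(self.entries["label"]) - {ACTIVE, DECOY}
        if bad:
            raise FormatError(f"unknown labels: {sorted(bad)}")
        if not np.all(np.isfinite(self.entries["score"].to_numpy(dtype=float))):
            raise ValueError("scores must be finite")
        key = self.entries["score"] if self.lower_is_better else -self.entries["score"]
        self.entries = (
            self.entries.iloc[np.argsort(key.to_numpy(), kind="stable")]
            .reset_index(drop=True)
            .assign(fitness=lambda df: -df["score"])
        )

    @classmethod
    def from_records(
        cls,
        ids: Sequence[str],
        labels: Sequence[str],
        scores: Sequence[float],
        lower_is_better: bool = True,
        clusters: Optional[Sequence] = None,
    ) -> "RankedLibrary":
        data = {"id": list(ids), "label": list(labels), "score": list(scores)}
        if clusters is not None:
            data["cluster"] = list(clusters)
        return cls(pd.DataFrame(data), lower_is_better=lower_is_better)

    @classmethod
    def from_csv(cls, path: str | Path, higher_is_better: Optional[bool] = None):
        """Read a score table CSV (id, label, score[, cluster]).

        A leading ``#`` comment line containing ``direction: higher`` (or
        ``lower``) sets the score direction unless overridden by the
        ``higher_is_better`` argument.  Default is lower-is-better.
        """
        path = Path(path)
        direction_higher = False
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            if "higher" in first.lower():
                direction_higher = True
        if higher_is_better is not None:
            direction_higher = higher_is_better
        frame = pd.read_csv(path, comment="#")
        frame.columns = [c.strip().lower() for c in frame.columns]
        return cls(frame, lower_is_better=not direction_higher)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# direction: %s\n" % ("lower" if self.lower_is_better else "higher")
            )
            self.entries.to_csv(fh, index=False)

    @property
    def labels(self) -> np.ndarray:
        return self.entries["label"].to_numpy()

    @property
    def n_actives(self) -> int:
        return int((self.labels == ACTIVE).sum())

    @property
    def n_decoys(self) -> int:
        return int((self.labels == DECOY).sum())

    def __len__(self) -> int:
        return len(self.entries)

    def _require_both_classes(self):
        if self.n_actives == 0 or self.n_decoys == 0:
            raise EmptyClassError(
                f"need at least one active and one decoy "
                f"(got {self.n_actives} actives, {self.n_decoys} decoys)"
            )


@dataclass
class ProcResult:
    """pROC-AUC with the per-active decoy fractions it averaged."""

    auc: float
    per_active_di: np.ndarray
    floor: float


@dataclass
class EnrichmentResult:
    """Enrichment factor at one library fraction."""

    fraction: float
    n_subset: int
    bioactives_subset: int
    ef: float


def roc_points(lib: RankedLibrary) -> np.ndarray:
    """Stepwise ROC curve points (fpr, tpr) from (0,0) to (1,1).

    Entries sharing a score advance jointly, producing a diagonal segment.
    """
    lib._require_both_classes()
    labels = lib.labels
    scores = lib.entries["score"].to_numpy(dtype=float)
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            j += 1
        tp += int((labels[i:j] == ACTIVE).sum())
        fp += int((labels[i:j] == DECOY).sum())
        points.append((fp / lib.n_decoys, tp / lib.n_actives))
        i = j
    return np.array(points)


def roc_auc(lib: RankedLibrary) -> float:
    """Trapezoidal area under the ROC curve."""
    pts = roc_points(lib)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def proc_auc(lib: RankedLibrary, floor: Optional[float] = None) -> ProcResult:
    """pROC-AUC: mean of −log10 of the per-active decoy fraction ranked above.

    ``floor`` clamps each decoy fraction from below; default is one-decoy
    resolution, 1/n_decoys, so perfect separation gives log10(n_decoys).
    """
    lib._require_both_classes()
    if floor is None:
        floor = 1.0 / lib.n_decoys
    if not (0 < floor < 1):
        raise ConfigurationError(f"floor must be in (0, 1), got {floor!r}")
    labels = lib.labels
    decoys_above = np.cumsum(labels == DECOY) - (labels == DECOY)
    di = decoys_above[labels == ACTIVE] / lib.n_decoys
    di = np.clip(di, floor, 1.0)
    return ProcResult(auc=float(np.mean(-np.log10(di))), per_active_di=di, floor=floor)


def enrichment_factor(lib: RankedLibrary, fraction: float) -> EnrichmentResult:
    """Enrichment factor over the top ``ceil(fraction × N)`` entries."""
    if len(lib) == 0:
        raise EmptyClassError("empty library")
    if not (0 < fraction <= 1):
        raise ConfigurationError(f"fraction must be in (0, 1], got {fraction!r}")
    lib._require_both_classes()
    n_total = len(lib)
    n_subset = math.ceil(fraction * n_total)
    bioactives_subset = int((lib.labels[:n_subset] == ACTIVE).sum())
    ef = (bioactives_subset / n_subset) / (lib.n_actives / n_total)
    return EnrichmentResult(
        fraction=fraction,
        n_subset=n_subset,
        bioactives_subset=bioactives_subset,
        ef=float(ef),
    )


def chemotype_table(lib: RankedLibrary, actives: CuratedActiveSet) -> pd.DataFrame:
    """Docking-ordered table joining actives to their chemotype annotations.

    One row per library entry, columns docking_rank, id, label, cluster,
    bioactivity_rank, loa, tod, fitness; decoy rows carry empty chemotype
    fields.  Every active entry must join to a curated record.
    """
    curated = actives.to_frame().set_index("id")
    rows = []
    unmatched = []
    for rank, entry in enumerate(lib.entries.itertuples(index=False), start=1):
        row = {
            "docking_rank": rank,
            "id": entry.id,
            "label": entry.label,
            "cluster": pd.NA,
            "bioactivity_rank": pd.NA,
            "loa": np.nan,
            "tod": pd.NA,
            "fitness": entry.fitness,
        }
        if entry.label == ACTIVE:
            if entry.id not in curated.index:
                unmatched.append(entry.id)
            else:
                rec = curated.loc[entry.id]
                row.update(
                    cluster=int(rec["cluster"]),
                    bioactivity_rank=int(rec["bioactivity_rank"]),
                    loa=float(rec["loa"]),
                    tod=rec["tod"],
                )
        rows.append(row)
    if unmatched:
        raise JoinError(f"active ids with no curated record: {unmatched}")
    table = pd.DataFrame(rows)
    table["cluster"] = table["cluster"].astype("Int64")
    table["bioactivity_rank"] = table["bioactivity_rank"].astype("Int64")
    return table


def cluster_fitness_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Five-number fitness summary (min, q1, median, q3, max) per cluster.

    Quartiles use linear interpolation; clusters with no active rows are
    simply absent from the output.
    """
    active_rows = table[table["label"] == ACTIVE].dropna(subset=["cluster"])
    out = []
    for cluster, group in active_rows.groupby("cluster", sort=True):
        values = group["fitness"].to_numpy(dtype=float)
        q = np.percentile(values, [0, 25, 50, 75, 100])
        out.append(
            {
                "cluster": int(cluster),
                "n": len(values),
                "min": q[0],
                "q1": q[1],
                "median": q[2],
                "q3": q[3],
                "max": q[4],
            }
        )
    return pd.DataFrame(out)
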