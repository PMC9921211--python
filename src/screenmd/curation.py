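"""Curation and potency ranking of a bioactive set.

A benchmarking study starts from a small set of compounds with measured
affinity for the target (here, inhibitors binding Fascin's actin-binding
site 2, each annotated with IC50 and/or Kd in µM and a chemotype cluster
label).  This module loads such a table, drops records with no usable
affinity, and assigns each retained compound:

* a *potency* — the most potent (smallest) determined affinity value,
* a *bioactivity rank* — dense rank 1..n ascending in potency,
* a *level of activity* (LOA) — the potency expressed in molar units,
* a *type of data* (TOD) tag — whether the potency came from an IC50 or
  a Kd measurement.

Affinity cells may read ``nd`` (not determined) or carry a ``<`` qualifier
(e.g. ``<100``); qualified values participate in cutoffs and ranking at
their nominal value but are flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, UndefinedPotencyError

logger = logging.getLogger(__name__)

__all__ = [
    "BioactiveRecord",
    "CuratedActiveSet",
    "load_active_table",
    "load_reference_actives",
    "curate",
    "potency",
    "bioactivity_ranks",
]

_REQUIRED_COLUMNS = ("id", "ic50", "kd", "cluster")
_NA_TOKENS = {"", "nd", "na", "n.d.", "none"}


@dataclass(frozen=True)
class BioactiveRecord:
    """One curated active with affinity data and a chemotype cluster label.

    Affinities are in µM; ``None`` means not determined.  ``*_qualified``
    marks values transcribed with a ``<`` qualifier.
    """

    id: str
    ic50: Optional[float] = None
    kd: Optional[float] = None
    cluster: int = 0
    smiles: Optional[str] = None
    name: Optional[str] = None
    ic50_qualified: bool = False
    kd_qualified: bool = False

    def __post_init__(self):
        for label, value in (("ic50", self.ic50), ("kd", self.kd)):
            if value is not None and not (math.isfinite(value) and value > 0):
                raise ValueError(f"{label} must be positive and finite, got {value!r}")
        if self.cluster < 0:
            raise ValueError(f"cluster label must be non-negative, got {self.cluster}")

    @property
    def has_affinity(self) -> bool:
        return self.ic50 is not None or self.kd is not None


def potency(record: BioactiveRecord) -> float:
    """Most potent determined affinity of ``record``, in µM.

    Defined as ``min`` over the determined values of {IC50, Kd}; raises
    :class:`UndefinedPotencyError` when neither is determined.
    """
    values = [v for v in (record.ic50, record.kd) if v is not None]
    if not values:
        raise UndefinedPotencyError(f"record {record.id!r} has no determined affinity")
    return min(values)


def _potency_source(record: BioactiveRecord) -> str:
    """TOD tag for the potency value: 'Kd' wins ties (direct binding assay)."""
    if record.kd is not None and (record.ic50 is None or record.kd <= record.ic50):
        return "Kd"
    return "IC50"


@dataclass
class CuratedActiveSet:
    """Ordered curated records with per-record rank, LOA and TOD annotations."""

    records: list[BioactiveRecord]
    bioactivity_rank: np.ndarray = field(init=False)
    loa: np.ndarray = field(init=False)
    tod: list[str] = field(init=False)

    def __post_init__(self):
        self.bioactivity_rank = bioactivity_ranks(self.records)
        # LOA: molar value of the best affinity (table is in µM).
        self.loa = np.array([potency(r) * 1e-6 for r in self.records], dtype=float)
        self.tod = [_potency_source(r) for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: str) -> BioactiveRecord:
        for r in self.records:
            if r.id == key:
                return r
        raise KeyError(key)

    def rank_of(self, record_id: str) -> int:
        for r, rank in zip(self.records, self.bioactivity_rank):
            if r.id == record_id:
                return int(rank)
        raise KeyError(record_id)

    @property
    def clusters(self) -> set[int]:
        return {r.cluster for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "name": [r.name for r in self.records],
                "ic50": [r.ic50 for r in self.records],
                "kd": [r.kd for r in self.records],
                "cluster": [r.cluster for r in self.records],
                "bioactivity_rank": self.bioactivity_rank,
                "loa": self.loa,
                "tod": self.tod,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _parse_affinity(cell, row_number: int, column: str) -> tuple[Optional[float], bool]:
    """Parse one affinity cell -> (value or None, qualified flag)."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None, False
    text = str(cell).strip()
    if text.lower() in _NA_TOKENS:
        return None, False
    qualified = text.startswith("<")
    if qualified:
        text = text[1:].strip()
    try:
        value = float(text)
    except ValueError:
        raise ParseError(
            f"row {row_number}: cannot parse {column} value {cell!r} "
            "(expected a number, '<number' or 'nd')"
        ) from None
    return value, qualified


def load_active_table(path: str | Path) -> list[BioactiveRecord]:
    """Read a delimited active table (CSV, or TSV by ``.tsv`` extension).

    Requires columns ``id``, ``ic50``, ``kd``, ``cluster`` (case-insensitive);
    ``smiles`` and ``name`` are optional.  Row order is preserved.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[BioactiveRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = row._asdict()
        ic50, ic50_q = _parse_affinity(row["ic50"], i, "ic50")
        kd, kd_q = _parse_affinity(row["kd"], i, "kd")
        try:
            cluster = int(str(row["cluster"]).strip())
        except ValueError:
            raise ParseError(
                f"row {i}: cannot parse cluster label {row['cluster']!r}"
            ) from None
        records.append(
            BioactiveRecord(
                id=str(row["id"]).strip(),
                ic50=ic50,
                kd=kd,
                cluster=cluster,
                smiles=(row.get("smiles") or "").strip() or None,
                name=(row.get("name") or "").strip() or None,
                ic50_qualified=ic50_q,
                kd_qualified=kd_q,
            )
        )
    return records


def load_reference_actives() -> list[BioactiveRecord]:
    """Load the packaged 25-compound Fascin binding-site-2 active table."""
    with resources.as_file(
        resources.files("screenmd.data") / "fascin_actives.csv"
    ) as path:
        return load_active_table(path)


def curate(
    records: Iterable[BioactiveRecord], kd_cutoff: float = 100.0
) -> CuratedActiveSet:
    """Retain records with at least one determined affinity ≤ ``kd_cutoff`` µM.

    Records whose only determined values exceed the cutoff (or that have no
    determined affinity at all) are dropped; each drop is logged.  An empty
    result is returned with a warning, never raised.
    """
    kept: list[BioactiveRecord] = []
    for record in records:
        values = [v for v in (record.ic50, record.kd) if v is not None]
        if values and min(values) <= kd_cutoff:
            kept.append(record)
        else:
            logger.info(
                "curate: dropping %s (affinities %s exceed %.3g µM or undetermined)",
                record.id,
                values or "none",
                kd_cutoff,
            )
    if not kept:
        logger.warning("curate: all records dropped (cutoff %.3g µM)", kd_cutoff)
    return CuratedActiveSet(records=kept)


def bioactivity_ranks(records: Sequence[BioactiveRecord]) -> np.ndarray:
    """Dense ascending-potency ranks 1..n; ties broken by input order."""
    potencies = np.array([potency(r) for r in records], dtype=float)
    order = np.argsort(potencies, kind="stable")
    ranks = np.empty(len(records), dtype=int)
    ranks[order] = np.arange(1, len(records) + 1)
    return ranks
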