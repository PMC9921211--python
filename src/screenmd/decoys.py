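"""Property-matched, topology-dissimilar decoy selection.

A credible virtual-screening benchmark embeds its actives in decoys that
share their physicochemical profile (so scoring functions cannot separate
the classes on bulk properties) while being topologically dissimilar (so no
decoy is a latent active).  This module implements that contract as a
greedy nearest-property selector:

1. each candidate gets a 7-component descriptor vector (MW, cLogP, H-bond
   donors/acceptors, rotatable bonds, aromatic rings, formal charge),
2. candidates whose maximum fingerprint Tanimoto similarity to any active
   reaches ``sim_threshold`` are excluded as latent actives,
3. for each active, in input order, the ``ratio`` unused eligible
   candidates with the smallest normalized property distance are taken.

The normalized property distance is the mean over descriptors of
``|a_i − b_i| / scale_i``; by default the scales are the actives' observed
descriptor ranges (1.0 where a range is zero), making the comparison
scale-free.  Selection is deterministic: candidate input order breaks
distance ties.

Descriptors and fingerprints for real molecules come from RDKit; synthetic
pools may supply property vectors and bit arrays directly, so the selector
itself needs no chemistry backend.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, ShortfallError

__all__ = [
    "DESCRIPTOR_NAMES",
    "PropertyVector",
    "CandidatePool",
    "DecoySet",
    "compute_properties",
    "compute_fingerprint",
    "normalized_property_distance",
    "default_scales",
    "tanimoto",
    "max_tanimoto_to_actives",
    "select_decoys",
]

DESCRIPTOR_NAMES = (
    "mw",
    "clogp",
    "hbd",
    "hba",
    "rotb",
    "aromatic_rings",
    "formal_charge",
)

DEFAULT_FP_BITS = 2048


@dataclass(frozen=True)
class PropertyVector:
    """Physicochemical descriptor vector used for decoy matching."""

    mw: float
    clogp: float
    hbd: int
    hba: int
    rotb: int
    aromatic_rings: int
    formal_charge: int

    def __post_init__(self):
        if self.mw <= 0:
            raise ValueError(f"mw must be positive, got {self.mw}")
        for name in ("hbd", "hba", "rotb", "aromatic_rings"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in DESCRIPTOR_NAMES], dtype=float)


def compute_properties(smiles: str) -> PropertyVector:
    """Descriptor vector of a molecule given as SMILES (via RDKit)."""
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    return PropertyVector(
        mw=Descriptors.MolWt(mol),
        clogp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        rotb=Lipinski.NumRotatableBonds(mol),
        aromatic_rings=rdMolDescriptors.CalcNumAromaticRings(mol),
        formal_charge=Chem.GetFormalCharge(mol),
    )


def compute_fingerprint(smiles: str, n_bits: int = DEFAULT_FP_BITS) -> np.ndarray:
    """Hashed circular-substructure (Morgan radius-2) bit vector as bool array."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    return np.array(gen.GetFingerprintAsNumPy(mol), dtype=bool)


def default_scales(actives: Sequence[PropertyVector]) -> np.ndarray:
    """Per-descriptor spans observed across the actives (0 → 1.0)."""
    matrix = np.array([a.as_array() for a in actives])
    spans = matrix.max(axis=0) - matrix.min(axis=0)
    spans[spans == 0] = 1.0
    return spans


def normalized_property_distance(
    a: PropertyVector, b: PropertyVector, scales: np.ndarray
) -> float:
    """Mean over descriptors of |a_i − b_i| / scale_i (0 iff a == b)."""
    scales = np.asarray(scales, dtype=float)
    if scales.shape != (len(DESCRIPTOR_NAMES),) or np.any(scales <= 0):
        raise ConfigurationError(
            f"scales must be {len(DESCRIPTOR_NAMES)} positive spans, got {scales!r}"
        )
    return float(np.mean(np.abs(a.as_array() - b.as_array()) / scales))


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| of two equal-length bit vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def max_tanimoto_to_actives(
    candidate: np.ndarray, actives: Sequence[np.ndarray]
) -> float:
    """Maximum Tanimoto similarity of ``candidate`` over the active set."""
    if len(actives) == 0:
        return 0.0
    return max(tanimoto(candidate, a) for a in actives)


@dataclass
class CandidatePool:
    """Candidate compounds for decoy selection.

    ``properties`` is an (n, 7) descriptor matrix in :data:`DESCRIPTOR_NAMES`
    order and ``fingerprints`` an (n, n_bits) bool array.
    """

    ids: list[str]
    properties: np.ndarray
    fingerprints: np.ndarray
    smiles: Optional[list[str]] = None

    def __post_init__(self):
        self.properties = np.asarray(self.properties, dtype=float)
        self.fingerprints = np.asarray(self.fingerprints, dtype=bool)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("candidate ids must be unique")
        if self.properties.shape != (n, len(DESCRIPTOR_NAMES)):
            raise ValueError(
                f"properties must be (n, {len(DESCRIPTOR_NAMES)}), "
                f"got {self.properties.shape}"
            )
        if self.fingerprints.ndim != 2 or self.fingerprints.shape[0] != n:
            raise ValueError("fingerprints must be an (n, n_bits) array")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_smiles(
        cls, entries: Sequence[tuple[str, str]], n_bits: int = DEFAULT_FP_BITS
    ) -> "CandidatePool":
        """Build a pool from (id, SMILES) pairs via RDKit."""
        ids, smiles = [str(i) for i, _ in entries], [s for _, s in entries]
        props = np.array([compute_properties(s).as_array() for s in smiles])
        fps = np.array([compute_fingerprint(s, n_bits) for s in smiles])
        return cls(ids=ids, properties=props, fingerprints=fps, smiles=smiles)

    @classmethod
    def from_property_csv(cls, path: str | Path) -> "CandidatePool":
        """Read a pool from CSV with id, the 7 descriptor columns, fingerprint.

        The fingerprint column holds a 0/1 string per candidate.
        """
        frame = pd.read_csv(path)
        fps = np.array(
            [[c == "1" for c in str(bits)] for bits in frame["fingerprint"]],
            dtype=bool,
        )
        return cls(
            ids=[str(i) for i in frame["id"]],
            properties=frame[list(DESCRIPTOR_NAMES)].to_numpy(dtype=float),
            fingerprints=fps,
        )

    def to_property_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.properties, columns=list(DESCRIPTOR_NAMES))
        frame.insert(0, "id", self.ids)
        frame["fingerprint"] = [
            "".join("1" if b else "0" for b in row) for row in self.fingerprints
        ]
        frame.to_csv(path, index=False)


@dataclass
class DecoySet:
    """Selected decoys with their matched active and match diagnostics."""

    table: pd.DataFrame  # decoy_id, matched_active, property_distance, max_tanimoto
    ratio: int
    sim_threshold: float

    def __len__(self) -> int:
        return len(self.table)

    @property
    def decoy_ids(self) -> list[str]:
        return list(self.table["decoy_id"])

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def select_decoys(
    actives: Sequence[tuple[str, PropertyVector, np.ndarray]],
    pool: CandidatePool,
    ratio: int = 30,
    sim_threshold: float = 0.3,
    scales: Optional[np.ndarray] = None,
) -> DecoySet:
    """Greedy property-matched decoy selection at ``ratio`` decoys per active.

    For each active in input order, takes the ``ratio`` unused eligible
    candidates closest in normalized property distance; candidates at or
    above ``sim_threshold`` maximum Tanimoto to *any* active (or sharing an
    active's id) are ineligible throughout.  Raises :class:`ShortfallError`
    naming the first active that cannot be served.
    """
    if ratio < 1:
        raise ConfigurationError(f"ratio must be >= 1, got {ratio}")
    if not actives:
        raise ConfigurationError("need at least one active")
    active_vectors = [pv for _, pv, _ in actives]
    active_fps = [np.asarray(fp, dtype=bool) for _, _, fp in actives]
    active_ids = {aid for aid, _, _ in actives}
    if scales is None:
        scales = default_scales(active_vectors)

    max_sim = np.array(
        [max_tanimoto_to_actives(fp, active_fps) for fp in pool.fingerprints]
    )
    eligible = (max_sim < sim_threshold) & np.array(
        [cid not in active_ids for cid in pool.ids]
    )

    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ConfigurationError("scales must be positive")
    used = np.zeros(len(pool), dtype=bool)
    rows = []
    for active_id, pv, _ in actives:
        available = np.flatnonzero(eligible & ~used)
        if len(available) < ratio:
            raise ShortfallError(active_id, needed=ratio, available=len(available))
        dists = (
            np.abs(pool.properties[available] - pv.as_array()) / scales
        ).mean(axis=1)
        take = available[np.argsort(dists, kind="stable")[:ratio]]
        used[take] = True
        order = np.argsort(dists, kind="stable")[:ratio]
        for idx, d in zip(take, dists[order]):
            rows.append(
                {
                    "decoy_id": pool.ids[idx],
                    "matched_active": active_id,
                    "property_distance": float(d),
                    "max_tanimoto": float(max_sim[idx]),
                }
            )
    return DecoySet(
        table=pd.DataFrame(rows), ratio=ratio, sim_threshold=sim_threshold
    )
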