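"""Synthetic inputs with known ground truth.

The benchmarking and trajectory modules consume outputs of docking engines
and MD engines.  At desk scale those engines are replaced by generators
whose ground truth is known exactly:

* **score lists** — active and decoy docking scores drawn from two normal
  distributions (lower-is-better, PLANTS-style); the active/decoy mean
  separation controls ranking difficulty (10σ ⇒ perfect separation, 0 ⇒
  random ranking),
* **property pools** — candidate descriptor vectors either perturbed from
  the actives (property-matched) or drawn from broad ranges, with sparse
  random fingerprints that stay dissimilar to any active,
* **toy trajectories** — harmonic per-atom oscillations with known
  amplitudes (RMSF → a/√2), i.i.d. Gaussian jitter (RMSF → σ√3), or a
  rigid-body drift (zero RMSD after superposition).

Every generator takes an explicit integer seed and is bit-reproducible;
the seed and ground-truth parameters are recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .decoys import DEFAULT_FP_BITS, CandidatePool, PropertyVector
from .screening import RankedLibrary
from .trajectory import Trajectory

__all__ = [
    "ScoreSimSpec",
    "TrajSimSpec",
    "simulate_scores",
    "simulate_actives",
    "simulate_pool",
    "simulate_trajectory",
    "make_reference_coords",
]


@dataclass(frozen=True)
class ScoreSimSpec:
    """Two-Gaussian score-list model (lower score = better pose)."""

    n_actives: int
    n_decoys: int
    mu_active: float = -110.0
    mu_decoy: float = -90.0
    sigma: float = 8.0
    seed: int = 0
    n_clusters: int = 7

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_actives < 0 or self.n_decoys < 0:
            raise ValueError("counts must be non-negative")


def simulate_scores(spec: ScoreSimSpec) -> RankedLibrary:
    """Draw a labeled, score-ordered library from the two-Gaussian model.

    Actives carry cyclic chemotype cluster labels 1..n_clusters so that
    chemotype joins can be exercised; decoys carry none.
    """
    rng = np.random.default_rng(spec.seed)
    active_scores = rng.normal(spec.mu_active, spec.sigma, spec.n_actives)
    decoy_scores = rng.normal(spec.mu_decoy, spec.sigma, spec.n_decoys)
    ids = [f"A{i+1:04d}" for i in range(spec.n_actives)] + [
        f"D{i+1:05d}" for i in range(spec.n_decoys)
    ]
    labels = ["active"] * spec.n_actives + ["decoy"] * spec.n_decoys
    clusters = [i % spec.n_clusters + 1 for i in range(spec.n_actives)] + [
        pd.NA
    ] * spec.n_decoys
    return RankedLibrary.from_records(
        ids=ids,
        labels=labels,
        scores=np.concatenate([active_scores, decoy_scores]),
        clusters=clusters,
        lower_is_better=True,
    )


#: broad drug-like descriptor ranges used when sampling unmatched candidates
_BROAD_RANGES = {
    "mw": (100.0, 900.0),
    "clogp": (-3.0, 8.0),
    "hbd": (0, 8),
    "hba": (0, 14),
    "rotb": (0, 15),
    "aromatic_rings": (0, 6),
    "formal_charge": (-2, 2),
}

_FP_DENSITY = 0.05  # sparse random fingerprints: expected pairwise Tanimoto ≈ 0.026


def _random_fingerprints(rng, n: int, n_bits: int) -> np.ndarray:
    return rng.random((n, n_bits)) < _FP_DENSITY


def simulate_actives(
    n: int, seed: int = 0, n_bits: int = DEFAULT_FP_BITS
) -> list[tuple[str, PropertyVector, np.ndarray]]:
    """Drug-like synthetic actives: (id, property vector, fingerprint)."""
    rng = np.random.default_rng(seed)
    fps = _random_fingerprints(rng, n, n_bits)
    out = []
    for i in range(n):
        pv = PropertyVector(
            mw=float(rng.uniform(250, 550)),
            clogp=float(rng.uniform(0, 5)),
            hbd=int(rng.integers(0, 5)),
            hba=int(rng.integers(2, 10)),
            rotb=int(rng.integers(0, 10)),
            aromatic_rings=int(rng.integers(1, 5)),
            formal_charge=int(rng.integers(-1, 2)),
        )
        out.append((f"ACT{i+1:03d}", pv, fps[i]))
    return out


def simulate_pool(
    n: int,
    actives: Sequence[PropertyVector],
    match_fraction: float = 1.0,
    seed: int = 0,
    n_bits: int = DEFAULT_FP_BITS,
) -> CandidatePool:
    """Candidate pool with a controllable fraction of property-matched entries.

    A matched candidate perturbs a randomly chosen active's descriptors
    (±2% on MW, ±0.1 log units on cLogP, ±1 on counts); the remainder are
    drawn uniformly from broad drug-like ranges.  All fingerprints are
    sparse random bit vectors, far below any latent-active threshold.
    """
    if not (0 <= match_fraction <= 1):
        raise ValueError("match_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if n == 0:
        return CandidatePool(
            ids=[],
            properties=np.empty((0, 7)),
            fingerprints=np.empty((0, n_bits), dtype=bool),
        )
    n_matched = int(round(match_fraction * n))
    rows = []
    for i in range(n):
        if i < n_matched and len(actives):
            base = actives[int(rng.integers(len(actives)))]
            pv = PropertyVector(
                mw=float(base.mw * (1 + rng.normal(0, 0.02))),
                clogp=float(base.clogp + rng.normal(0, 0.1)),
                hbd=int(max(0, base.hbd + rng.integers(-1, 2))),
                hba=int(max(0, base.hba + rng.integers(-1, 2))),
                rotb=int(max(0, base.rotb + rng.integers(-1, 2))),
                aromatic_rings=int(max(0, base.aromatic_rings + rng.integers(-1, 2))),
                formal_charge=int(base.formal_charge),
            )
        else:
            pv = PropertyVector(
                mw=float(rng.uniform(*_BROAD_RANGES["mw"])),
                clogp=float(rng.uniform(*_BROAD_RANGES["clogp"])),
                hbd=int(rng.integers(_BROAD_RANGES["hbd"][0], _BROAD_RANGES["hbd"][1] + 1)),
                hba=int(rng.integers(_BROAD_RANGES["hba"][0], _BROAD_RANGES["hba"][1] + 1)),
                rotb=int(rng.integers(_BROAD_RANGES["rotb"][0], _BROAD_RANGES["rotb"][1] + 1)),
                aromatic_rings=int(
                    rng.integers(
                        _BROAD_RANGES["aromatic_rings"][0],
                        _BROAD_RANGES["aromatic_rings"][1] + 1,
                    )
                ),
                formal_charge=int(
                    rng.integers(
                        _BROAD_RANGES["formal_charge"][0],
                        _BROAD_RANGES["formal_charge"][1] + 1,
                    )
                ),
            )
        rows.append(pv.as_array())
    return CandidatePool(
        ids=[f"P{i+1:05d}" for i in range(n)],
        properties=np.array(rows),
        fingerprints=_random_fingerprints(rng, n, n_bits),
    )


@dataclass(frozen=True)
class TrajSimSpec:
    """Toy trajectory model with known fluctuation ground truth.

    ``amplitude`` is the per-atom motion scale in Å: the sinusoid amplitude
    (harmonic), per-axis standard deviation (gaussian), or total rigid
    displacement over the run (drift).  A scalar applies to every atom.
    """

    reference: np.ndarray
    n_frames: int = 2000
    dt: float = 1.0  # ps
    amplitude: float | np.ndarray = 1.0
    mode: str = "harmonic"
    seed: int = 0
    n_periods: int = 5
    atoms: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.mode not in {"harmonic", "gaussian", "drift"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if np.any(np.asarray(self.amplitude) < 0):
            raise ValueError("amplitudes must be non-negative")


def make_reference_coords(n_atoms: int, seed: int = 0, spread: float = 15.0) -> np.ndarray:
    """A compact random-blob reference structure (n_atoms, 3), Å."""
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, spread / 3.0, (n_atoms, 3))


def _default_atoms(n_atoms: int) -> pd.DataFrame:
    """Pseudo Cα-only protein atom table (one residue per atom)."""
    return pd.DataFrame(
        {
            "name": ["CA"] * n_atoms,
            "element": ["C"] * n_atoms,
            "mass": [12.011] * n_atoms,
            "resid": np.arange(1, n_atoms + 1),
            "resname": ["ALA"] * n_atoms,
            "chain": ["A"] * n_atoms,
            "segment": ["protein"] * n_atoms,
        }
    )


def simulate_trajectory(spec: TrajSimSpec) -> Trajectory:
    """Generate a toy trajectory; ground truth goes into ``Trajectory.meta``."""
    rng = np.random.default_rng(spec.seed)
    ref = np.asarray(spec.reference, dtype=float)
    n_atoms = len(ref)
    amps = np.broadcast_to(np.asarray(spec.amplitude, dtype=float), (n_atoms,)).copy()
    times = np.arange(spec.n_frames) * spec.dt

    if spec.mode == "harmonic":
        directions = rng.normal(size=(n_atoms, 3))
        norms = np.linalg.norm(directions, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        directions /= norms
        phases = rng.uniform(0, 2 * np.pi, n_atoms)
        omega = 2 * np.pi * spec.n_periods / (spec.n_frames * spec.dt)
        osc = amps[None, :] * np.sin(omega * times[:, None] + phases[None, :])
        coords = ref[None, :, :] + osc[:, :, None] * directions[None, :, :]
    elif spec.mode == "gaussian":
        jitter = rng.normal(size=(spec.n_frames, n_atoms, 3)) * amps[None, :, None]
        coords = ref[None, :, :] + jitter
    else:  # drift: rigid translation ramp
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        frac = times / times[-1] if times[-1] > 0 else times
        displacement = amps.mean() * frac[:, None] * direction[None, :]
        coords = ref[None, :, :] + displacement[:, None, :]

    atoms = spec.atoms if spec.atoms is not None else _default_atoms(n_atoms)
    meta = {
        "generator": "screenmd.synthetic.simulate_trajectory",
        "mode": spec.mode,
        "seed": spec.seed,
        "dt_ps": spec.dt,
        "amplitude": amps,
        "n_periods": spec.n_periods,
    }
    return Trajectory(coords=coords, atoms=atoms, times=times, meta=meta)
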