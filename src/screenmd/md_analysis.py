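"""Trajectory post-analysis: RMSD, RMSF, RoG, H-bonds, distances, PCA, FEL.

All operations act on a :class:`~screenmd.trajectory.Trajectory` and a
selection mask (or expression).  Internal units are Å and ps; distance
series are reported in nm (divide Å by 10), RMSD/RMSF/RoG in Å.

Superposition is a closed-form least-squares rigid-body fit (Kabsch SVD
with the proper-rotation determinant correction).  RMSF is measured about
the time-mean structure after two passes of superposition to it.  PCA
diagonalizes the covariance of the 3N selected coordinates across frames
(via SVD of the centered frame matrix); the free-energy landscape is the
Boltzmann inversion −kT ln(counts/max counts) of the 2-D histogram of two
principal-component projections, in kcal/mol, with the most populated bin
at ΔG = 0 and empty bins at +inf.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DegenerateFitError, SelectionError
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "kabsch",
    "superpose",
    "rmsd_series",
    "atomic_rmsf",
    "rmsf",
    "radius_of_gyration",
    "rog_series",
    "hbond_count_series",
    "com_distance_series",
    "min_distance_series",
    "pca",
    "PCAResult",
    "free_energy_landscape",
    "FELGrid",
    "BOLTZMANN_KCAL",
]

#: Boltzmann constant in kcal/(mol·K)
BOLTZMANN_KCAL = 0.0019872

SelectionLike = Union[str, np.ndarray]


def _mask(traj: Trajectory, sel: Optional[SelectionLike]) -> np.ndarray:
    if sel is None:
        return np.ones(traj.n_atoms, dtype=bool)
    if isinstance(sel, str):
        return traj.select(sel)
    mask = np.asarray(sel, dtype=bool)
    if not mask.any():
        raise SelectionError("selection mask matches no atoms")
    return mask


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t with reference ≈ mobile @ R.T + t.

    Both inputs are (n, 3) paired point sets.  The rotation is proper
    (det = +1); degenerate sets (<3 points, or collinear) raise.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(mobile) < 3:
        raise DegenerateFitError(
            f"rotational fit needs >= 3 atoms, got {len(mobile)}"
        )
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-10) < 2:
        raise DegenerateFitError("selected atoms are collinear; rotation is undefined")
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = reference.mean(axis=0) - mobile.mean(axis=0) @ r.T
    return r, t


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    sel: Optional[np.ndarray] = None,
    rotate: bool = True,
) -> tuple[np.ndarray, float]:
    """Least-squares fit of a full frame onto a reference over a selection.

    The transform is computed on the selected atoms and applied to the whole
    frame; the returned RMSD is post-fit over the selection.  With
    ``rotate=False`` only centroids are matched (valid for any atom count).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mask = (
        np.ones(len(mobile), dtype=bool) if sel is None else np.asarray(sel, dtype=bool)
    )
    if rotate:
        r, t = kabsch(mobile[mask], reference[mask])
        moved = mobile @ r.T + t
    else:
        t = reference[mask].mean(axis=0) - mobile[mask].mean(axis=0)
        moved = mobile + t
    diff = moved[mask] - reference[mask]
    rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return moved, rmsd


def rmsd_series(
    traj: Trajectory,
    reference: Optional[np.ndarray] = None,
    sel: Optional[SelectionLike] = None,
    rotate: bool = True,
) -> np.ndarray:
    """Per-frame post-superposition RMSD (Å) over a selection.

    ``reference`` defaults to the first frame.
    """
    mask = _mask(traj, sel)
    if reference is None:
        reference = traj.coords[0]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, out[i] = superpose(traj.coords[i], reference, mask, rotate=rotate)
    return out


def _superposed_coords(
    coords: np.ndarray, superpose_first: bool, passes: int = 2
) -> np.ndarray:
    """Align frames of a (F, n, 3) stack to their mean structure (2 passes)."""
    if not superpose_first:
        return coords
    aligned = coords.copy()
    for _ in range(passes):
        mean = aligned.mean(axis=0)
        for i in range(len(aligned)):
            aligned[i], _ = superpose(aligned[i], mean)
    return aligned


def atomic_rmsf(
    traj: Trajectory,
    sel: Optional[SelectionLike] = None,
    superpose_first: bool = True,
) -> np.ndarray:
    """Per-atom RMSF (Å): sqrt of time-mean squared deviation from the
    time-mean position, optionally after superposing frames to the mean."""
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    mask = _mask(traj, sel)
    coords = _superposed_coords(traj.coords[:, mask], superpose_first)
    mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))


def rmsf(
    traj: Trajectory,
    sel: Optional[SelectionLike] = None,
    superpose_first: bool = True,
) -> pd.Series:
    """Per-residue RMSF (Å), indexed by residue number.

    Protein residues report their Cα atom's RMSF; residues of other
    segments (ligands etc.) report the mean over their atoms.
    """
    mask = _mask(traj, sel)
    per_atom = atomic_rmsf(traj, mask, superpose_first=superpose_first)
    atoms = traj.atoms[mask].reset_index(drop=True)
    atoms = atoms.assign(rmsf=per_atom)
    values = {}
    for resid, group in atoms.groupby("resid", sort=True):
        if (group["segment"] == "protein").any():
            ca = group[group["name"] == "CA"]
            values[resid] = (
                float(ca["rmsf"].iloc[0]) if len(ca) else float(group["rmsf"].mean())
            )
        else:
            values[resid] = float(group["rmsf"].mean())
    return pd.Series(values, name="rmsf").rename_axis("resid")


def radius_of_gyration(
    frame: np.ndarray,
    masses: Optional[np.ndarray] = None,
    mass_weighted: bool = True,
) -> float:
    """RoG (Å): sqrt(Σ m_i |r_i − r_com|² / Σ m_i); unit masses if unweighted."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 3 or len(frame) == 0:
        raise ValueError("frame must be a non-empty (n, 3) array")
    if not mass_weighted or masses is None:
        masses = np.ones(len(frame))
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * frame).sum(axis=0) / total
    return float(np.sqrt((masses * ((frame - com) ** 2).sum(axis=1)).sum() / total))


def rog_series(
    traj: Trajectory,
    sel: Optional[SelectionLike] = None,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame radius of gyration (Å) over a selection."""
    mask = _mask(traj, sel)
    masses = traj.masses[mask] if mass_weighted else None
    return np.array(
        [
            radius_of_gyration(frame[mask], masses, mass_weighted=mass_weighted)
            for frame in traj.coords
        ]
    )


def _attached_hydrogens(
    traj: Trajectory, donor_indices: np.ndarray, bond_cut: float = 1.25
) -> dict[int, list[int]]:
    """Map each donor heavy atom to hydrogens within ``bond_cut`` Å (frame 0)."""
    elements = traj.atoms["element"].astype(str).str.upper().to_numpy()
    h_idx = np.flatnonzero(elements == "H")
    frame0 = traj.coords[0]
    attached: dict[int, list[int]] = {}
    for d in donor_indices:
        if len(h_idx):
            dist = np.linalg.norm(frame0[h_idx] - frame0[d], axis=1)
            attached[d] = [int(h) for h in h_idx[dist <= bond_cut]]
        else:
            attached[d] = []
        if not attached[d]:
            logger.warning("hbond: donor atom index %d has no attached hydrogen", d)
    return attached


def hbond_count_series(
    traj: Trajectory,
    donors: SelectionLike,
    acceptors: SelectionLike,
    d_cut: float = 3.5,
    angle_cut: float = 30.0,
) -> np.ndarray:
    """Per-frame hydrogen-bond count between donor and acceptor selections.

    A donor–acceptor pair counts once per frame when the heavy-atom D···A
    distance is ≤ ``d_cut`` Å and some attached hydrogen gives a D–H···A
    angle ≥ 180° − ``angle_cut``.  Hydrogens are resolved by covalent
    distance to the donor in the first frame; donors without one are
    skipped with a warning.
    """
    donor_idx = np.flatnonzero(_mask(traj, donors))
    acceptor_idx = np.flatnonzero(_mask(traj, acceptors))
    attached = _attached_hydrogens(traj, donor_idx)
    donor_idx = np.array([d for d in donor_idx if attached[d]], dtype=int)
    min_angle = math.radians(180.0 - angle_cut)

    counts = np.zeros(traj.n_frames, dtype=int)
    for f, frame in enumerate(traj.coords):
        n = 0
        for d in donor_idx:
            da = np.linalg.norm(frame[acceptor_idx] - frame[d], axis=1)
            for a, dist in zip(acceptor_idx, da):
                if a == d or dist > d_cut:
                    continue
                for h in attached[d]:
                    hd = frame[d] - frame[h]
                    ha = frame[a] - frame[h]
                    denom = np.linalg.norm(hd) * np.linalg.norm(ha)
                    if denom == 0:
                        continue
                    angle = math.acos(np.clip(hd @ ha / denom, -1.0, 1.0))
                    if angle >= min_angle:
                        n += 1
                        break
        counts[f] = n
    return counts


def _com(frame: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return (masses[:, None] * frame).sum(axis=0) / masses.sum()


def com_distance_series(
    traj: Trajectory, a: SelectionLike, b: SelectionLike
) -> np.ndarray:
    """Per-frame |COM(a) − COM(b)| in nm (mass-weighted centers)."""
    mask_a, mask_b = _mask(traj, a), _mask(traj, b)
    m_a, m_b = traj.masses[mask_a], traj.masses[mask_b]
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.coords):
        out[i] = np.linalg.norm(_com(frame[mask_a], m_a) - _com(frame[mask_b], m_b))
    return out / 10.0


def min_distance_series(
    traj: Trajectory, a: SelectionLike, b: SelectionLike
) -> np.ndarray:
    """Per-frame minimum atom-pair distance between two selections, in nm."""
    mask_a, mask_b = _mask(traj, a), _mask(traj, b)
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.coords):
        out[i] = cdist(frame[mask_a], frame[mask_b]).min()
    return out / 10.0


@dataclass
class PCAResult:
    """Eigendecomposition of the 3N coordinate covariance across frames."""

    eigenvalues: np.ndarray  # descending, Å²
    eigenvectors: np.ndarray  # (3N, k), columns are modes
    projections: np.ndarray  # (frames, k), Å
    mean: np.ndarray  # (N, 3) mean structure


def pca(
    traj: Trajectory,
    sel: Optional[SelectionLike] = None,
    superpose_first: bool = True,
) -> PCAResult:
    """Principal component analysis of atomic fluctuations.

    Frames are superposed to the mean structure (unless disabled), the
    selected coordinates flattened to 3N, and the covariance matrix across
    frames diagonalized.  Projections are the centered coordinates on each
    eigenvector; their variance (ddof=1) equals the eigenvalue.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA requires at least 2 frames")
    mask = _mask(traj, sel)
    coords = _superposed_coords(traj.coords[:, mask], superpose_first)
    flat = coords.reshape(traj.n_frames, -1)
    centered = flat - flat.mean(axis=0)
    # economy SVD of the centered frame matrix: cov = V s² Vᵀ / (F−1)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (traj.n_frames - 1)
    eigenvectors = vt.T
    projections = centered @ eigenvectors
    return PCAResult(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        projections=projections,
        mean=coords.mean(axis=0),
    )


@dataclass
class FELGrid:
    """2-D binned free-energy surface over two PC projections."""

    pc1_edges: np.ndarray
    pc2_edges: np.ndarray
    counts: np.ndarray
    delta_g: np.ndarray  # kcal/mol; +inf for empty bins
    kt: float  # kcal/mol
    temperature: float  # K

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per bin with centers, count and ΔG."""
        c1 = 0.5 * (self.pc1_edges[:-1] + self.pc1_edges[1:])
        c2 = 0.5 * (self.pc2_edges[:-1] + self.pc2_edges[1:])
        i, j = np.meshgrid(np.arange(len(c1)), np.arange(len(c2)), indexing="ij")
        return pd.DataFrame(
            {
                "pc1": c1[i.ravel()],
                "pc2": c2[j.ravel()],
                "count": self.counts.ravel(),
                "delta_g": self.delta_g.ravel(),
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def free_energy_landscape(
    pc1: np.ndarray,
    pc2: np.ndarray,
    bins: int = 50,
    temperature: float = 300.0,
) -> FELGrid:
    """Boltzmann-inverted occupancy histogram over two projections.

    ΔG_bin = −kT ln(count_bin / count_max) with kT = 0.0019872·T kcal/mol;
    the most-populated bin sits at ΔG = 0 and empty bins at +inf.
    """
    pc1 = np.asarray(pc1, dtype=float)
    pc2 = np.asarray(pc2, dtype=float)
    if pc1.shape != pc2.shape or pc1.ndim != 1:
        raise ValueError("projections must be equal-length 1-D arrays")
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    counts, e1, e2 = np.histogram2d(pc1, pc2, bins=bins)
    kt = BOLTZMANN_KCAL * temperature
    with np.errstate(divide="ignore"):
        delta_g = -kt * np.log(counts / counts.max())
    delta_g[counts == 0] = np.inf
    return FELGrid(
        pc1_edges=e1,
        pc2_edges=e2,
        counts=counts,
        delta_g=delta_g,
        kt=kt,
        temperature=temperature,
    )
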