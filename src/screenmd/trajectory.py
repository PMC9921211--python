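"""Trajectory container, atom-selection mini-language, and file I/O.

A :class:`Trajectory` holds frames × atoms × 3 coordinates in Å, per-frame
times in ps, and a per-atom metadata table (name, element, mass, residue
number/name, chain, segment class).  The segment class partitions atoms
into ``protein`` / ``ligand`` / ``solvent``, which the selection language
exposes as bare keywords.

Selections are boolean expressions over atoms::

    protein and name CA
    resid 214 215 216
    segment ligand or resname LIG
    not element H

Grammar: ``or`` < ``and`` < ``not`` < primary; primaries are ``all``,
``protein``/``ligand``/``solvent``, and ``name|element|resid|resname|
chain|segment`` followed by one or more values (``resid`` also accepts
``a:b`` inclusive ranges).  Parentheses group.

On disk a trajectory is a multi-model PDB (or XYZ) for coordinates, read
and written through MDAnalysis, plus a sidecar atom-metadata CSV (masses
and segment classes do not survive PDB round-trips) and a JSON file with
times and generator ground-truth metadata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import SelectionError

__all__ = ["Trajectory", "select", "save_trajectory", "load_trajectory"]

ATOM_COLUMNS = ("name", "element", "mass", "resid", "resname", "chain", "segment")
SEGMENT_CLASSES = ("protein", "ligand", "solvent")


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinates (Å) with atom metadata and times (ps)."""

    coords: np.ndarray
    atoms: pd.DataFrame
    times: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite (no missing atoms)")
        missing = set(ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError("atom table length does not match coordinate array")
        if np.any(self.atoms["mass"].to_numpy(dtype=float) <= 0):
            raise ValueError("atom masses must be positive")
        if self.times is None:
            self.times = np.arange(self.coords.shape[0], dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length does not match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def masses(self) -> np.ndarray:
        return self.atoms["mass"].to_numpy(dtype=float)

    def select(self, expr: str) -> np.ndarray:
        """Boolean atom mask for a selection expression (see module docs)."""
        return select(self.atoms, expr)


# ---------------------------------------------------------------------------
# selection mini-language


def _tokenize(expr: str) -> list[str]:
    out = []
    for raw in expr.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


_FIELD_KEYWORDS = {"name", "element", "resid", "resname", "chain", "segment"}
# tokens that terminate a field's value list (segment-class words such as
# "ligand" must stay usable as values after the `segment` keyword)
_STOP_TOKENS = {"and", "or", "not", "(", ")"} | _FIELD_KEYWORDS


class _Parser:
    def __init__(self, atoms: pd.DataFrame, tokens: list[str]):
        self.atoms = atoms
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.parse_or()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def parse_or(self) -> np.ndarray:
        mask = self.parse_and()
        while self.peek() == "or":
            self.take()
            mask = mask | self.parse_and()
        return mask

    def parse_and(self) -> np.ndarray:
        mask = self.parse_not()
        while self.peek() == "and":
            self.take()
            mask = mask & self.parse_not()
        return mask

    def parse_not(self) -> np.ndarray:
        if self.peek() == "not":
            self.take()
            return ~self.parse_not()
        return self.parse_primary()

    def parse_primary(self) -> np.ndarray:
        tok = self.take()
        if tok == "(":
            mask = self.parse_or()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        if tok == "all":
            return np.ones(len(self.atoms), dtype=bool)
        if tok in SEGMENT_CLASSES:
            return self.atoms["segment"].to_numpy() == tok
        if tok in _FIELD_KEYWORDS:
            values = []
            while self.peek() is not None and self.peek() not in _STOP_TOKENS:
                values.append(self.take())
            if not values:
                raise SelectionError(f"{tok!r} requires at least one value")
            return self._field_mask(tok, values)
        raise SelectionError(f"unknown selection token {tok!r}")

    def _field_mask(self, fieldname: str, values: list[str]) -> np.ndarray:
        if fieldname == "resid":
            resids = self.atoms["resid"].to_numpy(dtype=int)
            mask = np.zeros(len(self.atoms), dtype=bool)
            for v in values:
                if ":" in v:
                    lo, hi = v.split(":", 1)
                    mask |= (resids >= int(lo)) & (resids <= int(hi))
                else:
                    mask |= resids == int(v)
            return mask
        column = self.atoms[fieldname].astype(str).to_numpy()
        return np.isin(column, values)


def select(atoms: pd.DataFrame, expr: str) -> np.ndarray:
    """Evaluate a selection expression over an atom table; non-empty result."""
    tokens = _tokenize(expr)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(atoms, tokens).parse()
    if not mask.any():
        raise SelectionError(f"selection {expr!r} matches no atoms")
    return mask


# ---------------------------------------------------------------------------
# file I/O (coordinates via MDAnalysis; metadata as CSV + JSON sidecars)


def save_trajectory(traj: Trajectory, basepath: str | Path, fmt: str = "pdb") -> dict:
    """Write ``<base>.pdb`` (or ``.xyz``), ``<base>.atoms.csv``, ``<base>.meta.json``.

    Returns the paths written.  Coordinates go through MDAnalysis; the atom
    table and times/ground-truth metadata ride in plain-text sidecars.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    if fmt not in {"pdb", "xyz"}:
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    coord_path = basepath.with_suffix(f".{fmt}")
    atoms_path = basepath.with_suffix(".atoms.csv")
    meta_path = basepath.with_suffix(".meta.json")

    atoms = traj.atoms
    resids = atoms["resid"].to_numpy(dtype=int)
    # consecutive-residue index for MDAnalysis topology
    boundaries = np.r_[True, np.diff(resids) != 0]
    resindex = np.cumsum(boundaries) - 1
    n_res = int(resindex[-1]) + 1
    u = mda.Universe.empty(
        n_atoms=traj.n_atoms,
        n_residues=n_res,
        atom_resindex=resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", atoms["name"].to_numpy(dtype=object))
    u.add_TopologyAttr("elements", atoms["element"].to_numpy(dtype=object))
    u.add_TopologyAttr("resids", resids[boundaries])
    u.add_TopologyAttr("resnames", atoms["resname"].to_numpy(dtype=object)[boundaries])
    u.add_TopologyAttr("segids", ["SYS"])
    u.load_new(traj.coords.astype(np.float64), format=MemoryReader)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(coord_path), n_atoms=traj.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)

    atoms.to_csv(atoms_path, index=False)
    meta = {"times_ps": traj.times.tolist(), "format": fmt}
    meta.update(_json_safe(traj.meta))
    meta_path.write_text(json.dumps(meta, indent=1))
    return {"coords": coord_path, "atoms": atoms_path, "meta": meta_path}


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    return obj


def load_trajectory(basepath: str | Path) -> Trajectory:
    """Load a trajectory written by :func:`save_trajectory`."""
    import MDAnalysis as mda

    basepath = Path(basepath)
    atoms = pd.read_csv(basepath.with_suffix(".atoms.csv"))
    meta_path = basepath.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    fmt = meta.get("format", "pdb")
    coord_path = basepath.with_suffix(f".{fmt}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(coord_path))
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    times = np.asarray(meta.pop("times_ps", np.arange(coords.shape[0])), dtype=float)
    meta.pop("format", None)
    return Trajectory(coords=coords, atoms=atoms, times=times, meta=meta)
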