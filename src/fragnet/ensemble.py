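"""Conformational-ensemble container and structure I/O.

The central data structure is :class:`ConformerEnsemble`: a stack of F frames
over a fixed atom table (A atoms), as produced by ensemble generators
(tCONCOORD-style samplers, MD trajectories dumped as multi-model PDB) or by
the synthetic generators in :mod:`fragnet.synth`.

Supported on-disk formats are multi-model PDB (MODEL/ENDMDL records, parsed
with gemmi) and a plain whitespace/tab coordinate table with columns
``frame chain resid resname atom x y z``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "AtomSelection",
    "ConformerEnsemble",
    "MalformedEnsembleError",
    "SelectionError",
    "read_ensemble",
    "select_subset",
    "write_annotated_pdb",
    "write_multimodel_pdb",
]


class MalformedEnsembleError(ValueError):
    """The file does not describe a consistent multi-frame ensemble."""


class SelectionError(ValueError):
    """An atom selection matched nothing."""


@dataclass(frozen=True)
class Atom:
    """One row of the atom table shared by all frames."""

    atom_index: int
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    residue_key: str = ""  # residue_index + insertion code, e.g. "52A"

    def __post_init__(self):
        if not self.residue_key:
            object.__setattr__(self, "residue_key", str(self.residue_index))


@dataclass
class AtomSelection:
    """Chain / residue-range / atom-name selection in author numbering.

    ``residue_range`` is inclusive on both ends; ``None`` leaves that axis
    unrestricted.  ``atom_names={"CA"}`` gives the usual Cα-only view.
    """

    chain_id: str | None = None
    residue_range: tuple[int, int] | None = None
    atom_names: frozenset[str] | None = None

    def __post_init__(self):
        if self.residue_range is not None:
            start, end = self.residue_range
            if start > end:
                raise ValueError(f"residue_range start {start} > end {end}")
        if self.atom_names is not None:
            self.atom_names = frozenset(self.atom_names)

    def matches(self, atom: Atom) -> bool:
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not lo <= atom.residue_index <= hi:
                return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        return True


# CA-only convenience used throughout the analysis modules.
CA_ONLY = AtomSelection(atom_names=frozenset({"CA"}))


@dataclass
class ConformerEnsemble:
    """F frames x A atoms x 3 coordinates (Å) with per-atom annotation.

    Attributes
    ----------
    atoms : list[Atom]
        Shared atom table; identical for every frame.
    coords : ndarray, shape (F, A, 3)
        Cartesian coordinates in Å.
    frame_interval : float | None
        Time between frames in ns (``None`` for time-free ensembles such as
        constraint-sampled conformer sets).
    source_label : str
        Free-text provenance.
    """

    atoms: list[Atom]
    coords: np.ndarray
    frame_interval: float | None = None
    source_label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (F, A, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coords has {self.coords.shape[1]} atoms but table has {len(self.atoms)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in ensemble")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def atom_indices(self, sel: AtomSelection) -> np.ndarray:
        """Indices (into the atom table) of atoms matching *sel*."""
        idx = np.array([i for i, a in enumerate(self.atoms) if sel.matches(a)], dtype=int)
        return idx

    def ca_indices(self) -> np.ndarray:
        return self.atom_indices(CA_ONLY)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, residue_index, residue_name) triples."""
        out: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_index)
            if key not in seen:
                seen.add(key)
                out.append((a.chain_id, a.residue_index, a.residue_name))
        return out

    def with_coords(self, coords: np.ndarray) -> "ConformerEnsemble":
        return ConformerEnsemble(
            atoms=self.atoms,
            coords=coords,
            frame_interval=self.frame_interval,
            source_label=self.source_label,
        )


# ---------------------------------------------------------------------------
# Reading


def _pick_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: keep highest occupancy, ties -> first."""
    best: dict[str, gemmi.Atom] = {}
    for at in residue:
        prev = best.get(at.name)
        if prev is None or at.occ > prev.occ + 1e-9:
            best[at.name] = at
    # preserve file order of first appearance
    order: list[str] = []
    for at in residue:
        if at.name not in order:
            order.append(at.name)
    return [best[name] for name in order]


def _element_of(at: gemmi.Atom) -> str:
    el = at.element.name
    if el and el != "X":
        return el
    # infer from the atom name: strip digits, take leading letter(s)
    name = at.name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _read_multimodel_pdb(path: Path) -> ConformerEnsemble:
    structure = gemmi.read_pdb(str(path))
    if len(structure) == 0:
        raise MalformedEnsembleError(f"{path}: no models found")
    frames: list[np.ndarray] = []
    atoms: list[Atom] | None = None
    ref_keys: list[tuple[str, str, str]] | None = None
    for model_no, model in enumerate(structure, start=1):
        model_atoms: list[Atom] = []
        xyz: list[tuple[float, float, float]] = []
        idx = 0
        for chain in model:
            for res in chain:
                if res.is_water():
                    continue
                for at in _pick_altloc(res):
                    seqid = res.seqid
                    icode = seqid.icode.strip()
                    model_atoms.append(
                        Atom(
                            atom_index=idx,
                            atom_name=at.name,
                            element=_element_of(at),
                            residue_index=seqid.num,
                            residue_name=res.name,
                            chain_id=chain.name,
                            residue_key=f"{seqid.num}{icode}",
                        )
                    )
                    xyz.append((at.pos.x, at.pos.y, at.pos.z))
                    idx += 1
        keys = [(a.chain_id, a.residue_key, a.atom_name) for a in model_atoms]
        if atoms is None:
            atoms, ref_keys = model_atoms, keys
        elif keys != ref_keys:
            raise MalformedEnsembleError(
                f"{path}: model {model_no} has {len(keys)} atoms / different atom "
                f"identities than model 1 ({len(ref_keys)})"
            )
        frames.append(np.array(xyz, dtype=float))
    assert atoms is not None
    return ConformerEnsemble(
        atoms=atoms, coords=np.stack(frames), source_label=str(path)
    )


_TABLE_COLUMNS = ["frame", "chain", "resid", "resname", "atom", "x", "y", "z"]


def _read_coord_table(path: Path) -> ConformerEnsemble:
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedEnsembleError(f"{path}: coord table missing columns {missing}")
    frames_ids = sorted(df["frame"].unique())
    groups = {f: g for f, g in df.groupby("frame", sort=False)}
    first = groups[frames_ids[0]]
    atoms = [
        Atom(
            atom_index=i,
            atom_name=str(r.atom),
            element=str(r.atom)[0].upper(),
            residue_index=int(r.resid),
            residue_name=str(r.resname),
            chain_id=str(r.chain),
        )
        for i, r in enumerate(first.itertuples())
    ]
    coords = []
    n0 = len(first)
    for f in frames_ids:
        g = groups[f]
        if len(g) != n0:
            raise MalformedEnsembleError(
                f"{path}: frame {f} has {len(g)} atoms, expected {n0}"
            )
        coords.append(g[["x", "y", "z"]].to_numpy(dtype=float))
    return ConformerEnsemble(atoms=atoms, coords=np.stack(coords), source_label=str(path))


def read_ensemble(path: str | Path, format: str = "multimodel-pdb") -> ConformerEnsemble:
    """Read a conformational ensemble from disk.

    Parameters
    ----------
    path : path to the file.
    format : ``"multimodel-pdb"`` or ``"coord-table"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "multimodel-pdb":
        return _read_multimodel_pdb(path)
    if format == "coord-table":
        return _read_coord_table(path)
    raise ValueError(f"unknown ensemble format {format!r}")


# ---------------------------------------------------------------------------
# Selection


def select_subset(ens: ConformerEnsemble, sel: AtomSelection) -> ConformerEnsemble:
    """Restrict the ensemble to atoms matching *sel*; frames are untouched."""
    idx = ens.atom_indices(sel)
    if idx.size == 0:
        raise SelectionError(
            f"selection {sel} matched no atoms; available chains: {ens.chain_ids}"
        )
    atoms = [replace(ens.atoms[i], atom_index=k) for k, i in enumerate(idx)]
    return ConformerEnsemble(
        atoms=atoms,
        coords=ens.coords[:, idx, :].copy(),
        frame_interval=ens.frame_interval,
        source_label=ens.source_label,
    )


# ---------------------------------------------------------------------------
# Writing

_B_MAX = 999.99


def _format_atom_line(serial: int, atom: Atom, pos: np.ndarray, b: float, occ: float = 1.0) -> str:
    name = atom.atom_name
    # PDB atom-name alignment: 1-3 char names start in column 14
    if len(name) < 4:
        name = f" {name:<3s}"
    icode = atom.residue_key[len(str(atom.residue_index)):] or " "
    return (
        f"ATOM  {serial:5d} {name:<4s} {atom.residue_name:<3s} {atom.chain_id[:1]:1s}"
        f"{atom.residue_index:4d}{icode:1s}   "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_multimodel_pdb(ens: ConformerEnsemble, path: str | Path,
                         bfactors: np.ndarray | None = None) -> Path:
    """Write every frame as a MODEL/ENDMDL block."""
    path = Path(path)
    b = np.zeros(ens.n_atoms) if bfactors is None else np.asarray(bfactors, float)
    lines: list[str] = []
    for f in range(ens.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for i, atom in enumerate(ens.atoms):
            lines.append(_format_atom_line(i + 1, atom, ens.coords[f, i], b[i]))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_annotated_pdb(
    ens: ConformerEnsemble,
    per_residue_values: Mapping[int | tuple[str, int], float],
    path: str | Path,
) -> Path:
    """Write frame 1 as a PDB with per-residue values in the B-factor column.

    Keys of *per_residue_values* are residue indices, or ``(chain, resid)``
    pairs when the value differs between chains.  Residues absent from the map
    get 0; values outside the fixed-width field are clamped to 999.99 with a
    logged warning.  Re-reading the file recovers the values to 2 decimals.
    """
    path = Path(path)
    b = np.zeros(ens.n_atoms)
    for i, atom in enumerate(ens.atoms):
        v = per_residue_values.get((atom.chain_id, atom.residue_index))
        if v is None:
            v = per_residue_values.get(atom.residue_index, 0.0)
        if not math.isfinite(v):
            raise ValueError(
                f"non-finite annotation value for residue {atom.chain_id}/{atom.residue_index}"
            )
        if abs(v) > _B_MAX:
            log.warning(
                "annotation value %.6g for residue %s/%d clamped to field width",
                v, atom.chain_id, atom.residue_index,
            )
            v = math.copysign(_B_MAX, v)
        b[i] = v
    single = ConformerEnsemble(
        atoms=ens.atoms, coords=ens.coords[:1], frame_interval=None,
        source_label=ens.source_label,
    )
    return write_multimodel_pdb(single, path, bfactors=b)
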