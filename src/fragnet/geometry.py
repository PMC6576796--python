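"""Segment strain and interface geometry.

End-to-end distance distributions quantify the strain of a regulatory
segment; Shrake-Rupley solvent-accessible surface areas and their
differences give the buried interface area of a complex; heavy-atom contact
lists and mean helical propensities complete the interface picture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .ensemble import AtomSelection, ConformerEnsemble, SelectionError

__all__ = [
    "DEFAULT_PROPENSITY_SCALE",
    "EndToEndResult",
    "PropensityScale",
    "SurfaceReport",
    "VDW_RADII",
    "buried_surface_area",
    "end_to_end_distance",
    "helical_propensity",
    "interface_contacts",
    "sasa",
]

# van der Waals radii (Å) for heavy-atom surface calculations; hydrogens are
# excluded by default (crystal structures rarely model them).
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
}


# ---------------------------------------------------------------------------
# End-to-end distance


@dataclass
class EndToEndResult:
    distances: np.ndarray          # (F,) Å
    bin_edges: np.ndarray
    bin_counts: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.distances.mean())


def end_to_end_distance(ens: ConformerEnsemble, segment: AtomSelection,
                        bin_width: float = 0.5) -> EndToEndResult:
    """Per-frame Cα end-to-end distance of a segment, with histogram."""
    idx = [i for i in ens.atom_indices(segment) if ens.atoms[i].atom_name == "CA"]
    if len(idx) < 2:
        raise SelectionError("segment needs >= 2 residues with CA atoms")
    first, last = idx[0], idx[-1]
    d = np.linalg.norm(ens.coords[:, last, :] - ens.coords[:, first, :], axis=1)
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    nbins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(d, bins=nbins, range=(lo, lo + nbins * bin_width))
    return EndToEndResult(distances=d, bin_edges=edges, bin_counts=counts)


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)


@dataclass
class SurfaceReport:
    per_atom: np.ndarray       # (A,) Å²
    total: float               # Å²
    probe_radius: float
    n_points: int
    atom_indices: np.ndarray   # indices into the source ensemble's atom table

    def per_residue(self, ens: ConformerEnsemble) -> dict[tuple[str, int], float]:
        out: dict[tuple[str, int], float] = {}
        for a_local, i in enumerate(self.atom_indices):
            atom = ens.atoms[i]
            key = (atom.chain_id, atom.residue_index)
            out[key] = out.get(key, 0.0) + float(self.per_atom[a_local])
        return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere quadrature points."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.c_[np.cos(theta) * np.sin(phi),
                 np.sin(theta) * np.sin(phi),
                 np.cos(phi)]


def _radii_for(ens: ConformerEnsemble, idx: np.ndarray,
               radii: dict[str, float]) -> np.ndarray:
    out = np.empty(idx.size)
    for k, i in enumerate(idx):
        el = ens.atoms[i].element.upper()
        if el not in radii:
            raise ValueError(
                f"no van der Waals radius for element {el!r} "
                f"(atom {ens.atoms[i].atom_name}); supply a radii override"
            )
        out[k] = radii[el]
    return out


def sasa(
    ens: ConformerEnsemble,
    frame: int = 0,
    selection: AtomSelection | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    include_hydrogens: bool = False,
    context: AtomSelection | None = None,
) -> SurfaceReport:
    """Shrake-Rupley solvent-accessible surface area of one frame.

    Each atom's accessible area is the fraction of ``n_points`` quadrature
    points on its probe-expanded sphere not occluded by any neighbour's
    probe-expanded sphere.  ``selection`` limits which atoms are *reported*;
    ``context`` limits which atoms occlude (default: the same selection, so
    SASA of a part "alone" is obtained by passing the part as both).
    """
    rad = dict(VDW_RADII)
    if radii:
        rad.update(radii)
    all_idx = np.arange(ens.n_atoms)

    def _filter(sel: AtomSelection | None) -> np.ndarray:
        idx = all_idx if sel is None else ens.atom_indices(sel)
        if not include_hydrogens:
            idx = np.array([i for i in idx if ens.atoms[i].element.upper() != "H"],
                           dtype=int)
        return idx

    rep_idx = _filter(selection)
    ctx_idx = _filter(context) if context is not None else rep_idx
    if rep_idx.size == 0:
        raise SelectionError("SASA selection matched no atoms")
    coords = ens.coords[frame]
    ctx_xyz = coords[ctx_idx]
    ctx_r = _radii_for(ens, ctx_idx, rad) + probe_radius
    rep_xyz = coords[rep_idx]
    rep_r = _radii_for(ens, rep_idx, rad) + probe_radius
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(ctx_xyz)
    max_ctx_r = ctx_r.max()
    ctx_pos = {int(g): k for k, g in enumerate(ctx_idx)}
    areas = np.empty(rep_idx.size)
    for a in range(rep_idx.size):
        r = rep_r[a]
        pts = rep_xyz[a] + r * sphere
        neigh = tree.query_ball_point(rep_xyz[a], r + max_ctx_r)
        self_k = ctx_pos.get(int(rep_idx[a]))
        neigh = [k for k in neigh if k != self_k]
        accessible = np.ones(n_points, dtype=bool)
        if neigh:
            nb_xyz = ctx_xyz[neigh]
            nb_r = ctx_r[neigh]
            close = np.linalg.norm(nb_xyz - rep_xyz[a], axis=1) < r + nb_r
            nb_xyz, nb_r = nb_xyz[close], nb_r[close]
            for j in range(nb_xyz.shape[0]):
                d2 = ((pts - nb_xyz[j]) ** 2).sum(axis=1)
                accessible &= d2 > nb_r[j] ** 2
                if not accessible.any():
                    break
        areas[a] = 4.0 * np.pi * r * r * accessible.mean()
    return SurfaceReport(per_atom=areas, total=float(areas.sum()),
                         probe_radius=probe_radius, n_points=n_points,
                         atom_indices=rep_idx)


def buried_surface_area(
    ens: ConformerEnsemble,
    part_a: AtomSelection,
    part_b: AtomSelection,
    frame: int = 0,
    segment: AtomSelection | None = None,
    **sasa_kwargs,
) -> dict:
    """Buried interface area of a two-part complex.

    BSA = SASA(A alone) + SASA(B alone) - SASA(A u B).  With ``segment`` (a
    sub-selection of one part, e.g. a captured regulatory peptide) the
    returned ``segment_contribution`` attributes the buried area to that
    segment: the Delta-SASA summed over the segment's atoms plus the matching
    Delta-SASA of the partner atoms it occludes (total minus the rest of its
    own part's contribution).
    """
    ia = ens.atom_indices(part_a)
    ib = ens.atom_indices(part_b)
    if np.intersect1d(ia, ib).size:
        raise SelectionError("part_a and part_b overlap")
    whole = AtomSelection()
    sa = sasa(ens, frame=frame, selection=part_a, context=part_a, **sasa_kwargs)
    sb = sasa(ens, frame=frame, selection=part_b, context=part_b, **sasa_kwargs)
    sa_in = sasa(ens, frame=frame, selection=part_a, context=whole, **sasa_kwargs)
    sb_in = sasa(ens, frame=frame, selection=part_b, context=whole, **sasa_kwargs)
    bsa = sa.total + sb.total - (sa_in.total + sb_in.total)
    out = {
        "bsa": float(bsa),
        "delta_a": float(sa.total - sa_in.total),
        "delta_b": float(sb.total - sb_in.total),
    }
    if segment is not None:
        seg_atoms = set(ens.atom_indices(segment).tolist())
        in_a = seg_atoms & set(ia.tolist())
        in_b = seg_atoms & set(ib.tolist())
        if in_a and in_b:
            raise SelectionError("segment must lie within one part")
        own, alone, incomplex = (
            (in_a, sa, sa_in) if in_a else (in_b, sb, sb_in)
        )
        partner_delta = out["delta_b"] if in_a else out["delta_a"]
        mask = np.array([int(i) in own for i in alone.atom_indices])
        seg_delta = float((alone.per_atom - incomplex.per_atom)[mask].sum())
        out["segment_delta"] = seg_delta
        out["segment_contribution"] = seg_delta + partner_delta
    return out


# ---------------------------------------------------------------------------
# Contacts


def interface_contacts(
    ens: ConformerEnsemble,
    part_a: AtomSelection,
    part_b: AtomSelection,
    frame: int = 0,
    cutoff: float = 4.0,
) -> pd.DataFrame:
    """Residue pairs with any heavy-atom distance <= cutoff, sorted by distance."""
    ia = [i for i in ens.atom_indices(part_a) if ens.atoms[i].element.upper() != "H"]
    ib = [i for i in ens.atom_indices(part_b) if ens.atoms[i].element.upper() != "H"]
    xyz = ens.coords[frame]
    tree_b = cKDTree(xyz[ib])
    best: dict[tuple, float] = {}
    for i in ia:
        for kb in tree_b.query_ball_point(xyz[i], cutoff):
            j = ib[kb]
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            ai, aj = ens.atoms[i], ens.atoms[j]
            key = (ai.chain_id, ai.residue_index, ai.residue_name,
                   aj.chain_id, aj.residue_index, aj.residue_name)
            if d < best.get(key, np.inf):
                best[key] = d
    rows = [k + (v,) for k, v in best.items()]
    df = pd.DataFrame(rows, columns=[
        "chain_a", "resid_a", "resname_a", "chain_b", "resid_b", "resname_b",
        "min_distance_A",
    ])
    return df.sort_values("min_distance_A", ignore_index=True)


# ---------------------------------------------------------------------------
# Helical propensity


@dataclass
class PropensityScale:
    """Residue -> helical propensity (kcal/mol)."""

    values: dict[str, float]
    name: str = "custom"

    def validate_complete(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name} missing residues {sorted(missing)}")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "PropensityScale":
        df = pd.read_csv(path, sep="\t", header=None, names=["residue", "value"])
        return cls(values=dict(zip(df["residue"], df["value"].astype(float))),
                   name=name or Path(path).stem)


# Helix propensities (kcal/mol, Ala reference) from the Pace-Scholtz
# consensus of peptide helix-coil experiments; packaged default, replaceable
# by any user scale (the sign/reference convention of scales varies).
DEFAULT_PROPENSITY_SCALE = PropensityScale(
    values={
        "A": 0.00, "L": 0.21, "R": 0.21, "M": 0.24, "K": 0.26,
        "Q": 0.39, "E": 0.40, "I": 0.41, "W": 0.49, "S": 0.50,
        "Y": 0.53, "F": 0.54, "H": 0.61, "V": 0.61, "N": 0.65,
        "T": 0.66, "C": 0.68, "D": 0.69, "G": 1.00, "P": 3.16,
    },
    name="pace-scholtz-1998",
)


def helical_propensity(sequence: str,
                       scale: PropensityScale = DEFAULT_PROPENSITY_SCALE) -> float:
    """Mean per-residue helical propensity of a one-letter sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    vals = []
    for res in sequence.upper():
        if res not in scale.values:
            raise ValueError(f"residue {res!r} not in scale {scale.name}")
        vals.append(scale.values[res])
    return float(np.mean(vals))
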