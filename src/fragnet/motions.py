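"""Collective-motion analysis: superposition, RMSF, essential-dynamics PCA,
subspace overlap across replicas, and conformer clustering.

PCA ("essential dynamics") diagonalises the mass-unweighted covariance
matrix of Cα positions of a superposed ensemble; the leading eigenvectors
describe the dominant collective motions.  Replica reproducibility is
measured with the cumulative root-mean-square inner product (RMSIP) of the
two eigenvector sets, and the sampled conformational space is compared by
projecting frames onto common principal axes and measuring the convex-hull
area and hull overlap of the PC1-PC2 clouds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation
from shapely.geometry import Polygon

from .ensemble import AtomSelection, CA_ONLY, ConformerEnsemble

__all__ = [
    "ClusterResult",
    "PCAResult",
    "ProjectionCloud",
    "SuperpositionResult",
    "cluster_conformers",
    "hull_overlap",
    "pca_ensemble",
    "project_and_spread",
    "rmsf_profile",
    "rmsip",
    "superpose",
]


# ---------------------------------------------------------------------------
# Superposition


@dataclass
class SuperpositionResult:
    ensemble: ConformerEnsemble        # all atoms, transformed
    rmsd: np.ndarray                   # per-frame fit RMSD over the selection
    reference_coords: np.ndarray       # selection coords of the reference


def _kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal proper rotation R and translation t: mobile @ R.T + t ≈ target."""
    mc, tc = mobile.mean(0), target.mean(0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - mc @ R.T
    return R, t


def superpose(
    ens: ConformerEnsemble,
    reference: int | np.ndarray = 0,
    selection: AtomSelection = CA_ONLY,
) -> SuperpositionResult:
    """Least-squares fit every frame onto a reference over *selection*.

    ``reference`` is a frame index, or an (n_sel, 3) coordinate array (an
    external structure already reduced to the selection atoms, in matching
    order).  The rotation/translation fitted on the selection is applied to
    all atoms of the frame.
    """
    idx = ens.atom_indices(selection)
    if idx.size < 3:
        raise ValueError(f"superposition needs >= 3 selected atoms, got {idx.size}")
    if isinstance(reference, (int, np.integer)):
        ref = ens.coords[int(reference), idx, :]
    else:
        ref = np.asarray(reference, float)
        if ref.shape != (idx.size, 3):
            raise ValueError(
                f"external reference must be ({idx.size}, 3), got {ref.shape}"
            )
    out = np.empty_like(ens.coords)
    rmsd = np.empty(ens.n_frames)
    for f in range(ens.n_frames):
        R, t = _kabsch(ens.coords[f, idx, :], ref)
        out[f] = ens.coords[f] @ R.T + t
        d = out[f, idx, :] - ref
        rmsd[f] = np.sqrt((d ** 2).sum() / idx.size)
    return SuperpositionResult(ensemble=ens.with_coords(out), rmsd=rmsd,
                               reference_coords=ref)


# ---------------------------------------------------------------------------
# Fluctuations

_B_CONV = 8.0 * np.pi ** 2 / 3.0


@dataclass
class RMSFProfile:
    atom_rmsf: np.ndarray                       # (A,) Å
    residue_rmsf: dict[tuple[str, int], float]  # CA value per residue
    pseudo_b: np.ndarray                        # (8 pi^2 / 3) * RMSF^2, Å²


def rmsf_profile(aligned: ConformerEnsemble) -> RMSFProfile:
    """Root-mean-square fluctuation per atom of a superposed ensemble.

    RMSF_a = sqrt( <|r_a(t) - <r_a>|^2> ); the pseudo-B-factor
    (8 pi^2 / 3) RMSF^2 is directly comparable to crystallographic B.
    """
    if aligned.n_frames < 2:
        raise ValueError("RMSF undefined for a single frame")
    mean = aligned.coords.mean(axis=0)
    dev = aligned.coords - mean
    rmsf = np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))
    residue = {
        (a.chain_id, a.residue_index): float(rmsf[i])
        for i, a in enumerate(aligned.atoms) if a.atom_name == "CA"
    }
    return RMSFProfile(atom_rmsf=rmsf, residue_rmsf=residue,
                       pseudo_b=_B_CONV * rmsf ** 2)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """Eigen-decomposition of the 3A x 3A Cα-coordinate covariance."""

    mean_structure: np.ndarray       # (A, 3) Å
    eigenvalues: np.ndarray          # Å², descending
    eigenvectors: np.ndarray         # (3A, n) orthonormal columns
    variance_fraction: np.ndarray
    cumulative_fraction: np.ndarray
    atom_indices: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def pca_ensemble(aligned: ConformerEnsemble,
                 selection: AtomSelection = CA_ONLY) -> PCAResult:
    """Principal component analysis of selected-atom coordinates."""
    if aligned.n_frames < 2:
        raise ValueError("PCA needs at least two frames")
    idx = aligned.atom_indices(selection)
    X = aligned.coords[:, idx, :].reshape(aligned.n_frames, -1)
    mean = X.mean(axis=0)
    dev = X - mean
    cov = dev.T @ dev / X.shape[0]
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    w = np.clip(w, 0.0, None)
    total = w.sum()
    frac = w / total if total > 0 else np.zeros_like(w)
    return PCAResult(
        mean_structure=mean.reshape(-1, 3),
        eigenvalues=w,
        eigenvectors=v,
        variance_fraction=frac,
        cumulative_fraction=np.cumsum(frac),
        atom_indices=idx,
    )


# ---------------------------------------------------------------------------
# Projections, spread and overlap


@dataclass
class ProjectionCloud:
    points: np.ndarray     # (F, k) Å
    hull_area: float       # Å² (k = 2), 0 for degenerate clouds
    components: tuple[int, ...]


def _hull_polygon(points: np.ndarray) -> Polygon | None:
    uniq = np.unique(points, axis=0)
    if uniq.shape[0] < 3:
        return None
    try:
        hull = ConvexHull(uniq)
    except Exception:
        return None  # collinear cloud
    return Polygon(uniq[hull.vertices])


def project_and_spread(ens: ConformerEnsemble, pca: PCAResult,
                       components: tuple[int, int] = (1, 2)) -> ProjectionCloud:
    """Project frames onto chosen PCs (1-based) and measure the hull area."""
    for c in components:
        if not 1 <= c <= pca.n_components:
            raise IndexError(f"component {c} out of range 1..{pca.n_components}")
    X = ens.coords[:, pca.atom_indices, :].reshape(ens.n_frames, -1)
    dev = X - pca.mean_structure.ravel()
    cols = [pca.eigenvectors[:, c - 1] for c in components]
    pts = dev @ np.stack(cols, axis=1)
    poly = _hull_polygon(pts[:, :2]) if pts.shape[1] >= 2 else None
    return ProjectionCloud(points=pts, hull_area=poly.area if poly else 0.0,
                           components=tuple(components))


def hull_overlap(a: ProjectionCloud, b: ProjectionCloud) -> float:
    """Fraction of cloud *a*'s hull area covered by cloud *b*'s hull."""
    pa, pb = _hull_polygon(a.points[:, :2]), _hull_polygon(b.points[:, :2])
    if pa is None or pa.area == 0.0:
        return 0.0
    if pb is None:
        return 0.0
    return pa.intersection(pb).area / pa.area


# ---------------------------------------------------------------------------
# Subspace overlap


def rmsip(pcs_a: np.ndarray, pcs_b: np.ndarray, k: int = 10):
    """Cumulative root-mean-square inner product of two PC sets.

    RMSIP = sqrt( (1/k) sum_i sum_j (v_i . w_j)^2 ) over the first k
    components of each set (columns).  Returns (value, k x k dot-product
    matrix).  1 for identical subspaces, 0 for orthogonal ones.
    """
    A = np.asarray(pcs_a, float)
    B = np.asarray(pcs_b, float)
    if A.shape[0] != B.shape[0]:
        raise ValueError(f"dimension mismatch: {A.shape[0]} vs {B.shape[0]}")
    if k > A.shape[1] or k > B.shape[1]:
        raise ValueError(f"k={k} exceeds available components")
    D = A[:, :k].T @ B[:, :k]
    value = float(np.sqrt((D ** 2).sum() / k))
    return min(1.0, value), D


# ---------------------------------------------------------------------------
# Conformer clustering (neighbour counting on the pairwise RMSD matrix)


@dataclass
class ClusterResult:
    labels: np.ndarray            # (F,) cluster id per frame, 0 = largest
    sizes: list[int]              # descending
    representatives: list[int]    # central frame per cluster
    rmsd_cutoff: float


def cluster_conformers(aligned: ConformerEnsemble, rmsd_cutoff: float = 2.0,
                       selection: AtomSelection = CA_ONLY) -> ClusterResult:
    """Neighbour-counting (GROMOS-style) clustering of a superposed ensemble.

    The frame with the most neighbours within ``rmsd_cutoff`` (pairwise Cα
    RMSD, no re-fitting) becomes a cluster centre; the cluster is removed and
    the procedure repeats.  Deterministic given frame order: ties resolve to
    the earliest frame.
    """
    if rmsd_cutoff <= 0:
        raise ValueError("rmsd_cutoff must be positive")
    idx = aligned.atom_indices(selection)
    X = aligned.coords[:, idx, :]
    F = X.shape[0]
    diff = X[:, None, :, :] - X[None, :, :, :]
    rmsd = np.sqrt((diff ** 2).sum(axis=(2, 3)) / idx.size)
    labels = np.full(F, -1, dtype=int)
    remaining = np.ones(F, dtype=bool)
    clusters: list[tuple[int, np.ndarray]] = []
    while remaining.any():
        neigh = (rmsd <= rmsd_cutoff) & remaining[None, :] & remaining[:, None]
        counts = np.where(remaining, neigh.sum(axis=1), -1)
        center = int(np.argmax(counts))
        members = np.where(neigh[center])[0]
        clusters.append((center, members))
        remaining[members] = False
    clusters.sort(key=lambda cm: (-len(cm[1]), cm[0]))
    sizes, reps = [], []
    for cid, (center, members) in enumerate(clusters):
        labels[members] = cid
        sizes.append(len(members))
        reps.append(center)
    return ClusterResult(labels=labels, sizes=sizes, representatives=reps,
                         rmsd_cutoff=rmsd_cutoff)
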