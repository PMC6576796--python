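"""Structural-alphabet encoding of 4-residue Cα fragments.

Every overlapping window of four consecutive Cα atoms is assigned the letter
of the alphabet prototype that minimises the least-squares superposition
distance (optimal proper rotation + translation, reflections forbidden).
A conformational ensemble thus becomes a frames x fragments categorical
matrix — the random variables of the downstream information-theoretic
coupling analysis.

The packaged built-in alphabet (ids ``"SA25"`` and ``"M32K25"``) is a
*synthetic* 25-letter set: its prototypes are ideal-geometry backbone
fragments built at 25 representative Ramachandran (phi, psi) points covering
the alpha-helical, extended/beta, polyproline-II, left-handed-helical and
turn regions (see :func:`build_ramachandran_alphabet`).  It stands in for
literature-derived fragment libraries whose coordinates are not
redistributable here; helix/sheet class membership is assigned from the
generating dihedrals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ensemble import ConformerEnsemble

__all__ = [
    "AlphabetFormatError",
    "FragmentStateMatrix",
    "GeometryError",
    "LetterDistribution",
    "StructuralAlphabet",
    "build_ramachandran_alphabet",
    "encode_ensemble",
    "encode_fragment",
    "letter_distribution",
    "load_alphabet",
    "superposition_rmsd",
]

FRAGMENT_LENGTH = 4
_BUILTIN_IDS = {"SA25", "M32K25"}
_BUILTIN_FILE = "sa25_synthetic.json"


class AlphabetFormatError(ValueError):
    """An alphabet definition failed validation."""


class GeometryError(ValueError):
    """Degenerate fragment geometry (e.g. coincident Cα positions)."""


# ---------------------------------------------------------------------------
# Superposition distance (Kabsch via SVD, reflections forbidden)


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=-2, keepdims=True)


def superposition_rmsd(frags: np.ndarray, protos: np.ndarray) -> np.ndarray:
    """Pairwise optimal-superposition RMSD between fragment sets.

    Parameters
    ----------
    frags : (..., M, 4, 3) fragment coordinates.
    protos : (L, 4, 3) prototype coordinates.

    Returns
    -------
    (..., M, L) matrix of RMSD values after optimal proper-rotation fit
    (determinant +1; mirror images are distinct states).
    """
    P = _center(np.asarray(frags, float))
    Q = _center(np.asarray(protos, float))
    n = P.shape[-2]
    # cross-covariance H[m,l] = P_m^T Q_l  -> (M, L, 3, 3)
    H = np.einsum("...mai,laj->...mlij", P, Q)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("...ij,...jk->...ik", U, Vt)))
    corr = S[..., 0] + S[..., 1] + d * S[..., 2]
    p2 = np.einsum("...mai,...mai->...m", P, P)
    q2 = np.einsum("lai,lai->l", Q, Q)
    msd = (p2[..., :, None] + q2 - 2.0 * corr) / n
    return np.sqrt(np.clip(msd, 0.0, None))


# ---------------------------------------------------------------------------
# Alphabet


@dataclass
class StructuralAlphabet:
    """An ordered set of canonical 4-Cα fragment geometries.

    Attributes
    ----------
    letters : ordered single-character codes.
    prototypes : (L, 4, 3) Cα coordinates, Å, centered at the origin.
    helix_class / sheet_class : letters representing α-helical / extended
        geometry (disjoint).
    name : identifier of the set.
    """

    letters: list[str]
    prototypes: np.ndarray
    helix_class: frozenset[str] = frozenset()
    sheet_class: frozenset[str] = frozenset()
    name: str = "custom"

    def __post_init__(self):
        self.prototypes = np.asarray(self.prototypes, float)
        self.helix_class = frozenset(self.helix_class)
        self.sheet_class = frozenset(self.sheet_class)
        L = len(self.letters)
        if self.prototypes.shape != (L, FRAGMENT_LENGTH, 3):
            raise AlphabetFormatError(
                f"expected ({L}, 4, 3) prototypes, got {self.prototypes.shape}"
            )
        if len(set(self.letters)) != L:
            raise AlphabetFormatError("duplicate letters in alphabet")
        if self.helix_class & self.sheet_class:
            raise AlphabetFormatError("helix and sheet classes overlap")
        unknown = (self.helix_class | self.sheet_class) - set(self.letters)
        if unknown:
            raise AlphabetFormatError(f"class letters not in alphabet: {sorted(unknown)}")
        self.prototypes = _center(self.prototypes)
        if L > 1:
            d = superposition_rmsd(self.prototypes, self.prototypes)
            off = d[~np.eye(L, dtype=bool)]
            if off.min() <= 1e-6:
                raise AlphabetFormatError("prototypes are not pairwise distinct")

    def __len__(self) -> int:
        return len(self.letters)

    def index(self, letter: str) -> int:
        return self.letters.index(letter)

    def validate(self, strict: bool = True) -> None:
        if strict and len(self) != 25:
            raise AlphabetFormatError(
                f"canonical alphabet must have 25 prototypes, got {len(self)}"
            )


# 25 Ramachandran (phi, psi) points: alpha-helical core and flanks, 3-10-like,
# turn/bridge, polyproline-II, beta/extended spread, left-handed alpha, and
# rare positive-phi states.  Helix class = canonical alpha-R basin; sheet
# class = extended beta basin.
_RAMACHANDRAN_POINTS: list[tuple[str, float, float, str]] = [
    ("A", -57.0, -47.0, "helix"),
    ("B", -63.0, -42.0, "helix"),
    ("C", -68.0, -35.0, "helix"),
    ("D", -50.0, -52.0, "helix"),
    ("E", -74.0, -28.0, "helix"),
    ("F", -49.0, -26.0, "other"),   # 3-10-like
    ("G", -80.0, -15.0, "other"),
    ("H", -90.0, 0.0, "other"),
    ("I", -95.0, 20.0, "other"),
    ("J", -85.0, 60.0, "other"),
    ("K", -75.0, 100.0, "other"),
    ("L", -75.0, 145.0, "other"),   # polyproline II
    ("M", -65.0, 155.0, "other"),
    ("N", -90.0, 130.0, "sheet"),
    ("O", -105.0, 115.0, "sheet"),
    ("P", -120.0, 130.0, "sheet"),
    ("Q", -135.0, 140.0, "sheet"),
    ("R", -150.0, 155.0, "sheet"),
    ("S", -160.0, 170.0, "sheet"),
    ("T", -115.0, 155.0, "sheet"),
    ("U", 57.0, 47.0, "other"),     # alpha-L
    ("V", 70.0, 25.0, "other"),
    ("W", 60.0, -120.0, "other"),
    ("X", -140.0, 80.0, "other"),
    ("Y", 100.0, 160.0, "other"),
]

# ideal backbone internal coordinates (Engh-Huber-like)
_BB = {
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329,
    "n_ca_c": 111.2, "ca_c_n": 116.2, "c_n_ca": 121.7,
    "omega": 180.0,
}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom d from internal coordinates w.r.t. a-b-c."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # collinear support: pick any perpendicular
        n = np.cross(bc, [1.0, 0.0, 0.0])
        if np.linalg.norm(n) < 1e-10:
            n = np.cross(bc, [0.0, 1.0, 0.0])
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _backbone_ca_trace(phi: float, psi: float, n_residues: int) -> np.ndarray:
    """Cα trace of an ideal-geometry peptide with uniform (phi, psi)."""
    g = _BB
    # seed residue 0
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([g["n_ca"], 0.0, 0.0])
    ang = np.deg2rad(g["n_ca_c"])
    C = CA + g["ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    cas = [CA]
    prev_n, prev_ca, prev_c = N, CA, C
    for _ in range(1, n_residues):
        Nn = _place_atom(prev_n, prev_ca, prev_c, g["c_n"], g["ca_c_n"], psi)
        CAn = _place_atom(prev_ca, prev_c, Nn, g["n_ca"], g["c_n_ca"], g["omega"])
        Cn = _place_atom(prev_c, Nn, CAn, g["ca_c"], g["n_ca_c"], phi)
        cas.append(CAn)
        prev_n, prev_ca, prev_c = Nn, CAn, Cn
    return np.asarray(cas)


def build_ramachandran_alphabet() -> StructuralAlphabet:
    """Construct the packaged synthetic 25-letter alphabet from scratch.

    Each prototype is the 4-Cα trace of an ideal-geometry tetrapeptide with
    uniform backbone dihedrals at one of 25 representative Ramachandran
    points.  Deterministic; used to (re)generate the packaged data file.
    """
    letters, protos, helix, sheet = [], [], set(), set()
    for letter, phi, psi, cls in _RAMACHANDRAN_POINTS:
        letters.append(letter)
        protos.append(_backbone_ca_trace(phi, psi, FRAGMENT_LENGTH))
        if cls == "helix":
            helix.add(letter)
        elif cls == "sheet":
            sheet.add(letter)
    return StructuralAlphabet(
        letters=letters, prototypes=np.asarray(protos),
        helix_class=frozenset(helix), sheet_class=frozenset(sheet),
        name="SA25-synthetic",
    )


def _alphabet_from_dict(data: dict, name: str) -> StructuralAlphabet:
    letters = [str(e["letter"]) for e in data["prototypes"]]
    coords = np.array([e["ca"] for e in data["prototypes"]], float)
    return StructuralAlphabet(
        letters=letters,
        prototypes=coords,
        helix_class=frozenset(data.get("helix_class", [])),
        sheet_class=frozenset(data.get("sheet_class", [])),
        name=data.get("name", name),
    )


def load_alphabet(source: str | Path = "SA25", relaxed: bool = False) -> StructuralAlphabet:
    """Load a structural alphabet from a built-in id or a JSON/TSV file.

    Built-in ids ``"SA25"`` and ``"M32K25"`` load the packaged synthetic
    25-letter set.  JSON layout: ``{"name":..., "prototypes":[{"letter":"A",
    "ca":[[x,y,z]x4]},...], "helix_class":[...], "sheet_class":[...]}``.
    TSV layout: columns ``letter x1 y1 z1 ... x4 y4 z4 class``.

    ``relaxed=True`` skips the 25-letter cardinality check so small toy
    alphabets can be used in tests.
    """
    if isinstance(source, str) and source in _BUILTIN_IDS:
        text = resources.files("fragnet.data").joinpath(_BUILTIN_FILE).read_text()
        alpha = _alphabet_from_dict(json.loads(text), source)
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"no such alphabet file or built-in id: {source}")
        if path.suffix.lower() == ".json":
            alpha = _alphabet_from_dict(json.loads(path.read_text()), path.stem)
        else:
            df = pd.read_csv(path, sep="\t")
            need = ["letter"] + [f"{ax}{i}" for i in range(1, 5) for ax in "xyz"]
            missing = [c for c in need if c not in df.columns]
            if missing:
                raise AlphabetFormatError(f"alphabet TSV missing columns {missing}")
            coords = df[need[1:]].to_numpy(float).reshape(-1, 4, 3)
            cls = df["class"] if "class" in df.columns else pd.Series([""] * len(df))
            alpha = StructuralAlphabet(
                letters=[str(x) for x in df["letter"]],
                prototypes=coords,
                helix_class=frozenset(df["letter"][cls == "helix"]),
                sheet_class=frozenset(df["letter"][cls == "sheet"]),
                name=path.stem,
            )
    alpha.validate(strict=not relaxed)
    return alpha


# ---------------------------------------------------------------------------
# Encoding


def encode_fragment(ca_coords: np.ndarray, alphabet: StructuralAlphabet) -> str:
    """Encode one 4-Cα fragment as its best-fitting alphabet letter.

    Ties on fit distance break towards the earlier letter in alphabet order.
    """
    ca = np.asarray(ca_coords, float)
    if ca.shape != (FRAGMENT_LENGTH, 3):
        raise ValueError(f"fragment must be (4, 3), got {ca.shape}")
    if not np.all(np.isfinite(ca)):
        raise GeometryError("non-finite fragment coordinates")
    diff = ca[:, None, :] - ca[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    if dist[~np.eye(4, dtype=bool)].min() < 1e-6:
        raise GeometryError("degenerate fragment: coincident Cα positions")
    d = superposition_rmsd(ca[None], alphabet.prototypes)[0]
    return alphabet.letters[int(np.argmin(d))]


@dataclass
class FragmentStateMatrix:
    """Frames x fragments categorical matrix of structural-alphabet letters.

    ``codes`` stores letter indices into ``alphabet.letters`` (int8);
    ``fragment_map`` maps fragment column -> (chain_id, first_residue_index),
    1-based on the first residue of the 4-residue window; ``centroids`` holds
    the per-frame mean position of each fragment's four Cα atoms.
    """

    codes: np.ndarray                      # (F, N) int
    fragment_map: list[tuple[str, int]]    # column -> (chain, first residue)
    centroids: np.ndarray                  # (F, N, 3) Å
    alphabet: StructuralAlphabet
    frame_interval: float | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        self.centroids = np.asarray(self.centroids, float)
        F, N = self.codes.shape
        if len(self.fragment_map) != N:
            raise ValueError("fragment_map length mismatch")
        if self.centroids.shape != (F, N, 3):
            raise ValueError(f"centroids must be {(F, N, 3)}, got {self.centroids.shape}")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= len(self.alphabet)):
            raise ValueError("letter codes outside alphabet range")

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    @property
    def n_fragments(self) -> int:
        return self.codes.shape[1]

    @property
    def n_candidate_pairs(self) -> int:
        """Number of unordered fragment pairs, n(n-1)/2 — the candidate
        coupling set of the network."""
        n = self.n_fragments
        return n * (n - 1) // 2

    def letters(self) -> np.ndarray:
        """(F, N) array of letter characters."""
        lut = np.array(self.alphabet.letters)
        return lut[self.codes]

    def fragment_residues(self, column: int) -> set[tuple[str, int]]:
        chain, first = self.fragment_map[column]
        return {(chain, first + k) for k in range(FRAGMENT_LENGTH)}

    def to_tsv(self, path: str | Path) -> Path:
        """Interchange format: rows = frames, columns = fragments (letters)."""
        path = Path(path)
        cols = [f"{c}:{r}" for c, r in self.fragment_map]
        pd.DataFrame(self.letters(), columns=cols).to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, alphabet: StructuralAlphabet,
                 frame_interval: float | None = None) -> "FragmentStateMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str)
        fragment_map = []
        for col in df.columns:
            chain, _, resid = col.rpartition(":")
            fragment_map.append((chain or "A", int(resid)))
        index = {c: i for i, c in enumerate(alphabet.letters)}
        codes = np.array([[index[v] for v in row] for row in df.to_numpy()], dtype=np.int8)
        F, N = codes.shape
        centroids = np.zeros((F, N, 3))
        centroids[:, :, 0] = 4.0 * np.arange(N)  # placeholder spacing
        return cls(codes=codes, fragment_map=fragment_map, centroids=centroids,
                   alphabet=alphabet, frame_interval=frame_interval)


def _chain_windows(ens: ConformerEnsemble) -> list[tuple[str, int, np.ndarray]]:
    """Valid 4-residue CA windows: (chain, first_residue, 4 CA atom indices).

    A residue-number gap > 1 or a chain change terminates the window run;
    chains with fewer than 4 consecutive residues contribute no fragments.
    """
    ca_idx = ens.ca_indices()
    runs: list[list[tuple[str, int, int]]] = []  # runs of (chain, resid, atom_idx)
    prev_chain, prev_resid = None, None
    for i in ca_idx:
        a = ens.atoms[i]
        if a.chain_id != prev_chain or prev_resid is None or a.residue_index - prev_resid > 1:
            runs.append([])
        runs[-1].append((a.chain_id, a.residue_index, i))
        prev_chain, prev_resid = a.chain_id, a.residue_index
    windows = []
    for run in runs:
        for k in range(len(run) - FRAGMENT_LENGTH + 1):
            chain, first, _ = run[k]
            idx = np.array([run[k + j][2] for j in range(FRAGMENT_LENGTH)])
            windows.append((chain, first, idx))
    return windows


def encode_ensemble(ens: ConformerEnsemble, alphabet: StructuralAlphabet,
                    chunk_frames: int = 256) -> FragmentStateMatrix:
    """Encode every 4-Cα fragment of every frame of an ensemble.

    Fragments never span chain breaks (residue gap > 1 or chain change).
    Encoding is batched over frames for speed; results are identical to
    per-fragment :func:`encode_fragment`.
    """
    windows = _chain_windows(ens)
    if not windows:
        raise ValueError("no encodable 4-residue fragment windows in ensemble")
    F = ens.n_frames
    N = len(windows)
    idx = np.stack([w[2] for w in windows])          # (N, 4)
    codes = np.empty((F, N), dtype=np.int8)
    centroids = np.empty((F, N, 3))
    for start in range(0, F, chunk_frames):
        sl = slice(start, min(start + chunk_frames, F))
        frags = ens.coords[sl][:, idx, :]             # (f, N, 4, 3)
        centroids[sl] = frags.mean(axis=2)
        f = frags.shape[0]
        d = superposition_rmsd(frags.reshape(f * N, 4, 3), alphabet.prototypes)
        codes[sl] = np.argmin(d, axis=1).reshape(f, N).astype(np.int8)
    return FragmentStateMatrix(
        codes=codes,
        fragment_map=[(c, r) for c, r, _ in windows],
        centroids=centroids,
        alphabet=alphabet,
        frame_interval=ens.frame_interval,
    )


# ---------------------------------------------------------------------------
# Letter distributions


@dataclass
class LetterDistribution:
    """Empirical per-letter frequencies for one fragment (or pooled)."""

    probabilities: np.ndarray     # (L,)
    n_samples: int
    alphabet: StructuralAlphabet
    helical_content: float = field(init=False)
    sheet_content: float = field(init=False)

    def __post_init__(self):
        p = np.asarray(self.probabilities, float)
        if p.size != len(self.alphabet):
            raise ValueError("probability vector length != alphabet size")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        self.probabilities = p
        helix = [i for i, l in enumerate(self.alphabet.letters)
                 if l in self.alphabet.helix_class]
        sheet = [i for i, l in enumerate(self.alphabet.letters)
                 if l in self.alphabet.sheet_class]
        self.helical_content = float(p[helix].sum())
        self.sheet_content = float(p[sheet].sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.probabilities, index=self.alphabet.letters)


def letter_distribution(m: FragmentStateMatrix,
                        fragment: int | None = None) -> LetterDistribution:
    """Letter frequencies of one fragment column, or pooled over all."""
    if m.n_frames < 1:
        raise ValueError("empty state matrix")
    col = m.codes if fragment is None else m.codes[:, fragment]
    counts = np.bincount(col.ravel(), minlength=len(m.alphabet)).astype(float)
    n = int(counts.sum())
    return LetterDistribution(probabilities=counts / n, n_samples=n, alphabet=m.alphabet)
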