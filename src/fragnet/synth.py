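"""Synthetic conformational ensembles with planted statistical structure.

The generators emulate the statistical features the coupling analysis
assumes — a multi-chain Cα polymer whose designated 4-residue segments
interconvert between a helix-like and an extended local geometry as
two-state Markov chains, with configurable *planted* couplings (a partner
segment copies its driver's state with a set probability), configurable
switch rates (slow vs fast dwell times) and additive Gaussian coordinate
noise.  No physics is modelled: the point is ground truth for every stage
of the pipeline, so recovery of planted couplings, communities and relays
can be asserted exactly.

All generators are pure functions of (spec, seed): reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import (FRAGMENT_LENGTH, FragmentStateMatrix, StructuralAlphabet,
                       encode_fragment, load_alphabet, superposition_rmsd)
from .ensemble import Atom, ConformerEnsemble

__all__ = [
    "HELIX_GEOMETRY",
    "EXTENDED_GEOMETRY",
    "SyntheticSpec",
    "coupled_two_state_ensemble",
    "ideal_helix",
    "markov_letters",
]

# Local-state curve parameters (rise Å, radius Å, twist deg/residue): the
# helix matches canonical alpha-helical Cα geometry; the extended state is a
# stretched, nearly flat zig-zag resembling a beta strand.
HELIX_GEOMETRY = {"rise": 1.5, "radius": 2.3, "twist": 100.0}
EXTENDED_GEOMETRY = {"rise": 3.3, "radius": 1.0, "twist": 180.0}


def _helical_curve(n: int, rise: float, radius: float, twist: float) -> np.ndarray:
    t = np.arange(n)
    ang = np.deg2rad(twist) * t
    return np.c_[radius * np.cos(ang), radius * np.sin(ang), rise * t]


def ideal_helix(n_residues: int, rise: float = 1.5, radius: float = 2.3,
                twist: float = 100.0, chain_id: str = "A") -> ConformerEnsemble:
    """Single-frame CA-only ensemble of an ideal helical curve.

    ``radius=0`` degenerates to a straight line with the given per-residue
    rise.  Default parameters give canonical alpha-helical Cα geometry
    (consecutive CA-CA distance ~3.88 Å).
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    coords = _helical_curve(n_residues, rise, radius, twist)
    atoms = [
        Atom(atom_index=i, atom_name="CA", element="C", residue_index=i + 1,
             residue_name="ALA", chain_id=chain_id)
        for i in range(n_residues)
    ]
    return ConformerEnsemble(atoms=atoms, coords=coords[None, :, :],
                             source_label=f"ideal_helix(rise={rise},radius={radius},twist={twist})")


# ---------------------------------------------------------------------------
# Internal Cα geometry derived from the two state curves


def _dihedral(p0, p1, p2, p3) -> float:
    """IUPAC-signed torsion angle in degrees (matches biotite's convention)."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(-(m1 @ n2), n1 @ n2)))


def _angle(p0, p1, p2) -> float:
    v1, v2 = p0 - p1, p2 - p1
    c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1, 1))))


def _state_internal(geom: dict) -> tuple[float, float, float]:
    """(bond, angle, torsion) of the Cα pseudo-chain for one state curve."""
    c = _helical_curve(4, **geom)
    return (float(np.linalg.norm(c[1] - c[0])), _angle(c[0], c[1], c[2]),
            _dihedral(c[0], c[1], c[2], c[3]))


def _extend_ca(p0, p1, p2, bond, angle_deg, torsion_deg) -> np.ndarray:
    """Place the next Cα from the three previous ones (NeRF)."""
    ang, tor = np.deg2rad(angle_deg), np.deg2rad(torsion_deg)
    bc = p2 - p1
    bc /= np.linalg.norm(bc)
    n = np.cross(p1 - p0, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(ang),
                  bond * np.sin(ang) * np.cos(tor),
                  bond * np.sin(ang) * np.sin(tor)])
    return p2 + d[0] * bc + d[1] * m + d[2] * n


# ---------------------------------------------------------------------------
# Spec


@dataclass
class SyntheticSpec:
    """Conditions for the coupled two-state ensemble generator.

    ``planted_pairs`` are (driver, partner) global fragment indices
    (fragment k of chain c has global index c*(n_residues-3) + k, first
    residue k+1).  ``coupling_strength`` is the probability per frame that
    the partner copies the driver's state; ``switch_rate`` the per-frame
    probability that a free segment flips state (stay probability
    1 - switch_rate).  ``background_fragments`` switch independently and
    provide null statistics.  ``seed`` is mandatory.
    """

    n_residues: int = 40
    n_chains: int = 1
    n_frames: int = 500
    frame_interval: float | None = 0.1   # ns
    planted_pairs: tuple[tuple[int, int], ...] = ()
    coupling_strength: float = 0.9
    switch_rate: float = 0.1
    coordinate_noise_sd: float = 0.15    # Å
    background_fragments: tuple[int, ...] = ()
    seed: int = None  # type: ignore[assignment]  # required, no silent default

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is required for synthetic generation")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must be in [0, 1]")
        if not 0.0 <= self.switch_rate <= 1.0:
            raise ValueError("switch_rate must be in [0, 1]")
        n_frag = self.fragments_per_chain * self.n_chains
        for pair in self.planted_pairs:
            for f in pair:
                if not 0 <= f < n_frag:
                    raise ValueError(f"planted fragment {f} out of range 0..{n_frag - 1}")
        for f in self.background_fragments:
            if not 0 <= f < n_frag:
                raise ValueError(f"background fragment {f} out of range")

    @property
    def fragments_per_chain(self) -> int:
        return self.n_residues - FRAGMENT_LENGTH + 1

    def fragment_chain_and_first(self, index: int) -> tuple[int, int]:
        """(chain number, first residue 1-based) of a global fragment index."""
        per = self.fragments_per_chain
        return index // per, index % per + 1

    def switching_fragments(self) -> list[int]:
        seen: list[int] = []
        for pair in self.planted_pairs:
            for f in pair:
                if f not in seen:
                    seen.append(f)
        for f in self.background_fragments:
            if f not in seen:
                seen.append(f)
        return seen


def _simulate_states(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[np.ndarray, list[int]]:
    """Two-state Markov trajectories for every switching fragment.

    Returns (F, S) 0/1 state matrix and the fragment-id order.  Partners of
    planted pairs copy their driver with probability ``coupling_strength``
    each frame, otherwise take an independent Markov step.
    """
    frags = spec.switching_fragments()
    pos = {f: s for s, f in enumerate(frags)}
    partner_of: dict[int, int] = {}
    for drv, prt in spec.planted_pairs:
        partner_of[prt] = drv  # later pairs override earlier (chained relays)
    F, S = spec.n_frames, len(frags)
    states = np.zeros((F, S), dtype=np.int8)
    if S == 0:
        return states, frags
    states[0] = rng.integers(0, 2, size=S)
    # pre-draw in fixed order for determinism
    flips = rng.random((F, S)) < spec.switch_rate
    copies = rng.random((F, S)) < spec.coupling_strength
    # the copy rule applies at t=0 as well, so the coupled pair starts at its
    # stationary relation (and switch_rate 0 yields a truly static ensemble)
    for prt, drv in partner_of.items():
        if copies[0, pos[prt]]:
            states[0, pos[prt]] = states[0, pos[drv]]
    for t in range(1, F):
        step = np.where(flips[t], 1 - states[t - 1], states[t - 1])
        states[t] = step
        for prt, drv in partner_of.items():
            s = pos[prt]
            if copies[t, s]:
                states[t, s] = states[t, pos[drv]]
    return states, frags


def coupled_two_state_ensemble(spec: SyntheticSpec):
    """Generate a coupled two-state polymer ensemble with ground truth.

    Returns ``(ensemble, state_log, fragment_ids)``: the CA-only
    :class:`ConformerEnsemble` (chains laid out side by side, Gaussian noise
    added), the (F, S) 0/1 ground-truth state matrix, and the global
    fragment ids of the S switching segments (state 0 = helix-like,
    1 = extended).

    Switching segments must not overlap in residues; all other residues stay
    helical.  At generation time the two noise-free local geometries are
    encoded against the packaged alphabet and asserted to map to different
    letters, guaranteeing the planted dynamics are visible to the encoder.
    """
    rng = np.random.default_rng(spec.seed)
    per = spec.fragments_per_chain
    switching = spec.switching_fragments()
    # residue spans (chain, residues) of switching fragments must be disjoint
    occupied: set[tuple[int, int]] = set()
    for f in switching:
        chain, first = spec.fragment_chain_and_first(f)
        span = {(chain, first + k) for k in range(FRAGMENT_LENGTH)}
        if span & occupied:
            raise ValueError(f"switching fragments overlap at fragment {f}")
        occupied |= span

    # sanity: the two local geometries are distinguishable to the encoder
    alpha = load_alphabet("SA25")
    helix_letter = encode_fragment(_helical_curve(4, **HELIX_GEOMETRY), alpha)
    ext_letter = encode_fragment(_helical_curve(4, **EXTENDED_GEOMETRY), alpha)
    assert helix_letter != ext_letter, "state geometries are not distinguishable"

    states, frag_ids = _simulate_states(spec, rng)
    pos = {f: s for s, f in enumerate(frag_ids)}
    geo = {0: _state_internal(HELIX_GEOMETRY), 1: _state_internal(EXTENDED_GEOMETRY)}

    # per-residue state per frame (residues are 1-based within a chain)
    res_state = np.zeros((spec.n_frames, spec.n_chains, spec.n_residues + 1), dtype=np.int8)
    for f in switching:
        chain, first = spec.fragment_chain_and_first(f)
        for k in range(FRAGMENT_LENGTH):
            res_state[:, chain, first + k] = states[:, pos[f]]

    helix_seed = _helical_curve(3, **HELIX_GEOMETRY)
    coords = np.empty((spec.n_frames, spec.n_chains * spec.n_residues, 3))
    for t in range(spec.n_frames):
        for c in range(spec.n_chains):
            chain_xyz = np.empty((spec.n_residues, 3))
            chain_xyz[:3] = helix_seed + np.array([60.0 * c, 0.0, 0.0])
            for r in range(3, spec.n_residues):
                bond, ang, tor = geo[int(res_state[t, c, r + 1])]
                chain_xyz[r] = _extend_ca(chain_xyz[r - 3], chain_xyz[r - 2],
                                          chain_xyz[r - 1], bond, ang, tor)
            coords[t, c * spec.n_residues:(c + 1) * spec.n_residues] = chain_xyz
    coords += rng.normal(0.0, spec.coordinate_noise_sd, size=coords.shape)

    atoms = []
    i = 0
    for c in range(spec.n_chains):
        chain_id = chr(ord("A") + c)
        for r in range(spec.n_residues):
            atoms.append(Atom(atom_index=i, atom_name="CA", element="C",
                              residue_index=r + 1, residue_name="ALA",
                              chain_id=chain_id))
            i += 1
    ens = ConformerEnsemble(atoms=atoms, coords=coords,
                            frame_interval=spec.frame_interval,
                            source_label=f"coupled_two_state(seed={spec.seed})")
    return ens, states, frag_ids


def markov_letters(
    n_fragments: int,
    n_frames: int,
    alphabet: StructuralAlphabet | None = None,
    planted_pairs: tuple[tuple[int, int], ...] = (),
    coupling_strength: float = 0.9,
    switch_rate: float = 0.1,
    seed: int = 0,
    frame_interval: float | None = None,
) -> FragmentStateMatrix:
    """Categorical fragment-state matrix with planted couplings, no geometry.

    Every fragment is an independent two-letter Markov chain (between the
    alphabet's first helix-class and first sheet-class letter) except the
    partners of ``planted_pairs``, which copy their driver's state with
    probability ``coupling_strength`` per frame.  A fast path for testing
    the information-network stage; centroids are placed on a line at 4 Å
    spacing so the spatial filter remains exercisable.
    """
    if alphabet is None:
        alphabet = load_alphabet("SA25")
    rng = np.random.default_rng(seed)
    letters = alphabet.letters
    a = letters.index(sorted(alphabet.helix_class)[0]) if alphabet.helix_class else 0
    b = letters.index(sorted(alphabet.sheet_class)[0]) if alphabet.sheet_class else 1
    partner_of = {prt: drv for drv, prt in planted_pairs}
    F, N = n_frames, n_fragments
    states = np.zeros((F, N), dtype=np.int8)
    states[0] = rng.integers(0, 2, size=N)
    flips = rng.random((F, N)) < switch_rate
    copies = rng.random((F, N)) < coupling_strength
    for t in range(1, F):
        states[t] = np.where(flips[t], 1 - states[t - 1], states[t - 1])
        for prt, drv in partner_of.items():
            if copies[t, prt]:
                states[t, prt] = states[t, drv]
    codes = np.where(states == 0, a, b).astype(np.int8)
    centroids = np.zeros((F, N, 3))
    centroids[:, :, 0] = 4.0 * np.arange(N)
    fragment_map = [("A", i + 1) for i in range(N)]
    return FragmentStateMatrix(codes=codes, fragment_map=fragment_map,
                               centroids=centroids, alphabet=alphabet,
                               frame_interval=frame_interval)
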