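# Methods

This note documents the models, estimators and design choices behind
`fragnet`, and what its synthetic validation does and does not show about
real data.

## Structural-alphabet encoding

Local backbone conformation is discretised by encoding every overlapping
window of four consecutive Cα atoms as one letter of a structural alphabet:
the letter whose prototype fragment minimises the least-squares
superposition RMSD (optimal translation + *proper* rotation; reflections
are forbidden because mirror-image backbone geometries are distinct states).
Ties break to the earlier letter in alphabet order, so encoding is
deterministic.  Windows never span chain breaks: a chain change or a
residue-numbering gap > 1 terminates the window run, and a chain of *n*
contiguous residues contributes *n* − 3 fragments.  Encoding is invariant
under rigid motion of a frame, which the test suite asserts directly.

### The packaged alphabet is synthetic

The packaged 25-letter set (built-in ids `SA25` and `M32K25`) is **not** a
literature-derived fragment library: those coordinate sets are not
redistributable here.  Instead, each prototype is the Cα trace of an
ideal-geometry tetrapeptide (Engh–Huber-like bond lengths/angles, ω = 180°)
built at one of 25 Ramachandran (φ, ψ) points chosen to cover the
α-helical basin (5 letters, the `helix_class`), the extended/β basin
(7 letters, the `sheet_class`), the polyproline-II region, the 3₁₀ and
turn/bridge regions, the left-handed helical basin and rare positive-φ
states.  The construction is deterministic (`build_ramachandran_alphabet`)
and the shipped JSON is its frozen output.  Consequences worth knowing:

* letter *identities* are not comparable with any published alphabet;
* helix/sheet class membership is assigned from the generating dihedrals,
  and an ideal α-helix curve (rise 1.5 Å, radius 2.3 Å, 100°/residue)
  encodes uniformly to a helix-class letter, an extended chain to a
  sheet-class letter (asserted in tests);
* several α-basin prototypes lie within ~0.01–0.1 Å RMSD of each other, so
  coordinate noise splits one physical state over a few adjacent letters.
  This only adds entropy to the letter columns; the information-theoretic
  machinery below is explicitly designed to be robust to such relabelling
  (nMI is invariant under letter permutation, and state information is
  preserved — a noisy helix column still carries its full switching
  signal).

Users can load their own alphabet from JSON or TSV; a `relaxed` flag admits
small toy alphabets for testing.

## Coupling statistics

For fragment-state columns *X*, *Y* over *N* frames, with Shannon entropies
in bits:

    I(X;Y)   = H(X) + H(Y) − H(X,Y)
    ε(X;Y)   = max(0, (B_xy − B_x − B_y + 1) / (2 N ln 2))
    nMI(X;Y) = max(0, I − ε) / H(X,Y),   defined as 0 when H(X,Y) = 0

ε is the standard first-order finite-sampling bias of the mutual
information (*B* = number of occupied states); subtracting it and clamping
at zero keeps the null expectation near zero — for independent uniform
25-letter columns at *N* = 1000 the corrected nMI averages below 0.02
(asserted by a Monte-Carlo test).  Entropies are in bits throughout; the
thermodynamic conversion ΔS = k_B·H is left to the caller.

**Replica averaging.**  Multiple replicas are combined by arithmetic
averaging of their per-replica nMI matrices, *not* by pooling frames:
pooling would count slow inter-replica drift as coupling.

**Thresholding.**  Significant couplings are pairs with
nMI ≥ mean + *k*·σ of the off-diagonal values (each unordered pair counted
once; default *k* = 2).  An explicit nMI threshold can override the σ rule.
The spatial filter removes pairs whose frame-averaged centroid–centroid
distance is below the long-range cutoff (default 12 Å).  Overlapping
4-residue windows share atoms and therefore couple trivially; the spatial
filter is what isolates genuine long-range communication.  Whether the σ
statistics themselves are computed over all pairs (default) or only
long-range pairs is exposed as `long_range_stats`.

**Centrality.**  Eigenvector centrality solves E·M = λ·E on the
(zero-diagonal, non-negative) nMI matrix; the Perron eigenvector is
reported max-normalised to 1.  It is computed by dense symmetric
eigendecomposition and cross-checked in tests against an independent
power-iteration oracle at 10⁻⁸.

**Communities.**  Girvan–Newman edge-betweenness removal on the thresholded
graph; the partition with maximum Newman modularity along the removal
dendrogram is kept (ties resolve to the fewest removals, and the initial
connected-components partition competes as a candidate).  Communities with
≤ 3 members (configurable) are reported as *unassigned*.  The community
graph collapses each community to a node whose size is the number of
distinct residues covered by its member fragments and whose edge weights
count the retained couplings between communities.

## Collective motions

* **Superposition**: per-frame Kabsch fit (via quaternion-free SVD /
  `scipy` rotation alignment) of a selection onto a reference frame or
  external coordinates; the fitted transform is applied to all atoms.
* **RMSF**: RMSF_a = √⟨|r_a − ⟨r_a⟩|²⟩ per atom; the pseudo-B-factor
  (8π²/3)·RMSF² is comparable to crystallographic B.  For isotropic
  Gaussian displacements of width σ the expectation is σ√3, which the
  suite verifies at ±2 %.
* **PCA**: eigendecomposition of the mass-unweighted 3A × 3A covariance of
  selected Cα coordinates (population covariance, ddof 0, so the eigenvalue
  sum equals the coordinate-variance trace exactly).
* **RMSIP**: √((1/k)ΣᵢΣⱼ(vᵢ·wⱼ)²) over the first *k* components
  (default 10), with the k × k dot-product matrix reported.
* **Spread and overlap**: frames are projected onto chosen PCs; the PC1–PC2
  cloud is summarised by its convex-hull area and two clouds by
  intersection-over-area of their hulls.  Hulls make the comparison
  deterministic but are sensitive to outlying frames; they quantify
  *relative* spread, not a density overlap.
* **Clustering**: GROMOS-style neighbour counting on the pairwise Cα RMSD
  matrix of the superposed ensemble (no per-pair refitting), iteratively
  removing the largest-neighbourhood cluster; ties resolve to the earliest
  frame, making the procedure deterministic given frame order.  Default
  cutoff 2.0 Å.

## Interface geometry

SASA uses the Shrake–Rupley construction with a deterministic Fibonacci
sphere (default 960 points, probe 1.4 Å) and a bundled van der Waals radius
table (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å; hydrogens excluded
by default, radii overridable).  Accuracy: within 1 % of the two-sphere
closed form at 960 points and within 0.2 % of an independent library
implementation on a random cluster (both asserted).  Buried surface area is
BSA = SASA(A) + SASA(B) − SASA(A∪B); the contribution of a sub-segment
(e.g. a captured regulatory peptide) is attributed as its own ΔSASA plus
the partner's ΔSASA.  Contacts are residue pairs with any heavy-atom
distance ≤ 4 Å (k-d tree, verified against a brute-force pair scan).

Helical propensity is the arithmetic mean of per-residue values from a
scale supplied as data; the packaged default is the Pace–Scholtz helix
propensity scale (kcal/mol, Ala = 0).  Published propensity scales differ
in sign and reference conventions, so absolute values are only meaningful
relative to the scale in use.

## Coupling time series

Windowed nMI applies the full bias-corrected estimator to sliding windows
(default 50 frames, stride 10 — chosen so a 1000-frame input yields ≥ 20
windows; both are configurable).  Short windows occupy fewer states, so the
bias correction is what keeps the windowed null near zero.  The CCF is the
per-lag Pearson correlation of the mean-centred overlapping segments (no
FFT wrap-around, avoiding bias from shrinking overlap); it reports peak
amplitude, peak lag, and a correlation time τ defined as the interpolated
lag beyond the peak where |CCF| first falls to peak/e — on an AR(1) process
with decay constant τ this recovers τ within 10 %.  Dwell times are exact
run-length encodings of the letter series; for a two-state Markov chain
with stay probability *p* the mean dwell is 1/(1−p), verified at 100 000
frames.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes — and
nothing else.  A multi-chain Cα polymer is grown by NeRF-style placement
from per-residue internal coordinates taken from one of two local
geometries: helix-like (rise 1.5 Å, radius 2.3 Å, 100°/residue) or
extended (rise 3.3 Å, radius 1.0 Å, 180°/residue).  Designated
non-overlapping 4-residue segments switch between the two geometries as
two-state Markov chains (stay probability 1 − switch_rate); for each
planted (driver, partner) pair the partner copies the driver's state with
probability `coupling_strength` each frame (including frame 0, so the
zero-switch-rate limit is truly static), otherwise it steps independently.
Optional background segments switch independently to provide null
statistics.  Isotropic Gaussian noise (default σ = 0.15 Å) is added to all
coordinates.  Internal-coordinate handedness is verified against an
external dihedral implementation, and at generation time the two noise-free
local geometries are encoded and asserted to map to different letters.

Everything is a pure function of (spec, seed); the seed is mandatory and
reruns are bit-identical.  `markov_letters` provides the same planting
semantics directly in letter space (no geometry) as a fast path for testing
the information-network stage.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no excluded volume or physics of any kind, no
side chains, no anisotropic or correlated noise, no slow global motions
superimposed on the local switching, and switching segments are
non-overlapping by construction.  Real ensembles add all of these; the
synthetic suite validates the *estimators*, not the biology.

## Demonstration scale

The end-to-end relay demonstration uses a two-chain, 30-residue-per-chain
polymer over 2000 frames with a three-link relay (A→B→B→A) at coupling
strength 0.9 and the default 2σ + 12 Å filter.  2000 frames was chosen by
statistical power: the sampling error of an nMI estimate at this length
(~0.01) is small against the separation between planted long-range
couplings (nMI ≈ 0.18–0.28) and the threshold (≈ 0.16), making recovery a
property of the method rather than of a particular seed (verified over ten
seeds).  Production ensembles are typically one to two orders of magnitude
larger; all estimators scale linearly in frames and quadratically in
fragments.

## Numerical choices and degenerate inputs

* Entropy terms use 0·log 0 = 0; nMI is clamped into [0, 1]; H(X,Y) = 0
  (both columns constant) defines nMI = 0.
* Encoding ties and clustering ties break deterministically (alphabet
  order / earliest frame).
* Alternate locations in PDB input keep the highest-occupancy conformer
  (ties → first in file); insertion codes are appended to the residue key;
  modified residues (e.g. phosphothreonine) are first-class, with elements
  inferred from atom names when the element column is blank.
* B-factor annotation values are clamped to the fixed-width PDB field
  (±999.99) with a logged warning; non-finite values are errors.
* An all-zero coupling matrix has no principal direction and is an error
  for centrality; an edgeless network yields an all-unassigned partition,
  not an error; a threshold that removes every edge yields an empty
  network with the threshold recorded.
* Degenerate fragments (coincident Cα) are geometry errors; chains with
  < 4 residues contribute no fragments (warning, not error).

## Known limitations

* The synthetic alphabet is a stand-in: analyses that depend on the letter
  semantics of a published alphabet require loading that alphabet from
  file.
* Hull-based spread/overlap is outlier-sensitive and defined for two
  components only.
* Girvan–Newman is O(E²·N)-ish and intended for thresholded (sparse)
  networks, not for the dense candidate matrix.
* The SASA module expects heavy-atom coordinates with recognisable
  elements; exotic elements need explicit radius overrides.
* Pairwise-RMSD clustering stores an F × F matrix; very long trajectories
  should be strided first.
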