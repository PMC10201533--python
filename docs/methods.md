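# Methods

`xmecp` locates minimum-energy crossing points (MECPs) between diabatic
electronic states — including higher-lying and three-state crossings — on a
non-self-consistent tight-binding surface, without derivative coupling
vectors.  This note records the model, its parameters, the numerical choices,
and what the shipped tests do and do not demonstrate.

## Electronic model

The electronic problem is a one-electron extended-Hückel treatment in a
valence minimal basis of Slater-type orbitals.  Each valence shell is a
3-term Gaussian expansion of the corresponding Slater function (exponents
scaled by ζ²), so every overlap integral is closed form; the expansion
tables for 1s/2s/2p are the standard published fits, while the sulfur 3s/3p
expansions were fitted once by the same overlap-maximization criterion and
frozen in the source.  The Hamiltonian is built from the overlap by the
Wolfsberg–Helmholz rule

    H_mn = K/2 (H_mm + H_nn) S_mn,  K = 1.75,  H_mm = shell on-site energy,

with classic extended-Hückel valence-state ionization energies and Slater
exponents for H, C, N, O, S (data file `src/xmecp/data/eht_params.yaml`,
versioned and loadable by path override).

Because `H` does not depend on the electron distribution, the generalized
eigenproblem `H C = S C ε` is solved **once per geometry** and every
electronic state — ground, singly excited, doubly excited, non-Aufbau with
holes — is obtained from the same orbitals by choosing a different
occupation vector.  A state's electronic energy is

    E_el = Σ_mn P_mn H_nm = Σ_i n'_i ε_i,  P = C diag(n') Cᵀ,

and the full state energy adds the classical pair term below.  The package
verifies in its tests that the diagonalization count is exactly one per
geometry regardless of the number of states requested.

## Classical pair energy

Bare extended-Hückel theory binds through orbital overlap but systematically
underbinds lone-pair-rich bonds: with a purely repulsive classical
complement, relaxed azobenzene comes out with N=N ≈ 1.86 Å and the torsional
physics of the azo bridge disappears.  The classical term therefore combines
Born–Mayer repulsion with a short-range attractive bond well centered at the
covalent-radius sum (the same role the short-range bond correction plays in
modern tight-binding methods):

    E_cl = Σ_{A<B} [ Z_A Z_B / R · exp(−b R^c)
                     − d √(Z_A Z_B) · exp(−β (R − r_A − r_B)²) ]

with Z the valence electron counts, r the per-element well radii, and
globals b = 0.8, c = 2.0 (a.u.), d = 0.08 hartree, β = 1.1 bohr⁻².  The
four globals and the radii were tuned once against the relaxed internal
coordinates of trans-azobenzene (experimental N=N 1.25 Å, C–N 1.43 Å,
C–N=N 114°) plus H₂/diatomic sanity, and then frozen.  Residual bias of the
frozen model: relaxed N=N ≈ 1.40 Å, C–N ≈ 1.43 Å, C–C ≈ 1.45 Å, C–H ≈
1.17 Å, C–N=N ≈ 123°; H₂ binds at 0.92 Å with a single interior minimum.
E_cl is identical for all electronic states, so it cancels exactly in every
state-energy difference — only state *averages* feel it.

## States and hole-tolerant Fermi smearing

A diabatic state is a per-spin 0/1 reference occupation over the
energy-ordered spatial orbitals (spin-restricted: α and β share orbitals).
Holes — an empty orbital below a filled one — encode non-Aufbau
configurations such as `OS2 = (HOMO−1 → LUMO)`.  At electronic temperature
T_el each spin channel is fractionally smeared around its reference:

    n'_iσ = ref_iσ + (1 − 2 ref_iσ) · h(|ε_i − ε_F^σ| / k_B T_el),
    h(z) = e^(−z) / (1 + e^(−z)),

a two-sided Fermi-type distribution centred on the channel's Fermi level.
For an Aufbau reference this is exactly ordinary Fermi–Dirac smearing; for
hole references, orbitals above the hole smear partially back into it, which
is what keeps optimizations stable near orbital crossings.  ε_F^σ starts at
the frontier-orbital midpoint and is adjusted so the channel's electron
count is conserved (to 1e-10 e).  The particle-number residual of this form
is not globally monotone in ε_F — it vanishes at ε_F → ±∞ — so the solver
brackets sign changes on a grid around the frontier window and refines the
crossing nearest the initial guess with Brent's method.  For a small class
of exotic references (e.g. a single filled orbital below several empties)
no single ε_F balances the channel at all; the implementation then holds
ε_F at the frontier midpoint and rescales the loss and gain sides of the
smearing to the smaller of the two, which conserves the count exactly and
preserves the T_el → 0 limit.  T_el = 0 is an explicit branch returning the
integer reference.  **No electronic entropy term is computed** from the
fractional occupations: state energies are plain occupation-weighted sums,
which is what allows a gap penalty to reach zero at a crossing.

Defaults: T_el = 3000 K; k_B = 3.166811563×10⁻⁶ hartree/K.  Occupation
references are defined against the energy-ordered orbitals of each geometry
(no diabatic orbital tracking); near orbital crossings along a scan the
fixed ordering can swap orbital character between neighbouring points, which
shows up as cusps in state-energy profiles.  This is documented behaviour,
not hidden.

## Seam surface and gap penalty

Crossing points are minima of the artificial seam surface

    E_seam = E_avg + Σ_{(i,j)∈pairs} V_gap(E_i − E_j),

where E_avg is the arithmetic mean over the states involved in penalized
pairs, and

    V_gap(ΔE) = σ [ ΔE²/(|ΔE| + α) + k (√(ΔE² + α²) − α) ].

At k = 0 this is the classic smoothed gap penalty of derivative-coupling-
vector-free crossing-point searches; the k term adds a linearly growing
far-field bias (asymptotic slope σ(1+k)) that prevents artificial maxima
from ringing the MECP when the state surfaces separate steeply.  The penalty
is zero at the seam, even, monotone in |ΔE| and once-differentiable
everywhere; its derivative at ΔE = 0 is taken as its analytic limit (zero by
parity).  Defaults σ = 10.0, α = 0.005 hartree, k = 0.25; system-dependent
adjustment should be made mainly through σ.  Pair selection is explicit —
a tristate search lists all three pairs — and the seam gradient is the exact
chain rule over per-state gradients, so no coupling vectors appear:

    ∇E_seam = (1/n) Σ_i g_i + Σ_{(i,j)} V'_gap(ΔE_ij) (g_i − g_j).

With finite σ the optimized point carries a small residual gap; it shrinks
monotonically as σ grows (verified on quadratic models over σ ∈ {1, 10,
100}).  Validation compares the package's optimizer against a brute-force
minimizer of the *same* penalty surface at matched α, and separately against
the exact constrained minimizer (Lagrange closed form for two isotropic
quadratics; multi-start SLSQP certified by KKT residual < 1e-6 otherwise).

## Gradients and optimization

Nuclear gradients are central finite differences of the total energy (step
1e-4 bohr per Cartesian component; translational force sums vanish to
< 1e-6 hartree/bohr).  State gradients re-smear the occupations at every
displaced geometry; one displacement costs one diagonalization for *all*
states.  Analytic gradients are an extension point.

The minimizer is a limited-memory quasi-Newton (L-BFGS, memory 12) with a
backtracking Armijo line search (c = 1e-4, shrink 0.5) and the initial step
bounded to 0.2 bohr per coordinate; on the tight-binding backend line-search
trials use the cheap value-only evaluation (one diagonalization) while
gradients (~150 diagonalizations) are computed only at accepted points.
After three consecutive line-search failures the history is dropped and a
small steepest-descent trust step is attempted.  Convergence requires RMS
gradient < 1e-4 **and** maximum component < 2e-4 hartree/bohr (common
tight-binding optimizer defaults; the choice is this package's).
Optimization coordinates are plain Cartesians.  Non-convergence is a flagged
result with the full iteration trace, never an exception.

## Relaxed torsional scans

`relaxed_scan` restrains one dihedral with a harmonic term (default force
constant 5 hartree/rad², constraint tolerance 0.5°; stiff π torsions such as
ethylene's warrant ~20), relaxes a chosen state at every grid angle, then
reports any number of states at the relaxed geometry from one extra
diagonalization.  Each point warm-starts from the previous relaxed geometry
with the distal fragment rigidly pre-rotated about the scanned bond to the
new target angle (fragment found by a covalent-radius connectivity cut), so
the restraint starts at zero force; in-scan relaxations use a slightly
looser gradient threshold (RMS 3e-4 hartree/bohr) than stationary-point
searches.  A relaxed single-dihedral scan is a *minimum-energy path* probe:
soft degrees of freedom re-arrange around the restrained coordinate.  For
ethylene this matters — the CH₂ groups distort rather than cleanly twist the
π bond, so the rigid twist, not the relaxed path, exhibits the textbook
π/π* crossing at 90°; the test suite probes exactly that.  For azobenzene
the rings are rigid and the C–N=N–C dihedral faithfully tracks the azo
π twist.

A warm-started sweep carries hysteresis: once it passes a state crossing it
can drop into a metastable branch of the relaxed state (for azobenzene, a
CNN-opened structure whose frontier gap stays pinned near zero, a genuine
local minimum a few mhartree above the proper branch) and drag that branch
across the remaining grid.  `relaxed_scan_segments` cures this by sweeping
the grid in segments that each approach the crossings from a cold anchor —
for a full torsional period, four quarter-sweeps anchored at both period
ends and the midpoint — and keeping, per grid angle, the candidate with the
lower relaxed-state energy.  The production azobenzene analysis uses this
protocol; the plain single sweep remains available and is what the segments
are built from.

## Fixture molecules

All test inputs are generated from fixed internal coordinates (natural-
extension construction from an internal Z-matrix): H₂ (0.74 Å), planar
ethylene (C=C 1.33 Å, C–H 1.09 Å, HCC 121.5°, twistable), azobenzene
(N=N 1.25 Å, C–N 1.43 Å, aromatic C–C 1.39 Å, C–H 1.09 Å, C–N=N 115°,
requested C–N=N–C dihedral).  Near the cis side, planar rings would collide
(ortho H···H far below contact distance), so the generator applies a smooth
conrotatory phenyl twist — 55° at cis, 0 at trans, overridable via
`ring_twist` — mirroring the real cis-azobenzene conformation.  Fixtures are
bit-for-bit reproducible and require no downloads.

## What the tests show — and what they do not

The quadratic model surfaces have closed-form or certified crossing points;
agreement there validates the *seam machinery* (penalty, chain rule,
optimizer) independent of electronic structure.  The azobenzene scan
validates the *whole stack* qualitatively: the GS–OS1 gap closes at the
twisted dihedrals, symmetric about 180°.  None of this demonstrates
quantitative excited-state energetics: the electronic model is a classic
extended-Hückel surrogate with a purpose-built classical complement, its
energy gaps are one-electron estimates, spin multiplicities are
indistinguishable (no spin-discriminating terms; open-shell patterns stand
for singlet and triplet alike), and charge transfer and Fock exchange are
absent.  Crossing-point *geometries* are the intended product; energies are
qualitative.  Known limitations: relaxed N=N ~0.15 Å long and C–N=N ~9°
wide versus experiment; no analytic gradients; elements limited to the
shipped table; no periodic systems; no oscillator strengths or state
classification.

One consequence of the soft C–N=N bend deserves emphasis: along the
azobenzene torsional scan the relaxed ground state does not merely touch
the GS–OS1 degeneracy at the perpendicular twist — it *rides* it, opening
the C–N=N angles at negligible energetic cost so that the gap stays below
~5·10⁻⁴ hartree over a plateau roughly 25° wide centred near the
perpendicular geometry (and its mirror image).  The gap closure, the
plateau's location in the twisted region and its symmetry about the trans
geometry are robust; the *single grid angle* minimizing the gap is not — on
a 1° grid it is selected by relaxation noise (~10⁻⁵ hartree) somewhere on
the plateau, typically at an edge.  Better-parametrized tight-binding
models with a stiffer azo bend localize this crossing sharply near 90°.

## Problem sizes

Default test and acceptance runs use: quadratic models in 2–3 dimensions
(30 random instances); H₂/ethylene for identity and gradient checks; one
azobenzene relaxed scan at 1° over the full period (four quarter-sweeps,
~722 relaxations of a 24-atom molecule, 66 basis functions) — several
minutes on one CPU.  Hot paths (eigenvalues-only diagonalization,
incremental single-atom overlap updates for finite-difference
displacements, warm-started Fermi levels) are verified against the plain
implementations in the test suite.
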