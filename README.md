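# xmecp

Minimum-energy crossing points (MECPs) between diabatic electronic states —
including higher-lying and three-state crossings — from a **single
diagonalization** of a non-self-consistent extended-Hückel tight-binding
Hamiltonian, with a derivative-coupling-vector-free penalty seam search.

Photochemistry lives on the seams where potential-energy surfaces cross:
minimum-energy conical intersections (MECIs) play the role that transition
states play for ground-state reactions.  Locating them *ab initio* is
expensive (derivative coupling vectors, multireference treatments), so a
cheap prescreening level is valuable: MECPs between *diabatic* states —
states pinned by fixed orbital-occupation patterns — approximate MECIs well
enough to seed refinement at a higher level.  `xmecp` is such a prescreener
for desk-scale organic molecules (H, C, N, O, S), aimed at method
exploration and teaching: because the one-electron Hamiltonian is
independent of the electron distribution, one diagonalization per geometry
yields energies and gradients for *arbitrarily many* states, including
non-Aufbau configurations with holes.

## The model in brief

* **Electronic energy** `E_el = Σ_i n'_i ε_i` from `H C = S C ε`, with the
  Wolfsberg–Helmholz Hamiltonian `H_mn = K/2 (H_mm + H_nn) S_mn` (K = 1.75)
  over a valence minimal Slater basis (3-Gaussian expansions), plus a
  classical pair term (Born–Mayer repulsion + short-range bond well) that is
  identical for all states and cancels in every gap.
* **States** are per-spin 0/1 reference occupations, possibly with holes
  (e.g. `OS2 = HOMO−1 → LUMO`).  A hole-tolerant two-sided Fermi smearing

  `n'_iσ = ref_iσ + (1 − 2 ref_iσ) h(|ε_i − ε_F^σ|/k_B T_el)`,
  `h(z) = e^(−z)/(1+e^(−z))`,

  reduces to ordinary Fermi–Dirac for Aufbau references, lets electrons
  smear back into holes, and conserves each spin channel's count by
  adjusting `ε_F^σ`.  No electronic entropy is added.
* **Seam surface** `E_seam = E_avg + Σ_(i,j) V_gap(E_i − E_j)` with

  `V_gap(ΔE) = σ[ΔE²/(|ΔE|+α) + k(√(ΔE²+α²) − α)]`,

  zero at the seam, asymptotically linear (slope σ(1+k)); defaults
  σ = 10.0, α = 0.005, k = 0.25.  Minimizing `E_seam` (L-BFGS with exact
  chain-rule gradients over finite-difference state gradients) yields the
  MECP; summing pairwise penalties extends the same machinery to tristate
  crossings.

See `docs/methods.md` for assumptions, parameter provenance and limitations.

## Worked example

Crossing-point search between the ground state and the HOMO→LUMO state of
H₂ (the σ/σ* crossing lies toward dissociation):

```python
import numpy as np
from xmecp import build_fixture, make_state, optimize_mecp
from xmecp.seam import SeamParams

geom = build_fixture("h2", r=0.9)                      # start at 0.9 A
gs  = make_state("GS",  1, 1, [], n_orbitals=2)
os1 = make_state("OS1", 1, 1, [("HOMO", "LUMO", "alpha")], n_orbitals=2)

res = optimize_mecp(geom, [gs, os1], SeamParams(t_el=3000.0),
                    backend="tight-binding")
r = np.linalg.norm(res.point[3:] - res.point[:3]) * 0.52917721092
print(res.converged, round(r, 3), f"{res.gaps[(0, 1)]:.2e}")
```

prints

```
True 3.569 -1.68e-04
```

— the optimizer walks the bond out to 3.57 Å where the σ/σ* gap has closed
to 1.7·10⁻⁴ hartree (the small residual is the finite-penalty signature; it
shrinks as σ grows).  The same call with three states and
`pairs=((0,1),(1,2),(0,2))` optimizes a tristate crossing.  The examples
directory holds one short script per capability:

* `examples/multi_state_energies.py` — four states of ethylene from one
  diagonalization,
* `examples/mecp_on_model_surface.py` — seam optimizer vs the exact
  constrained minimizer on analytic quadratic models,
* `examples/azobenzene_torsion_scan.py` — coarse relaxed torsional scan of
  azobenzene with the GS–OS1 gap closing near the perpendicular twist.

A thin CLI mirrors the drivers: `xmecp energies`, `xmecp scan`,
`xmecp mecp` (see `--help`; accepts XYZ files or built-in fixtures).

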