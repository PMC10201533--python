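# Extended-Hueckel element parameters, version 1.
#
# Slater exponents (zeta, a.u.) and on-site energies (hartree) are the classic
# extended-Hueckel values (valence-state ionization potentials: H 13.6 eV;
# C 21.4/11.4; N 26.0/13.4; O 32.3/14.8; S 20.0/13.3 eV for s/p).
#
# The classical pair energy (all quantities a.u., Z = valence electron count,
# r_cov per element in bohr) is
#   E_cl = sum_{A<B} [ Z_A Z_B / R * exp(-b R^c)
#                      - d sqrt(Z_A Z_B) exp(-beta (R - r_cov,A - r_cov,B)^2) ]
# i.e. Born-Mayer repulsion plus a short-range bond well that compensates the
# systematic underbinding of bare extended-Hueckel theory for lone-pair-rich
# bonds.  (b, c, d, beta) and the radii were tuned once against the relaxed
# bond lengths of azobenzene and model diatomics (see docs/methods.md) and
# are frozen here.
version: 1
wolfsberg_helmholz: 1.75
repulsion:
  b: 0.8000
  c: 2.0000
srb:
  d: 0.0800
  beta: 1.1000
elements:
  H:
    valence_electrons: 1
    r_cov: 0.6236
    shells:
      - {n: 1, l: s, zeta: 1.300, h_onsite: -0.49979078}
  C:
    valence_electrons: 4
    r_cov: 1.3417
    shells:
      - {n: 2, l: s, zeta: 1.625, h_onsite: -0.78643549}
      - {n: 2, l: p, zeta: 1.625, h_onsite: -0.41894227}
  N:
    valence_electrons: 5
    r_cov: 1.2283
    shells:
      - {n: 2, l: s, zeta: 1.950, h_onsite: -0.95548238}
      - {n: 2, l: p, zeta: 1.950, h_onsite: -0.49244092}
  O:
    valence_electrons: 6
    r_cov: 1.2473
    shells:
      - {n: 2, l: s, zeta: 2.275, h_onsite: -1.18700311}
      - {n: 2, l: p, zeta: 2.275, h_onsite: -0.54388997}
  S:
    valence_electrons: 6
    r_cov: 1.9843
    shells:
      - {n: 3, l: s, zeta: 2.122, h_onsite: -0.73498644}
      - {n: 3, l: p, zeta: 1.827, h_onsite: -0.48876598}
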