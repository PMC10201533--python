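"""Several diabatic states of ethylene from one diagonalization.

Builds planar ethylene, defines four occupation-pattern states (the closed-
shell ground state GS, the HOMO->LUMO single excitation OS1, the HOMO->LUMO
double excitation CS1 and the HOMO-1->LUMO excitation OS2) and evaluates all
of them at T_el = 3000 K from a single orbital solution.
"""

from xmecp import build_fixture, evaluate_states, make_state
from xmecp.constants import HARTREE_TO_EV
from xmecp.eht import EHTCalculator

geom = build_fixture("ethylene")
norb = EHTCalculator(geom).basis.n_functions  # 12 valence functions

states = [
    make_state("GS", 6, 6, [], n_orbitals=norb),
    make_state("OS1", 6, 6, [("HOMO", "LUMO", "alpha")], n_orbitals=norb),
    make_state("CS1", 6, 6, [("HOMO", "LUMO", "alpha"), ("HOMO", "LUMO", "beta")],
               n_orbitals=norb),
    make_state("OS2", 6, 6, [("HOMO-1", "LUMO", "alpha")], n_orbitals=norb),
]

result = evaluate_states(geom, states, t_el=3000.0)

print("state   E_total [hartree]   dE vs GS [eV]")
e0 = result.energies[0]
for st, e in zip(states, result.energies):
    print(f"{st.label:5s}   {e:16.8f}   {(e - e0) * HARTREE_TO_EV:10.3f}")

# The excitation energies are one-electron orbital-energy differences (plus
# smearing effects): OS1 ~ eps(LUMO) - eps(HOMO); CS1 roughly twice that;
# OS2 is larger since it digs one orbital deeper.  All four states share the
# classical pair energy, which cancels in every difference.
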