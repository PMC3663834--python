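"""Solve EEM atomic charges for a toy phenol and its phenolate anion.

Builds a planar phenol-like molecule, deletes the acidic hydrogen to get
the anion (total charge -1, geometry untouched), and solves the
electronegativity-equalization system for both under a synthetic parameter
set.  The printed charges sum exactly to the molecular charge; chi_bar is
the equalized molecular electronegativity.
"""

from eempka import gen_parameter_set, gen_toy_phenol, make_dissociated, solve_eem

params = gen_parameter_set(3)
mol, site = gen_toy_phenol(substituent_shift=0.0, seed=1)
anion, mapping = make_dissociated(mol, site)

for m in (mol, anion):
    res = solve_eem(m, params)
    print(f"\n{m.id}  (Q = {m.total_charge:+d}, chi_bar = {res.chi_bar:.4f})")
    for idx, (atom, q) in enumerate(zip(m.atoms, res.charges)):
        print(f"  {idx:2d} {atom.element:<2} {q:+.4f}")
    print(f"  sum(q) = {res.charges.sum():+.2e}")

print(
    "\nSite charges (descriptors): "
    f"q_H = {solve_eem(mol, params).charges[site.h_index]:+.4f}, "
    f"q_O = {solve_eem(mol, params).charges[site.o_index]:+.4f}, "
    f"q_OD = {solve_eem(anion, params).charges[mapping[site.o_index]]:+.4f}"
)
print("q_OD is more negative than q_O: the anion localizes charge on O.")
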