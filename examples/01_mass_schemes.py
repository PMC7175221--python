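"""Hydrogen-mass schemes on reference topologies.

Builds united-atom and all-atom topology texts for the six-unit sugar
macrocycle and the dodecyl-sulfate surfactant, applies the HMR (mass
repartitioning, total mass conserved) and H2Q (hydrogen-to-quadium, polar H
set to 4 Da) schemes, and prints the resulting mass changes.
"""

from cdsolv import topology as tp
from cdsolv.synth import alpha_cd_topology, sds_topology

for label, text, hydrogens in (
    ("macrocycle, all-atom, all 60 H", alpha_cd_topology("all_atom"), "all"),
    ("macrocycle, united-atom, 18 polar H", alpha_cd_topology("united"), None),
    ("surfactant salt, all-atom, 25 H", sds_topology("all_atom"), "all"),
):
    mol = tp.parse_topology(text).molecule()
    mod = tp.apply_h2q(mol, hydrogens=hydrogens)
    rep = tp.mass_increase_report(mol, mod)
    print(f"{label}: {mol.total_mass:8.2f} Da, +3 Da per H adds "
          f"{rep['added']:6.1f} Da = {rep['percent']:5.2f} % of the molecule")

ua = tp.parse_topology(alpha_cd_topology("united")).molecule()
hmr = tp.apply_hmr(ua)
print(f"\nHMR on the united-atom macrocycle: total mass change "
      f"{hmr.total_mass - ua.total_mass:+.1f} Da (mass moves O->H, sum conserved)")
pair = tp.identify_polar_hydrogens(ua)[0]
h_mod, o_mod = hmr.atom(pair.index), hmr.atom(pair.partner)
h_orig, o_orig = ua.atom(pair.index), ua.atom(pair.partner)
print(f"e.g. one hydroxyl after HMR: H {h_orig.mass:g} -> {h_mod.mass:g} Da, "
      f"its O {o_orig.mass:g} -> {o_mod.mass:g} Da")

# The small united-atom percentage is why heavier polar hydrogens are cheap
# for united-atom force fields: only 18 of the 60 hydrogens are explicit.
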