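"""Conceptual-DFT reactivity descriptors from HOMO/LUMO energies.

Builds the full descriptor table (energy gap, chemical potential,
hardness, I, A, electronegativity, electrophilicity) for digitoxin free
and in three docked conformers, from the published orbital energies.
"""

from bindscope import OrbitalEnergies, descriptor_table

orbital_sets = [
    OrbitalEnergies(-6.507, -0.933, "free"),
    OrbitalEnergies(-6.41, -0.911, "conformer 1"),
    OrbitalEnergies(-6.541, -0.85, "conformer 2"),
    OrbitalEnergies(-6.509, -1.36, "conformer 3"),
]

table = descriptor_table(orbital_sets)
print(table.to_string(float_format=lambda v: f"{v:.9g}"))
# A smaller HOMO-LUMO gap (conformer 3) means lower kinetic stability
# and higher reactivity; the larger electrophilicity index there marks
# the strongest electron-accepting tendency of the bound ligand.
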