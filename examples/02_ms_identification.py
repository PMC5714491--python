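"""Identify flavonoids from negative-mode MS/MS peaks by pure arithmetic.

Wild-type petals accumulate apigenin glycosides (flavones): the 445 m/z
ion is deprotonated apigenin-7-glucuronide and its 269 m/z product ion
is free apigenin after a glucuronyl (176 Da) neutral loss.  Mutant
petals accumulate naringenin glycosides (flavanones) instead: the free
aglycone appears at its nominal mass 272, and retro-Diels-Alder
cleavage of the C ring (across O1-C2 and C3-C4) yields the diagnostic
151/119 fragment pair.
"""

from bsakit import (
    LibrarySpecies,
    annotate_spectrum,
    deprotonated_mz,
    neutral_loss,
    nominal_mass,
    parse_formula,
    rda_fragments,
)

apigenin = parse_formula("C15H10O5")
glucuronide = parse_formula("C21H18O11")
naringenin = parse_formula("C15H12O5")
eriodictyol = parse_formula("C15H12O6")

print("apigenin [M-H]-            :", deprotonated_mz(apigenin))
print("apigenin-7-glucuronide [M-H]-:", deprotonated_mz(glucuronide))
print("445 -> 269 neutral loss    :", [r.name for r in neutral_loss(445, 269)])
print("naringenin nominal mass    :", nominal_mass(naringenin))
frags = rda_fragments(naringenin)
print("naringenin 1,3-RDA ions    :", frags.a_ion_mz, "/", frags.b_ion_mz)
print("eriodictyol [M-H]-         :", deprotonated_mz(eriodictyol))

print("\nannotating the mutant-petal product-ion spectrum [272, 151, 119]:")
for a in annotate_spectrum([272, 151, 119], [LibrarySpecies("naringenin", naringenin)]):
    print(f"  m/z {a.observed_mz:>5}: {a.species} ({a.ion_type}, {a.rule})")
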