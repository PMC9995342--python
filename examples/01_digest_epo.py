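"""Digest mature erythropoietin with Glu-C + trypsin and find glycosites.

The combined rule cleaves C-terminal to E/D/R/K with up to two missed
cleavages; the three N-glycosylation sequons of the mature chain sit at
Asn24, Asn38 and Asn83, and each is carried by one of the printed
glycopeptide backbones.
"""

import glycotarget as gt
from glycotarget.digestion import peptides_to_frame

epo = gt.load_epo_mature()
print(f"mature EPO: {len(epo)} residues")

sites = gt.find_sequons(epo)
print("N-glycosylation sequons:", [(a.protein_position, a.sequon) for a in sites])

peptides = gt.digest(epo, gt.GLUC_TRYPSIN)
df = peptides_to_frame(peptides)
print(f"{len(df)} fully specific peptides with <= 2 missed cleavages")

backbones = df[df.sequence.isin(
    ["AENITTGCAE", "HCSLNENITVPDTK", "GQALLVNSSQPWEPLQLHVDK"]
)]
print("\nglycopeptide backbones covering the three sites:")
print(backbones.to_string(index=False))

# each backbone x one glycan composition -> candidate glycopeptides
glycans = [gt.parse_glycan_composition("HexNAc(6)Hex(7)Fuc(1)NeuAc(4)")]
cands = gt.enumerate_candidates(
    [p for p in peptides if p.sequence == "HCSLNENITVPDTK"],
    [a for a in sites if a.protein_position == 38],
    glycans,
)
print(f"\ncandidate: {cands[0].name}, neutral mass {cands[0].mass:.4f} Da")
# The mass is the sum of the carbamidomethylated peptide (1626.767 Da) and
# the tetra-sialylated glycan (3663.286 Da).
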