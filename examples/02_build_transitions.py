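"""Compute the target transition and export a vendor-neutral inclusion list.

The SIM method monitors the M+2 isotopologue of the 4+ precursor of
HCSLNENITVPDTK_6_7_1_4 (the most intense cluster member at ~5.3 kDa) and
confirms identity with five diagnostic oxonium/di-/tri-saccharide product
ions in MS2.
"""

import glycotarget as gt

pep = gt.Peptide(sequence="HCSLNENITVPDTK", start=32, end=45, missed_cleavages=2)
gp = gt.Glycopeptide(pep, gt.parse_glycan_composition("_6_7_1_4"), site=38)

print(f"peptide monoisotopic mass : {gt.peptide_monoisotopic_mass(pep):.5f} Da")
print(f"glycan residue mass       : {gt.glycan_mass(gp.glycan):.5f} Da")
print(f"[M+4H]4+ monoisotopic     : {gt.glycopeptide_mz(gp, 4, 0):.4f} m/z")
print(f"[M+4H]4+ M+2 isotopologue : {gt.glycopeptide_mz(gp, 4, 2):.4f} m/z  <- SIM target")

cluster = gt.isotope_cluster(gt.glycopeptide_mass(gp), 4, 5)
print("\nisotopologue cluster (m/z, relative intensity):")
for mz, rel in cluster:
    print(f"  {mz:.4f}  {rel:.3f}")
# the M+2 member is the most intense one, which is why the method monitors it

entry = gt.build_transition_list([gp], charge=4, monitored_isotopologue=2,
                                 rt_window=(10.0, 14.0))[0]
print("\ndiagnostic products (+1):")
for p in entry.products:
    print(f"  {p.label:>18s}: {p.mz:.4f}")

gt.write_transition_csv([entry], "scratch_transitions.csv")
back = gt.read_transition_csv("scratch_transitions.csv")
print(f"\nwrote scratch_transitions.csv; round-trip precursor "
      f"{back[0].precursor_mz:.4f} (bit-exact: {back[0].precursor_mz == entry.precursor_mz})")
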