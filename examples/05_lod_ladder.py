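"""Estimate the synthetic assay's limit of detection on a dilution ladder.

Five replicates per concentration; a level passes when every replicate is
a full detection (S/N > 3 plus MS2 product confirmation).  The LOD is the
lowest concentration from which all higher levels also pass; the stricter
reference level uses S/N > 5.
"""

import glycotarget as gt
from glycotarget.pipeline import run_lod_ladder

t = gt.target_transition()
base = gt.SyntheticRunConfig(transition=t, concentration=0.0, seed=0)

result = run_lod_ladder(base, [0.125, 0.25, 0.5, 1.0, 2.0], replicates=5, seed=11)

print("per-level replicate S/N (0 = failed product confirmation):")
for conc, snrs in result.per_level_snr:
    print(f"  {conc:7.3f} ng/mL : " + ", ".join(f"{s:5.1f}" for s in snrs))
print(f"\nLOD (all replicates S/N > 3): {result}")
print(f"reference level (S/N > 5)   : {result.lod_reference} ng/mL")
# With the default response calibration the S/N = 3 crossing sits between
# 0.25 and 0.5 ng/mL — the same order as the real assay's sub-500 pg/mL LOD.
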