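# Methods

`glycotarget` implements the computational side of a targeted LC–HRMS assay
for a tetra-sialylated N-glycopeptide of recombinant erythropoietin (rEPO):
mass arithmetic, in-silico digestion, transition building, targeted
detection in centroided runs, a bioanalytical validation battery, and a
synthetic-run generator that makes the whole pipeline testable without
instrument data.

## Mass model

All masses are monoisotopic. A glycan composition is a multiset of
dehydrated monosaccharide residue classes — HexNAc (203.079373 Da), Hex
(162.052824), Fuc (146.057909), NeuAc (291.095417), plus an optional
O-acetyl (42.010565) — so an attached glycan contributes a plain residue-mass
sum with no extra water. Peptide mass = residue sum + water (18.010565) +
fixed modifications; carbamidomethylation of Cys (+57.021464, from
chloroacetamide alkylation) is fixed by default and variable modifications
are out of scope. Glycopeptide mass is strictly additive in the peptide and
glycan masses. m/z of the k-th isotopologue of `[M+zH]z+` is
`(M + k·1.003355 + z·1.007276)/z`.

Two composition notations are parsed and written:
`HexNAc(6)Hex(7)Fuc(1)NeuAc(4)` and the peptide-suffix form `_6_7_1_4` with
digit order (HexNAc, Hex, Fuc, NeuAc). The suffix notation is sometimes
glossed elsewhere with hexose first; only the HexNAc-first reading is
consistent between the composition tables and the published precursor m/z
(1324.02 at z = 4), so HexNAc-first is the implemented convention.

**Monitored isotopologue.** The monoisotopic `[M+4H]4+` of the target
HCSLNENITVPDTK_6_7_1_4 computes to 1323.5205; the SIM method's printed
precursor 1324.02 is the M+2 cluster member — the most intense isotopologue
at ~5.3 kDa (a binomial ¹³C model with an averagine carbon estimate puts
the cluster mode at k = 2). Transitions therefore carry an explicit
monitored-isotopologue index, default 2.

## Digestion

C-terminal cleavage rules with missed cleavages: trypsin (after K/R), Glu-C
(after E/D), and the combined rule (after E/D/R/K) that models sequential
Glu-C + trypsin digestion. Proline blocking of the following residue is on
by default for trypsin and the combined rule (standard convention; the
assay description is silent on it) and configurable off. Digestion is fully
specific; every peptide carries 1-based coordinates and its
missed-cleavage count, and the zero-missed-cleavage set partitions the
protein. Sequon discovery reports every N-X-[S/T] motif with X ≠ P,
including overlapping ones. The packaged mature erythropoietin chain is the
165-residue mature sequence (signal peptide removed, C-terminal Arg
processed), on which the glycosites are Asn24/Asn38/Asn83.

## Fragments and transitions

Oxonium ions are singly protonated residue(-combination) masses; the
NeuAc water-loss variant and the HexNAc+Hex / HexNAc+Hex+NeuAc combinations
are generated when counts allow. Backbone b/y ladders use the glycan-free
peptide convention. Y-ladders trim NeuAc (and O-acetyl) first, then Fuc,
then Hex, then HexNAc, so the ladder built up from the bare peptide starts
with the core GlcNAc; the ordering is a convention — detection matches by
m/z membership only.

The transition list carries the five diagnostic products of a sialylated
glycopeptide (204.0866, 274.0921, 292.1027, 366.1395, 657.2349), not the
plain Hex/Fuc oxonium ions, which are computed but not monitored. Two
published labels are deliberately not followed: the 204.08 ion is the
HexNAc oxonium (the hexose oxonium is 163.06), and the published sixth
product at 658.23 — labelled y6 although y6 of TVPDTK computes to 660.36,
while 658.24 is the first ¹³C isotopologue of the 657.23 ion — is offered
as an optional transition without asserting its identity. Ions are named by
computed composition throughout.

## Detection

- **XIC**: per-scan sum of centroid intensities within ±10 ppm (the
  search-setting default) of the monitored precursor, inside the
  transition's retention-time window.
- **S/N**: apex intensity over a robust noise level, median + 1.4826·MAD of
  the points outside the peak region (apex ± 3 scan widths). The estimator
  is unsmoothed; an all-zero background with a peak reports infinite S/N
  with a flag. Note a consequence of this definition: a pure-noise trace
  has S/N near 1 (its apex is necessarily above its median), not below 1,
  which still sits far under the detection threshold of 3.
- **Quantification**: background-subtracted trapezoid-free area
  (intensity × minutes) over apex ± 0.3 min. The trace is despiked first —
  a point exceeding twice its larger neighbour is replaced by the local
  3-point median — because a single-scan shot-noise spike is not
  chromatographic signal; on smooth peaks the rule is exactly neutral. The
  integration window is likewise centred on the despiked apex so a spike
  elsewhere in the window cannot steal the region. S/N is *not* despiked.
- **Detection call**: positive iff XIC S/N > 3 *and* at least 4 of the 5
  diagnostic products match within ±0.01 m/z in an MS2 scan whose isolation
  window (2 m/z default) covers the precursor and whose rt lies in the
  window. 4/5 rather than 5/5 because the published sixth product has
  ambiguous identity; strict policies are configurable. Absence of MS2
  coverage forces a negative call with a diagnostic.

## Validation battery

Thresholds follow the assay's stated criteria and are strict inequalities:
carryover pass iff blank/high area ratio < 5 %, intraday precision pass iff
every level's %CV < 15 %, detection S/N > 3 with reference level 5.

- Linearity: OLS of mean area vs nominal concentration (0–800 ng/mL, 7
  replicates per level); 1/x and 1/x² weighting available.
- Back-calculation for precision uses a **blank-corrected 1/x² weighted
  calibration**: slope from the weighted fit, intercept from the measured
  mean blank-level area. With the lowest nonzero standard at 25 ng/mL, an
  unweighted regression intercept carries more uncertainty (±25–80 area
  units) than the entire signal of a 0.5 ng/mL QC sample, so inverting
  through it yields nonsensical (even negative) concentrations at the low
  end; the blank level measures the additive offset directly.
- %CV is 100·sd(ddof = 1)/mean per level and is scale-invariant.
- LOD: lowest concentration from which all higher ladder levels pass; a
  level passes when all replicates (default) or the mean replicate
  (configurable) exceeds S/N 3; the S/N > 5 reference level is reported
  alongside. No level passing reports "above max tested".
- Selectivity: pass iff every spiked sample is detected and no negative is.

## Synthetic runs: the stated world

One run = SIM MS1 scans every 0.02 min over 10–14 min plus one MS2 per 5
MS1 scans. The precursor's 5-member isotopologue cluster elutes as a
Gaussian (FWHM 0.2 min, apex 12.0 min) scaled so the background-subtracted
XIC area equals concentration × response; the default response (55 area
units per ng/mL) was calibrated once so that the synthetic assay's S/N = 3
crossing lands just below 0.5 ng/mL, the same order as the real assay's
reported sub-500 pg/mL LOD. Noise is an additive positive baseline (30)
with Gaussian scatter (sd 10), sparse ×10 shot-noise spikes (rate 0.005) on
random-m/z interference centroids (10 per scan over a ±5 m/z SIM window),
and a persistent chemical-background centroid at the monitored m/z so blank
XICs carry realistic noise instead of zeros. MS2 scans carry the five
products at fixed relative intensities scaled by concentration and the
elution envelope; centroids below the noise floor (30) are not emitted, so
product confirmation fails naturally at low concentration.

The validation-study generator mirrors the assay's design (8 × 7
calibration, five 1000 ng/mL carryover pairs with 2 % injected carryover,
3 × 5 precision at 0.5/50/200 ng/mL, 5 + 5 selectivity at 10 ng/mL, five
urine/neat matrix pairs with 0.9 injected suppression) under a 5 %
proportional run-to-run response scatter, and returns a ledger of the
injected truths. Runs are bitwise reproducible per seed, including the
written mzML bytes.

What a green recovery test establishes: the computations (XIC, S/N, areas,
fits, ratios, thresholds) are correct on data whose truth is known. What it
does not establish: performance on real urine backgrounds, retention-time
drift, ionization variability, or detector saturation — none of which the
generator emulates.

Recovery tolerances are evaluated on means across 10 study seeds: a single
5-replicate precision level has a %CV sampling sd of roughly CV/√8, wider
than the 3-point recovery tolerance itself. At the 0.5 ng/mL level the
recovered %CV (~7–8 %) sits above the injected 5 % because the additive
noise floor contributes comparably to the proportional scatter there; this
is a property of the stated world, not an estimator bias.

## Numerical choices

- m/z comparisons against printed two-decimal values use ±0.01 (printed
  precision); residue masses are verified against an independent
  elemental-composition oracle to 1e-4 Da.
- Product matching is closest-first one-to-one assignment; ties break to
  the lower expected m/z.
- Degenerate inputs are explicit: empty sequences, non-positive charges,
  zero denominators (carryover high, matrix neat, precision mean) are
  rejected or flagged rather than propagated as NaN silently.

## Interfaces

The package is a library: the importable API plus `examples/` scripts (one
per capability) are the interface; there is no CLI. File formats: FASTA in
(Biopython), centroided mzML in/out (minimal internal reader/writer on
stdlib XML; profile-mode input is rejected with guidance), transition lists
and peptide/measurement tables as CSV (pandas), validation reports as
JSON-ready dicts.

## Known limitations

- The mzML layer covers the SIM/ddMS2 subset only (no chromatogram arrays,
  no zlib/numpress encodings, minute/second units only).
- No retention-time alignment, co-elution deconvolution, or
  collision-energy/intensity prediction.
- The isotopologue model is binomial in ¹³C with an averagine carbon count;
  fine structure and other elements' isotopes are ignored (adequate for
  choosing the monitored cluster member, not for fitting measured
  patterns).
- Semi- and non-specific digestion are not modelled.
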