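# neuropep

Presence–absence calling and label-free quantitation of secreted
neuropeptides from induced-neuron (iN) culture media.

## The problem

Neuropeptides — peptide neurotransmitters excised from proneuropeptide
precursors such as chromogranin B (CHGB), C-type natriuretic peptide
(NPPC), neurotensin (NTS) and somatostatin (SST) — can be profiled in the
secretion media of patient-derived induced neurons by nano-LC-MS/MS.  In a
case–control design (schizophrenia vs healthy control, KCl-depolarized vs
basal secretion) the scientific readout is *which* peptides each group
secretes, and at what level.  This package implements that readout as a
reusable pipeline for anyone analysing PEAKS-style peptide
identification/quantitation exports from nested secretion experiments:

1. **core model / IO** — long-format observation tables (one identified
   peptide feature per technical injection, with XIC area-under-curve
   abundance, quality, RT, m/z and full design coordinates) and precursor
   FASTA;
2. **filtering** — optional target–decoy FDR gate, strict abundance
   (> 1×10⁴) and quality (> 0.3) gates, and cross-injection feature
   reliability (RT span ≤ 3 min, precursor mass within 20 ppm of the
   feature-group median);
3. **precursor mapping** — each peptide anchored to 1-based inclusive
   residue coordinates on its full-length precursor (e.g. CHGB 588–596),
   PTM-aware (Met oxidation, pyro-Glu, N-term acetylation, C-term
   amidation), with per-residue coverage maps;
4. **presence calling** — the hierarchical rule: detected in ≥ 1 of 2
   technical injections → culture replicate; ≥ 2 of 3 culture replicates →
   subject; ≥ 5 of 7 SZ or ≥ 4 of 6 HC subjects → group;
5. **signatures** — set algebra over the peptide × (group, condition)
   matrix: Venn partitions between groups and between conditions,
   per-precursor tallies, SZ-only / HC-only / shared labels;
6. **quantitation** — LFQ summaries as mean ± s.e.m. (sample sd / √n over
   subject-level abundances, themselves means of culture means of injection
   means) and two-tailed pooled-variance Student's t-tests
   (df = n₁ + n₂ − 2), computed only where both sides of a contrast are
   called present;
7. **synthetic data** — a generator that emulates the identified-peptide
   output of a search engine under the study design, with known ground
   truth, plus the published 29-peptide presence matrix as an in-package
   fixture.

## Worked example

Realize the published presence matrix as a minimal observation table and
run the full pipeline (this is `analysis/01_fixture_presence.py`):

```
$ python analysis/01_fixture_presence.py
KCl:   union 27, SZ 9 (SZ-only 0), HC 27 (HC-only 18), shared 9
basal: union 18, SZ 8, HC 18, HC-only 10
HC: KCl-unique 9, both conditions 18, basal-only 0
SZ: KCl-unique 1, both conditions 8, basal-only 0
```

Reading the numbers: under KCl depolarization 27 distinct neuropeptides
are secreted in total; the schizophrenia group secretes only 9 of them,
every one also present in controls, while 18 are control-only — the SZ
neurons have lost two-thirds of the normal secreted repertoire.  Under
basal secretion SZ shows 8 peptides against 18 in controls.  Controls
release 9 peptides in a KCl activity-dependent manner; SZ neurons show only
1 KCl-unique peptide.  The per-precursor tally
(`results/reference_matrix/pipeline/tally_KCl.tsv`) shows the CHGB breakdown: 18
control CHGB peptides, of which 12 are control-only and 6 shared with SZ.

The same stages are available as a CLI (`neuropep generate|fixture|filter|
map|call|signatures|quant|run`) and as library functions.

Other drivers: `analysis/02_recovery_calibration.py` checks the counting
rule's sensitivity/specificity against its closed-form binomial
composition by simulation; `analysis/03_synthetic_cohort.py` runs the
pipeline end to end on a noisy synthetic cohort (intensity noise, quality
dropout, decoys, FDR gate on) and verifies the ground-truth matrix is
recovered cell for cell.

Precursor sequences shipped by the synthetic module are deterministic
random stand-ins with the real proteins' lengths (see
`docs/methods.md`); supply your own FASTA (`>ACCESSION SYMBOL ...`) for
real analyses.

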