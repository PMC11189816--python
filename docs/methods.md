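# Methods

## Data model

The pipeline's input boundary is the *identified peptide*, not the
spectrum: one row per identified peptide feature per technical LC-MS
injection, carrying the peptide sequence, modification list, XIC
area-under-curve abundance (arbitrary intensity units), a unitless feature
quality, retention time (minutes), precursor m/z, and the design
coordinates subject / group / condition / culture replicate / technical
replicate.  Spectrum scoring and peak integration are upstream
(search-engine) concerns; this package consumes their export.  A
configurable column-name mapping (`io.Dialect`) adapts foreign exports to
the canonical TSV schema, which decouples the pipeline from any vendor
format.

An identified-but-unquantified feature stores abundance as missing, never
as zero: a zero would be a measured quantity and would corrupt LFQ means.
No between-run intensity normalization is applied anywhere; none is part
of the upstream quantitation this pipeline models, and silently rescaling
XIC areas would change the reported means.  Users needing normalization
should apply it before import.

## Study design and presence rule

The default design is the secretion experiment the package was built
around: 7 schizophrenia (SZ) subjects (A–G) and 6 healthy controls (HC,
H–M), two secretion conditions (50 mM KCl depolarization vs basal), three
cell-culture replicates per subject and condition, two technical
injections per sample.  The hierarchical presence rule is literal
counting with configurable thresholds:

* culture replicate: detected in ≥ 1 of 2 *distinct* technical injections
  (repeat detections within one injection count once);
* subject: ≥ 2 of 3 culture replicates;
* group: ≥ 5 of 7 SZ subjects, or ≥ 4 of 6 HC subjects.

Peptide identity at the presence level is the coordinate triple
(precursor symbol, start, end): modification states collapse onto one
peptide, since the published matrices key peptides by coordinates only.
Subjects with missing culture replicates are called on the available ones
against the same absolute threshold — with detection-absence and
data-absence indistinguishable in a long-format export, an absent culture
simply contributes a false call, which is the conservative reading.
Peptides whose detections never reach threshold anywhere are kept as
all-absent rows in exports (absence is informative) but excluded from all
set-algebra counts; that is why a 29-row matrix yields a 27-peptide union.

## Filters

* **Target–decoy FDR** (optional, off by default): retain targets scoring
  at least the smallest cutoff whose decoy/target ratio at-or-above the
  cutoff stays strictly below `fdr_max` (default 0.003).  Real search
  engines apply their own FDR internally before export, hence the
  off-by-default; the synthetic generator labels decoys so the gate can be
  exercised end to end.  The strict (<) comparison is deliberate: at the
  boundary the estimated FDR equals the ceiling and admitting the tied
  score would admit the decoy that produced the tie.
* **Abundance/quality**: strict inequalities, abundance > 1×10⁴ and
  quality > 0.3.  Rows with missing abundance are rejected here (they
  cannot enter LFQ) and counted separately in the filter report.
* **RT/mass reliability**: within each peptide identity × subject ×
  condition × culture replicate, keep the largest subset of injections
  whose RT span is ≤ 3 min and whose m/z all lie within 20 ppm of the
  subset median; ties broken by total abundance, then earliest RT.  Group
  sizes are bounded by the number of injections, so exact subset
  enumeration is used (greedy fallback beyond 12 members).  Only RT and
  mass are enforced numerically; peak-height/isotope-pattern reliability
  has no portable threshold and is left to the upstream software.

## Coordinate mapping

Coordinates are 1-based inclusive over the *full-length* precursor,
signal peptide included — the convention that reproduces published spans
such as CHGB 588–596.  Users supplying mature-chain FASTA must expect
shifted coordinates.  Matching is exhaustive substring search; all
occurrences across all precursors are recorded, the lexicographically
smallest (symbol, start) is primary, and multi-site peptides are flagged
ambiguous.  Ambiguous peptides stay in totals and contrasts but are
excluded from per-precursor tallies, which assume unique assignment.
Isoleucine and leucine are distinct (search engines report sequences;
collapsing them would fabricate ambiguity).  PTMs are mass-only for
matching purposes; N-terminal pyro-glutamate is matched against the
encoded Q/E.

## Quantitation

Subject-level abundance is the mean of culture means, each culture mean
the mean over its technical injections — respecting the nesting rather
than pooling all injections, so an unbalanced culture cannot dominate a
subject.  Group summaries are mean ± s.e.m. with the sample (n−1)
standard deviation.  Contrasts use the pooled-variance two-tailed
Student's t-test (df = n₁ + n₂ − 2) rather than Welch, matching the
similar group variances of this kind of data; the statistic is computed
in-package from the closed form and the p-value from the t distribution.
Degenerate inputs are conventionalized: both variances zero with equal
means → p = 1; with unequal means → p = 0 plus a runtime warning.  Tests
are computed only where the presence matrix calls the peptide present on
both sides of the contrast — abundances of absent peptides are never
imputed.  Raw p < 0.05 defines significance by default;
Benjamini–Hochberg adjustment is available (`bh=True`) but off by
default.  Condition contrasts are unpaired by default with a paired
option, since either reading of a within-subject KCl/basal comparison is
defensible.

## Synthetic data

The generator emulates a search-engine export under the study design with
the published presence matrix as ground truth.  Per injection, a truly
present peptide is detected with probability 0.9 and an absent one with
probability 0.01; intensities are log-normal around a per-peptide scale
drawn log-uniformly from 1×10⁵–1×10⁷ (log-sd 0.5), standard behaviour for
LFQ intensity data; RT jitter is Gaussian (sd 0.5 min) around a
per-peptide elution time; quality is Beta(4, 2), putting ≈ 97% of rows
above the 0.3 gate; precursor m/z (monoisotopic, charge 2, computed with
pyteomics) carries 2 ppm Gaussian error.  Match scores for targets and
decoys are drawn from well-separated normals (70 ± 10 vs 20 ± 6),
mimicking a search engine's filtered export.  Decoy rows (5% of targets)
are length-preserving shuffles rejection-sampled to match no precursor,
so they are guaranteed to fail mapping.  Per-subject biological
heterogeneity beyond Bernoulli dropout is exposed only through the
detection probabilities (no per-subject random effect by default).

The shipped precursor set is **synthetic**: deterministic random
amino-acid sequences with the real human proneuropeptide lengths (CHGB
677 aa, NPPC 126, NTS 170, SST 116, TMSB4X 44, TMSB10 44, ADM 185),
regenerated until every fixture peptide region occurs exactly once across
the set.  This realizes the published coordinates without shipping
third-party sequence data; all coordinate arithmetic is identical on real
FASTA.  Consequently, passing tests demonstrate the counting, mapping and
statistics machinery — not anything about real spectra, real sequence
redundancy (e.g. the genuine TMSB4X/TMSB10 homology), chromatographic
drift structure, or correlated detection failures, none of which the
generator models.

`recovery_experiment` samples detection events and applies the presence
hierarchy vectorized in numpy rather than materializing full observation
tables per simulation; a test cross-checks that the full
generate→pipeline path estimates the same recovery probability.  The
independent oracle is the closed-form binomial composition
P(injection)→P(culture)→P(subject)→P(group); at the default detection
probability the rule's group-level sensitivity exceeds 1 − 10⁻⁹ and false
group calls are essentially impossible, i.e. the published counts are
limited by biology, not by the counting rule.  Recovery is measured at
the presence-calling stage (detection events), not through the
quality/FDR gates, which would otherwise convolve the score model into
the calibration.

## Known discrepancy in the published tallies

Recomputing the per-precursor KCl tally from the published presence
matrix forces NPPC SZ = 1 (one shared peptide, none SZ-only), whereas the
published summary table prints NPPC SZ = 2 alongside shared = 1 and
SZ-only = 0 — internally inconsistent under the partition identities
SZ = SZ-only + shared.  The pipeline enforces the identities and reports
the recomputed value; no special-casing is applied.

## Problem sizes

The test suite and drivers run the fixture (936 observations), cohorts of
~2 200 noisy observations, and 1000-simulation recovery calibrations;
everything completes in seconds on one CPU, with exhaustive enumeration
(subject-level patterns: 2⁷ and 2⁶) used wherever the space is small
enough to brute-force.
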