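# Methods

## Model and assumptions

`mutspot` treats somatic SNV recurrence as a local rate contrast. The
genome is tiled into non-overlapping windows of width `w` (default
50 bp, kept as a shorter trailing window at each chromosome end and
scored with its true length). For a window with `T` mutations the
recurrence statistic is the ratio of the window's per-base mutation
rate to the rate of its flanking region:

    raw = (T / T0) / ((L + R) / (L0 + R0))

where the left and right flanks are the `f` bases (default 0.5 Mb) on
either side of the window, truncated at chromosome ends, with the
window itself excluded. Flank bases whose mappability is below the
threshold — or whose mappability value is missing — are removed from
`L0`/`R0`, and mutations at such bases are not counted in `L`/`R`
(the counts and the lengths describe the same base set, so their ratio
is a rate).

The underlying assumption is that mutational processes are locally
smooth at the megabase scale: whatever regional process drives the
flanking rate also drives the window's expected rate, so a large ratio
indicates *focal* enrichment. Processes that are themselves focal at
the window scale defeat this assumption; that failure mode is exactly
what the hypermutation flag (below) is designed to catch.

The conservation statistic is the mean of a per-base conservation
track (PhyloP-like: positive = conserved, negative = accelerated) over
the *mutations* in a window — per mutation, not per distinct base, so
a base mutated in k tumours contributes k terms. A per-position mode is
exposed (`conservation_per_position`) for sensitivity analyses.

Both raw scores are standardized over the candidate set by subtracting
the median and dividing by the median absolute deviation; the combined
score is their simple average. Normalization is pooled across the whole
cohort (or within one cancer type in per-cohort mode), never per
sample: single-sample mutation sets are far too sparse to estimate a
flanking rate.

### Candidate filtering

Windows enter scoring only if mutated in at least `min_samples`
distinct tumours (default 3; below that "recurrence" is not a
meaningful claim) and if the mean mappability over their mutations is
at least `min_mean_mappability` (default 0.5, boundary inclusive:
0.50 passes). Windows whose mutations all lack a track value have an
undefined mean and are excluded rather than imputed — a silent default
would fabricate signal. Assembly-gap handling relies solely on the
mappability filter; no separate N-run exclusion is applied.

### Cohort filters

Two filters precede scoring, in this order: (1) mutations at known
germline-variant positions are removed unless the position also occurs
in a somatic catalogue — matching is by position only, not allele, so
two different alt alleles at one germline site are both removed;
(2) samples with fewer than `min_sample_burden` total mutations
(default 1000, appropriate for whole genomes) are dropped entirely.
The order matters because the first filter lowers per-sample counts.
Non-SNV records are dropped with a count; exact duplicate records
(same sample, position, alt) are collapsed with a warning, since merged
multi-source call sets can double-count.

### Hypermutation flag and spectra

For every mutated window the multiplicity `T / n_samples` (mutations
per *mutated* tumour, not per cohort member) is compared to a threshold
(default 1.2, strictly greater). Mutual exclusivity — at most one hit
per tumour — is the signature of selection on activating events;
multiplicities well above 1 indicate a focal mutational process. The
threshold-sensitivity analysis reclassifies all regions with more than
`min_T` (default 2) mutations at alternative thresholds (default 1.1,
1.3, 1.4, 1.5) and reports percent agreement with the reference.
Windows are labeled RHM (hypermutated and normalized recurrence > 10),
HM (hypermutated only) or OR, and mutation shares per cancer type are
tabulated per label.

Spectra use the standard 96-channel trinucleotide classification with
pyrimidine-reference strand collapse; context comes from the reference
genome (sample genomes are not available). Mutations at chromosome
edges, with reference-allele mismatches, or with N in the context are
excluded and counted, so classified + excluded always equals input.

### Validation statistics

Score distributions between region classes are compared with
Mann–Whitney U (scipy: exact null for small untied samples,
tie-corrected normal approximation otherwise). The driver-median test
draws, with replacement, |driver| scores from the non-driver pool,
takes the median, repeats `n_resamples` times (default 10,000), and
counts resample medians **≥** the observed driver median (counting
equality is conservative). The reported empirical p carries the add-one
correction (x+1)/(N+1) so it is never exactly zero; the raw exceedance
count is reported alongside so "none exceeded" remains expressible.
CTCF-class comparisons use mutually exclusive groups (CTCF-only,
CTCF+DNase, other); no multiple-testing correction is applied to the
three pairwise tests.

### Motif scanning

JASPAR text PFMs are parsed with Biopython. Counts become probabilities
after adding a pseudocount of 0.8 distributed by the background
frequencies (uniform 0.25 by default); log-odds are in natural-log
units. Both strands are scanned; the relative score of a hit is
(score − min) / (max − min) over the attainable range, with a default
reporting threshold of 80%. An N base contributes 0 log-odds
(background-neutral). The ref-vs-mutant analysis applies one
substitution per mutant sequence and classifies the change in the
maximum hit score as disruptive/creating/neutral around a configurable
dead-band (default 0: any change in the maximum counts).

## Numerical choices

- Coordinates are 0-based half-open everywhere (BED convention).
- The MAD is scaled by 1.4826 (consistency with the normal SD);
  `mad_constant=1.0` gives the plain MAD.
- A window whose flanks contain no valid bases, or no mutations, gets
  an undefined (NaN) recurrence score with an explanatory flag and is
  excluded from normalization — assigning infinity would let a single
  isolated cluster dominate every ranking.
- `normalize()` raises on a zero MAD; the pipeline instead degrades
  gracefully (normalized columns NaN, every record flagged
  `degenerate_normalization`) because a tiny cohort can legitimately
  yield one candidate, and ranking by recurrence remains well defined
  on raw scores (Eq. normalization is monotone).
- Ranking ties are broken by (chrom, start) so output tables are
  byte-reproducible; NaN-scored records sort last.
- Track queries outside the covered bounds raise rather than return a
  default; missing values inside bounds are NaN and are excluded from
  means.
- Robustness modes: flank rates can exclude user-supplied intervals
  (e.g. coding exons), and samples with burden > mean + 2 SD can be
  dropped before counting.

## The synthetic-data generator

`synthetic_fixtures` emulates the structure of a pan-cancer whole-genome
call set at desk scale. Defaults: three cancer-type cohorts of 30
samples on a 2 × 1 Mb uniform-random genome; background 1e-5
mutations/bp/sample placed uniformly (or under a piecewise-constant
rate map); per-sample lognormal rate multipliers with σ = 1.15 and unit
mean, which spreads burdens over roughly three orders of magnitude
across cohort tails, as real tumour cohorts do; 5% of each sample's
background count added again at germline-variant sites (0.2% of the
genome), 10% of which also appear in the somatic catalogue and are
therefore rescued by the germline filter. Planted hotspots give each
hit sample exactly one mutation in the region; planted hypermutated
foci give each hit sample ≥ 2. Background placement skips planted
intervals so planted multiplicity is exact. Conservation is
piecewise-constant N(0, 0.5) noise over 200-bp tiles with conserved
elements at a fixed elevated level; mappability is 1.0 with planted
low-mappability stretches at 0.1.

What the generator does **not** emulate: realistic human sequence
composition, replication-timing or expression covariates of mutation
rate, signature-accurate trinucleotide preferences, indels, subclonal
structure, or caller-specific artefacts. Passing tests therefore
demonstrate that the implementation computes its statistics correctly
and recovers planted structure under the stated noise model — not that
the scores are well calibrated on real tumour genomes.

## Problem sizes used in tests

The test suite and acceptance script run entirely on simulated data:
the brute-force oracle comparison uses a 2 × 5 kb genome with 1.5-kb
flanks; hotspot-recovery experiments use a 1 Mb genome, 100 samples,
background 1e-5/bp/sample and a 20-sample planted hotspot (100
replicates in the test suite, 40 in the acceptance script);
resampling-calibration uses a pool of 1000 scores, 25 drivers and
10,000 draws (500 null replicates in the suite, 200 in the script).
These sizes are the package's chosen desk-scale study conditions; all
scale linearly if enlarged.

## Known limitations

- No analytical p-value accompanies the recurrence score; regions are
  ranked, not tested. The resampling machinery applies only to the
  driver/non-driver validation design.
- The flanking-rate model cannot distinguish a selected hotspot from a
  window-scale focal mutational process with mutually exclusive hits;
  the multiplicity flag catches multi-hit processes only.
- The germline filter is position-based, mirroring positional variant
  catalogues; an allele-aware filter would be stricter.
- Only single-nucleotide variants are scored.
- Text formats only (FASTA, BED, bedGraph, TSV, JASPAR text); no
  bigWig/2bit support.
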