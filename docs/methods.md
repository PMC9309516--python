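# Methods

## Quality trimming

A read is scanned 5'→3' in windows of `trim_window` = 10 bases advancing
by `trim_step` = 4; the read is truncated at the start of the first window
whose mean Phred score drops below `trim_min_mean_q` = 20. Both ends are
then trimmed while the terminal base is below `trim_min_end_q` = 20, and
reads shorter than `trim_min_len` = 50 are dropped. Two details are fixed
here because any trimming tool must pick *some* order of operations: the
scan runs 5'→3' with truncation before end-trimming, and a final partial
window is evaluated over the bases it covers (otherwise a low-quality tail
shorter than the window could never trigger truncation). Trimming is
idempotent and monotone in the quality threshold; the test suite checks
both and compares against an exhaustive pure-python reference on 10 000
random reads.

## Host depletion

A read is removed iff it has at least one alignment to any supplied host
genome with percent identity ≥ 60 and query coverage ≥ 60 (both
inclusive — the thresholds are minima). Query coverage is
`100 · alignment_length / query_length`, i.e. measured along the read;
measuring along the subject is the other defensible reading, but coverage
of the query is what limits how much of the read the alignment explains.
Removals are tallied per host genome (a read hitting two proxy genomes
counts once in each tally but once overall).

## Recruitment statistics

**Best hit.** After the same 60/60 filter, the winner per read is the
record with maximal bit score; ties break on higher identity, then
lexicographically smallest genome id. The tie-break order is a convention
chosen for determinism — with real alignment scores ties are rare; with
the synthetic decoys they are astronomically unlikely but must still
resolve reproducibly.

**Sections and RSD.** Each genome's contigs are concatenated in manifest
order into one [0, L) axis split into ten half-open intervals of width
⌊L/10⌋ (the last absorbs the remainder). A read belongs to the section
containing the midpoint of its subject interval — robust for reads
straddling a boundary. RSD is the sample (n−1) standard deviation of the
ten counts divided by their mean; `sd_mode = population` switches to the
n denominator. RSD is undefined (NaN, never a number) at zero reads. The
extreme single-section pile-up gives exactly √10 ≈ 3.1623 regardless of
read count, comfortably above the 0.8 decision boundary — this is the
statistic's designed purpose.

**ANI.** The unweighted mean percent identity of the recruited reads; a
read-based screening proxy, not a genome-to-genome ANI.

**Two-cloud detection.** The published workflow spotted bimodal identity
distributions by eye; here the 1%-binned histogram over [60, 100] is
smoothed with a centred 3-bin moving average, local maxima reaching 5% of
the recruited reads count as peaks, and two clouds are declared when two
peaks are separated by a valley no higher than half the smaller peak, with
each side of the deepest valley holding ≥ 50 reads (`min_cloud_reads`, a
support floor so sparse histograms cannot fake bimodality). Cloud means
use bin centres. The thresholds are config-exposed defaults; they
reproduce the planted bimodal fixtures and never fire on unimodal ones,
but visual inspection they are not.

**Presence rule.** Present iff n_reads ≥ 1000 and RSD < 0.8 (strict).
The identity band (95–100 / 90–95 / 80–90 / 70–80 / below-70, lower bounds
inclusive) follows the ANI, except that with two clouds whose high cloud
averages above 90% the band follows the high cloud. Presence-call tables
mark calls whose band falls below 70% as non-reportable rather than
flipping the call itself. Relative abundances use the sample's
quality-trimmed read count as denominator (`abundance_denominator =
trimmed`; `depleted` is the alternative) — whether plant-depleted or
trimmed totals anchor the percentages is a genuine free choice, and
trimmed keeps percentages comparable before and after depletion.

## Database selection and composition categories

A genus enters the recruitment database when any classifier reports it at
≥ 0.1% in any sample; one representative genome per species where
available; a curated lactic/acetic-acid-bacteria extension list enters
regardless of genus with its own `source` value. Representative-genome
choice is an input mapping, not an algorithm — it is a curation act the
module validates rather than performs. In composition summaries, genera
below 0.9% in *every* method fold into "Minorities"; "Higher than genus",
"Unassigned" and "No hits" are reserved categories and per-method
percentages must sum to 100 ± 0.01. All "at least" thresholds are
inclusive, all "below" thresholds exclusive.

## Community statistics

* Simpson is reported in Gini–Simpson form D = 1 − Σp² (higher = more
  diverse), the orientation under which the least diverse sample scores
  lowest. Pielou is Je = (−Σp ln p)/ln S over the S nonzero taxa, natural
  log; undefined (NaN) for S < 2. Both renormalise input, so percentages
  and proportions are interchangeable.
* Bray-Curtis BC = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ).
* PERMANOVA partitions Σ_{i<j} d²ᵢⱼ/n into within- and between-group sums;
  pseudo-F = (SS_b/(k−1))/(SS_w/(n−k)); p = (1 + #{F* ≥ F})/(1 + P) with
  P = `n_permutations` = 999 seeded label permutations by default. The
  all-identical degenerate case returns NaN, flagged. Pairwise comparisons
  run per group pair with optional Benjamini–Hochberg adjustment (default
  none). The implementation is cross-checked against scikit-bio's
  PERMANOVA in the test suite and calibrated on exchangeable null data
  (12 samples, 3 groups, 1000 datasets at 199 permutations — sizes chosen
  to make the calibration a routine desk computation).
* SIMPER: per group pair and taxon, the mean over cross-group sample pairs
  of |xᵢ−yᵢ|/Σⱼ(xⱼ+yⱼ); contributions sum to the mean between-group
  Bray-Curtis exactly.
* PCA is unscaled (mean-centred only — relative abundances share a unit;
  `scale=True` standardises), restricted to taxa reaching ≥ 0.9% in at
  least one sample, eigendecomposed from the covariance matrix, with each
  component's sign fixed so its largest-magnitude loading is positive.
  Zero-variance-after-filtering input is rejected rather than ordinated.

## Synthetic communities

The generator defines the conditions under which every recovery claim is
made, so its defaults matter:

* Genomes: i.i.d. uniform A/C/G/T, multi-contig, fully seeded. No GC skew,
  no repeats — so cross-mapping arises only where the design plants it.
* Reads: origins drawn multinomially from the design fractions (members,
  host, sourceless "random" reads emulating the no-hit fraction); lengths
  normal(200, 20) clipped at 60, matching short-read single-end data;
  member divergence applied as i.i.d. substitutions (no indels), which
  keeps identity analytically 100·(L−m)/L and makes every downstream
  identity assertion exact. Indel realism is deliberately traded away.
* Qualities: two-segment profile (plateau Q32 over the first 60% of the
  read, linear decay to Q22, jitter sd 2) — enough texture to exercise the
  trimmer without destroying reads. Base-call errors are off by default
  (`error_rate = 0`); when enabled they fold into the truth substitution
  count so identity consistency survives.
* Alignments: one primary record per genome/host read at the planted
  interval; members with a `sister_id` emit one decoy secondary record at
  `sister_extra_divergence` (default +5 percentage points, +20 in the
  recovery benchmark) so best-hit tie-breaking and cloud detection face
  actual competition. Host reads diverge 2% from the host genome.
* Benchmarks (`frpipe.studies`): the recovery community plants five
  members at 13% each (≥ 2600 reads of 20 000) at divergences 0–5%, an
  artifact genome at 9% with single-region coverage, and two decoys fed
  only cross-mapped hits; the host benchmark plants 15% host reads. The
  20 000-read scale keeps every benchmark a seconds-scale computation
  while leaving multinomial noise well inside the asserted tolerances.

What passing on this generator does **not** show: robustness to indels and
homopolymer errors, to biased base composition, to genuinely shared
sequence between related genomes (decoy competition here is planted, not
emergent), or to real library-size heterogeneity. Results on real surface
metagenomes depend on database completeness in ways no synthetic fixture
can certify.

## Known limitations

* The presence rule automates what was originally a manual decision;
  borderline ANI cases near band edges follow the stated rule, nothing
  more.
* Cloud summaries are histogram-based (1% bins), so cloud means carry
  ± 0.5% quantisation.
* The bundled survey table ships exactly as printed in its source,
  including one internal inconsistency (one sample's Firmicutes class
  total does not equal the sum of its species cells); rollups here always
  recompute from the species cells.
* PERMANOVA assumes exchangeability under the null; with sampling years
  confounded with fruit types (as in the motivating survey) a significant
  result cannot separate fruit effects from year effects. The package
  reports the statistic; the caveat travels with the design, and no
  correction is applied because none is defensible from the data alone.
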