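# Methods

## Model and assumptions

`tema` models one transposon family as a set of unlinked diploid insertion
loci, each carrying 0, 1, or 2 copies. Three processes act on a lineage:

1. **Meiotic segregation** (sexual lines only). A selfing bout resamples
   every locus independently from the exact Mendelian kernel: a
   heterozygote becomes absent/het/hom with probabilities 1/4, 1/2, 1/4;
   0 and 2 copies are absorbing. Iterating the kernel gives the *k*-bout
   chain with `p_het = (1/2)^k` and the remainder split equally between
   loss and fixation. Loci are assumed unlinked and to assort
   independently; crossover and linkage are not modelled, because the
   segregation predictions being tested are pure independent-assortment
   arithmetic. "Outcrossing" is implemented only as mating with an
   unoccupied partner (loss probability 1/2 for a heterozygote) — the one
   case needed for the qualitative ordering clonal ≤ selfing ≤ outcross.

2. **Local loss and repair** (every clonal generation). Each copy excises
   with probability `excision_rate`. The assay cannot distinguish
   excision from deletion or mitotic recombination, so these are pooled
   into the single rate. An excised copy at a homozygous locus is
   restored by homologue-templated repair with `reconstitution_prob`
   (default 1.0 — homozygous loci are effectively shielded); a
   heterozygous locus drops to zero copies and its band disappears.

3. **Transposition.** Each copy founds a new heterozygous locus at a
   fresh, unique fragment size with `germline_transposition_rate` per
   generation. New insertions are always heterozygous: a fresh insertion
   occupies one homologue.

Somatic insertions are non-heritable by construction: they are drawn once
at assay time, Poisson with mean `somatic_rate × (occupied loci)` per
lineage, rather than tracked through the pedigree. This collapses a
generation-by-generation somatic process into its observable endpoint,
which is the only thing the assay measures.

## Transposon-display emulation

Each lineage is assayed in triplicate. Every occupied locus produces a
peak at its integer fragment size in all three replicates — presence only,
dosage invisible. Somatic peaks appear in one or two replicates, never
three (the detection probability per replicate is truncated to that
window, since a thrice-replicated peak would be scored germline by
definition). Peak heights are arbitrary fluorescence units:
ancestral/germline peaks ~N(1200, 150) floored at 600, somatic peaks
~N(350, 80) floored at 150. The default scoring threshold (100) sits below
both floors, so with default settings no true peak is ever discarded;
thresholds for real Genemapper-style exports must be supplied by the user.
Fragment sizes are unique integers per locus within a lineage (the real
assay resolves ~1 bp); somatic peaks never collide with a lineage's own
locus sizes, so a somatic peak can never mask a scored loss. Cross-lineage
collisions between independently gained sizes are allowed and are handled
correctly by scoring (each lineage gets its own call).

## Scoring rules

- Peaks below the height threshold are discarded; surviving sizes are
  binned cohort-wide (exact integer match by default; a bp-tolerance knob
  greedily chains sorted sizes for real exports).
- A size is **ancestral** when fully replicable (3/3) in at least
  `min_share` (default 0.5) of lineages. The 0.5 default tolerates the
  ~25% segregational loss expected at heterozygous loci in selfed lines.
- Losses are scored purely as band absence: a matrix entry is absent iff
  the ancestral size shows zero peaks in all three replicates. A
  lost-then-regained size would be scored from the endpoint assay only.
- Novel sizes: 3/3 replicates → germline gain; 1–2/3 → putative somatic.
  A novel size shared by several lineages is tested against the ancestral
  share first; only sizes failing that test can be gains.
- **High-loss loci** are ancestral loci absent in strictly more than
  `min_lineages` (default 3) lineages — the signature of ancestral
  heterozygosity segregating after sex.

Threshold monotonicity: raising the height threshold can only remove
calls while it stays below the germline height floor (the regime
thresholds are for — separating noise from signal). Pushed into the
germline height distribution itself, a threshold can strip a size of its
ancestral status and re-classify its remaining 3/3 lineages as germline
gains, so monotonicity of every category is only guaranteed, and only
tested, in the sub-germline regime.

## Rate estimation and statistics

- Loss rate per lineage = losses / (generations × ancestral copies), with
  ancestral copies = number of ancestral matrix columns (TD loci), not
  genomic copy number: the assay defines rates per scored ancestral
  element. Treatment SE = sample SD across lineages / √n.
- Germline gain rate = gains / (ancestral copies × summed line-generations);
  somatic gain rate = non-replicable peaks / ancestral peaks at the assay
  endpoint (not divided by generations).
- Treatment comparison: Student's pooled-variance t-test, one-tailed with
  H1: sexual > asexual — the direction segregation predicts a priori;
  Welch and two-tailed variants by flag. Identical constant samples are
  reported as t = 0, p = 0.5 (one-tailed).
- ANCOVA: `rate ~ treatment + copy_number`, Type II F tests via
  statsmodels OLS (interaction by flag, additive by default since the
  design question is a main treatment effect). An all-constant response
  short-circuits to F = 0, p = 1 (the 0/0 case); single-treatment or
  collinear designs raise a rank-deficiency error.
- Regression of per-copy somatic rate on family copy number is fit on the
  untransformed scale by default with a log-copy-number option, since the
  appropriate scale is data-dependent. No multiple-testing correction is
  applied across families by default (raw p-values are reported;
  a Bonferroni-style correction can be applied downstream if desired).
- Expected losses at high-loss loci treat each such locus as ancestrally
  heterozygous: `n_sexual × p_absent(k bouts)` (11.25 for 45 lines, one
  bout). Loci with observed > expected are flagged as carrying local
  removal on top of chromosomal segregation.

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| `n_sexual` / `n_asexual` | 47 / 47 | lineages per treatment |
| `generations_mean` (`_sd`) | 40 (0) | MA generations per line |
| `n_ancestral_loci` | 25 | TD loci per family |
| `fraction_heterozygous` | 0.2 | ancestral het share |
| `excision_rate` | 1e-4 | per copy per clonal generation |
| `reconstitution_prob` | 1.0 | repair at homozygous loci |
| `germline_transposition_rate` | 1e-4 | new loci per copy per generation |
| `somatic_rate` | 0.05 | somatic peaks per occupied locus at assay |
| `somatic_replicate_detection` | 0.4 | per-replicate detection, truncated to 1–2/3 |
| `n_selfings` / `selfing_generation` | 1 / mid-experiment | bout schedule |
| `fragment_size_range` | (60, 1200) bp | sizing-ladder window |

Event rates are at the small magnitudes reported for DNA transposons
(loss/transposition of order 1e-4 to 1e-6 per element per generation);
`n_ancestral_loci` and `fraction_heterozygous` are free parameters of the
generator, set to a typical TD locus count and a modest ancestral
heterozygosity. All lines default to exactly 40 generations; per-line
variation is available through `generations_sd`. With multiple bouts
requested, bouts are spread evenly over the line's lifetime.

## Determinism

One integer seed fully determines a cohort: ancestor construction and each
lineage's propagation and TD assay draw from substreams derived from
`(seed, stage, lineage index)`, so reruns are bit-identical, independent
of lineage iteration order. The CLI writes a manifest (config snapshot,
seed, SHA-256 digests) per stage; a run is re-derivable from its manifest.

## What the generator does and does not emulate

It emulates: triplicate reactions, dosage blindness, rare germline events,
frequent non-replicable somatic peaks, shared ancestry across lines, and
treatment structure (clonal-only vs ≥1 selfing bout). It does not emulate:
electropherogram noise (peak-height thresholds on real traces are a
scoring judgement), PCR dropout of long fragments, per-line generation
count variation (off by default), linkage, selection, or population-level
dynamics. Consequently, passing tests demonstrate correctness of the
scoring and estimation machinery under clean assay behaviour, not
robustness to trace-level artefacts of real fragment analysis.

Two known estimator biases, both properties of the assay rather than
bugs: (i) per-copy rates are normalised by scored TD loci, so when some
ancestral loci are homozygous the true copy number exceeds the locus
count and per-copy transposition rates are overestimated by roughly the
copies-per-locus factor; (ii) band-loss rates underestimate per-copy
excision at homozygous loci, which require two independent hits (and lose
no band at all under full reconstitution). Parameter-recovery benchmarks
therefore use an all-heterozygous ancestor, where locus count equals copy
number and both biases vanish (residual bias ~1% from per-locus loss
saturation over 40 generations, well inside the Monte Carlo error of the
benchmarks).

## Problem sizes in the test suite

Monte Carlo checks use sizes chosen for statistical resolution: 4,000
replicate cohorts for the 25%-loss calibration (bringing the Monte Carlo
SE of the mean loss count to ~0.05, comfortably inside the ±0.1 band
checked), 100 cohorts for estimator recovery (2-SE criterion), and
short-generation cohorts wherever the quantity under test is independent
of generation count (with excision off, segregational outcomes do not
depend on how many clonal generations surround the bout).
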