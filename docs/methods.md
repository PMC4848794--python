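# Methods

This note records the models, conventions and numerical choices behind
`cortimir`, and what the synthetic benchmarks do and do not demonstrate.

## Read quantification

Adapter trimming follows the fastx-clipper convention: a read is cut at the
first position where the rest of the read matches a prefix of the 3'
adapter — the full adapter when the occurrence is internal, at least
`min_overlap` (default 6) bases when the adapter runs off the read's 3'
end. Reads shorter than `min_length` (default 16 nt) after trimming are
discarded; 16 nt is the shortest insert that still maps near-uniquely on a
hairpin reference set of this size.

Mapping is exact substring search of the trimmed read against the hairpin
set, forward strand only: small-RNA library protocols are stranded, and a
deterministic exact matcher is sufficient at this scale, so no
mismatch-tolerant aligner is embedded. Multi-placed reads carry their total
placement count.

The counting rule attributes an alignment `[a, b)` to a mature region
`[s, e)` on the same hairpin iff `a ≥ s − v` and `b ≤ e + v` with overhang
`v = 4` nt by default. This is containment with slack: templated isomiR
ends (which vary by a few nucleotides) are retained, while a 1-nt-overlap
rule would also sweep in star-arm and loop fragments. Multi-mapping policy
is fractional 1/n weighting by default; `all` and `discard` are available
because no single convention dominates in practice.

All coordinates are 0-based half-open internally; BED input is native.

RPM divides counts by the per-sample number of hairpin-aligned reads (in
millions). An alternative `mirna_assigned` denominator (sum of
mature-assigned counts) is provided because the two library-size notions
differ whenever a substantial fraction of aligned reads falls outside
mature regions, and published count/RPM ratios are not always recoverable
from either definition alone.

QC: pairwise Spearman correlation between replicate columns (constant
columns yield an undefined coefficient, reported as missing with a
warning), and PCA of row-centered normalized expression via SVD, components
ordered by explained variance.

## Differential expression

The model is the classic two-condition negative-binomial workflow:

* **Size factors** — for sample j, the median over genes (restricted to
  genes with a positive geometric mean across samples) of
  `K_gj / geomean_g`. The median is taken on the ratio scale. When no gene
  is positive everywhere, an optional pseudo-reference fallback uses
  geometric means over positive entries of genes expressed in at least half
  the samples.
* **Dispersions** — on common-scale counts `q = K/s`, the method-of-moments
  estimate is `α̂ = (s² − μ̂ z̄) / μ̂²`, where `s²` pools within-condition
  sample variances, `μ̂` is the base mean and `z̄` the mean inverse size
  factor (the `μ̂ z̄` term is the shot noise a Poisson gene would show). The
  mean-dispersion trend `d(μ) = a0 + a1/μ` is fitted by gamma-family
  regression with identity link on genes with `α̂ > 0` (ordinary least
  squares as fallback), and the working dispersion is
  `max(α̂, d(μ̂), 10⁻⁸)`. The max rule only ever inflates a gene's
  dispersion, keeping tests conservative for genes whose few replicates
  agreed by chance. A `blind` mode pools all samples for unreplicated
  designs.
* **Exact test** — conditioned on the total `K_S = K_A + K_B`, each
  condition total is NB with mean `μ_c = q̂ Σ_j s_j` (`q̂ = K_S / Σ s_j`
  over all samples) and variance `μ_c + α q̂² Σ_j s_j²`, i.e. the sum of
  per-sample NB variances — an m-replicate condition total has effective
  dispersion ≈ α/m. The p-value sums `P(a)·P(K_S − a)` over all splits with
  probability ≤ the observed split's, normalized by the total over all
  splits. Floating-point ties with the observed probability are included
  (relative tolerance 1e−7). All-zero genes get p = 1 by convention.
* **Multiple testing** — Benjamini–Hochberg step-up, ties sharing the
  sorted treatment. Note the step-up transform is not idempotent in
  general; only flat adjusted plateaus are fixed points.
* **Reporting** — the released fold change is `log2(meanRPM_B / meanRPM_A)`
  computed from per-condition mean RPM (this is the convention that
  reproduces the screen's published summary column at 2 decimals), while
  the test statistic works on size-factor-normalized counts. Mean count
  columns report raw means. Genes with a zero mean RPM on either side get a
  missing log2 ratio — no pseudo-count — but still receive a p-value, and
  are excluded from DE calls with a warning. Both DE gates are strict
  inequalities: |log2 ratio| > 1, adjusted p < 0.01.

## Target integration

Seed sites on a 3'UTR (RNA alphabet; T is normalized to U) are the three
canonical classes for a miRNA read 5'→3': an 8mer is the reverse complement
of miRNA positions 2–8 followed by A (the A anchors opposite position 1), a
7mer-m8 the reverse complement of 2–8 alone, a 7mer-A1 the reverse
complement of 2–7 plus A. 8mers take precedence: a 7mer-m8 at the same
start, or a 7mer-A1 nested one base downstream of an 8mer, is not
double-reported. Conservation is evaluated on a user-supplied multiple
alignment: a site is conserved iff the identical, gap-free site string
occupies the aligned columns in at least `min_species` (default 2)
non-reference species. Branch-length or context scoring is out of scope.

Predictions with no conserved site are dropped; human-run predictions are
rekeyed to mouse genes through a homolog table (one-to-many expands,
unmatched rows are dropped with a logged count). Genes present in all three
prediction runs have span `all_three`, in some but not all
`mouse_or_human`. The evidence classes, in priority order:

| class | prediction span | literature trust |
|-------|-----------------|------------------|
| 1 | any | Present |
| 2 | all three runs | Probably present |
| 3 | all three runs | Not likely present |
| 4 | all three runs | none |
| 5 | partial | none |

Class 1 deliberately does not require prediction support: a directly
reported interaction outranks in-silico evidence regardless of span. The
two remaining combinations (partial span with Probably present / Not likely
present) have no defined class; such genes are excluded with a log line
rather than silently re-binned. Gene identifiers are the primary keys;
symbols are display-only.

## MirTrap enrichment

Per replicate and arm, `ΔCt_g,r = Ct_g,r − Ct_ref,r` (GAPDH reference by
default; undetermined wells propagate as missing and drop that replicate).
`ΔΔCt = mean ΔCt(trap) − mean ΔCt(scrambled)` and `fold = 2^(−ΔΔCt)`.
Averaging replicates on the Ct scale equals taking the geometric mean of
folds, matching the approximately log-additive error structure of qPCR.
Enrichment is strictly `fold > 2`. Undetermined Cts are excluded
replicate-wise, not imputed at a maximum cycle number. Overlap against the
predicted list is a case-insensitive set intersection; the fraction is
reported over the predicted list and undefined when that list is empty.
No amplification-efficiency correction is applied.

## Synthetic data: what it emulates, and what not

The generator reproduces the screen's study conditions: five precursor
(33 °C) versus three differentiating (39 °C) replicates; NB counts with
`variance = μ + αμ²` (matching the DE model's parameterization), default
dispersion α = 0.05; a configurable DE fraction (default 10 %) with exact
effect magnitude `log2_effect` (default 2) and alternating signs, since
the screen found near-symmetric up/down regulation. Baseline means are
log-normal with natural-log mean 6.0 (≈ 400 expected counts) and a fixed
natural-log sd of 1.5, a deep-library miRNA abundance spread covering
roughly two orders of magnitude.

Reads are a mature sequence, optionally shifted up to ±6 nt (templated
isomiR ends), followed by the full 33-nt TruSeq small-RNA 3' adapter and
truncated to the read length (poly-A filler if the template runs out);
per-miRNA totals are Poisson; 5 % of reads come from non-mature hairpin
windows as background. No substitution errors, quality-score realism or
non-templated isomiR biology are simulated — passing the round-trip tests
therefore shows the pipeline's bookkeeping is exact, not that it is robust
to sequencing error.

Ct plates are built to invert exactly: the scrambled-arm ΔCt of every gene
is a fixed offset, the trap arm subtracts log2(true fold), so 2^(−ΔΔCt)
equals the true fold when noise is zero. Gaussian noise (default sd 0.2
cycles) is placed independently on each target-gene well; the reference
well's own fluctuation is absorbed into that per-gene sd rather than
simulated as a shared term, so gene-level errors are independent and
cross-gene averages converge on the true folds.

Evidence-table generation inverts the class rules (class k genes receive
exactly the evidence pattern of class k and nothing stronger), which makes
`integrate ∘ generate = identity` a testable contract.

The packaged summary tables are transcriptions of the screen's published
tables, shipped as TSV. One internal inconsistency of the published tables
is preserved as printed: the enrichment table marks 8 genes as overlapping
the in-silico list, but the raw symbol intersection of the two gene lists
contains 9 (Tcf7l2 appears in both without an overlap mark). The overlap
operation reports the computed intersection; the discrepancy is documented,
not patched. The enrichment table also lists 24 rows where the screen's
text counts 25 positives; the transcription keeps the 24 printed rows.

## Problem sizes and runtime choices

The benchmark suite runs the DE parameter-recovery experiment at 1000
miRNAs × (5 + 3) samples, null calibration at 1500 miRNAs, exact-test
enumeration up to conditioned totals of 30, counting-rule and seed-site
equivalence on 100–150 random instances, and Monte-Carlo Ct experiments at
10⁴ genes — sizes at which every check completes in seconds while Monte-
Carlo error stays well inside the asserted margins. All randomness flows
through explicit integer seeds; generators are pure functions of
(arguments, seed), and the pipeline derives per-stage seeds from the global
seed via `numpy` seed sequences so stages can be re-run in isolation.

## Known limitations

* The exact matcher tolerates no mismatches; real data with sequencing
  errors or SNPs will undercount relative to a mismatch-tolerant aligner.
* Dispersion estimation by moments is noisy at 3–5 replicates; the max rule
  compensates by design (conservatively), and no shrinkage estimator is
  provided.
* The seed-site scanner models site classes and conservation only — no
  context scoring, so its output ranks site presence, not efficacy.
* The five-class scheme leaves two evidence combinations undefined;
  datasets rich in partial-span literature-supported genes will see many
  exclusions (each is logged).
* qPCR amplification efficiency is assumed to be exactly 2 per cycle.
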