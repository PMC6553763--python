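# Methods

## Tracer model and assumptions

The pipeline treats each fatty acid (FA) of a consumer as a two-source
carbon pool: internal carbon present before the feeding window and dietary
carbon assimilated during it. Feeding a diet uniformly labelled with ¹³C
makes the dietary fraction observable: the atom percent excess (APE) of a
FA over its unlabelled baseline, divided by the diet's enrichment level L,
estimates the proportion of that FA's carbon that is dietary (PA). This is
a single-pool, end-point estimator; it assumes the label is well mixed in
the diet, that baseline consumers represent the fed consumers' pre-feeding
state, and it does not resolve multi-compartment kinetics or growth
dilution within the window.

Two deliberate features of the baseline rule:

* **L averages over all diet FAs except 18:0.** Consumers elongate and
  desaturate small amounts of dietary FAs, so the enrichment any one
  consumer FA inherits is better represented by the diet-wide mean than by
  its same-name diet FA. 18:0 is excluded because it labels far more
  weakly than the rest in algal cultures; consumer 18:0 is divided by the
  diet's own 18:0 level instead.
* **Per-FA consumer baselines.** APE is taken against the per-FA mean
  atom% of the unlabelled (in-situ) group. FAs absent from that group fall
  back to a configurable natural-abundance baseline, default δ¹³C = −25 ‰
  (typical marine lipid), and are flagged in the output; the original study
  does not state its choice for these acids.

## Derivatization carbon

FAs are quantified as methyl esters, so the measured mass includes one
methyl carbon from (unlabelled) methanol. The carbon-mass correction uses
the FAME molar mass in the denominator with that carbon entered as pure
¹²C (mass 12 u), while the numerator carries only the acid's own A carbons
at the enrichment-weighted mass w. The measured per-FA mass is interpreted
as the FAME-quantified mass — the denominator being the FAME molar mass
forces this reading — and no further methanol δ-correction is applied.
Constants are configuration: R_standard = 0.0112372 (VPDB), atomic masses
12.0000 / 13.00335 / 1.00794 / 15.9994 u for ¹²C / ¹³C / H / O.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `default_baseline_delta` | −25 | ‰ | baseline for FAs absent in situ |
| elapsed days Δt | per sample (5 in the fixture) | d | turnover denominator |
| `tfa_filter_percent` | 1.0 | % TFA | FA inclusion for clustering |
| logit ε | half the smallest nonzero proportion | — | compositional zeroes |
| R_standard, atomic masses | VPDB / IUPAC | — | isotope algebra |

Negative APE (sample below baseline, possible under noise) is clamped to
zero with a logged warning — PA is a proportion; PA > 1 is flagged but
passed through. Aggregate rows (TFA, ΣSFA/ΣMUFA/ΣPUFA) sum masses and
carbon terms over member FAs and never multiply a mean APE by a summed
mass; their APE column is the unweighted mean of member APEs. Replicates
are analysed independently and reported as mean ± SD; a mean-profile mode
(average the profiles first, then analyse once) is available for
transcribed table means. Absent measurements are excluded from means but
count as zero mass in sums.

## Similarity clustering

Bray–Curtis similarity, S = 100·(1 − Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)), on either
absolute masses or logit-transformed relative compositions; only FAs whose
mean relative content exceeds 1 % TFA in at least one sample group enter
the matrix (an acid passing in any group is kept for all samples). Logit
output can be negative, which Bray–Curtis does not admit; the matrix is
shifted by its global minimum first, and the shift is logged. Clustering is
group-average linkage on d = 100 − S; distance computation and the merge
sequence are delegated to scipy (`pdist`, `hierarchy.linkage`) and
cross-checked in the tests against hand-enumerated UPGMA on small
instances. Output is a merge list (joined clusters + average similarity)
and a Newick export; no graphics are produced.

## Synthetic experiments and what they show

The generator emulates the study design: n diet batches whose enrichment
shares a per-batch shift (days differ more than FAs within a day) plus
small per-FA jitter; baseline consumers at natural abundance; fed
consumers built in *pipeline-inverse* form — atom% = baseline + PA·L_FA
and final C_mass = initial/(1 − PA), i.e. final = initial + assimilated
with assimilated = PA·final. FAs absent from the baseline pool but
supplied by the diet are given an explicit (final mass, PA) influx, since
the initial/(1 − PA) construction is degenerate at zero initial mass.
Bioconversion edges move a transfer fraction of a source FA's assimilated
carbon into a product FA with the carried label attenuated (< 1), so
products are enriched but less than direct dietary acids — the recorded
ground truth is the tracer-visible PA an exact pipeline recovers. Measured
FAME masses are back-computed from carbon masses through the derivatization
correction, closing the loop through the same equation the pipeline
inverts. Noise is applied last: log-normal on masses (CV 5 %), normal on
the δ scale (SD 0.3 ‰); all draws flow from one seeded generator.

Because the construction is pipeline-inverse, noise-free recovery is exact
by design — that test validates the implementation's algebra, not the
biology. What the noisy tests add: the estimator is unbiased under the
stated measurement-noise model (mean PA error within 2 SE over 200
replicates for every truly assimilated FA; the FA with PA = 0 is positively
biased by the clamp, as truncation at a boundary must be). The generator
does not model growth, mortality, gut-content vs tissue separation, or
isotopic fractionation beyond the single attenuation factor, so passing
tests do not certify those aspects of real data.

## Numerical choices and degenerate inputs

δ ↔ atom% conversions are closed-form and round-trip to < 10⁻⁹ relative
error over δ ∈ [−100, 5000] ‰; δ ≤ −1000 ‰, negative ratios, masses < 0
and atom% outside [0, 100] are rejected. An all-zero sample pair has no
Bray–Curtis similarity and is rejected; clustering ties break by scipy's
deterministic ordering. The study-table fixture stores consumer masses as
carbon masses (as printed) and flags this so the FAME correction is not
applied twice; diet batch observations are per-FA means because
batch-level raw values are not published — their mean reproduces the
printed L = 3.62 atom% exactly.

## Problem sizes

The fixture analysis is 13 FAs × 1 mean profile per group and runs in
milliseconds. The Monte-Carlo calibration uses 200 replicate experiments
(5 diet batches, 3 + 3 consumer pools each), a few seconds on one core —
ample for a standard-error assessment of bias at the 10⁻⁴ level. The
clustering driver uses six jittered replicates, matching the original
3 + 3 design.

## Known limitations

Single-pool turnover only; no compartmental kinetics. The APE/L estimator
inherits the study's approximation of dividing an *excess* by an
*absolute* enrichment level; at natural-abundance baselines (~1.08 atom%)
this undershoots the true dietary fraction by a few percent relative — the
generator adopts the same convention so truth and estimate agree by
definition. Published aggregate APEs (e.g. the whole-pool 1.16) are
replicate-level means that cannot be recomputed from per-FA printed means;
they are carried as data, not recomputed. Exact dendrogram similarity
values from the original figures are likewise unreproducible without
replicate-level raw data; clustering is validated by properties and
qualitative group separation instead.
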