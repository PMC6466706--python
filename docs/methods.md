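# Methods

This note documents the statistical procedures implemented in `senesig`,
the choices made where the design was genuinely open, and the limits of
what the synthetic data can establish.

## Study design being emulated

The pipeline models a two-condition perturbation comparison in one cell
line: condition A (ionizing radiation, which arrests cells with a strong
DNA-damage response) and condition B (ectopic p21 expression, which
arrests without DNA damage), each measured against its own untreated
control arm on an Illumina HT-12-class expression array. The scientific
object is the *shared concordant* differentially expressed gene set —
genes moving the same direction under both arrests — treated as a
candidate core signature of accelerated senescence, and its use as a
query against a connectivity-style database of small-molecule expression
profiles to nominate compounds that phenocopy the state.

## Preprocessing

**Quantile normalization.** Every sample column is forced onto the
reference distribution defined as the row-wise mean of the per-column
sorted vectors. Ties within a column receive the mean of the reference
values at their tied rank positions. With this tie rule the transform is
exactly idempotent on tie-free data; with ties, a second application can
drift values by at most the reference spread inside a tie group (the
tie-averaged output perturbs the second-pass reference slightly). The
normalizer operates on whatever scale is supplied and is documented as
log2; background correction is out of scope — input is taken as already
background-corrected, since the original instrument-vendor model is
proprietary.

**Detection filter.** A probe is kept when its detection p-value is
≤ alpha (default 0.05) in at least `min_detected` samples. The default
`min_detected="all"` (every sample of the treated/control pair) is the
conservative reading; the original report does not say whether its
filter was per-sample, per-condition or averaged, so the rule is
configuration, not a guess baked in. Missing values are rejected, not
imputed, because SAM downstream assumes complete matrices.

## SAM differential expression

Two-class unpaired SAM: `d_i = (x̄_treated − x̄_control) / (s_i + s0)`
with `s_i` the pooled standard error
`sqrt((1/n1 + 1/n2) · SS / (n1 + n2 − 2))`.

- **Fudge factor `s0`.** Candidates are the 0th–100th percentiles (step
  5) of `s`; the winner minimizes the coefficient of variation of the
  median absolute deviation of `d` computed within 100 moving
  s-percentile windows. On homoscedastic data this criterion selects a
  large `s0` (the statistic degrades gracefully toward the plain mean
  difference), which is also the best-powered choice in our simulations.
- **Permutation null.** Distinct treated-group assignments, enumerated
  exhaustively when fewer than the requested number exist (for 4 vs 4
  arrays there are only C(8,4) = 70), otherwise sampled without
  replacement, seeded. Each permuted `d` column is sorted;
  `d_expected` is the row-wise mean of the sorted columns. `s0` is held
  fixed across permutations.
- **Delta selection.** Over a 200-point grid from 0 to
  `max|d − d_expected|`, the smallest delta whose estimated median FDR
  meets the target is chosen. FDR(delta) = `π0 ×` median permuted calls /
  observed calls, with `π0 = min(1, 2 × proportion of observed d inside
  the IQR of the pooled permuted d)`. Zero observed calls define
  FDR = 0, so a null dataset resolves to an (empty) selection rather
  than an error. Per-probe q-values are the minimum FDR over the grid at
  which the probe is called.
- **Fold filter.** Two-sided and boundary-inclusive on the linear scale:
  keep `|log2fc| ≥ log2(min_fold)` (default 1.5), where the fold change
  is the ratio of group geometric means, i.e. `2^(difference of log2
  means)`.
- **Probe collapsing.** Gene log2 fold change = arithmetic mean of its
  probes' log2 fold changes (a `linear` averaging mode is available;
  tests pin the log2 default). Gene q-value = minimum over member
  probes. Genes whose probes cancel to exactly zero have no assignable
  direction and are dropped with a warning.

## Signature construction

Genes present in both gene-level DEG tables are *shared*; strict sign
agreement of the two log2 fold changes splits them into up/down
(concordant) versus discordant. Zero gene-level fold changes cannot
survive the fold filter, so no tie rule is needed. Concordant genes
expand to probe-level tag lists on the target platform; genes without a
target-platform probe are recorded as unmapped, not fatal (an empty
resulting tag list is fatal — the query is impossible). Discordant genes
never enter the tag lists. Cross-platform symbol matching is exact and
case-sensitive on the annotation as supplied; no alias resolution is
attempted, for determinism.

## Connectivity scoring

An *instance* is one treatment's complete probe ranking (rank 1 = most
up-regulated). For a tag list of size `t` at ascending ranks `V(j)` in
`n` probes:

    a = max_j [ j/t − V(j)/n ],   b = max_j [ V(j)/n − (j−1)/t ]
    ks = a  if a > b  else  −b

`a` and `b` are exactly the one-sample Kolmogorov–Smirnov D+ / D−
statistics of `V/n` against the uniform, which the test suite exploits
as an independent oracle. The raw instance score is `ks_up − ks_down`
when the two statistics disagree in sign and 0 otherwise; raw scores are
scaled into [−1, 1] by dividing positives by the maximum positive raw
and negatives by the magnitude of the most negative raw (each branch
divides by 1 when empty), so whenever any positive raw exists exactly
one instance attains +1.

**Aggregation.** Instances are ordered by scaled score descending; ties
(notably the zero-score block) are broken by an md5 hash of the instance
id — deterministic, but uncorrelated with perturbagen membership, so a
perturbagen's instances do not artificially cluster inside a tie block
(with a lexicographic tie-break they do, which visibly inflates null
enrichment). Each perturbagen reports the arithmetic mean of its
instances' scaled scores, the instance count `n`, the signed
position-KS `enrichment` of its instances within the ordering, and a
permutation p-value: the tail of the null enrichment (random size-`n`
position sets) in the observed direction, add-one corrected, **doubled**
(floor `2/(n_draws+1)`). The doubling makes the p-value uniform under a
null database — a directional one-sided p is capped near 0.5 and cannot
be — and leaves the ranking order unchanged. Reported p-values that are
integer multiples of `2/(n_draws+1)` are a signature of this convention.
Single-instance perturbagens have a structural p floor of about
`2/N_instances` regardless of how perfectly they match; perturbagen-level
significance needs replicate instances.

**Ranking.** Primary key p-value ascending; secondary key |enrichment|
*descending* (the printed hit tables order the top tie block by
decreasing enrichment); final tie alphabetical. A "specificity" column
is reported as NA: it would require the historical corpus of past
queries, which is not reproducible here.

**Query options.** Metadata filters restrict instances by exact match
(e.g. `cell_line=MCF7`); a positive-enrichment-only mode mirrors the
original screen. Instances missing query tags raise an error by
default; an explicit `drop_missing_tags` mode removes absent tags per
query and renormalizes `t`, because silent dropping across platforms
must be opt-in.

## Enrichment statistics

Over-representation uses the one-sided hypergeometric tail
`P(X ≥ overlap)` per gene set (each set intersected with the universe
first), Benjamini–Hochberg adjusted across sets; both raw and adjusted
p-values are reported. The universe should be the detected background of
the experiment, not the genome. The activation z-score is the simple
`(consistent − inconsistent)/√N` over a regulator's DEG targets with
signed expected effects, `|z| ≥ 2` declaring activated/inhibited. This
is deliberately the plain form: commercial literature-weighted variants
are proprietary, so published regulator tables built with them are not
reproduction targets for this package.

## Synthetic data: what it emulates, and what it does not

**Expression generator.** Log2-additive Gaussian model: per-probe
baseline `N(8, 1.5²)`, residual noise `N(0, noise_sd²)` per cell
(default 0.5). Planted genes shift by exactly `±effect_log2fc` (default
1.5) in the treated arm, shared genes with the same sign in both
conditions; each probe adds a jitter `N(0, (noise_sd/2)²)` drawn once
per probe — probe affinity is probe-intrinsic, so a weak probe is weak
in both conditions — which makes probe collapsing non-trivial but
recoverable. Detection failure is likewise a probe property (an
unexpressed transcript fails everywhere): a `detection_fail_rate`
fraction of probes (default 0.2) receives detection p ~ U(0.05, 1) in
every cell and the rest U(0, 0.05), so with ~20k simulated probes the
detected count lands near the ~16k of the emulated study. Planted genes
are expressed by construction. Default design: 378/391 shared up/down
genes, condition-specific pools of 911 and 754 so per-condition DEG
totals land near the study's 1.7k/1.5k, 1–3 probes per gene, 4 arrays
per arm (the original replicate count per arm is not stated; 4 is the
configurable default).

**Instance generator.** Instance rankings come from a latent uniform
score per probe, ascending order = most up-regulated first. In
concordant perturbagens every instance subtracts
`strength × (1 + U(0,1))` from the latent score of each shared-up probe
and adds the same to each shared-down probe; the `1 +` term guarantees
the limit contract that at strength 1 every up probe outranks every
down probe, while strength 0 is exactly null. All other instances are
uniform random permutations. Defaults (1000 perturbagens, 1–10 instances
each) mirror the ~7000 instances / ~1300 molecules ratio of the emulated
database. Instances carry perturbagen, concentration, batch and
cell-line labels; concordant instances are always assigned the queried
cell line.

**Not emulated:** bead-level array structure, scanner or batch effects,
dye bias, correlated gene modules, heavy-tailed noise, dose–response
structure across an perturbagen's instances, and platform differences
between discovery and database probe sets. Passing tests therefore
demonstrate correctness of the statistical machinery and recoverability
under the declared noise model — not robustness to every artifact of
real microarray data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full design at its
default scale (~20k probes, 4 vs 4 arrays, exhaustive 70-permutation
null) and scale the database side to a few hundred perturbagens with
thousands of permutation draws; these sizes give stable statistics while
keeping a full run to seconds. Calibration checks use 20 null
simulations of 5000 probes; signature recovery uses 10 seeds at the
default design, where the mean Jaccard between recovered and planted
shared genes is ≈ 0.81 — the residual loss is real statistical cost
(probes whose jittered effect falls under the FDR-0.01 threshold in one
of the two conditions), not an implementation artifact. Degenerate
inputs fail loudly: single-sample normalization, non-binary labels,
groups of one, empty tag lists, tags absent from rankings, and
out-of-domain thresholds all raise typed errors naming the offending
field or identifiers.
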