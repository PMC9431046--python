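# Methods

This note records the models, rules and numerical choices behind
`phyllocore`, and what the synthetic benchmark does and does not show.

## Data model and run merging

The pipeline's currency is a samples × ASVs matrix of non-negative
integer read counts, with sample metadata (type ∈ {plant, arthropod,
blank}; crop, greenhouse, department, week for plants; batch for
arthropods; sequencing run; replicate group) and a genus-level taxonomy
carrying an organelle flag.  TSV is the primary on-disk format (samples
as rows, ASVs as columns); BIOM 1.0 JSON is offered for interoperability,
written with a fixed creation date so output is byte-stable.

Re-sequenced aliquots of one physical sample share a `replicate_group`;
merging keeps the aliquot with the largest bacterial read total (all
reads if no taxonomy is supplied).  Ties go to the latest run, then the
lexicographically first sample id — the tie rule is arbitrary but fixed,
because determinism matters more than any particular choice.  ASV
identity across runs is harmonized by exact sequence string when
sequences are available, else by id.

## Quality control

*Organelle removal* drops ASVs whose lineage contains
chloroplast/plastid/mitochondrial labels and reports the per-sample
fraction of reads removed.  Samples left empty are retained until the
global minimum-read filter (100 reads) drops them, so bookkeeping stays
per-stage.

*Contaminant screening* is a per-run threshold rule: an ASV is flagged
when it is present (≥ 1 read) in at least one blank of a run **and** its
maximum count over that run's real samples is **≤ 10 reads, inclusive**.
The inclusive bound is deliberate: the worked example shipped with the
package removes ASVs whose maximum sample count is exactly 10, which is
only consistent with ≤ 10.  Blanks indict ASVs only within their own
run.  Statistical contaminant models (frequency/prevalence, decontam-
style) are deliberately not used; contamination that blanks cannot see —
an ASV abundant in unrelated samples multiplexed on the same run — is
expressed as an explicit `(asv_id, action, reason)` override, never
inferred.  Whether blank presence should require ≥ 2 reads is unsettled;
≥ 1 is used.

## Diversity primitives

Inverse Simpson (1/Σp²) and Bray-Curtis (1 − 2Σmin/(Σx+Σy)) are computed
from first principles and cross-checked against scipy/scikit-bio in the
test suite.  Rarefaction subsamples without replacement via a seeded
multivariate hypergeometric draw — one draw per sample, no averaging —
and drops samples below the target depth (default 500 reads).

**Subset-restricted Bray-Curtis.**  For cumulative core-set
contributions, the dissimilarity of a pair restricted to an ASV subset S
is Σ_{i∈S}|xᵢ−yᵢ| divided by the pair's *full* read total.  This makes a
subset's contribution additive, growing from 0 to the ordinary
Bray-Curtis as S grows; renormalizing within the subset would let a
2-taxon set claim a dissimilarity of 1.  On rarefied tables (equal
totals) this is identical to restricting relative abundances.

**PERMANOVA** is the single-factor distance decomposition: with total
sum of squared distances SS_T = Σ_{i<j} d²ᵢⱼ/n and within-group
SS_W = Σ_g Σ_{i<j∈g} d²ᵢⱼ/n_g, the statistic is
F = (SS_A/(a−1))/(SS_W/(n−a)) and R² = SS_A/SS_T.  p-values use the +1
correction, p = (1 + #{F* ≥ F})/(1 + n_perm), so p is never 0 at finite
permutations; an exact mode enumerates all distinct label arrangements
for small designs.  Multi-factor sequential partitioning is out of
scope — factors are tested one at a time.  PCoA is classical scaling via
scikit-bio with negative eigenvalues reported, not corrected.

## Core-taxon prioritization

Ranking cells are the department × week crossing: replicates are samples
of the same department, occupancy is time-specific, and crossing the two
is the only grouping that uses both.  The index is the equal-weight mean
of (a) mean per-cell occupancy and (b) the fraction of cells occupied in
*every* replicate; weights are exposed in the API.  Presence for
occupancy is ≥ 1 read on the rarefied table — rarefaction already
suppresses singleton noise; the stricter ≥ 2-read rule is reserved for
the overlap/Venn layer, where presence claims cross sample groups.  Ties
are broken by mean relative abundance, then ASV id.

The elbow statistic `(C_p − C_1)/p − (C_n − C_p)/(n − p)` is evaluated
at every split position 1 ≤ p < n and the first maximizer wins.  Note a
strictly linear curve has no elbow: the statistic then increases with p
and the rule returns the last position — a degenerate input, not a tie.
`lastcall` returns the deepest rank whose contribution ratio to the
previous rank is ≥ 1.02 (2% gain); the first element's "increase" is
defined as C₁ itself, and when nothing qualifies the rule falls back to
the elbow.

## Neutral community model

Local relative abundance of a taxon with source mean abundance p is
modeled as Beta(N·m·p, N·m·(1−p)); expected occupancy is the upper tail
beyond the detection threshold d/N.  In this pipeline N is the
rarefaction depth (libraries are uniform by construction) and d = 1 read,
matching the occupancy definition above.  m is fitted by bounded scalar
minimization of squared occupancy residuals on log₁₀ m ∈ [−4, 2] — the
response is monotone in m, so no multi-start is needed.  R² is
1 − SSE/SS_tot on the occupancy scale.  The 95% envelope applies Wilson
score bounds to the predicted occupancy at the observed number of
samples; taxa are classified above/within/below.  Least squares on the
occupancy scale with Wilson envelopes follows the widely used
implementation lineage for this model; neither the loss nor the envelope
construction is canonical, and logit-scale fits would weight rare taxa
differently.

Two simulators back the model: a count-level one (beta draws realized by
binomial sampling — realistic tables) and a record-level one whose
detection rule is the model's own threshold on the beta draw.  Parameter
recovery is assessed on the latter, because binomial detection
(1 − (1−q)^N) is not the threshold detection the fitted formula assumes
and induces a known bias that grows with m; the record-level simulator
also carries the true source abundance on the abundance axis, avoiding
errors-in-variables flattening at small N·m.  Recovery at N = 500, 300
taxa, 30 samples gives median relative errors of a few percent for
m ∈ {0.01, 0.1, 0.5}.

## Arthropod overlap

Association requires ≥ 2 reads in at least one arthropod sample.  Sample
qualification defaults to "total associated reads ≥ 2"; the alternative
reading "≥ 2 distinct associated ASVs" is implemented as
`rule="distinct_asvs"` because both phrasings circulate for this kind of
index and they differ on edge cases (one ASV at 2 reads).  The transfer
index averages per-sample percentages, unweighted — pooling reads would
let one deep sample dominate.  The "combined" source is the union of the
per-source associated sets.

## Synthetic data

The generator emulates the study shape the analysis assumes: 4
departments × 5 weeks × 2 samples; bacterial depths log-uniform on
10²–10⁴ reads; host reads appended at a per-sample nonbacterial fraction
uniform on 30–95%; 300 plant ASVs of which 3 are planted core taxa
jointly holding ~50% of each sample's reads (Dirichlet-split between
them, so they both saturate occupancy and dominate between-sample
dissimilarity); one department-specific bloom taxon per department
(~20% share); a neutral background with migration parameter m = 0.1;
bumblebee (3 batches) and predatory-mite (2 batches) communities on a
reserved ASV id space, injected into 80% of plant samples at a 15%
transfer fraction; 5 contaminant ASVs seeded into blanks (1–15 reads)
and sparsely into plant samples at ≤ 10 reads; and a quarter of plant
samples re-sequenced in a second run under a shared replicate group.
All draws flow through one seeded generator, so outputs are reproducible
to the byte.

What passing on this benchmark shows: the pipeline's rules recover
planted structure (core taxa, contaminants, transfer fractions, the
migration parameter) when the data actually obey the generator's
assumptions, and every index agrees with brute-force oracles.  What it
does not show: robustness to taxonomic misannotation, chimeras or
index-hopping (upstream of this artifact), to core taxa with weak effect
sizes, to arthropod/plant ASV collisions (disabled by default via the
reserved id space), or to compositional effects at depths far below the
rarefaction target.  Real-data shapes such as a strong occupancy–
abundance relationship in one crop but not another are emulated only to
the extent the neutral background produces them.

## Problem sizes

Default test and acceptance runs use the generator defaults above
(40 plant samples before filtering, ~400 ASVs), 20 replicates per
condition for recovery studies, 500 replicates for the PERMANOVA
calibration check and 99–999 permutations per test — sizes chosen so the
whole suite completes in a few minutes on one core while keeping Monte
Carlo error well below the decision margins.
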