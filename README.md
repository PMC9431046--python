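# phyllocore

Analysis pipeline for greenhouse phyllosphere amplicon surveys: from
per-run ASV count tables to core-taxon calls, a fitted Sloan neutral
community model, and indices quantifying how much of the leaf microbiome
arrives on the backs of introduced arthropods (pollinator bumblebees,
predatory mites).

Greenhouse crops carry sparse, low-diversity bacterial communities —
per-sample bacterial read counts of 10²–10⁴ are typical after host
(chloroplast/mitochondrial) reads are stripped.  At such depths the
interesting questions are structural: which few taxa are *core* to the
crop across departments and weeks, whether the remaining occupancy–
abundance cloud is explainable by neutral assembly, and how strongly the
community overlaps with the contact microbiome of arthropods released for
integrated pest management.  `phyllocore` implements that analysis as a
tested, reusable library with a thin CLI, plus a synthetic-data generator
with complete ground truth so every stage can be validated without any
sequencing download.

## What it computes

**Preprocessing.** Sequencing runs are merged keeping, per re-sequenced
sample, the aliquot with the most bacterial reads.  Organelle ASVs are
removed (reporting per-sample % nonbacterial).  Contaminants are screened
per run from no-template blanks: an ASV present in a blank whose maximum
count in that run's real samples is ≤ 10 reads is removed; cross-domain
cases are handled by explicit overrides, never inferred.  Samples under
100 total reads are discarded.

**Core-taxon prioritization.** On the table rarefied to 500 reads, each
ASV *i* gets an occupancy/consistency index over department × week cells
*g* (with occupancy *o₍ᵢg₎* = fraction of the cell's samples containing
*i*, and *G* cells):

```
index_i = ½ · [ mean_g(o_ig)  +  (1/G)·#{g : o_ig = 1} ]
```

Prospective core sets grow along the ranking; the mean pairwise
Bray-Curtis dissimilarity restricted to the top-*k* set (numerator
Σ|x−y| over the ranked subset, denominator the full totals), divided by
the full-community value, is the set's cumulative contribution to beta
diversity.  The **elbow** stopping rule picks the split position *p*
maximizing `(C_p − C_1)/p − (C_n − C_p)/(n − p)`; the laxer **lastcall**
rule keeps every rank whose addition still improves explained beta
diversity by ≥ 2%.

**Neutral model.** The Sloan neutral community model predicts a taxon's
occupancy from its mean relative abundance *p*:

```
occupancy(p) = 1 − F_Beta(d/N; N·m·p, N·m·(1−p))
```

with depth *N* (the rarefaction depth), detection limit *d* = 1 read and
a single free migration parameter *m*, fitted by least squares on the
occupancy scale.  Taxa above the 95% envelope (Wilson bounds) are more
prevalent than their abundance explains — the signature of deterministic
selection or active dispersal; taxa below are dispersal-limited.

**Arthropod overlap.**  An ASV is arthropod-associated if it reaches ≥ 2
reads in any arthropod sample.  The **dispersal index** is the percentage
of plant samples carrying ≥ 2 reads of associated ASVs; the **transfer
index** is the mean share (%) of such a sample's reads that are
associated.  Venn partitions of shared ASVs across 2–3 sample groups and
single-factor permutation PERMANOVA (R², pseudo-F, +1-corrected p; exact
enumeration available for small designs) round out the reporting.

## Worked example

```python
import phyllocore as pc

ds = pc.generate_dataset(pc.SimulationConfig(seed=1))
res = pc.run_pipeline(ds.tables, ds.metadata, ds.taxonomy)

for crop, ranking in res.core.items():
    print(f"{crop}: elbow rank {ranking.elbow_rank}, core = {sorted(ranking.core_elbow)}")
print(res.neutral["tomato"].summary())
rep = res.overlap[("tomato", "bumblebee")]
print(f"tomato x bumblebee: dispersal {rep.dispersal_index:.1f}%, transfer {rep.transfer_index:.1f}%")
```

prints

```
strawberry: elbow rank 3, core = ['P0000', 'P0001', 'P0002']
tomato: elbow rank 3, core = ['P0000', 'P0001', 'P0002']
Sloan neutral community model (least squares on occupancy)
----------------------------------------------------------
migration parameter m : 0.757182
effective depth N     : 500 reads
detection limit d     : 1 reads
R-squared             : 0.6598
taxa fitted           : 244
above envelope        : 12
within envelope       : 229
below envelope        : 3
tomato x bumblebee: dispersal 75.0%, transfer 9.9%
```

The elbow core recovers exactly the three taxa the generator planted with
full occupancy and a dominant share of between-sample dissimilarity.
Three-quarters of the tomato samples carry at least two reads of
bumblebee-associated ASVs, and in those samples such reads average ~10%
of the library — the planted transfer structure.  The 12 taxa above the
neutral envelope are the planted core, bloom and transferred taxa; the
neutral background sits within it.

The same stages are available as CLI subcommands
(`phyllocore simulate | preprocess | rarefy | core | neutral | overlap |
diversity | all`).

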