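# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, the design decisions that were genuinely open, and what the
synthetic-data generator does and does not emulate.

## Data model and conventions

Coordinates are 1-based inclusive throughout; BED input is converted on
read. Chromosome names are normalized (`chr1` ≡ `1`). Genome-fraction
denominators (GII, adGII, LOH fraction, the doubling statistic) cover
autosomes only by default — sex-chromosome ploidy is ambiguous in mixed-sex
cohorts — and are configurable via `include_chroms`. VAF denominators are
`t_alt + t_ref`: reads supporting third alleles are not modeled. Sectors
without copy-number profiles are allowed; SCNA/WGD/timing stages mark them
absent while mutation stages still use them.

## Filter rules

The exome and deep-seq rules are threshold tests on read counts and VAFs
(see the `filters` module docstrings for the exact rule set). Boundary
conventions that the rules themselves do not pin down:

* all VAF thresholds use ≥ at the boundary (e.g. tumor VAF exactly 0.2
  passes the low-VAF ratio guard);
* "tumor VAF at least N× normal VAF" with normal VAF = 0 passes — the limit
  of the ratio test;
* germline subtraction is represented as an optional blacklist of variant
  keys in the pipeline config; germline calling itself is upstream of the
  count tables this package consumes.

Every decision carries the list of failed rule identifiers, so the pass
boolean is redundant with (and checked against) the rule list.

## Presence, classification, pITH

A mutation is present in a sector iff it passes deep-seq validation there
(the pipeline's presence rule; any predicate can be supplied). Mutations
validated nowhere are dropped; sectors without a count row for a mutation
are imputed absent, which is correct for targeted panels that cover every
discovered variant in every sector. Trunk/branch/private follow the sector
counts exactly, so pITH + trunk% = 100 by construction — the test suite
asserts this as an identity, not a tolerance.

Subsampling statistics (`subsample_trunk_ratio`, `burden_gain`) draw k
sectors without replacement for a fixed number of iterations (default 20,
matching the emulated analysis) and average. The burden-gain baseline is
the mean single-sector burden *of the drawn k sectors*; alternatives (first
drawn sector, patient-wide mean) change the number but not the ordering, and
the choice is an explicit argument of the enumeration oracle in the tests.
Draws that observe zero mutations are skipped rather than counted as zero.

## Trees

Hamming distances between sector presence profiles count discordant
mutations; the normal outgroup is the all-absent profile, so its distance
to a sector is that sector's burden and the edge from the normal to the
tumor clade renders the trunk. Neighbor joining is delegated to scikit-bio;
negative branch lengths (possible for non-additive inputs) are clamped to
zero after construction. With two taxa a degenerate path tree is returned
with a warning. Topology correctness is cross-checked against an
independent NJ implementation (dendropy) on random additive matrices.

## Ploidy, GII, adGII

Median integer ploidy is the weighted median of per-segment total copy
number: SNP-count weights when every segment has them, otherwise segment
lengths (mixed weights fall back to lengths for all segments — the units
are not comparable). The median is the smallest value at which cumulative
weight reaches half the total, breaking exact ties to the lower integer.

GII counts the length fraction with |total CN − ploidy| ≥ 1, adGII with
≥ 2, so GII ≥ adGII always and both are invariant to splitting a segment in
two. Only total copy number enters: copy-neutral LOH does not count toward
GII. Note an arithmetic consequence of the relative definition: doubling
every allele doubles both the ploidy and every deviation, so gain/loss
*direction* and GII are invariant under doubling while deviation magnitudes
(and hence adGII) scale — the property tests check exactly this.

Feature mapping uses the 25%-overlap rule only to arbitrate between
multiple overlapping segments (largest qualifying overlap wins; overlap
fraction is measured against the feature's length); a feature covered by a
single segment takes its copy number regardless. SCNA-level ITH compares
per-sector alteration directions, sign only: truncal = same nonzero
direction in every evaluable sector, late = altered in some sectors or in
conflicting directions, unaltered otherwise; patients need at least three
sectors with profiles.

## Whole-genome doubling test

Observed statistic: length fraction of the included genome with major
allele copy number ≥ 2. Null model: starting from a non-doubled 1+1 genome
with the sample's own segment structure, each segment independently gains a
single copy with probability p_gain and loses one with probability p_loss,
where the rates are the observed genome fractions with total copy number
above/below the sample's median integer ploidy. For a non-doubled (ploidy
2) sample this is exactly the fraction deviating from the non-doubled
expectation of 2, which makes the test self-calibrating on undoubled
genomes (the observed statistic sits at the center of its own null); for a
doubled sample the observed rates are small while the statistic is near 1,
which is what gives the test its power. The reference level is exposed as
`rate_reference` ("ploidy" or "diploid"). Losses drawn from 1+1 remove the
minor allele and cannot raise the major count, so they drop out of the
simulated statistic. The p-value uses the add-one estimator
(1 + #{T_sim ≥ T_obs})/(1 + n_sim) with 10,000 simulations by default.
Decisions are ploidy-dependent: p < 0.001 for ploidy ≤ 3, p < 0.05 at
ploidy 4 (to avoid underestimating doubling in high-ploidy samples), and
doubled unconditionally above ploidy 4; integer median ploidy makes the
three cases exhaustive. The tumor-level call in reports is the majority of
per-sector calls. The exact published null this concretizes is not restated
anywhere at this level of detail; every ingredient (rates, reference,
statistic, thresholds) is therefore a keyword argument rather than a
constant.

## CCF and timing

With VAF f, purity ρ and local total copy number CNt, the mutant allele
copy number is n_mut = f·(ρ·CNt + 2(1−ρ))/ρ; multiplicity m is n_mut
rounded and clamped to [1, n_major] (a mutation cannot occupy more copies
than the larger haplotype has); CCF = n_mut/m, not capped at 1. The 95% CI
is Clopper–Pearson on the alt-read count pushed through the same linear
map — exact, deterministic and conservative; a bootstrap alternative would
add noise without changing any decision at deep-seq depths. Clonal ⇔ the
CCF interval overlaps 1 (an interval entirely above 1 is therefore
subclonal — rare and conservative). Timing: indels, 1+1 regions and
single-copy regions are never evaluable; otherwise early ⇔ clonal and
round(n_mut) ≥ 2, else late. At 3860X the CI half-width on CCF is ~0.04,
so the early-timing sensitivity on truly pre-doubling clonal mutations is
essentially the CI coverage (~95%, measured 94–95% on simulated cohorts).

## Dominance

d_j counts distinct mutated driver genes per patient (not events), so a
double-hit tumor suppressor counts once and hypermutators do not deflate
every score; `count_events=True` switches to event counting. Genes below
the carrier threshold (default 5 patients) are excluded from ranking; ties
are broken by carrier count then gene name for determinism.

## Synthetic cohorts

Defaults are the emulated study's conditions: 16 patients, 3–11 sectors,
exome 114X, deep-seq 3860X, purity 0.4–0.8, doubling probability 0.8
(12/15 tumors in the emulated cohort), 40/40/20 trunk/branch/private
mutations per tumor (~100 validated mutations, pITH 60%, near the emulated
cohort's 62.3% median), truncal copy alterations on ~40% of the genome with
~7% high-copy (GII ≈ 48%, adGII ≈ 7% medians), and ~8% per-sector private
alterations. Branch clades are internal edges of a random binary tree over
the sectors; each sector is a pure sample of its clade path (an admixture
model is deliberately out of scope — the emulated analyses treat sectors as
units). Copy number: doubling first (truncal wherever present), then shared
events, then per-sector events; losses strip the minor allele first and
never reduce a segment below one total copy, which slightly compresses
high-copy losses on undoubled genomes. Pre-doubling truncal SNVs carry
multiplicity 2 where the doubled haplotype is retained. Read counts are
binomial at Poisson depths around the assay means, with an optional
symmetric error rate (default 0) for filter stress-tests; `noiseless=True`
replaces sampling with expectations so truth-recovery checks can be exact.
The generator does **not** emulate: mutational signature context, subclonal
copy-number mixtures within a sector, germline contamination, alignment or
panel-design artifacts, or real segment-length distributions (40 segments
over 22 autosomes at Mb scale). Passing tests therefore demonstrate
correctness of the *inference rules* under the stated generative model, not
robustness to every artifact of real data.

Problem sizes in the test suite and acceptance script (1000 random
matrices, 100 random trees, 200 null and 200 doubled profiles at 2000
simulations, 5–6 tumors for timing, 50 dominance cohorts) were chosen so
the whole run completes on a laptop-class single core in well under a
minute per stage while keeping binomial assertion tolerances (3 SE, 99%
detection, 95% ranking recovery) meaningful.

## Known limitations

* The doubling-test null treats segments as independent; real gains are
  correlated along chromosome arms, so the null is anti-conservative in
  principle for arm-level events — mitigated by the coarse segment template
  and the stringent 0.001 threshold, and the per-arm granularity can be
  emulated by supplying arm-sized segments.
* CCF is single-sample; no joint multi-sector clustering of CCFs is
  attempted.
* The timing rule cannot distinguish a mutation predating a single-copy
  gain from one predating a full doubling; on doubled genomes both read as
  "early", which matches the intended interpretation.
* Validation rates on simulated cohorts are near 1 by construction
  (both assays observe the same planted truth); the rate machinery exists
  for real data where the assays disagree.
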