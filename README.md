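# clonarch

Clonal-architecture analysis of multi-region (multi-sector) tumor sequencing
data, built for studies in which each tumor is cut into spatially distinct
sectors that are exome-sequenced for discovery and re-sequenced by targeted
deep sequencing for validation — the design used to characterize intra-tumor
heterogeneity in EGFR-mutant lung adenocarcinoma. It is a library plus a thin
`clonarch` CLI for analysts who have per-sector somatic read-count tables and
ASCAT-style allele-specific copy-number segments and want the downstream
evolutionary analyses, not the upstream alignment/calling.

## What it computes

**Variant filtering and validation.** Post-caller somatic filters for exome
SNVs (≤5 alt reads in the normal at ≤0.05 normal VAF, ≥6 tumor alt reads, and
tumor VAF ≥ 0.2 or ≥ 10× the normal VAF) and indels (>4 reads, VAF ≥ 0.1),
and deep-seq validation rules (SNVs: exome-called, ≥10 alt reads or ≥15 when
VAF < 0.05, VAF ≥ 0.01 and ≥ 5× normal; indels: strand balance ≤ 90%, ≥10
reads, VAF ≥ 0.03 and ≥ 5× normal), with per-rule audit trails and
validation-rate summaries.

**Phylogeny and pITH.** Per patient, a boolean mutation × sector presence
matrix from validated calls; mutations classified *trunk* (all sectors),
*branch* (some) or *private* (one); proportional intra-tumor heterogeneity

    pITH = 100 × (n_branch + n_private) / n_total

neighbor-joining trees on Hamming distances with an all-absent normal
outgroup; and sector-subsampling statistics (mean trunk ratio and mutation
burden gain at fixed k) that make trunk fractions comparable across cohorts
with different sector counts.

**Copy-number instability.** Median integer ploidy (weighted median of
per-segment total copy number), GII and adGII (genome fraction altered by
≥1 and ≥2 copies relative to ploidy), LOH fractions, gene/cytoband copy
assignment with the 25%-largest-overlap rule, and truncal vs late SCNA
classification across sectors.

**Whole-genome doubling.** A simulation test comparing the genome fraction
with major allele copy ≥2 against a null of independent single-copy events
at the sample's own rates, with ploidy-dependent decision thresholds
(p < 0.001 for ploidy ≤ 3, p < 0.05 at ploidy 4, doubled above 4).

**CCF and mutation timing.** Mutant allele copy number
`n_mut = VAF · (purity·CNt + 2(1−purity)) / purity`, multiplicity, cancer
cell fraction with exact binomial confidence intervals, clonal/subclonal
calls, and early/late timing relative to copy gains (early ⇔ clonal and
rounded multiplicity ≥ 2; indels and unaltered or single-copy regions are
not evaluable).

**Driver dominance.** For driver gene *i* with carriers *j* (patients with a
non-silent mutation in *i*) and per-patient driver burden *d_j*,

    D_i = (Σ_j 1/d_j) / N_i

ranks drivers by how often they appear without co-drivers (D = 1 means
always the sole driver).

**Simulator.** A synthetic cohort generator (`clonarch.simulate`) with
planted truth — clade labels, copy-number profiles, doubling status,
pre/post-doubling multiplicities, driver co-occurrence — matching the
emulated study's conditions (16 patients, 3–11 sectors, 114X exome, 3860X
deep-seq), so every stage can be tested against known ground truth.

## Worked example

```python
from clonarch.pipeline import PipelineConfig, run_pipeline
from clonarch.simulate import SimConfig

cfg = PipelineConfig(out_dir="demo", seed=7, simulate=SimConfig(n_patients=3))
cohort = run_pipeline(cfg)
for pid, r in sorted(cohort["patients"].items()):
    ph, w = r["phylo"], r["wgd"]
    print(f"{pid}: {ph['n_sectors']} sectors, {ph['n_mutations']} mutations "
          f"({ph['n_trunk']} trunk / {ph['n_branch']} branch / {ph['n_private']} private), "
          f"pITH {ph['pith_percent']:.1f}%, burden gain {ph['burden_gain_percent']:.1f}%, "
          f"doubled={w['tumor_doubled']}")
print("cohort median pITH:", cohort["pith_median_percent"])
```

prints

```
P001: 4 sectors, 100 mutations (40 trunk / 40 branch / 20 private), pITH 60.0%, burden gain 36.0%, doubled=True
P002: 9 sectors, 100 mutations (40 trunk / 40 branch / 20 private), pITH 60.0%, burden gain 29.0%, doubled=True
P003: 7 sectors, 100 mutations (40 trunk / 40 branch / 20 private), pITH 60.0%, burden gain 39.2%, doubled=True
cohort median pITH: 60.0
```

Each simulated tumor planted 40 trunk, 40 branch and 20 private mutations,
so pITH is 60% (the 60 non-truncal mutations out of 100); the burden gain is
the average extra mutation yield of sequencing three random sectors instead
of one (it varies by patient with the tree shape); `doubled` is the
majority call of the per-sector genome-doubling test. `demo/` contains the
JSON/TSV reports and one Newick tree per patient.

The same pipeline runs from files:

```sh
clonarch all --config analysis.yaml --seed 7 --out-dir out/
```

where the YAML names the exome/deep-seq variant TSVs, segment + purity
tables, cytoband/gene feature files and driver lists (see
`clonarch.pipeline.PipelineConfig` for all keys; individual stages are also
exposed as `clonarch filter|phylo|ith|scna|wgd|dominance|simulate`).

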