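"""Whole-genome-doubling test, cancer-cell-fraction estimation and mutation
timing relative to copy gains.

WGD test
--------
The observed statistic is the genome length fraction with major allele copy
number >= 2 — after a doubling every locus starts with two copies of each
haplotype, so this fraction is near 1 in doubled genomes and near the gained
fraction otherwise.  The null asks how often independent single-copy gains,
drawn at the sample's own event rates, could push the statistic that high
without a doubling: starting from a non-doubled 1+1 genome with the sample's
segment structure, each segment independently gains one copy with
probability p_gain (and loses one with probability p_loss, which cannot
raise the major allele and so never increases the statistic).  Event rates
are the genome fractions with total copy number above/below the sample's
median integer ploidy by default (for a non-doubled, ploidy-2 sample this is
exactly the fraction above/below the non-doubled expectation of 2);
``rate_reference="diploid"`` pins the reference at 2 instead.  The decision
combines the simulation p-value with ploidy-dependent thresholds: p < 0.001
for ploidy <= 3, p < 0.05 at ploidy 4 (to avoid underestimating doubling in
high-ploidy samples), and doubled unconditionally above ploidy 4.

CCF and timing
--------------
For a mutation with VAF f in a sector of purity rho and local total copy
number CNt, the mutant allele copy number is

    n_mut = f * (1/rho) * (rho * CNt + 2 * (1 - rho))

the multiplicity m is n_mut rounded and clamped to [1, n_major], and
CCF = n_mut / m (not capped at 1).  The 95% CI is an exact (Clopper-Pearson)
binomial interval on the VAF pushed through the same linear map; a mutation
is clonal when the CCF interval overlaps 1.  A clonal mutation whose rounded
mutant copy number is >= 2 must have preceded the local gain/doubling and is
labeled early; indels, 1+1 regions and single-copy regions cannot be timed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import binomtest

from .types import AUTOSOMES, Segment, SectorProfile, VariantRecord, normalize_chrom
from .scna import median_integer_ploidy


@dataclass
class WGDResult:
    sector_id: str
    t_obs: float  # genome fraction with n_major >= 2
    p_value: float
    n_sim: int
    ploidy: int
    doubled: bool


def classify_wgd(ploidy: int, p_value: float,
                 alpha_low: float = 0.001, alpha_ploidy4: float = 0.05) -> bool:
    """Ploidy-dependent decision rule on the simulation p-value."""
    if ploidy > 4:
        return True
    if ploidy == 4:
        return p_value < alpha_ploidy4
    return p_value < alpha_low


def wgd_test(
    p: SectorProfile,
    n_sim: int = 10000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    rate_reference: str = "ploidy",
    include_chroms: Optional[frozenset[str]] = None,
    alpha_low: float = 0.001,
    alpha_ploidy4: float = 0.05,
) -> WGDResult:
    """Simulation test for whole-genome doubling on one sector profile."""
    allowed = AUTOSOMES if include_chroms is None else include_chroms
    segs = [s for s in p.segments if normalize_chrom(s.chrom) in allowed]
    if not segs:
        raise ValueError(f"sector {p.sector_id}: no segments on included chromosomes")
    rng = rng if rng is not None else np.random.default_rng(seed)

    lengths = np.array([s.length for s in segs], dtype=float)
    total = lengths.sum()
    major = np.array([s.n_major for s in segs])
    cn = np.array([s.total_cn for s in segs])
    t_obs = float(lengths[major >= 2].sum() / total)

    ploidy = median_integer_ploidy(p)
    if rate_reference == "ploidy":
        ref = ploidy
    elif rate_reference == "diploid":
        ref = 2
    else:
        raise ValueError(f"unknown rate_reference {rate_reference!r}")
    p_gain = float(lengths[cn > ref].sum() / total)

    # Under the null only gains create a second major copy; losses from 1+1
    # remove the minor allele and leave the statistic untouched.
    gained = rng.random((n_sim, len(segs))) < p_gain
    t_sim = gained @ lengths / total
    p_value = float((1 + np.sum(t_sim >= t_obs - 1e-12)) / (1 + n_sim))

    return WGDResult(
        sector_id=p.sector_id,
        t_obs=t_obs,
        p_value=p_value,
        n_sim=n_sim,
        ploidy=ploidy,
        doubled=classify_wgd(ploidy, p_value, alpha_low, alpha_ploidy4),
    )


@dataclass
class CCFEstimate:
    """Cancer cell fraction and timing call for one mutation observation."""

    key: tuple
    sector_id: str
    evaluable: bool
    n_mut: Optional[float] = None  # continuous mutant allele copy number
    multiplicity: Optional[int] = None
    ccf: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    clonal: Optional[bool] = None
    timing: str = "not_evaluable"  # early | late | not_evaluable

    def __post_init__(self) -> None:
        if self.timing == "early" and not (
            self.clonal and self.n_mut is not None and round(self.n_mut) >= 2
        ):
            raise ValueError("early timing requires clonal and round(n_mut) >= 2")


def ccf(
    v: VariantRecord,
    purity: float,
    local_cn: Segment,
    conf_level: float = 0.95,
) -> CCFEstimate:
    """Cancer cell fraction for one mutation in one sector.

    Returns a non-evaluable estimate when the local total copy number is 0
    (no template to mutate); raises on zero tumor depth or invalid purity.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0,1], got {purity}")
    depth = v.tumor_depth
    if depth == 0:
        raise ValueError(f"zero tumor depth for {v.key}: VAF undefined")
    cnt = local_cn.total_cn
    if cnt == 0:
        return CCFEstimate(key=v.key, sector_id=v.sector_id, evaluable=False)

    scale = (purity * cnt + 2.0 * (1.0 - purity)) / purity
    vaf = v.tumor_vaf
    n_mut = vaf * scale
    m = int(np.clip(round(n_mut), 1, max(local_cn.n_major, 1)))
    ci = binomtest(v.t_alt, depth).proportion_ci(
        confidence_level=conf_level, method="exact"
    )
    ci_low = ci.low * scale / m
    ci_high = ci.high * scale / m
    est_ccf = n_mut / m
    clonal = bool(ci_low <= 1.0 <= ci_high)
    return CCFEstimate(
        key=v.key,
        sector_id=v.sector_id,
        evaluable=True,
        n_mut=float(n_mut),
        multiplicity=m,
        ccf=float(est_ccf),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        clonal=clonal,
    )


def time_mutation(
    e: CCFEstimate, v: VariantRecord, local_cn: Segment
) -> CCFEstimate:
    """Attach the early/late timing label to a CCF estimate.

    Indels, regions with no copy alteration (1+1) and single-copy regions
    cannot be timed and are not evaluable.  Otherwise the mutation is early
    iff it is clonal and its rounded mutant copy number is >= 2 (it must
    have been present on the haplotype before it was multiplied), else late.
    """
    if (
        not e.evaluable
        or v.is_indel
        or (local_cn.n_major == 1 and local_cn.n_minor == 1)
        or local_cn.total_cn <= 1
    ):
        e.timing = "not_evaluable"
        return e
    if e.clonal and round(e.n_mut) >= 2:
        e.timing = "early"
    else:
        e.timing = "late"
    return e


def ccf_and_timing(
    v: VariantRecord, purity: float, local_cn: Segment
) -> CCFEstimate:
    """CCF estimation followed by the timing call."""
    return time_mutation(ccf(v, purity, local_cn), v, local_cn)
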