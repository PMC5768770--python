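"""Synthetic multi-sector tumor cohorts with known ground truth.

The generator emulates a multi-region sequencing study of EGFR-mutant lung
adenocarcinoma: 16 patients, 3-11 sectors per tumor, exome discovery at
~114X and targeted deep-seq validation at ~3860X, with configurable
trunk/branch/private mutation counts, purity, whole-genome doubling and
driver co-occurrence.  Every observable table is paired with a
:class:`TruthBundle` (true clade labels, true copy-number profiles, true WGD
status, true pre/post-doubling multiplicity) so each pipeline stage can be
scored against planted truth.

Model sketch
------------
A random binary tree over the sectors supplies the clades: trunk mutations
sit on the root edge (all sectors), branch mutations on internal edges
(proper sector subsets), private mutations on leaf edges.  Each sector is a
pure sample of its clade mixture (one dominant clade per sector), so a
mutation's cancer cell fraction is 1 in carrier sectors and 0 elsewhere.
Copy number starts from a 1+1 template of 40 segments over 22 autosomes;
doubling (when present) is truncal and applied first, then shared truncal
gains/losses, then small per-sector events.  Truncal SNVs predating the
doubling carry the mutation on both copies of their haplotype
(multiplicity 2).  Expected VAF in a sector follows

    E[f] = purity * m * CCF / (purity * CNt + 2 * (1 - purity))

and read counts are binomial at Poisson-distributed depths (an optional
symmetric error rate stresses the filters; `noiseless=True` replaces
sampling with expectations for exact truth-recovery checks).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .types import Segment, SectorProfile, VariantRecord

# Approximate autosome lengths in Mb, hg-scale; abstract units are fine for
# length-weighted statistics.
_AUTOSOME_MB = [
    249, 243, 198, 191, 181, 171, 159, 146, 141, 136,
    135, 133, 115, 107, 102, 90, 81, 78, 59, 63, 48, 51,
]
_MB = 1_000_000


def default_segment_template() -> list[tuple[str, int, int]]:
    """40 segments over the 22 autosomes: two per chromosome for the 18
    largest, one for the rest; 1-based inclusive coordinates."""
    template: list[tuple[str, int, int]] = []
    for i, mb in enumerate(_AUTOSOME_MB, start=1):
        length = mb * _MB
        chrom = str(i)
        if i <= 18:
            mid = length // 2
            template.append((chrom, 1, mid))
            template.append((chrom, mid + 1, length))
        else:
            template.append((chrom, 1, length))
    return template


class SimulationConfigError(ValueError):
    """The requested cohort is infeasible (e.g. branch mutations with <3
    sectors)."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: 16 patients with 3-11 sectors,
    ~100 validated mutations per tumor split 40/40/20 trunk/branch/private
    (pITH 60%), exome depth 114X, deep-seq depth 3860X, ASCAT-style purities
    0.4-0.8, doubling in ~80% of tumors, ~40% of the genome under shared
    copy alterations of which ~7% are high-copy.
    """

    n_patients: int = 16
    sectors_min: int = 3
    sectors_max: int = 11
    n_trunk: int = 40
    n_branch: int = 40
    n_private: int = 20
    exome_depth: float = 114.0
    deepseq_depth: float = 3860.0
    purity_min: float = 0.4
    purity_max: float = 0.8
    wgd_prob: float = 0.8
    wgd_timing: str = "pre"  # doubling before ("pre") or after ("post") branching
    pre_wgd_trunk_fraction: float = 0.5
    truncal_scna_fraction: float = 0.4
    truncal_high_copy_fraction: float = 0.07
    private_scna_fraction: float = 0.08
    indel_fraction: float = 0.05
    non_silent_fraction: float = 0.3
    error_rate: float = 0.0
    noiseless: bool = False
    scna_missing_sector_prob: float = 0.0
    segment_template: list[tuple[str, int, int]] = field(
        default_factory=default_segment_template
    )

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.sectors_min < 2 or self.sectors_max < self.sectors_min:
            raise SimulationConfigError("need >=1 patient and >=2 sectors")
        for name in ("n_trunk", "n_branch", "n_private"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name} must be >= 0")
        if self.exome_depth <= 0 or self.deepseq_depth <= 0:
            raise SimulationConfigError("depths must be > 0")
        if not (0 < self.purity_min <= self.purity_max <= 1):
            raise SimulationConfigError("purity range must lie in (0, 1]")
        if self.n_branch > 0 and self.sectors_min < 3:
            raise SimulationConfigError(
                "branch mutations (several-but-not-all sectors) need >=3 sectors"
            )
        if self.n_private > 0 and self.sectors_min < 2:
            raise SimulationConfigError("private mutations need >=2 sectors")
        if self.wgd_timing not in ("pre", "post"):
            raise SimulationConfigError(f"unknown wgd_timing {self.wgd_timing!r}")
        for name in ("truncal_scna_fraction", "private_scna_fraction",
                     "indel_fraction", "error_rate", "wgd_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise SimulationConfigError(f"{name} must be in [0, 1]")
        if self.truncal_high_copy_fraction > self.truncal_scna_fraction:
            raise SimulationConfigError(
                "high-copy fraction cannot exceed total truncal SCNA fraction"
            )


@dataclass
class TruthBundle:
    """Ground truth emitted alongside the observable tables."""

    patient_id: str
    clade_label: dict[str, str]  # mutation key string -> trunk|branch|private
    carriers: dict[str, frozenset[str]]  # key -> carrier sector ids
    pre_wgd: dict[str, bool]  # key -> mutation predates the doubling
    wgd: bool
    profiles: dict[str, SectorProfile]  # true per-sector CN (complete)
    multiplicity: dict[tuple[str, str], int]  # (key, sector) -> copies carrying
    segment_index: dict[str, int]  # key -> template segment index
    driver_genes: frozenset[str]


@dataclass
class SimulatedTumor:
    patient_id: str
    sectors: list[str]
    exome_variants: list[VariantRecord]
    deepseq_variants: list[VariantRecord]
    profiles: dict[str, SectorProfile]  # observed (may omit sectors)
    truth: TruthBundle


def patient_seed(master_seed: int, patient_id: str) -> int:
    """Stable per-patient seed derived from a master seed; independent of
    the order patients are generated in."""
    return zlib.crc32(f"{master_seed}:{patient_id}".encode()) % (2**31)


# ---------------------------------------------------------------------------
# copy-number generation


def _truncal_deltas(rng: np.random.Generator, n_seg: int, cfg: SimConfig) -> np.ndarray:
    """Per-segment shared copy deviations: 0, +-1 or +-2."""
    deltas = np.zeros(n_seg, dtype=int)
    event = rng.random(n_seg) < cfg.truncal_scna_fraction
    high = rng.random(n_seg) < (
        cfg.truncal_high_copy_fraction / cfg.truncal_scna_fraction
        if cfg.truncal_scna_fraction > 0
        else 0.0
    )
    sign = np.where(rng.random(n_seg) < 0.5, 1, -1)
    deltas[event] = (np.where(high, 2, 1) * sign)[event]
    return deltas


def _apply_delta(major: np.ndarray, minor: np.ndarray, deltas: np.ndarray) -> None:
    """Apply integer copy deviations in place: gains go to the major allele,
    losses strip the minor allele first and never reduce a segment below one
    total copy."""
    for i, d in enumerate(deltas):
        if d > 0:
            major[i] += d
        elif d < 0:
            take = min(minor[i], -d)
            minor[i] -= take
            rem = -d - take
            major[i] -= min(rem, major[i] - 1)


def simulate_profiles(
    rng: np.random.Generator,
    sectors: Sequence[str],
    cfg: SimConfig,
    wgd: bool,
) -> dict[str, SectorProfile]:
    """True copy-number profiles for all sectors of one tumor: doubling (if
    any) first, then shared truncal events, then per-sector events."""
    template = cfg.segment_template
    n_seg = len(template)
    base = 2 if wgd else 1
    major0 = np.full(n_seg, base, dtype=int)
    minor0 = np.full(n_seg, base, dtype=int)
    _apply_delta(major0, minor0, _truncal_deltas(rng, n_seg, cfg))

    purities = rng.uniform(cfg.purity_min, cfg.purity_max, size=len(sectors))
    profiles: dict[str, SectorProfile] = {}
    for sector, purity in zip(sectors, purities):
        major, minor = major0.copy(), minor0.copy()
        event = rng.random(n_seg) < cfg.private_scna_fraction
        sign = np.where(rng.random(n_seg) < 0.5, 1, -1)
        _apply_delta(major, minor, np.where(event, sign, 0))
        segments = [
            Segment(
                sector_id=sector,
                chrom=chrom,
                start=start,
                end=end,
                n_major=int(max(major[i], minor[i])),
                n_minor=int(min(major[i], minor[i])),
            )
            for i, (chrom, start, end) in enumerate(template)
        ]
        profiles[sector] = SectorProfile(
            sector_id=sector, purity=float(purity), segments=segments
        )
    return profiles


# ---------------------------------------------------------------------------
# clade structure


def _random_clades(rng: np.random.Generator, sectors: list[str]) -> list[frozenset[str]]:
    """Internal-edge clades (proper subsets, size >=2) of a random binary
    tree over the sectors, built by recursive random partition."""
    n_total = len(sectors)
    clades: list[frozenset[str]] = []

    def split(group: list[str]) -> None:
        if len(group) < 2:
            return
        if 2 <= len(group) < n_total:
            clades.append(frozenset(group))
        perm = list(rng.permutation(group))
        cut = int(rng.integers(1, len(group)))
        split(perm[:cut])
        split(perm[cut:])

    split(sectors)
    return clades


# ---------------------------------------------------------------------------
# read counts


def _draw_counts(
    rng: np.random.Generator,
    mean_depth: float,
    expected_vaf: float,
    error_rate: float,
    noiseless: bool,
) -> tuple[int, int]:
    """(ref, alt) read counts at a given mean depth and expected VAF."""
    p = expected_vaf * (1.0 - error_rate) + (1.0 - expected_vaf) * error_rate
    if noiseless:
        depth = max(int(round(mean_depth)), 1)
        alt = int(round(depth * p))
    else:
        depth = max(int(rng.poisson(mean_depth)), 1)
        alt = int(rng.binomial(depth, p))
    return depth - alt, alt


_BASES = np.array(list("ACGT"))


def simulate_tumor(
    cfg: SimConfig,
    seed: Union[int, np.random.Generator],
    patient_id: str = "P001",
) -> SimulatedTumor:
    """One multi-sector tumor: observable variant tables (exome + deep-seq),
    per-sector copy-number profiles and the truth bundle."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sectors = int(rng.integers(cfg.sectors_min, cfg.sectors_max + 1))
    sectors = [f"{patient_id}-S{i + 1:02d}" for i in range(n_sectors)]
    if cfg.n_branch > 0 and n_sectors < 3:
        raise SimulationConfigError("branch mutations need >=3 sectors")

    wgd = bool(rng.random() < cfg.wgd_prob)
    profiles = simulate_profiles(rng, sectors, cfg, wgd)
    clades = _random_clades(rng, sectors)

    template = cfg.segment_template
    seg_lengths = np.array([end - start + 1 for _, start, end in template], dtype=float)
    seg_weights = seg_lengths / seg_lengths.sum()

    labels = ["trunk"] * cfg.n_trunk + ["branch"] * cfg.n_branch + ["private"] * cfg.n_private
    clade_label: dict[str, str] = {}
    carriers: dict[str, frozenset[str]] = {}
    pre_wgd: dict[str, bool] = {}
    multiplicity: dict[tuple[str, str], int] = {}
    segment_index: dict[str, int] = {}
    driver_genes = {"EGFR"}

    exome_rows: list[VariantRecord] = []
    deepseq_rows: list[VariantRecord] = []

    for idx, label in enumerate(labels):
        seg_i = int(rng.choice(len(template), p=seg_weights))
        chrom, start, end = template[seg_i]
        pos = int(rng.integers(start, end + 1))
        is_indel = bool(rng.random() < cfg.indel_fraction)
        if is_indel:
            variant_class = "INS" if rng.random() < 0.5 else "DEL"
            ref, alt = ("A", "AT") if variant_class == "INS" else ("AT", "A")
        else:
            variant_class = "SNV"
            ref = str(rng.choice(_BASES))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        # the tumor-initiating driver is a truncal SNV; other genes are unique
        if idx == 0 and label == "trunk":
            gene, effect, variant_class, ref, alt = "EGFR", "non_silent", "SNV", "T", "G"
        else:
            gene = f"G{idx:04d}"
            effect = "non_silent" if rng.random() < cfg.non_silent_fraction else (
                "silent" if rng.random() < 0.5 else "other"
            )

        if label == "trunk":
            carrier_set = frozenset(sectors)
        elif label == "branch":
            carrier_set = clades[int(rng.integers(len(clades)))]
        else:
            carrier_set = frozenset([sectors[int(rng.integers(n_sectors))]])

        key = f"{chrom}:{pos}:{ref}:{alt}"
        if key in clade_label:  # collision: same site drawn twice; skip silently
            continue
        clade_label[key] = label
        carriers[key] = carrier_set
        segment_index[key] = seg_i
        is_pre = (
            wgd
            and cfg.wgd_timing == "pre"
            and label == "trunk"
            and not is_indel
            and bool(rng.random() < cfg.pre_wgd_trunk_fraction)
        )
        pre_wgd[key] = is_pre

        for sector in sectors:
            profile = profiles[sector]
            seg = profile.segments[seg_i]
            in_sector = sector in carrier_set
            m = 0
            if in_sector:
                m = 2 if (is_pre and seg.n_major >= 2) else 1
            multiplicity[(key, sector)] = m
            denom = profile.purity * seg.total_cn + 2.0 * (1.0 - profile.purity)
            expected_vaf = (profile.purity * m / denom) if denom > 0 and m else 0.0

            t_ref, t_alt = _draw_counts(
                rng, cfg.deepseq_depth, expected_vaf, cfg.error_rate, cfg.noiseless
            )
            n_ref, n_alt = _draw_counts(
                rng, cfg.deepseq_depth, 0.0, cfg.error_rate, cfg.noiseless
            )
            strand = None
            if is_indel:
                fwd = (t_alt + 1) // 2 if cfg.noiseless else int(rng.binomial(t_alt, 0.5))
                strand = (fwd, t_alt - fwd)
            deepseq_rows.append(
                VariantRecord(
                    patient_id=patient_id,
                    sector_id=sector,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    variant_class=variant_class,
                    gene=gene,
                    effect=effect,
                    assay="deepseq",
                    t_ref=t_ref,
                    t_alt=t_alt,
                    n_ref=n_ref,
                    n_alt=n_alt,
                    alt_fwd=None if strand is None else strand[0],
                    alt_rev=None if strand is None else strand[1],
                )
            )
            if in_sector:  # exome discovery rows only where the clone lives
                et_ref, et_alt = _draw_counts(
                    rng, cfg.exome_depth, expected_vaf, cfg.error_rate, cfg.noiseless
                )
                en_ref, en_alt = _draw_counts(
                    rng, cfg.exome_depth, 0.0, cfg.error_rate, cfg.noiseless
                )
                exome_rows.append(
                    VariantRecord(
                        patient_id=patient_id,
                        sector_id=sector,
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        variant_class=variant_class,
                        gene=gene,
                        effect=effect,
                        assay="exome",
                        t_ref=et_ref,
                        t_alt=et_alt,
                        n_ref=en_ref,
                        n_alt=en_alt,
                    )
                )

    observed_profiles = {
        s: p
        for s, p in profiles.items()
        if not (rng.random() < cfg.scna_missing_sector_prob)
    }
    truth = TruthBundle(
        patient_id=patient_id,
        clade_label=clade_label,
        carriers=carriers,
        pre_wgd=pre_wgd,
        wgd=wgd,
        profiles=profiles,
        multiplicity=multiplicity,
        segment_index=segment_index,
        driver_genes=frozenset(driver_genes),
    )
    return SimulatedTumor(
        patient_id=patient_id,
        sectors=sectors,
        exome_variants=exome_rows,
        deepseq_variants=deepseq_rows,
        profiles=observed_profiles,
        truth=truth,
    )


def simulate_cohort(cfg: SimConfig, seed: int) -> list[SimulatedTumor]:
    """A cohort of tumors with per-patient seeds derived from the master
    seed, so any one patient regenerates identically in isolation."""
    tumors = []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        tumors.append(simulate_tumor(cfg, patient_seed(seed, pid), patient_id=pid))
    return tumors


# ---------------------------------------------------------------------------
# driver co-occurrence cohorts


@dataclass
class PlantedDriver:
    """One driver gene planted into a dominance cohort: carried by
    ``n_patients`` patients, each with ``co_drivers`` additional mutated
    driver genes (with probability ``noise_prob``, one extra)."""

    gene: str
    n_patients: int
    co_drivers: int
    noise_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SimulationConfigError("planted driver needs >=1 patient")
        if self.co_drivers < 0 or not 0 <= self.noise_prob <= 1:
            raise SimulationConfigError("invalid co-driver spec")


def simulate_cohort_for_dominance(
    plant: Sequence[PlantedDriver],
    seed: Union[int, np.random.Generator],
    filler_pool: int = 30,
) -> tuple[list[VariantRecord], dict[str, frozenset[str]], frozenset[str]]:
    """Cohort mutation table with planted driver co-occurrence.

    Each planted gene gets its own disjoint set of patients; co-drivers are
    drawn round-robin from a pool of filler genes so no filler accumulates
    enough carriers to enter the ranking at the usual threshold.  Returns
    (variant rows, per-patient true driver sets, full driver gene list).
    """
    if not plant:
        raise SimulationConfigError("empty planting spec")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fillers = [f"FILLER{k:03d}" for k in range(filler_pool)]
    filler_cycle = list(rng.permutation(fillers))
    cursor = 0

    def next_fillers(n: int) -> list[str]:
        nonlocal cursor, filler_cycle
        out: list[str] = []
        while len(out) < n:
            if cursor >= len(filler_cycle):
                filler_cycle = list(rng.permutation(fillers))
                cursor = 0
            g = filler_cycle[cursor]
            cursor += 1
            if g not in out:
                out.append(g)
        return out

    rows: list[VariantRecord] = []
    truth: dict[str, frozenset[str]] = {}
    pos = 0
    for spec in plant:
        if spec.co_drivers >= filler_pool:
            raise SimulationConfigError(
                f"co_drivers for {spec.gene} exceeds the filler pool"
            )
        for j in range(spec.n_patients):
            patient = f"{spec.gene}_pt{j + 1:03d}"
            n_co = spec.co_drivers + (1 if rng.random() < spec.noise_prob else 0)
            genes = [spec.gene] + next_fillers(n_co)
            truth[patient] = frozenset(genes)
            for gene in genes:
                pos += 1
                rows.append(
                    VariantRecord(
                        patient_id=patient,
                        sector_id=f"{patient}-S01",
                        chrom="1",
                        pos=pos,
                        ref="A",
                        alt="T",
                        variant_class="SNV",
                        gene=gene,
                        effect="non_silent",
                        assay="deepseq",
                        t_ref=50,
                        t_alt=50,
                        n_ref=60,
                        n_alt=0,
                    )
                )
    all_genes = frozenset(g for gs in truth.values() for g in gs)
    return rows, truth, all_genes
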