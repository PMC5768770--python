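"""Copy-number instability metrics and feature-level copy assignment.

Everything here is computed *relative to the median integer ploidy* of the
sector: a segment is a gain/loss when its total copy number deviates from
the weighted-median total copy number by at least one.  GII (genomic
instability index) is the genome length fraction with |deviation| >= 1;
adGII restricts to high-copy events (|deviation| >= 2), so GII >= adGII
always.  The genome denominator covers autosomes by default — sex-chromosome
ploidy is ambiguous — and can be widened via ``include_chroms``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .types import (
    AUTOSOMES,
    Feature,
    Segment,
    SectorProfile,
    normalize_chrom,
)


def _included(segments: Iterable[Segment],
              include_chroms: Optional[frozenset[str]]) -> list[Segment]:
    allowed = AUTOSOMES if include_chroms is None else include_chroms
    return [s for s in segments if normalize_chrom(s.chrom) in allowed]


def median_integer_ploidy(p: SectorProfile) -> int:
    """Weighted median of per-segment total copy number.

    Weights are SNP counts when every segment carries one, otherwise segment
    lengths (a mix falls back to lengths for all — mixed weighting units are
    not comparable).  The median is the smallest copy number at which the
    cumulative weight reaches half the total, which breaks exact ties to the
    lower integer.
    """
    if not p.segments:
        raise ValueError(f"sector {p.sector_id}: empty profile, ploidy undefined")
    use_snps = all(s.n_snps is not None for s in p.segments)
    values = np.array([s.total_cn for s in p.segments], dtype=float)
    weights = np.array(
        [s.n_snps if use_snps else s.length for s in p.segments], dtype=float
    )
    order = np.argsort(values, kind="stable")
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights)
    idx = int(np.searchsorted(cum, cum[-1] / 2.0))
    return int(values[idx])


@dataclass
class RelativeCall:
    """A segment's copy state relative to the sector's median ploidy."""

    segment: Segment
    delta: int
    cls: str  # loss2 | loss1 | neutral | gain1 | gain2plus

    @staticmethod
    def class_of(delta: int) -> str:
        if delta <= -2:
            return "loss2"
        if delta == -1:
            return "loss1"
        if delta == 0:
            return "neutral"
        if delta == 1:
            return "gain1"
        return "gain2plus"


def relative_calls(
    p: SectorProfile, ploidy: Optional[int] = None
) -> list[RelativeCall]:
    ploidy = p.ploidy if ploidy is None else ploidy
    return [
        RelativeCall(segment=s, delta=s.total_cn - ploidy,
                     cls=RelativeCall.class_of(s.total_cn - ploidy))
        for s in p.segments
    ]


@dataclass
class InstabilityScores:
    sector_id: str
    gii: float
    adgii: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.adgii <= self.gii <= 1.0):
            raise ValueError(
                f"invalid instability scores gii={self.gii} adgii={self.adgii}"
            )


def instability_scores(
    p: SectorProfile,
    include_chroms: Optional[frozenset[str]] = None,
) -> InstabilityScores:
    """GII and adGII: genome length fractions altered by >=1 and >=2 copies
    relative to the median integer ploidy.

    Only total copy number is compared, so copy-neutral LOH does not count
    as an alteration.  The denominator is the covered length of included
    chromosomes (autosomes unless ``include_chroms`` says otherwise).
    """
    segs = _included(p.segments, include_chroms)
    if not segs:
        return InstabilityScores(sector_id=p.sector_id, gii=0.0, adgii=0.0)
    ploidy = p.ploidy
    lengths = np.array([s.length for s in segs], dtype=float)
    deltas = np.array([abs(s.total_cn - ploidy) for s in segs])
    total = lengths.sum()
    gii = float(lengths[deltas >= 1].sum() / total)
    adgii = float(lengths[deltas >= 2].sum() / total)
    return InstabilityScores(sector_id=p.sector_id, gii=gii, adgii=adgii)


@dataclass
class FeatureCN:
    """Copy number assigned to a cytoband or gene in one sector."""

    feature: str
    sector_id: str
    assigned: bool
    total_cn: Optional[int] = None
    n_major: Optional[int] = None
    n_minor: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.assigned and self.total_cn is not None:
            raise ValueError("unassigned feature must have empty CN fields")


def map_to_features(
    p: SectorProfile,
    features: Sequence[Feature],
    min_overlap: float = 0.25,
) -> list[FeatureCN]:
    """Assign segment copy numbers to features (cytobands/genes) by overlap.

    A feature overlapped by a single segment takes that segment's copy
    number.  When several segments overlap, only segments covering at least
    ``min_overlap`` of the feature's length qualify and the largest overlap
    wins; if none qualifies the feature is left unassigned.
    """
    by_chrom: dict[str, list[Segment]] = {}
    for s in p.segments:
        by_chrom.setdefault(normalize_chrom(s.chrom), []).append(s)

    out: list[FeatureCN] = []
    for f in features:
        candidates = []
        for s in by_chrom.get(normalize_chrom(f.chrom), []):
            ov = min(f.end, s.end) - max(f.start, s.start) + 1
            if ov > 0:
                candidates.append((ov, s))
        chosen: Optional[Segment] = None
        if len(candidates) == 1:
            chosen = candidates[0][1]
        elif len(candidates) > 1:
            qualifying = [
                (ov, s) for ov, s in candidates if ov / f.length >= min_overlap
            ]
            if qualifying:
                chosen = max(qualifying, key=lambda t: t[0])[1]
        if chosen is None:
            out.append(FeatureCN(feature=f.name, sector_id=p.sector_id, assigned=False))
        else:
            out.append(
                FeatureCN(
                    feature=f.name,
                    sector_id=p.sector_id,
                    assigned=True,
                    total_cn=chosen.total_cn,
                    n_major=chosen.n_major,
                    n_minor=chosen.n_minor,
                )
            )
    return out


@dataclass
class LOHSummary:
    sector_id: str
    flags: list[bool]  # parallel to profile.segments
    genome_fraction: float  # LOH length fraction of included genome


def detect_loh(
    p: SectorProfile, include_chroms: Optional[frozenset[str]] = None
) -> LOHSummary:
    """Flag loss-of-heterozygosity segments (minor copy number 0, locus
    retained) and the genome length fraction they cover."""
    flags = [s.is_loh for s in p.segments]
    segs = _included(p.segments, include_chroms)
    total = sum(s.length for s in segs)
    loh_len = sum(s.length for s in segs if s.is_loh)
    frac = loh_len / total if total else 0.0
    return LOHSummary(sector_id=p.sector_id, flags=flags, genome_fraction=frac)


@dataclass
class ScnaIthResult:
    labels: dict[str, str]  # feature -> truncal | late | unaltered
    late_fraction: Optional[float]
    n_sectors: int


def scna_ith(
    feature_cn: Mapping[str, Sequence[FeatureCN]],
    ploidies: Mapping[str, int],
    min_sectors: int = 3,
) -> ScnaIthResult:
    """Classify per-feature copy alterations as truncal, late or unaltered
    across a patient's sectors.

    ``feature_cn`` maps sector id -> per-feature assignments; direction in a
    sector is sign(total CN - sector ploidy).  Truncal: the same nonzero
    direction in every evaluable sector.  Late: nonzero in some but not all
    sectors, or conflicting directions.  Unaltered: zero everywhere.
    Features must be assigned in at least ``min_sectors`` sectors to be
    classified.  Patients with fewer than ``min_sectors`` sectors overall
    are not evaluable and raise ``ValueError``.
    """
    sectors = list(feature_cn)
    if len(sectors) < min_sectors:
        raise ValueError(
            f"SCNA-ITH needs >= {min_sectors} sectors with profiles, "
            f"got {len(sectors)}"
        )
    directions: dict[str, list[int]] = {}
    for sector in sectors:
        ploidy = ploidies[sector]
        for fc in feature_cn[sector]:
            if not fc.assigned:
                continue
            directions.setdefault(fc.feature, []).append(
                int(np.sign(fc.total_cn - ploidy))
            )
    labels: dict[str, str] = {}
    for feature, dirs in directions.items():
        if len(dirs) < min_sectors:
            continue
        nonzero = [d for d in dirs if d != 0]
        if not nonzero:
            labels[feature] = "unaltered"
        elif len(nonzero) == len(dirs) and len(set(nonzero)) == 1:
            labels[feature] = "truncal"
        else:
            labels[feature] = "late"
    n = len(labels)
    late = sum(1 for v in labels.values() if v == "late")
    return ScnaIthResult(
        labels=labels,
        late_fraction=late / n if n else None,
        n_sectors=len(sectors),
    )
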