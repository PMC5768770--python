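"""Core domain types for multi-sector tumor analysis.

Coordinates are 1-based inclusive throughout (SEG/MAF convention); BED input
is converted on read.  A "sector" is a spatially distinct piece of one tumor
that was sequenced separately; every per-sector quantity (purity, copy-number
profile, read counts) hangs off a sector id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

VariantClass = str  # "SNV" | "INS" | "DEL"
Effect = str  # "non_silent" | "silent" | "other"
Assay = str  # "exome" | "deepseq"

VARIANT_CLASSES = ("SNV", "INS", "DEL")
EFFECTS = ("non_silent", "silent", "other")
ASSAYS = ("exome", "deepseq")

AUTOSOMES = frozenset(str(i) for i in range(1, 23))


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so ``chr1`` and ``1`` compare equal."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


class ValidationError(ValueError):
    """A record violates a domain-type invariant."""


MutationKey = tuple[str, int, str, str]  # (chrom, pos, ref, alt); unique per patient


@dataclass
class VariantRecord:
    """One somatic SNV/indel observation in one tumor sector.

    Tumor/normal read counts are for the ref and alt alleles only; the VAF
    denominator is ``t_alt + t_ref`` (reads carrying other alleles are not
    modeled).  ``alt_fwd``/``alt_rev`` split the tumor alt reads by strand and
    are only needed for deep-seq indel validation.
    """

    patient_id: str
    sector_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    assay: Assay
    t_ref: int
    t_alt: int
    n_ref: int
    n_alt: int
    gene: str = ""
    effect: Effect = "other"
    alt_fwd: Optional[int] = None
    alt_rev: Optional[int] = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(f"unknown variant_class {self.variant_class!r}")
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}")
        if self.effect not in EFFECTS:
            raise ValidationError(f"unknown effect {self.effect!r}")
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        for name in ("t_ref", "t_alt", "n_ref", "n_alt"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if (self.alt_fwd is None) != (self.alt_rev is None):
            raise ValidationError("alt_fwd and alt_rev must be given together")
        if self.alt_fwd is not None:
            if self.alt_fwd < 0 or self.alt_rev < 0:
                raise ValidationError("strand counts must be >= 0")
            if self.alt_fwd + self.alt_rev != self.t_alt:
                raise ValidationError(
                    f"alt_fwd+alt_rev ({self.alt_fwd}+{self.alt_rev}) != t_alt ({self.t_alt})"
                )

    @property
    def key(self) -> MutationKey:
        return (normalize_chrom(self.chrom), self.pos, self.ref, self.alt)

    @property
    def tumor_depth(self) -> int:
        return self.t_ref + self.t_alt

    @property
    def normal_depth(self) -> int:
        return self.n_ref + self.n_alt

    @property
    def tumor_vaf(self) -> float:
        """Tumor variant allele fraction; NaN at zero depth."""
        d = self.tumor_depth
        return self.t_alt / d if d > 0 else math.nan

    @property
    def normal_vaf(self) -> float:
        """Normal VAF; defined as 0 at zero normal depth (no evidence)."""
        d = self.normal_depth
        return self.n_alt / d if d > 0 else 0.0

    @property
    def is_indel(self) -> bool:
        return self.variant_class in ("INS", "DEL")


@dataclass
class Segment:
    """Allele-specific copy-number segment (ASCAT-style nMajor/nMinor)."""

    sector_id: str
    chrom: str
    start: int
    end: int
    n_major: int
    n_minor: int
    n_snps: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"bad segment coordinates {self.chrom}:{self.start}-{self.end}"
            )
        if self.n_minor < 0 or self.n_major < 0:
            raise ValidationError("copy numbers must be >= 0")
        if self.n_major < self.n_minor:
            raise ValidationError(
                f"n_major ({self.n_major}) < n_minor ({self.n_minor}): alleles swapped?"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def total_cn(self) -> int:
        return self.n_major + self.n_minor

    @property
    def is_loh(self) -> bool:
        """Loss of heterozygosity: minor allele absent but locus retained."""
        return self.n_minor == 0 and self.total_cn >= 1

    def contains(self, chrom: str, pos: int) -> bool:
        return (
            normalize_chrom(self.chrom) == normalize_chrom(chrom)
            and self.start <= pos <= self.end
        )


@dataclass
class SectorProfile:
    """Purity plus allele-specific copy-number segments for one sector."""

    sector_id: str
    purity: float
    segments: list[Segment] = field(default_factory=list)
    _ploidy: Optional[int] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValidationError(f"purity must be in (0,1], got {self.purity}")
        _check_no_overlap(self.segments)

    @property
    def ploidy(self) -> int:
        """Median integer ploidy (weighted median of per-segment total CN)."""
        if self._ploidy is None:
            from .scna import median_integer_ploidy

            self._ploidy = median_integer_ploidy(self)
        return self._ploidy

    def segment_at(self, chrom: str, pos: int) -> Optional[Segment]:
        for seg in self.segments:
            if seg.contains(chrom, pos):
                return seg
        return None


def _check_no_overlap(segments: Sequence[Segment]) -> None:
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(normalize_chrom(seg.chrom), []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping segments on chromosome {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


@dataclass
class Feature:
    """A named genomic interval (cytoband or gene) in 1-based coordinates."""

    name: str
    chrom: str
    start: int
    end: int
    kind: str  # "cytoband" | "gene"

    def __post_init__(self) -> None:
        if self.kind not in ("cytoband", "gene"):
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"bad feature coordinates for {self.name}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FeatureTable:
    features: list[Feature]

    def __post_init__(self) -> None:
        for kind in ("cytoband", "gene"):
            names = [f.name for f in self.features if f.kind == kind]
            if len(names) != len(set(names)):
                raise ValidationError(f"duplicate {kind} feature names")

    def of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


@dataclass
class DriverCatalog:
    """Driver-gene lists: a tumor-type-specific core set and an extended
    pan-cancer superset."""

    luad_drivers: frozenset[str]
    extended_drivers: frozenset[str]

    def __post_init__(self) -> None:
        self.luad_drivers = frozenset(self.luad_drivers)
        self.extended_drivers = frozenset(self.extended_drivers)
        if not self.luad_drivers <= self.extended_drivers:
            raise ValidationError("luad_drivers must be a subset of extended_drivers")

    def genes(self, gene_set: str = "luad") -> frozenset[str]:
        if gene_set == "luad":
            return self.luad_drivers
        if gene_set == "extended":
            return self.extended_drivers
        raise ValueError(f"unknown gene_set {gene_set!r}")


def group_by_patient(variants: Iterable[VariantRecord]) -> dict[str, list[VariantRecord]]:
    out: dict[str, list[VariantRecord]] = {}
    for v in variants:
        out.setdefault(v.patient_id, []).append(v)
    return out
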