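"""Readers and writers for the pipeline's tabular and tree formats.

Variant and segment tables are plain TSV with headers; cytobands use the UCSC
``cytoBand.txt`` dialect; gene intervals use BED (0-based half-open, converted
to 1-based inclusive on read); trees are Newick via scikit-bio.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Union

from skbio import TreeNode

from .types import (
    DriverCatalog,
    Feature,
    FeatureTable,
    Segment,
    SectorProfile,
    ValidationError,
    VariantRecord,
)

PathLike = Union[str, Path]

VARIANT_COLUMNS = [
    "patient_id",
    "sector_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "gene",
    "effect",
    "assay",
    "t_ref",
    "t_alt",
    "n_ref",
    "n_alt",
    "alt_fwd",
    "alt_rev",
]

SEGMENT_COLUMNS = ["sector_id", "chrom", "start", "end", "nMajor", "nMinor", "nSNPs"]


class ParseError(ValueError):
    """A file could not be parsed; carries the offending row number."""

    def __init__(self, path: PathLike, row: Optional[int], message: str):
        self.path = str(path)
        self.row = row
        loc = f"{path}" if row is None else f"{path}, row {row}"
        super().__init__(f"{loc}: {message}")


def _int_field(value: str, name: str, *, optional: bool = False) -> Optional[int]:
    value = value.strip()
    if value in ("", "NA", ".", "None"):
        if optional:
            return None
        raise ValueError(f"missing required integer field {name!r}")
    try:
        parsed = int(value)
    except ValueError:
        raise ValueError(f"malformed integer in field {name!r}: {value!r}") from None
    return parsed


# ---------------------------------------------------------------------------
# variants


def read_variants(path: PathLike, assay: Optional[str] = None) -> list[VariantRecord]:
    """Read a variant TSV; optionally restrict to one assay.

    Raises :class:`ParseError` naming the offending row on any malformed or
    invariant-violating record.
    """
    records: list[VariantRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError(path, None, "empty file (no header)")
        missing = set(VARIANT_COLUMNS[:14]) - set(reader.fieldnames)
        if missing:
            raise ParseError(path, None, f"missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # header is row 1
            try:
                rec = VariantRecord(
                    patient_id=row["patient_id"].strip(),
                    sector_id=row["sector_id"].strip(),
                    chrom=row["chrom"].strip(),
                    pos=_int_field(row["pos"], "pos"),
                    ref=row["ref"].strip(),
                    alt=row["alt"].strip(),
                    variant_class=row["variant_class"].strip(),
                    gene=row.get("gene", "").strip(),
                    effect=row.get("effect", "other").strip() or "other",
                    assay=row["assay"].strip(),
                    t_ref=_int_field(row["t_ref"], "t_ref"),
                    t_alt=_int_field(row["t_alt"], "t_alt"),
                    n_ref=_int_field(row["n_ref"], "n_ref"),
                    n_alt=_int_field(row["n_alt"], "n_alt"),
                    alt_fwd=_int_field(row.get("alt_fwd", ""), "alt_fwd", optional=True),
                    alt_rev=_int_field(row.get("alt_rev", ""), "alt_rev", optional=True),
                )
            except (ValueError, ValidationError, KeyError) as exc:
                raise ParseError(path, i, str(exc)) from exc
            if assay is None or rec.assay == assay:
                records.append(rec)
    return records


def write_variants(records: Iterable[VariantRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.sector_id,
                    r.chrom,
                    r.pos,
                    r.ref,
                    r.alt,
                    r.variant_class,
                    r.gene,
                    r.effect,
                    r.assay,
                    r.t_ref,
                    r.t_alt,
                    r.n_ref,
                    r.n_alt,
                    "" if r.alt_fwd is None else r.alt_fwd,
                    "" if r.alt_rev is None else r.alt_rev,
                ]
            )


# ---------------------------------------------------------------------------
# segments + purity


def read_segments(
    seg_path: PathLike, purity_path: Optional[PathLike] = None
) -> dict[str, SectorProfile]:
    """Read ASCAT-style segments (and an optional companion purity table)
    into per-sector profiles, keyed by sector id.

    Sectors absent from the purity table default to purity 1.0.  Overlapping
    segments within a sector, or nMinor > nMajor, raise a validation error.
    """
    purity: dict[str, float] = {}
    if purity_path is not None:
        with open(purity_path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for i, row in enumerate(reader, start=2):
                try:
                    purity[row["sector_id"].strip()] = float(row["purity"])
                except (KeyError, ValueError) as exc:
                    raise ParseError(purity_path, i, str(exc)) from exc

    segments: dict[str, list[Segment]] = {}
    with open(seg_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError(seg_path, None, "empty file (no header)")
        missing = set(SEGMENT_COLUMNS[:6]) - set(reader.fieldnames)
        if missing:
            raise ParseError(seg_path, None, f"missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                seg = Segment(
                    sector_id=row["sector_id"].strip(),
                    chrom=row["chrom"].strip(),
                    start=_int_field(row["start"], "start"),
                    end=_int_field(row["end"], "end"),
                    n_major=_int_field(row["nMajor"], "nMajor"),
                    n_minor=_int_field(row["nMinor"], "nMinor"),
                    n_snps=_int_field(row.get("nSNPs", ""), "nSNPs", optional=True),
                )
            except (ValueError, ValidationError, KeyError) as exc:
                raise ParseError(seg_path, i, str(exc)) from exc
            segments.setdefault(seg.sector_id, []).append(seg)

    profiles: dict[str, SectorProfile] = {}
    for sector_id, segs in segments.items():
        profiles[sector_id] = SectorProfile(
            sector_id=sector_id,
            purity=purity.get(sector_id, 1.0),
            segments=segs,
        )
    return profiles


def write_segments(profiles: Iterable[SectorProfile], seg_path: PathLike,
                   purity_path: Optional[PathLike] = None) -> None:
    profiles = list(profiles)
    with open(seg_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SEGMENT_COLUMNS)
        for p in profiles:
            for s in p.segments:
                writer.writerow(
                    [s.sector_id, s.chrom, s.start, s.end, s.n_major, s.n_minor,
                     "" if s.n_snps is None else s.n_snps]
                )
    if purity_path is not None:
        with open(purity_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["sector_id", "purity"])
            for p in profiles:
                writer.writerow([p.sector_id, repr(p.purity)])


# ---------------------------------------------------------------------------
# features


def read_cytobands(path: PathLike) -> list[Feature]:
    """Read a UCSC ``cytoBand.txt`` file (chrom, 0-based start, end, band,
    stain); feature names are chromosome+band, e.g. ``1p36.33``."""
    feats: list[Feature] = []
    with open(path, newline="") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(path, i, "expected >=4 tab-separated columns")
            chrom, start, end, band = parts[0], parts[1], parts[2], parts[3]
            try:
                feats.append(
                    Feature(
                        name=f"{chrom.removeprefix('chr')}{band}",
                        chrom=chrom,
                        start=int(start) + 1,  # UCSC is 0-based half-open
                        end=int(end),
                        kind="cytoband",
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(path, i, str(exc)) from exc
    return feats


def read_bed(path: PathLike, kind: str = "gene") -> list[Feature]:
    """Read a BED file (0-based half-open) into 1-based inclusive features."""
    feats: list[Feature] = []
    with open(path, newline="") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(path, i, "expected >=4 BED columns (need a name)")
            try:
                feats.append(
                    Feature(
                        name=parts[3],
                        chrom=parts[0],
                        start=int(parts[1]) + 1,
                        end=int(parts[2]),
                        kind=kind,
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(path, i, str(exc)) from exc
    return feats


def read_gene_list(path: PathLike) -> frozenset[str]:
    genes = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.add(g)
    return frozenset(genes)


def read_driver_catalog(luad_path: PathLike,
                        extended_path: Optional[PathLike] = None) -> DriverCatalog:
    luad = read_gene_list(luad_path)
    extended = luad | (read_gene_list(extended_path) if extended_path else frozenset())
    return DriverCatalog(luad_drivers=luad, extended_drivers=extended)


# ---------------------------------------------------------------------------
# trees


def write_newick(tree: TreeNode, path: Optional[PathLike] = None) -> str:
    """Serialize a tree as Newick with branch lengths.

    Raises ``ValueError`` for an empty or single-taxon tree, which has no
    Newick representation with branch lengths.
    """
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError(f"tree must have >=2 taxa, got {len(tips)}")
    newick = str(tree).strip()
    if path is not None:
        Path(path).write_text(newick + "\n")
    return newick


def read_newick(source) -> TreeNode:
    """Parse Newick from a path or a file-like object."""
    if isinstance(source, (str, Path)):
        source = str(source)
    return TreeNode.read(source, format="newick")
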