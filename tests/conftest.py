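"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from clonarch.types import Segment, SectorProfile, VariantRecord


def make_variant(**kwargs) -> VariantRecord:
    """A valid variant record with overridable fields."""
    defaults = dict(
        patient_id="P1",
        sector_id="S1",
        chrom="1",
        pos=1000,
        ref="A",
        alt="T",
        variant_class="SNV",
        assay="exome",
        t_ref=50,
        t_alt=50,
        n_ref=60,
        n_alt=0,
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)


def make_profile(spec, sector_id="S1", purity=0.6, chrom_per_segment=False):
    """Profile from a list of (length, n_major, n_minor[, n_snps]) tuples.

    Segments are laid end-to-end on one chromosome unless
    ``chrom_per_segment`` spreads them over successive autosomes.
    """
    segments = []
    cursor: dict[str, int] = {}
    for i, entry in enumerate(spec):
        length, n_major, n_minor = entry[:3]
        n_snps = entry[3] if len(entry) > 3 else None
        chrom = str((i % 22) + 1) if chrom_per_segment else "1"
        start = cursor.get(chrom, 0) + 1
        cursor[chrom] = start + length - 1
        segments.append(
            Segment(
                sector_id=sector_id,
                chrom=chrom,
                start=start,
                end=start + length - 1,
                n_major=n_major,
                n_minor=n_minor,
                n_snps=n_snps,
            )
        )
    return SectorProfile(sector_id=sector_id, purity=purity, segments=segments)


def random_profile(rng: np.random.Generator, n_segments: int = 24) -> SectorProfile:
    """Random valid profile: non-overlapping autosome segments, n_major >= n_minor."""
    spec = []
    for _ in range(n_segments):
        length = int(rng.integers(1_000_000, 50_000_000))
        minor = int(rng.integers(0, 3))
        major = int(rng.integers(minor, minor + 4))
        if major == 0:
            major = 1  # keep at least one copy somewhere
        spec.append((length, major, minor))
    return make_profile(spec, chrom_per_segment=True)


def random_presence_matrix(
    rng: np.random.Generator, n_mut: int = 30, n_sectors: int = 5
) -> pd.DataFrame:
    """Random boolean matrix with no all-absent row."""
    mat = rng.random((n_mut, n_sectors)) < rng.uniform(0.2, 0.8)
    empty = ~mat.any(axis=1)
    mat[empty, rng.integers(0, n_sectors, size=int(empty.sum()))] = True
    return pd.DataFrame(
        mat,
        index=[f"m{i}" for i in range(n_mut)],
        columns=[f"S{j}" for j in range(n_sectors)],
    )


# ---------------------------------------------------------------------------
# exhaustive enumeration oracles for the subsampling statistics


def exhaustive_trunk_stats(df: pd.DataFrame, k: int) -> tuple[float, float]:
    """(mean, population SD) of the trunk proportion over all C(n,k) subsets."""
    vals = []
    for combo in itertools.combinations(df.columns, k):
        counts = df[list(combo)].sum(axis=1)
        observed = int((counts > 0).sum())
        if observed:
            vals.append(float((counts == k).sum()) / observed)
    return float(np.mean(vals)), float(np.std(vals))


def exhaustive_burden_gain_stats(df: pd.DataFrame, k: int) -> tuple[float, float]:
    """(mean, population SD) of the burden gain over all C(n,k) subsets."""
    vals = []
    for combo in itertools.combinations(df.columns, k):
        sub = df[list(combo)]
        union = float((sub.sum(axis=1) > 0).sum())
        mean_single = float(sub.sum(axis=0).mean())
        if mean_single > 0:
            vals.append(100.0 * (union - mean_single) / mean_single)
    return float(np.mean(vals)), float(np.std(vals))


# ---------------------------------------------------------------------------
# random additive trees (independent of the package's tree code)


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random binary tree with random branch lengths, built by repeatedly
    merging random subtrees.

    Returns (newick string, taxon labels, additive distance matrix); pairwise
    distances are accumulated directly at the merge step where two subtrees
    first meet, independently of any tree library.
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    index = {lab: i for i, lab in enumerate(labels)}
    dist = np.zeros((n_taxa, n_taxa))
    live = [(lab, {lab: 0.0}) for lab in labels]
    while len(live) > 1:
        i, j = sorted(rng.choice(len(live), size=2, replace=False))
        (nwk_j, d_j) = live.pop(j)
        (nwk_i, d_i) = live.pop(i)
        li, lj = rng.uniform(0.5, 2.0, size=2)
        for ta, da in d_i.items():
            for tb, db in d_j.items():
                d = da + li + db + lj
                dist[index[ta], index[tb]] = d
                dist[index[tb], index[ta]] = d
        merged = {t: d + li for t, d in d_i.items()}
        merged.update({t: d + lj for t, d in d_j.items()})
        live.append((f"({nwk_i}:{li:.6f},{nwk_j}:{lj:.6f})", merged))
    return live[0][0] + ";", labels, dist


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
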