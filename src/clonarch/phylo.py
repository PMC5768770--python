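"""Mutation presence matrices, trunk/branch/private classification, pITH,
neighbor-joining trees and sector-subsampling statistics.

The central object is the per-patient :class:`PresenceMatrix`: validated
mutations (rows) by tumor sectors (columns), boolean.  A *trunk* mutation is
present in every sector, a *private* mutation in exactly one, and everything
in between is *branch*.  pITH — proportional intra-tumor heterogeneity — is
the percentage of mutations that are branch or private.  Trees are built by
neighbor joining on Hamming distances between sector presence profiles, with
an all-absent "normal" outgroup so that the trunk appears as the edge from
the normal to the tumor clade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .types import MutationKey, VariantRecord

NORMAL_TAXON = "normal"


@dataclass
class PresenceMatrix:
    """Mutations x sectors boolean detection matrix for one patient."""

    patient_id: str
    matrix: pd.DataFrame  # index: mutation key strings; columns: sector ids

    def __post_init__(self) -> None:
        if self.matrix.shape[1] < 2:
            raise ValueError(
                f"patient {self.patient_id}: need >=2 sectors, "
                f"got {self.matrix.shape[1]}"
            )
        self.matrix = self.matrix.astype(bool)
        if self.matrix.shape[0] and not self.matrix.any(axis=1).all():
            raise ValueError("presence matrix contains an all-absent mutation row")

    @property
    def sectors(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_mutations(self) -> int:
        return self.matrix.shape[0]


@dataclass
class CladeClassification:
    patient_id: str
    labels: pd.Series  # mutation key -> {"trunk","branch","private"}
    n_trunk: int
    n_branch: int
    n_private: int

    @property
    def total(self) -> int:
        return self.n_trunk + self.n_branch + self.n_private


def format_key(key: MutationKey) -> str:
    chrom, pos, ref, alt = key
    return f"{chrom}:{pos}:{ref}:{alt}"


def build_presence_matrix(
    variants: Iterable[VariantRecord],
    sectors: Optional[Sequence[str]] = None,
    present: Optional[Callable[[VariantRecord], bool]] = None,
) -> PresenceMatrix:
    """Build the boolean presence matrix from per-sector variant observations.

    ``present`` decides whether an observation counts as detected in its
    sector (default: every supplied record does — pass only validated
    records, or supply the validation predicate).  A mutation appears as a
    row iff it is present in at least one sector; sectors without a record
    for that mutation are imputed absent.
    """
    variants = list(variants)
    patients = {v.patient_id for v in variants}
    if len(patients) > 1:
        raise ValueError(f"variants span multiple patients: {sorted(patients)}")
    patient_id = patients.pop() if patients else ""
    if sectors is None:
        sectors = sorted({v.sector_id for v in variants})
    sectors = list(sectors)
    if len(sectors) < 2:
        raise ValueError(f"need >=2 sectors, got {len(sectors)}")

    present = present or (lambda v: True)
    cells: dict[str, dict[str, bool]] = {}
    order: list[str] = []
    for v in variants:
        if v.sector_id not in sectors:
            continue
        k = format_key(v.key)
        if k not in cells:
            cells[k] = {}
            order.append(k)
        if present(v):
            cells[k][v.sector_id] = True

    rows = {k: [bool(cells[k].get(s, False)) for s in sectors] for k in order}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=sectors)
    df = df.loc[df.any(axis=1)] if len(df) else df
    return PresenceMatrix(patient_id=patient_id, matrix=df.astype(bool))


def classify_mutations(m: PresenceMatrix) -> CladeClassification:
    """Label each mutation trunk (all sectors), private (one sector) or
    branch (in between)."""
    counts = m.matrix.sum(axis=1)
    n_sectors = m.matrix.shape[1]
    labels = pd.Series(
        np.where(counts == n_sectors, "trunk",
                 np.where(counts == 1, "private", "branch")),
        index=m.matrix.index,
        dtype=object,
    )
    return CladeClassification(
        patient_id=m.patient_id,
        labels=labels,
        n_trunk=int((labels == "trunk").sum()),
        n_branch=int((labels == "branch").sum()),
        n_private=int((labels == "private").sum()),
    )


def compute_pith(c: CladeClassification) -> Optional[float]:
    """Proportional ITH: percentage of mutations that are branch or private.

    Returns None for a mutation-free matrix (undefined, reported missing).
    """
    if c.total == 0:
        return None
    return 100.0 * (c.n_branch + c.n_private) / c.total


def hamming_distances(
    m: PresenceMatrix, include_normal: bool = True
) -> tuple[list[str], np.ndarray]:
    """Pairwise Hamming distances (counts of discordant mutations) between
    sector presence profiles; the normal is an all-absent profile, so its
    distance to a sector equals that sector's mutation burden."""
    mat = m.matrix.to_numpy(dtype=np.int64)
    labels = list(m.matrix.columns)
    profiles = mat.T  # sectors x mutations
    if include_normal:
        labels = labels + [NORMAL_TAXON]
        profiles = np.vstack([profiles, np.zeros((1, mat.shape[0]), dtype=np.int64)])
    diff = (profiles[:, None, :] != profiles[None, :, :]).sum(axis=2)
    return labels, diff.astype(float)


def neighbor_joining(labels: Sequence[str], dist: np.ndarray) -> TreeNode:
    """Neighbor-joining tree from a distance matrix, with negative branch
    lengths clamped to zero.

    With fewer than 3 taxa a degenerate two-leaf tree is returned with a
    warning (the NJ agglomeration needs >=3 taxa).
    """
    labels = list(labels)
    dist = np.asarray(dist, dtype=float)
    if len(labels) < 2:
        raise ValueError("need >=2 taxa for a tree")
    if len(labels) == 2:
        warnings.warn("fewer than 3 taxa: returning a degenerate path tree")
        half = float(dist[0, 1]) / 2.0
        a = TreeNode(name=labels[0], length=half)
        b = TreeNode(name=labels[1], length=half)
        return TreeNode(children=[a, b])
    dm = DistanceMatrix(np.asarray(dist, dtype=float), ids=labels)
    tree = nj(dm)
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def build_tree(m: PresenceMatrix, include_normal: bool = True) -> TreeNode:
    """Convenience: Hamming distances then neighbor joining."""
    labels, dist = hamming_distances(m, include_normal=include_normal)
    return neighbor_joining(labels, dist)


def trunk_length(tree: TreeNode) -> float:
    """Branch length from the normal outgroup to its attachment node, i.e.
    the rendered trunk of the tumor tree."""
    node = tree.find(NORMAL_TAXON)
    return float(node.length or 0.0)


def _trunk_proportion(sub: pd.DataFrame) -> Optional[float]:
    """Trunk fraction among mutations present in >=1 of the given sectors."""
    counts = sub.sum(axis=1)
    observed = counts > 0
    n_obs = int(observed.sum())
    if n_obs == 0:
        return None
    return float((counts == sub.shape[1]).sum()) / n_obs


def subsample_trunk_ratio(
    m: PresenceMatrix,
    k: int,
    n_iter: int = 20,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Mean trunk proportion after repeatedly subsampling ``k`` sectors.

    The trunk fraction in a tree depends on how many sectors were sequenced;
    conditioning on a fixed ``k`` makes it comparable across patients and
    cohorts.  Each iteration draws ``k`` sectors without replacement,
    recomputes trunk = present-in-all-k over mutations present in >=1 of the
    k, and the mean over iterations is returned.  Draws in which no mutation
    is observed are ignored.
    """
    if not 2 <= k <= len(m.sectors):
        raise ValueError(f"k must be in [2, {len(m.sectors)}], got {k}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    sectors = np.array(m.sectors)
    vals = []
    for _ in range(n_iter):
        chosen = rng.choice(sectors, size=k, replace=False)
        p = _trunk_proportion(m.matrix[list(chosen)])
        if p is not None:
            vals.append(p)
    return float(np.mean(vals)) if vals else float("nan")


def burden_gain(
    m: PresenceMatrix,
    k: int = 3,
    n_iter: int = 20,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Mean percentage increase in mutation burden from sequencing ``k``
    sectors instead of one.

    Per iteration ``k`` sectors are drawn without replacement; the gain is
    (union burden - mean single-sector burden of those k) / mean
    single-sector burden x 100.  ``k=1`` is 0 by definition.
    """
    if not 1 <= k <= len(m.sectors):
        raise ValueError(f"k must be in [1, {len(m.sectors)}], got {k}")
    if k == 1:
        return 0.0
    rng = rng if rng is not None else np.random.default_rng(seed)
    sectors = np.array(m.sectors)
    gains = []
    for _ in range(n_iter):
        chosen = list(rng.choice(sectors, size=k, replace=False))
        sub = m.matrix[chosen]
        union = float((sub.sum(axis=1) > 0).sum())
        mean_single = float(sub.sum(axis=0).mean())
        if mean_single > 0:
            gains.append(100.0 * (union - mean_single) / mean_single)
    return float(np.mean(gains)) if gains else float("nan")
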