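"""Clustered gene filtering (CGF).

CGF selects a discriminatory gene subset from the binary mutation matrix
in three moves: (1) rank genes by mutation occurrence frequency (row
sums); (2) walk that ranking greedily, seeding a group at each
still-ungrouped gene and merging every later ungrouped gene whose Jaccard
similarity with the seed exceeds the threshold ``d_cgf``; (3) from each
group with at least ``n_cgf`` members keep the ``n_cgf`` most frequently
mutated genes, and return the union as the gene index set ``g_out``.

All gene indices are 1-based (row order of the input matrix).  Every
tie — in the frequency ranking and in the per-group selection — is broken
by ascending gene index, so the whole procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_mut import BinaryMutationMatrix


class EmptyGeneSubsetError(ValueError):
    """CGF retained no genes; lower ``n_cgf`` or ``d_cgf``."""


@dataclass
class CgfParams:
    """Similarity threshold ``d_cgf`` in [0, 1] and per-group element
    threshold ``n_cgf`` (defaults 0.7 and 5)."""

    d_cgf: float = 0.7
    n_cgf: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_cgf <= 1.0:
            raise ValueError("d_cgf must lie in [0, 1]")
        if self.n_cgf < 1:
            raise ValueError("n_cgf must be >= 1")


@dataclass
class FrequencyRanking:
    """Gene indices sorted by descending mutation occurrence frequency.

    ``order`` is a 1-based permutation of 1..m; ``row_sums`` holds the
    per-gene mutation counts in original row order.  Ties in the sort
    appear in ascending original index.
    """

    order: np.ndarray
    row_sums: np.ndarray

    def rank_position(self) -> np.ndarray:
        """0-based position of each gene (original order) in the ranking."""
        pos = np.empty(len(self.order), dtype=np.int64)
        pos[self.order - 1] = np.arange(len(self.order))
        return pos


@dataclass
class GeneGrouping:
    """Partition of the genes: ``group_id[g-1]`` is the group (1..G) of
    gene ``g``; ids are contiguous in seed (ranking) order."""

    group_id: np.ndarray


@dataclass
class DiscriminatorySubset:
    """The selected gene index set ``g_out`` (1-based, strictly ascending)."""

    gene_indices: np.ndarray

    def __post_init__(self) -> None:
        self.gene_indices = np.asarray(self.gene_indices, dtype=np.int64)
        if len(np.unique(self.gene_indices)) != len(self.gene_indices):
            raise ValueError("duplicate gene indices in subset")


def rank_genes(matrix: BinaryMutationMatrix) -> FrequencyRanking:
    """Sort genes by descending row sum, ties by ascending gene index."""
    row_sums = matrix.values.sum(axis=1).astype(np.int64)
    # lexsort: last key is primary; negate for descending, index breaks ties
    order = np.lexsort((np.arange(matrix.m), -row_sums)) + 1
    return FrequencyRanking(order=order, row_sums=row_sums)


def jaccard(p: np.ndarray, q: np.ndarray) -> float:
    """Jaccard coefficient |p ∧ q| / |p ∨ q| of two binary vectors.

    Two all-zero vectors get similarity 0 by convention: genes with no
    mutations carry no signal and must never merge with each other.
    """
    p = np.asarray(p, dtype=bool)
    q = np.asarray(q, dtype=bool)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    union = np.logical_or(p, q).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(p, q).sum() / union)


def group_genes(
    matrix: BinaryMutationMatrix, ranking: FrequencyRanking, d_cgf: float
) -> GeneGrouping:
    """Greedy single-pass grouping along the frequency ranking.

    Each still-ungrouped gene seeds a new group; every later
    still-ungrouped gene whose Jaccard similarity with the seed is
    strictly greater than ``d_cgf`` joins that group immediately (and is
    therefore never compared again).  The result is a partition.
    """
    rows = matrix.values.astype(bool)
    m = matrix.m
    group_id = np.zeros(m, dtype=np.int64)
    n_groups = 0
    order0 = ranking.order - 1
    for pos, i in enumerate(order0):
        if group_id[i]:
            continue
        n_groups += 1
        group_id[i] = n_groups
        rest = order0[pos + 1:]
        rest = rest[group_id[rest] == 0]
        if rest.size == 0:
            continue
        seed = rows[i]
        inter = np.logical_and(rows[rest], seed).sum(axis=1)
        union = np.logical_or(rows[rest], seed).sum(axis=1)
        with np.errstate(invalid="ignore"):
            sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        group_id[rest[sim > d_cgf]] = n_groups
    return GeneGrouping(group_id=group_id)


def select_subset(
    matrix: BinaryMutationMatrix,
    grouping: GeneGrouping,
    ranking: FrequencyRanking,
    n_cgf: int,
) -> DiscriminatorySubset:
    """Keep the ``n_cgf`` most frequent genes of each group with at least
    ``n_cgf`` members; groups below the threshold are discarded.

    Genes with zero mutation occurrence carry no signal: they never merge
    (all-zero Jaccard convention) and are excluded from selection here,
    so they cannot slip in as singleton groups when ``n_cgf`` is 1.
    """
    row_sums = ranking.row_sums
    selected: list[int] = []
    for g in range(1, int(grouping.group_id.max(initial=0)) + 1):
        members = np.flatnonzero(grouping.group_id == g)  # ascending index
        members = members[row_sums[members] > 0]
        if members.size < n_cgf:
            continue
        top = members[np.lexsort((members, -row_sums[members]))[:n_cgf]]
        selected.extend((top + 1).tolist())
    return DiscriminatorySubset(gene_indices=np.sort(np.array(selected, dtype=np.int64)))


def apply_cgf(
    matrix: BinaryMutationMatrix, subset: DiscriminatorySubset
) -> BinaryMutationMatrix:
    """Row-slice the matrix to the selected genes (sample order preserved)."""
    idx = subset.gene_indices
    if idx.size == 0:
        raise EmptyGeneSubsetError(
            "no gene group met the selection thresholds; lower n_cgf or d_cgf"
        )
    if idx.min() < 1 or idx.max() > matrix.m:
        raise ValueError(f"gene index out of range 1..{matrix.m}")
    rows = idx - 1
    return BinaryMutationMatrix(
        values=matrix.values[rows],
        gene_ids=[matrix.gene_ids[r] for r in rows],
        sample_ids=matrix.sample_ids,
    )


def fit_cgf(matrix: BinaryMutationMatrix, params: CgfParams) -> DiscriminatorySubset:
    """Rank → group → select in one call."""
    ranking = rank_genes(matrix)
    grouping = group_genes(matrix, ranking, params.d_cgf)
    return select_subset(matrix, grouping, ranking, params.n_cgf)


def write_subset_tsv(subset: DiscriminatorySubset, gene_ids: list[str], path) -> None:
    """Persist a fitted subset as (gene_index, gene_id) rows."""
    with open(path, "w") as fh:
        fh.write("gene_index\tgene_id\n")
        for g in subset.gene_indices:
            fh.write(f"{g}\t{gene_ids[g - 1]}\n")
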