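"""Indexed sparsity reduction (ISR).

A binary gene vector over tens of thousands of genes is almost entirely
zeros.  ISR replaces it with the fixed-length list of its non-zero gene
indices: if the sample has more than ``n_isr`` mutated genes, the
``n_isr`` genes ranking highest in the cohort-wide frequency ranking are
kept; otherwise all mutated genes are listed and the tail is padded with
zeros.  Indices are always emitted in ascending order, are 1-based, and 0
is reserved for the padding symbol, so the encoding is unambiguous and —
whenever the number of non-zeros does not exceed ``n_isr`` — exactly
invertible.

For use as network input the indices can be scaled into [0, 1] by
dividing by the gene count ``m``; raw indices of magnitude ~1e4 make the
first layer's activations blow up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cgf import FrequencyRanking


@dataclass
class IsrParams:
    """Output length ``n_isr`` (default 800) and whether indices are
    scaled by 1/m before entering the classifier (default True)."""

    n_isr: int = 800
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.n_isr < 1:
            raise ValueError("n_isr must be >= 1")


@dataclass
class IsrVector:
    """Length-``n_isr`` vector of 1-based gene indices, zero-padded.

    Non-zero entries are strictly increasing and padding zeros form a
    suffix; ``n_nz`` records the non-zero count of the source sample.
    """

    indices: np.ndarray
    n_nz: int


def isr_transform(
    p: np.ndarray, params: IsrParams, ranking: FrequencyRanking
) -> IsrVector:
    """Encode one binary gene vector as its non-zero index list."""
    p = np.asarray(p)
    m = len(ranking.row_sums)
    if p.shape != (m,):
        raise ValueError(f"sample has length {p.shape}, expected ({m},)")
    nz = np.flatnonzero(p) + 1  # 1-based, already ascending
    n_nz = int(nz.size)
    if n_nz >= params.n_isr:
        # keep the n_isr non-zero genes of highest cohort frequency
        pos = ranking.rank_position()[nz - 1]
        keep = nz[np.argsort(pos, kind="stable")[: params.n_isr]]
        indices = np.sort(keep)
    else:
        indices = np.concatenate(
            [nz, np.zeros(params.n_isr - n_nz, dtype=np.int64)]
        )
    return IsrVector(indices=indices.astype(np.int64), n_nz=n_nz)


def isr_inverse(v: IsrVector, m: int) -> np.ndarray:
    """Decode an index vector back to a length-``m`` binary vector.

    Lossless whenever the source sample had ``n_nz <= n_isr``; otherwise
    the recovery is the kept subset of the original support.
    """
    idx = np.asarray(v.indices, dtype=np.int64)
    nz = idx[idx > 0]
    if nz.size and nz.max() > m:
        raise ValueError(f"index {nz.max()} exceeds gene count {m}")
    out = np.zeros(m, dtype=np.uint8)
    out[nz - 1] = 1
    return out


def scale_indices(v: IsrVector, m: int) -> np.ndarray:
    """Map indices elementwise into [0, 1] by dividing by ``m``.

    Padding zeros map to 0.0 and the order is preserved.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.asarray(v.indices, dtype=np.float64) / m


def isr_transform_matrix(
    values: np.ndarray, params: IsrParams, ranking: FrequencyRanking
) -> np.ndarray:
    """Encode every column (sample) of a gene × sample binary matrix.

    Returns an (n_samples, n_isr) float array, scaled per ``params``.
    """
    m, n = values.shape
    out = np.zeros((n, params.n_isr), dtype=np.float64)
    for j in range(n):
        v = isr_transform(values[:, j], params, ranking)
        out[j] = scale_indices(v, m) if params.normalize else v.indices
    return out


def write_isr_tsv(vectors: list[IsrVector], sample_ids: list[str], path) -> None:
    """One row per sample: sample_id, n_nz, then the index vector."""
    with open(path, "w") as fh:
        for sid, v in zip(sample_ids, vectors):
            fh.write(sid + "\t" + str(v.n_nz) + "\t"
                     + "\t".join(map(str, v.indices)) + "\n")
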