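"""Contact-matrix computation.

Distance-expected profile, observed/expected normalization, the bin-level
Pearson correlation matrix, overlap-proportional gene-to-bin weights, and
weighted gene-pair interaction values.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
from scipy.stats import rankdata

from .core_io import ContactMatrix, CorrelationMatrix, Gene
from .errors import InsufficientDataError, UsageError, ValidationError

__all__ = [
    "expected_by_distance",
    "observed_over_expected",
    "correlation_matrix",
    "gene_bin_weights",
    "gene_weight_matrix",
    "gene_pair_interaction",
    "pairwise_gene_interactions",
    "percentile_ranks",
]


def expected_by_distance(m: ContactMatrix) -> np.ndarray:
    """Mean contact count at each genomic-distance offset d = 0..n_bins-1."""
    c = m.counts
    n = m.n_bins
    return np.array([np.diagonal(c, d).mean() for d in range(n)])


def observed_over_expected(m: ContactMatrix) -> np.ndarray:
    """O/E matrix: counts divided by the distance-expected value.

    Offsets with zero expected contact become NaN (missing), never zero —
    a zero-expected cell carries no depletion information.
    """
    e = expected_by_distance(m)
    n = m.n_bins
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    ed = e[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(ed > 0, m.counts / ed, np.nan)
    return oe


def _pairwise_pearson_masked(oe: np.ndarray, min_shared: int) -> np.ndarray:
    n = oe.shape[0]
    out = np.full((n, n), np.nan)
    defined = np.isfinite(oe)
    for i in range(n):
        for j in range(i + 1, n):
            mask = defined[i] & defined[j]
            if int(mask.sum()) < min_shared:
                continue
            xi = oe[i, mask]
            xj = oe[j, mask]
            xi = xi - xi.mean()
            xj = xj - xj.mean()
            denom = np.sqrt((xi * xi).sum() * (xj * xj).sum())
            if denom == 0:
                continue
            r = float((xi * xj).sum() / denom)
            out[i, j] = out[j, i] = min(1.0, max(-1.0, r))
    return out


def correlation_matrix(
    oe: np.ndarray,
    chrom: str = "",
    cell_type: str = "",
    resolution: int = 0,
    min_shared: int = 3,
) -> CorrelationMatrix:
    """Row-by-row Pearson correlation of an O/E matrix.

    Entry (i, j) correlates rows i and j over the columns defined in both;
    fewer than ``min_shared`` shared columns or zero variance gives NaN.
    The diagonal is forced to 1.
    """
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    if np.all(np.isfinite(oe)):
        # fast path: standardize rows, single matrix product
        mu = oe.mean(axis=1, keepdims=True)
        xc = oe - mu
        sd = np.sqrt((xc * xc).sum(axis=1))
        ok = sd > 0
        vals = np.full((n, n), np.nan)
        if ok.any() and oe.shape[1] >= min_shared:
            xs = np.zeros_like(xc)
            xs[ok] = xc[ok] / sd[ok, None]
            r = xs @ xs.T
            vals[np.ix_(ok, ok)] = np.clip(r[np.ix_(ok, ok)], -1.0, 1.0)
            vals[~ok, :] = np.nan
            vals[:, ~ok] = np.nan
    else:
        vals = _pairwise_pearson_masked(oe, min_shared)
    np.fill_diagonal(vals, 1.0)
    return CorrelationMatrix(chrom, cell_type, resolution, vals, n)


def gene_bin_weights(g: Gene, resolution: int, n_bins: int) -> Dict[int, float]:
    """Overlap fraction of the gene body falling into each fixed-width bin.

    Weights sum to 1; bins with zero overlap are absent from the result.
    """
    if g.start < 0 or g.end > n_bins * resolution:
        raise ValidationError(
            f"gene {g.id} [{g.start}, {g.end}) outside matrix span "
            f"[0, {n_bins * resolution})"
        )
    first = g.start // resolution
    last = (g.end - 1) // resolution
    weights: Dict[int, float] = {}
    for k in range(first, last + 1):
        overlap = min(g.end, (k + 1) * resolution) - max(g.start, k * resolution)
        if overlap > 0:
            weights[k] = overlap / g.length
    return weights


def gene_weight_matrix(
    genes: Sequence[Gene], resolution: int, n_bins: int
) -> np.ndarray:
    """Stacked gene-to-bin weight rows (len(genes) x n_bins), rows sum to 1."""
    w = np.zeros((len(genes), n_bins))
    for row, g in enumerate(genes):
        for k, wk in gene_bin_weights(g, resolution, n_bins).items():
            w[row, k] = wk
    return w


def gene_pair_interaction(
    ga: Gene, gb: Gene, mat: np.ndarray, resolution: int
) -> float:
    """Weighted average of matrix cells over both genes' bin weights.

    NaN cells are excluded and the remaining weights renormalized; if every
    contributing cell is NaN the result is NaN.
    """
    if ga.chrom != gb.chrom:
        raise UsageError(
            f"genes {ga.id} ({ga.chrom}) and {gb.id} ({gb.chrom}) are on "
            "different chromosomes; interaction is intra-chromosomal only"
        )
    mat = np.asarray(mat, dtype=float)
    n_bins = mat.shape[0]
    wa = gene_bin_weights(ga, resolution, n_bins)
    wb = gene_bin_weights(gb, resolution, n_bins)
    num = 0.0
    den = 0.0
    for k, wk in wa.items():
        for l, wl in wb.items():
            v = mat[k, l]
            if np.isfinite(v):
                num += wk * wl * v
                den += wk * wl
    return num / den if den > 0 else float("nan")


def pairwise_gene_interactions(
    weights: np.ndarray, mat: np.ndarray
) -> np.ndarray:
    """All-pairs weighted interactions W @ M @ W.T with NaN renormalization.

    ``weights`` is a gene-by-bin matrix whose rows sum to 1. Equivalent to
    calling :func:`gene_pair_interaction` for every gene pair, vectorized.
    """
    mat = np.asarray(mat, dtype=float)
    defined = np.isfinite(mat)
    filled = np.where(defined, mat, 0.0)
    num = weights @ filled @ weights.T
    den = weights @ defined.astype(float) @ weights.T
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 1e-15, num / den, np.nan)


def percentile_ranks(values) -> np.ndarray:
    """Average-ranks divided by n, in (0, 1]; NaN inputs keep NaN ranks."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        raise InsufficientDataError("percentile_ranks: no finite values")
    out = np.full(v.shape, np.nan)
    out[finite] = rankdata(v[finite], method="average") / finite.sum()
    return out
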