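"""Distance-decay curves, interaction-decay-exponent (IDE) fits, and
per-distance z-score / subtractive matrices for two-condition comparison.

The decay curve averages balanced cis contact values over all unmasked bin
pairs at each genomic separation (diagonal excluded). The IDE is the slope of
an ordinary least-squares fit of log10(frequency) on log10(distance) inside a
fit range. The z-score transform standardises each cis diagonal stratum per
chromosome (Crane-style normalisation); the difference of two z matrices is
the subtractive interaction matrix used to compare conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import AlignmentError
from .contact import ContactMatrix

__all__ = ["DecayCurve", "IdeFit", "decay_curve", "fit_ide", "zscore_matrix", "subtract"]


@dataclass
class DecayCurve:
    """Mean contact frequency as a function of genomic separation (bp)."""

    distances: np.ndarray  # strictly increasing, bp
    mean_frequency: np.ndarray
    chromosome: str | None = None  # None = genome-wide (cis pooled)

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.mean_frequency = np.asarray(self.mean_frequency, dtype=float)
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be strictly increasing")
        if np.any(self.mean_frequency < 0):
            raise ValueError("frequencies must be non-negative")

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("distance_bp\tmean_frequency\n")
            for d, f in zip(self.distances, self.mean_frequency):
                fh.write(f"{int(d)}\t{float(f)!r}\n")


@dataclass
class IdeFit:
    exponent: float
    intercept: float
    stderr: float
    fit_range: tuple[float, float]
    n_points: int


def _cis_stratum_sums(matrix: ContactMatrix, chrom: str):
    """Per-separation (sum, count) over unmasked pairs of one chromosome."""
    sl = matrix.bins.chrom_slice(chrom)
    block = matrix.values[sl, sl]
    m = matrix.mask[sl]
    n = block.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n)
    for sep in range(1, n):
        diag = np.diagonal(block, offset=sep)
        valid = m[:-sep] & m[sep:]
        sums[sep] = diag[valid].sum()
        counts[sep] = valid.sum()
    return sums, counts


def decay_curve(matrix: ContactMatrix, chromosome: str | None = None) -> DecayCurve:
    """Average cis contact frequency per separation; diagonal excluded.

    Pools all chromosomes when ``chromosome`` is None. Separations with no
    valid pair are omitted.
    """
    chroms = [chromosome] if chromosome else matrix.bins.chrom_sizes.names
    max_n = max(matrix.bins.n_chrom_bins(c) for c in chroms)
    if max_n < 2:
        raise ValueError("degenerate input: no cis data off the diagonal")
    sums = np.zeros(max_n)
    counts = np.zeros(max_n)
    for c in chroms:
        s, k = _cis_stratum_sums(matrix, c)
        sums[: s.size] += s
        counts[: k.size] += k
    seps = np.flatnonzero(counts[1:]) + 1
    if seps.size == 0:
        raise ValueError("degenerate input: no cis data off the diagonal")
    freqs = sums[seps] / counts[seps]
    return DecayCurve(seps * matrix.bins.bin_size, freqs, chromosome)


def fit_ide(curve: DecayCurve, fit_range: tuple[float, float] | None = None, bin_size: int | None = None) -> IdeFit:
    """Least-squares fit of log10 frequency vs log10 distance.

    The default fit range is [2 * bin granularity, 10 Mb]; the bin granularity
    is inferred from the smallest distance on the curve when ``bin_size`` is
    not given. Points with zero frequency are excluded.
    """
    if fit_range is None:
        step = bin_size if bin_size is not None else float(np.min(curve.distances))
        fit_range = (2 * step, 10_000_000.0)
    lo, hi = fit_range
    sel = (curve.distances >= lo) & (curve.distances <= hi) & (curve.mean_frequency > 0)
    if sel.sum() < 3:
        raise ValueError(f"fit error: only {int(sel.sum())} usable points in range {fit_range}")
    x = np.log10(curve.distances[sel])
    y = np.log10(curve.mean_frequency[sel])
    res = stats.linregress(x, y)
    return IdeFit(float(res.slope), float(res.intercept), float(res.stderr), (float(lo), float(hi)), int(sel.sum()))


def zscore_matrix(matrix: ContactMatrix) -> ContactMatrix:
    """Standardise each cis diagonal stratum per chromosome; trans as one stratum.

    Within each chromosome, entries at separation ``d`` are z-scored against
    the mean and (population) SD of the unmasked entries at that separation.
    A zero-SD stratum maps to z = 0. Trans entries are z-scored jointly.
    """
    n = matrix.n_bins
    z = np.zeros((n, n))
    mask2d = np.outer(matrix.mask, matrix.mask)
    for chrom in matrix.bins.chrom_sizes:
        sl = matrix.bins.chrom_slice(chrom)
        block = matrix.values[sl, sl]
        bm = matrix.mask[sl]
        nb = block.shape[0]
        zb = np.zeros_like(block)
        for sep in range(0, nb):
            diag = np.diagonal(block, offset=sep)
            valid = bm[: nb - sep] & bm[sep:]
            if valid.sum() == 0:
                continue
            mu = diag[valid].mean()
            sd = diag[valid].std()
            zs = np.zeros_like(diag)
            # a numerically constant stratum counts as sd = 0 (z = 0)
            if sd > 1e-10 * max(abs(mu), 1e-300):
                zs[valid] = (diag[valid] - mu) / sd
            idx = np.arange(nb - sep)
            zb[idx, idx + sep] = zs
            zb[idx + sep, idx] = zs
        z[sl, sl] = zb
    cis2d = matrix.cis_mask_2d()
    trans_sel = (~cis2d) & mask2d
    if trans_sel.any():
        vals = matrix.values[trans_sel]
        mu, sd = vals.mean(), vals.std()
        if sd > 1e-10 * max(abs(mu), 1e-300):
            z[trans_sel] = (matrix.values[trans_sel] - mu) / sd
    return ContactMatrix(matrix.bins, z, matrix.mask, balanced=False)


def subtract(z1: ContactMatrix, z2: ContactMatrix) -> ContactMatrix:
    """Elementwise z1 - z2 (the subtractive interaction matrix).

    Antisymmetric under swapping the samples. Requires identical bin grids
    and masks.
    """
    if z1.bins != z2.bins:
        raise AlignmentError("bin grids differ")
    if not np.array_equal(z1.mask, z2.mask):
        raise AlignmentError("masks differ")
    return ContactMatrix(z1.bins, z1.values - z2.values, z1.mask, balanced=False)
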