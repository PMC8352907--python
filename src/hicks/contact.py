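"""Binned Hi-C contact matrices: construction, masking, iterative balancing.

The matrix is held dense (the package targets desk-scale genomes); values are
symmetric with masked rows/columns zeroed. Balancing follows the iterative
correction (ICE) contract: a multiplicative per-bin bias vector ``b`` such
that ``balanced[i, j] = raw[i, j] / (b[i] * b[j])`` and all unmasked row sums
are equal. The bias is normalised to geometric mean 1 over unmasked bins so
the balanced matrix keeps the raw matrix's overall scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .core import AlignmentError, BinTrack, ChromSizes, FormatError, GenomeBins

__all__ = [
    "ValidPairRecord",
    "ContactMatrix",
    "read_pairs",
    "write_pairs",
    "bin_pairs",
    "mask_low_coverage",
    "ice_balance",
    "map_resolution",
    "read_coo",
    "write_coo",
]


@dataclass(frozen=True)
class ValidPairRecord:
    """One valid Hi-C contact: two genomic positions (0-based bp, unordered)."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int


def read_pairs(path) -> Iterator[ValidPairRecord]:
    """Stream a 4DN-style ``.pairs`` text file.

    Columns: readID chrom1 pos1 chrom2 pos2 [strand1 strand2]; header lines
    start with ``#``. Positions are 1-based on disk and converted to the
    package's 0-based convention here.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"line {lineno}: expected >= 5 tab-separated columns")
            _, c1, p1, c2, p2 = fields[:5]
            yield ValidPairRecord(c1, int(p1) - 1, c2, int(p2) - 1)


def write_pairs(records: Iterable[ValidPairRecord], path, chrom_sizes: ChromSizes | None = None) -> None:
    """Write records as 4DN ``.pairs`` text (positions re-expressed 1-based)."""
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n")
        if chrom_sizes is not None:
            for name, length in chrom_sizes.items():
                fh.write(f"#chromsize: {name} {length}\n")
        for i, r in enumerate(records):
            fh.write(f"r{i}\t{r.chrom1}\t{r.pos1 + 1}\t{r.chrom2}\t{r.pos2 + 1}\t+\t-\n")


class ContactMatrix:
    """Symmetric non-negative contact counts over global genome bins."""

    def __init__(self, bins: GenomeBins, values, mask=None, balanced=False, bias=None, converged=True):
        values = np.asarray(values, dtype=float)
        if values.shape != (bins.n_bins, bins.n_bins):
            raise AlignmentError("matrix shape does not match bin grid")
        if mask is None:
            mask = np.ones(bins.n_bins, dtype=bool)
        mask = np.asarray(mask, dtype=bool).copy()
        values = values.copy()
        values[~mask, :] = 0.0
        values[:, ~mask] = 0.0
        self.bins = bins
        self.values = values
        self.mask = mask
        self.balanced = bool(balanced)
        self.bias = None if bias is None else np.asarray(bias, dtype=float).copy()
        self.converged = bool(converged)

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    def mass(self) -> float:
        """Total contacts counted once per unordered pair (upper triangle + diagonal)."""
        return float(np.triu(self.values).sum())

    def marginals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def cis_mask_2d(self) -> np.ndarray:
        """Boolean matrix selecting intra-chromosomal (cis) entries."""
        c = self.bins.chrom_of(np.arange(self.n_bins))
        return c[:, None] == c[None, :]

    def chrom_block(self, chrom: str) -> np.ndarray:
        sl = self.bins.chrom_slice(chrom)
        return self.values[sl, sl]

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.bins, self.values, self.mask, self.balanced, self.bias, self.converged
        )


def bin_pairs(pairs: Iterable[ValidPairRecord], bins: GenomeBins) -> ContactMatrix:
    """Aggregate valid pairs into a symmetric binned contact matrix.

    Total matrix mass equals the number of input records; a pair with both
    ends in the same bin contributes 1 to the diagonal.
    """
    n = bins.n_bins
    values = np.zeros((n, n))
    i_idx, j_idx = [], []
    for k, rec in enumerate(pairs):
        try:
            i = bins.locate(rec.chrom1, rec.pos1)
            j = bins.locate(rec.chrom2, rec.pos2)
        except (KeyError, ValueError) as exc:
            raise FormatError(f"record {k}: {exc}") from None
        i_idx.append(i)
        j_idx.append(j)
    if i_idx:
        i_arr = np.asarray(i_idx)
        j_arr = np.asarray(j_idx)
        lo, hi = np.minimum(i_arr, j_arr), np.maximum(i_arr, j_arr)
        np.add.at(values, (lo, hi), 1.0)
        tri = np.triu(values, 1)
        values = values + tri.T
    return ContactMatrix(bins, values)


def bin_counts_upper(pairs: Iterable[ValidPairRecord], bins: GenomeBins):
    """Marginal helper used by map_resolution; counts each record once per end."""
    marg = np.zeros(bins.n_bins)
    for k, rec in enumerate(pairs):
        try:
            i = bins.locate(rec.chrom1, rec.pos1)
            j = bins.locate(rec.chrom2, rec.pos2)
        except (KeyError, ValueError) as exc:
            raise FormatError(f"record {k}: {exc}") from None
        marg[i] += 1
        marg[j] += 1
    return marg


def mask_low_coverage(matrix: ContactMatrix, fraction: float = 0.02) -> ContactMatrix:
    """Mask zero-coverage bins plus the lowest ``fraction`` of nonzero marginals.

    The quantile is taken over bins with nonzero marginal only, so
    ``fraction=0`` masks exactly the dead bins.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    marg = matrix.marginals()
    mask = matrix.mask.copy()
    mask &= marg > 0
    nonzero = marg[mask]
    if fraction > 0 and nonzero.size:
        cutoff = np.quantile(nonzero, fraction)
        mask &= marg > cutoff
    return ContactMatrix(matrix.bins, matrix.values, mask, matrix.balanced, matrix.bias)


def ice_balance(matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-8) -> ContactMatrix:
    """Iteratively correct multiplicative per-bin biases (ICE).

    Repeatedly divides by the normalised marginal until the variance of the
    unmasked marginals over their squared mean drops below ``tol``. Returns a
    balanced matrix whose ``bias`` satisfies
    ``balanced = raw / outer(bias, bias)`` exactly, with ``bias`` normalised
    to geometric mean 1 over unmasked bins. Sets ``converged=False`` (with a
    warning) if ``max_iter`` is exhausted first.
    """
    unmasked = matrix.mask
    if unmasked.sum() < 2:
        raise ValueError("degenerate input: fewer than 2 unmasked bins")
    raw = matrix.values
    work = raw.copy()
    bias = np.ones(matrix.n_bins)
    converged = False
    for _ in range(max_iter):
        marg = work.sum(axis=1)
        m = marg[unmasked].mean()
        if m == 0:
            raise ValueError("degenerate input: all unmasked marginals are zero")
        var = float(np.mean((marg[unmasked] - m) ** 2)) / m**2
        if var < tol:
            converged = True
            break
        s = marg / m
        s[~unmasked] = 1.0
        s[s == 0] = 1.0
        bias *= s
        work /= np.outer(s, s)
    else:
        # loop body may still have reached tol on the last update
        marg = work.sum(axis=1)
        m = marg[unmasked].mean()
        var = float(np.mean((marg[unmasked] - m) ** 2)) / m**2
        converged = var < tol
    if not converged:
        warnings.warn(f"iterative correction did not converge in {max_iter} iterations")
    gm = np.exp(np.mean(np.log(bias[unmasked])))
    bias = bias / gm
    denom = np.outer(bias, bias)
    balanced = np.zeros_like(raw)
    np.divide(raw, denom, out=balanced, where=denom > 0)
    bias_out = bias.copy()
    bias_out[~unmasked] = np.nan
    return ContactMatrix(matrix.bins, balanced, unmasked, balanced=True, bias=bias_out, converged=converged)


def map_resolution(
    pairs: Sequence[ValidPairRecord],
    chrom_sizes: ChromSizes,
    candidate_bin_sizes: Sequence[int],
    min_contacts: int = 1000,
    fraction: float = 0.80,
    include_empty_bins: bool = True,
) -> int | None:
    """Smallest bin size at which >= ``fraction`` of bins reach ``min_contacts``.

    Implements the map-resolution rule "the smallest locus size such that 80%
    of the loci had at least 1000 contacts". Fully empty bins count in the
    denominator by default (configurable). Returns None if no candidate
    qualifies.
    """
    if not candidate_bin_sizes:
        raise ValueError("empty candidate list")
    sizes = sorted(int(s) for s in candidate_bin_sizes)
    pairs = list(pairs)
    for size in sizes:
        bins = GenomeBins(chrom_sizes, size)
        marg = bin_counts_upper(pairs, bins)
        denom_mask = np.ones_like(marg, dtype=bool) if include_empty_bins else marg > 0
        denom = int(denom_mask.sum())
        if denom == 0:
            continue
        frac_ok = float((marg[denom_mask] >= min_contacts).sum()) / denom
        if frac_ok >= fraction:
            return size
    return None


def write_coo(matrix: ContactMatrix, path, bed_path=None) -> None:
    """Write the upper triangle (incl. diagonal) as ``bin1 bin2 value`` text.

    An optional sidecar BED describes the bin grid (4th column: global index,
    5th: 0/1 mask flag).
    """
    iu = np.triu_indices(matrix.n_bins)
    with open(path, "w") as fh:
        for i, j in zip(*iu):
            v = matrix.values[i, j]
            if v != 0:
                fh.write(f"{i}\t{j}\t{float(v)!r}\n")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for g in range(matrix.n_bins):
                chrom, start, end = matrix.bins.bin_interval(g)
                fh.write(f"{chrom}\t{start}\t{end}\t{g}\t{int(matrix.mask[g])}\n")


def read_coo(path, bins: GenomeBins, mask=None) -> ContactMatrix:
    """Read a ``bin1 bin2 value`` triple file into a symmetric ContactMatrix."""
    values = np.zeros((bins.n_bins, bins.n_bins))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i_s, j_s, v_s = line.split()[:3]
            i, j = int(i_s), int(j_s)
            if not (0 <= i < bins.n_bins and 0 <= j < bins.n_bins):
                raise FormatError(f"line {lineno}: bin index out of range")
            values[i, j] += float(v_s)
            if i != j:
                values[j, i] += float(v_s)
    return ContactMatrix(bins, values, mask)
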