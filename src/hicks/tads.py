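"""Insulation-score TAD analysis: track computation, boundary/domain calling,
two-condition differential insulation, and boundary overlap bookkeeping.

The insulation score of bin *i* is the log2 ratio of the mean contact value
in the square window upstream x downstream of *i* to the chromosome-wide mean
of that same statistic, so a uniform matrix scores 0 everywhere and global
rescaling leaves the track unchanged. TAD boundaries are strong local minima
of the track; domains are the intervals between consecutive boundaries.
Differential insulation slides a short window along two tracks and flags the
maximal runs of bins whose every covering window has Pearson r below a
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import AlignmentError, BinTrack, GenomeBins
from .contact import ContactMatrix

__all__ = [
    "InsulationTrack",
    "TadSet",
    "DiffInsulationRegion",
    "insulation_track",
    "call_boundaries",
    "differential_insulation",
    "boundary_overlap",
]


class InsulationTrack(BinTrack):
    """BinTrack of insulation scores; bins within the square of a chromosome
    edge are masked."""

    def __init__(self, bins, values, mask=None, square_size: int = 10):
        super().__init__(bins, values, mask)
        self.square_size = int(square_size)


@dataclass
class TadSet:
    """Boundaries (with strength) and the domains between them."""

    bins: GenomeBins
    boundaries: list  # (global_bin, strength), strictly increasing bins
    domains: list  # (start_bin, end_bin) half-open, non-overlapping

    def boundary_bins(self) -> list[int]:
        return [b for b, _ in self.boundaries]


@dataclass
class DiffInsulationRegion:
    chrom: str
    start_bin: int  # global, half-open
    end_bin: int
    min_r: float


def insulation_track(matrix: ContactMatrix, square_size: int = 10) -> InsulationTrack:
    """Insulation score per bin at the matrix's bin size.

    score[i] = log2( mean of the square (i-s..i-1) x (i+1..i+s)
                     / chromosome mean of that statistic ).
    Chromosomes shorter than 2*square_size+1 bins come back fully masked with
    a warning. Masked matrix bins propagate: a window mean uses only pairs of
    unmasked bins; a bin whose window has no valid pair is masked.
    """
    s = int(square_size)
    if s < 1:
        raise ValueError("square_size must be >= 1")
    n = matrix.n_bins
    values = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    for chrom in matrix.bins.chrom_sizes:
        sl = matrix.bins.chrom_slice(chrom)
        block = matrix.values[sl, sl]
        bm = matrix.mask[sl]
        nb = block.shape[0]
        if nb < 2 * s + 1:
            warnings.warn(f"{chrom}: shorter than {2 * s + 1} bins, insulation fully masked")
            continue
        raw = np.full(nb, np.nan)
        for i in range(s, nb - s):
            rows = bm[i - s : i]
            cols = bm[i + 1 : i + 1 + s]
            if not rows.any() or not cols.any():
                continue
            window = block[i - s : i, i + 1 : i + 1 + s]
            sel = np.outer(rows, cols)
            raw[i] = window[sel].mean()
        valid = np.isfinite(raw) & bm
        if valid.sum() == 0:
            continue
        chrom_mean = raw[valid].mean()
        if chrom_mean <= 0:
            warnings.warn(f"{chrom}: zero mean insulation statistic, track masked")
            continue
        with np.errstate(divide="ignore"):
            score = np.where(valid, np.log2(np.where(valid, raw, 1.0) / chrom_mean), np.nan)
        score[valid & (raw == 0)] = -np.inf
        finite = valid & np.isfinite(score)
        values[sl] = np.where(finite, score, np.nan)
        mask[sl] = finite
    return InsulationTrack(matrix.bins, values, mask, square_size=s)


def _local_minima(v: np.ndarray, valid: np.ndarray) -> list[int]:
    """Indices i with v[i] strictly below both valid neighbours."""
    out = []
    for i in range(1, v.size - 1):
        if not (valid[i] and valid[i - 1] and valid[i + 1]):
            continue
        if v[i] < v[i - 1] and v[i] < v[i + 1]:
            out.append(i)
    return out


def call_boundaries(track: InsulationTrack, delta_window: int = 3, min_strength: float = 0.1) -> TadSet:
    """TAD boundaries as strong insulation minima; domains between them.

    Boundary strength is the lower of the two flanking maxima (within
    ``delta_window`` bins each side) minus the minimum value; boundaries with
    strength below ``min_strength`` are dropped. Domains span consecutive
    boundaries and the stretches to the first/last valid bin of each
    chromosome.
    """
    boundaries: list[tuple[int, float]] = []
    domains: list[tuple[int, int]] = []
    w = int(delta_window)
    for chrom in track.bins.chrom_sizes:
        sl = track.bins.chrom_slice(chrom)
        v = track.values[sl]
        valid = track.mask[sl]
        chrom_bounds = []
        if valid.any():
            for i in _local_minima(v, valid):
                left = v[max(0, i - w) : i]
                right = v[i + 1 : i + 1 + w]
                lv = left[np.isfinite(left)]
                rv = right[np.isfinite(right)]
                if lv.size == 0 or rv.size == 0:
                    continue
                strength = float(min(lv.max(), rv.max()) - v[i])
                if strength >= min_strength:
                    chrom_bounds.append((i, strength))
            first = int(np.flatnonzero(valid)[0])
            last = int(np.flatnonzero(valid)[-1]) + 1
            edges = [first] + [i for i, _ in chrom_bounds] + [last]
            off = sl.start
            for a, b in zip(edges[:-1], edges[1:]):
                if b > a:
                    domains.append((off + a, off + b))
            boundaries.extend((off + i, st) for i, st in chrom_bounds)
    return TadSet(track.bins, boundaries, domains)


def differential_insulation(
    track1: InsulationTrack,
    track2: InsulationTrack,
    window: int = 11,
    step: int = 1,
    r_threshold: float = 0.6,
) -> list[DiffInsulationRegion]:
    """Regions where the two insulation profiles disagree.

    A length-``window`` window slides by ``step`` along each chromosome's
    jointly valid span; the Pearson r between the two tracks is computed per
    window (a window where either track is constant counts as r = 1, i.e.
    "not different"). A bin is differential only if *every* window covering
    it has r < ``r_threshold``; maximal runs of differential bins are
    reported with the minimum window r observed inside.
    """
    if track1.bins != track2.bins:
        raise AlignmentError("tracks are on different bin grids")
    regions: list[DiffInsulationRegion] = []
    w = int(window)
    for chrom in track1.bins.chrom_sizes:
        sl = track1.bins.chrom_slice(chrom)
        v1, v2 = track1.values[sl], track2.values[sl]
        both = track1.mask[sl] & track2.mask[sl]
        nb = both.size
        # contiguous jointly-valid runs
        run_start = None
        runs = []
        for i in range(nb + 1):
            if i < nb and both[i]:
                if run_start is None:
                    run_start = i
            elif run_start is not None:
                runs.append((run_start, i))
                run_start = None
        for a, b in runs:
            if b - a < w:
                continue
            diff_flag = np.ones(b - a, dtype=bool)  # all covering windows below threshold
            covered = np.zeros(b - a, dtype=bool)
            min_r = np.full(b - a, np.inf)
            for start in range(a, b - w + 1, step):
                x = v1[start : start + w]
                y = v2[start : start + w]
                if np.std(x) == 0 or np.std(y) == 0:
                    r = 1.0
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                lo, hi = start - a, start - a + w
                covered[lo:hi] = True
                min_r[lo:hi] = np.minimum(min_r[lo:hi], r)
                if r >= r_threshold:
                    diff_flag[lo:hi] = False
            diff_flag &= covered
            i = 0
            while i < diff_flag.size:
                if diff_flag[i]:
                    j = i
                    while j < diff_flag.size and diff_flag[j]:
                        j += 1
                    regions.append(
                        DiffInsulationRegion(chrom, sl.start + a + i, sl.start + a + j, float(min_r[i:j].min()))
                    )
                    i = j
                else:
                    i += 1
    return regions


def boundary_overlap(tads1: TadSet, tads2: TadSet, slack: int = 1) -> dict:
    """Classify boundaries as shared / gained (only in 2) / lost (only in 1).

    Two boundaries match when within ``slack`` bins on the same chromosome.
    """
    if tads1.bins != tads2.bins:
        raise AlignmentError("TAD sets are on different bin grids")
    b1 = np.array(tads1.boundary_bins(), dtype=int)
    b2 = np.array(tads2.boundary_bins(), dtype=int)
    c1 = tads1.bins.chrom_of(b1) if b1.size else np.array([], dtype=int)
    c2 = tads2.bins.chrom_of(b2) if b2.size else np.array([], dtype=int)

    def has_match(b, c, other_b, other_c):
        return bool(((np.abs(other_b - b) <= slack) & (other_c == c)).any()) if other_b.size else False

    shared = [int(b) for b, c in zip(b2, c2) if has_match(b, c, b1, c1)]
    gained = [int(b) for b, c in zip(b2, c2) if not has_match(b, c, b1, c1)]
    lost = [int(b) for b, c in zip(b1, c1) if not has_match(b, c, b2, c2)]
    return {"shared": shared, "gained": gained, "lost": lost}
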