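"""Genome coordinate model, fixed-width binning, and per-bin track I/O.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
Chromosome order is always the order of the chrom.sizes file, never a
lexicographic sort, so matrix layouts match the input genome ordering.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "FormatError",
    "AlignmentError",
    "ChromSizes",
    "GenomeBins",
    "BinTrack",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "make_bins",
    "read_bedgraph",
    "write_bedgraph",
]


class FormatError(ValueError):
    """An on-disk file violates its format contract."""


class AlignmentError(ValueError):
    """Two binned objects (or a file and a bin grid) do not share a grid."""


class ChromSizes:
    """Ordered chromosome name -> length (bp) table.

    Names must be unique and non-empty; lengths strictly positive integers.
    Iteration order is insertion (file) order.
    """

    def __init__(self, items):
        items = [(str(n), int(l)) for n, l in items]
        names = [n for n, _ in items]
        if len(names) != len(set(names)):
            raise FormatError("duplicate chromosome names")
        for n, l in items:
            if not n:
                raise FormatError("empty chromosome name")
            if l <= 0:
                raise FormatError(f"non-positive length for chromosome {n!r}")
        self._names = names
        self._lengths = dict(items)

    @property
    def names(self) -> list[str]:
        return list(self._names)

    @property
    def lengths(self) -> list[int]:
        return [self._lengths[n] for n in self._names]

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, name) -> bool:
        return name in self._lengths

    def __getitem__(self, name) -> int:
        return self._lengths[name]

    def __iter__(self):
        return iter(self._names)

    def items(self):
        return [(n, self._lengths[n]) for n in self._names]

    def __eq__(self, other):
        return isinstance(other, ChromSizes) and self.items() == other.items()

    def __repr__(self):
        return f"ChromSizes({len(self)} chromosomes, {self.total_length} bp)"


def read_chrom_sizes(path) -> ChromSizes:
    """Parse a UCSC-style two-column chrom.sizes file, preserving order."""
    items = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"line {lineno}: expected 2 columns, got {len(fields)}")
            name, raw_len = fields[0], fields[1]
            try:
                length = int(raw_len)
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer length {raw_len!r}") from None
            if length <= 0:
                raise FormatError(f"line {lineno}: non-positive length {length}")
            items.append((name, length))
    if not items:
        raise FormatError("no chromosomes")
    return ChromSizes(items)


def write_chrom_sizes(chrom_sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for name, length in chrom_sizes.items():
            fh.write(f"{name}\t{length}\n")


class GenomeBins:
    """Fixed-width, non-overlapping genomic bins over a whole genome.

    Bins are 0-based half-open; the last bin of each chromosome may be short.
    Global bin indices are contiguous in chromosome order: chromosome ``c``
    occupies ``[offset(c), offset(c) + n_bins(c))``.
    """

    def __init__(self, chrom_sizes: ChromSizes, bin_size: int):
        bin_size = int(bin_size)
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.chrom_sizes = chrom_sizes
        self.bin_size = bin_size
        counts = [-(-l // bin_size) for l in chrom_sizes.lengths]  # ceil div
        self._counts = dict(zip(chrom_sizes.names, counts))
        offsets = np.concatenate([[0], np.cumsum(counts)])
        self._offsets = dict(zip(chrom_sizes.names, offsets[:-1].tolist()))
        self.n_bins = int(offsets[-1])
        # per-global-bin lookup arrays
        self._chrom_idx = np.repeat(np.arange(len(chrom_sizes)), counts)
        starts = np.empty(self.n_bins, dtype=np.int64)
        for name in chrom_sizes:
            o, c = self._offsets[name], self._counts[name]
            starts[o : o + c] = np.arange(c, dtype=np.int64) * bin_size
        self._starts = starts

    def n_chrom_bins(self, chrom: str) -> int:
        return self._counts[chrom]

    def offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        o = self._offsets[chrom]
        return slice(o, o + self._counts[chrom])

    def locate(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing ``pos`` (0-based bp)."""
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom} (length {self.chrom_sizes[chrom]})")
        return self._offsets[chrom] + int(pos) // self.bin_size

    def bin_interval(self, gidx: int) -> tuple[str, int, int]:
        """(chrom, start, end) of the global bin ``gidx``; end is clipped."""
        if not 0 <= gidx < self.n_bins:
            raise IndexError(f"bin index {gidx} out of range")
        chrom = self.chrom_sizes.names[self._chrom_idx[gidx]]
        start = int(self._starts[gidx])
        end = min(start + self.bin_size, self.chrom_sizes[chrom])
        return chrom, start, end

    def chrom_of(self, gidx) -> np.ndarray:
        """Chromosome index (into chrom_sizes.names) per global bin."""
        return self._chrom_idx[gidx]

    def __eq__(self, other):
        return (
            isinstance(other, GenomeBins)
            and self.bin_size == other.bin_size
            and self.chrom_sizes == other.chrom_sizes
        )

    def __repr__(self):
        return f"GenomeBins({len(self.chrom_sizes)} chromosomes, bin_size={self.bin_size}, n_bins={self.n_bins})"


def make_bins(chrom_sizes: ChromSizes, bin_size: int) -> GenomeBins:
    """Bin every chromosome into fixed non-overlapping intervals."""
    return GenomeBins(chrom_sizes, bin_size)


class BinTrack:
    """One real value per genomic bin with a validity mask.

    Masked-out bins carry NaN and are excluded from all statistics and from
    file output. Used for insulation scores, compartment eigenvectors, gene
    density, FIRE z-scores and similar per-bin signals.
    """

    def __init__(self, bins: GenomeBins, values, mask=None):
        values = np.asarray(values, dtype=float).copy()
        if values.shape != (bins.n_bins,):
            raise AlignmentError(
                f"track length {values.shape} does not match bin count {bins.n_bins}"
            )
        if mask is None:
            mask = np.isfinite(values)
        mask = np.asarray(mask, dtype=bool).copy()
        if mask.shape != (bins.n_bins,):
            raise AlignmentError("mask length does not match bin count")
        values[~mask] = np.nan
        self.bins = bins
        self.values = values
        self.mask = mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def __len__(self):
        return self.bins.n_bins


def write_bedgraph(track: BinTrack, path) -> None:
    """Write valid bins as 0-based half-open bedGraph lines; masked bins are omitted."""
    bins = track.bins
    with open(path, "w") as fh:
        for gidx in np.flatnonzero(track.mask):
            chrom, start, end = bins.bin_interval(int(gidx))
            fh.write(f"{chrom}\t{start}\t{end}\t{float(track.values[gidx])!r}\n")


def read_bedgraph(path, bins: GenomeBins) -> BinTrack:
    """Read a bedGraph into a BinTrack on ``bins``; absent bins are masked.

    Every interval must coincide exactly with one bin of the grid.
    """
    values = np.full(bins.n_bins, np.nan)
    mask = np.zeros(bins.n_bins, dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split()[:4]
            start, end = int(start), int(end)
            if chrom not in bins.chrom_sizes:
                raise FormatError(f"line {lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < bins.chrom_sizes[chrom]) or start // bins.bin_size >= bins.n_chrom_bins(chrom):
                raise AlignmentError(f"line {lineno}: interval start {start} outside {chrom}")
            gidx = bins.offset(chrom) + start // bins.bin_size
            expect = bins.bin_interval(gidx)
            if expect[1] != start or expect[2] != end:
                raise AlignmentError(
                    f"line {lineno}: interval [{start}, {end}) not aligned to {bins.bin_size}-bp grid"
                )
            values[gidx] = float(value)
            mask[gidx] = True
    return BinTrack(bins, values, mask)
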