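"""A/B compartment calling from the first eigenvector (PC1) of the
distance-normalised contact correlation matrix, and two-condition
differential compartments.

Per chromosome: the balanced cis matrix is divided by its per-separation mean
(observed/expected), the Pearson correlation matrix of the O/E rows is
formed, and its leading eigenvector is extracted. The eigenvector sign is
arbitrary, so it is oriented per chromosome to correlate positively with an
activity track (gene density by default; GC content works as a fallback):
positive PC1 = A (active, gene-dense), negative = B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import AlignmentError, BinTrack, GenomeBins
from .contact import ContactMatrix

__all__ = [
    "CompartmentCall",
    "CompartmentDiff",
    "observed_expected",
    "call_compartments",
    "differential_compartments",
]

LABEL_A, LABEL_B, LABEL_NA = "A", "B", "NA"


@dataclass
class CompartmentCall:
    """Per-bin PC1 values and A/B/NA labels over the whole bin grid."""

    bins: GenomeBins
    eigenvector: np.ndarray  # NaN where NA
    labels: np.ndarray  # array of "A"/"B"/"NA"
    explained_variance: dict = field(default_factory=dict)  # chrom -> fraction
    warnings_: list = field(default_factory=list)

    def track(self) -> BinTrack:
        return BinTrack(self.bins, self.eigenvector, np.isfinite(self.eigenvector))


@dataclass
class CompartmentDiff:
    """Bins whose A/B label flips between two samples."""

    bins: GenomeBins
    flipped: list  # (global_bin, label1, label2, ev1, ev2)

    @property
    def n_a_to_b(self) -> int:
        return sum(1 for _, l1, l2, _, _ in self.flipped if l1 == LABEL_A and l2 == LABEL_B)

    @property
    def n_b_to_a(self) -> int:
        return sum(1 for _, l1, l2, _, _ in self.flipped if l1 == LABEL_B and l2 == LABEL_A)

    def bin_indices(self) -> list[int]:
        return [g for g, *_ in self.flipped]


def observed_expected(matrix: ContactMatrix, chromosome: str) -> np.ndarray:
    """Cis O/E block: each entry divided by the mean at its separation.

    Means are taken over unmasked pairs; strata with zero mean map to 0.
    Masked rows/columns are zero.
    """
    sl = matrix.bins.chrom_slice(chromosome)
    block = matrix.values[sl, sl]
    m = matrix.mask[sl]
    n = block.shape[0]
    oe = np.zeros_like(block)
    for sep in range(0, n):
        diag = np.diagonal(block, offset=sep)
        valid = m[: n - sep] & m[sep:]
        if valid.sum() == 0:
            continue
        mu = diag[valid].mean()
        vals = np.zeros_like(diag)
        if mu > 0:
            vals[valid] = diag[valid] / mu
        idx = np.arange(n - sep)
        oe[idx, idx + sep] = vals
        oe[idx + sep, idx] = vals
    return oe


def _pc1(corr: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading eigenvector of a symmetric matrix and its variance fraction."""
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    v = evecs[:, order[0]]
    pos = np.clip(evals, 0, None)
    frac = float(pos[0] / pos.sum()) if pos.sum() > 0 else 0.0
    return v, frac


def call_compartments(
    matrix: ContactMatrix,
    orientation_track: BinTrack,
    chromosome: str | None = None,
    min_bins: int = 10,
    min_variance_fraction: float = 0.05,
) -> CompartmentCall:
    """Assign each bin to the A or B compartment from the sign of PC1.

    ``orientation_track`` (gene density or GC content) fixes the arbitrary
    eigenvector sign per chromosome so that A correlates with activity.
    With ``chromosome=None`` every chromosome is processed; chromosomes that
    are degenerate (too few unmasked bins, or zero-variance correlation)
    come back all-NA with a recorded warning instead of raising.
    """
    if orientation_track.bins != matrix.bins:
        raise AlignmentError("orientation track is on a different bin grid")
    single = chromosome is not None
    chroms = [chromosome] if single else matrix.bins.chrom_sizes.names
    ev = np.full(matrix.n_bins, np.nan)
    labels = np.full(matrix.n_bins, LABEL_NA, dtype=object)
    explained: dict = {}
    warns: list[str] = []
    for chrom in chroms:
        sl = matrix.bins.chrom_slice(chrom)
        m = matrix.mask[sl]
        if int(m.sum()) < min_bins:
            msg = f"{chrom}: fewer than {min_bins} unmasked bins"
            if single:
                raise ValueError("degenerate input: " + msg)
            warns.append(msg)
            continue
        oe = observed_expected(matrix, chrom)
        sub = oe[np.ix_(m, m)]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(sub)
        if not np.isfinite(corr).any():
            warns.append(f"{chrom}: zero-variance correlation matrix, all-NA call")
            warnings.warn(warns[-1])
            continue
        corr = np.nan_to_num(corr, nan=0.0)
        v, frac = _pc1(corr)
        explained[chrom] = frac
        if frac < min_variance_fraction:
            warns.append(f"{chrom}: PC1 explains only {frac:.3f} of variance")
            warnings.warn(warns[-1])
        orient = orientation_track.values[sl][m]
        ok = np.isfinite(orient)
        if ok.sum() >= 2 and np.std(orient[ok]) > 0 and np.std(v[ok]) > 0:
            r = np.corrcoef(v[ok], orient[ok])[0, 1]
            if np.isfinite(r) and r < 0:
                v = -v
        evc = np.full(m.size, np.nan)
        evc[m] = v
        ev[sl] = evc
    finite = np.isfinite(ev)
    labels[finite & (ev > 0)] = LABEL_A
    labels[finite & (ev < 0)] = LABEL_B
    return CompartmentCall(matrix.bins, ev, labels, explained, warns)


def differential_compartments(call1: CompartmentCall, call2: CompartmentCall) -> CompartmentDiff:
    """Bins with non-NA, unequal labels between two samples (A->B / B->A)."""
    if call1.bins != call2.bins:
        raise AlignmentError("compartment calls are on different bin grids")
    flipped = []
    for g in range(call1.bins.n_bins):
        l1, l2 = call1.labels[g], call2.labels[g]
        if LABEL_NA in (l1, l2) or l1 == l2:
            continue
        flipped.append((g, l1, l2, float(call1.eigenvector[g]), float(call2.eigenvector[g])))
    return CompartmentDiff(call1.bins, flipped)


def write_compartment_bed(call: CompartmentCall, path) -> None:
    """A/B labels as BED with the label in the name field."""
    with open(path, "w") as fh:
        for g in range(call.bins.n_bins):
            if call.labels[g] == LABEL_NA:
                continue
            chrom, start, end = call.bins.bin_interval(g)
            fh.write(f"{chrom}\t{start}\t{end}\t{call.labels[g]}\t{call.eigenvector[g]:.6g}\n")


def write_diff_bed(diff: CompartmentDiff, path) -> None:
    with open(path, "w") as fh:
        for g, l1, l2, ev1, ev2 in diff.flipped:
            chrom, start, end = diff.bins.bin_interval(g)
            name = "A2B" if l1 == LABEL_A else "B2A"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{ev1:.6g}\t{ev2:.6g}\n")
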