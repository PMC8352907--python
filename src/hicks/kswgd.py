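"""Nei-Gojobori (NG86) Ka/Ks estimation, Ks-distribution peak detection, and
whole-genome-duplication dating by T = Ks / (2r).

Site counting follows the yn00 NG convention: at each codon position the
synonymous site fraction is the share of synonymous changes among the
possible single-nucleotide changes that do not create a stop codon, so every
codon contributes exactly 3 sites split between S and N; per-pair sites are
averaged over the two sequences. Codons differing at k positions are
resolved by averaging synonymous/nonsynonymous step counts over all k!
minimal substitution pathways, excluding pathways that pass through a stop
codon. Proportions are corrected for multiple hits with the Jukes-Cantor
formula K = -(3/4) ln(1 - (4/3) p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

__all__ = [
    "SaturationError",
    "CodonSequencePair",
    "KsEstimate",
    "KsDistribution",
    "ng86",
    "ks_distribution",
    "divergence_time",
    "read_pair_fasta",
    "write_ks_table",
]

BASES = "ACGT"
CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"


class SaturationError(ValueError):
    """A substitution proportion reached the Jukes-Cantor saturation limit."""


def _site_fractions(codon: str) -> float:
    """Synonymous site count of one codon (0..3).

    Per position: synonymous changes / changes not creating a stop codon.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        sensible = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            sensible += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        if sensible:
            s += syn / sensible
    return s


_SYN_SITES = {c: _site_fractions(c) for c in CODON_TO_AA if c not in STOP_CODONS}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averages over all minimal substitution pathways that avoid intermediate
    stop codons; if every pathway is blocked, averages over all pathways with
    steps to/from a stop counted as nonsynonymous.
    """
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    if k == 1:
        same = CODON_TO_AA[c1] == CODON_TO_AA[c2]
        return (1.0, 0.0) if same else (0.0, 1.0)

    def walk(order):
        syn = nonsyn = 0
        cur = c1
        blocked = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in STOP_CODONS and nxt != c2:
                blocked = True
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn, blocked

    results = [walk(order) for order in permutations(diff_pos)]
    open_paths = [(s, n) for s, n, blocked in results if not blocked]
    if not open_paths:
        open_paths = [(s, n) for s, n, _ in results]
    sd = float(np.mean([s for s, _ in open_paths]))
    nd = float(np.mean([n for _, n in open_paths]))
    return sd, nd


@dataclass
class CodonSequencePair:
    """Two aligned coding sequences, pairwise-degapped to complete codons.

    Codon columns where either sequence carries a non-ACGT character are
    dropped from both sequences; the number of dropped codons is recorded.
    Internal stop codons (after cleaning) are rejected.
    """

    seq1: str
    seq2: str
    n_dropped_codons: int = 0

    @classmethod
    def from_alignment(cls, seq1: str, seq2: str) -> "CodonSequencePair":
        seq1, seq2 = seq1.upper(), seq2.upper()
        if len(seq1) != len(seq2):
            raise ValueError("aligned sequences must have equal length")
        if len(seq1) % 3 != 0:
            raise ValueError("aligned length must be divisible by 3")
        keep1, keep2, dropped = [], [], 0
        for k in range(0, len(seq1), 3):
            a, b = seq1[k : k + 3], seq2[k : k + 3]
            if all(ch in BASES for ch in a + b):
                keep1.append(a)
                keep2.append(b)
            else:
                dropped += 1
        return cls("".join(keep1), "".join(keep2), dropped)

    def __post_init__(self):
        if len(self.seq1) != len(self.seq2):
            raise ValueError("sequences must have equal length")
        if len(self.seq1) % 3 != 0:
            raise ValueError("length must be divisible by 3")
        for seq in (self.seq1, self.seq2):
            for k in range(0, len(seq), 3):
                codon = seq[k : k + 3]
                if any(ch not in BASES for ch in codon):
                    raise ValueError(f"non-ACGT codon {codon!r}; use from_alignment to clean")
                if codon in STOP_CODONS and k < len(seq) - 3:
                    raise ValueError(f"internal stop codon {codon!r} at position {k}")

    @property
    def n_codons(self) -> int:
        return len(self.seq1) // 3

    def codons(self):
        for k in range(0, len(self.seq1), 3):
            yield self.seq1[k : k + 3], self.seq2[k : k + 3]


@dataclass
class KsEstimate:
    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    pS: float
    pN: float
    Ks: float
    Ka: float


def _jukes_cantor(p: float, label: str) -> float:
    if p >= 0.75:
        raise SaturationError(f"{label} = {p:.4f} >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * float(np.log(1 - (4.0 / 3.0) * p)) if p > 0 else 0.0


def ng86(pair: CodonSequencePair) -> KsEstimate:
    """NG-model Ka/Ks for one aligned codon pair. Symmetric in its inputs."""
    if pair.n_codons == 0:
        raise ValueError("zero-length codon pair")
    S = Sd = Nd = 0.0
    for c1, c2 in pair.codons():
        # terminal stop codons were allowed through validation; skip them
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        S += 0.5 * (_SYN_SITES[c1] + _SYN_SITES[c2])
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    n_counted = sum(
        1 for c1, c2 in pair.codons() if c1 not in STOP_CODONS and c2 not in STOP_CODONS
    )
    if n_counted == 0:
        raise ValueError("no countable codons")
    N = 3.0 * n_counted - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(pS, "pS")
    Ka = _jukes_cantor(pN, "pN")
    return KsEstimate(S, N, Sd, Nd, pS, pN, Ks, Ka)


@dataclass
class KsDistribution:
    """Ks values with a Gaussian kernel-density estimate and detected peaks."""

    values: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    peaks: list  # peak locations, ascending
    ks_range: tuple[float, float]
    n_excluded: int = 0
    n_saturated: int = 0


def ks_distribution(
    pairs_or_values,
    bandwidth=None,
    ks_range: tuple[float, float] = (0.0, 3.0),
    peak_floor: float = 0.10,
    grid_points: int = 512,
) -> KsDistribution:
    """KDE of Ks over gene pairs and its local maxima.

    Accepts CodonSequencePair objects (Ks computed here; saturated pairs
    skipped and counted) or precomputed Ks values. Values outside
    ``ks_range`` are excluded before density estimation. Peaks are local
    maxima of the density exceeding ``peak_floor`` of the global maximum.
    Bandwidth defaults to Silverman's rule.
    """
    values = []
    n_sat = 0
    for item in pairs_or_values:
        if isinstance(item, CodonSequencePair):
            try:
                values.append(ng86(item).Ks)
            except SaturationError:
                n_sat += 1
        else:
            values.append(float(item))
    values = np.asarray(values, dtype=float)
    lo, hi = ks_range
    in_range = values[(values > lo) & (values < hi)]
    n_excluded = values.size - in_range.size
    if in_range.size < 20:
        raise ValueError(f"insufficient data: {in_range.size} estimable Ks values (< 20)")
    grid = np.linspace(lo, hi, grid_points)
    if np.ptp(in_range) == 0:
        density = np.zeros_like(grid)
        peak = float(in_range[0])
        density[np.argmin(np.abs(grid - peak))] = 1.0
        return KsDistribution(in_range, grid, density, [peak], ks_range, n_excluded, n_sat)
    kde = stats.gaussian_kde(in_range, bw_method=bandwidth or "silverman")
    density = kde(grid)
    floor = peak_floor * density.max()
    peaks = [
        float(grid[i])
        for i in range(1, grid_points - 1)
        if density[i] > density[i - 1] and density[i] >= density[i + 1] and density[i] >= floor
    ]
    return KsDistribution(in_range, grid, density, peaks, ks_range, n_excluded, n_sat)


@dataclass
class DivergenceTime:
    years: float
    mya: float


def divergence_time(ks: float, r: float = 8e-9) -> DivergenceTime:
    """Divergence time T = Ks / (2 r), in years and millions of years.

    ``r`` is the synonymous substitution rate per site per year
    (default 8e-9).
    """
    if r <= 0:
        raise ValueError("rate r must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    years = ks / (2.0 * r)
    return DivergenceTime(years, years / 1e6)


def read_pair_fasta(path) -> CodonSequencePair:
    """Read one aligned pair from a FASTA file holding exactly two records."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 records, found {len(records)}")
    return CodonSequencePair.from_alignment(str(records[0].seq), str(records[1].seq))


def write_ks_table(estimates: dict, path) -> None:
    """Write pair_id -> KsEstimate as a TSV table."""
    with open(path, "w") as fh:
        fh.write("pair_id\tS\tN\tSd\tNd\tpS\tpN\tKs\tKa\n")
        for pid, e in estimates.items():
            fh.write(
                f"{pid}\t{e.S:.4f}\t{e.N:.4f}\t{e.Sd:.4f}\t{e.Nd:.4f}\t"
                f"{e.pS:.6f}\t{e.pN:.6f}\t{e.Ks:.6f}\t{e.Ka:.6f}\n"
            )
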