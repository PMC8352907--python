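"""Seeded synthetic-data generators with planted ground truth.

Every pipeline stage in this package is verifiable against these generators:
Hi-C valid pairs with a power-law distance decay, checkerboard compartment
structure, block-diagonal TAD enrichment, multiplicative per-bin bias,
homoeolog-boosted trans contacts and Poisson sampling noise; aligned codon
pairs with purely synonymous third-position substitutions; and omics tables
with a planted correlated gene module. All randomness derives from the seed,
so identical specs give byte-identical outputs.

The cis expectation for bins i, j at separation d (in bins) is

    E[c_ij]  proportional to  b_i b_j f(d) (1 + delta s_i s_j) tau_ij

with the exact power-law kernel f(d) = d^alpha for d >= 1 and a finite
diagonal level f(0) = 1, where s is the +/-1 compartment state, delta the
checkerboard contrast, and tau_ij = tau when i and j fall in the same TAD
block (else 1). Keeping the off-diagonal kernel an exact power law makes the
planted exponent identifiable by the standard log-log decay fit (the
diagonal is excluded from decay fitting throughout the package, so the
d = 0 singularity never enters). Expectations are normalised to the
requested sequencing depth and sampled cell-wise Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ChromSizes, GenomeBins
from .contact import ValidPairRecord

__all__ = [
    "SyntheticSpec",
    "expected_cis",
    "expected_trans",
    "simulate_hic",
    "simulate_condition_pair",
    "simulate_codon_pairs",
    "simulate_omics",
]


@dataclass
class SyntheticSpec:
    """Full parameterisation of a simulated Hi-C experiment.

    Defaults reflect realistic plant Hi-C conditions: decay exponent -0.9
    (between typical measured genome-wide values near -0.85 and -0.91),
    moderate checkerboard contrast, and no bias unless planted.
    """

    chrom_sizes: ChromSizes
    bin_size: int
    decay_exponent: float = -0.9
    compartment_delta: float = 0.0  # checkerboard contrast, in [0, 1)
    compartment_states: np.ndarray | None = None  # +/-1 per bin
    tad_boundaries: list = field(default_factory=list)  # global bin indices
    tad_tau: float = 1.0  # same-block enrichment, >= 1
    bias: np.ndarray | None = None  # positive per-bin multiplicative bias
    homoeolog_pairs: list = field(default_factory=list)  # (chromA, chromB)
    homoeolog_boost: float = 1.0
    cis_depth: float = 100_000.0
    trans_depth: float = 0.0
    seed: int = 0

    def bins(self) -> GenomeBins:
        return GenomeBins(self.chrom_sizes, self.bin_size)

    def validate(self, bins: GenomeBins) -> None:
        if not 0 <= self.compartment_delta < 1:
            raise ValueError("compartment_delta must be in [0, 1)")
        if self.tad_tau < 1:
            raise ValueError("tad_tau must be >= 1")
        if self.cis_depth < 0 or self.trans_depth < 0:
            raise ValueError("depths must be >= 0")
        if self.bias is not None and (len(self.bias) != bins.n_bins or np.any(np.asarray(self.bias) <= 0)):
            raise ValueError("bias must be positive and one per bin")
        if self.compartment_states is not None and len(self.compartment_states) != bins.n_bins:
            raise ValueError("compartment_states must have one entry per bin")
        if bins.n_bins == 0:
            raise ValueError("zero bins")


def random_compartment_states(bins: GenomeBins, rng, min_block: int = 5, max_block: int = 20) -> np.ndarray:
    """Alternating +/-1 blocks of random length per chromosome."""
    s = np.empty(bins.n_bins)
    for chrom in bins.chrom_sizes:
        sl = bins.chrom_slice(chrom)
        nb = sl.stop - sl.start
        state = 1.0 if rng.random() < 0.5 else -1.0
        i = 0
        while i < nb:
            blk = int(rng.integers(min_block, max_block + 1))
            s[sl.start + i : sl.start + min(i + blk, nb)] = state
            state = -state
            i += blk
    return s


def _domain_ids(bins: GenomeBins, boundaries) -> np.ndarray:
    """Integer TAD block label per bin; blocks never cross chromosomes."""
    ids = np.zeros(bins.n_bins, dtype=int)
    cuts = sorted(set(int(b) for b in boundaries))
    label = 0
    for chrom in bins.chrom_sizes:
        sl = bins.chrom_slice(chrom)
        edges = [sl.start] + [c for c in cuts if sl.start < c < sl.stop] + [sl.stop]
        for a, b in zip(edges[:-1], edges[1:]):
            ids[a:b] = label
            label += 1
    return ids


def expected_cis(spec: SyntheticSpec) -> np.ndarray:
    """Expected cis count matrix, normalised so the upper triangle including
    the diagonal sums to ``cis_depth``. Trans entries are zero."""
    bins = spec.bins()
    spec.validate(bins)
    n = bins.n_bins
    b = np.ones(n) if spec.bias is None else np.asarray(spec.bias, dtype=float)
    s = spec.compartment_states
    dom = _domain_ids(bins, spec.tad_boundaries)
    E = np.zeros((n, n))
    for chrom in bins.chrom_sizes:
        sl = bins.chrom_slice(chrom)
        nb = sl.stop - sl.start
        idx = np.arange(nb)
        d = np.abs(idx[:, None] - idx[None, :])
        block = np.where(d > 0, np.maximum(d, 1).astype(float) ** spec.decay_exponent, 1.0)
        if s is not None and spec.compartment_delta > 0:
            sc = s[sl]
            block = block * (1.0 + spec.compartment_delta * np.outer(sc, sc))
        dm = dom[sl]
        same = dm[:, None] == dm[None, :]
        if spec.tad_tau != 1.0:
            block = block * np.where(same, spec.tad_tau, 1.0)
        block = block * np.outer(b[sl], b[sl])
        E[sl, sl] = block
    total = np.triu(E).sum()
    if total > 0 and spec.cis_depth > 0:
        E *= spec.cis_depth / total
    elif spec.cis_depth == 0:
        E[:] = 0.0
    return E


def expected_trans(spec: SyntheticSpec) -> np.ndarray:
    """Expected trans count matrix, upper triangle summing to trans_depth."""
    bins = spec.bins()
    spec.validate(bins)
    n = bins.n_bins
    if spec.trans_depth <= 0:
        return np.zeros((n, n))
    b = np.ones(n) if spec.bias is None else np.asarray(spec.bias, dtype=float)
    chrom_idx = bins.chrom_of(np.arange(n))
    E = np.outer(b, b).astype(float)
    E[chrom_idx[:, None] == chrom_idx[None, :]] = 0.0
    if spec.homoeolog_pairs and spec.homoeolog_boost != 1.0:
        names = bins.chrom_sizes.names
        for a, h in spec.homoeolog_pairs:
            ai, hi = names.index(a), names.index(h)
            sel = (chrom_idx[:, None] == ai) & (chrom_idx[None, :] == hi)
            E[sel | sel.T] *= spec.homoeolog_boost
    total = np.triu(E).sum()
    if total > 0:
        E *= spec.trans_depth / total
    return E


def _emit_records(counts: np.ndarray, bins: GenomeBins, rng) -> list[ValidPairRecord]:
    """Turn a Poisson count matrix (upper triangle used) into pair records
    with uniform positions inside each bin."""
    records = []
    names = bins.chrom_sizes.names
    iu = np.triu_indices(bins.n_bins)
    for i, j in zip(*iu):
        k = int(counts[i, j])
        if k == 0:
            continue
        c1, s1, e1 = bins.bin_interval(int(i))
        c2, s2, e2 = bins.bin_interval(int(j))
        p1 = rng.integers(s1, e1, size=k)
        p2 = rng.integers(s2, e2, size=k)
        for a, b in zip(p1, p2):
            records.append(ValidPairRecord(c1, int(a), c2, int(b)))
    return records


def simulate_hic(spec: SyntheticSpec):
    """Draw a valid-pairs stream from the spec's expectation model.

    Returns ``(records, truth)`` where truth carries the planted decay
    exponent, compartment states, TAD boundaries, bias vector, homoeolog
    pairing, and the expectation matrices used.
    """
    bins = spec.bins()
    rng = np.random.default_rng(spec.seed)
    Ec = expected_cis(spec)
    Et = expected_trans(spec)
    E = np.triu(Ec + Et)
    counts = rng.poisson(E)
    records = _emit_records(counts, bins, rng)
    truth = {
        "decay_exponent": spec.decay_exponent,
        "compartment_states": None if spec.compartment_states is None else np.asarray(spec.compartment_states).copy(),
        "tad_boundaries": sorted(int(b) for b in spec.tad_boundaries),
        "bias": None if spec.bias is None else np.asarray(spec.bias, dtype=float).copy(),
        "homoeolog_pairs": list(spec.homoeolog_pairs),
        "homoeolog_boost": spec.homoeolog_boost,
        "expected_cis": Ec,
        "expected_trans": Et,
        "n_records": len(records),
    }
    return records, truth


def simulate_condition_pair(
    spec: SyntheticSpec,
    flips=(),
    boundary_add=(),
    boundary_remove=(),
    perturbed_blocks=(),
    perturb_fraction: float = 0.1,
    perturb_factor: float = 5.0,
    condition2_seed_offset: int = 1_000_003,
):
    """Two-condition experiment sharing condition 1's expectations.

    Condition 2 differs only by: compartment states negated at ``flips``
    (global bin indices), TAD boundaries added/removed, and sparse strong
    rewiring of the cis expectation among bin pairs falling inside any of
    ``perturbed_blocks`` (half-open global bin intervals): each in-block
    pair is independently, with probability ``perturb_fraction``, boosted by
    ``perturb_factor`` or suppressed by its inverse (equal odds) - the
    gain/loss of specific strong contacts. Sparse-and-strong is deliberate:
    per-separation z-scoring standardises each stratum, so a dense or
    stratum-wide change inflates the stratum spread and hides itself, while
    a few strongly rewired pairs stand out as genuine outliers. Condition
    1's stream depends only on ``spec.seed`` and is bitwise unaffected by
    the condition-2 parameters.
    """
    bins = spec.bins()
    spec.validate(bins)
    flips = sorted(set(int(f) for f in flips))
    add = set(int(x) for x in boundary_add)
    rem = set(int(x) for x in boundary_remove)
    if add & rem:
        raise ValueError(f"contradictory boundary changes: {sorted(add & rem)}")
    existing = set(int(x) for x in spec.tad_boundaries)
    if rem - existing:
        raise ValueError(f"cannot remove non-existent boundaries: {sorted(rem - existing)}")
    records1, truth1 = simulate_hic(spec)

    s2 = None if spec.compartment_states is None else np.asarray(spec.compartment_states, dtype=float).copy()
    if flips:
        if s2 is None:
            raise ValueError("flips requested but spec has no compartment states")
        s2[flips] = -s2[flips]
    spec2 = replace(
        spec,
        compartment_states=s2,
        tad_boundaries=sorted((existing - rem) | add),
    )
    rng2 = np.random.default_rng((spec.seed + condition2_seed_offset) % (2**31))
    Ec2 = expected_cis(spec2)
    Et2 = expected_trans(spec2)
    chrom_idx = bins.chrom_of(np.arange(bins.n_bins))
    for a, b in perturbed_blocks:
        a, b = int(a), int(b)
        nb = b - a
        sel = np.zeros(bins.n_bins, dtype=bool)
        sel[a:b] = True
        pair_sel = np.outer(sel, sel) & (chrom_idx[:, None] == chrom_idx[None, :])
        hit = rng2.random((nb, nb)) < perturb_fraction
        updown = np.where(rng2.random((nb, nb)) < 0.5, perturb_factor, 1.0 / perturb_factor)
        factors = np.where(hit, updown, 1.0)
        factors = np.triu(factors) + np.triu(factors, 1).T  # symmetric field
        full = np.ones((bins.n_bins, bins.n_bins))
        full[a:b, a:b] = factors
        Ec2 = np.where(pair_sel, Ec2 * full, Ec2)
    counts2 = rng2.poisson(np.triu(Ec2 + Et2))
    records2 = _emit_records(counts2, bins, rng2)
    truth = {
        "condition1": truth1,
        "flipped_bins": flips,
        "boundaries2": spec2.tad_boundaries,
        "boundary_added": sorted(add),
        "boundary_removed": sorted(rem),
        "perturbed_blocks": [(int(a), int(b)) for a, b in perturbed_blocks],
        "compartment_states2": s2,
        "expected_cis2": Ec2,
    }
    return records1, records2, truth


# codon families whose first two positions admit no synonymous change, so a
# third-position substitution is always synonymous and S = n_codons exactly
_ROBUST_FAMILIES = ["GG", "GC", "CC", "AC", "GT"]


def simulate_codon_pairs(n_pairs: int, codons_per_pair: int, target_ps: float, seed: int = 0):
    """Aligned codon pairs whose differences are all synonymous.

    Ancestor codons come from four-fold-degenerate family boxes; each third
    position mutates with probability ``target_ps`` to one of the other three
    bases, so the expected synonymous proportion pS equals ``target_ps``.
    Returns ``(pairs, truth)``.
    """
    if not 0 <= target_ps < 0.75:
        raise ValueError("target_ps must be in [0, 0.75)")
    from .kswgd import CodonSequencePair

    rng = np.random.default_rng(seed)
    bases = "ACGT"
    pairs = []
    n_sub_total = 0
    for _ in range(n_pairs):
        fams = rng.integers(0, len(_ROBUST_FAMILIES), size=codons_per_pair)
        thirds = rng.integers(0, 4, size=codons_per_pair)
        anc = "".join(_ROBUST_FAMILIES[f] + bases[t] for f, t in zip(fams, thirds))
        mutate = rng.random(codons_per_pair) < target_ps
        shift = rng.integers(1, 4, size=codons_per_pair)
        der = list(anc)
        for k in np.flatnonzero(mutate):
            der[3 * k + 2] = bases[(thirds[k] + shift[k]) % 4]
        n_sub_total += int(mutate.sum())
        pairs.append(CodonSequencePair(anc, "".join(der)))
    truth = {
        "target_ps": target_ps,
        "n_substitutions": n_sub_total,
        "codons_per_pair": codons_per_pair,
    }
    return pairs, truth


def simulate_omics(
    n_genes: int,
    n_metabolites: int,
    n_samples: int,
    planted: tuple | None = None,
    seed: int = 0,
):
    """Gene and metabolite tables with an optionally planted correlated module.

    ``planted = (n_planted_genes, metabolite_index, rho)``: the planted genes
    are generated as the metabolite profile times rho plus Gaussian noise of
    variance 1 - rho^2, so their population correlation with the metabolite
    is rho. Returns ``(genes_df, metabolites_df, truth)``.
    """
    import pandas as pd

    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    samples = [f"s{k}" for k in range(n_samples)]
    metab = rng.standard_normal((n_metabolites, n_samples))
    genes = rng.standard_normal((n_genes, n_samples))
    planted_ids: list[str] = []
    focus_id = None
    if planted is not None:
        n_planted, m_idx, rho = planted
        if not 0 <= rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        profile = metab[m_idx]
        noise = rng.standard_normal((n_planted, n_samples))
        genes[:n_planted] = rho * profile + np.sqrt(1 - rho**2) * noise
        planted_ids = [f"g{k}" for k in range(n_planted)]
        focus_id = f"m{m_idx}"
    genes_df = pd.DataFrame(genes, index=[f"g{k}" for k in range(n_genes)], columns=samples)
    metab_df = pd.DataFrame(metab, index=[f"m{k}" for k in range(n_metabolites)], columns=samples)
    truth = {"planted_genes": planted_ids, "focus_metabolite": focus_id, "rho": None if planted is None else planted[2]}
    return genes_df, metab_df, truth
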