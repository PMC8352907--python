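"""Significant cis/trans interaction calling in the Fit-Hi-C style, plus
homoeolog interaction fractions.

The cis expected model stratifies in-range bin pairs into ``b`` distance
strata of (near-)equal total contact occupancy, estimates a per-pair contact
probability per stratum, smooths the probabilities to be non-increasing in
distance by isotonic regression, and renormalises so the prior sums to 1
over all tested pairs. A second pass refits after removing pairs called
significant in the first. P values are upper-tail binomial probabilities of
the observed count given the total in-range contact count and the pair's
prior; q values are Benjamini-Hochberg. A call is significant iff
P < 0.01, q < 0.01 and count > 2 (i.e. >= 3). Raw (unbalanced) counts are
tested. Trans pairs use a uniform prior over all possible trans pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .contact import ContactMatrix

__all__ = [
    "ExpectedModel",
    "fit_expected",
    "call_cis",
    "call_trans",
    "homoeolog_fraction",
    "write_bedpe",
]

CALL_COLUMNS = ["bin1", "bin2", "count", "prob", "pvalue", "qvalue", "significant"]


@dataclass
class ExpectedModel:
    """Distance-conditional prior contact probability for cis pairs."""

    L: int
    U: int
    n_strata: int
    distances: np.ndarray  # distinct pair distances (bp), ascending
    probs: np.ndarray  # per-pair prior probability at each distance
    n_pairs_at: np.ndarray  # number of tested pairs at each distance
    N: int  # total in-range cis contacts
    n_passes: int

    def pair_prob(self, d) -> np.ndarray:
        """Prior probability for pairs at distance(s) ``d`` (must be in range)."""
        d = np.atleast_1d(np.asarray(d, dtype=float))
        idx = np.searchsorted(self.distances, d)
        if np.any(idx >= self.distances.size) or np.any(self.distances[np.clip(idx, 0, None)] != d):
            raise ValueError("distance not covered by the model")
        return self.probs[idx]


def _in_range_pairs(matrix: ContactMatrix, L: int, U: int):
    """(i, j, distance_bp, count) arrays for cis pairs with L <= d <= U."""
    bs = matrix.bins.bin_size
    ii, jj, dd, cc = [], [], [], []
    for chrom in matrix.bins.chrom_sizes:
        sl = matrix.bins.chrom_slice(chrom)
        nb = sl.stop - sl.start
        bm = matrix.mask[sl]
        max_sep = min(nb - 1, U // bs)
        for sep in range(1, max_sep + 1):
            d = sep * bs
            if d < L or d > U:
                continue
            valid = bm[: nb - sep] & bm[sep:]
            if not valid.any():
                continue
            i = np.flatnonzero(valid)
            ii.append(i + sl.start)
            jj.append(i + sep + sl.start)
            dd.append(np.full(i.size, d))
            cc.append(np.diagonal(matrix.values[sl, sl], offset=sep)[valid])
    if not ii:
        empty = np.array([])
        return empty.astype(int), empty.astype(int), empty, empty
    return (np.concatenate(ii), np.concatenate(jj), np.concatenate(dd), np.concatenate(cc))


def _fit_strata(distances, counts, b):
    """Equal-occupancy distance strata -> isotonic non-increasing per-pair prob.

    Returns (distinct_distances, per-pair prob at each distance, pairs at each
    distance), with probabilities normalised to sum to 1 over all pairs.
    """
    order = np.argsort(distances, kind="stable")
    d_sorted = distances[order]
    c_sorted = counts[order]
    dist_vals, start_idx = np.unique(d_sorted, return_index=True)
    n_classes = dist_vals.size
    b_eff = min(b, n_classes)
    if b_eff < b:
        warnings.warn(f"only {n_classes} distinct distances; using {b_eff} strata")
    class_counts = np.add.reduceat(c_sorted, start_idx)
    class_pairs = np.diff(np.append(start_idx, d_sorted.size))
    total = class_counts.sum()
    # cut distance classes into b_eff strata of ~equal contact occupancy
    target = total / b_eff if total > 0 else 0
    strata = np.zeros(n_classes, dtype=int)
    acc, s = 0.0, 0
    for k in range(n_classes):
        strata[k] = s
        acc += class_counts[k]
        if total > 0 and acc >= target * (s + 1) and s < b_eff - 1:
            s += 1
    n_strata = s + 1
    s_counts = np.bincount(strata, weights=class_counts, minlength=n_strata)
    s_pairs = np.bincount(strata, weights=class_pairs, minlength=n_strata)
    s_dist = np.bincount(strata, weights=dist_vals * class_pairs, minlength=n_strata) / s_pairs
    with np.errstate(divide="ignore", invalid="ignore"):
        s_prob = np.where(s_pairs > 0, s_counts / max(total, 1) / s_pairs, 0.0)
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    s_prob_smooth = iso.fit_transform(s_dist, s_prob, sample_weight=s_pairs)
    class_prob = s_prob_smooth[strata]
    norm = float((class_prob * class_pairs).sum())
    if norm > 0:
        class_prob = class_prob / norm
    return dist_vals, class_prob, class_pairs, n_strata


def fit_expected(
    matrix: ContactMatrix,
    L: int = 20_000,
    U: int = 2_000_000,
    b: int = 200,
    passes: int = 2,
    alpha_p: float = 0.01,
    alpha_q: float = 0.01,
    min_count: int = 3,
) -> ExpectedModel:
    """Fit the distance-decay prior on raw cis counts in [L, U].

    Pass 2 (and beyond) refits the strata after removing pairs the previous
    pass called significant, so strong point interactions do not inflate
    their own expectation.
    """
    i, j, d, c = _in_range_pairs(matrix, L, U)
    if d.size == 0:
        raise ValueError("no cis pairs in the distance range")
    N = int(round(c.sum()))
    keep = np.ones(d.size, dtype=bool)
    model = None
    for p in range(max(1, passes)):
        dist_vals, class_prob, _, n_strata = _fit_strata(d[keep], c[keep], b)
        # probabilities renormalised over *all* in-range pairs
        # exact at surviving distance classes; interpolates any class whose
        # pairs were all removed in an earlier pass
        probs_all = np.interp(d, dist_vals, class_prob)
        norm = probs_all.sum()
        if norm > 0:
            probs_all /= norm
        all_dists, inv = np.unique(d, return_inverse=True)
        # per-distance prob (identical within a distance class by construction)
        per_dist = np.zeros(all_dists.size)
        per_dist[inv] = probs_all
        n_pairs_at = np.bincount(inv, minlength=all_dists.size)
        model = ExpectedModel(L, U, n_strata, all_dists, per_dist, n_pairs_at, N, p + 1)
        if p + 1 < max(1, passes):
            pv = stats.binom.sf(np.round(c).astype(int) - 1, N, probs_all)
            qv = stats.false_discovery_control(pv, method="bh")
            sig = (pv < alpha_p) & (qv < alpha_q) & (c >= min_count)
            if not sig.any():
                model.n_passes = max(1, passes)
                break
            keep = ~sig
    return model


def _calls_frame(bin1, bin2, count, prob, alpha_p, alpha_q, min_count):
    count_int = np.round(count).astype(int)
    N = int(count_int.sum())
    pvalue = stats.binom.sf(count_int - 1, N, prob) if N > 0 else np.ones_like(prob)
    qvalue = stats.false_discovery_control(pvalue, method="bh") if pvalue.size else pvalue
    significant = (pvalue < alpha_p) & (qvalue < alpha_q) & (count_int >= min_count)
    return pd.DataFrame(
        {
            "bin1": bin1,
            "bin2": bin2,
            "count": count_int,
            "prob": prob,
            "pvalue": pvalue,
            "qvalue": qvalue,
            "significant": significant,
        }
    )


def call_cis(
    matrix: ContactMatrix,
    model: ExpectedModel,
    alpha_p: float = 0.01,
    alpha_q: float = 0.01,
    min_count: int = 3,
) -> pd.DataFrame:
    """Test every in-range cis pair against the expected model.

    Pairs outside [L, U] are excluded from testing entirely. Returns one row
    per tested pair with columns bin1, bin2, count, prob, pvalue, qvalue,
    significant.
    """
    i, j, d, c = _in_range_pairs(matrix, model.L, model.U)
    if d.size == 0:
        return pd.DataFrame(columns=CALL_COLUMNS)
    prob = model.pair_prob(d)
    count_int = np.round(c).astype(int)
    pvalue = stats.binom.sf(count_int - 1, model.N, prob)
    qvalue = stats.false_discovery_control(pvalue, method="bh")
    significant = (pvalue < alpha_p) & (qvalue < alpha_q) & (count_int >= min_count)
    return pd.DataFrame(
        {
            "bin1": i,
            "bin2": j,
            "count": count_int,
            "prob": prob,
            "pvalue": pvalue,
            "qvalue": qvalue,
            "significant": significant,
        }
    )


def call_trans(
    matrix: ContactMatrix,
    alpha_p: float = 0.01,
    alpha_q: float = 0.01,
    min_count: int = 3,
) -> pd.DataFrame:
    """Test trans (inter-chromosomal) pairs against a uniform prior.

    The prior for every possible unmasked trans pair is 1 / (number of such
    pairs); the binomial total is the observed trans contact count.
    """
    n = matrix.n_bins
    cis2d = matrix.cis_mask_2d()
    mask2d = np.outer(matrix.mask, matrix.mask)
    iu = np.triu_indices(n, k=1)
    sel = (~cis2d[iu]) & mask2d[iu]
    i, j = iu[0][sel], iu[1][sel]
    c = matrix.values[i, j]
    if i.size == 0 or c.sum() == 0:
        return pd.DataFrame(columns=CALL_COLUMNS)
    prob = np.full(i.size, 1.0 / i.size)
    return _calls_frame(i, j, c, prob, alpha_p, alpha_q, min_count)


def homoeolog_fraction(matrix: ContactMatrix, pairing: list[tuple[str, str]]) -> pd.DataFrame:
    """Fraction of each chromosome's trans contacts that hit its homoeolog.

    ``pairing`` lists (chrom, homoeolog) partners (each pair once or twice;
    both directions are reported). Chromosomes absent from the pairing are
    excluded with a warning. Returns a DataFrame with per-chromosome
    fractions; ``df.attrs["range"]`` holds the (min, max) fraction.
    """
    partner: dict[str, str] = {}
    for a, b in pairing:
        partner[a] = b
        partner[b] = a
    names = matrix.bins.chrom_sizes.names
    missing = [c for c in names if c not in partner]
    if missing:
        warnings.warn(f"chromosomes without homoeolog pairing excluded: {missing}")
    rows = []
    cis2d = matrix.cis_mask_2d()
    chrom_idx = matrix.bins.chrom_of(np.arange(matrix.n_bins))
    for c in names:
        if c not in partner:
            continue
        h = partner[c]
        ci = names.index(c)
        hi = names.index(h)
        rows_c = chrom_idx == ci
        trans_total = matrix.values[rows_c][:, ~rows_c].sum()
        to_h = matrix.values[rows_c][:, chrom_idx == hi].sum()
        frac = float(to_h / trans_total) if trans_total > 0 else np.nan
        rows.append({"chrom": c, "homoeolog": h, "homoeolog_contacts": to_h, "trans_contacts": trans_total, "fraction": frac})
    df = pd.DataFrame(rows)
    if len(df) and df["fraction"].notna().any():
        df.attrs["range"] = (float(df["fraction"].min()), float(df["fraction"].max()))
    else:
        df.attrs["range"] = (np.nan, np.nan)
    return df


def write_bedpe(calls: pd.DataFrame, bins, path) -> None:
    """Emit interaction calls as BEDPE with count, P, q and the flag."""
    with open(path, "w") as fh:
        for k, row in enumerate(calls.itertuples(index=False)):
            c1, s1, e1 = bins.bin_interval(int(row.bin1))
            c2, s2, e2 = bins.bin_interval(int(row.bin2))
            fh.write(
                f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}\tint{k}\t{row.count}\t"
                f"{row.pvalue:.6g}\t{row.qvalue:.6g}\t{int(row.significant)}\n"
            )
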