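"""End-to-end recovery experiments on planted synthetic truth.

Each function simulates data with the generators in :mod:`hicks.synth`,
runs the corresponding pipeline stage exactly as a user would, and reports
how well the planted ground truth is recovered. These are the package's
self-calibration experiments: they quantify, under stated simulation
conditions, the label accuracy, boundary recall/precision, exponent error,
false-discovery rate and module-recovery F1 the methods achieve.
"""

from __future__ import annotations

import numpy as np

from . import compartments as comp_mod
from . import contact, core, decay, interactions, network, synth, tads


def _balanced(matrix, max_iter=2000, tol=1e-10):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return contact.ice_balance(contact.mask_low_coverage(matrix), max_iter=max_iter, tol=tol)


def ice_equivalence(n_matrices: int = 50, n_bins: int = 200, seed: int = 0) -> dict:
    """Balance random dense matrices; report worst row-sum deviation and
    planted-bias recovery.

    Row sums of every balanced matrix are compared pairwise (max relative
    deviation from the mean). Bias recovery correlates the estimated bias
    with a planted multiplicative bias on a flat-decay Poisson simulation,
    where the planted bias is the only row-wise factor.
    """
    rng = np.random.default_rng(seed)
    bins = core.make_bins(core.ChromSizes([("chr1", n_bins)]), 1)
    worst = 0.0
    for _ in range(n_matrices):
        v = rng.random((n_bins, n_bins)) + 0.05
        m = contact.ContactMatrix(bins, np.triu(v) + np.triu(v, 1).T)
        bal = contact.ice_balance(m, max_iter=5000, tol=1e-14)
        marg = bal.marginals()[bal.mask]
        worst = max(worst, float(np.abs(marg - marg.mean()).max() / marg.mean()))

    cs = core.ChromSizes([("chr1", 8_000_000)])
    gb = core.make_bins(cs, 40_000)
    bias = rng.uniform(0.5, 2.0, gb.n_bins)
    spec = synth.SyntheticSpec(cs, 40_000, decay_exponent=0.0, bias=bias,
                               cis_depth=500_000, seed=int(rng.integers(2**31)))
    recs, truth = synth.simulate_hic(spec)
    bal = _balanced(contact.bin_pairs(recs, gb), max_iter=5000, tol=1e-14)
    r = float(np.corrcoef(bal.bias[bal.mask], truth["bias"][bal.mask])[0, 1])
    return {"max_rowsum_rel_dev": worst, "bias_recovery_r": r,
            "n": n_matrices}


def ide_recovery(n_seeds: int = 10, exponent: float = -0.85, genome_mb: int = 20,
                 bin_size: int = 40_000, depth: float = 500_000, seed: int = 0) -> dict:
    """Recover a planted decay exponent from Poisson pair simulations."""
    errors = []
    for k in range(n_seeds):
        cs = core.ChromSizes([("chr1", genome_mb * 1_000_000)])
        spec = synth.SyntheticSpec(cs, bin_size, decay_exponent=exponent,
                                   cis_depth=depth, seed=seed * 1000 + k)
        recs, _ = synth.simulate_hic(spec)
        bal = _balanced(contact.bin_pairs(recs, spec.bins()))
        fit = decay.fit_ide(decay.decay_curve(bal), bin_size=bin_size)
        errors.append(abs(fit.exponent - exponent))
    return {"mean_abs_error": float(np.mean(errors)), "errors": errors,
            "planted_exponent": exponent, "n": n_seeds}


def _orientation_track(bins, states, rng):
    # gene density: planted-active bins gene-dense, plus measurement noise
    vals = np.where(states > 0, 10.0, 2.0) + rng.normal(0, 0.5, bins.n_bins)
    return core.BinTrack(bins, vals)


def compartment_recovery(seed: int = 7, delta: float = 0.3,
                         depth_per_chrom: float = 200_000) -> dict:
    """Label accuracy of PC1 compartment calls on a planted checkerboard."""
    rng = np.random.default_rng(seed)
    cs = core.ChromSizes([("chr1", 10_000_000), ("chr2", 10_000_000)])
    bins = core.make_bins(cs, 100_000)
    states = synth.random_compartment_states(bins, rng)
    spec = synth.SyntheticSpec(cs, 100_000, compartment_delta=delta,
                               compartment_states=states,
                               cis_depth=depth_per_chrom * 2, seed=seed)
    recs, _ = synth.simulate_hic(spec)
    bal = _balanced(contact.bin_pairs(recs, bins))
    call = comp_mod.call_compartments(bal, _orientation_track(bins, states, rng))
    truth_labels = np.where(states > 0, "A", "B")
    ok = call.labels != "NA"
    accuracy = float((call.labels[ok] == truth_labels[ok]).mean())
    return {"label_accuracy": accuracy, "n": int(ok.sum())}


def compartment_flip_recovery(n_seeds: int = 10, n_flips: int = 6, seed: int = 0) -> dict:
    """Recall of planted A/B flips in two-condition differential calls."""
    recalls = []
    for k in range(n_seeds):
        s = seed * 1000 + k
        rng = np.random.default_rng(s)
        cs = core.ChromSizes([("chr1", 10_000_000), ("chr2", 10_000_000)])
        bins = core.make_bins(cs, 100_000)
        states = synth.random_compartment_states(bins, rng)
        # two 3-bin flip runs, one per chromosome, away from chromosome ends
        flips = [15, 16, 17, 115, 116, 117][:n_flips]
        spec = synth.SyntheticSpec(cs, 100_000, compartment_delta=0.3,
                                   compartment_states=states, cis_depth=400_000, seed=s)
        recs1, recs2, truth = synth.simulate_condition_pair(spec, flips=flips)
        calls = []
        for recs, st in ((recs1, states), (recs2, truth["compartment_states2"])):
            bal = _balanced(contact.bin_pairs(recs, bins))
            gd = core.BinTrack(bins, np.where(st > 0, 10.0, 2.0))
            calls.append(comp_mod.call_compartments(bal, gd))
        diff = comp_mod.differential_compartments(calls[0], calls[1])
        found = set(diff.bin_indices())
        recalls.append(len(found & set(flips)) / len(flips))
    return {"mean_recall": float(np.mean(recalls)), "recalls": recalls, "n": n_seeds}


def tad_boundary_recovery(n_seeds: int = 10, tau: float = 2.0,
                          depth: float = 300_000, seed: int = 0) -> dict:
    """Recall/precision of planted TAD boundaries within +/-1 bin."""
    planted = [30, 80, 140]
    hits = n_called = 0
    for k in range(n_seeds):
        cs = core.ChromSizes([("chr1", 8_000_000)])
        spec = synth.SyntheticSpec(cs, 40_000, tad_boundaries=planted, tad_tau=tau,
                                   cis_depth=depth, seed=seed * 1000 + k + 11)
        recs, _ = synth.simulate_hic(spec)
        bal = _balanced(contact.bin_pairs(recs, spec.bins()))
        tadset = tads.call_boundaries(tads.insulation_track(bal, 10))
        called = tadset.boundary_bins()
        n_called += len(called)
        hits += sum(1 for p in planted if any(abs(c - p) <= 1 for c in called))
    return {
        "recall": hits / (n_seeds * len(planted)),
        "precision": hits / max(n_called, 1),
        "n": n_seeds,
    }


def diff_insulation_recovery(n_seeds: int = 10, seed: int = 0) -> dict:
    """Overlap of called differential-insulation regions with a planted
    boundary-reorganised segment; identical tracks must yield zero regions."""
    bins = core.make_bins(core.ChromSizes([("chr1", 70)]), 1)
    overlaps = []
    n_regions_identical = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed * 1000 + k)
        i = np.arange(70)
        base = 0.3 * np.sin(2 * np.pi * i / 14) + 0.05 * rng.standard_normal(70)
        v2 = base.copy()
        seg = np.arange(20, 50)
        v2[20:50] = 0.3 * np.sin(2 * np.pi * seg / 14 + np.pi) + 0.05 * rng.standard_normal(30)
        t1 = tads.InsulationTrack(bins, base, np.isfinite(base), 5)
        t2 = tads.InsulationTrack(bins, v2, np.isfinite(v2), 5)
        regions = tads.differential_insulation(t1, t2)
        covered = set()
        for r in regions:
            covered |= set(range(r.start_bin, r.end_bin))
        overlaps.append(len(covered & set(range(20, 50))) / 30)
        n_regions_identical += len(tads.differential_insulation(t1, t1))
    return {"mean_overlap": float(np.mean(overlaps)), "overlaps": overlaps,
            "n_regions_on_identical_tracks": n_regions_identical, "n": n_seeds}


def _null_matrix_and_model(seed, depth=50_000):
    cs = core.ChromSizes([("chr1", 2_000_000)])
    bins = core.make_bins(cs, 10_000)
    n = bins.n_bins
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    E = np.where(d > 0, np.maximum(d, 1) ** -0.9, 1.0)
    E *= depth / np.triu(E).sum()
    base = contact.ContactMatrix(bins, np.round(E * 100))
    model = interactions.fit_expected(base, b=50, passes=1)
    return bins, base, model, depth


def significance_null_rate(n_seeds: int = 10, seed: int = 0) -> dict:
    """Empirical rate of q < 0.01 calls when counts are drawn from the
    fitted expected model itself (null self-consistency of the caller)."""
    bins, base, model, depth = _null_matrix_and_model(seed)
    n = bins.n_bins
    rates = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed * 1000 + k + 100)
        i, j, dd, _ = interactions._in_range_pairs(base, model.L, model.U)
        p = model.pair_prob(dd)
        counts = rng.multinomial(int(depth), p / p.sum())
        v = np.zeros((n, n))
        v[i, j] = counts
        m = contact.ContactMatrix(bins, v + np.triu(v, 1).T)
        null_model = interactions.fit_expected(m, b=50, passes=2)
        calls = interactions.call_cis(m, null_model)
        rates.append(float((calls.qvalue < 0.01).mean()))
    return {"mean_null_rate": float(np.mean(rates)), "rates": rates, "n": n_seeds}


def boosted_pair_detection(n_seeds: int = 10, boost: float = 20.0,
                           depth: float = 100_000, seed: int = 0) -> dict:
    """Detection rate of one pair boosted far above its distance expectation,
    and the count>2 filter on a planted low-count pair."""
    cs = core.ChromSizes([("chr1", 3_000_000)])
    bins = core.make_bins(cs, 10_000)
    n = bins.n_bins
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    E0 = np.where(d > 0, np.maximum(d, 1) ** -1.0, 1.0)
    E0 *= depth / np.triu(E0).sum()
    detected = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed * 1000 + k)
        E = E0.copy()
        E[40, 60] *= boost
        E[60, 40] = E[40, 60]
        counts = rng.poisson(np.triu(E))
        m = contact.ContactMatrix(bins, counts + np.triu(counts, 1).T)
        model = interactions.fit_expected(m, b=50, passes=2)
        calls = interactions.call_cis(m, model)
        hit = calls[(calls.bin1 == 40) & (calls.bin2 == 60)]
        if len(hit) and bool(hit.significant.iloc[0]):
            detected += 1
    # count = 2 must never pass the filter, whatever its P value
    v = np.zeros((n, n))
    for start in range(0, n - 5, 3):
        v[start, start + 5] = 1.0
    v[0, 5] = 2.0
    m2 = contact.ContactMatrix(bins, v + np.triu(v, 1).T)
    model2 = interactions.fit_expected(m2, b=10, passes=1)
    calls2 = interactions.call_cis(m2, model2)
    row = calls2[(calls2.bin1 == 0) & (calls2.bin2 == 5)]
    count2_called = bool(row.significant.iloc[0]) if len(row) else False
    return {"detection_rate": detected / n_seeds, "count2_significant": count2_called,
            "n": n_seeds}


def map_resolution_check(seed: int = 0) -> dict:
    """The 80%-of-bins >= 1000-contacts rule at two depths (monotone)."""
    rng = np.random.default_rng(seed)
    cs = core.ChromSizes([("chr1", 200_000)])
    base = [
        contact.ValidPairRecord("chr1", int(rng.integers(0, 200_000)),
                                "chr1", int(rng.integers(0, 200_000)))
        for _ in range(3000)
    ]
    candidates = [10_000, 20_000, 50_000, 100_000, 200_000]
    shallow = contact.map_resolution(base, cs, candidates)
    deep = contact.map_resolution(base * 10, cs, candidates)
    rank = {None: np.inf}
    monotone = rank.get(deep, deep) <= rank.get(shallow, shallow)
    return {"resolution_shallow_bp": shallow, "resolution_deep_bp": deep,
            "monotone_in_depth": bool(monotone), "n": len(base)}


def network_recovery(n_seeds: int = 10, rho: float = 0.95, seed: int = 0) -> dict:
    """F1 of recovering a planted correlated 20-gene module."""
    f1s = []
    for k in range(n_seeds):
        genes, metab, truth = synth.simulate_omics(200, 5, 12, planted=(20, 0, rho),
                                                   seed=seed * 1000 + k + 4)
        edges = network.correlate(genes, metab, threshold=0.8)
        found = set(network.top_candidates(edges, ["m0"], r2_threshold=0.8))
        planted = set(truth["planted_genes"])
        tp = len(found & planted)
        prec = tp / max(len(found), 1)
        rec = tp / len(planted)
        f1s.append(2 * prec * rec / max(prec + rec, 1e-12))
    return {"mean_f1": float(np.mean(f1s)), "f1s": f1s, "n": n_seeds}
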