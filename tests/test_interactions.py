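"""Fit-Hi-C-style expected model, significant interaction calls, homoeolog fractions."""

import numpy as np
import pytest
from scipy import stats

from hicks import contact, core, interactions, synth


def decay_matrix(bins, exponent=-1.0, scale=100.0):
    n = bins.n_bins
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    v = scale * np.where(d > 0, np.maximum(d, 1) ** exponent, 1.0)
    return contact.ContactMatrix(bins, np.round(v))


@pytest.fixture
def bins10kb():
    # 3 Mb at 10 kb: separations 10 kb .. 2.99 Mb
    return core.make_bins(core.ChromSizes([("chr1", 3_000_000)]), 10_000)


class TestFitExpected:
    def test_power_law_counts_give_power_law_expectation(self, bins10kb):
        m = decay_matrix(bins10kb, exponent=-1.0, scale=100_000.0)
        model = interactions.fit_expected(m, L=20_000, U=2_000_000, b=50, passes=1)
        # the smoothed probability is flat within an equal-occupancy stratum;
        # at each stratum's occupancy-weighted mean distance it must track
        # d^-1 within 1% relative
        sel = model.n_pairs_at > 0
        d, p, w = model.distances[sel], model.probs[sel], model.n_pairs_at[sel]
        strata = np.unique(p)[::-1]
        for sp in strata:
            grp = p == sp
            dbar = np.average(d[grp], weights=w[grp])
            assert abs(sp * dbar / (p[0] * d[0]) - 1.0) < 0.01

    def test_uniform_counts_give_constant_expectation(self, bins10kb):
        n = bins10kb.n_bins
        m = contact.ContactMatrix(bins10kb, np.full((n, n), 5.0))
        model = interactions.fit_expected(m, b=50, passes=1)
        assert np.allclose(model.probs, model.probs[0])

    def test_prior_sums_to_one_over_tested_pairs(self, bins10kb):
        rng = np.random.default_rng(0)
        n = bins10kb.n_bins
        v = rng.poisson(5, (n, n)).astype(float)
        m = contact.ContactMatrix(bins10kb, np.triu(v) + np.triu(v, 1).T)
        model = interactions.fit_expected(m, b=100, passes=2)
        total = float((model.probs * model.n_pairs_at).sum())
        assert abs(total - 1.0) < 1e-3

    def test_outlier_pair_lowers_second_pass_expectation(self, bins10kb):
        m = decay_matrix(bins10kb, exponent=-1.0, scale=200.0)
        i, j = 10, 15  # 50 kb apart, inside [L, U]
        m.values[i, j] = m.values[j, i] = 50_000.0
        m1 = interactions.fit_expected(m, b=50, passes=1)
        m2 = interactions.fit_expected(m, b=50, passes=2)
        d = (j - i) * 10_000
        assert m2.pair_prob(d)[0] < m1.pair_prob(d)[0]

    def test_too_few_distances_reduces_strata_with_warning(self):
        bins = core.make_bins(core.ChromSizes([("chr1", 100_000)]), 10_000)
        m = decay_matrix(bins, scale=50.0)
        with pytest.warns(UserWarning, match="strata"):
            model = interactions.fit_expected(m, L=10_000, U=90_000, b=200, passes=1)
        assert model.n_strata < 200


class TestCallCis:
    def test_count_two_never_significant(self, bins10kb):
        # even a vanishing P value cannot rescue a count of 2
        m = decay_matrix(bins10kb, exponent=-1.0, scale=0.0)
        n = bins10kb.n_bins
        v = np.zeros((n, n))
        for k in range(0, n - 5, 3):
            v[k, k + 5] = v[k + 5, k] = 1.0
        v[0, 5] = v[5, 0] = 2.0
        m = contact.ContactMatrix(bins10kb, v)
        model = interactions.fit_expected(m, b=10, passes=1)
        calls = interactions.call_cis(m, model)
        sub = calls[(calls.bin1 == 0) & (calls.bin2 == 5)]
        assert not bool(sub.significant.iloc[0])
        assert int(sub["count"].iloc[0]) == 2

    def test_boosted_pair_is_called(self):
        # a pair boosted far above expectation must be significant
        cs = core.ChromSizes([("chr1", 3_000_000)])
        bins = core.make_bins(cs, 10_000)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = bins.n_bins
            idx = np.arange(n)
            d = np.abs(idx[:, None] - idx[None, :]).astype(float)
            E = np.where(d > 0, np.maximum(d, 1) ** -1.0, 1.0)
            E *= 100_000 / np.triu(E).sum()
            E[40, 60] = E[60, 40] = E[40, 60] * 20.0
            counts = rng.poisson(np.triu(E))
            m = contact.ContactMatrix(bins, counts + np.triu(counts, 1).T)
            model = interactions.fit_expected(m, b=50, passes=2)
            calls = interactions.call_cis(m, model)
            hit = calls[(calls.bin1 == 40) & (calls.bin2 == 60)]
            assert bool(hit.significant.iloc[0]), f"seed {seed}"

    def test_null_fdr_controlled(self):
        # counts drawn from the fitted model itself: q < 0.01 calls ~ none
        cs = core.ChromSizes([("chr1", 2_000_000)])
        bins = core.make_bins(cs, 10_000)
        n = bins.n_bins
        idx = np.arange(n)
        d = np.abs(idx[:, None] - idx[None, :]).astype(float)
        E = np.where(d > 0, np.maximum(d, 1) ** -0.9, 1.0)
        E *= 50_000 / np.triu(E).sum()
        base = contact.ContactMatrix(bins, np.round(E * 100))
        model = interactions.fit_expected(base, b=50, passes=1)
        rates = []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            probs = []
            i, j, dd, _ = interactions._in_range_pairs(base, model.L, model.U)
            p = model.pair_prob(dd)
            counts = rng.multinomial(50_000, p / p.sum())
            v = np.zeros((n, n))
            v[i, j] = counts
            m = contact.ContactMatrix(bins, v + np.triu(v, 1).T)
            null_model = interactions.fit_expected(m, b=50, passes=2)
            calls = interactions.call_cis(m, null_model)
            rates.append((calls.qvalue < 0.01).mean())
        assert np.mean(rates) <= 0.02

    def test_bh_monotone_in_alpha(self, bins10kb):
        rng = np.random.default_rng(1)
        n = bins10kb.n_bins
        v = rng.poisson(3, (n, n)).astype(float)
        m = contact.ContactMatrix(bins10kb, np.triu(v) + np.triu(v, 1).T)
        model = interactions.fit_expected(m, b=50, passes=1)
        strict = interactions.call_cis(m, model, alpha_q=0.001)
        loose = interactions.call_cis(m, model, alpha_q=0.01)
        assert set(map(tuple, strict[strict.significant][["bin1", "bin2"]].values)) <= set(
            map(tuple, loose[loose.significant][["bin1", "bin2"]].values)
        )

    def test_out_of_range_pairs_never_tested(self, bins10kb):
        m = decay_matrix(bins10kb, scale=100.0)
        model = interactions.fit_expected(m, L=20_000, U=200_000, b=20, passes=1)
        calls = interactions.call_cis(m, model)
        seps = (calls.bin2 - calls.bin1) * 10_000
        assert seps.min() >= 20_000 and seps.max() <= 200_000


class TestCallTrans:
    def _two_chrom_matrix(self, trans_values):
        cs = core.ChromSizes([("chr1", 200_000), ("chr2", 200_000)])
        bins = core.make_bins(cs, 10_000)
        n = bins.n_bins
        v = np.zeros((n, n))
        v[:20, 20:] = trans_values
        v[20:, :20] = trans_values.T
        return contact.ContactMatrix(bins, v), bins

    def test_uniform_trans_yields_no_calls(self):
        m, _ = self._two_chrom_matrix(np.full((20, 20), 5.0))
        calls = interactions.call_trans(m)
        assert int(calls.significant.sum()) == 0

    def test_hot_pair_detected(self):
        tv = np.full((20, 20), 2.0)
        tv[3, 7] = 120.0  # ~10% of all trans contacts in one pair
        m, _ = self._two_chrom_matrix(tv)
        calls = interactions.call_trans(m)
        hit = calls[(calls.bin1 == 3) & (calls.bin2 == 27)]
        assert bool(hit.significant.iloc[0])

    def test_empty_trans_gives_empty_frame(self):
        m, _ = self._two_chrom_matrix(np.zeros((20, 20)))
        calls = interactions.call_trans(m)
        assert len(calls) == 0


class TestHomoeologFraction:
    def _matrix(self, n_chrom=4, boost_pairs=(), boost=1.0):
        cs = core.ChromSizes([(f"chr{i+1}", 100_000) for i in range(n_chrom)])
        bins = core.make_bins(cs, 100_000)
        spec = synth.SyntheticSpec(
            cs, 100_000, cis_depth=0.0, trans_depth=60_000,
            homoeolog_pairs=list(boost_pairs), homoeolog_boost=boost, seed=5,
        )
        recs, truth = synth.simulate_hic(spec)
        return contact.bin_pairs(recs, bins), truth

    def test_exclusive_homoeolog_contacts_give_fraction_one(self):
        cs = core.ChromSizes([(f"chr{i+1}", 100_000) for i in range(4)])
        bins = core.make_bins(cs, 100_000)
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = 50.0
        v[2, 3] = v[3, 2] = 30.0
        m = contact.ContactMatrix(bins, v)
        df = interactions.homoeolog_fraction(m, [("chr1", "chr2"), ("chr3", "chr4")])
        assert np.allclose(df["fraction"], 1.0)

    def test_uniform_trans_gives_one_over_n_minus_one(self):
        n = 16
        cs = core.ChromSizes([(f"chr{i+1}", 100_000) for i in range(n)])
        bins = core.make_bins(cs, 100_000)
        v = np.ones((n, n)) - np.eye(n)
        m = contact.ContactMatrix(bins, v)
        pairing = [(f"chr{2*i+1}", f"chr{2*i+2}") for i in range(n // 2)]
        df = interactions.homoeolog_fraction(m, pairing)
        assert np.allclose(df["fraction"], 1.0 / (n - 1))

    def test_boosted_pairing_matches_generator_expectation(self):
        pairing = [("chr1", "chr2"), ("chr3", "chr4")]
        m, truth = self._matrix(4, pairing, boost=3.0)
        df = interactions.homoeolog_fraction(m, pairing)
        # expected fraction per chromosome: 3 / (3 + 2) with 3 partners, one boosted
        expected = 3.0 / 5.0
        for _, row in df.iterrows():
            n_t = row["trans_contacts"]
            se = np.sqrt(expected * (1 - expected) / n_t)
            assert abs(row["fraction"] - expected) <= 3 * se

    def test_unpaired_chromosome_excluded_with_warning(self):
        cs = core.ChromSizes([("chr1", 100_000), ("chr2", 100_000), ("chr3", 100_000)])
        bins = core.make_bins(cs, 100_000)
        v = np.ones((3, 3)) - np.eye(3)
        m = contact.ContactMatrix(bins, v)
        with pytest.warns(UserWarning, match="chr3"):
            df = interactions.homoeolog_fraction(m, [("chr1", "chr2")])
        assert set(df["chrom"]) == {"chr1", "chr2"}
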