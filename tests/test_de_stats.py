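import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from xslux import de_stats
from xslux.io_formats import CountMatrix


def _matrix(values, species="Xx"):
    values = np.asarray(values)
    counts = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    lengths = pd.Series(1000, index=counts.index)
    return CountMatrix(species, counts, lengths)


def _samples(n_hl, n_ll, species="Xx"):
    n = n_hl + n_ll
    return pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(n)],
            "species_id": [species] * n,
            "treatment": ["HL"] * n_hl + ["LL"] * n_ll,
            "replicate": list(range(1, n_hl + 1)) + list(range(1, n_ll + 1)),
        }
    )


class TestSizeFactors:
    def test_doubled_sample(self):
        cm = _matrix([[10, 20], [50, 100], [3, 6]])
        sf = de_stats.size_factors(cm)
        assert sf.to_numpy() == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_samples(self):
        cm = _matrix([[10, 10, 10], [7, 7, 7]])
        assert de_stats.size_factors(cm).to_numpy() == pytest.approx([1, 1, 1])

    def test_no_common_nonzero_gene_is_error(self):
        cm = _matrix([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            de_stats.size_factors(cm)

    def test_matches_reference_median_of_ratios_implementation(self):
        # independent cross-check against the DESeq2 reference implementation
        # (identical up to the geometric-mean-1 rescaling convention)
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.integers(1, 1000, size=(8, 60)),
            index=[f"s{j}" for j in range(8)],
            columns=[f"g{i}" for i in range(60)],
        )
        meta = pd.DataFrame(
            {"condition": ["A"] * 4 + ["B"] * 4}, index=counts.index
        )
        dds = DeseqDataSet(
            counts=counts, metadata=meta, design="~condition", quiet=True
        )
        dds.fit_size_factors()
        ref = dds.obs["size_factors"].to_numpy()
        ref = ref / np.exp(np.mean(np.log(ref)))
        cm = _matrix(counts.T.to_numpy())
        assert de_stats.size_factors(cm).to_numpy() == pytest.approx(ref)

    @given(st.integers(0, 2**31 - 1), st.floats(0.25, 4.0))
    def test_scaling_one_sample_scales_its_factor(self, seed, c):
        rng = np.random.default_rng(seed)
        values = rng.integers(1, 1000, size=(30, 4))
        sf = de_stats.size_factors(_matrix(values))
        scaled = values.astype(float).copy()
        scaled[:, 0] = np.round(scaled[:, 0] * c)
        # rounding to integers perturbs the ratio slightly
        sf2 = de_stats.size_factors(_matrix(scaled.astype(int)))
        ratio = (sf2 / sf).to_numpy()
        # factor of sample 0 grows ~c relative to the others
        assert ratio[0] / ratio[1:].mean() == pytest.approx(c, rel=0.05)
        assert np.exp(np.mean(np.log(sf2))) == pytest.approx(1.0)


class TestDispersion:
    def test_constant_gene_gets_zero(self):
        norm = pd.DataFrame([[10.0, 10, 10, 10]], index=["g0"],
                            columns=[f"s{j}" for j in range(4)])
        alpha = de_stats.estimate_dispersion(norm, _samples(2, 2))
        assert alpha["g0"] == 0.0

    def test_poisson_alpha_vanishes_with_replicates(self):
        rng = np.random.default_rng(3)
        n = 200
        values = rng.poisson(200, size=(500, 2 * n))
        norm = pd.DataFrame(values.astype(float),
                            columns=[f"s{j}" for j in range(2 * n)],
                            index=[f"g{i}" for i in range(500)])
        alpha = de_stats.estimate_dispersion(norm, _samples(n, n))
        assert np.median(alpha) < 0.002

    def test_nb_alpha_recovered(self):
        rng = np.random.default_rng(4)
        alpha_true, mu, n = 0.1, 300.0, 50
        r = 1 / alpha_true
        values = rng.negative_binomial(r, r / (r + mu), size=(800, 2 * n))
        norm = pd.DataFrame(values.astype(float),
                            columns=[f"s{j}" for j in range(2 * n)],
                            index=[f"g{i}" for i in range(800)])
        alpha = de_stats.estimate_dispersion(norm, _samples(n, n))
        assert np.median(alpha) == pytest.approx(alpha_true, abs=0.03)


class TestAdjustBH:
    def test_step_up_forces_equal_values(self):
        out = de_stats.adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert de_stats.adjust_bh([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de_stats.adjust_bh([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_manual_step_up(self, pvals):
        out = de_stats.adjust_bh(pvals)
        # independent step-up oracle
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expected[i] = running
        assert out == pytest.approx(expected)
        assert (out >= p - 1e-12).all() and (out <= 1 + 1e-12).all()


class TestWaldDETest:
    def test_identical_samples_make_no_calls(self):
        cm = _matrix(np.tile([[50], [200], [7]], (1, 8)))
        res = de_stats.wald_de_test(cm, _samples(4, 4))
        tested = res[res["call"] != "untested"]
        assert (tested["log2fc"] == 0).all()
        assert not (tested["call"].isin(["up", "down"])).any()

    def test_requires_two_replicates(self):
        cm = _matrix([[5, 5, 5]])
        with pytest.raises(ValueError):
            de_stats.wald_de_test(cm, _samples(1, 2))

    def test_low_expression_genes_untested(self):
        rng = np.random.default_rng(5)
        values = rng.poisson(100, size=(50, 8))
        values[0] = 0  # all-zero gene
        res = de_stats.wald_de_test(_matrix(values), _samples(4, 4))
        assert res.iloc[0]["call"] == "untested"
        assert np.isnan(res.iloc[0]["padj"])
        # the bottom decile of expressed genes is filtered too
        assert (res["call"] == "untested").sum() >= 4

    def test_doubling_one_sample_leaves_log2fc_invariant(self):
        rng = np.random.default_rng(6)
        values = rng.poisson(300, size=(60, 8))
        res1 = de_stats.wald_de_test(_matrix(values), _samples(4, 4))
        doubled = values.copy()
        doubled[:, 0] *= 2
        res2 = de_stats.wald_de_test(_matrix(doubled), _samples(4, 4))
        keep = res1["base_mean"] > 5
        assert res2.loc[keep, "log2fc"].to_numpy() == pytest.approx(
            res1.loc[keep, "log2fc"].to_numpy(), abs=0.02
        )

    def test_planted_effects_recovered(self):
        rng = np.random.default_rng(7)
        mu = np.full(400, 400.0)
        lfc = np.zeros(400)
        lfc[:50] = 2.0  # 4-fold planted effects at high expression
        r = 1 / 0.05
        m_hl = mu * 2.0**lfc
        hl = rng.negative_binomial(r, r / (r + m_hl[:, None]), size=(400, 5))
        ll = rng.negative_binomial(r, r / (r + mu[:, None]), size=(400, 5))
        res = de_stats.wald_de_test(
            _matrix(np.hstack([hl, ll])), _samples(5, 5)
        )
        recall = (res["call"].iloc[:50] == "up").mean()
        assert recall >= 0.9

    def test_call_invariants(self, sim_bundle):
        for res in sim_bundle["de"].values():
            sig = res["padj"].notna() & (res["padj"] < 0.05)
            assert ((res["call"] == "up") == (sig & (res["log2fc"] > 0))).all()
            assert ((res["call"] == "down") == (sig & (res["log2fc"] < 0))).all()
            assert (res.loc[res["padj"].isna(), "call"] == "untested").all()


class TestDEGSummary:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((3346, 3027, 21226), (12.1, 11.0, 76.9)),
            # 32050/46480 = 68.954% -> 69.0 under consistent half-up rounding
            ((7292, 7138, 32050), (15.7, 15.4, 69.0)),
            ((4723, 4052, 50934), (7.9, 6.8, 85.3)),
            ((4284, 4334, 23900), (13.2, 13.3, 73.5)),
            ((1, 0, 0), (100.0, 0.0, 0.0)),
        ],
    )
    def test_one_decimal_percentages(self, counts, expected):
        assert de_stats.deg_percentages(*counts) == expected

    def test_percentages_sum_to_100(self, sim_bundle):
        summary = de_stats.summarize_deg_counts(sim_bundle["de"])
        sums = summary[["pct_up", "pct_down", "pct_unchanged"]].sum(axis=1)
        assert ((sums - 100).abs() <= 0.1).all()
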