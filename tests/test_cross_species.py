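import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from xslux import abundance, cross_species as cs
from xslux.io_formats import CountMatrix, HomologyTable


class TestExceedanceAndOffset:
    def test_exceedance_counts_strictly_greater(self):
        assert cs.exceedance_fraction([0.5, 1.5, 2.0, -1.0], 1.0) == 0.50

    def test_symmetric_vector_at_zero(self):
        assert cs.exceedance_fraction([-2, -1, 1, 2], 0.0) == 0.5

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=50),
        st.floats(0, 2),
    )
    def test_shift_is_monotone(self, ratios, c):
        base = cs.exceedance_fraction(ratios, 1.0)
        shifted = cs.exceedance_fraction(np.asarray(ratios) + c, 1.0)
        assert shifted >= base

    def test_offset_is_median(self):
        assert cs.baseline_offset([0.2, 0.4, 0.6]) == pytest.approx(0.4)
        assert cs.baseline_offset([0.0, 0.0]) == 0.0

    def test_empty_vector_is_error(self):
        with pytest.raises(ValueError):
            cs.exceedance_fraction([], 0.0)
        with pytest.raises(ValueError):
            cs.baseline_offset([])


class TestCorrectedRatio:
    def test_arithmetic(self):
        assert cs.corrected_ratio(8, 2, 0.5) == pytest.approx(1.5, abs=0.01)

    def test_identity(self):
        assert cs.corrected_ratio(4, 4, 0.0) == 0.0

    def test_antisymmetry(self):
        r = cs.corrected_ratio(9, 2, 0.3)
        assert cs.corrected_ratio(2, 9, -0.3) == pytest.approx(-r)


class TestBaselineSelection:
    def test_rules(self, sim_bundle):
        cls, table = sim_bundle["cls"], sim_bundle["truth"].homology
        groups = set(sim_bundle["baseline_groups"])
        assert len(groups) >= 300
        for gid in itertools.islice(groups, 50):
            assert cls.loc[gid, "membership"] == "core"
            assert cls.loc[gid, "de_status"] == "nonDE"
            for sp in sim_bundle["cfg"].species:
                genes = table.species_genes(gid, sp)
                assert len(genes) == 1
                assert sim_bundle["mean_tpm"][sp][genes[0]] >= 1.0

    def test_multi_copy_and_de_groups_excluded(self, sim_bundle):
        cls, table = sim_bundle["cls"], sim_bundle["truth"].homology
        groups = set(sim_bundle["baseline_groups"])
        focal = sim_bundle["cfg"].focal_species
        for gid in cls.index:
            if cls.loc[gid, "de_status"] == "DE":
                assert gid not in groups
            elif table.copy_number(gid, focal) > 1:
                assert gid not in groups

    def test_low_tpm_threshold_respected(self, sim_bundle):
        strict = cs.select_baseline_groups(
            sim_bundle["cls"],
            sim_bundle["truth"].homology,
            sim_bundle["mean_tpm"],
            min_tpm=50.0,
        )
        assert set(strict) <= set(sim_bundle["baseline_groups"])
        assert len(strict) < len(sim_bundle["baseline_groups"])


class TestBaselineModel:
    def test_pairwise_ratio_arithmetic(self):
        table = HomologyTable(
            {"HG1": [("A", "a1"), ("B", "b1")], "HG2": [("A", "a2"), ("B", "b2")]}
        )
        means = {
            "A": pd.Series({"a1": 4.0, "a2": 1.0}),
            "B": pd.Series({"b1": 1.0, "b2": 1.0}),
        }
        model = cs.pairwise_log2_ratios(["HG1", "HG2"], table, means)
        assert model.ratios("A", "B") == pytest.approx([2.0, 0.0])
        assert model.offset("A", "B") == pytest.approx(1.0)

    def test_antisymmetry(self, sim_bundle):
        model = sim_bundle["baseline"]
        for a, b in itertools.combinations(model.species, 2):
            assert model.ratios(a, b) == pytest.approx(-model.ratios(b, a))
            assert model.offset(a, b) == pytest.approx(-model.offset(b, a))

    def test_identical_species_vectors_give_zero(self):
        table = HomologyTable({"HG1": [("A", "a1"), ("B", "b1")]})
        means = {"A": pd.Series({"a1": 3.0}), "B": pd.Series({"b1": 3.0})}
        model = cs.pairwise_log2_ratios(["HG1"], table, means)
        assert model.offset("A", "B") == 0.0

    def test_exceedance_reflects_planted_gaps(self, sim_bundle):
        model = sim_bundle["baseline"]
        offsets = sim_bundle["truth"].offsets
        for a, b in itertools.permutations(model.species, 2):
            if offsets[a] - offsets[b] >= 0.3:
                assert model.exceedance(a, b, 0.0) > 0.5


class TestCumulativeAndPools:
    def _tpm(self):
        counts = pd.DataFrame(
            {
                "s0": [100, 120, 80, 300],
                "s1": [110, 110, 90, 310],
                "s2": [10, 10, 10, 40],
                "s3": [12, 10, 12, 38],
            },
            index=["c1", "c2", "c3", "other"],
        )
        cm = CountMatrix("Hi", counts, pd.Series(1000, index=counts.index))
        samples = pd.DataFrame(
            {
                "sample_id": ["s0", "s1", "s2", "s3"],
                "species_id": ["Hi"] * 4,
                "treatment": ["HL", "HL", "LL", "LL"],
                "replicate": [1, 2, 1, 2],
            }
        )
        return abundance.tpm(cm), samples

    def test_sum_then_average(self):
        t, samples = self._tpm()
        out = cs.cumulative_paralog_abundance(["c1", "c2", "c3"], t, samples)
        expected_hl = t.tpm.loc[["c1", "c2", "c3"], ["s0", "s1"]].sum(0).mean()
        assert out["HL"] == pytest.approx(expected_hl)

    def test_single_copy_equals_own_mean(self):
        t, samples = self._tpm()
        out = cs.cumulative_paralog_abundance(["other"], t, samples)
        assert out["LL"] == pytest.approx(t.tpm.loc["other", ["s2", "s3"]].mean())

    def test_relabeling_invariance(self):
        t, samples = self._tpm()
        a = cs.cumulative_paralog_abundance(["c1", "c2", "c3"], t, samples)
        b = cs.cumulative_paralog_abundance(["c3", "c1", "c2"], t, samples)
        assert a == b

    def test_pool_fractions(self):
        t, samples = self._tpm()
        table = HomologyTable(
            {
                "HGa": [("Hi", "c1")],
                "HGb": [("Hi", "c2")],
                "HGc": [("Hi", "other")],
            }
        )
        frac = cs.pool_fractions(
            ["HGa", "HGb", "HGc"], "Hi", "HL", table, t, samples
        )
        assert frac.sum() == pytest.approx(1.0)
        abund = {
            g: cs.cumulative_paralog_abundance(
                table.species_genes(g, "Hi"), t, samples
            )["HL"]
            for g in ["HGa", "HGb", "HGc"]
        }
        total = sum(abund.values())
        for g in abund:
            assert frac[g] == pytest.approx(abund[g] / total)

    def test_empty_pool_is_error(self):
        t, samples = self._tpm()
        with pytest.raises(ValueError):
            cs.pool_fractions([], "Hi", "HL", HomologyTable({}), t, samples)


class TestModeClassifier:
    """Constructed mini-cases where each rule fires by design."""

    def _setup(self, focal_counts, other_counts, focal_call="ns", other_call="ns"):
        genes = {"At": ["a0"], "Hi": [f"h{i}" for i in range(len(focal_counts))]}
        table = HomologyTable(
            {
                "HG": [("At", "a0")] + [("Hi", g) for g in genes["Hi"]],
                # filler group so TPM normalization has company
                "BG": [("At", "At_bg"), ("Hi", "Hi_bg")],
                "NOF": [("At", "At_nof")],
            }
        )
        tpms, rows = {}, []
        for sp, vals in (("At", [other_counts]), ("Hi", focal_counts)):
            data = {}
            for j, trt in enumerate(["HL", "HL", "LL", "LL"]):
                col = [v[j] if isinstance(v, (list, tuple)) else v for v in vals]
                col.append(10000)  # background gene keeps TPM shares stable
                if sp == "At":
                    col.append(500)  # gene of the focal-less group
                data[f"{sp}_s{j}"] = col
                rows.append(
                    {
                        "sample_id": f"{sp}_s{j}",
                        "species_id": sp,
                        "treatment": trt,
                        "replicate": j % 2 + 1,
                    }
                )
            index = genes[sp] + [f"{sp}_bg"] + (["At_nof"] if sp == "At" else [])
            counts = pd.DataFrame(data, index=index)
            cm = CountMatrix(sp, counts, pd.Series(1000, index=counts.index))
            tpms[sp] = abundance.tpm(cm)
        samples = pd.DataFrame(rows)
        de = {
            "At": pd.DataFrame(
                {"call": [other_call, "ns", "ns"]}, index=["a0", "At_bg", "At_nof"]
            ),
            "Hi": pd.DataFrame(
                {"call": [focal_call] * len(genes["Hi"]) + ["ns"]},
                index=genes["Hi"] + ["Hi_bg"],
            ),
        }
        model = cs.BaselineModel(species=("At", "Hi"), group_ids=["BG"])
        model._ratios[("At", "Hi")] = np.zeros(5)
        return table, de, model, tpms, samples

    def test_constitutive_high(self):
        # single focal copy, ns, ~8x the other species in both treatments
        table, de, model, tpms, samples = self._setup(
            focal_counts=[8000], other_counts=1000
        )
        call = cs.classify_expression_mode(
            "HG", "Hi", de, model, table, tpms, samples
        )
        assert call.mode == "constitutive_high"

    def test_cumulative_paralog(self):
        # three modest focal copies whose sum dominates
        table, de, model, tpms, samples = self._setup(
            focal_counts=[900, 900, 900], other_counts=1000
        )
        call = cs.classify_expression_mode(
            "HG", "Hi", de, model, table, tpms, samples
        )
        assert call.mode == "cumulative_paralog"

    def test_treatment_de(self):
        table, de, model, tpms, samples = self._setup(
            focal_counts=[(4000, 4000, 1000, 1000)],
            other_counts=1000,
            focal_call="up",
        )
        call = cs.classify_expression_mode(
            "HG", "Hi", de, model, table, tpms, samples
        )
        assert call.mode == "treatment_DE"

    def test_treatment_de_blocked_by_other_species_call(self):
        table, de, model, tpms, samples = self._setup(
            focal_counts=[(4000, 4000, 1000, 1000)],
            other_counts=1000,
            focal_call="up",
            other_call="down",
        )
        call = cs.classify_expression_mode(
            "HG", "Hi", de, model, table, tpms, samples
        )
        assert call.mode != "treatment_DE"

    def test_none_when_balanced(self):
        table, de, model, tpms, samples = self._setup(
            focal_counts=[1000], other_counts=1000
        )
        call = cs.classify_expression_mode(
            "HG", "Hi", de, model, table, tpms, samples
        )
        assert call.mode == "none"

    def test_missing_focal_gene_is_error(self):
        table, de, model, tpms, samples = self._setup(
            focal_counts=[1000], other_counts=1000
        )
        with pytest.raises(ValueError, match="absent"):
            cs.classify_expression_mode(
                "NOF", "Hi", de, model, table, tpms, samples
            )
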