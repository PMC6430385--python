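import itertools
import math

import numpy as np
import pandas as pd
import pytest

import thermoscope as ts
from thermoscope import qpcr


def cq_rows(entries):
    """entries: (sample, group, gene, replicate, cq)."""
    return pd.DataFrame(
        entries, columns=["sample_id", "group", "gene", "replicate", "cq"]
    )


def rq_rows(entries):
    """entries: (sample, group, gene, rq)."""
    return pd.DataFrame(entries, columns=["sample_id", "group", "gene", "rq"])


class TestCollapseReplicates:
    def test_mean_of_three(self):
        table = cq_rows([("s1", "g", "x", i, c) for i, c in enumerate((20.0, 20.1, 20.2))])
        out = qpcr.collapse_replicates(table)
        assert out["cq"].iloc[0] == pytest.approx(20.1)
        assert out["flags"].iloc[0] == ""

    def test_single_replicate_flagged(self):
        out = qpcr.collapse_replicates(cq_rows([("s1", "g", "x", 1, 21.0)]))
        assert out["cq"].iloc[0] == 21.0
        assert qpcr.N_EQ_1 in out["flags"].iloc[0]

    def test_noisy_replicates_warned_not_dropped(self):
        table = cq_rows([("s1", "g", "x", i, c) for i, c in enumerate((20.0, 22.0, 20.1))])
        out = qpcr.collapse_replicates(table)
        assert out["cq"].iloc[0] == pytest.approx(np.mean([20.0, 22.0, 20.1]))
        assert qpcr.HIGH_REPLICATE_SD in out["flags"].iloc[0]


class TestEfficiency:
    def test_perfect_doubling_slope(self):
        x = np.array([0.0, -1.0, -2.0, -3.0])
        cq = 20.0 - 3.321928094887362 * x
        assert qpcr.efficiency_from_standard_curve(x, cq) == pytest.approx(2.0, abs=1e-12)

    def test_suboptimal_slope(self):
        x = np.array([0.0, -1.0, -2.0, -3.0])
        cq = 20.0 - 3.6 * x
        expected = 10.0 ** (1.0 / 3.6)  # ~1.896
        assert qpcr.efficiency_from_standard_curve(x, cq) == pytest.approx(expected, rel=1e-12)

    def test_two_points_rejected(self):
        with pytest.raises(ts.ThermoscopeError):
            qpcr.efficiency_from_standard_curve([0.0, -1.0], [20.0, 23.3])


class TestRelativeQuantities:
    def test_one_cycle_below_mean_doubles(self):
        mean_cq = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "group": "g", "gene": "x",
             "cq": [19.0, 20.0, 21.0]}
        )
        out = qpcr.relative_quantities(mean_cq, 2.0)
        np.testing.assert_allclose(out["rq"], [2.0, 1.0, 0.5])

    def test_custom_efficiency(self):
        mean_cq = pd.DataFrame(
            {"sample_id": ["a", "b"], "group": "g", "gene": "x", "cq": [19.0, 21.0]}
        )
        out = qpcr.relative_quantities(mean_cq, {"x": 1.9})
        # delta Cq of 2 at E=1.9 -> ratio 1.9^2 = 3.61
        assert out["rq"].iloc[0] / out["rq"].iloc[1] == pytest.approx(3.61)

    def test_out_of_range_efficiency_rejected(self):
        mean_cq = pd.DataFrame(
            {"sample_id": ["a"], "group": "g", "gene": "x", "cq": [19.0]}
        )
        with pytest.raises(ts.ThermoscopeError):
            qpcr.relative_quantities(mean_cq, 2.5)


def two_sample_rq(delta_cq_target=1.0, e=2.0):
    """Two samples; identical references; target differs by delta_cq_target."""
    cq_bar = 25.0
    rq_t1 = e ** (cq_bar - (cq_bar - delta_cq_target / 2))
    rq_t2 = e ** (cq_bar - (cq_bar + delta_cq_target / 2))
    return rq_rows(
        [
            ("s1", "a", "ref1", 1.0),
            ("s1", "a", "ref2", 1.0),
            ("s1", "a", "tgt", rq_t1),
            ("s2", "b", "ref1", 1.0),
            ("s2", "b", "ref2", 1.0),
            ("s2", "b", "tgt", rq_t2),
        ]
    )


class TestCnrq:
    def test_single_sample_all_at_gene_means_gives_unity(self):
        table = rq_rows(
            [("s1", "a", "ref1", 1.0), ("s1", "a", "ref2", 1.0), ("s1", "a", "tgt", 1.0)]
        )
        out = qpcr.cnrq(table, ["ref1", "ref2"])
        assert out["cnrq"].iloc[0] == pytest.approx(1.0)

    def test_one_cycle_target_difference_doubles_cnrq_ratio(self):
        out = qpcr.cnrq(two_sample_rq(1.0), ["ref1", "ref2"])
        by_sample = out.set_index("sample_id")["cnrq"]
        assert by_sample["s1"] / by_sample["s2"] == pytest.approx(2.0)

    def test_run_geometric_mean_is_one_under_all_sample_calibration(self):
        rng = np.random.default_rng(0)
        entries = []
        for i in range(6):
            for gene in ("ref1", "ref2", "tgt"):
                entries.append((f"s{i}", "a" if i < 3 else "b", gene,
                                float(rng.lognormal(0, 0.5))))
        out = qpcr.cnrq(rq_rows(entries), ["ref1", "ref2"])
        log_mean = np.mean(np.log(out["cnrq"]))
        assert log_mean == pytest.approx(0.0, abs=1e-12)

    def test_between_sample_ratios_invariant_to_calibration(self):
        table = two_sample_rq(1.7)
        all_cal = qpcr.cnrq(table, ["ref1", "ref2"], calibration="all_samples")
        grp_cal = qpcr.cnrq(table, ["ref1", "ref2"], calibration="b")
        r_all = all_cal.set_index("sample_id")["cnrq"]
        r_grp = grp_cal.set_index("sample_id")["cnrq"]
        assert r_all["s1"] / r_all["s2"] == pytest.approx(r_grp["s1"] / r_grp["s2"])

    def test_fewer_than_two_references_rejected(self):
        with pytest.raises(ts.ThermoscopeError):
            qpcr.cnrq(two_sample_rq(), ["ref1"])


class TestGenormM:
    def test_proportional_genes_have_zero_m(self):
        entries = []
        for i, scale in enumerate((1.0, 2.0, 5.0, 0.3)):
            entries.append((f"s{i}", "a", "g1", scale))
            entries.append((f"s{i}", "a", "g2", 3.0 * scale))
        m = qpcr.genorm_m(rq_rows(entries))
        assert m["g1"] == pytest.approx(0.0, abs=1e-12)
        assert m["g2"] == pytest.approx(0.0, abs=1e-12)

    def test_ratio_sequence_1_2_4_gives_m_of_one(self):
        entries = []
        for i, ratio in enumerate((1.0, 2.0, 4.0)):
            entries.append((f"s{i}", "a", "g1", ratio))
            entries.append((f"s{i}", "a", "g2", 1.0))
        m = qpcr.genorm_m(rq_rows(entries))
        # log2 ratios {0,1,2}: sample sd = 1.0
        assert m["g1"] == pytest.approx(1.0)
        assert m["g2"] == pytest.approx(1.0)

    def test_matches_brute_force_on_three_gene_fixture(self):
        rng = np.random.default_rng(7)
        samples = [f"s{i}" for i in range(4)]
        genes = ["g1", "g2", "g3"]
        rq = {(s, g): float(rng.lognormal(0, 0.4)) for s in samples for g in genes}
        table = rq_rows([(s, "a", g, rq[(s, g)]) for s in samples for g in genes])
        m = qpcr.genorm_m(table)
        # independent direct evaluation of the pairwise log-ratio-sd formula
        for gj in genes:
            vs = []
            for gk in genes:
                if gk == gj:
                    continue
                ratios = [math.log2(rq[(s, gj)] / rq[(s, gk)]) for s in samples]
                mean = sum(ratios) / len(ratios)
                sd = math.sqrt(sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1))
                vs.append(sd)
            assert m[gj] == pytest.approx(sum(vs) / len(vs), rel=1e-12)

    def test_noisy_gene_has_largest_m(self):
        rng = np.random.default_rng(1)
        entries = []
        for i in range(8):
            base = float(rng.lognormal(0, 0.3))
            entries.append((f"s{i}", "a", "stable1", base))
            entries.append((f"s{i}", "a", "stable2", base * 1.05))
            entries.append((f"s{i}", "a", "noisy", base * float(rng.lognormal(0, 1.0))))
        m = qpcr.genorm_m(rq_rows(entries))
        assert m["noisy"] > m["stable1"]
        assert m["noisy"] > m["stable2"]

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        entries = [
            (f"s{i}", "a", g, float(rng.lognormal(0, 0.4)))
            for i in range(5)
            for g in ("g1", "g2", "g3")
        ]
        table = rq_rows(entries)
        m0 = qpcr.genorm_m(table)
        scaled = table.copy()
        scaled.loc[scaled["gene"] == "g2", "rq"] *= 37.0
        m1 = qpcr.genorm_m(scaled)
        for g in ("g1", "g2", "g3"):
            assert m1[g] == pytest.approx(m0[g], rel=1e-12)


class TestGroupSummary:
    def _cnrq(self, values, group="g"):
        return pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(values))],
             "group": group, "gene": "tgt", "cnrq": values}
        )

    def test_zero_variance_collapses_interval(self):
        out = qpcr.group_summary(self._cnrq([2.0, 2.0, 2.0]))
        assert out["geo_mean"].iloc[0] == pytest.approx(2.0)
        assert out["ci_low"].iloc[0] == pytest.approx(2.0)
        assert out["ci_high"].iloc[0] == pytest.approx(2.0)

    def test_geometric_mean_of_two(self):
        out = qpcr.group_summary(self._cnrq([1.0, 4.0]))
        assert out["geo_mean"].iloc[0] == pytest.approx(2.0)

    def test_multiplicative_symmetry_on_random_fixtures(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            vals = rng.lognormal(0, 1.0, size=rng.integers(2, 12))
            out = qpcr.group_summary(self._cnrq(vals))
            high, mean, low = (
                out["ci_high"].iloc[0], out["geo_mean"].iloc[0], out["ci_low"].iloc[0]
            )
            assert high / mean == pytest.approx(mean / low, rel=1e-12)

    def test_singleton_group_flagged_without_interval(self):
        out = qpcr.group_summary(self._cnrq([3.0]))
        assert out["flags"].iloc[0] == qpcr.N_EQ_1
        assert np.isnan(out["ci_low"].iloc[0])


def enumeration_pvalue(a, b):
    """Brute-force exact two-sided Mann-Whitney p by full relabeling."""
    pooled = list(a) + list(b)
    n_a = len(a)
    mu = n_a * len(b) / 2.0

    def u_of(indices):
        group = [pooled[i] for i in indices]
        rest = [pooled[i] for i in range(len(pooled)) if i not in indices]
        return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in group for y in rest)

    u_obs = u_of(tuple(range(n_a)))
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n_a)]
    extreme = sum(1 for u in us if abs(u - mu) >= abs(u_obs - mu) - 1e-12)
    return u_obs, extreme / len(us)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = qpcr.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings as extreme

    def test_identical_groups_p_one(self):
        u, p = qpcr.mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    @pytest.mark.parametrize("n_a,n_b", [(na, nb) for na in range(1, 7) for nb in range(1, 7)])
    def test_exact_mode_matches_enumeration_oracle(self, n_a, n_b):
        rng = np.random.default_rng(100 * n_a + n_b)
        a = rng.normal(0, 1, n_a)
        b = rng.normal(0.8, 1, n_b)
        u, p = qpcr.mann_whitney(a, b, mode="exact")
        u_ref, p_ref = enumeration_pvalue(a, b)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, rel=1e-12)
        assert 0.0 < p <= 1.0

    def test_large_tied_samples_use_normal_approximation(self):
        rng = np.random.default_rng(5)
        a = np.round(rng.normal(0, 1, 30), 1)
        b = np.round(rng.normal(0.5, 1, 30), 1)
        _, p = qpcr.mann_whitney(a, b, mode="auto")
        assert 0.0 < p <= 1.0


class TestAnalyzeCqTable:
    def test_full_chain_on_generated_table(self):
        cq, manifest = ts.generate_cq(ts.CqScenario(), seed=2)
        res = qpcr.analyze_cq_table(
            cq,
            ["actb", "18s"],
            ["hsp70"],
            comparisons=[("heat_41C", "control_29C"), ("cold_17C", "control_29C")],
        )
        assert set(res["genorm"]["gene"]) == {"actb", "18s"}
        assert (res["genorm"]["M"] < 0.5).all()
        comp = res["comparisons"].set_index("group_a")
        assert comp.loc["heat_41C", "p_value"] < 0.01
        assert comp.loc["heat_41C", "stars"] == "**"
        assert comp.loc["heat_41C", "n_b"] == 16  # pooled control size

    def test_missing_reference_gene_named(self):
        cq, _ = ts.generate_cq(ts.CqScenario(), seed=2)
        with pytest.raises(ts.ThermoscopeError, match="nope"):
            qpcr.analyze_cq_table(cq, ["actb", "nope"], ["hsp70"])

    def test_pooling_relabels_groups(self):
        cq, _ = ts.generate_cq(ts.CqScenario(), seed=2)
        res = qpcr.analyze_cq_table(
            cq,
            ["actb", "18s"],
            ["hsp70"],
            pooling={"treated": ["heat_41C", "cold_17C"]},
            comparisons=[("treated", "control_29C")],
        )
        comp = res["comparisons"].iloc[0]
        assert comp["n_a"] == 16
        assert comp["n_b"] == 16
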