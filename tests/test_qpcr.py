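"""qPCR quantification: efficiency, Cq, noRT, geNorm, CNRQ, statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from aquasig.errors import AnalysisError
from aquasig.qpcr import (brown_forsythe, compute_cnrq, compute_cq,
                          estimate_efficiency, filter_noRT, genorm_stability,
                          scheffe_posthoc)
from aquasig.synth import QpcrSimDesign, WellRecord, simulate_qpcr_run


def doubling_well(start=0.01, plateau=100.0, cycles=40, sample="s1"):
    f = tuple(min(start * 2 ** c, plateau) for c in range(1, cycles + 1))
    return WellRecord(sample, "t", "sample", f)


class TestEfficiency:
    def test_noise_free_doubling_curve(self):
        est = estimate_efficiency([doubling_well()])
        assert est.efficiency == pytest.approx(2.0, abs=1e-3)

    def test_flat_curve_excluded(self):
        flat = WellRecord("s1", "t", "sample", (0.05,) * 40)
        with pytest.raises(AnalysisError, match="no exponential phase"):
            estimate_efficiency([flat])

    def test_simulated_well_recovery(self):
        # E = 1.90, 1% multiplicative noise: plate mean within +-0.02
        design = QpcrSimDesign(
            targets={"t": 1.90}, reference_targets=("t",),
            samples=tuple((f"s{i}", "A") for i in range(12)),
            expression={("A", "t"): 1.0}, noise_sigma=0.01, seed=3)
        wells = [w for w in simulate_qpcr_run(design) if w.well_type == "sample"]
        est = estimate_efficiency(wells)
        assert est.efficiency == pytest.approx(1.90, abs=0.02)

    def test_recovery_across_efficiency_range(self):
        # mean absolute error over the plausible E band stays small
        errs = []
        for i, e_true in enumerate(np.linspace(1.7, 2.0, 20)):
            design = QpcrSimDesign(
                targets={"t": float(e_true)}, reference_targets=("t",),
                samples=tuple((f"s{i}", "A") for i in range(6)),
                expression={("A", "t"): 1.0}, noise_sigma=0.01, seed=50 + i)
            wells = [w for w in simulate_qpcr_run(design)
                     if w.well_type == "sample"]
            errs.append(abs(estimate_efficiency(wells).efficiency - e_true))
        assert np.mean(errs) <= 0.03


class TestComputeCq:
    def test_closed_form_inversion(self):
        # 0.01 * 2^c = 10.24  =>  c = 10
        w = doubling_well()
        assert compute_cq(w, threshold=10.24) == pytest.approx(10.0)

    def test_shift_equivariance(self):
        w1 = doubling_well()
        f2 = (0.005, 0.0075) + w1.fluorescence[:-2]
        w2 = WellRecord("s", "t", "sample", f2)
        cq1 = compute_cq(w1, threshold=10.24)
        cq2 = compute_cq(w2, threshold=10.24)
        assert cq2 - cq1 == pytest.approx(2.0)

    def test_never_crossing_is_censored(self):
        w = WellRecord("s", "t", "sample",
                       tuple(10.0 / (c + 1) for c in range(40)))
        assert compute_cq(w, threshold=50.0) is None


class TestNoRtRule:
    def test_delta_four_drops(self):
        assert filter_noRT(22.0, 26.0).keep is False

    def test_delta_eight_keeps(self):
        assert filter_noRT(22.0, 30.0).keep is True

    def test_censored_nort_keeps(self):
        assert filter_noRT(22.0, None).keep is True

    def test_missing_sample_cq_drops_with_reason(self):
        d = filter_noRT(None, 30.0)
        assert d.keep is False and "missing" in d.reason


class TestGeNorm:
    @staticmethod
    def _table(columns):
        return pd.DataFrame(columns, index=[f"s{i}" for i in range(6)])

    def test_proportional_pair_selected(self):
        rng = np.random.default_rng(0)
        stable = np.linspace(20, 25, 6)
        table = self._table({
            "a": stable, "b": stable + 1.0,          # perfectly proportional RQs
            "c": stable + rng.normal(0, 1.5, 6)})
        eff = {"a": 2.0, "b": 2.0, "c": 2.0}
        rank = genorm_stability(table, eff)
        assert set(rank.selected_pair) == {"a", "b"}
        assert rank.exclusion_order == ("c",)

    def test_identical_candidates_tie_broken_by_input_order(self):
        col = np.array([20.0, 21, 22, 23, 24, 25])
        table = self._table({"a": col, "b": col, "c": col, "d": col})
        rank = genorm_stability(table, {k: 2.0 for k in "abcd"})
        assert all(m == 0.0 for m in rank.m_values.values())
        assert rank.exclusion_order == ("d", "c")
        assert rank.selected_pair == ("a", "b")

    def test_exclusion_order_invariant_to_input_order(self):
        rng = np.random.default_rng(4)
        cols = {k: 20 + rng.normal(0, s, 8)
                for k, s in zip("abcde", (0.1, 0.2, 0.9, 0.5, 1.4))}
        df = pd.DataFrame(cols, index=[f"s{i}" for i in range(8)])
        eff = {k: 2.0 for k in cols}
        base = genorm_stability(df, eff)
        shuffled = genorm_stability(df[["d", "b", "e", "a", "c"]], eff)
        assert set(base.exclusion_order) == set(shuffled.exclusion_order)
        assert set(base.selected_pair) == set(shuffled.selected_pair)

    def test_missing_value_errors_naming_candidate(self):
        table = self._table({"a": np.arange(6.0), "b": np.arange(6.0),
                             "c": [1.0, 2, np.nan, 4, 5, 6]})
        with pytest.raises(AnalysisError, match="'c'"):
            genorm_stability(table, {k: 2.0 for k in "abc"})

    def test_two_candidates_rejected(self):
        table = self._table({"a": np.arange(6.0), "b": np.arange(6.0)})
        with pytest.raises(AnalysisError, match="3 candidate"):
            genorm_stability(table, {"a": 2.0, "b": 2.0})


class TestCnrq:
    def test_all_equal_cq_gives_unit_cnrq(self):
        rows = [(s, t, 24.0) for s in ("s1", "s2", "s3")
                for t in ("g1", "ref")]
        cq = pd.DataFrame(rows, columns=["sample", "target", "cq"])
        out = compute_cnrq(cq, {"g1": 2.0, "ref": 2.0}, ["ref"])
        assert np.allclose(out.table["cnrq"], 1.0)

    def test_rq_definition_single_target(self):
        cq = pd.DataFrame([("s1", "g", 23.0), ("s2", "g", 25.0)],
                          columns=["sample", "target", "cq"])
        out = compute_cnrq(cq, {"g": 2.0}, ["g"])
        rq = out.table.set_index("sample")["rq"]
        # mean Cq = 24; one cycle below the mean doubles the quantity
        assert rq["s1"] == pytest.approx(2.0)
        assert rq["s2"] == pytest.approx(0.5)

    def test_calibration_invariant_geomean_one(self):
        rng = np.random.default_rng(7)
        rows = [(f"s{i}", t, float(20 + rng.uniform(0, 8)))
                for i in range(9) for t in ("g1", "g2", "r1", "r2")]
        cq = pd.DataFrame(rows, columns=["sample", "target", "cq"])
        eff = {"g1": 1.9, "g2": 2.0, "r1": 1.911, "r2": 1.911}
        out = compute_cnrq(cq, eff, ["r1", "r2"])
        for t, grp in out.table.groupby("target"):
            gm = np.exp(np.log(grp["cnrq"].dropna()).mean())
            assert gm == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_constant_cq_shift_per_target(self):
        rng = np.random.default_rng(8)
        rows = [(f"s{i}", t, float(22 + rng.uniform(0, 6)))
                for i in range(6) for t in ("g", "r1", "r2")]
        cq = pd.DataFrame(rows, columns=["sample", "target", "cq"])
        eff = {"g": 1.88, "r1": 1.911, "r2": 1.911}
        base = compute_cnrq(cq, eff, ["r1", "r2"])
        shifted = cq.copy()
        shifted.loc[shifted.target == "g", "cq"] += 3.0
        out = compute_cnrq(shifted, eff, ["r1", "r2"])
        merged = base.table.merge(out.table, on=["sample", "target"])
        assert np.allclose(merged["cnrq_x"], merged["cnrq_y"])

    def test_missing_reference_censors_sample(self):
        rows = [("s1", "g", 24.0), ("s1", "r", 22.0),
                ("s2", "g", 25.0), ("s2", "r", np.nan)]
        cq = pd.DataFrame(rows, columns=["sample", "target", "cq"])
        out = compute_cnrq(cq, {"g": 2.0, "r": 2.0}, ["r"])
        s2 = out.table[(out.table["sample"] == "s2")
                       & (out.table["target"] == "g")]
        assert math.isnan(float(s2["cnrq"].iloc[0]))

    def test_simulated_fold_change_recovery(self):
        # programmed 2x and 4x steps between tissue groups come back
        design = QpcrSimDesign(
            targets={"g": 1.9, "r1": 1.911, "r2": 1.911},
            reference_targets=("r1", "r2"),
            samples=tuple((f"{t}{i}", t) for t in "ABC" for i in range(3)),
            expression={("A", "g"): 1.0, ("B", "g"): 2.0, ("C", "g"): 4.0,
                        **{(t, r): 1.0 for t in "ABC" for r in ("r1", "r2")}},
            noise_sigma=0.01, seed=11)
        wells = simulate_qpcr_run(design)
        rows = [(w.sample, w.target, compute_cq(w)) for w in wells
                if w.well_type == "sample"]
        cq = pd.DataFrame(rows, columns=["sample", "target", "cq"])
        out = compute_cnrq(cq, design.targets, design.reference_targets)
        tab = out.table[out.table["target"] == "g"].copy()
        tab["tissue"] = tab["sample"].str[0]
        gm = {t: float(np.exp(np.log(g["cnrq"]).mean()))
              for t, g in tab.groupby("tissue")}
        assert gm["B"] / gm["A"] == pytest.approx(2.0, rel=0.05)
        assert gm["C"] / gm["A"] == pytest.approx(4.0, rel=0.05)


class TestBrownForsythe:
    def test_equal_sizes_reduces_to_classic_anova(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1.0, 6) for m in (0.0, 0.4, 1.0)]
        bf = brown_forsythe(groups)
        classic = sps.f_oneway(*groups)
        assert bf.f_star == pytest.approx(classic.statistic)

    def test_identical_groups_give_f_zero_p_one(self):
        g = np.array([1.0, 2.0, 3.0])
        bf = brown_forsythe([g, g.copy()])
        assert bf.f_star == 0.0 and bf.p_value == 1.0

    def test_unequal_sizes_differ_from_classic(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 1, 4), rng.normal(0, 3, 12)]
        bf = brown_forsythe(groups)
        assert bf.df2 != pytest.approx(len(groups[0]) + len(groups[1]) - 2)

    def test_group_of_one_rejected(self):
        with pytest.raises(AnalysisError):
            brown_forsythe([[1.0], [1.0, 2.0]])


class TestScheffe:
    def test_identical_groups_nothing_significant(self):
        g = [1.0, 2.0, 3.0]
        out = scheffe_posthoc([g, list(g), list(g)])
        assert not any(c.significant for c in out)

    def test_strongly_shifted_group_flagged_in_both_pairs(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0, 1, 8)
        c = rng.normal(10 * 1.0, 1, 8)       # 10 SD away
        out = scheffe_posthoc([a, b, c])
        flags = {tuple(x.pair): x.significant for x in out}
        assert flags[(0, 2)] and flags[(1, 2)]
        assert not flags[(0, 1)]

    def test_scheffe_implies_unadjusted_pairwise_f(self):
        # conservativeness: any Scheffe-significant pair is significant
        # under the unadjusted pairwise F test too
        rng = np.random.default_rng(6)
        for _ in range(25):
            groups = [rng.normal(rng.uniform(-1, 1), 1.0,
                                 int(rng.integers(3, 8))) for _ in range(4)]
            n = sum(len(g) for g in groups)
            k = len(groups)
            crit_unadj = sps.f.isf(0.05, 1, n - k)
            for comp in scheffe_posthoc(groups):
                if comp.significant:
                    assert comp.f_pair > crit_unadj
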