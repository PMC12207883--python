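"""Exhaustion-marker panel: gating, positivity, MFI, concordance."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from ctlkit.panel import (LINEAGE_CHAIN, direction_concordance,
                          fmo_thresholds, gate_threshold,
                          load_expected_directions, mfi, panel_stats,
                          percent_positive, percent_positive_stats,
                          separation_check, sequential_gate, to_wide)
from ctlkit.sim import gen_marker_experiments, gen_marker_table


class TestGateThreshold:
    def test_constant_fmo(self):
        assert gate_threshold([5.0] * 20) == 5.0

    def test_quantile_one_is_max(self):
        assert gate_threshold([1.0, 9.0, 4.0], quantile=1.0) == 9.0

    def test_false_positive_rate_near_half_percent(self):
        rng = np.random.default_rng(0)
        fmo = rng.lognormal(np.log(100), 0.5, 100_000)
        thr = gate_threshold(fmo)
        fresh = rng.lognormal(np.log(100), 0.5, 100_000)
        rate = np.mean(fresh > thr)
        assert rate == pytest.approx(0.005, abs=0.002)


class TestPercentPositive:
    def test_bounds(self):
        assert percent_positive([2.0, 3.0], 1.0) == 100.0
        assert percent_positive([2.0, 3.0], 5.0) == 0.0

    def test_binomial_recovery_of_positive_fraction(self):
        rng = np.random.default_rng(1)
        neg = rng.lognormal(np.log(100), 0.5, 5000)
        pos = rng.lognormal(np.log(3000), 0.4, 5000)
        x = np.concatenate([neg, pos])
        thr = gate_threshold(rng.lognormal(np.log(100), 0.5, 50_000))
        assert percent_positive(x, thr) == pytest.approx(50.0, abs=2.0)

    def test_monotone_non_increasing_in_threshold(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(5, 1, 1000)
        pp = [percent_positive(x, t) for t in np.linspace(0, 2000, 30)]
        assert all(a >= b for a, b in zip(pp, pp[1:]))


class TestMfiAndSeparation:
    def test_whole_population_median(self):
        assert mfi([1.0, 2.0, 3.0]) == 2.0

    def test_positive_only_needs_threshold_and_cells(self):
        with pytest.raises(ValueError, match="threshold"):
            mfi([1.0, 2.0], mode="positive_only")
        with pytest.raises(ValueError, match="positive"):
            mfi([1.0, 2.0], mode="positive_only", threshold=10.0)

    def test_well_separated_positive_median(self):
        rng = np.random.default_rng(3)
        neg = rng.lognormal(np.log(100), 0.4, 5000)
        pos = rng.lognormal(np.log(10_000), 0.4, 5000)
        x = np.concatenate([neg, pos])
        got = mfi(x, mode="positive_only", threshold=1000.0)
        assert got == pytest.approx(10_000.0, rel=0.05)

    def test_unimodal_not_separated(self):
        rng = np.random.default_rng(4)
        x = rng.lognormal(np.log(500), 0.4, 5000)
        assert separation_check(x, float(np.median(x))) is False

    def test_hundredfold_gap_separated(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.lognormal(np.log(100), 0.3, 500),
                            rng.lognormal(np.log(10_000), 0.3, 500)])
        assert separation_check(x, 1000.0) is True

    def test_separation_monotone_in_median_gap(self):
        rng = np.random.default_rng(6)
        neg = rng.lognormal(np.log(100), 0.3, 2000)
        outcomes = []
        for fold in (2, 5, 12, 40, 150):
            pos = rng.lognormal(np.log(100.0 * fold), 0.3, 2000)
            x = np.concatenate([neg, pos])
            thr = float(np.sqrt(100.0 * 100.0 * fold))
            outcomes.append(separation_check(x, thr))
        assert outcomes == sorted(outcomes)


@pytest.fixture(scope="module")
def table():
    table, _ = gen_marker_table(["1G4_CTL"], 800, 11)
    return table


class TestSequentialGate:

    def test_empty_chain_is_identity(self, table):
        wide = to_wide(table)
        thr = fmo_thresholds(table)
        assert len(sequential_gate(wide, [], thr)) == len(wide)

    def test_always_failing_gate_empties(self, table):
        wide = to_wide(table)
        thr = dict(fmo_thresholds(table), CD45=np.inf)
        assert len(sequential_gate(wide, [("CD45", "+")], thr)) == 0

    def test_idempotence(self, table):
        wide = to_wide(table)
        thr = fmo_thresholds(table)
        once = sequential_gate(wide, LINEAGE_CHAIN, thr)
        twice = sequential_gate(once, LINEAGE_CHAIN, thr)
        assert once.equals(twice)

    def test_recovers_labelled_cd8_cells(self, table):
        """The lineage chain recovers >= 98% of ground-truth CD8 T cells
        and excludes nearly all others."""
        wide = to_wide(table)
        pops = (table[~table["is_fmo"]]
                .drop_duplicates("cell_id").set_index("cell_id")["population"])
        gated = sequential_gate(wide, LINEAGE_CHAIN, fmo_thresholds(table))
        gated_pops = pops.loc[gated["cell_id"]]
        cd8_total = (pops == "cd8_t").sum()
        assert (gated_pops == "cd8_t").sum() >= 0.98 * cd8_total
        assert (gated_pops != "cd8_t").mean() < 0.02


def exact_mannwhitney_p(x, y):
    """Brute-force two-sided Mann-Whitney p by full enumeration."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def ustat(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum(float((xi > ys).sum()) + 0.5 * float((xi == ys).sum())
                   for xi in xs)

    obs = ustat(range(n1))
    us = np.array([ustat(c)
                   for c in combinations(range(len(pooled)), n1)])
    return min(1.0, 2 * min((us <= obs).mean(), (us >= obs).mean()))


def test_mannwhitney_matches_exact_enumeration():
    """The U test behind concordance scoring agrees with a brute-force
    rank enumeration for n <= 10 per group."""
    rng = np.random.default_rng(7)
    for n1, n2 in ((4, 5), (6, 6), (8, 7), (10, 9)):
        x = rng.normal(0, 1, n1)
        y = rng.normal(0.8, 1, n2)
        p_scipy = mannwhitneyu(x, y, alternative="two-sided",
                               method="exact").pvalue
        assert p_scipy == pytest.approx(exact_mannwhitney_p(x, y), abs=1e-12)


class TestDirectionConcordance:
    def stats_frame(self, a_vals, b_vals, marker="PD-1"):
        rows = [{"condition": "ref", "marker": marker, "value": v}
                for v in a_vals]
        rows += [{"condition": "test", "marker": marker, "value": v}
                 for v in b_vals]
        return pd.DataFrame(rows)

    def expected(self, marker="PD-1", direction="up"):
        return pd.DataFrame({"marker": [marker], "expected": [direction],
                             "marker_class": ["primary"]})

    def test_identical_distributions_unchanged(self):
        stats = self.stats_frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = direction_concordance(stats, self.expected(),
                                    [("ref", "test")])
        assert res.per_marker["category"].item() == "unchanged"

    def test_large_expected_shift_is_concordant_significant(self):
        stats = self.stats_frame([1, 2, 3, 2, 1, 2], [9, 10, 11, 10, 9, 11])
        res = direction_concordance(stats, self.expected(),
                                    [("ref", "test")])
        assert res.per_marker["category"].item() == "concordant-significant"

    def test_opposite_shift_is_discordant(self):
        stats = self.stats_frame([9, 10, 11, 10, 9, 11], [1, 2, 3, 2, 1, 2])
        res = direction_concordance(stats, self.expected(),
                                    [("ref", "test")])
        assert res.per_marker["category"].item() == "discordant"

    def test_five_of_seven_markers_concordant(self):
        """Six simulated experiments, SIL vs three-day-stimulated PBMC:
        exactly five of the seven panel markers shift as expected for
        exhaustion with p < 0.05; TIGIT is unchanged and TCF-1 moves the
        wrong way."""
        table = gen_marker_experiments(["PBMC_stim3d", "1G4_SIL"], 250, 6, 42)
        pp = percent_positive_stats(table, LINEAGE_CHAIN)
        res = direction_concordance(pp, load_expected_directions(),
                                    [("PBMC_stim3d", "1G4_SIL")])
        per = res.per_marker.set_index("marker")
        sig = per[per["category"] == "concordant-significant"]
        assert len(sig) == 5
        assert per.loc["TCF-1", "category"] == "discordant"
        assert per.loc["TIGIT", "category"] in ("concordant-ns", "unchanged",
                                                "discordant")
        assert per.loc["TIGIT", "p_value"] > 0.05


class TestGenerator:
    def test_zero_cells_empty_table_no_error(self):
        table, _ = gen_marker_table(["1G4_CTL"], 0, 0)
        assert len(table) == 0

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="unknown condition"):
            gen_marker_table(["made_up"], 10, 0)

    def test_fmo_present_for_every_scored_marker(self):
        table, _ = gen_marker_table(["1G4_SIL"], 50, 1)
        scored = set(table.loc[~table["is_fmo"], "marker"])
        fmo = set(table.loc[table["is_fmo"], "marker"])
        assert scored == fmo

    def test_panel_stats_runs_gated(self):
        table, _ = gen_marker_table(["1G4_CTL"], 400, 2)
        stats = panel_stats(table, gate_chain=LINEAGE_CHAIN)
        pd1 = stats.set_index("marker").loc["PD-1"]
        assert 40 < pd1["percent_positive"] < 80
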