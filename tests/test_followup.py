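"""Follow-up analysis tests: paired t against the textbook formula,
star mapping, dose trend, mechanism classification and washout."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import erythroscreen as es
from erythroscreen.simulate import (
    CompoundProfile,
    simulate_dose_response,
    simulate_kinetics,
    simulate_morphology_counts,
    simulate_washout,
)


def oracle_paired_t(treated, control):
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)), two-sided p."""
    d = np.asarray(treated, float) - np.asarray(control, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return t, p


class TestPairedTTest:
    def test_equal_arms_give_t0_p1_ns(self):
        res = es.paired_ttest([50.0, 60.0, 70.0], [50.0, 60.0, 70.0])
        assert res.t_statistic == 0.0 and res.p_value == 1.0 and res.stars == "ns"
        assert res.degenerate  # constant (zero) differences

    def test_matches_textbook_formula(self):
        treated = [50.0, 55.0, 60.0, 52.0]
        control = [65.0, 70.0, 72.0, 66.0]
        res = es.paired_ttest(treated, control)
        t, p = oracle_paired_t(treated, control)
        assert res.t_statistic == pytest.approx(t, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    @given(
        st.lists(st.floats(0, 100), min_size=3, max_size=8),
        st.integers(0, 2**31 - 1),
    )
    @settings(deadline=None, max_examples=50)
    def test_matches_oracle_on_random_vectors(self, control, seed):
        rng = np.random.default_rng(seed)
        control = np.asarray(control)
        treated = control - rng.uniform(0.5, 30.0, size=control.size)
        res = es.paired_ttest(treated, control)
        t, p = oracle_paired_t(treated, control)
        assert res.t_statistic == pytest.approx(t, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_zero_variance_nonzero_mean_is_degenerate_p0(self):
        res = es.paired_ttest([40.0, 50.0], [50.0, 60.0])
        assert res.p_value == 0.0 and res.degenerate

    def test_length_mismatch_and_small_n_rejected(self):
        with pytest.raises(ValueError):
            es.paired_ttest([1.0, 2.0], [1.0])
        with pytest.raises(ValueError, match=">= 2"):
            es.paired_ttest([1.0], [2.0])

    @pytest.mark.parametrize(
        "p,stars",
        [
            (0.9, "ns"), (0.05, "ns"), (0.049, "*"), (0.009, "**"),
            (0.0009, "***"), (0.00009, "****"), (0.0, "****"),
        ],
    )
    def test_star_mapping_boundaries(self, p, stars):
        assert es.p_to_stars(p) == stars

    def test_validate_compounds_table(self):
        rows = []
        for exp in range(1, 5):
            rows.append(("HIT", f"e{exp}", "treated", 30.0 + exp))
            rows.append(("HIT", f"e{exp}", "control", 65.0 + exp))
            rows.append(("NULL", f"e{exp}", "treated", 64.0 + exp))
            rows.append(("NULL", f"e{exp}", "control", 65.0 + 0.5 * (exp % 2)))
        tab = pd.DataFrame(rows, columns=["compound_id", "experiment_id", "arm", "enucleation_pct"])
        out = es.validate_compounds(tab).set_index("compound_id")
        assert bool(out.loc["HIT", "significant"])
        assert out.loc["HIT", "stars"] != "ns"


class TestDoseTrend:
    def test_strictly_decreasing_rho_minus_one(self):
        res = es.dose_trend([0.01, 0.1, 1.0, 10.0, 100.0], [65, 60, 40, 20, 5])
        assert res.rho == pytest.approx(-1.0)
        assert res.monotone_inhibition

    def test_constant_response_negative_verdict(self):
        res = es.dose_trend([0.1, 1.0, 10.0], [50.0, 50.0, 50.0])
        assert res.rho == 0.0 and not res.monotone_inhibition

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            es.dose_trend([0.1, 1.0], [60, 40])

    def test_hill_curve_detected_reliably(self):
        # simulation oracle: a real concentration-dependent inhibitor is
        # flagged in >= 95% of simulated dose series
        prof = CompoundProfile("H", "arrest", max_inhibition=0.8, ec50=0.3)
        conc = [0.01, 0.1, 0.3, 1.0, 3.0]
        master = np.random.default_rng(123)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            df = simulate_dose_response(prof, conc, seed=master, noise_sd=0.03)
            res = es.dose_trend(df["concentration_uM"], df["enucleation_pct"])
            hits += res.monotone_inhibition
        assert hits / n_sim >= 0.95


class TestMechanismClassification:
    def _call(self, profile, seed):
        df = simulate_kinetics(profile, [5.0, 10.0], seed=seed, n_experiments=3)
        piv = df.pivot_table(
            index="experiment", columns=["arm", "timepoint_h"], values="enucleation_pct"
        )
        return es.classify_mechanism(
            piv[("treated", 5.0)], piv[("control", 5.0)],
            piv[("treated", 10.0)], piv[("control", 10.0)],
            compound_id=profile.compound_id,
        )

    def test_delay_compound_called_delay(self):
        prof = CompoundProfile("D", "delay", max_inhibition=0.8, recovery_halftime=0.8)
        assert self._call(prof, seed=1).call == "delay"

    def test_arrest_compound_called_arrest(self):
        prof = CompoundProfile("A", "arrest", max_inhibition=0.8)
        assert self._call(prof, seed=2).call == "arrest"

    def test_inert_compound_called_no_effect(self):
        prof = CompoundProfile("N", "none")
        assert self._call(prof, seed=3).call == "no_effect"

    def test_equal_arms_no_effect(self):
        call = es.classify_mechanism(
            [60.0, 62.0, 58.0], [60.0, 62.0, 58.0],
            [70.0, 71.0, 69.0], [70.0, 71.0, 69.0],
        )
        assert call.call == "no_effect"


class TestWashout:
    def test_immediate_recovery_when_equal(self):
        res = es.washout_recovery([0.5, 1, 3, 5], [70, 70, 70, 70], [70, 70, 70, 70])
        assert res.recovered and res.recovery_time_h == 0.5

    def test_flat_treated_not_recovered(self):
        res = es.washout_recovery([0.5, 1, 3, 5], [5, 5, 5, 5], [60, 65, 70, 70])
        assert not res.recovered and res.recovery_time_h is None

    def test_reversible_arrest_recovers_in_simulation(self):
        # simulation oracle: washed-out arrest compounds read as recovered
        prof = CompoundProfile("A", "arrest", max_inhibition=0.8)
        master = np.random.default_rng(7)
        rec = 0
        n_sim = 200
        for _ in range(n_sim):
            df = simulate_washout(prof, seed=master, n_experiments=3)
            g = df.groupby(["timepoint_h", "arm"])["enucleation_pct"].mean().unstack()
            res = es.washout_recovery(g.index, g["treated"], g["control"])
            rec += res.recovered
        assert rec / n_sim >= 0.95

    def test_irreversible_compound_stays_suppressed(self):
        prof = CompoundProfile("A", "arrest", max_inhibition=0.9)
        df = simulate_washout(prof, seed=9, reversible=False)
        g = df.groupby(["timepoint_h", "arm"])["enucleation_pct"].mean().unstack()
        res = es.washout_recovery(g.index, g["treated"], g["control"])
        assert not res.recovered

    def test_no_timepoints_rejected(self):
        with pytest.raises(ValueError):
            es.washout_recovery([], [], [])


class TestMorphology:
    def test_single_experiment_proportions(self):
        counts = pd.DataFrame(
            {"experiment_id": ["e1", "e1"], "class": ["A", "B"], "count": [50, 50]}
        )
        summ = es.morphology_proportions(counts)
        assert summ.mean_proportion == {"A": 0.5, "B": 0.5}
        assert summ.sd_proportion == {"A": 0.0, "B": 0.0}

    def test_identical_experiments_zero_sd(self):
        rows = [(f"e{i}", c, n) for i in range(3) for c, n in (("A", 30), ("B", 70))]
        counts = pd.DataFrame(rows, columns=["experiment_id", "class", "count"])
        summ = es.morphology_proportions(counts)
        assert summ.mean_proportion["A"] == pytest.approx(0.3)
        assert summ.sd_proportion["A"] == pytest.approx(0.0)

    def test_proportions_sum_to_one_per_experiment(self):
        df = simulate_morphology_counts(
            {"a": 0.2, "b": 0.3, "c": 0.5}, n_cells=(112, 541), n_experiments=5, seed=4
        )
        summ = es.morphology_proportions(df)
        assert np.allclose(summ.per_experiment.sum(axis=1), 1.0)

    def test_segmentation_probability_recovered(self):
        # multinomial oracle: the segmented-nucleus share, simulated at
        # 30%, is recovered within 4 standard errors of its mean
        p_seg, n, n_exp = 0.30, 500, 3
        probs = {
            "round_nucleus": 0.25, "polarized_nucleus": 0.25,
            "extruding": 0.1, "segmented_nucleus": p_seg, "reticulocyte": 0.1,
        }
        df = simulate_morphology_counts(probs, n_cells=n, n_experiments=n_exp, seed=6)
        summ = es.morphology_proportions(df)
        se = np.sqrt(p_seg * (1 - p_seg) / n) / np.sqrt(n_exp)
        assert abs(summ.mean_proportion["segmented_nucleus"] - p_seg) < 4 * se

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame(
            {"experiment_id": ["e1"], "class": ["A"], "count": [-1]}
        )
        with pytest.raises(ValueError):
            es.morphology_proportions(counts)
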