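"""Tests of the synthetic-data generators against binomial/multinomial
oracles and their stated invariants."""

import numpy as np
import pandas as pd
import pytest

import erythroscreen as es
from erythroscreen.simulate import (
    CompoundProfile,
    KineticsTruth,
    ScreenDesign,
    WellTruth,
    make_library,
    simulate_cellcycle_events,
    simulate_kinetics,
    simulate_morphology_counts,
    simulate_screen,
    simulate_well_events,
    treated_curve,
)


class TestWellEvents:
    @pytest.mark.parametrize(
        "prob,dead,check",
        [
            (0.0, 0.05, "no_enucleation"),
            (1.0, 0.0, "no_orthochromatic"),
            (0.5, 1.0, "all_dead"),
        ],
    )
    def test_degenerate_probabilities(self, prob, dead, check):
        truth = WellTruth("A1", "X", prob, dead_fraction=dead, n_cells=2000)
        ev = simulate_well_events(truth, seed=0)
        labels = ev["truth_label"]
        if check == "no_enucleation":
            assert (labels.isin(["reticulocyte", "free_nucleus"])).sum() == 0
        elif check == "no_orthochromatic":
            assert (labels == "orthochromatic_erythroblast").sum() == 0
        else:
            assert (labels == "dead_cell").all()

    def test_enucleated_fraction_matches_binomial_oracle(self):
        # binomial SE oracle: at p=0.5, n=30000 the labeled fraction of
        # enucleation-origin cells is within 4*sqrt(p(1-p)/n) of p
        n, p = 30_000, 0.5
        truth = WellTruth("A1", "X", p, dead_fraction=0.0, n_cells=n)
        ev = simulate_well_events(truth, seed=123)
        n_enuc = (ev["truth_label"] == "reticulocyte").sum()
        frac = n_enuc / n
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_particle_conservation_and_nucleus_pairing(self):
        # every cell is accounted for; each enucleation yields exactly one
        # reticulocyte and one free nucleus
        truth = WellTruth("A1", "X", 0.65, dead_fraction=0.1, n_cells=5000)
        ev = simulate_well_events(truth, seed=5)
        counts = ev["truth_label"].value_counts()
        n_retic = counts.get("reticulocyte", 0)
        assert counts.get("free_nucleus", 0) == n_retic
        n_cells_accounted = (
            counts.get("orthochromatic_erythroblast", 0)
            + n_retic
            + counts.get("dead_cell", 0)
            + counts.get("late_erythroblast", 0)
        )
        assert n_cells_accounted == truth.n_cells
        assert len(ev) == truth.n_cells + n_retic

    def test_identical_seeds_are_byte_identical(self):
        truth = WellTruth("A1", "X", 0.4, n_cells=1000)
        a = simulate_well_events(truth, seed=9)
        b = simulate_well_events(truth, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_measured_enucleation_monotone_in_true_prob(self):
        # expected measured enucleation % is non-decreasing in the truth
        fracs = []
        for p in (0.1, 0.3, 0.5, 0.7, 0.9):
            truth = WellTruth("A1", "X", p, n_cells=20_000)
            ev = simulate_well_events(truth, seed=77)
            c = es.gate_counts_for_well(ev)
            fracs.append(es.net_enucleation(c["n_enucleated"], c["n_nucleated"]))
        assert all(a < b for a, b in zip(fracs, fracs[1:]))

    def test_rejects_invalid_truth(self):
        with pytest.raises(ValueError):
            WellTruth("A1", "X", 1.5)
        with pytest.raises(ValueError):
            WellTruth("A1", "X", 0.5, n_cells=0)


class TestScreen:
    def test_null_library_compound_wells_at_baseline(self):
        # with every compound inert, the clean (pre-noise) probability of
        # each compound well equals the baseline
        design = ScreenDesign(n_compounds=8, seed=1, between_day_sd=0.0, within_plate_sd=0.0)
        lib = [CompoundProfile(f"C{i}") for i in range(8)]
        wells, _ = simulate_screen(design, lib, seed=1)
        comp = wells.loc[wells["role"] == "compound"]
        assert np.allclose(comp["true_enucleation_prob"], design.baseline_enucleation)

    def test_cytochalasin_d_wells_near_zero(self, default_screen):
        # positive-control wells: enucleation is blocked (< 5% readout)
        _, _, wells = default_screen
        pos = wells.loc[wells["role"] == "pos_control"]
        pct = 100 * pos["n_enucleated"] / (pos["n_enucleated"] + pos["n_nucleated"])
        assert pct.mean() < 5.0

    def test_replicate_correlation_rises_as_day_noise_vanishes(self):
        # Monte-Carlo correlation oracle: same compound effects, different
        # day-noise draws; shrinking between-day sd raises per-compound
        # raw-readout correlation
        lib = make_library(n_compounds=88, n_arrest=5, n_delay=5, n_toxic=0, seed=3)
        rs = []
        for sd in (12.0, 0.5):
            design = ScreenDesign(
                n_compounds=88, seed=3, between_day_sd=sd, n_cells_per_well=2000
            )
            wells, _ = simulate_screen(design, lib, seed=3)
            comp = wells.loc[wells["role"] == "compound"]
            pct = 100 * comp["n_enucleated"] / (comp["n_enucleated"] + comp["n_nucleated"])
            wide = comp.assign(pct=pct).pivot_table(
                index="compound_id", columns="replicate", values="pct"
            )
            rs.append(es.replicate_correlation(wide[1], wide[2]))
        assert rs[1] > rs[0]

    def test_library_size_mismatch_raises(self):
        design = ScreenDesign(n_compounds=8, seed=0)
        with pytest.raises(ValueError, match="does not match"):
            simulate_screen(design, [CompoundProfile("C1")], seed=0)

    def test_every_compound_in_every_replicate(self, small_screen):
        design, library, wells = small_screen
        comp = wells.loc[wells["role"] == "compound"]
        per_rep = comp.groupby("replicate")["compound_id"].apply(set)
        expected = {p.compound_id for p in library}
        assert all(s == expected for s in per_rep)

    def test_seed_determinism(self, small_screen):
        design, library, wells = small_screen
        again, _ = simulate_screen(design, library, seed=7, mode="counts")
        pd.testing.assert_frame_equal(wells, again)


class TestKinetics:
    def test_inert_compound_tracks_control(self):
        t = np.linspace(0, 10, 21)
        prof = CompoundProfile("C1", "none")
        kin = KineticsTruth()
        assert np.allclose(treated_curve(prof, t, kin), kin.control(t))

    def test_control_curve_rises_linearly_to_plateau(self):
        kin = KineticsTruth()
        t = np.array([0.0, 3.0, 6.0, 10.0])
        ctrl = kin.control(t)
        assert ctrl[0] == 0.0
        assert np.isclose(ctrl[1], kin.plateau / 2)
        assert ctrl[2] == ctrl[3] == kin.plateau

    def test_delay_compound_closes_the_gap_by_10h(self):
        prof = CompoundProfile("D", "delay", max_inhibition=0.8, recovery_halftime=1.0)
        kin = KineticsTruth()
        t5, t10 = treated_curve(prof, np.array([5.0, 10.0]), kin)
        c5, c10 = kin.control(np.array([5.0, 10.0]))
        assert abs(t10 - c10) < abs(t5 - c5)

    def test_arrest_compound_flat_from_5_to_10h(self):
        prof = CompoundProfile("A", "arrest", max_inhibition=0.8)
        kin = KineticsTruth()
        t5, t10 = treated_curve(prof, np.array([5.0, 10.0]), kin)
        assert t10 - t5 < 0.05  # only the residual control rise to plateau

    def test_curves_non_decreasing_and_bounded(self):
        t = np.linspace(0, 12, 49)
        for mech, kw in (("arrest", {}), ("delay", {"recovery_halftime": 0.5})):
            prof = CompoundProfile("X", mech, max_inhibition=0.9, **kw)
            y = treated_curve(prof, t, KineticsTruth())
            assert np.all(np.diff(y) >= -1e-12)
            assert np.all((y >= 0) & (y <= 1))

    def test_noisy_simulation_layout(self):
        df = simulate_kinetics(CompoundProfile("C", "none"), [5, 10], seed=0, n_experiments=4)
        assert set(df["arm"]) == {"treated", "control"}
        assert df.shape[0] == 4 * 2 * 2
        assert df["enucleation_pct"].between(0, 100).all()

    def test_empty_timepoints_rejected(self):
        with pytest.raises(ValueError):
            simulate_kinetics(CompoundProfile("C", "none"), [], seed=0)


class TestCellCycle:
    def test_all_g0g1_when_no_s_or_g2m(self):
        ev = simulate_cellcycle_events(0.0, 0.0, 1000, seed=0)
        fr = es.cellcycle_fractions(ev)
        assert fr["non_proliferating"] == 1.0 and fr["S"] == 0.0

    def test_all_s_phase_brdu_positive(self):
        ev = simulate_cellcycle_events(1.0, 0.0, 1000, seed=0)
        assert es.cellcycle_fractions(ev)["S"] == 1.0

    def test_nonproliferating_fraction_matches_binomial_oracle(self):
        # gated non-proliferating fraction within 4*binomial SE of truth
        n, f_s = 50_000, 0.08
        ev = simulate_cellcycle_events(f_s, 0.03, n, seed=21)
        fr = es.cellcycle_fractions(ev)
        se = np.sqrt(f_s * (1 - f_s) / n)
        assert abs(fr["non_proliferating"] - (1 - f_s)) < 4 * se

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            simulate_cellcycle_events(0.7, 0.5, 100, seed=0)


class TestMorphology:
    def test_single_class_takes_all_counts(self):
        df = simulate_morphology_counts({"a": 1.0, "b": 0.0}, n_cells=200, n_experiments=2, seed=0)
        assert (df.loc[df["class"] == "b", "count"] == 0).all()
        assert (df.loc[df["class"] == "a", "count"] == 200).all()

    def test_uniform_counts_within_multinomial_se(self):
        # 4 equal classes at n=400: each count within 4*sqrt(n p (1-p)) of 100
        df = simulate_morphology_counts(
            {c: 0.25 for c in "abcd"}, n_cells=400, n_experiments=1, seed=13
        )
        se = np.sqrt(400 * 0.25 * 0.75)
        assert (df["count"] - 100).abs().max() < 4 * se

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_morphology_counts({"a": 0.5, "b": 0.4}, n_cells=100, seed=0)

    def test_enumeration_range_respected(self):
        df = simulate_morphology_counts(
            {"a": 0.5, "b": 0.5}, n_cells=(112, 541), n_experiments=6, seed=2
        )
        totals = df.groupby("experiment_id")["count"].sum()
        assert totals.between(112, 541).all()
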