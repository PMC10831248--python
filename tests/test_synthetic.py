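import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from massphot import (
    BindingTruth,
    EventTable,
    InstrumentModel,
    SpeciesSpec,
    equilibrium_fraction_bound,
    simulate_sample,
    simulate_titration,
)
from massphot.synthetic import EmptySampleWarning

from oracles import fraction_bound_fixed_point

GOLDEN_RATIO_FRACTION = (3 - math.sqrt(5)) / 2  # root of f^2 - 3f + 1 at R=L=K


class TestEquilibriumFractionBound:
    def test_no_ligand(self):
        assert equilibrium_fraction_bound(200, 0, 50) == 0.0

    def test_infinitely_tight_with_excess_ligand(self):
        assert equilibrium_fraction_bound(100, 200, 0) == 1.0

    @pytest.mark.parametrize("c", [0.1, 1.0, 7.0, 200.0, 1e4])
    def test_equal_triple_closed_form(self, c):
        assert equilibrium_fraction_bound(c, c, c) == pytest.approx(
            GOLDEN_RATIO_FRACTION, abs=1e-12
        )

    @pytest.mark.parametrize(
        "R,L,K",
        [(-1, 10, 10), (0, 10, 10), (10, -1, 10), (10, 10, -1), (float("nan"), 1, 1), (1, float("inf"), 1)],
    )
    def test_invalid_inputs(self, R, L, K):
        with pytest.raises(ValueError):
            equilibrium_fraction_bound(R, L, K)

    def test_fixed_point_oracle_agreement(self, rng):
        for _ in range(100):
            R = rng.uniform(1, 1000)
            L = rng.uniform(0, 2000)
            K = rng.uniform(0.01, 500)
            fast = equilibrium_fraction_bound(R, L, K)
            slow = fraction_bound_fixed_point(R, L, K)
            assert fast == pytest.approx(slow, rel=1e-9, abs=1e-9)

    def test_free_ligand_consistency(self, rng):
        # free = L - f R must be non-negative and satisfy K = (R - C) free / C
        for _ in range(50):
            R = rng.uniform(1, 500)
            L = rng.uniform(0.1, 1000)
            K = rng.uniform(0.1, 300)
            f = equilibrium_fraction_bound(R, L, K)
            free = L - f * R
            assert free >= -1e-9
            if 0 < f < 1:
                assert (R - f * R) * free / (f * R) == pytest.approx(K, rel=1e-6)

    @given(
        L1=st.floats(0, 1000),
        dL=st.floats(0.1, 1000),
        K=st.floats(0.01, 500),
    )
    @settings(max_examples=100)
    def test_monotone_in_ligand(self, L1, dL, K):
        assert equilibrium_fraction_bound(100, L1 + dL, K) >= equilibrium_fraction_bound(
            100, L1, K
        )

    @given(
        L=st.floats(0.1, 1000),
        K1=st.floats(0.01, 500),
        dK=st.floats(0.1, 500),
    )
    @settings(max_examples=100)
    def test_monotone_in_kd(self, L, K1, dK):
        assert equilibrium_fraction_bound(100, L, K1 + dK) <= equilibrium_fraction_bound(
            100, L, K1
        )


class TestSimulateSample:
    def test_zero_noise_limit(self):
        inst = InstrumentModel(mass_sigma=0.0, detection_limit=40.0)
        table = simulate_sample([SpeciesSpec("x", 130.0)], inst, n_events=100, seed=1)
        assert table.n_events == 100
        assert np.all(table.masses == 130.0)

    def test_two_species_fraction(self, instrument):
        # law-of-large-numbers check: the fraction of events past the midpoint
        # must match the analytic expectation, which accounts for the ~11 %
        # cross-midpoint leakage of each population at sigma = 12
        from scipy.stats import norm

        species = [SpeciesSpec("r", 208.0, 0.7), SpeciesSpec("c", 237.4, 0.3)]
        table = simulate_sample(species, instrument, n_events=5000, seed=42)
        midpoint = (208.0 + 237.4) / 2
        frac_heavy = np.mean(table.masses > midpoint)
        expected = 0.7 * norm.sf(midpoint, 208.0, 12.0) + 0.3 * norm.sf(midpoint, 237.4, 12.0)
        assert frac_heavy == pytest.approx(expected, abs=0.02)

    def test_two_species_fraction_well_separated(self):
        # with negligible overlap the event split reproduces the weights directly
        inst = InstrumentModel(mass_sigma=5.0, detection_limit=40.0)
        species = [SpeciesSpec("r", 208.0, 0.7), SpeciesSpec("c", 237.4, 0.3)]
        table = simulate_sample(species, inst, n_events=5000, seed=42)
        frac_heavy = np.mean(table.masses > (208.0 + 237.4) / 2)
        assert frac_heavy == pytest.approx(0.30, abs=0.02)

    def test_below_detection_limit_all_lost(self):
        inst = InstrumentModel(mass_sigma=1.0, detection_limit=40.0)
        with pytest.warns(EmptySampleWarning):
            table = simulate_sample([SpeciesSpec("ligand", 29.4)], inst, n_events=200, seed=3)
        assert table.n_events == 0

    def test_determinism(self, instrument):
        species = [SpeciesSpec("r", 208.0, 0.6), SpeciesSpec("c", 237.4, 0.4)]
        a = simulate_sample(species, instrument, n_events=1000, seed=7)
        b = simulate_sample(species, instrument, n_events=1000, seed=7)
        pd.testing.assert_frame_equal(a.events, b.events)
        c = simulate_sample(species, instrument, n_events=1000, seed=8)
        assert not a.events["mass_kda"].equals(c.events["mass_kda"])

    def test_poisson_count_mode(self, instrument):
        table = simulate_sample([SpeciesSpec("r", 208.0)], instrument, seed=5)
        assert 0 < table.n_events < 3 * instrument.events_expected

    def test_dilution_reduces_counts_only(self, instrument):
        diluted = simulate_sample(
            [SpeciesSpec("r", 208.0)], instrument, seed=5, dilution_factor=11.0
        )
        neat = simulate_sample([SpeciesSpec("r", 208.0)], instrument, seed=5)
        assert diluted.n_events < neat.n_events

    def test_mean_converges_to_true_mass(self, instrument):
        table = simulate_sample([SpeciesSpec("r", 208.0)], instrument, n_events=100_000, seed=9)
        tol = 3 * instrument.mass_sigma / math.sqrt(table.n_events)
        assert table.masses.mean() == pytest.approx(208.0, abs=tol)

    def test_seed_required(self, instrument):
        with pytest.raises(ValueError, match="seed"):
            simulate_sample([SpeciesSpec("r", 208.0)], instrument, n_events=10)

    def test_contrast_is_linear_in_mass(self, instrument):
        table = simulate_sample([SpeciesSpec("r", 208.0)], instrument, n_events=500, seed=2)
        expected = instrument.contrast_slope * table.masses + instrument.contrast_intercept
        np.testing.assert_allclose(table.contrasts, expected, rtol=0, atol=0)


class TestEventTable:
    def test_csv_round_trip(self, instrument, tmp_path):
        table = simulate_sample(
            [SpeciesSpec("r", 208.0)],
            instrument,
            n_events=50,
            seed=4,
            sample_id="demo",
            nominal_receptor_total=200.0,
            nominal_ligand_total=50.0,
        )
        path = tmp_path / "demo.events.csv"
        table.to_csv(path)
        back = EventTable.from_csv(path)
        assert back.sample_id == "demo"
        assert back.nominal_ligand_total == 50.0
        np.testing.assert_allclose(back.masses, table.masses)

    def test_duplicate_event_index_rejected(self):
        frame = pd.DataFrame(
            {"event_index": [0, 0], "contrast": [0.1, 0.2], "mass_kda": [100.0, 200.0]}
        )
        with pytest.raises(ValueError, match="unique"):
            EventTable(sample_id="bad", events=frame)


class TestBindingTruth:
    def test_requires_zero_ligand_condition(self):
        with pytest.raises(ValueError, match="zero-ligand"):
            BindingTruth(kd_true=50, receptor_total=200, ligand_totals=(25, 50))

    def test_requires_ordered_asymptotes(self):
        with pytest.raises(ValueError):
            BindingTruth(
                kd_true=50, receptor_total=200, ligand_totals=(0, 50), a_true=0.8, b_true=0.2
            )


class TestSimulateTitration:
    def test_zero_ligand_all_receptor(self, instrument):
        truth = BindingTruth(kd_true=50, receptor_total=200, ligand_totals=(0.0, 100.0), seed=1)
        tables, record = simulate_titration(truth, 208.0, 29.4, instrument, n_events=2000)
        zero = tables[0]
        assert record["conditions"][0]["fraction_measurable_true"] == 0.0
        assert np.all(np.abs(zero.masses - 208.0) < 6 * instrument.mass_sigma)

    def test_saturation_all_complex(self):
        inst = InstrumentModel(mass_sigma=1.0, detection_limit=40.0)
        truth = BindingTruth(
            kd_true=1e-9, receptor_total=200, ligand_totals=(0.0, 2000.0), seed=2
        )
        tables, record = simulate_titration(truth, 208.0, 29.4, inst, n_events=2000)
        assert record["conditions"][1]["fraction_measurable_true"] == pytest.approx(1.0)
        receptor_events = tables[1].masses[tables[1].masses > 100]
        assert np.all(np.abs(receptor_events - 237.4) < 6.0)

    def test_determinism_and_truth_record(self, instrument):
        truth = BindingTruth(
            kd_true=50, receptor_total=200, ligand_totals=(0.0, 50.0, 200.0), seed=11
        )
        t1, r1 = simulate_titration(truth, 208.0, 29.4, instrument, n_events=500)
        t2, r2 = simulate_titration(truth, 208.0, 29.4, instrument, n_events=500)
        assert r1 == r2
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.events, b.events)
        # free ligand in the record obeys conservation with the occupancy
        for cond in r1["conditions"]:
            assert cond["ligand_free_true"] == pytest.approx(
                cond["ligand_total"] - cond["occupancy_true"] * 200, abs=1e-9
            )
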