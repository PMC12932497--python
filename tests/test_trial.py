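"""Synthetic split-plot trial generator: determinism, the saturating
tissue-N response, file round-trips and statistical calibration."""

import math
from dataclasses import replace

import numpy as np
import pytest

from croprank import (
    ConfigurationError,
    GeneratorModel,
    PlotRecord,
    read_trial,
    simulate_trial,
    tissue_n_concentration,
    write_trial,
)
from croprank.trial import TrialParseError, records_to_frame

from conftest import zero_noise


class TestSimulate:
    def test_fixed_seed_is_bit_identical(self, toy_treatments, toy_seasons, toy_model):
        a = simulate_trial(toy_treatments, toy_seasons, toy_model)
        b = simulate_trial(toy_treatments, toy_seasons, toy_model)
        assert a == b

    def test_different_seed_differs(self, toy_treatments, toy_seasons, toy_model):
        a = simulate_trial(toy_treatments, toy_seasons, toy_model)
        b = simulate_trial(toy_treatments, toy_seasons, replace(toy_model, seed=8))
        assert a != b

    def test_zero_noise_degeneracy(self, toy_treatments, toy_seasons, toy_model):
        """With all noise off every replicate equals the configured cell mean."""
        records = simulate_trial(toy_treatments, toy_seasons, zero_noise(toy_model))
        for r in records:
            assert r.grain_yield == toy_model.mean_yield[(r.treatment_id, r.season_id)]
            assert r.dry_matter == pytest.approx(
                r.grain_yield / toy_model.harvest_index_mean)

    def test_replicate_count(self, toy_treatments, toy_seasons, toy_model):
        records = simulate_trial(toy_treatments, toy_seasons, toy_model)
        assert len(records) == len(toy_treatments) * len(toy_seasons) * 3

    def test_substreams_stable_under_added_treatment(
            self, toy_treatments, toy_seasons, toy_model):
        """Adding a treatment must not perturb the other cells' draws."""
        base = simulate_trial(toy_treatments[:2], toy_seasons, replace(
            toy_model))
        full = simulate_trial(toy_treatments, toy_seasons, toy_model)
        subset = [r for r in full if r.treatment_id in ("CK", "A")]
        assert base == subset

    def test_missing_cell_mean_names_pair(self, toy_treatments, toy_seasons, toy_model):
        broken = replace(toy_model, mean_yield={
            k: v for k, v in toy_model.mean_yield.items() if k != ("B", "m1")})
        with pytest.raises(ConfigurationError, match="'B'.*'m1'"):
            simulate_trial(toy_treatments, toy_seasons, broken)

    def test_nonpositive_mean_rejected(self, toy_model):
        with pytest.raises(ConfigurationError):
            replace(toy_model, mean_yield={("A", "w1"): -1.0})


class TestNitrogenResponse:
    def test_closed_form_values(self):
        """Saturating response at 0 vs 195 kg N with the stated parameters."""
        base, mx, k = 0.008, 0.014, 0.015
        assert tissue_n_concentration(0.0, base, mx, k) == pytest.approx(0.008)
        expected = 0.008 + 0.006 * (1 - math.exp(-0.015 * 195))  # = 0.013678...
        assert tissue_n_concentration(195.0, base, mx, k) == pytest.approx(expected)
        assert expected == pytest.approx(0.01368, abs=5e-6)

    def test_monotone_nondecreasing_uptake(self, toy_seasons, toy_model):
        """With zero noise, raising the N rate never lowers simulated uptake."""
        from croprank import TreatmentSpec

        model = zero_noise(toy_model, mean_yield={
            (f"N{n}", s.season_id): 8000.0
            for n in range(0, 300, 30) for s in toy_seasons})
        uptakes = []
        for n in range(0, 300, 30):
            t = TreatmentSpec(f"N{n}", float(n), 0, 0, 1.0 if n else 0,
                              irrigation_method="drip", is_zero_n=(n == 0))
            recs = simulate_trial([t], toy_seasons, model)
            uptakes.append(recs[0].n_uptake)
        assert all(b >= a for a, b in zip(uptakes, uptakes[1:]))

    def test_uptake_within_physical_band(self, toy_treatments, toy_seasons, toy_model):
        for r in simulate_trial(toy_treatments, toy_seasons, toy_model):
            assert 0 <= r.n_uptake <= r.dry_matter * 0.05
            assert r.dry_matter >= r.grain_yield * 0.5


class TestCalibration:
    def test_sample_mean_recovers_configured_mean(self, toy_treatments, toy_seasons,
                                                  toy_model):
        """Cell sample means converge to the configured means (3 SE band)."""
        model = replace(toy_model, n_replicates=200)
        records = simulate_trial(toy_treatments, toy_seasons, model)
        df = records_to_frame(records)
        for (tid, sid), grp in df.groupby(["treatment_id", "season_id"]):
            mean = toy_model.mean_yield[(tid, sid)]
            sd = toy_model.yield_cv * mean
            se = sd / np.sqrt(len(grp))
            assert abs(grp.grain_yield_kg_ha.mean() - mean) < 3 * se


class TestRoundTrip:
    def test_csv_round_trip(self, tmp_path, toy_treatments, toy_seasons, toy_model):
        records = simulate_trial(toy_treatments, toy_seasons, toy_model)
        path = tmp_path / "plots.csv"
        write_trial(records, path)
        assert read_trial(path) == records

    def test_full_precision_fixture_value(self, tmp_path):
        """A record holding the reference wheat yield survives bit-exact."""
        rec = PlotRecord("T4", "w1", 1, 8532.5, 11081.2, 104.37)
        path = tmp_path / "one.csv"
        write_trial([rec], path)
        assert read_trial(path) == [rec]

    def test_empty_round_trip(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_trial([], path)
        assert read_trial(path) == []

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "treatment_id,season_id,replicate,grain_yield_kg_ha,"
            "dry_matter_kg_ha,n_uptake_kg_ha\nT1,w1,1,100,200,oops\n")
        with pytest.raises(TrialParseError, match="line 2"):
            read_trial(path)

    def test_negative_quantity_rejected(self):
        with pytest.raises(ValueError):
            PlotRecord("T1", "w1", 1, -5.0, 10.0, 1.0)
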