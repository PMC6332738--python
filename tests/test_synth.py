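"""Simulator ground truth: recruitment, wind-up, drug kinetics, determinism."""

import numpy as np
import pytest

from dhmea.io import ValidationError
from dhmea.laminar import band_sums
from dhmea.preprocess import extract_epochs
from dhmea.synth import (
    BackgroundParams,
    CohortSpec,
    amplitude_series_events,
    default_fibres,
    default_postdischarge,
    drug_factor,
    duration_series_events,
    expected_evoked_sum,
    frequency_train_events,
    morphine_schedule,
    natural_events,
    recruitment_fraction,
    simulate_cohort,
    simulate_natural,
    simulate_train,
    windup_gain,
)

FIBRES = default_fibres()


class TestRecruitment:
    @pytest.mark.parametrize("name", ["Abeta", "Adelta", "C"])
    def test_zero_amplitude_silent(self, name):
        assert recruitment_fraction(FIBRES[name], 0.0, 2.0) == 0.0

    @pytest.mark.parametrize("name", ["Abeta", "Adelta", "C"])
    def test_chronaxie_doubles_threshold(self, name):
        # Weiss law: I_th at d = chronaxie equals 2 x rheobase, where the
        # logistic sits exactly at its midpoint
        f = FIBRES[name]
        i_th = f.rheobase_mA * (1.0 + f.chronaxie_ms / f.chronaxie_ms)
        assert i_th == 2 * f.rheobase_mA
        mid = recruitment_fraction(f, i_th, f.chronaxie_ms)
        assert mid == pytest.approx(0.5)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValidationError):
            recruitment_fraction(FIBRES["C"], 1.0, 0.0)

    def test_threshold_ordering_over_test_amplitudes(self):
        amps = (0.1, 0.5, 1.0, 5.0, 10.0)
        lowest = {}
        for name, f in FIBRES.items():
            active = [a for a in amps if recruitment_fraction(f, a, 2.0) > 0]
            lowest[name] = min(active)
        assert lowest["Abeta"] <= lowest["Adelta"] <= lowest["C"]
        assert (lowest["Abeta"], lowest["Adelta"], lowest["C"]) == (0.5, 1.0, 5.0)

    def test_duration_series_monotone_recruitment(self):
        # Weiss threshold falls with duration, so C recruitment at fixed
        # 5 mA never decreases and rises strictly once unclamped
        fracs = [recruitment_fraction(FIBRES["C"], 5.0, d) for d in (0.2, 1.0, 2.0, 10.0, 20.0)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        unclamped = [f for f in fracs if 0.0 < f < 1.0]
        assert all(b > a for a, b in zip(unclamped, unclamped[1:]))
        assert fracs[-1] > fracs[0]


class TestWindupGain:
    def test_low_frequency_has_no_windup(self):
        assert windup_gain(0.15, 10, 7, 0.1) == 1.0

    def test_gain_grows_then_caps(self):
        gains = [windup_gain(0.15, 10, i, 0.5) for i in range(20)]
        assert gains[0] == 1.0
        assert all(b >= a for a, b in zip(gains, gains[1:]))
        assert gains[10] == gains[19] == 1.0 + 0.15 * 10


class TestDrugFactor:
    def test_no_effect_at_application(self):
        assert drug_factor(FIBRES["C"], "deep", 0.0) == 1.0

    def test_c_fibre_asymptote(self):
        assert drug_factor(FIBRES["C"], "deep", 1e6) == pytest.approx(0.2)

    def test_abeta_superficial_insensitive(self):
        for t in (0.0, 30.0, 90.0, 1e4):
            assert drug_factor(FIBRES["Abeta"], "superficial", t) == 1.0

    def test_delay_defers_onset(self):
        f = FIBRES["Adelta"]  # delay 10 min
        assert drug_factor(f, "deep", 5.0) == 1.0
        assert drug_factor(f, "deep", 30.0) < 1.0


class TestSimulateTrain:
    def test_determinism(self, geometry):
        events = amplitude_series_events(amplitudes=(5.0,), n_per_train=5)
        s1 = simulate_train(events, geometry, seed=123)
        s2 = simulate_train(events, geometry, seed=123)
        assert s1 == s2

    def test_subthreshold_amplitude_matches_background(self, geometry):
        # 0.1 mA evokes nothing: band sums equal matched no-stimulus windows
        # to within 2 SE over 200 stimuli
        events = amplitude_series_events(amplitudes=(0.1,), n_per_train=200)
        spikes = simulate_train(events, geometry, seed=7)
        tensor = extract_epochs(spikes, events)
        summary = band_sums(tensor)
        for band in ("Abeta", "Adelta", "C", "PD"):
            per_stim = summary.band(band).sum(axis=1)
            lo, hi = dict(summary.bands.windows)[band]
            width_s = (hi - lo) / 1000.0
            expected = 2.0 * 16 * width_s  # background only
            se = np.sqrt(expected / len(events))
            assert abs(per_stim.mean() - expected) < 2 * se, band

    def test_full_recruitment_c_band_expectation(self, geometry):
        # 10 mA x 2 ms: C recruitment ~1; observed mean within 3 SE
        events = amplitude_series_events(amplitudes=(10.0,), n_per_train=300, rest_s=10.0)
        spikes = simulate_train(events, geometry, seed=3)
        tensor = extract_epochs(spikes, events)
        summary = band_sums(tensor)
        per_stim = summary.band("C").sum(axis=1)
        mu = expected_evoked_sum("C", 10.0, 2.0) + 2.0 * 16 * 0.21
        se = per_stim.std(ddof=1) / np.sqrt(len(events))
        assert abs(per_stim.mean() - mu) < 3 * se

    def test_windup_series_monotone_in_expectation(self, geometry):
        mus = [
            expected_evoked_sum("C", 5.0, 2.0, index_in_train=i, train_frequency_hz=0.5)
            for i in range(20)
        ]
        assert all(b >= a for a, b in zip(mus, mus[1:]))
        assert mus[12] == mus[19]  # capped
        flat = [
            expected_evoked_sum("C", 5.0, 2.0, index_in_train=i, train_frequency_hz=0.1)
            for i in range(20)
        ]
        assert len(set(flat)) == 1


class TestSimulateNatural:
    def test_determinism(self, geometry):
        events = natural_events("mechanical", (8.0,))
        s1 = simulate_natural(events, geometry, seed=9)
        s2 = simulate_natural(events, geometry, seed=9)
        assert s1 == s2

    def test_light_hair_silent_in_superficial_sustained(self, geometry):
        from dhmea.synth import _mech_envelope

        t = np.arange(0.0, 6.0, 0.01)
        env = _mech_envelope(t, 1.4, 5.0, "superficial")
        sustained = (t >= 0.5) & (t < 5.0)
        assert np.all(env[sustained] == 0.0)
        # region thresholds: intermediate recruits at light hairs,
        # superficial only at the noxious 26 g hair
        assert _mech_envelope(t, 2.0, 5.0, "intermediate")[sustained].min() > 0.0
        assert _mech_envelope(t, 26.0, 5.0, "superficial")[sustained].min() > 0.0

    def test_thermal_contact_transient_shared(self, geometry):
        from dhmea.synth import _thermal_envelope

        t = np.arange(0.0, 6.0, 0.01)
        onset = (t >= 0.0) & (t < 0.3)
        for region in ("superficial", "intermediate", "deep"):
            e30 = _thermal_envelope(t, 30.0, 5.0, region)
            e55 = _thermal_envelope(t, 55.0, 5.0, region)
            np.testing.assert_allclose(e30[onset], e55[onset])

    def test_noxious_heat_late_ramp_superficial_deep_only(self, geometry):
        from dhmea.synth import _thermal_envelope

        t = np.arange(0.0, 6.0, 0.01)
        late = (t >= 4.5) & (t < 5.0)
        for region, grows in (("superficial", True), ("deep", True), ("intermediate", False)):
            extra = _thermal_envelope(t, 55.0, 5.0, region) - _thermal_envelope(t, 30.0, 5.0, region)
            assert (extra[late].max() > 0) == grows

    def test_overlapping_applications_rejected(self, geometry):
        events = natural_events("mechanical", (8.0, 10.0), gap_s=1.0)
        with pytest.raises(ValidationError, match="overlap"):
            simulate_natural(events, geometry)


class TestCohort:
    def test_deterministic_directory_tree(self, tmp_path, geometry):
        spec = CohortSpec(protocol="frequency_trains", n_animals=2, seed=7)
        c1 = simulate_cohort(spec, geometry, out_dir=tmp_path / "a")
        c2 = simulate_cohort(spec, geometry, out_dir=tmp_path / "b")
        for f1, f2 in zip(sorted((tmp_path / "a").iterdir()), sorted((tmp_path / "b").iterdir())):
            assert f1.read_bytes() == f2.read_bytes()

    def test_animals_are_distinct(self, geometry):
        spec = CohortSpec(protocol="frequency_trains", n_animals=3, seed=1)
        cohort = simulate_cohort(spec, geometry)
        assert cohort[0].spikes != cohort[1].spikes != cohort[2].spikes

    def test_refuses_to_overwrite(self, tmp_path, geometry):
        spec = CohortSpec(protocol="frequency_trains", n_animals=1, seed=1)
        simulate_cohort(spec, geometry, out_dir=tmp_path)
        with pytest.raises(FileExistsError):
            simulate_cohort(spec, geometry, out_dir=tmp_path)

    def test_morphine_schedule_layout(self):
        events, t_app = morphine_schedule()
        saline = [e for e in events if e.label == "saline"]
        drug = [e for e in events if e.label == "morphine"]
        assert len(saline) == 27 and len(drug) == 81
        assert saline[-1].time_s < t_app < drug[0].time_s

    def test_duration_series_protocol(self):
        events = duration_series_events()
        assert len(events) == 100
        assert sorted({e.duration_ms for e in events}) == [0.2, 1.0, 2.0, 10.0, 20.0]

    def test_frequency_trains_protocol(self):
        events = frequency_train_events()
        f01 = [e for e in events if e.train_id == "freq_0.1"]
        f05 = [e for e in events if e.train_id == "freq_0.5"]
        assert len(f01) == len(f05) == 20
        assert np.allclose(np.diff([e.time_s for e in f05]), 2.0)
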