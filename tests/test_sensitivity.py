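"""LOD/LOQ threshold scan, the conservative reference rule, and censoring."""

import pytest
from hypothesis import given, settings, strategies as st

import wbequant as w
from wbequant.sensitivity import ReferenceState


def obs(compound, pairs):
    return [w.SnObservation(compound, level, sn) for level, sn in pairs]


class TestRunLodLoq:
    def test_threshold_scan(self):
        lod, loq = w.run_lod_loq(
            obs("x", [(0.01, 1), (0.05, 4), (0.1, 12), (1, 40)])
        )
        assert (lod, loq) == (0.05, 0.1)

    def test_all_levels_above_loq_threshold(self):
        lod, loq = w.run_lod_loq(obs("x", [(0.01, 15), (0.1, 30), (1, 60)]))
        assert lod == loq == 0.01

    def test_monotone_suffix_rule_on_dip(self):
        # a dip below threshold at 0.05 invalidates the lower crossing
        lod, _ = w.run_lod_loq(obs("x", [(0.01, 5), (0.05, 2), (0.1, 12)]))
        assert lod == 0.1

    def test_not_determined_sentinel(self):
        lod, loq = w.run_lod_loq(obs("x", [(0.01, 1), (0.1, 2)]))
        assert lod is None and loq is None

    def test_loq_at_least_lod(self):
        series = obs("x", [(0.01, 4), (0.05, 6), (0.1, 11), (1, 50)])
        lod, loq = w.run_lod_loq(series)
        assert loq >= lod

    def test_mixed_compounds_rejected(self):
        with pytest.raises(ValueError, match="mixes"):
            w.run_lod_loq(
                [w.SnObservation("a", 1, 5), w.SnObservation("b", 1, 5)]
            )


class TestReferenceRule:
    def test_run_below_reference_reports_average(self):
        history = [0.005] * 5
        assert w.apply_reference_rule(history, 0.002) == 0.005

    def test_run_above_reference_reports_run(self):
        history = [0.005] * 5
        assert w.apply_reference_rule(history, 0.008) == 0.008

    def test_fixed_point(self):
        history = [0.001] * 5
        assert w.apply_reference_rule(history, 0.001) == 0.001

    def test_before_five_runs_reports_run_value(self):
        assert w.apply_reference_rule([0.01, 0.02], 0.003) == 0.003

    @given(
        history=st.lists(
            st.floats(min_value=1e-4, max_value=1.0), min_size=5, max_size=9
        ),
        run=st.floats(min_value=1e-4, max_value=1.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_conservatism(self, history, run):
        reference = sum(history[:5]) / 5
        reported = w.apply_reference_rule(history, run)
        assert reported >= reference
        assert reported >= run

    def test_state_freezes_after_five_determinations(self, tmp_path):
        state = ReferenceState()
        for i, v in enumerate([0.001, 0.002, 0.003, 0.002, 0.002]):
            rec = state.update("x", f"run{i}", v, v * 3)
            assert rec.lod_reported == v  # reference not yet formed
        assert state.reference("x", "lod") == pytest.approx(0.002)
        rec = state.update("x", "run5", 0.0005, 0.0015)
        assert rec.lod_reported == pytest.approx(0.002)
        # a sixth low run does not shift the frozen reference
        state.update("x", "run6", 0.0001, 0.0003)
        assert state.reference("x", "lod") == pytest.approx(0.002)
        # round-trips through the JSON state file
        path = tmp_path / "lodloq.json"
        state.save(path)
        again = ReferenceState.load(path)
        assert again.reference("x", "lod") == pytest.approx(0.002)

    def test_nondetect_runs_do_not_count_toward_reference(self):
        state = ReferenceState()
        for i in range(3):
            state.update("x", f"run{i}", None, None)
        for i in range(5):
            state.update("x", f"det{i}", 0.01, 0.03)
        assert state.reference("x", "lod") == pytest.approx(0.01)


class TestCensor:
    @pytest.mark.parametrize(
        "conc,expected",
        [
            (0.0005, "below_lod"),
            (0.003, "between_lod_loq"),
            (0.006, "quantified"),  # boundary: half-open [lod, loq)
            (-0.1, "below_lod"),
            (0.001, "between_lod_loq"),  # exactly at LOD
        ],
    )
    def test_statuses(self, conc, expected):
        assert w.censor(conc, lod=0.001, loq=0.006) == expected

    def test_inverted_limits_rejected(self):
        with pytest.raises(ValueError):
            w.censor(1.0, lod=2.0, loq=1.0)


def test_sn_series_from_peaks():
    peaks = [
        w.PeakRecord("c0", "x", "quant", 100.0, height=30.0, noise_sd=10.0),
        w.PeakRecord("c1", "x", "quant", 200.0, height=0.0, noise_sd=10.0),
    ]
    manifest = [
        w.SampleMeta("c0", "calibrant", nominal={"x": 0.1}),
        w.SampleMeta("c1", "calibrant", nominal={"x": 0.2}),
    ]
    series = w.sn_series(peaks, manifest)
    assert [(o.level, o.sn) for o in series] == [(0.1, 3.0), (0.2, 0.0)]


def test_sn_series_missing_noise_warns():
    peaks = [w.PeakRecord("c0", "x", "quant", 100.0, height=30.0)]
    manifest = [w.SampleMeta("c0", "calibrant", nominal={"x": 0.1})]
    with pytest.warns(UserWarning, match="noise_sd"):
        assert w.sn_series(peaks, manifest) == []


def test_estimated_lod_clears_threshold_on_synthetic_series(panel):
    """On a simulated dilution series the S/N at the scan's LOD is >= 3 and
    at the LOQ >= 10, and with vanishing noise LOD approaches the lowest level."""
    cfg = w.SimConfig(seed=5, height_slope=300.0, noise_floor_sd=10.0)
    peaks, manifest = w.simulate_sn_series(cfg, compound="amphetamine")
    series = w.sn_series(peaks, manifest)
    lod, loq = w.run_lod_loq(series)
    sn_at = {o.level: o.sn for o in series}
    assert sn_at[lod] >= 3.0
    assert sn_at[loq] >= 10.0
    # noise-free limit: every level detectable
    cfg0 = w.SimConfig(seed=5, height_slope=300.0, noise_floor_sd=1e-9)
    peaks0, manifest0 = w.simulate_sn_series(cfg0)
    lod0, _ = w.run_lod_loq(w.sn_series(peaks0, manifest0))
    assert lod0 == pytest.approx(0.001)
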