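"""Concentration scaling, batch quantitation, QC gates, run queues."""

import numpy as np
import pytest

import wbequant as w
from wbequant.quantify import QuantifyError


class TestConcentrationFactor:
    def test_reference_aliquot(self):
        # 100 g at density 1.0 -> 0.1 L; 0.5 mL extract -> factor 5
        assert w.concentration_factor(100, 1.0, 0.5) == pytest.approx(5.0)
        assert 10 * w.concentration_factor(100, 1.0, 0.5) == pytest.approx(50.0)

    def test_density_mass_ratio_invariance(self):
        assert w.concentration_factor(102, 1.02, 0.5) == pytest.approx(
            w.concentration_factor(100, 1.00, 0.5)
        )

    def test_unit_coherence(self):
        base = w.concentration_factor(100, 1.0, 0.5)
        assert w.concentration_factor(200, 1.0, 0.5) == pytest.approx(base / 2)
        assert w.concentration_factor(100, 1.0, 1.0) == pytest.approx(base * 2)

    @pytest.mark.parametrize("mass,density,vol", [(0, 1, 0.5), (100, 0, 0.5), (100, 1, 0)])
    def test_nonpositive_inputs_rejected(self, mass, density, vol):
        with pytest.raises(QuantifyError):
            w.concentration_factor(mass, density, vol)


def _fit(compound, slope=1.0, intercept=0.0):
    return w.CalibrationFit(compound, slope, intercept, "1/x", 1.0, (0.001, 200), 22, True)


class TestQuantifyBatch:
    def test_field_sample_scaling_and_status(self, panel):
        peaks = [
            w.PeakRecord("f1", "cocaine", "quant", 10_000.0),
            w.PeakRecord("f1", "cocaine-d3", "quant", 1_000.0),
        ]
        manifest = [w.SampleMeta("f1", "field", mass_g=100.0, site_id="s")]
        ms = w.quantify_batch(
            peaks, manifest, {"cocaine": _fit("cocaine")},
            {"cocaine": (0.01, 0.05)}, panel,
        )
        (m,) = ms
        assert m.extract_conc == pytest.approx(10.0)
        assert m.sample_conc == pytest.approx(50.0)  # x5 concentration factor
        assert m.status == "quantified"
        assert m.lod_ngl == pytest.approx(0.05)

    def test_negative_inversion_zero_censored(self, panel):
        peaks = [
            w.PeakRecord("f1", "cocaine", "quant", 0.0),
            w.PeakRecord("f1", "cocaine-d3", "quant", 1_000.0),
        ]
        manifest = [w.SampleMeta("f1", "field", mass_g=100.0)]
        (m,) = w.quantify_batch(
            peaks, manifest, {"cocaine": _fit("cocaine", intercept=0.1)},
            {"cocaine": (0.01, 0.05)}, panel,
        )
        assert m.extract_conc < 0
        assert m.status == "below_lod"
        assert m.sample_conc == 0.0

    def test_unaccepted_fit_not_quantified(self, panel):
        bad = w.CalibrationFit("cocaine", 1.0, 0.0, "1/x", 0.9, (0.001, 200), 22, False)
        peaks = [
            w.PeakRecord("f1", "cocaine", "quant", 10.0),
            w.PeakRecord("f1", "cocaine-d3", "quant", 10.0),
        ]
        manifest = [w.SampleMeta("f1", "field", mass_g=100.0)]
        with pytest.warns(UserWarning, match="not quantifiable"):
            ms = w.quantify_batch(
                peaks, manifest, {"cocaine": bad}, {"cocaine": (0.01, 0.05)}, panel
            )
        assert ms == []

    def test_blank_sample_clean_on_noise_free_data(self, panel):
        cfg = w.SimConfig(seed=3, compounds=("cocaine",), noise_cv=0.0,
                          suppression_range=(1.0, 1.0), n_sites=1, n_weeks=1)
        peaks, manifest, _, _ = w.simulate_batch(cfg, panel)
        fits = {"cocaine": _fit("cocaine", slope=0.1)}
        ms = w.quantify_batch(peaks, manifest, fits, {"cocaine": (0.001, 0.006)}, panel)
        blanks = [m for m in ms if m.sample_id == "blank0"]
        assert blanks and all(m.status == "below_lod" for m in blanks)


class TestQcEvaluate:
    def mk(self, values):
        return [
            w.Measurement(f"qc{i}", "cocaine", v, v, "quantified", 0.01, 0.05)
            for i, v in enumerate(values)
        ]

    def test_accuracy_within_band_passes(self):
        report = w.qc_evaluate(self.mk([110, 110, 110]), {"cocaine": 100})
        assert report.accuracy_pct["cocaine"] == pytest.approx(110.0)
        assert report.accuracy_pass

    def test_accuracy_outside_band_fails(self):
        report = w.qc_evaluate(self.mk([79, 79, 79]), {"cocaine": 100})
        assert report.accuracy_pct["cocaine"] == pytest.approx(79.0)
        assert not report.accuracy_pass

    def test_boundary_inclusive(self):
        report = w.qc_evaluate(self.mk([80, 80, 80]), {"cocaine": 100})
        assert report.accuracy_pass

    def test_zero_rsd(self):
        report = w.qc_evaluate(self.mk([100, 100, 100]), {"cocaine": 100})
        assert report.rsd_pct["cocaine"] == pytest.approx(0.0)
        assert report.precision_pass

    def test_single_replicate_rejected(self):
        with pytest.raises(QuantifyError, match="2 QC replicates"):
            w.qc_evaluate(self.mk([100]), {"cocaine": 100})

    def test_zero_nominal_rejected(self):
        with pytest.raises(QuantifyError, match="nonzero"):
            w.qc_evaluate(self.mk([1, 1]), {"cocaine": 0})


class TestRunQueue:
    def test_deterministic_permutation(self):
        ids = [f"s{i}" for i in range(20)]
        q1 = w.build_run_queue(ids, seed=42)
        q2 = w.build_run_queue(ids, seed=42)
        assert q1 == q2
        assert sorted(q1) == sorted(ids)

    def test_different_seeds_differ(self):
        ids = [f"s{i}" for i in range(20)]
        assert w.build_run_queue(ids, seed=1) != w.build_run_queue(ids, seed=2)


def test_substitution_policies():
    below = w.Measurement("s", "c", -0.1, 0.0, "below_lod", 10.0, 30.0)
    assert w.substitute(below, "half_lod") == pytest.approx(5.0)
    assert w.substitute(below, "zero") == 0.0
    assert w.substitute(below, "lod_over_sqrt2") == pytest.approx(10 / np.sqrt(2))
    assert w.substitute(below, "exclude") is None
    quant = w.Measurement("s", "c", 2.0, 10.0, "quantified", 1.0, 3.0)
    assert w.substitute(quant, "half_lod") == 10.0


def test_recovery_correction_divides_out_efficiency(panel):
    peaks = [
        w.PeakRecord("f1", "cocaine", "quant", 10_000.0),
        w.PeakRecord("f1", "cocaine-d3", "quant", 1_000.0),
    ]
    manifest = [w.SampleMeta("f1", "field", mass_g=100.0)]
    fits = {"cocaine": _fit("cocaine")}
    limits = {"cocaine": (0.01, 0.05)}
    (plain,) = w.quantify_batch(peaks, manifest, fits, limits, panel)
    (corrected,) = w.quantify_batch(
        peaks, manifest, fits, limits, panel, recovery_correction={"cocaine": 0.8}
    )
    assert corrected.sample_conc == pytest.approx(plain.sample_conc / 0.8)
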