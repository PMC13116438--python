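"""Per-capita excretion and consumption back-calculation."""

import datetime

import pytest
from hypothesis import given, settings, strategies as st

import wbequant as w
from wbequant.backcalc import BackcalcError, pk_for_compound


class TestExcretionRate:
    def test_unit_arithmetic(self):
        # 1000 ng/L * 1e7 L/day = 1e10 ng/day = 1e4 mg/day; per 100 thousand-inh
        assert w.excretion_rate(1000, 1e7, 100_000) == pytest.approx(100.0)

    def test_zero_concentration(self):
        assert w.excretion_rate(0, 1e7, 100_000) == 0.0

    def test_population_proportionality(self):
        assert w.excretion_rate(50, 1e6, 200_000) == pytest.approx(
            w.excretion_rate(50, 1e6, 100_000) / 2
        )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(BackcalcError):
            w.excretion_rate(1, 0, 1000)
        with pytest.raises(BackcalcError):
            w.excretion_rate(1, 1e6, 0)

    @given(
        conc=st.floats(0, 1e5),
        flow=st.floats(1e5, 1e8),
        pop=st.floats(1e3, 1e7),
        c=st.floats(0.1, 10),
    )
    @settings(deadline=None, max_examples=100)
    def test_linearity_in_concentration_and_flow(self, conc, flow, pop, c):
        base = w.excretion_rate(conc, flow, pop)
        assert w.excretion_rate(c * conc, flow, pop) == pytest.approx(c * base, rel=1e-12)
        assert w.excretion_rate(conc, c * flow, pop) == pytest.approx(c * base, rel=1e-12)


class TestConsumptionRate:
    def test_parent_measured(self):
        pk = w.PkConstants(0.5, 300.0, 300.0)
        assert w.consumption_rate(100, pk, measured_is_metabolite=False) == pytest.approx(200)

    def test_metabolite_measured_mw_correction(self):
        pk = w.PkConstants(0.5, 360.0, 300.0)  # mw ratio 1.2
        assert w.consumption_rate(100, pk, measured_is_metabolite=True) == pytest.approx(240)

    def test_full_excretion_identity(self):
        pk = w.PkConstants(1.0, 300.0, 300.0)
        assert w.consumption_rate(123.4, pk, False) == pytest.approx(123.4)

    def test_consumption_at_least_excretion(self):
        pk = w.PkConstants(0.3, 303.35, 289.33)
        assert w.consumption_rate(10, pk, True) >= 10


def test_pk_from_panel_benzoylecgonine(panel):
    pk, parent, is_metab = pk_for_compound(panel, "benzoylecgonine")
    assert parent == "cocaine" and is_metab
    assert pk.mw_parent == pytest.approx(303.35)
    assert pk.mw_metabolite == pytest.approx(289.33)


def test_pk_missing_fraction_gives_none(panel):
    pk, parent, is_metab = pk_for_compound(panel, "carfentanil")
    assert pk is None and parent == "carfentanil" and not is_metab


class TestRatesForDataset:
    def make(self, n_sites=2, n_weeks=3):
        date = datetime.date(2025, 1, 6)
        manifest, measurements, sites = [], [], []
        for k in range(n_sites):
            sid = f"site{k}"
            sites.append(w.SiteMeta(sid, population=100_000, flow_l_per_day=1e7))
            for t in range(n_weeks):
                sample = f"f{k}w{t}"
                manifest.append(
                    w.SampleMeta(
                        sample, "field", mass_g=100.0, site_id=sid,
                        collected_on=date + datetime.timedelta(weeks=t),
                    )
                )
                measurements.append(
                    w.Measurement(sample, "benzoylecgonine", 200.0, 1000.0,
                                  "quantified", 1.0, 3.0)
                )
        return measurements, manifest, sites

    def test_one_record_per_field_measurement(self, panel):
        measurements, manifest, sites = self.make()
        records, means = w.rates_for_dataset(measurements, manifest, sites, panel)
        assert len(records) == len(measurements)  # n_sites x n_weeks
        assert means["benzoylecgonine"] == pytest.approx(100.0)

    def test_metabolite_attributed_to_parent(self, panel):
        measurements, manifest, sites = self.make(1, 1)
        (rec,), _ = w.rates_for_dataset(measurements, manifest, sites, panel)
        assert rec.compound == "benzoylecgonine"
        assert rec.parent_compound == "cocaine"
        # excretion 100; /0.29 and x (303.35/289.33)
        assert rec.excretion_rate == pytest.approx(100.0)
        assert rec.consumption_rate == pytest.approx(100 / 0.29 * 303.35 / 289.33)

    def test_missing_site_join_errors_with_ids(self, panel):
        measurements, manifest, _ = self.make(1, 1)
        with pytest.raises(BackcalcError, match="f0w0"):
            w.rates_for_dataset(measurements, manifest, [], panel)

    def test_censored_contribution_follows_policy(self, panel):
        _, manifest, sites = self.make(1, 1)
        below = [
            w.Measurement("f0w0", "benzoylecgonine", -1.0, 0.0, "below_lod", 50.0, 150.0)
        ]
        (rec,), means = w.rates_for_dataset(below, manifest, sites, panel)
        assert rec.flags == "below_lod"
        # LOD/2 = 25 ng/L -> 2.5 mg/day/1000
        assert rec.excretion_rate == pytest.approx(2.5)
        records, means = w.rates_for_dataset(
            below, manifest, sites, panel, substitution="exclude"
        )
        assert records == [] and means == {}

    def test_dated_site_record_wins_over_constant(self, panel):
        measurements, manifest, sites = self.make(1, 1)
        dated = w.SiteMeta(
            "site0", population=100_000, flow_l_per_day=2e7,
            measured_on=datetime.date(2025, 1, 6),
        )
        (rec,), _ = w.rates_for_dataset(measurements, manifest, sites + [dated], panel)
        assert rec.excretion_rate == pytest.approx(200.0)  # used the dated flow
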