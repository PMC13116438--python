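"""Back-calculate per-capita excretion and consumption rates.

1000 ng/L of benzoylecgonine at a plant treating 10 ML/day for 100 000
people is a 10 g/day load, i.e. 100 mg/day per 1000 inhabitants excreted;
dividing by the urinary excretion fraction (0.29) and correcting by the
cocaine/benzoylecgonine molecular-weight ratio gives cocaine consumption.
"""

import wbequant as w

panel = w.default_panel()

exc = w.excretion_rate(conc_ngl=1000.0, flow_l_per_day=1e7, population=100_000)
print(f"excretion rate: {exc:.1f} mg/day per 1000 inhabitants")

pk, parent, is_metab = w.backcalc.pk_for_compound(panel, "benzoylecgonine")
cons = w.consumption_rate(exc, pk, is_metab)
print(f"consumption of {parent}: {cons:.1f} mg/day per 1000 inhabitants "
      f"(f_excr={pk.excretion_fraction}, MW ratio={pk.mw_parent/pk.mw_metabolite:.4f})")
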