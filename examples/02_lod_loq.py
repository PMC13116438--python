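"""Estimate LOD/LOQ from signal-to-noise and apply the conservative
five-run reference rule.

The scan returns the lowest calibrant level from which every higher level
keeps S/N >= 3 (LOD) or >= 10 (LOQ). After five runs, the reported limit is
max(run value, five-run mean) — a run is never trusted below the reference.
"""

import wbequant as w

cfg = w.SimConfig(seed=3, height_slope=300.0, noise_floor_sd=10.0)
peaks, manifest = w.simulate_sn_series(cfg, compound="amphetamine")
series = w.sn_series(peaks, manifest)
lod, loq = w.run_lod_loq(series)
print(f"run LOD = {lod:.4f} ng/mL, LOQ = {loq:.4f} ng/mL "
      f"(theory: S/N=3 at {3*cfg.noise_floor_sd/cfg.height_slope:.3f} ng/mL)")

state = w.ReferenceState()
for run in range(7):
    cfg = w.SimConfig(seed=100 + run, height_slope=300.0, noise_floor_sd=10.0)
    peaks, manifest = w.simulate_sn_series(cfg, compound="amphetamine")
    lod, loq = w.run_lod_loq(w.sn_series(peaks, manifest))
    rec = state.update("amphetamine", f"run{run}", lod, loq)
    ref = f"{rec.reference_lod:.4f}" if rec.reference_lod else "not yet set"
    print(f"run{run}: lod_run={rec.lod_run:.4f} -> reported={rec.lod_reported:.4f} "
          f"(reference {ref})")
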