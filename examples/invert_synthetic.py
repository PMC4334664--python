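"""Bayesian inversion and hierarchy comparison on one synthetic dataset.

Draws a circuit from the prior, generates its noisy cross spectra at a
signal-to-noise variance ratio of exp(7), and fits two competing models:
one with the true (veridical) forward/backward arrangement and one with
the hierarchy reversed.  The free-energy difference is the log evidence
for the true model; exp of it is the posterior odds.
"""

import numpy as np

import cmcsd

prior = cmcsd.PriorDensity.default()
freqs = np.arange(4.0, 81.0, 4.0)

truth = cmcsd.sample_prior(prior, seed=11)
dataset = cmcsd.generate_dataset(truth, freqs, log_precision=7.0, seed=42)

report = cmcsd.compare_models(dataset.data, prior, max_iter=48)

print("free energy (log evidence bound):")
for d, F in report.free_energy.items():
    print(f"  {d:<10} {F:10.2f}")
print(f"difference:     {report.delta_free_energy:+.2f} "
      "(positive favors the veridical hierarchy)")
print(f"selected model: {report.selected}")
odds = report.odds_ratio
print(f"posterior odds: {'> 1e6' if odds > 1e6 else f'{odds:.3g}'} : 1")
print("reduced (accuracy-only) evidence on the cross-spectral block:")
for d, r in report.reduced_cross.items():
    print(f"  {d:<10} {r:10.2f}")
print("(a difference of 3 already corresponds to about 20:1 odds)")
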