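"""Noise and initialization robustness of the EZ estimate.

Reduced replicas of the two validation experiments on the bundled
24-region scenario: (a) add Gaussian sensor noise at decreasing SNR and
find where perfect EZ recovery breaks; (b) start the optimizer away from
the prior means with increasing proposal SD and find where recovery
degrades.

This is the long-running example (several full MAP fits; expect ~10
minutes on one CPU at this scale; widen the grids and replicate counts
for smoother curves).
"""

from epimap.forward import SeizureScenario, scenario_network
from epimap.mapping import init_robustness_experiment, snr_robustness_experiment

connectome, gain = scenario_network(seed=0)
scenario = SeizureScenario()

snr_table = snr_robustness_experiment(
    scenario, connectome, gain,
    snr_grid=[0.1, 0.9, 2.5], n_replicates=1, seed=0)
print(snr_table.groupby("snr")[["precision", "recall", "perfect"]].mean())
print(f"critical SNR for perfect recovery: {snr_table.attrs['critical_snr']}")

init_table = init_robustness_experiment(
    scenario, connectome, gain,
    sd_grid=[0.1, 0.7, 0.9], n_starts=1, seed=0)
print(init_table.groupby("sd")[["precision", "recall", "perfect"]].mean())
print(f"recovery degrades at proposal SD: "
      f"{init_table.attrs['degradation_sd']}")
# Recovery is perfect at the top of the SNR range and collapses towards
# the bottom; initializations sampled close to the prior means reach the
# same optimum, while wide proposals increasingly land in spurious modes.
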