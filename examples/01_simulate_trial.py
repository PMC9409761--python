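"""Generate a synthetic augmented trial and inspect its ground truth.

The generator emulates a landrace characterisation trial: 4 blocks, 3
replicated check varieties, 100 unreplicated test entries (112 plots) and
17 correlated quantitative traits at realistic means and variances.
"""

from phenodiv import default_simulation_config, simulate_augmented_trial

config = default_simulation_config(seed=1)
trial, truth = simulate_augmented_trial(config)

print(f"plots: {len(trial.records)}  genotypes: {len(trial.genotypes)} "
      f"({len(trial.checks)} checks x {len(trial.blocks)} blocks + {len(trial.tests)} tests)")
print("\nGround truth for the first five traits (variances in squared trait units):")
print(truth.as_frame().head().to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\nh2_true is the proportion of plot-level variance that is genotypic; the")
print("analysis pipeline should recover these values from the simulated plots.")
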