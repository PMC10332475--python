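"""Score the pipeline on a small synthetic cohort with known ground truth.

Simulates seedlings across the 15-30 cm height range, runs the full
pipeline on each, and reports Pearson R, RMSE, MAE and accuracy
(100 (1 - MAE/mean)) per trait.  The leaf-count model is calibrated first
on a separate cohort.  A small n keeps this demo quick; the acceptance
script runs the full 20-plant protocol.
"""

from seedlingpheno.pipeline import calibrate_density_model, cohort_eval

model = calibrate_density_model(n_plants=4, seed=900)
print(f"leaf-count model: count = {model.slope:.0f} * density + {model.intercept:.1f} "
      f"(R^2 = {model.r_squared:.2f}, {model.n_samples} regions)")

cohort = cohort_eval(n_plants=6, seed=42, density_model=model)
for trait in ("height", "diameter", "stem_length", "regional_leaf_length"):
    ev = cohort.summary[trait]
    print(f"{trait:22s} R={ev.r:+.3f}  MAE={ev.mae:.4g}  accuracy={ev.accuracy:.1f}%")
print(f"leaf count relative MAE: {cohort.summary['leaf_count_relative_mae_pct']:.1f}% "
      "of the mean true count")
# Height recovers almost exactly; stem length and leaf traits carry the
# method's slice/convex-hull biases; diameter runs above truth because 1 mm
# noise widens a millimetre-scale stem shell.
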