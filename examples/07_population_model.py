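"""The three-layer probabilistic population-code model vs an accumulator.

Runs single trials through the stimulus (kappa=5) -> template (kappa=2) ->
decision layers, then compares the decision-layer dissimilarity structure
of the population model with the single-node matched-filter accumulator.
"""

import numpy as np

from popdecode import popmodel, rsa

model = popmodel.PopulationModel()

print("delta   decision peak (deg)   peak height")
for d in (0.0, 11.25, 33.75, 90.0):
    out = model.run_trial((90.0 + d) % 180.0, 90.0)
    r = out["readout"]
    print(f"{d:5.2f}   {r.peak_location_deg:+8.2f}            "
          f"{r.peak_height:.3f}")

rdms = popmodel.model_rdms(model)
acc = popmodel.model_rdms(model, accumulator=True)
g = rdms["delta_grid"]
print("\nsign separability d(+tilt, -tilt) in the decision layer:")
for tilt in (11.25, 22.5, 33.75):
    ia = int(np.flatnonzero(np.isclose(g, tilt))[0])
    ib = int(np.flatnonzero(np.isclose(g, -tilt))[0])
    print(f"  {tilt:5.2f} deg: population {rdms['decision_layer'][ia, ib]:.3f}"
          f"   accumulator {acc['decision_layer'][ia, ib]:.3f}")

pop_xy = rsa.mds_embed(rdms["decision_layer"]).std(axis=0)
acc_xy = rsa.mds_embed(acc["decision_layer"]).std(axis=0)
print(f"\nMDS extent (dim1, dim2): population ({pop_xy[0]:.2f}, "
      f"{pop_xy[1]:.2f}), accumulator ({acc_xy[0]:.2f}, {acc_xy[1]:.2f})")
print("The population code separates clockwise from counterclockwise "
      "mismatches (elliptical 2-D geometry); the scalar accumulator "
      "carries only the magnitude and its geometry collapses to a line.")
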