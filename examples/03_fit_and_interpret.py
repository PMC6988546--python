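"""Fit one maximum-entropy model and interpret it.

Shows the feature expansion under the autofeature rule, the cloglog
suitability index, covariate percent contribution (path-dependent) and
permutation importance, and a single-variable response curve.
"""

import streamsdm as sdm
from streamsdm.synthetic import RiverscapeParams, generate_riverscape

params = RiverscapeParams(n_segments=2000, n_presences=40, seed=1)
segments, presences, _ = generate_riverscape(params)
presences = sdm.dedupe_presences(presences, segments)

features = sdm.build_features(segments, presences.segment_ids, classes="auto")
print(f"autofeature at n={len(presences)}: classes {features.classes}, "
      f"{len(features)} features")

model = sdm.fit(features, presences.segment_ids, segments, beta=1.0)
print(f"nonzero coefficients: {sdm.count_nonzero(model)}")

pred = sdm.predict(model, segments)
print(f"raw density sums to {pred.raw.sum():.6f} over the background; "
      f"cloglog suitability spans {pred.cloglog.min():.3f}-{pred.cloglog.max():.3f}")

print("percent contribution (%):")
print(sdm.percent_contribution(model).round(1).to_string())
print("permutation importance (%):")
print(sdm.permutation_importance(model, presences.segment_ids, segments,
                                 seed=5).round(1).to_string())

curve = sdm.response_curve(model, "Q", n_points=8)
print("discharge response curve (cloglog vs m^3/s):")
print(curve.round(3).to_string(index=False))
print("Suitability rises with discharge and saturates - the single "
      "covariate driving the synthetic truth dominates both importance "
      "measures.")
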