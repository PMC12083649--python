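"""Spatial-vs-pooled recapitulation benchmark (ROC / AUC).

The pooled assay's per-sgRNA detection fraction (share of tumor lobes in
which the guide was seen) predicts the spatial response "sgRNA area > 2
spots".  On synthetic data the coupling is logistic in clone size, so the
AUC is well above chance.
"""

from spotscreen.roc import build_benchmark, roc_auc
from spotscreen.sim import SceneParams, simulate_scene

scene = simulate_scene(SceneParams(), seed=0)
print(scene.pooled.sort_values("spatial_area", ascending=False)
      .head(8).to_string(index=False))

bench = build_benchmark(scene.pooled, area_cutoff=2, pooled_cutoff=0.25)
res = roc_auc(bench["scores"], bench["labels"])
print(f"\nAUC = {res['auc']:.3f} "
      f"({res['n_pos']} spatially detected, {res['n_neg']} not)")
print("confusion at pooled fraction > 0.25:", bench["confusion"])
# AUC is the probability that a randomly chosen spatially detected sgRNA
# has a higher pooled detection fraction than an undetected one (ties
# count half); 0.5 would mean the two assays do not agree at all.
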