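"""Spike-in scaling of read counts between samples.

Each sample's primary-genome count is divided by its spike-genome count
and multiplied by the smallest spike count in the batch, so the sample
with the fewest spike reads keeps its raw count and the others are scaled
onto the same absolute footing.
"""
from loophub import SpikeCounts, chiprx_factors, interaction_fold_change

batch = [
    SpikeCounts("control", 1000, 200),
    SpikeCounts("treated", 800, 100),
]
for s in chiprx_factors(batch):
    print(f"{s.sample_id:8s} primary={s.primary_count:6.0f} spike={s.spike_count:4.0f}"
          f"  factor={s.scale_factor:.2f}  normalised={s.normalized:.0f}")

print("\nThe treated sample had half the spike reads, so its primary signal "
      "is kept while the control is scaled down by 0.5: an apparent 1000 vs "
      "800 becomes a true 500 vs 800.")

fc = interaction_fold_change(n_treated=800, factor_treated=1.0,
                             n_control=1000, factor_control=0.5)
print(f"spike-corrected fold change of total interactions: {fc:.2f}")
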