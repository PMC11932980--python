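"""The ordered target statistic: leakage-free categorical encoding.

Encodes a categorical feature by the running mean of earlier items'
labels (plus a prior), visiting items in a random order — the device
ordered boosting uses so an item's own label never leaks into its encoding.
"""

from evoppi import TargetStatConfig, ordered_target_statistic

categories = ["kinase", "kinase", "receptor", "kinase", "receptor"]
labels = [1, 0, 1, 1, 0]

encoded = ordered_target_statistic(
    categories, labels,
    TargetStatConfig(prior_p=0.5, prior_weight=1.0,
                     permutation=(0, 1, 2, 3, 4)))

for cat, lab, enc in zip(categories, labels, encoded):
    print(f"{cat:>9}  label={lab}  encoded={enc:.3f}")
# the first item of each category gets the pure prior (0.5); later items
# shift toward the mean label of the earlier items in the same category
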