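"""Compare median-fold-change and mean (TIC) normalization under asymmetric
biological change.

A growing fraction of features is multiplied by 3 (increases only) in each
spectrum; the table shows the median relative error of the recovered
per-spectrum scale factors.  The median of ratios ignores any minority of
changing features, so mfc stays exact up to (but excluding) half of the
features changed, while the mean is dragged up immediately.
"""

from msistream.synthetic import mfc_recovery_study

df = mfc_recovery_study(n_spectra=100, n_features=2000, n_seeds=5,
                        fractions=[0.0, 0.1, 0.2, 0.3, 0.4, 0.45, 0.5], seed=0)
table = df.pivot(index="fraction", columns="method", values="median_rel_error")
print("median relative error of recovered scale factors:")
print(table.round(3).to_string())
largest = df[(df.method == "mfc") & (df.median_rel_error <= 0.05)]["fraction"].max()
print(f"\nmfc remains within 5% up to a perturbed fraction of {largest:.2f};")
print("at exactly 0.5 the median of ratios sits between the clean and the")
print("3-fold group (its breakdown boundary), and the mean method is already")
print("off by tens of percent at 0.1.")
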