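"""Multi-way factor analysis of the packaged Rome year tables.

Standardises the four 9x7 mean-patch-size tables (1949, 1974, 1999,
2016), fits the MFA and prints the eigenvalue spectrum, the retained
axes and the between-year RV similarity matrix.
"""

from morphoscape import datasets, fit, standardize

tables = datasets.load_mean_patch_size()
std = {year: standardize(t) for year, t in tables.items()}
result = fit(std, variant="mfa")

print("eigenvalues and variance shares:")
for i, (lam, pct) in enumerate(zip(result.eigenvalues, result.percent_variance), 1):
    kept = "retained" if i <= result.n_retained else ""
    print(f"  axis {i}: eigenvalue {lam:6.3f}  {pct:5.1f} %  {kept}")
print(f"\n{result.n_retained} axes have eigenvalue > 1; together they carry "
      f"{result.percent_variance[: result.n_retained].sum():.1f} % of the variance.")

print("\nRV similarity between year configurations (1 = identical):")
print(result.rv.round(3).to_string())
print("\nThe lowest RV marks the pair of consecutive dates with the most")
print("intense landscape reorganisation between them.")
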