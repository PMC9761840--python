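"""Probit analysis of an observed mixture bioassay.

Takes the observed 96-h mortality of Nile tilapia exposed to the
mancozeb-chlorpyrifos mixture (20 fish per concentration), fits the
probit line probit(p) = a + b*log10(C) by maximum likelihood, and reports
the 96-h LC50 with Fieller 95% limits plus the standard acute-toxicity
category.
"""

from lethaltime import classify_toxicity, effective_level, fit_probit
from lethaltime import datasets as ds

rows = ds.OBSERVED_MORTALITY[(ds.TILAPIA, ds.MC)]
groups = [(conc, 20, 20 * pcts[-1] / 100) for conc, pcts in rows]
print("concentration (mg/L) vs observed 96-h mortality:")
for conc, pcts in rows:
    print(f"  {conc:5.2f}  {pcts[-1]:3d}%")

fit = fit_probit(groups, metameter="concentration")
lc50 = effective_level(fit, 0.5)
print(f"\nprobit line: probit(p) = {fit.intercept:.3f} + {fit.slope:.3f}*log10(C)")
print(f"goodness of fit: chi2 = {fit.chi2:.2f} on {fit.df} df "
      f"(heterogeneity {fit.heterogeneity:.2f})")
print(f"96-h LC50 = {lc50.estimate:.2f} mg/L "
      f"(95% fiducial limits {lc50.lower95:.2f}-{lc50.upper95:.2f})")
print(f"category: {classify_toxicity(lc50.estimate)}")
print("\nThe slope measures how steeply mortality rises per tenfold "
      "concentration increase; the limits widen if chi2/df > 1.")
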