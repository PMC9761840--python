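"""Concentration-addition prediction and the model deviation ratio.

Combines the single-pesticide lethal concentrations of atrazine and
mancozeb for catfish at five effect levels with the proportion-weighted
harmonic rule LCx_mix = 1/sum(p_i/LCx_i), fits a probit line through the
resulting (effect, LCx_mix) points to get the CA-predicted 96-h mixture
LC50, and scores it against the observed mixture LC50 with
MDR = predicted/observed.
"""

from lethaltime import ca_predicted_lc50, ca_rows_from_lcx, classify_interaction, mdr
from lethaltime import datasets as ds
from lethaltime.pipeline import ca_proportions

species, mixture = ds.CATFISH, ds.AM
props = ca_proportions(species, mixture)
lcx_by_level = {
    x: [ds.COMPONENT_LCX[(species, n)][j] for n in (ds.ATRAZINE, ds.MANCOZEB)]
    for j, x in enumerate(ds.EFFECT_LEVELS)
}
rows = ca_rows_from_lcx(lcx_by_level, props)
print("effect  LCx_atrazine  LCx_mancozeb  LCx_mix (mg/L)")
for r in rows:
    print(f"{100 * r.x:5.0f}%  {r.component_lcx[0]:12.3f}  {r.component_lcx[1]:12.3f}"
          f"  {r.lcx_mix:7.2f}")

lvl = ca_predicted_lc50(rows)
observed = ds.PREDICTED_VS_OBSERVED[(species, mixture)][0]
res = mdr(lvl.estimate, observed)
print(f"\nCA-predicted 96-h LC50: {lvl.estimate:.2f} mg/L")
print(f"observed 96-h LC50:     {observed:.2f} mg/L")
print(f"MDR = {res.mdr_display:.2f} -> {classify_interaction(res.mdr)} "
      f"({'inside' if res.valid else 'outside'} the 0.5-2 compliance band)")
print("\nMDR near 1 means the mixture behaved as the additivity model "
      "predicts; >2 would suggest synergism, <0.5 antagonism.")
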