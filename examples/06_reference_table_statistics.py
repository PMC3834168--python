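"""Group statistics over the packaged 17-patient reference table.

Reproduces the ipsilateral summary row, the deviation-size correlation, and
the lambda-chart classification of the extreme diffusivity regimes.
"""

import numpy as np

from tractbench import stats

df = stats.load_reference_table()
summ = stats.summarize(df)
print("ipsilateral summary (mean +- SD):")
for col in ("planar_area_mm2", "deviation_index", "fa", "md", "ad", "rd"):
    print(f"  {col:<16} {summ.loc[col, 'mean']:6.2f} +- "
          f"{summ.loc[col, 'sd']:.2f}")

r, p = stats.pearson(df["deviation_index"], df["planar_area_mm2"])
print(f"\nPearson r (tract deviation vs planar tumour area) = {r:.2f}, "
      f"p = {p:.4f}")
print("-> larger tumours displace the corticospinal tract further.")

chart = stats.lambda_chart(df)
lo = [int(p) for p in
      chart.patient[(chart.ad_outside == -1) & (chart.rd_outside == -1)]]
hi = [int(p) for p in
      chart.patient[(chart.ad_outside == 1) & (chart.rd_outside == 1)]]
print(f"\nlambda chart vs contralateral mean +- 2 SD bands:")
print(f"  AD and RD both reduced (compression regime): patients {lo}")
print(f"  AD and RD both increased (oedema regime):     patients {hi}")
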