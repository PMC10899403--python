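"""Recompute the reference clinical cohort's printed statistics.

The only quantities of the original study that are recomputable from its
published tables alone: the demographic chi-squares (sex, marital status)
and the Cohen's d of the eyes-open right-minus-left temporal beta1
asymmetry from its group means/SDs.  Everything else depends on the raw
recordings, which are not deposited.
"""

import json
from pathlib import Path

from eegmdd import experiments

demo = experiments.demographic_chi_squares()
d = experiments.reference_asymmetry_effect_size()

out = {"chi2_sex": demo["chi2_sex"], "p_sex": demo["p_sex"],
       "chi2_marital": demo["chi2_marital"], "p_marital": demo["p_marital"],
       "cohen_d_rtlt_beta1_eo": d}
Path("results").mkdir(exist_ok=True)
Path("results/printed_statistics.json").write_text(json.dumps(out, indent=1))

print(f"sex chi-square: {demo['chi2_sex']:.3f} (p = {demo['p_sex']:.3f})")
print(f"marital chi-square: {demo['chi2_marital']:.3f} (p = {demo['p_marital']:.3f})")
print(f"RT-LT beta1 (EO) Cohen's d from printed summaries: {d:.3f}")
print("wrote results/printed_statistics.json")
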