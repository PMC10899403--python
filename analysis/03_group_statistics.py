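"""Group contrasts: Welch t-tests, BH-FDR within families, Cohen's d.

Reads the feature table from 02 plus the metadata from 01 and writes the
150-row contrast table (2 eye states x [10 regions x 6 bands + 3 pairs x
5 bands]) and the clinical correlation table.  Prints the FDR-leading
features — in the default cohort the frontal beta2 elevations should head
the power family.
"""

import argparse
from pathlib import Path

import pandas as pd

from eegmdd.stats import clinical_correlations, group_contrast_table

ap = argparse.ArgumentParser()
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

features = pd.read_csv(args.out / "features.csv")
meta = pd.read_csv(args.out / "metadata.csv")

stats_df = group_contrast_table(features, meta, variant="welch")
corr_df = clinical_correlations(features, meta)
stats_df.to_csv(args.out / "group_stats.csv", index=False)
corr_df.to_csv(args.out / "correlations.csv", index=False)

cols = ["eye_state", "feature_type", "region_or_pair", "band",
        "t", "p_raw", "p_fdr", "cohen_d"]
print("strongest group contrasts (by FDR-adjusted p):")
print(stats_df.sort_values("p_fdr")[cols].head(8).to_string(index=False,
                                                            float_format="%.4f"))
n_sig = (stats_df.p_fdr < 0.05).sum()
print(f"{n_sig} of {len(stats_df)} features significant after FDR")
print(f"wrote {args.out / 'group_stats.csv'} and correlations.csv")
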