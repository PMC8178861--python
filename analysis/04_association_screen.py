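#!/usr/bin/env python
"""Screen every extracted feature against each consensus rating (Spearman,
p < 0.05) and contrast impairment odds between clinical groups.

Reads results/features.csv, results/consensus.csv, and the cohort labels;
writes results/screen_<characteristic>.csv and results/odds.csv.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from picdesc.association import group_odds_ratio, spearman_screen

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

features = pd.read_csv(args.out / "features.csv", index_col=0)
consensus = pd.read_csv(args.out / "consensus.csv")
labels = pd.read_csv(args.cohort / "labels.csv", index_col=0)["group"]

or_rows = []
for ch, block in consensus.groupby("characteristic"):
    ratings = block.set_index("sample_id")["consensus"].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        screened = spearman_screen(features, ratings)
    df = pd.DataFrame([
        {"feature": r.feature, "rho": r.rho, "p": r.p_value,
         "n": r.n_used, "selected": r.selected}
        for r in screened
    ]).sort_values("p")
    df.to_csv(args.out / f"screen_{ch}.csv", index=False)
    top = df.iloc[0]
    print(f"{ch:15s} {int(df.selected.sum()):3d} features selected; "
          f"strongest: {top.feature} (rho={top.rho:+.2f})")
    for a, b in (("AD", "HC"), ("MCI", "HC"), ("AD", "MCI")):
        res = group_odds_ratio(ratings, labels, a, b)
        or_rows.append({
            "characteristic": ch, "groupA": a, "groupB": b,
            "or": res.or_estimate, "lo": res.ci95[0], "hi": res.ci95[1],
            "corrected": res.corrected,
        })

pd.DataFrame(or_rows).to_csv(args.out / "odds.csv", index=False)
print(f"wrote per-characteristic screens and {args.out}/odds.csv")
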