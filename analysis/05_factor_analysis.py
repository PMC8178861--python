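#!/usr/bin/env python
"""Factor the screened variables per characteristic: parallel analysis for
the factor count, principal-axis extraction, oblimin rotation, and 0.6-cutoff
variable assignment.

Reads results/features.csv and results/screen_<characteristic>.csv; writes
results/efa_<characteristic>.csv in the report layout (variable, family,
rho, F1..Fk loadings at or above the cutoff).
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from picdesc.efa import run_efa
from picdesc.linguistic import feature_manifest

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--cutoff", type=float, default=0.6)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

features = pd.read_csv(args.out / "features.csv", index_col=0)
family = {name: fam for name, fam, _ in feature_manifest()}

for ci, screen_path in enumerate(sorted(args.out.glob("screen_*.csv"))):
    ch = screen_path.stem.removeprefix("screen_")
    screen = pd.read_csv(screen_path)
    selected = screen[screen.selected]
    if selected.empty:
        print(f"{ch:15s} no selected variables; skipping EFA")
        continue
    sub = features[selected.feature.tolist()]
    sub = sub.fillna(sub.mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_efa(sub, cutoff=args.cutoff, seed=args.seed * 1000 + ci)
    rho = dict(zip(selected.feature, selected.rho))
    rows = []
    for i, var in enumerate(res.variables):
        row = {"variable": var, "family": family.get(var, ""), "rho": rho[var]}
        for j in range(res.k):
            keep = res.assignments[var] == j and abs(res.pattern[i, j]) >= args.cutoff
            row[f"F{j + 1}"] = res.pattern[i, j] if keep else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(args.out / f"efa_{ch}.csv", index=False)
    pct = ", ".join(f"F{j + 1}={100 * v:.1f}%" for j, v in enumerate(res.var_prop))
    assigned = sum(v is not None for v in res.assignments.values())
    print(f"{ch:15s} k={res.k} ({pct}); {assigned}/{len(res.variables)} "
          f"variables assigned at |loading| >= {args.cutoff}")

print(f"wrote EFA reports to {args.out}/efa_<characteristic>.csv")
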