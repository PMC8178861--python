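#!/usr/bin/env python
"""Simulate the study cohort: 30 one-minute picture descriptions (10 HC,
10 MCI, 10 AD) with severity-linked timing, wording, and parses.

Writes transcript JSON files, group labels, and the latent severity manifest
under results/cohort/.
"""

import argparse
from pathlib import Path

from picdesc.corpus_io import write_transcript_json
from picdesc.simulate import simulate_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

cohort = simulate_cohort(seed=args.seed)
args.out.mkdir(parents=True, exist_ok=True)
for t in cohort.transcripts:
    write_transcript_json(t, args.out / f"{t.sample_id}.json")
cohort.labels.rename("group").to_csv(args.out / "labels.csv")
cohort.true_severities.round(4).to_csv(args.out / "true_severities.csv")

per_group = cohort.labels.value_counts().to_dict()
words = [len(t.tokens()) for t in cohort.transcripts]
durations = [t.duration for t in cohort.transcripts]
print(f"simulated {len(cohort.transcripts)} transcripts {per_group}")
print(f"words per sample: {min(words)}-{max(words)}; "
      f"duration: {min(durations):.0f}-{max(durations):.0f} s")
print(f"wrote transcripts, labels, and severity manifest to {args.out}/")
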