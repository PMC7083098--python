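#!/usr/bin/env python
"""Transform raw trial records to the standardized analysis scale.

Tracklength becomes body lengths (species mean SL), time-in-middle is
square-root transformed, and all four traits are centred and scaled to
global SD units pooled over every observation of every species.  Writes
data/trials_sdu.csv and the inverse-transform constants to
results/scaling.json.
"""

import argparse
from pathlib import Path

from fishid import datasets
from fishid.preprocessing import preprocess

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--trials", type=Path, default=Path("data/trials.csv"))
parser.add_argument("--outdir", type=Path, default=Path("data"))
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

raw = datasets.read_trial_table(args.trials)
sdu, rec = preprocess(raw)

args.outdir.mkdir(parents=True, exist_ok=True)
args.results.mkdir(parents=True, exist_ok=True)
sdu.to_csv(args.outdir / "trials_sdu.csv", index=False)
rec.save(args.results / "scaling.json")

print("global scaling (mean, SD) per trait:")
for t in ("TL", "Act", "AC", "TIM"):
    print(f"  {t}: {rec.means[t]:8.3f}, {rec.sds[t]:6.3f}")
print(f"wrote {args.outdir / 'trials_sdu.csv'}")
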