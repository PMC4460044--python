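#!/usr/bin/env python
"""Univariate scale-scan recovery: can cross-validated single-variable
models find the scale a virtual species actually responds to?

The species responds to deciduous cover summarised in a 1,500 m window;
the scan fits it at all eight candidate scales (500-6,000 m) over ten
independently seeded landscapes.  Writes results/scale_recovery.csv.
"""

import argparse
from pathlib import Path

from maxscale.experiments import scale_recovery_experiment

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/scale_recovery.csv"))
args = parser.parse_args()

res = scale_recovery_experiment(n_seeds=10, base_seed=args.seed)
args.out.parent.mkdir(parents=True, exist_ok=True)
res["per_seed"].to_csv(args.out, index=False)

print(res["per_seed"].to_string(index=False))
print(f"\ntrue scale (1,500 m) recovered in {res['hits']}/{res['n_seeds']} seeds")
print(f"written to {args.out}")
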