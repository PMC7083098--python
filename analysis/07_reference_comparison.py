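#!/usr/bin/env python
"""Comparison-only reanalysis of the published point estimates.

Uses no raw or simulated trial data: rebuilds the pairwise θ and 2−K tables
from the published eigen-decompositions and correlates them with the
patristic distances of the reference phylogeny.  This is the workflow that
reproduces the published comparison tables directly.
"""

import argparse
import json
from pathlib import Path

from fishid.pipeline import run_comparison_only

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

res = run_comparison_only()
args.results.mkdir(parents=True, exist_ok=True)
res["theta"].to_long().to_csv(args.results / "reference_theta_long.csv",
                              index=False)
res["two_k"].to_long().to_csv(args.results / "reference_twoK_long.csv",
                              index=False)
(args.results / "reference_taus.json").write_text(
    json.dumps(res["taus"], indent=1))

th = res["theta"].values
tk = res["two_k"].values
print("recomputed from published eigenvectors:")
print(f"  theta X. maculatus - L. nigrofasciata: "
      f"{th.loc['Xiphophorus maculatus', 'Lima nigrofasciata']:.1f} deg")
print(f"  theta X. birchmanni - X. hellerii: "
      f"{th.loc['Xiphophorus birchmanni', 'Xiphophorus hellerii']:.1f} deg")
print(f"  2-K X. hellerii - X. eiseni: "
      f"{tk.loc['Xiphophorus hellerii', 'Xenotoca eiseni']:.3f}")
print(f"  tau-b(patristic, 2-K) = {res['taus']['two_k']:.3f}; "
      f"tau-b(patristic, theta) = {res['taus']['theta']:.3f}")
print("subspace shape shows a positive phylogenetic correlation; "
      "leading-axis orientation does not")
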