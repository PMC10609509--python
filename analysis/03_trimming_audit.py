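#!/usr/bin/env python
"""Slow-fast audit of a (simulated) alignment: trimming schemes compared.

Simulates one dataset, then runs the full audit pipeline the way it would be
applied to real data: invariant-site removal, rate-category assignment under
a guide tree, the three trimming schemes (drop slow categories 1-4, drop
fast categories 10-12, drop both), per-partition bootstrap tree samples,
per-partition amino-acid composition, and an MDS picture of the tree space
the partitions explore.

Writes results/audit/ (site_rates.tsv, trimmed_*.fasta, recovery_table.tsv,
composition.tsv, mds_coordinates.tsv, rf_matrix.tsv, bootstrap_rsap*.nwk).

Usage: python analysis/03_trimming_audit.py [--seed 7]
"""

import argparse
from pathlib import Path

from slowfast.models import discretize_gamma, load_model
from slowfast.simulate import simulate_dataset
from slowfast.study import ExperimentConfig, run_audit

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=7)
args = parser.parse_args()

N_LEAVES, N_SITES = 40, 800
lg = load_model("LG")
cats = discretize_gamma(0.803, 12)
sim = simulate_dataset(N_LEAVES, N_SITES, lg, cats, seed=args.seed)

config = ExperimentConfig(
    n_leaves=N_LEAVES, n_sites=N_SITES, n_bootstrap=50, seed=args.seed
)
out = Path(__file__).resolve().parent.parent / "results" / "audit"
report = run_audit(sim.alignment, sim.tree, config, outdir=out)

print(f"invariant sites removed: {report['n_invariant_removed']}")
print("\ntrim schemes (sites kept of the variable alignment):")
for name, rep in report["trim_reports"].items():
    print(f"  {name:<10} kept {rep['n_kept']:4d}/{rep['n_input_sites']} "
          f"({rep['kept_fraction']:.1%})")
stats = report["statistics"]
if stats is not None:
    print(
        "\nSpearman rho (partition rate vs median recovered branch length): "
        f"{stats['spearman_rho']:.3f} (p={stats['spearman_p']:.3g})"
    )
comp = report["composition"]
print("\ncomposition SSE by partition (vs the variable alignment):")
print(comp[["partition", "n_residues", "sse"]].to_string(index=False))
print(f"\nfull report in {out}")
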