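#!/usr/bin/env python
"""Expected-substitution accounting across rate categories.

For a branch of 0.05 substitutions/site in a 2596-site alignment (129.8
expected substitutions in total), tabulate how many substitutions each of
the 12 discrete-gamma categories (alpha=0.803) contributes and what share
of the branch total that is. The slowest category contributes ~0.25
substitutions (~0.19%), the fastest ~41.4 (~31.9%) — the quantitative core
of why slow sites cannot resolve short branches.

Writes results/worked_examples.tsv.
"""

from pathlib import Path

import pandas as pd

from slowfast.models import discretize_gamma, expected_substitutions

BRANCH_LENGTH = 0.05
N_SITES = 2596
K = 12

cats = discretize_gamma(0.803, K)
rows = []
for c, rate in enumerate(cats.rates, start=1):
    count, fraction = expected_substitutions(BRANCH_LENGTH, N_SITES, K, rate)
    rows.append(
        {
            "category": c,
            "rate_multiplier": round(rate, 5),
            "expected_substitutions": round(count, 4),
            "fraction_of_branch_total_pct": round(100 * fraction, 4),
        }
    )
table = pd.DataFrame(rows)

out = Path(__file__).resolve().parent.parent / "results"
out.mkdir(exist_ok=True)
table.to_csv(out / "worked_examples.tsv", sep="\t", index=False)

total = N_SITES * BRANCH_LENGTH
print(f"branch {BRANCH_LENGTH} subst/site x {N_SITES} sites = {total:.1f} substitutions")
print(table.to_string(index=False))
print(
    f"\nslowest category: {table.iloc[0].expected_substitutions:.2f} substitutions "
    f"({table.iloc[0].fraction_of_branch_total_pct:.3f}% of the branch total); "
    f"fastest: {table.iloc[-1].expected_substitutions:.2f} "
    f"({table.iloc[-1].fraction_of_branch_total_pct:.2f}%)"
)
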