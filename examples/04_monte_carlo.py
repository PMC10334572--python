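"""Probabilistic risk: propagate concentration uncertainty by Monte Carlo.

A lognormal distribution is moment-matched to the pooled arsenic summary
and pushed through the THQ and ILCR equations 10,000 times; risk is read
at the 95th percentile of the simulated distribution.
"""

from eggrisk import MCConfig, build_distribution, run_mcs, summarize_mcs
from eggrisk.defaults import DEFAULT_EXPOSURE, TOX_PROFILES

# pooled As: mean 0.795 µg/kg with a sample sd reflecting survey spread
spec = build_distribution(0.795, sd=0.5, family="lognormal")
print(f"concentration model: {spec.describe()}, mean {spec.analytic_mean:.3f} µg/kg\n")

cfg = MCConfig(n_iterations=10_000, seed=1, percentiles=(5, 50, 95))
for metric in ("THQ", "ILCR"):
    res = run_mcs(spec, DEFAULT_EXPOSURE, TOX_PROFILES["As"], cfg, metric=metric)
    row = summarize_mcs(res)
    print(
        f"As {metric}: mean={row['mean']:.3E}  p5={row['p5']:.3E}"
        f"  p50={row['p50']:.3E}  p95={row['p95']:.3E}"
    )

print(
    "\nThe p95 column is the risk for the most-exposed 5% of the simulated"
    " population; identical seeds reproduce these numbers bit for bit."
)
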