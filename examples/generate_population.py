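"""Generate a synthetic mating market and inspect its structure.

Builds a 500-agent population whose per-sex trait/preference moments and
32x32 correlation structure follow the package's default synthetic target
statistics, then splits it into 5 markets of 100.
"""

import numpy as np

from matesearch import default_synthetic_stats, generate_population, split_markets

stats = default_synthetic_stats(seed=0)
pop = generate_population(stats, n_agents=500, seed=1)
pop = split_markets(pop, n_groups=5, seed=2)

counts = pop.frame.groupby(["market_id", "sex"]).size().unstack()
print(counts)
# each market holds 50 females and 50 males: markets are always sex-balanced

values = pop.frame.filter(like="trait_").to_numpy()
emp = np.corrcoef(pop.sex_block("female").filter(like="trait_").to_numpy().T)
req = stats.female.corr[16:, 16:]
print(f"max |empirical - requested| trait correlation: "
      f"{np.abs(emp - req).max():.3f}")
# small deviation: the Cholesky step imposes the requested covariance
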