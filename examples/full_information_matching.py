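"""Full-information mate choice with the resource allocation model.

Agents perceive every potential mate's true mate value (a rescaled Euclidean
preference-trait distance, 10 = perfect match) and iteratively concentrate a
fixed courtship budget on mates who invest back. Pairing is by mutual
plurality of final investment.
"""

from matesearch import default_synthetic_stats, generate_population, mv_matrix, run_allocation

stats = default_synthetic_stats(seed=0)
pop = generate_population(stats, n_agents=500, seed=1)
mv = mv_matrix(pop)
print(f"mate values span {mv.pooled_values().min():.2f} to "
      f"{mv.pooled_values().max():.2f} on the 0-10 scale")

outcome = run_allocation(mv, n_steps=50, budget=10.0, seed=2)
print(f"{outcome.n_couples} couples formed, {outcome.n_singles} agents single")
# agents stay single when their most-invested mate invests most elsewhere
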