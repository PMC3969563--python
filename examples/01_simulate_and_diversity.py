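"""Simulate one population of RAD tags and compute its diversity indices.

Generates 12 diploids at 400 tag locations under a constant-size coalescent
(theta = 1 per 144-bp tag, i.e. per-site diversity ~0.007), applies the
site-filter cascade, and prints pi, Watterson's theta_W and Tajima's D.
Under neutrality pi and theta_W estimate the same quantity and D ~ 0;
theta_W also converts to an effective population size via theta = 4 Ne mu.
"""

from radpop import (
    Constants,
    SimulationConfig,
    diversity_stats,
    filter_sites,
    group_tag_locations,
    ne_from_theta,
    simulate_population,
)

config = SimulationConfig(seed=1, n_per_pop=12, theta_per_tag=1.0, n_tags=400)
matrix, truth = simulate_population(config)
matrix = filter_sites(matrix)
tags = group_tag_locations(matrix)

result = diversity_stats(matrix, "sim", tags=tags)
print(f"samples            : {matrix.n_samples} diploids "
      f"({result.n_chrom} chromosomes)")
print(f"sites (L)          : {result.L:,} ({result.S:,} segregating)")
print(f"pi per site  x1e3  : {result.pi_per_site * 1e3:.2f} "
      f"+- {result.pi_sd * 1e3:.2f} (jackknife over tags)")
print(f"theta_W/site x1e3  : {result.theta_w_per_site * 1e3:.2f}")
print(f"Tajima's D         : {result.tajimas_d:+.3f}   (~0 under neutrality)")
ne = ne_from_theta(result.theta_w_per_site, Constants())
print(f"implied Ne         : {ne:,.0f}  (theta = 4 Ne mu at mu = 1.1e-9/gen)")
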