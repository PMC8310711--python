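"""TE divergence landscape on a simulated genome.

Plants three cohorts of ERV copies mutated to different Kimura 2-parameter
distances from their consensus (young, middle-aged, old insertions), then
bins TE-occupied bp by divergence.  On real genomes the same table drawn
per chromosome class shows the W chromosome dominated by young, low-
divergence ERVs.
"""

from refugium.landscape import build_landscape, te_bp_by_chromosome
from refugium.simulate import (
    ElementPlan,
    FamilyPlan,
    SimulationConfig,
    plant_and_mutate,
)

cfg = SimulationConfig(
    chromosomes=(("chr1", "autosome", 400_000),),
    families=(FamilyPlan("ERV_sim1", "erv", "LTR/ERV1"),),
    elements=(
        ElementPlan("fl_erv", "ERV_sim1", "autosome", 8, divergence_k=0.02),
        ElementPlan("fl_erv", "ERV_sim1", "autosome", 8, divergence_k=0.10),
        ElementPlan("fl_erv", "ERV_sim1", "autosome", 8, divergence_k=0.25),
    ),
)
sim = plant_and_mutate(cfg, seed=4)

density = te_bp_by_chromosome(sim.hits, sim.genome)
print("TE density per chromosome (percent of assembled length):")
print(density[["chromosome", "te_bp", "length_bp", "pct_te_obs"]].to_string(index=False))

landscape = build_landscape(sim.hits, sim.genome, bin_width=2.0)
print("\nbp occupied per divergence bin (three planted age cohorts):")
print(landscape[["bin_low", "bin_high", "bp", "bp_per_mb"]].to_string(index=False))
print("\nThe three peaks sit near the planted mutation doses (~2%, ~10%, ~22%")
print("raw mismatch for K = 0.02 / 0.10 / 0.25); bp_per_mb normalizes by")
print("chromosome length so classes of different size are comparable.")
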