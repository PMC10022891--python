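"""A desk-scale genetic-algorithm design run on the surrogate oracle.

Evolves 24-mers over the reduced helix-prone alphabet toward the most
negative scaled sensing free energy.  The surrogate landscape rewards
hydrophobic content but the cosine surface constraint zeroes the score
of peptides that would dissolve or go transmembrane, so the population
converges to mixed hydrophobic/charged ("amphipathic") compositions.
"""

import curvsense as cv
from curvsense.surrogate import SurrogateBackend, hydrophobic_fraction

config = cv.GAConfig(population_size=48, parent_pool=12, max_generations=30, seed=3)
trace = cv.run(config, SurrogateBackend(config=config))

print("generation   best fitness   mean fitness   best sequence")
for g in range(0, len(trace.best_fitness), 5):
    print(
        f"{g:10d} {trace.best_fitness[g]:14.2f} {trace.mean_fitness[g]:14.2f}   "
        f"{trace.best_sequences[g]}"
    )

top = [m.sequence for m in trace.final_population.members[:config.parent_pool]]
print(f"\nconsensus of top {config.parent_pool}: {trace.consensus_pfm.consensus()}")
print(f"hydrophobic fraction of best: {hydrophobic_fraction(trace.best_sequences[-1]):.2f}")
print(
    "\nFitness is kJ/mol (more negative = stronger curvature sensing under\n"
    "the toy oracle); the ~0.5 hydrophobic fraction mirrors the amphipathic\n"
    "trade-off between membrane insertion and staying surface-bound."
)
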