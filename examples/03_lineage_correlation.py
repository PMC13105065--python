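"""End-to-end lineage tracing: does fast-state occupancy predict fitness?

Lineages enter drug treatment with different shares of their cells in the
fast-dividing persister state. On the fitness-coupled landscape the fast
state grows and the slow state regresses, so a lineage's barcode-abundance
fold-change should correlate with the fraction of its cells found in the
fast cluster — the package's version of the clone-fitness readout.
"""

from idletrace.experiments import lineage_correlation_study

for label, coupled in (("fitness-coupled", True), ("neutral", False)):
    res = lineage_correlation_study(coupled=coupled, seed=11,
                                    n_permutations=1000)
    print(f"{label} landscape: Pearson r = {res['pearson_r']:+.3f} "
          f"over {res['n_lineages']} lineages "
          f"(permutation p = {res['p_permutation']:.3f})")

print()
print("Coupled dynamics produce a strong positive correlation; under the")
print("neutral landscape the same pipeline returns a correlation that the")
print("permutation test cannot distinguish from zero.")
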