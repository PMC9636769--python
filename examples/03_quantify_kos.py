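"""From fragment counts to KO-level abundance and expression.

AMG abundance is the parent vOTU's FPKM; KO abundance sums member AMGs;
the KO expression level is transcript FPKM over KO abundance.
"""

from viramg.pipeline import analyze_community, ko_profiles
from viramg.simulate import SimulationConfig, simulate_community, simulate_counts
from viramg.stats import diversity_table

cfg = SimulationConfig(seed=42)
genomes, truth = simulate_community(cfg)
mg, mt = simulate_counts(truth, cfg)
analysis = analyze_community(genomes)
tables = ko_profiles(analysis, mg, mt)

profile = tables["ko_profile"].values
print(f"KO profile: {profile.shape[0]} KOs x {profile.shape[1]} samples")
div = diversity_table(profile)
print(div.head(3).round(3))

expr = tables["expression_level"]
defined = expr.notna().to_numpy().mean()
print(f"expression levels defined for {100 * defined:.0f}% of KO x sample cells")
# Richness counts KOs present per sample; Shannon uses natural log.
# Expression is undefined (NaN) exactly where a KO has zero abundance.
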