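"""Lifestyle and habitat enrichment of AMG functions.

Occurrence-frequency enrichment counts carrier viruses per pathway
(Fisher's exact test); habitat enrichment ranks KO relative abundance
across habitats (Kruskal-Wallis); PERMANOVA partitions Bray-Curtis
distances of per-sample KO profiles.
"""

from viramg.pipeline import analyze_community, ko_profiles
from viramg.simulate import SimulationConfig, simulate_community, simulate_counts
from viramg import stats as vs

cfg = SimulationConfig(seed=42)
genomes, truth = simulate_community(cfg)
mg, _ = simulate_counts(truth, cfg)
analysis = analyze_community(genomes)

print("pathway occurrence by lifestyle (carriers / total, Fisher p):")
for r in vs.pathway_occurrence(analysis.lifestyle_of, analysis.retained_amgs):
    direction = {"a": r.group_a, "b": r.group_b, "none": "-"}[r.direction]
    print(f"  {r.unit:22s} {r.group_a_count:2d}/{r.group_a_total} vs "
          f"{r.group_b_count:2d}/{r.group_b_total}  p={r.p_value:.2e}  -> {direction}")

tables = ko_profiles(analysis, mg)
rel = vs.relative_abundance(tables["ko_profile"].values)
habitat_of = {s.sample_id: s.habitat for s in mg}
kw = vs.habitat_enrichment(rel, habitat_of)
print(f"\nhabitat-enriched KOs (Kruskal-Wallis p<0.05): "
      f"{(kw.enriched_habitat != '').sum()} of {len(kw)}")

dm = vs.bray_curtis(rel)
res = vs.permanova(dm, [habitat_of[s] for s in rel.columns], seed=0)
print(f"habitat PERMANOVA on KO composition: R2={res.r_squared:.2f} p={res.p_value}")
# Planted lytic/temperate pathways separate cleanly; habitat multipliers
# drive both the enriched-KO list and the PERMANOVA partition.
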