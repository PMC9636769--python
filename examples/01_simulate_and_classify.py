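"""Simulate a small viral community and classify vOTU lifestyles.

Temperate calls need positive evidence: a provirus signal from both
upstream tools, or a lysogeny-specific gene (integrase, recombinase, ...).
"""

from collections import Counter

from viramg.lifestyle import classify_all
from viramg.simulate import SimulationConfig, simulate_community

cfg = SimulationConfig(n_lytic=30, n_temperate=8, seed=42)
genomes, truth = simulate_community(cfg)
calls = classify_all(genomes)

counts = Counter(c.lifestyle for c in calls.values())
correct = sum(calls[v].lifestyle == truth.lifestyles[v] for v in calls)
print(f"{len(genomes)} vOTUs -> {counts['lytic']} lytic, {counts['temperate']} temperate")
print(f"agreement with planted lifestyles: {100 * correct / len(calls):.0f}%")

example = next(c for c in calls.values() if c.lifestyle == "temperate")
print(f"evidence for {example.votu_id}: "
      + "; ".join(f"{e.kind} ({e.detail})" for e in example.evidence))
# With complete annotations every planted lifestyle is recovered; the
# evidence trail records which rule fired for each temperate call.
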