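"""End-to-end orchestration: annotation bundle -> lifestyle + AMG results.

Thin convenience layer over the per-module functions, used by the CLI, the
examples and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import amg as vamg
from . import lifestyle as vlife
from . import quantify as vquant
from .io import SampleTable, VirusGenome


@dataclass
class CommunityAnalysis:
    genomes: list[VirusGenome]
    lifestyles: dict[str, vlife.LifestyleCall]
    amg_calls: list[vamg.AMGCall]  # retained and removed, in call order
    genome_stats: dict[str, vamg.GenomeStats] = field(default_factory=dict)

    @property
    def retained_amgs(self) -> list[vamg.AMGCall]:
        return vamg.retained(self.amg_calls)

    @property
    def lifestyle_of(self) -> dict[str, str]:
        return {v: c.lifestyle for v, c in self.lifestyles.items()}

    def amg_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "votu_id": c.votu_id,
                    "ko_id": c.ko_id,
                    "functional_label": c.functional_label,
                    "pathways": ";".join(sorted(c.pathways)),
                    "amg_class": c.amg_class,
                    "curation_status": c.curation_status,
                    "removal_reason": c.removal_reason,
                }
                for c in self.amg_calls
            ]
        )


def analyze_community(
    genomes: Sequence[VirusGenome],
    blacklist: vamg.CurationBlacklist | None = None,
    pmap: vamg.PathwayMap | None = None,
    lexicon: vlife.LysogenyLexicon | None = None,
    lifestyle_mode: str = "any",
    flanking: str = "span",
) -> CommunityAnalysis:
    """Classify lifestyles, call/curate/classify AMGs, compute genome stats."""
    pmap = pmap or vamg.PathwayMap.default()
    blacklist = blacklist or vamg.CurationBlacklist.default()
    genomes = list(genomes)
    lifestyles = vlife.classify_all(genomes, lexicon, lifestyle_mode)
    calls: list[vamg.AMGCall] = []
    stats: dict[str, vamg.GenomeStats] = {}
    for genome in genomes:
        genome_calls = vamg.call_amgs(genome, blacklist, pmap, flanking)
        calls.extend(genome_calls)
        if genome.n_genes:
            stats[genome.votu_id] = vamg.genome_stats(genome, vamg.retained(genome_calls))
    return CommunityAnalysis(genomes, lifestyles, calls, stats)


def ko_profiles(
    analysis: CommunityAnalysis,
    mg_samples: Sequence[SampleTable],
    mt_samples: Sequence[SampleTable] = (),
) -> dict[str, object]:
    """vOTU FPKM, AMG abundance, KO profile and (optionally) expression levels."""
    votu_lengths = {g.votu_id: g.length_bp for g in analysis.genomes}
    votu_fpkm = vquant.fpkm_matrix(mg_samples, votu_lengths)
    amg_fpkm = vquant.amg_abundance(analysis.retained_amgs, votu_fpkm)
    amg_to_ko = {c.gene_id: c.ko_id for c in analysis.retained_amgs}
    profile = vquant.aggregate_ko(amg_fpkm, amg_to_ko)
    out: dict[str, object] = {
        "votu_fpkm": votu_fpkm,
        "amg_fpkm": amg_fpkm,
        "ko_profile": profile,
    }
    if mt_samples:
        gene_lengths: Mapping[str, int] = {
            gene.gene_id: gene.length_bp
            for genome in analysis.genomes
            for gene in genome.genes()
        }
        transcript = vquant.fpkm_matrix(mt_samples, gene_lengths)
        out["transcript_fpkm"] = transcript
        out["expression_level"] = vquant.ko_expression_level(transcript.values, profile)
    return out
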