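"""Temperate vs lytic lifestyle calls for vOTUs.

A vOTU is called temperate only on positive evidence: a prophage signal
reported by *both* upstream provirus-detection tools, or at least one
lysogeny-specific gene (integrase, recombinase, transposase, excisionase,
CI/Cro repressor, parA/parB) among its consensus-labelled ORFs.  Everything
else is a potential lytic virus.  Because incompletely assembled temperate
genomes may carry neither signal, misclassification is one-directional:
true temperates can be called lytic, never the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import PUTATIVE, GeneRecord, VirusGenome

DEFAULT_LYSOGENY_KEYWORDS = frozenset(
    {
        "integrase",
        "recombinase",
        "transposase",
        "excisionase",
        "ci repressor",
        "cro repressor",
        "para",
        "parb",
    }
)


@dataclass(frozen=True)
class LysogenyLexicon:
    """Lower-cased keyword set matched token-wise against consensus labels."""

    keywords: frozenset[str] = DEFAULT_LYSOGENY_KEYWORDS

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("lysogeny lexicon must be non-empty")
        object.__setattr__(
            self, "keywords", frozenset(k.casefold().strip() for k in self.keywords)
        )

    def matches(self, label: str) -> bool:
        if not label or label == PUTATIVE:
            return False
        tokens = label.casefold().split()
        for keyword in self.keywords:
            kw_tokens = keyword.split()
            n = len(kw_tokens)
            if any(tokens[i : i + n] == kw_tokens for i in range(len(tokens) - n + 1)):
                return True
        return False


@dataclass(frozen=True)
class LifestyleEvidence:
    kind: str  # prophage_both_tools | lysogeny_gene
    detail: str


@dataclass
class LifestyleCall:
    votu_id: str
    lifestyle: str  # temperate | lytic
    evidence: list[LifestyleEvidence] = field(default_factory=list)


def detect_lysogeny_genes(
    genome: VirusGenome, lexicon: LysogenyLexicon | None = None
) -> list[GeneRecord]:
    """Genes whose consensus label contains a lysogeny keyword.

    Matching is whole-token and case-insensitive against consensus labels
    only, so descriptions carried by rejected alignments cannot trigger a
    call; unresolved ("putative protein") genes never match.
    """
    lexicon = lexicon or LysogenyLexicon()
    return [g for g in genome.genes() if lexicon.matches(g.consensus_label)]


def classify_lifestyle(
    genome: VirusGenome,
    lexicon: LysogenyLexicon | None = None,
    mode: str = "any",
) -> LifestyleCall:
    """Call one genome temperate or lytic.

    ``mode="any"`` (default): temperate if both provirus flags are set OR a
    lysogeny gene is present.  ``mode="both"`` requires the two evidence
    kinds simultaneously.  A single tool's provirus flag never suffices.
    """
    if mode not in ("any", "both"):
        raise ValueError(f"unknown lifestyle mode {mode!r}")
    evidence: list[LifestyleEvidence] = []
    if genome.provirus_flag_tool_a and genome.provirus_flag_tool_b:
        evidence.append(
            LifestyleEvidence("prophage_both_tools", "provirus signal from both tools")
        )
    for gene in detect_lysogeny_genes(genome, lexicon):
        evidence.append(
            LifestyleEvidence("lysogeny_gene", f"{gene.gene_id}: {gene.consensus_label}")
        )
    kinds = {e.kind for e in evidence}
    if mode == "any":
        temperate = bool(evidence)
    else:
        temperate = kinds == {"prophage_both_tools", "lysogeny_gene"}
    if not temperate:
        evidence = []
    return LifestyleCall(
        votu_id=genome.votu_id,
        lifestyle="temperate" if temperate else "lytic",
        evidence=evidence,
    )


def classify_all(
    genomes: Iterable[VirusGenome],
    lexicon: LysogenyLexicon | None = None,
    mode: str = "any",
) -> dict[str, LifestyleCall]:
    return {g.votu_id: classify_lifestyle(g, lexicon, mode) for g in genomes}


def lifestyle_table(calls: Sequence[LifestyleCall] | dict[str, LifestyleCall]):
    """Flatten calls into rows ready for TSV export."""
    import pandas as pd

    if isinstance(calls, dict):
        calls = list(calls.values())
    return pd.DataFrame(
        [
            {
                "votu_id": c.votu_id,
                "lifestyle": c.lifestyle,
                "evidence": "; ".join(f"{e.kind}[{e.detail}]" for e in c.evidence),
            }
            for c in calls
        ]
    )
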