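"""Conserved-region AMG calling, curation, class assignment and genome stats.

Candidate auxiliary metabolic genes (AMGs) are only called inside viral
conserved regions — per-contig gene spans whose boundary genes carry viral
hallmark or viral-like annotations.  Nonviral, functionally annotated ORFs
strictly inside such a span are candidates; a categorical curation blacklist
then removes illegitimate calls (DNA-related reactions, nucleotide
metabolism, lysis enzymes, viral-component modification, structural and
ribosomal proteins, transcription/translation regulators, eukaryote-specific
genes).  Retained AMGs are class I when their KO maps to any KEGG
"Metabolism" pathway and class II otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

from .io import PUTATIVE, VirusGenome

VIRAL_CATEGORIES = frozenset({"viral_hallmark", "viral_like"})


@dataclass(frozen=True)
class ConservedRegion:
    """Indices (inclusive) into a contig's ordered gene list."""

    contig_id: str
    first_gene_index: int
    last_gene_index: int

    def __post_init__(self) -> None:
        if self.first_gene_index > self.last_gene_index:
            raise ValueError("conserved region indices out of order")


@dataclass
class AMGCall:
    gene_id: str
    votu_id: str
    ko_id: str
    functional_label: str
    pathways: frozenset[str] = frozenset()
    amg_class: str = ""  # "I" | "II" once assigned, retained calls only
    curation_status: str = "retained"  # retained | removed
    removal_reason: str = ""


def _match_token_seq(label_tokens: list[str], keyword: str) -> bool:
    kw = keyword.casefold().split()
    n = len(kw)
    return any(label_tokens[i : i + n] == kw for i in range(len(label_tokens) - n + 1))


@dataclass(frozen=True)
class BlacklistCategory:
    category_id: str
    ko_ids: frozenset[str]
    keywords: frozenset[str]

    def matches(self, ko_id: str, label: str) -> bool:
        if ko_id and ko_id in self.ko_ids:
            return True
        tokens = label.casefold().split()
        return any(_match_token_seq(tokens, kw) for kw in self.keywords)


@dataclass(frozen=True)
class CurationBlacklist:
    categories: tuple[BlacklistCategory, ...]

    def __post_init__(self) -> None:
        ids = [c.category_id for c in self.categories]
        if len(ids) != len(set(ids)):
            raise ValueError("blacklist category ids must be unique")
        for c in self.categories:
            if not c.ko_ids and not c.keywords:
                raise ValueError(f"category {c.category_id!r} is empty")

    def first_match(self, ko_id: str, label: str) -> str | None:
        for category in self.categories:
            if category.matches(ko_id, label):
                return category.category_id
        return None

    @classmethod
    def from_yaml(cls, path_or_stream) -> "CurationBlacklist":
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                raw = yaml.safe_load(fh)
        cats = tuple(
            BlacklistCategory(
                category_id=c["category_id"],
                ko_ids=frozenset(c.get("ko_ids") or []),
                keywords=frozenset(c.get("keywords") or []),
            )
            for c in raw["categories"]
        )
        return cls(cats)

    @classmethod
    def default(cls) -> "CurationBlacklist":
        with resources.files("viramg.data").joinpath("blacklist.yaml").open() as fh:
            return cls.from_yaml(fh)


@dataclass(frozen=True)
class PathwayMap:
    """KO -> pathway memberships plus pathway -> BRITE top category."""

    ko_to_pathways: Mapping[str, frozenset[str]]
    pathway_top_category: Mapping[str, str]
    ko_labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ko, pathways in self.ko_to_pathways.items():
            for p in pathways:
                if p not in self.pathway_top_category:
                    raise ValueError(f"pathway {p!r} (KO {ko}) lacks a top category")

    @classmethod
    def from_yaml(cls, path_or_stream) -> "PathwayMap":
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                raw = yaml.safe_load(fh)
        return cls(
            ko_to_pathways={k: frozenset(v) for k, v in raw["ko_pathways"].items()},
            pathway_top_category=dict(raw["top_categories"]),
            ko_labels=dict(raw.get("ko_labels", {})),
        )

    @classmethod
    def default(cls) -> "PathwayMap":
        with resources.files("viramg.data").joinpath("pathways.yaml").open() as fh:
            return cls.from_yaml(fh)


# ---------------------------------------------------------------------------
# Region finding and candidate calling
# ---------------------------------------------------------------------------


def find_conserved_regions(genome: VirusGenome) -> list[ConservedRegion]:
    """Per contig, the maximal span from the first to the last viral gene.

    Contigs with fewer than two viral-category genes yield no region; the
    junction of circular genomes is not considered.
    """
    regions: list[ConservedRegion] = []
    for contig_id, genes in genome.contigs.items():
        viral_idx = [i for i, g in enumerate(genes) if g.is_viral]
        if len(viral_idx) < 2:
            continue
        regions.append(ConservedRegion(contig_id, viral_idx[0], viral_idx[-1]))
    return regions


def call_candidate_amgs(
    genome: VirusGenome,
    regions: Sequence[ConservedRegion],
    flanking: str = "span",
) -> list[AMGCall]:
    """Nonviral, annotated ORFs strictly inside a conserved region.

    Boundary genes are excluded and unresolved ("putative protein") genes
    never become candidates.  ``flanking="immediate"`` additionally requires
    the candidate's direct neighbours on both sides to be viral-category.
    """
    if flanking not in ("span", "immediate"):
        raise ValueError(f"unknown flanking mode {flanking!r}")
    by_contig = {r.contig_id: r for r in regions}
    calls: list[AMGCall] = []
    for contig_id, genes in genome.contigs.items():
        region = by_contig.get(contig_id)
        if region is None:
            continue
        for i in range(region.first_gene_index + 1, region.last_gene_index):
            gene = genes[i]
            if gene.is_viral or gene.consensus_label == PUTATIVE:
                continue
            if flanking == "immediate" and not (genes[i - 1].is_viral and genes[i + 1].is_viral):
                continue
            calls.append(
                AMGCall(
                    gene_id=gene.gene_id,
                    votu_id=genome.votu_id,
                    ko_id=gene.ko_id,
                    functional_label=gene.consensus_label,
                )
            )
    return calls


def curate_amgs(
    candidates: Iterable[AMGCall], blacklist: CurationBlacklist | None = None
) -> list[AMGCall]:
    """Mark blacklist matches as removed (first matching category wins).

    The output preserves input order and includes removed records, so the
    curation trail remains auditable; the operation is idempotent.
    """
    blacklist = blacklist or CurationBlacklist.default()
    curated = []
    for call in candidates:
        reason = blacklist.first_match(call.ko_id, call.functional_label)
        if reason is None:
            curated.append(replace(call, curation_status="retained", removal_reason=""))
        else:
            curated.append(
                replace(call, curation_status="removed", removal_reason=reason,
                        amg_class="", pathways=frozenset())
            )
    return curated


def assign_amg_class(amg: AMGCall, pmap: PathwayMap) -> AMGCall:
    """Class I iff any mapped pathway has top category "Metabolism".

    KOs absent from the map (or calls without a KO) default to class II by
    exclusion.  Removed calls are returned unchanged.
    """
    if amg.curation_status != "retained":
        return amg
    pathways = frozenset(pmap.ko_to_pathways.get(amg.ko_id, frozenset()))
    is_class_i = any(pmap.pathway_top_category[p] == "Metabolism" for p in pathways)
    return replace(amg, pathways=pathways, amg_class="I" if is_class_i else "II")


def retained(calls: Iterable[AMGCall]) -> list[AMGCall]:
    return [c for c in calls if c.curation_status == "retained"]


def call_amgs(
    genome: VirusGenome,
    blacklist: CurationBlacklist | None = None,
    pmap: PathwayMap | None = None,
    flanking: str = "span",
) -> list[AMGCall]:
    """Full per-genome chain: regions -> candidates -> curation -> class."""
    pmap = pmap or PathwayMap.default()
    regions = find_conserved_regions(genome)
    candidates = call_candidate_amgs(genome, regions, flanking=flanking)
    return [assign_amg_class(c, pmap) for c in curate_amgs(candidates, blacklist)]


# ---------------------------------------------------------------------------
# Per-genome statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeStats:
    votu_id: str
    gene_density: float  # ORFs per kbp
    amg_ratio: float  # retained AMGs / total ORFs
    annotation_rate: float  # fraction of ORFs with a resolved label


def genome_stats(genome: VirusGenome, retained_amgs: Sequence[AMGCall]) -> GenomeStats:
    if genome.length_bp <= 0:
        raise ValueError(f"vOTU {genome.votu_id!r} has non-positive length")
    n_genes = genome.n_genes
    if n_genes == 0:
        raise ValueError(f"vOTU {genome.votu_id!r} has no genes")
    n_amg = sum(1 for a in retained_amgs
                if a.votu_id == genome.votu_id and a.curation_status == "retained")
    n_annotated = sum(1 for g in genome.genes() if g.consensus_label != PUTATIVE)
    return GenomeStats(
        votu_id=genome.votu_id,
        gene_density=n_genes / (genome.length_bp / 1000.0),
        amg_ratio=n_amg / n_genes,
        annotation_rate=n_annotated / n_genes,
    )


def filter_by_annotation_rate(
    stats: Sequence[GenomeStats],
    genomes: Sequence[VirusGenome],
    threshold: float = 0.5,
) -> list[VirusGenome]:
    """Drop genomes whose annotation rate is <= threshold (inclusive)."""
    rates = {s.votu_id: s.annotation_rate for s in stats}
    return [g for g in genomes if rates.get(g.votu_id, 0.0) > threshold]
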