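"""Virus-host linkage from three evidence channels, plus taxonomy voting.

Evidence channels and their retention thresholds:

* genome homology (blastn-style): identity >= 70, query coverage >= 75,
  e-value <= 1e-3, bit score >= 50;
* shared tRNA: identity = 100 and coverage = 100 exactly;
* CRISPR spacer match: coverage = 100, mismatches <= 3, e-value <= 1e-6
  (the word size of the upstream search is recorded for provenance only).

Hosts predicted by any channel are unioned into one link per (virus, host)
pair.  Host-range summaries and single-host-order grouping feed the
host-order enrichment analysis; per-ORF viral taxonomy is combined by a
strict-majority (> 50%) vote with lowest-common-ancestor fallback.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

METHODS = frozenset({"homology", "trna", "crispr"})


@dataclass(frozen=True)
class EvidenceHit:
    votu_id: str
    host_genome_id: str
    method: str
    identity_pct: float = 0.0
    query_coverage_pct: float = 0.0
    e_value: float = 1.0
    bit_score: float = 0.0
    word_size: int = 0  # provenance of the upstream spacer search
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown evidence method {self.method!r}")
        if not (0 <= self.identity_pct <= 100 and 0 <= self.query_coverage_pct <= 100):
            raise ValueError("percentages must lie in [0, 100]")
        if self.mismatches < 0:
            raise ValueError("mismatches must be non-negative")


@dataclass(frozen=True)
class HostLink:
    votu_id: str
    host_genome_id: str
    lineage: tuple[str, ...]  # names for RANKS, "" where unresolved
    methods: frozenset[str]

    def rank(self, name: str) -> str:
        return self.lineage[RANKS.index(name)]


@dataclass(frozen=True)
class HostRangeSummary:
    votu_id: str
    n_host_phyla: int
    is_broad: bool  # >= 2 host phyla
    is_cross_domain: bool
    host_orders: frozenset[str]


def filter_homology(
    hits: Iterable[EvidenceHit],
    min_identity: float = 70.0,
    min_query_coverage: float = 75.0,
    e_max: float = 1e-3,
    bs_min: float = 50.0,
) -> list[EvidenceHit]:
    """Genome-homology retention; all four bounds inclusive."""
    return [
        h
        for h in hits
        if h.method == "homology"
        and h.identity_pct >= min_identity
        and h.query_coverage_pct >= min_query_coverage
        and h.e_value <= e_max
        and h.bit_score >= bs_min
    ]


def filter_trna(hits: Iterable[EvidenceHit]) -> list[EvidenceHit]:
    """Shared-tRNA evidence demands an exact full-length match."""
    return [
        h
        for h in hits
        if h.method == "trna" and h.identity_pct == 100.0 and h.query_coverage_pct == 100.0
    ]


def filter_crispr(
    hits: Iterable[EvidenceHit],
    max_mismatches: int = 3,
    e_max: float = 1e-6,
) -> list[EvidenceHit]:
    """Spacer matches: full coverage, at most 3 mismatches, e <= 1e-6."""
    return [
        h
        for h in hits
        if h.method == "crispr"
        and h.query_coverage_pct == 100.0
        and h.mismatches <= max_mismatches
        and h.e_value <= e_max
    ]


def filter_evidence(hits: Iterable[EvidenceHit]) -> list[EvidenceHit]:
    """Route every hit through its method's filter."""
    hits = list(hits)
    return (
        filter_homology(hits) + filter_trna(hits) + filter_crispr(hits)
    )


def combine_links(
    filtered_hits: Iterable[EvidenceHit],
    host_taxonomy: Mapping[str, Sequence[str]],
) -> list[HostLink]:
    """Union hosts over methods; duplicate pairs merge their method sets."""
    merged: dict[tuple[str, str], set[str]] = {}
    for hit in filtered_hits:
        merged.setdefault((hit.votu_id, hit.host_genome_id), set()).add(hit.method)
    links = []
    for (votu_id, host_id), methods in sorted(merged.items()):
        if host_id not in host_taxonomy:
            raise KeyError(f"host genome {host_id!r} has no taxonomy lineage")
        lineage = tuple(host_taxonomy[host_id])
        if len(lineage) != len(RANKS):
            raise ValueError(f"lineage for {host_id!r} must carry {len(RANKS)} ranks")
        if not any(lineage):
            raise ValueError(f"lineage for {host_id!r} has no resolved rank")
        links.append(HostLink(votu_id, host_id, lineage, frozenset(methods)))
    return links


def host_range(links: Iterable[HostLink]) -> dict[str, HostRangeSummary]:
    """Distinct host phyla/orders/domains per virus."""
    by_votu: dict[str, list[HostLink]] = {}
    for link in links:
        by_votu.setdefault(link.votu_id, []).append(link)
    out = {}
    for votu_id, vlinks in sorted(by_votu.items()):
        phyla = {l.rank("phylum") for l in vlinks if l.rank("phylum")}
        domains = {l.rank("domain") for l in vlinks if l.rank("domain")}
        orders = {l.rank("order") for l in vlinks if l.rank("order")}
        out[votu_id] = HostRangeSummary(
            votu_id=votu_id,
            n_host_phyla=len(phyla),
            is_broad=len(phyla) >= 2,
            is_cross_domain=len(domains) >= 2,
            host_orders=frozenset(orders),
        )
    return out


def single_order_groups(links: Iterable[HostLink]) -> dict[str, str]:
    """Viruses whose links resolve to exactly one host order.

    Viruses linked to several orders, or with no order-resolved link, are
    excluded; the result feeds occurrence-frequency enrichment by host order.
    """
    orders: dict[str, set[str]] = {}
    for link in links:
        order = link.rank("order")
        if order:
            orders.setdefault(link.votu_id, set()).add(order)
    return {v: next(iter(o)) for v, o in sorted(orders.items()) if len(o) == 1}


def vote_taxonomy(orf_lineages: Sequence[Sequence[str]]) -> tuple[str, ...]:
    """Combine per-ORF viral lineages by strict majority, LCA as fallback.

    Lineages are root-to-leaf name lists (deepest rank typically the family).
    Starting from the deepest rank and moving up, the first taxon held by
    more than half of the assigned ORFs wins and the vote returns its
    lineage prefix.  If no rank produces a strict majority the lowest common
    ancestor (longest common prefix) is returned; no taxonomy at all yields
    an empty lineage.
    """
    lineages = [tuple(l) for l in orf_lineages if l]
    if not lineages:
        return ()
    n = len(lineages)
    max_depth = max(len(l) for l in lineages)
    for depth in range(max_depth - 1, -1, -1):
        prefixes = Counter(l[: depth + 1] for l in lineages if len(l) > depth)
        if not prefixes:
            continue
        best, count = prefixes.most_common(1)[0]
        if count * 2 > n:
            return best
    # Lowest common ancestor: longest prefix shared by every lineage.
    lca: list[str] = []
    for names in zip(*lineages):
        if len(set(names)) == 1:
            lca.append(names[0])
        else:
            break
    return tuple(lca)


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

EVIDENCE_COLUMNS = [
    "votu_id", "host_genome_id", "method", "identity_pct", "query_coverage_pct",
    "e_value", "bit_score", "word_size", "mismatches",
]


def read_evidence_tsv(path) -> list[EvidenceHit]:
    table = pd.read_csv(path, sep="\t", dtype={"votu_id": str, "host_genome_id": str})
    missing = set(EVIDENCE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"evidence table is missing columns: {sorted(missing)}")
    return [
        EvidenceHit(
            votu_id=r.votu_id,
            host_genome_id=r.host_genome_id,
            method=r.method,
            identity_pct=float(r.identity_pct),
            query_coverage_pct=float(r.query_coverage_pct),
            e_value=float(r.e_value),
            bit_score=float(r.bit_score),
            word_size=int(r.word_size),
            mismatches=int(r.mismatches),
        )
        for r in table.itertuples(index=False)
    ]


def write_evidence_tsv(hits: Sequence[EvidenceHit], path) -> None:
    pd.DataFrame(
        [
            {
                "votu_id": h.votu_id,
                "host_genome_id": h.host_genome_id,
                "method": h.method,
                "identity_pct": h.identity_pct,
                "query_coverage_pct": h.query_coverage_pct,
                "e_value": h.e_value,
                "bit_score": h.bit_score,
                "word_size": h.word_size,
                "mismatches": h.mismatches,
            }
            for h in hits
        ],
        columns=EVIDENCE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_lineage_tsv(path) -> dict[str, tuple[str, ...]]:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = ({"genome_id"} | set(RANKS)) - set(table.columns)
    if missing:
        raise ValueError(f"lineage table is missing columns: {sorted(missing)}")
    # "class" is a keyword, so row access must go through column labels.
    return {
        row["genome_id"]: tuple(row[rank] for rank in RANKS)
        for _, row in table.iterrows()
    }


def write_lineage_tsv(host_taxonomy: Mapping[str, Sequence[str]], path) -> None:
    rows = [
        {"genome_id": gid, **dict(zip(RANKS, lineage))}
        for gid, lineage in sorted(host_taxonomy.items())
    ]
    pd.DataFrame(rows, columns=["genome_id", *RANKS]).to_csv(path, sep="\t", index=False)
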