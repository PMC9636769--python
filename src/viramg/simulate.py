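"""Synthetic annotated viral communities with planted ground truth.

The generator emulates the statistical structure the analysis assumes: a
mixture of lytic and temperate vOTUs; temperate genomes marked by both-tool
provirus flags and/or lysogeny-specific genes; AMGs planted strictly inside
viral-flanked conserved regions with pathway carriage probabilities that
differ by lifestyle; decoy KO genes outside regions and blacklist-matching
decoys inside them; negative-binomial fragment counts with per-habitat
abundance multipliers; and three-channel host evidence with sub-threshold
decoys.  Every emitted file uses the reader's dialect, and a fixed seed
yields byte-identical output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as vio
from .amg import PathwayMap
from .hosts import EvidenceHit, write_evidence_tsv, write_lineage_tsv
from .io import GeneRecord, HitRecord, SampleTable, VirusGenome

HABITATS = ("FL", "PA", "SE")

# ---------------------------------------------------------------------------
# Label vocabularies
# ---------------------------------------------------------------------------

HALLMARK_LABELS = (
    "terminase large subunit",
    "major capsid protein",
    "portal protein",
    "tail sheath protein",
    "baseplate wedge protein",
)

VIRAL_LIKE_LABELS = (
    "phage protein",
    "tail fiber protein",
    "head-tail connector protein",
    "virion structural protein",
    "phage minor structural protein",
)

LYSOGENY_LABELS = (
    "site-specific integrase",
    "tyrosine recombinase XerC",
    "excisionase",
    "CI repressor",
    "ParB partition protein",
    "IS3 family transposase",
)

# Blacklist-matching labels planted inside conserved regions; the pipeline
# must remove these during curation.  None of them contains a lysogeny
# lexicon token (that would flip a planted-lytic genome to temperate).
CURATION_DECOY_LABELS = (
    "DNA polymerase I",
    "ribosomal protein L31",
    "thymidylate synthase",
    "peptidase M23 family protein",
    "glycosyltransferase family 2 protein",
    "transcriptional regulator",
)

# Host-like labels planted only outside conserved regions.
HOST_LIKE_LABELS = (
    "ABC transporter permease",
    "MFS transporter",
    "outer membrane protein",
    "sodium:proton antiporter",
    "membrane-bound lytic transglycosylase",
)

VIRAL_FAMILIES = {
    "Siphoviridae": ("Viruses", "Caudovirales", "Siphoviridae"),
    "Myoviridae": ("Viruses", "Caudovirales", "Myoviridae"),
    "Podoviridae": ("Viruses", "Caudovirales", "Podoviridae"),
}

#: Synthetic host panel: GTDB-style lineages for a handful of MAG stand-ins,
#: spanning several phyla, two genomes of one order, and one archaeon so
#: cross-domain linkage is exercised.
HOST_PANEL: dict[str, tuple[str, ...]] = {
    "MAG_001": ("Bacteria", "Cyanobacteria", "Cyanophyceae", "Synechococcales",
                "Synechococcaceae", "Synechococcus", "Synechococcus sp001"),
    "MAG_002": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales",
                "Enterobacteriaceae", "Escherichia", "Escherichia sp002"),
    "MAG_003": ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Sphingomonadales",
                "Sphingomonadaceae", "Sphingomonas", "Sphingomonas sp003"),
    "MAG_004": ("Bacteria", "Bacteroidota", "Bacteroidia", "Flavobacteriales",
                "Flavobacteriaceae", "Flavobacterium", "Flavobacterium sp004"),
    "MAG_005": ("Bacteria", "Actinobacteriota", "Actinomycetia", "Streptosporangiales",
                "Streptosporangiaceae", "Streptosporangium", "Streptosporangium sp005"),
    "MAG_006": ("Bacteria", "Verrucomicrobiota", "Verrucomicrobiae", "Opitutales",
                "Opitutaceae", "Opitutus", "Opitutus sp006"),
    "MAG_007": ("Archaea", "Nanoarchaeota", "Nanoarchaeia", "Nanoarchaeales",
                "Nanoarchaeaceae", "Nanoarchaeum", "Nanoarchaeum sp007"),
    "MAG_008": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales",
                "Vibrionaceae", "Vibrio", "Vibrio sp008"),
}


@dataclass(frozen=True)
class PathwayEffect:
    pathway_id: str
    carriage_prob_lytic: float
    carriage_prob_temperate: float

    @property
    def direction(self) -> str:
        if self.carriage_prob_lytic > self.carriage_prob_temperate:
            return "lytic"
        if self.carriage_prob_temperate > self.carriage_prob_lytic:
            return "temperate"
        return ""


#: Default lifestyle effects mirror the qualitative pattern of estuarine
#: communities: chaperone/signalling/lipid functions enriched in lytic
#: viruses, defense and two-component systems in temperates, folate
#: biosynthesis shared.  Purely synthetic defaults for demonstration.
DEFAULT_PATHWAY_EFFECTS = (
    PathwayEffect("chaperones_folding", 0.70, 0.00),
    PathwayEffect("signaling_proteins", 0.60, 0.00),
    PathwayEffect("lipid_metabolism", 0.55, 0.00),
    PathwayEffect("defense_system", 0.02, 0.90),
    PathwayEffect("two_component_system", 0.02, 0.85),
    PathwayEffect("folate_biosynthesis", 0.30, 0.30),
)

DEFAULT_HABITAT_EFFECTS: dict[str, dict[str, float]] = {
    "FL": {"lipid_metabolism": 1.5},
    "PA": {},
    "SE": {"two_component_system": 3.0, "folate_biosynthesis": 2.0},
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic community; defaults define the study conditions."""

    n_lytic: int = 50
    n_temperate: int = 10
    genome_length_range: tuple[int, int] = (12_000, 45_000)
    genes_per_kbp: float = 1.4
    p_viral_gene: float = 0.6
    pathway_effects: tuple[PathwayEffect, ...] = DEFAULT_PATHWAY_EFFECTS
    habitat_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_HABITAT_EFFECTS)
    )
    n_samples_per_habitat: int = 4
    depth_mean: float = 1e6
    dispersion: float = 100.0  # negative-binomial size; np.inf -> Poisson
    lysogeny_gene_prob: float = 0.8
    prophage_flag_probs: tuple[float, float] = (0.7, 0.7)
    p_false_provirus: float = 0.05
    annotation_dropout: float = 0.0
    p_multi_contig: float = 0.15
    p_decoy_ko: float = 0.6
    p_curation_decoy: float = 0.4
    p_broad_host: float = 0.12
    host_weights: Mapping[str, float] | None = None
    expression_mean: float = 2.0
    mt_depth_factor: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lytic < 1 or self.n_temperate < 1:
            raise ValueError("need at least one vOTU of each lifestyle")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        probs = [
            self.p_viral_gene, self.lysogeny_gene_prob, self.p_false_provirus,
            self.annotation_dropout, self.p_multi_contig, self.p_decoy_ko,
            self.p_curation_decoy, self.p_broad_host, *self.prophage_flag_probs,
        ]
        for pe in self.pathway_effects:
            probs += [pe.carriage_prob_lytic, pe.carriage_prob_temperate]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        min_genes = (self.genome_length_range[0] / 1000.0) * self.genes_per_kbp
        if min_genes < 9:
            raise ValueError(
                "infeasible config: shortest genome would carry fewer than 9 "
                "genes, too few for a viral-flanked region plus flanks"
            )


@dataclass
class GroundTruth:
    """Planted facts every emitted record derives from."""

    config: SimulationConfig
    lifestyles: dict[str, str]
    gene_roles: dict[str, str]
    amg_genes: dict[str, tuple[str, str, str]]  # gene_id -> (votu, ko, pathway)
    amg_gene_lengths: dict[str, int]
    carriage: dict[str, frozenset]
    pathway_directions: dict[str, str]
    votu_lengths: dict[str, int]
    base_weights: dict[str, float]
    viral_family: dict[str, str]
    host_links: set[tuple[str, str]]
    host_lineages: dict[str, tuple[str, ...]]
    expression_ratio: dict[str, float]
    expected_fpkm: pd.DataFrame | None = None
    sample_habitats: dict[str, str] = field(default_factory=dict)

    @property
    def lysogeny_gene_ids(self) -> list[str]:
        return [g for g, r in self.gene_roles.items() if r == "lysogeny"]


# ---------------------------------------------------------------------------
# Community
# ---------------------------------------------------------------------------


def _gene_coords(contig_len: int, n_genes: int) -> list[tuple[int, int]]:
    step = contig_len // n_genes
    body = max(90, int(step * 0.85))
    return [(k * step, min(k * step + body, contig_len)) for k in range(n_genes)]


def simulate_community(
    cfg: SimulationConfig, pmap: PathwayMap | None = None
) -> tuple[list[VirusGenome], GroundTruth]:
    """Build the annotated community and its truth ledger."""
    pmap = pmap or PathwayMap.default()
    rng = np.random.default_rng([cfg.seed, 0])
    pathway_kos = {
        p: sorted(k for k, ps in pmap.ko_to_pathways.items() if p in ps)
        for pe in cfg.pathway_effects
        for p in [pe.pathway_id]
    }
    for p, kos in pathway_kos.items():
        if not kos:
            raise ValueError(f"pathway {p!r} has no KOs in the pathway map")

    host_ids = sorted(HOST_PANEL)
    if cfg.host_weights:
        weights = np.array([cfg.host_weights.get(h, 0.0) for h in host_ids], float)
    else:
        weights = np.ones(len(host_ids))
    weights = weights / weights.sum()

    genomes: list[VirusGenome] = []
    truth = GroundTruth(
        config=cfg, lifestyles={}, gene_roles={}, amg_genes={},
        amg_gene_lengths={}, carriage={}, pathway_directions={
            pe.pathway_id: pe.direction for pe in cfg.pathway_effects
        },
        votu_lengths={}, base_weights={}, viral_family={}, host_links=set(),
        host_lineages=dict(HOST_PANEL), expression_ratio={},
    )

    lifestyles = ["lytic"] * cfg.n_lytic + ["temperate"] * cfg.n_temperate
    for index, lifestyle in enumerate(lifestyles):
        votu_id = f"vOTU_{index + 1:04d}"
        genome = _simulate_genome(votu_id, lifestyle, cfg, rng, pathway_kos, pmap, truth)
        genomes.append(genome)
        truth.lifestyles[votu_id] = lifestyle
        truth.votu_lengths[votu_id] = genome.length_bp
        truth.base_weights[votu_id] = float(rng.lognormal(mean=0.0, sigma=1.2))

        # Host assignment: one host, sometimes a second from another phylum.
        host = str(rng.choice(host_ids, p=weights))
        truth.host_links.add((votu_id, host))
        if rng.random() < cfg.p_broad_host:
            phylum = HOST_PANEL[host][1]
            others = [h for h in host_ids if HOST_PANEL[h][1] != phylum]
            truth.host_links.add((votu_id, str(rng.choice(others))))

    for pe in cfg.pathway_effects:
        for ko in pathway_kos[pe.pathway_id]:
            truth.expression_ratio.setdefault(
                ko, float(rng.lognormal(np.log(cfg.expression_mean), 0.5))
            )

    if cfg.annotation_dropout > 0:
        genomes = degrade_annotations(
            genomes, cfg.annotation_dropout, seed=int(rng.integers(2**31))
        )
    return genomes, truth


def _hit(gene_id, database, subject, label="", ko="", taxonomy="",
         hallmark=False, e=1e-10, bits=120.0) -> HitRecord:
    return HitRecord(
        gene_id=gene_id, database=database, subject_id=subject, e_value=e,
        bit_score=bits, functional_label=label, ko_id=ko, taxonomy=taxonomy,
        is_hallmark=hallmark,
    )


def _simulate_genome(votu_id, lifestyle, cfg, rng, pathway_kos, pmap, truth) -> VirusGenome:
    lo, hi = cfg.genome_length_range
    total_len = int(rng.integers(lo, hi + 1))
    family = str(rng.choice(sorted(VIRAL_FAMILIES)))
    lineage = VIRAL_FAMILIES[family]
    truth.viral_family[votu_id] = family

    # Optional second contig (vMAG); the conserved region lives on contig 1.
    contig_lens = [total_len]
    if rng.random() < cfg.p_multi_contig:
        frac = rng.uniform(0.6, 0.75)
        n1 = round(total_len * frac / 1000.0 * cfg.genes_per_kbp)
        if n1 >= max(9, len(cfg.pathway_effects) + 5):
            first = int(total_len * frac)
            contig_lens = [first, total_len - first]

    # Lifestyle evidence plan.
    flag_a = flag_b = False
    wants_lysogeny = False
    if lifestyle == "temperate":
        flag_a = rng.random() < cfg.prophage_flag_probs[0]
        flag_b = rng.random() < cfg.prophage_flag_probs[1]
        wants_lysogeny = rng.random() < cfg.lysogeny_gene_prob
        if not (flag_a and flag_b) and not wants_lysogeny:
            wants_lysogeny = True  # every temperate keeps at least one signal
    else:
        flag_a = rng.random() < cfg.p_false_provirus
        flag_b = (not flag_a) and rng.random() < cfg.p_false_provirus

    carried = frozenset(
        pe.pathway_id
        for pe in cfg.pathway_effects
        if rng.random() < (
            pe.carriage_prob_lytic if lifestyle == "lytic" else pe.carriage_prob_temperate
        )
    )
    truth.carriage[votu_id] = carried

    contigs: dict[str, list[GeneRecord]] = {}
    gene_counter = 0
    for c_index, contig_len in enumerate(contig_lens):
        contig_id = f"{votu_id}_c{c_index + 1}"
        n_genes = max(3, round(contig_len / 1000.0 * cfg.genes_per_kbp))
        coords = _gene_coords(contig_len, n_genes)
        roles = ["outside"] * n_genes
        boundary_idx: set[int] = set()

        if c_index == 0:
            r0 = int(rng.integers(1, 3))
            r1 = n_genes - 1 - int(rng.integers(1, 3))
            if r1 - r0 < 4 or r1 - r0 - 1 < len(carried):
                r0, r1 = 1, n_genes - 2
            if r1 - r0 - 1 < len(carried):
                raise ValueError(
                    f"infeasible config: contig of {n_genes} genes cannot hold "
                    f"{len(carried)} planted AMGs inside a viral-flanked span"
                )
            boundary_idx = {r0, r1}
            roles[r0] = roles[r1] = "viral"
            interior = list(range(r0 + 1, r1))
            amg_slots = rng.choice(interior, size=len(carried), replace=False)
            for slot, pathway in zip(amg_slots, sorted(carried)):
                roles[slot] = f"amg:{pathway}"
            free = [i for i in interior if roles[i] == "outside"]
            if free and rng.random() < cfg.p_curation_decoy:
                roles[int(rng.choice(free))] = "curation_decoy"
            for i in interior:
                if roles[i] == "outside":
                    roles[i] = "viral" if rng.random() < cfg.p_viral_gene else "putative"
            outside = [i for i in range(n_genes) if roles[i] == "outside"]
            if lifestyle == "temperate" and wants_lysogeny:
                slot = int(rng.choice(outside))
                roles[slot] = "lysogeny"
                outside.remove(slot)
            if outside and rng.random() < cfg.p_decoy_ko:
                slot = int(rng.choice(outside))
                roles[slot] = "decoy_ko"
                outside.remove(slot)
            for i in outside:
                roles[i] = "host_like" if rng.random() < 0.5 else "putative"
        else:
            # Secondary contig: no conserved region (at most one viral gene).
            if n_genes >= 2 and rng.random() < 0.5:
                roles[int(rng.integers(0, n_genes))] = "viral"
            for i in range(n_genes):
                if roles[i] == "outside":
                    if rng.random() < cfg.p_decoy_ko / 2:
                        roles[i] = "decoy_ko"
                    else:
                        roles[i] = "host_like" if rng.random() < 0.5 else "putative"

        genes = []
        for i, ((start, end), role) in enumerate(zip(coords, roles)):
            gene_counter += 1
            gene_id = f"{votu_id}_g{gene_counter:03d}"
            hits: list[HitRecord] = []
            boundary = i in boundary_idx
            if role == "viral":
                hallmark = bool(rng.random() < (0.8 if boundary else 0.3))
                label = str(rng.choice(HALLMARK_LABELS if hallmark else VIRAL_LIKE_LABELS))
                db = "pvog" if hallmark or rng.random() < 0.6 else "checkv_hmm"
                hits.append(_hit(gene_id, db, f"{db.upper()}{rng.integers(1000):04d}",
                                 label=label, hallmark=hallmark and db == "pvog",
                                 e=1e-12, bits=150.0))
                if rng.random() < 0.7:
                    hits.append(_hit(gene_id, "refseq_virus", "ref_" + family,
                                     label=label, taxonomy=";".join(lineage),
                                     e=1e-15, bits=200.0))
                truth.gene_roles[gene_id] = "viral"
            elif role.startswith("amg:"):
                pathway = role.split(":", 1)[1]
                ko = str(rng.choice(pathway_kos[pathway]))
                label = pmap.ko_labels.get(ko, ko)
                hits.append(_hit(gene_id, "kegg", ko, label=label, ko=ko))
                if rng.random() < 0.5:
                    hits.append(_hit(gene_id, "pfam", f"PF{rng.integers(10000):05d}",
                                     label=label, e=1e-8, bits=90.0))
                truth.gene_roles[gene_id] = "amg"
                truth.amg_genes[gene_id] = (votu_id, ko, pathway)
                truth.amg_gene_lengths[gene_id] = end - start
            elif role == "curation_decoy":
                label = str(rng.choice(CURATION_DECOY_LABELS))
                hits.append(_hit(gene_id, "kegg", f"K{rng.integers(90000, 99999):05d}",
                                 label=label))
                truth.gene_roles[gene_id] = "curation_decoy"
            elif role == "decoy_ko":
                pathway = str(rng.choice(sorted(pathway_kos)))
                ko = str(rng.choice(pathway_kos[pathway]))
                hits.append(_hit(gene_id, "kegg", ko, label=pmap.ko_labels.get(ko, ko),
                                 ko=ko))
                truth.gene_roles[gene_id] = "decoy_ko"
            elif role == "lysogeny":
                label = str(rng.choice(LYSOGENY_LABELS))
                hits.append(_hit(gene_id, "kegg", f"K{rng.integers(90000, 99999):05d}",
                                 label=label))
                truth.gene_roles[gene_id] = "lysogeny"
            elif role == "host_like":
                label = str(rng.choice(HOST_LIKE_LABELS))
                hits.append(_hit(gene_id, "eggnog", f"COG{rng.integers(6000):04d}",
                                 label=label, e=1e-7, bits=80.0))
                truth.gene_roles[gene_id] = "host_like"
            else:
                truth.gene_roles[gene_id] = "putative"
            # Occasional sub-threshold noise hit; the reader must discard it.
            if rng.random() < 0.25:
                hits.append(_hit(gene_id, "cog", f"COG{rng.integers(6000):04d}",
                                 label="unrelated weak homolog", e=1e-3, bits=25.0))
            gene = GeneRecord(
                gene_id=gene_id, votu_id=votu_id, contig_id=contig_id,
                start=start, end=end,
                strand="+" if rng.random() < 0.5 else "-", hits=hits,
            )
            vio.annotate_gene(gene)
            genes.append(gene)
        contigs[contig_id] = genes

    return VirusGenome(
        votu_id=votu_id,
        contigs=contigs,
        length_bp=total_len,
        completeness_pct=float(np.round(rng.uniform(25, 100), 1)),
        is_circular_or_complete=bool(rng.random() < 0.2),
        provirus_flag_tool_a=flag_a,
        provirus_flag_tool_b=flag_b,
        taxonomy=";".join(lineage),
    )


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.asarray(mu, float)
    if not np.isfinite(dispersion):
        return rng.poisson(mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    p = dispersion / (dispersion + mu[pos])
    out[pos] = rng.negative_binomial(dispersion, p)
    return out


def simulate_counts(
    truth: GroundTruth, cfg: SimulationConfig | None = None
) -> tuple[list[SampleTable], list[SampleTable]]:
    """Draw metagenome and metatranscriptome fragment counts.

    Metagenome counts cover all habitats; metatranscriptome counts (per AMG
    gene) cover the two water fractions only, under the same sample ids so
    expression can be matched to abundance.  Expected per-sample FPKM is
    recorded in the truth ledger.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng([cfg.seed, 1])
    votus = sorted(truth.votu_lengths)
    votu_pos = {v: i for i, v in enumerate(votus)}
    weights = np.array([truth.base_weights[v] for v in votus])
    lengths = np.array([truth.votu_lengths[v] for v in votus], float)

    mg_samples: list[SampleTable] = []
    mt_samples: list[SampleTable] = []
    expected = {}
    for habitat in HABITATS:
        effects = cfg.habitat_effects.get(habitat, {})
        mult = np.array(
            [
                float(np.prod([effects.get(p, 1.0) for p in sorted(truth.carriage[v])]))
                for v in votus
            ]
        )
        for k in range(cfg.n_samples_per_habitat):
            sample_id = f"{habitat}{k + 1:02d}"
            truth.sample_habitats[sample_id] = habitat
            props = weights * mult
            props = props / props.sum()
            mu = props * cfg.depth_mean
            counts = _nb_draw(rng, mu, cfg.dispersion)
            total = int(max(1, counts.sum()))
            mg_samples.append(
                SampleTable(
                    sample_id=sample_id, habitat=habitat, assay="metagenome",
                    counts={v: int(c) for v, c in zip(votus, counts)},
                    total_mapped=total,
                )
            )
            expected[sample_id] = mu / ((lengths / 1e3) * (cfg.depth_mean / 1e6))

            if habitat in ("FL", "PA"):
                amg_ids = sorted(truth.amg_genes)
                mu_t = np.array(
                    [
                        props[votu_pos[truth.amg_genes[g][0]]]
                        * truth.expression_ratio[truth.amg_genes[g][1]]
                        * (truth.amg_gene_lengths[g]
                           / truth.votu_lengths[truth.amg_genes[g][0]])
                        * cfg.depth_mean * cfg.mt_depth_factor
                        for g in amg_ids
                    ]
                )
                t_counts = _nb_draw(rng, mu_t, cfg.dispersion)
                mt_samples.append(
                    SampleTable(
                        sample_id=sample_id, habitat=habitat,
                        assay="metatranscriptome",
                        counts={g: int(c) for g, c in zip(amg_ids, t_counts)},
                        total_mapped=int(max(1, t_counts.sum())),
                    )
                )
    truth.expected_fpkm = pd.DataFrame(expected, index=votus)
    return mg_samples, mt_samples


# ---------------------------------------------------------------------------
# Host evidence
# ---------------------------------------------------------------------------


def simulate_host_evidence(
    truth: GroundTruth, fp_rate: float = 0.2, cfg: SimulationConfig | None = None
) -> tuple[list[EvidenceHit], dict[str, tuple[str, ...]]]:
    """Supra-threshold hits for planted links plus sub-threshold decoys."""
    cfg = cfg or truth.config
    rng = np.random.default_rng([cfg.seed, 2])
    methods = ("homology", "crispr", "trna")
    hits: list[EvidenceHit] = []
    for votu_id, host_id in sorted(truth.host_links):
        chosen = [str(rng.choice(methods, p=[0.5, 0.3, 0.2]))]
        if rng.random() < 0.2:
            chosen.append(str(rng.choice([m for m in methods if m != chosen[0]])))
        for method in chosen:
            hits.append(_evidence_hit(rng, votu_id, host_id, method, passing=True))

    n_decoys = int(round(fp_rate * len(truth.host_links)))
    votus = sorted(truth.votu_lengths)
    host_ids = sorted(truth.host_lineages)
    for _ in range(n_decoys):
        hits.append(
            _evidence_hit(
                rng,
                str(rng.choice(votus)),
                str(rng.choice(host_ids)),
                str(rng.choice(methods)),
                passing=False,
            )
        )
    return hits, dict(truth.host_lineages)


def _evidence_hit(rng, votu_id, host_id, method, passing: bool) -> EvidenceHit:
    if method == "homology":
        if passing:
            return EvidenceHit(votu_id, host_id, method,
                               identity_pct=float(np.round(rng.uniform(80, 100), 2)),
                               query_coverage_pct=float(np.round(rng.uniform(80, 100), 2)),
                               e_value=1e-20, bit_score=float(np.round(rng.uniform(200, 900), 1)))
        arm = rng.integers(0, 3)
        return EvidenceHit(votu_id, host_id, method,
                           identity_pct=float(np.round(rng.uniform(40, 69.5), 2)) if arm == 0
                           else float(np.round(rng.uniform(80, 100), 2)),
                           query_coverage_pct=float(np.round(rng.uniform(20, 70), 2)) if arm == 1
                           else float(np.round(rng.uniform(80, 100), 2)),
                           e_value=0.05 if arm == 2 else 1e-10,
                           bit_score=45.0 if arm == 2 else 300.0)
    if method == "trna":
        if passing:
            return EvidenceHit(votu_id, host_id, method, identity_pct=100.0,
                               query_coverage_pct=100.0, e_value=1e-30, bit_score=150.0)
        return EvidenceHit(votu_id, host_id, method,
                           identity_pct=float(np.round(rng.uniform(90, 99.9), 2)),
                           query_coverage_pct=100.0, e_value=1e-20, bit_score=120.0)
    if passing:
        return EvidenceHit(votu_id, host_id, method, identity_pct=100.0,
                           query_coverage_pct=100.0, e_value=1e-10,
                           bit_score=60.0, word_size=16,
                           mismatches=int(rng.integers(0, 4)))
    return EvidenceHit(votu_id, host_id, method, identity_pct=100.0,
                       query_coverage_pct=float(rng.choice([90.0, 100.0])),
                       e_value=1e-8, bit_score=50.0, word_size=16,
                       mismatches=int(rng.integers(4, 9)))


# ---------------------------------------------------------------------------
# Degradation
# ---------------------------------------------------------------------------


def degrade_annotations(
    genomes: Sequence[VirusGenome],
    dropout: float,
    seed: int,
    gene_ids: Sequence[str] | None = None,
    drop_viral: bool = False,
) -> list[VirusGenome]:
    """Blank the functional labels of a seeded random fraction of genes.

    Only genes carrying a label are eligible; a restriction to ``gene_ids``
    (e.g. the planted lysogeny genes) scopes the dropout.  Viral-category
    evidence is untouched unless ``drop_viral`` is set.
    """
    if not 0 <= dropout <= 1:
        raise ValueError("dropout must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    allowed = set(gene_ids) if gene_ids is not None else None
    out = copy.deepcopy(list(genomes))
    for genome in out:
        for gene in genome.genes():
            if allowed is not None and gene.gene_id not in allowed:
                continue
            if gene.consensus_label == vio.PUTATIVE and not drop_viral:
                continue
            if rng.random() >= dropout:
                continue
            for hit in gene.hits:
                hit.functional_label = ""
                hit.ko_id = ""
            if drop_viral:
                gene.hits = [h for h in gene.hits
                             if h.database not in vio.VIRAL_SOURCES]
            vio.annotate_gene(gene)
    return out


# ---------------------------------------------------------------------------
# Full bundle emission
# ---------------------------------------------------------------------------


def write_truth(truth: GroundTruth, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        sorted(truth.lifestyles.items()), columns=["votu_id", "lifestyle"]
    ).to_csv(out_dir / "lifestyles.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.gene_roles.items()), columns=["gene_id", "role"]
    ).to_csv(out_dir / "gene_roles.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, *v) for g, v in sorted(truth.amg_genes.items())],
        columns=["gene_id", "votu_id", "ko_id", "pathway"],
    ).to_csv(out_dir / "amg_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.host_links), columns=["votu_id", "host_genome_id"]
    ).to_csv(out_dir / "host_links.tsv", sep="\t", index=False)
    if truth.expected_fpkm is not None:
        truth.expected_fpkm.to_csv(out_dir / "expected_fpkm.tsv", sep="\t")


def simulate_bundle(cfg: SimulationConfig, out_dir, fp_rate: float = 0.2) -> GroundTruth:
    """Emit the complete input bundle (plus truth ledger) under ``out_dir``."""
    out_dir = Path(out_dir)
    genomes, truth = simulate_community(cfg)
    vio.write_annotation_bundle(genomes, out_dir)
    mg, mt = simulate_counts(truth, cfg)
    vio.write_count_tables(mg, out_dir / "metagenome_counts.tsv",
                           out_dir / "metagenome_samples.tsv")
    vio.write_count_tables(mt, out_dir / "metatranscriptome_counts.tsv",
                           out_dir / "metatranscriptome_samples.tsv")
    hits, lineages = simulate_host_evidence(truth, fp_rate=fp_rate, cfg=cfg)
    write_evidence_tsv(hits, out_dir / "host_evidence.tsv")
    write_lineage_tsv(lineages, out_dir / "host_lineages.tsv")
    write_truth(truth, out_dir / "truth")
    return truth
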