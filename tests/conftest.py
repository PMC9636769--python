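import pytest
from hypothesis import settings

from viramg.io import GeneRecord, HitRecord, VirusGenome

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from viramg.simulate import SimulationConfig, simulate_community


def make_gene(gene_id, category="nonviral", label="putative protein", ko="",
              votu="vOTU_T", contig="vOTU_T_c1", start=0, end=300):
    """Bare gene with pre-set derived fields (no hits), for rule-level tests."""
    g = GeneRecord(gene_id=gene_id, votu_id=votu, contig_id=contig,
                   start=start, end=end)
    g.gene_category = category
    g.consensus_label = label
    g.ko_id = ko
    return g


def make_genome(categories_labels, votu="vOTU_T", length_bp=30_000,
                flag_a=False, flag_b=False, completeness=None, circular=False):
    """Genome from a list of (category, label[, ko]) tuples on one contig."""
    genes = []
    for i, spec in enumerate(categories_labels):
        category, label = spec[0], spec[1]
        ko = spec[2] if len(spec) > 2 else ""
        genes.append(
            make_gene(f"{votu}_g{i:03d}", category, label, ko, votu=votu,
                      contig=f"{votu}_c1", start=i * 1000, end=i * 1000 + 900)
        )
    return VirusGenome(
        votu_id=votu, contigs={f"{votu}_c1": genes}, length_bp=length_bp,
        completeness_pct=completeness, is_circular_or_complete=circular,
        provirus_flag_tool_a=flag_a, provirus_flag_tool_b=flag_b,
    )


def hit(gene_id="g", database="kegg", e=1e-10, bits=120.0, label="", ko="",
        taxonomy="", hallmark=False):
    return HitRecord(gene_id=gene_id, database=database, subject_id="subj",
                     e_value=e, bit_score=bits, functional_label=label,
                     ko_id=ko, taxonomy=taxonomy, is_hallmark=hallmark)


@pytest.fixture(scope="session")
def golden_cfg():
    """The reference study conditions: 60 vOTUs, 12 metagenome samples."""
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def golden_community(golden_cfg):
    return simulate_community(golden_cfg)
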