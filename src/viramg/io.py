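"""Reading, writing and normalisation of the annotation bundle.

The external dialect is deliberately plain: a GFF3 file of predicted genes
(one ``gene`` feature per ORF, ``ID`` and ``votu_id`` attributes), a TSV of
per-gene alignment evidence (one row per database hit), a TSV of per-vOTU
metadata, and long-format fragment-count tables.  Everything downstream works
on the in-memory types defined here.

Internally all coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is honoured only at the file boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
import pandas as pd

#: Annotation sources accepted in the evidence table.
DATABASES = frozenset(
    {"kegg", "eggnog", "cog", "refseq_virus", "pfam", "vog", "pvog", "checkv_hmm"}
)

#: Databases whose hits mark a gene as viral (hallmark or viral-like).
VIRAL_SOURCES = frozenset({"pvog", "checkv_hmm"})

#: Label given to genes whose function cannot be resolved consistently.
PUTATIVE = "putative protein"

#: Global alignment-retention thresholds applied to every database search.
DEFAULT_E_MAX = 1e-5
DEFAULT_BITSCORE_MIN = 50.0

ANNOTATION_COLUMNS = [
    "gene_id",
    "votu_id",
    "database",
    "subject_id",
    "e_value",
    "bit_score",
    "functional_label",
    "ko_id",
    "is_hallmark",
    "taxonomy",
]

METADATA_COLUMNS = [
    "votu_id",
    "length_bp",
    "completeness_pct",
    "circular_complete",
    "provirus_flag_a",
    "provirus_flag_b",
]


@dataclass
class HitRecord:
    """One retained-or-raw alignment of a gene against a reference database."""

    gene_id: str
    database: str
    subject_id: str
    e_value: float
    bit_score: float
    functional_label: str = ""
    ko_id: str = ""
    taxonomy: str = ""
    is_hallmark: bool = False

    def __post_init__(self) -> None:
        if self.database not in DATABASES:
            raise ValueError(
                f"unknown annotation database {self.database!r} for gene "
                f"{self.gene_id!r}; expected one of {sorted(DATABASES)}"
            )


@dataclass
class GeneRecord:
    """One predicted ORF with coordinates and its functional evidence.

    ``start``/``end`` are 0-based half-open on the parent contig.
    """

    gene_id: str
    votu_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    gene_category: str = "nonviral"  # viral_hallmark | viral_like | nonviral
    consensus_label: str = PUTATIVE
    ko_id: str = ""
    hits: list[HitRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start ({self.start}) > end ({self.end})"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def is_viral(self) -> bool:
        return self.gene_category in ("viral_hallmark", "viral_like")


@dataclass
class VirusGenome:
    """One vOTU: ordered genes per contig plus upstream-tool metadata."""

    votu_id: str
    contigs: dict[str, list[GeneRecord]]
    length_bp: int
    completeness_pct: float | None = None
    is_circular_or_complete: bool = False
    provirus_flag_tool_a: bool = False
    provirus_flag_tool_b: bool = False
    taxonomy: str = ""

    def genes(self) -> Iterator[GeneRecord]:
        for contig_id in self.contigs:
            yield from self.contigs[contig_id]

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.contigs.values())


@dataclass
class SampleTable:
    """Fragment counts for one sample of one assay."""

    sample_id: str
    habitat: str  # FL | PA | SE
    assay: str  # metagenome | metatranscriptome
    counts: dict[str, int]
    total_mapped: int

    def __post_init__(self) -> None:
        if self.total_mapped <= 0:
            raise ValueError(f"sample {self.sample_id!r}: total_mapped must be > 0")
        if self.counts and self.total_mapped < max(self.counts.values()):
            raise ValueError(
                f"sample {self.sample_id!r}: total_mapped below the largest "
                "single-feature count"
            )


# ---------------------------------------------------------------------------
# Hit filtering and label consensus
# ---------------------------------------------------------------------------


def filter_hits(
    hits: Iterable[HitRecord],
    e_max: float = DEFAULT_E_MAX,
    bs_min: float = DEFAULT_BITSCORE_MIN,
) -> list[HitRecord]:
    """Apply the global alignment thresholds (e-value <= e_max, bits >= bs_min).

    Both bounds are inclusive.  Records with a negative e-value or bit score
    are malformed and dropped with a warning.  Input order is preserved and
    the operation is idempotent.
    """
    kept: list[HitRecord] = []
    for hit in hits:
        if hit.e_value < 0 or hit.bit_score < 0:
            warnings.warn(
                f"rejecting malformed hit for gene {hit.gene_id!r} "
                f"(e={hit.e_value}, bits={hit.bit_score})",
                stacklevel=2,
            )
            continue
        if hit.e_value <= e_max and hit.bit_score >= bs_min:
            kept.append(hit)
    return kept


def _norm_label(label: str) -> str:
    return " ".join(label.casefold().split())


def _labels_compatible(a: str, b: str) -> bool:
    """Two normalised labels agree, or one is a bare gene symbol.

    A single-token label (a gene symbol such as ``phoH``) does not contradict
    a longer description whose first token is that symbol.
    """
    if a == b:
        return True
    ta, tb = a.split(), b.split()
    if len(ta) == 1 and tb and tb[0] == ta[0]:
        return True
    if len(tb) == 1 and ta and ta[0] == tb[0]:
        return True
    return False


def consensus_function(hits: Sequence[HitRecord]) -> str:
    """Build a single functional label from already-filtered hits.

    KEGG is the primary source: its label wins when no other database's
    retained label contradicts it.  Without a KEGG label, a unanimous label
    is returned.  Any disagreement between databases, or the absence of any
    label, yields :data:`PUTATIVE` — the conservative correction applied when
    databases disagree.
    """
    labelled = [(h, _norm_label(h.functional_label)) for h in hits if h.functional_label.strip()]
    if not labelled:
        return PUTATIVE
    kegg = next((pair for pair in labelled if pair[0].database == "kegg"), None)
    if kegg is not None:
        ref = kegg[1]
        if all(_labels_compatible(ref, other) for _, other in labelled):
            return kegg[0].functional_label.strip()
        return PUTATIVE
    first_norm = labelled[0][1]
    if all(_labels_compatible(first_norm, other) for _, other in labelled):
        # Prefer the most descriptive spelling of the agreed label.
        best = max(labelled, key=lambda pair: len(pair[1]))
        return best[0].functional_label.strip()
    return PUTATIVE


def gene_category_from_hits(hits: Sequence[HitRecord]) -> str:
    """Derive viral_hallmark / viral_like / nonviral from retained hits.

    Hallmark status requires a pVOG hit flagged as hallmark in the evidence
    table; any other hit from a viral source gives viral_like.
    """
    category = "nonviral"
    for hit in hits:
        if hit.database == "pvog" and hit.is_hallmark:
            return "viral_hallmark"
        if hit.database in VIRAL_SOURCES:
            category = "viral_like"
    return category


def annotate_gene(gene: GeneRecord, e_max: float = DEFAULT_E_MAX,
                  bs_min: float = DEFAULT_BITSCORE_MIN) -> GeneRecord:
    """Filter a gene's hits in place and refresh its derived fields."""
    gene.hits = filter_hits(gene.hits, e_max=e_max, bs_min=bs_min)
    gene.gene_category = gene_category_from_hits(gene.hits)
    gene.consensus_label = consensus_function(gene.hits)
    ko = ""
    for hit in gene.hits:
        if hit.database == "kegg" and hit.ko_id:
            ko = hit.ko_id
            break
    gene.ko_id = ko
    return gene


# ---------------------------------------------------------------------------
# Bundle reading
# ---------------------------------------------------------------------------

_TRUE_TOKENS = {"true", "t", "yes", "y", "1"}
_FALSE_TOKENS = {"false", "f", "no", "n", "0", ""}


def _parse_bool(value) -> bool:
    token = str(value).strip().casefold()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS or token == "nan":
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean flag")


def _validate_gff_lines(gff_path: Path) -> None:
    """Pre-scan for malformed coordinates so errors can name the line."""
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{gff_path}:{lineno}: expected 9 GFF3 columns")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{gff_path}:{lineno}: non-integer coordinate") from exc
            if start > end:
                raise ValueError(
                    f"{gff_path}:{lineno}: malformed coordinates (start {start} > end {end})"
                )
            if start < 1:
                raise ValueError(f"{gff_path}:{lineno}: GFF3 coordinates are 1-based")


def read_votu_metadata(votu_meta_path) -> pd.DataFrame:
    meta = pd.read_csv(votu_meta_path, sep="\t", dtype={"votu_id": str})
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"vOTU metadata is missing columns: {sorted(missing)}")
    return meta


def read_annotation_table(annot_tsv_path) -> dict[str, list[HitRecord]]:
    """Read the per-gene evidence TSV into raw (unfiltered) hits per gene."""
    table = pd.read_csv(annot_tsv_path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"annotation table is missing columns: {sorted(missing)}")
    hits_by_gene: dict[str, list[HitRecord]] = {}
    for row in table.itertuples(index=False):
        hit = HitRecord(
            gene_id=row.gene_id,
            database=row.database,
            subject_id=row.subject_id,
            e_value=float(row.e_value),
            bit_score=float(row.bit_score),
            functional_label=row.functional_label,
            ko_id=row.ko_id,
            taxonomy=row.taxonomy,
            is_hallmark=_parse_bool(row.is_hallmark),
        )
        hits_by_gene.setdefault(row.gene_id, []).append(hit)
    return hits_by_gene


def read_annotation_bundle(
    gff_path,
    annot_tsv_path,
    votu_meta_path,
    e_max: float = DEFAULT_E_MAX,
    bs_min: float = DEFAULT_BITSCORE_MIN,
) -> list[VirusGenome]:
    """Assemble :class:`VirusGenome` objects from the three bundle files.

    Genes are attached to their vOTU, ordered by (contig_id, start), hit
    thresholds applied, and consensus labels / categories derived.
    """
    gff_path = Path(gff_path)
    _validate_gff_lines(gff_path)
    meta = read_votu_metadata(votu_meta_path)
    hits_by_gene = read_annotation_table(annot_tsv_path)

    genomes: dict[str, VirusGenome] = {}
    for row in meta.itertuples(index=False):
        completeness = None
        if str(row.completeness_pct).strip() not in ("", "NA", "nan"):
            completeness = float(row.completeness_pct)
        genomes[row.votu_id] = VirusGenome(
            votu_id=row.votu_id,
            contigs={},
            length_bp=int(row.length_bp),
            completeness_pct=completeness,
            is_circular_or_complete=_parse_bool(row.circular_complete),
            provirus_flag_tool_a=_parse_bool(row.provirus_flag_a),
            provirus_flag_tool_b=_parse_bool(row.provirus_flag_b),
        )

    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        gene_id = feat.attributes["ID"][0]
        votu_values = feat.attributes.get("votu_id", [])
        votu_id = votu_values[0] if votu_values else ""
        if votu_id not in genomes:
            raise ValueError(
                f"gene {gene_id!r} references unknown vOTU {votu_id!r}"
            )
        gene = GeneRecord(
            gene_id=gene_id,
            votu_id=votu_id,
            contig_id=feat.seqid,
            start=feat.start - 1,  # to 0-based half-open
            end=feat.end,
            strand=feat.strand if feat.strand in ("+", "-") else "+",
            hits=hits_by_gene.get(gene_id, []),
        )
        annotate_gene(gene, e_max=e_max, bs_min=bs_min)
        genomes[votu_id].contigs.setdefault(feat.seqid, []).append(gene)

    for genome in genomes.values():
        ordered = {}
        for contig_id in sorted(genome.contigs):
            genes = sorted(genome.contigs[contig_id], key=lambda g: (g.start, g.end))
            seen: set[tuple[int, int]] = set()
            for g in genes:
                if (g.start, g.end) in seen:
                    raise ValueError(
                        f"contig {contig_id!r}: duplicate gene coordinates "
                        f"({g.start + 1}, {g.end})"
                    )
                seen.add((g.start, g.end))
            ordered[contig_id] = genes
        genome.contigs = ordered
    return [genomes[v] for v in sorted(genomes)]


def filter_votus(
    genomes: Iterable[VirusGenome],
    min_len: int = 10_000,
    keep_complete: bool = True,
) -> list[VirusGenome]:
    """Retain vOTUs at least ``min_len`` bp long, or circular/complete ones."""
    return [
        g
        for g in genomes
        if g.length_bp >= min_len or (keep_complete and g.is_circular_or_complete)
    ]


# ---------------------------------------------------------------------------
# Bundle writing (round-trip partner of read_annotation_bundle)
# ---------------------------------------------------------------------------


def write_annotation_bundle(genomes: Sequence[VirusGenome], out_dir) -> dict[str, Path]:
    """Write genes.gff3 / annotations.tsv / votu_metadata.tsv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gff_path = out_dir / "genes.gff3"
    annot_path = out_dir / "annotations.tsv"
    meta_path = out_dir / "votu_metadata.tsv"

    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for genome in genomes:
            for gene in genome.genes():
                gff.write(
                    "\t".join(
                        [
                            gene.contig_id,
                            "viramg",
                            "gene",
                            str(gene.start + 1),
                            str(gene.end),
                            ".",
                            gene.strand,
                            ".",
                            f"ID={gene.gene_id};votu_id={gene.votu_id}",
                        ]
                    )
                    + "\n"
                )

    rows = []
    for genome in genomes:
        for gene in genome.genes():
            for hit in gene.hits:
                rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "votu_id": gene.votu_id,
                        "database": hit.database,
                        "subject_id": hit.subject_id,
                        "e_value": repr(hit.e_value),
                        "bit_score": repr(hit.bit_score),
                        "functional_label": hit.functional_label,
                        "ko_id": hit.ko_id,
                        "is_hallmark": str(hit.is_hallmark),
                        "taxonomy": hit.taxonomy,
                    }
                )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(annot_path, sep="\t", index=False)

    meta_rows = [
        {
            "votu_id": g.votu_id,
            "length_bp": g.length_bp,
            "completeness_pct": "" if g.completeness_pct is None else repr(g.completeness_pct),
            "circular_complete": str(g.is_circular_or_complete),
            "provirus_flag_a": str(g.provirus_flag_tool_a),
            "provirus_flag_b": str(g.provirus_flag_tool_b),
        }
        for g in genomes
    ]
    pd.DataFrame(meta_rows, columns=METADATA_COLUMNS).to_csv(meta_path, sep="\t", index=False)
    return {"gff": gff_path, "annotations": annot_path, "metadata": meta_path}


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


def read_count_tables(counts_tsv_path, sample_meta_path) -> list[SampleTable]:
    """Read long-format fragment counts plus sample metadata."""
    counts = pd.read_csv(counts_tsv_path, sep="\t", dtype={"sample_id": str, "feature_id": str})
    meta = pd.read_csv(sample_meta_path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "feature_id", "fragments"):
        if col not in counts.columns:
            raise ValueError(f"counts table is missing column {col!r}")
    for col in ("sample_id", "habitat", "assay", "total_mapped"):
        if col not in meta.columns:
            raise ValueError(f"sample metadata is missing column {col!r}")
    grouped = {
        sid: dict(zip(sub.feature_id, sub.fragments.astype(int)))
        for sid, sub in counts.groupby("sample_id")
    }
    tables = []
    for row in meta.itertuples(index=False):
        tables.append(
            SampleTable(
                sample_id=row.sample_id,
                habitat=row.habitat,
                assay=row.assay,
                counts=grouped.get(row.sample_id, {}),
                total_mapped=int(row.total_mapped),
            )
        )
    return tables


def write_count_tables(samples: Sequence[SampleTable], counts_tsv_path, sample_meta_path) -> None:
    rows = []
    for s in samples:
        for feature_id in sorted(s.counts):
            rows.append({"sample_id": s.sample_id, "feature_id": feature_id,
                         "fragments": s.counts[feature_id]})
    pd.DataFrame(rows, columns=["sample_id", "feature_id", "fragments"]).to_csv(
        counts_tsv_path, sep="\t", index=False
    )
    meta = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "habitat": s.habitat,
                "assay": s.assay,
                "total_mapped": s.total_mapped,
            }
            for s in samples
        ]
    )
    meta.to_csv(sample_meta_path, sep="\t", index=False)
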