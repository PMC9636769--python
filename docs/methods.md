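# Methods

## Scope and data model

`viramg` implements the analysis layer of a community-wide viral AMG study.
Upstream computation — assembly, viral sequence identification, ORF
prediction, database searches, read mapping — is out of scope; the package
consumes their tabular products. The unit of analysis is the vOTU (viral
operational taxonomic unit), possibly a multi-contig vMAG, carrying ordered
genes per contig; every gene carries raw database hits from eight sources
(kegg, eggnog, cog, refseq_virus, pfam, vog, pvog, checkv_hmm).

All alignment evidence passes one global retention rule — e-value ≤ 10⁻⁵
and bit score ≥ 50, both bounds inclusive — before anything downstream sees
it. Internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted at the file boundary only.

## Consensus functional labels

Databases disagree, and the original curation of such conflicts was manual
and irreproducible. The deterministic stand-in: KEGG's label wins when no
other retained label contradicts it; without a KEGG hit a unanimous label is
used; any contradiction, or no label at all, yields "putative protein".
Labels are compared case-folded with collapsed whitespace, and a bare gene
symbol (single token) does not contradict a longer description whose first
token is that symbol (e.g. `phoH` vs `PhoH family ...`). This is a design
choice in the face of an open adjudication question; its main consequence is
conservatism — disagreeing genes drop out of AMG calling and lysogeny
detection entirely.

## Lifestyle classification

Temperate evidence is either (a) provirus flags from both upstream tools —
a single tool never suffices — or (b) at least one gene whose consensus
label matches the lysogeny lexicon (integrase, recombinase, transposase,
excisionase, "CI repressor", "Cro repressor", parA, parB) as a contiguous,
case-insensitive token sequence. The default combination is OR; an AND mode
exists for stricter studies. Matching consensus labels (not raw hit
descriptions) prevents rejected alignments from triggering calls. Whether a
lysogeny gene must lie inside a detected prophage region is deliberately
not imposed. Because all evidence is positive, annotation dropout can only
flip temperate → lytic, reproducing the known underestimation of temperate
viruses from incomplete assemblies; this one-sidedness is property-tested.

## Conserved regions and AMG calling

A conserved region is, per contig, the maximal span from the first to the
last viral-category gene (hallmark = pVOG hit flagged hallmark; viral-like =
any other pVOG/CheckV-HMM hit), provided at least two such genes exist. This
maximal-span rule is the weakest deterministic reading of "both boundary
genes viral"; a stricter `flanking="immediate"` option requires viral
neighbours on both sides of each candidate. Regions never span the junction
of circular genomes. Candidates are nonviral ORFs strictly inside a region
with a resolved label; unresolved genes neither become AMGs nor break
regions.

Curation applies a categorical blacklist (DNA-related reactions, nucleotide
metabolism, viral invasion/lysis, viral-component modification, structural
proteins, ribosomal proteins, transcription/translation regulators,
eukaryote-specific genes) in declared order, first match supplying the
removal reason; removed calls stay in the output as an audit trail, and
curation is idempotent. The shipped blacklist keeps small KO seeds and lets
keyword arms carry the load — the published category lists are categorical,
not enumerated — and is an editable YAML. Class assignment: class I iff any
mapped pathway has BRITE top category "Metabolism" (membership in any
Metabolism pathway dominates); unmapped KOs default to class II. The shipped
KO→pathway map is likewise a curated seed meant to be replaced by a full
KEGG dump in real studies.

Per-genome statistics: gene density = ORFs/kbp, AMG ratio = retained
AMGs/ORFs, annotation rate = labelled ORFs/ORFs; genomes with annotation
rate ≤ 50% (inclusive) are excluded from genomic-property comparisons.

## Quantification

FPKM uses per-sample fragments mapped to the vOTU catalogue as the
denominator total (not raw library size). AMG abundance equals the parent
vOTU's FPKM — AMGs are mostly host-derived, so mapping reads to the gene
itself would absorb host reads. KO abundance sums member AMGs (provenance
recorded); expression level = Σ member-AMG transcript FPKM / KO abundance,
undefined (NaN) exactly where the abundance is zero. Transcript counts are
consumed as given; the 100%-identity/100%-coverage mapping strictness is an
upstream contract. Multi-contig vMAGs are quantified as one feature of
total length. Rarefaction is a single seeded draw without replacement; if
lytic vOTUs are fewer than temperate ones, all lytic are kept with a
warning. The completeness filter keeps ≥ 40% (inclusive).

## Statistics

- Shannon uses the natural log (the convention of the ecology tooling this
  mirrors); richness counts positive features.
- Bray–Curtis via scipy's pairwise distances; an all-zero sample pair is
  assigned distance 0 by convention.
- PERMANOVA follows Anderson's partition: SS_total from all squared
  distances /N, SS_within from within-group squared distances /n_g;
  pseudo-F and R² from the partition, p by seeded label permutation with
  the +1/+1 convention (so 1/(n_perm+1) ≤ p ≤ 1, and p > 0 always).
  Permutations are batched in numpy; the statistic is cross-checked against
  scikit-bio in the test suite.
- Mantel correlates condensed distance vectors (Pearson), permuting rows
  and columns of one matrix simultaneously; the default alternative is
  "greater", matching the vegan convention. A constant distance vector is
  an error.
- Fisher enrichment is the two-sided exact test on carrier counts; the
  counting unit is the virus (presence/absence), never the AMG. With more
  than two groups, each group is tested against the pooled rest. Raw
  p-values are the default (the original analyses star raw p-values); a
  Benjamini–Hochberg helper is provided.
- Habitat enrichment applies Kruskal–Wallis per KO to per-sample relative
  abundance (normalised to the per-sample KO sum, one of two possible
  normalisations and the one chosen here); significant KOs are tagged with
  the habitat of highest mean rank. An all-identical row is reported as
  H = 0, p = 1 rather than an error.
- Mann–Whitney U is exact for tie-free combined n ≤ 20, otherwise normal
  approximation with tie correction.
- Taxonomy voting: at each rank from the deepest upward, a taxon held by
  strictly more than half of the assigned ORFs wins; otherwise the lowest
  common ancestor (longest common lineage prefix). Exactly half is not a
  majority.

## Host linkage

Homology, tRNA and CRISPR-spacer channels are filtered independently
(70/75/10⁻³/50; exact 100/100; coverage = 100, mismatches ≤ 3, e ≤ 10⁻⁶).
The CRISPR e-value bound is applied as a per-hit filter; word size is an
upstream search setting recorded for provenance only. Links are the union
over channels, merging duplicate (virus, host) pairs. Host taxonomy comes
from a supplied lineage TSV (GTDB-style ranks); no live lookups. Host range
counts distinct phyla (broad = ≥ 2) and domains (cross-domain = ≥ 2);
host-order enrichment uses only viruses resolving to exactly one order. No
confidence weighting across channels is attempted — cross-domain links
resting on a single channel should be read with that caveat.

## Synthetic communities

The generator's defaults define the reference study conditions: 50 lytic +
10 temperate vOTUs of 12–45 kb at 1.4 genes/kbp, three habitats (FL, PA,
SE) × 4 samples, 10⁶ expected fragments per sample. Each genome carries one
conserved region; planted AMGs sit strictly inside it, KO-bearing decoys
strictly outside, and blacklist-matching decoys inside (so curation has
real work to do). Temperate genomes draw provirus flags (0.7 per tool) and
a lysogeny gene (0.8), with at least one signal guaranteed; lytic genomes
may carry a single-tool false flag (0.05) but never both. Pathway carriage
is Bernoulli per virus, matching the occurrence-frequency counting unit.
Default effects give each planted direction a clean contrast (lytic-enriched
pathways have a zero temperate arm; temperate-enriched pathways pair
0.02 with 0.85–0.90) so that direction recovery is a property of the
pipeline rather than of a lucky draw, plus one neutral pathway as a
negative control.

Counts are negative binomial with dispersion 100 (variance μ + μ²/100,
i.e. ~10% extra CV at high depth — mild technical overdispersion;
biological variation lives in the per-vOTU lognormal weights and habitat
multipliers). The Poisson limit (`dispersion=inf`) is moment-tested. The
truth ledger stores expected FPKM from expected counts and expected totals;
the recovery check compares the across-sample mean observed/expected ratio
per vOTU and requires the community-mean absolute error under 5% at depth
10⁶ over ~20 samples. Host evidence plants supra-threshold hits for every
planted link (channel sampled per link) and sub-threshold decoys at a
configurable rate, so exact link recovery is well-defined.

What the generator does **not** emulate: nucleotide-level sequences, codon
usage, read-level errors, chimeric assembly, correlated annotation errors
across databases, compositionality beyond per-sample renormalisation, or
both-tool false provirus calls on lytic genomes. Passing tests therefore
show the analysis logic is correct under the stated statistical model, not
that upstream tool error modes are handled.

## Problem sizes and numerical choices

The reference end-to-end run uses 60 vOTUs × 12 samples; calibration uses
500 null replicates (999 permutations each) and power checks 200 replicates
at n = 100 per group — sizes chosen to make the checks statistically sharp
while keeping the whole suite fast on one CPU. Floating-point tolerances:
FPKM scale invariance at 1e-12, PERMANOVA partition identity at 1e-10.
Seeds: every stochastic component takes an explicit seed; the generator
derives independent streams for community, counts and evidence from the
config seed, and a fixed seed yields byte-identical emitted files.

## Known limitations

- The consensus-label and conserved-region rules are deterministic
  stand-ins for manual curation steps; alternative readings (e.g.
  immediate-flank candidacy) are exposed as options, not defaults.
- Conserved regions cannot span circular-genome junctions.
- KO/pathway and blacklist content ship as small seeds, adequate for the
  synthetic communities and for demonstrating the machinery, not as a
  curated biological resource.
- Kruskal–Wallis relative abundance is renormalised per sample, so a strong
  habitat effect on one KO necessarily perturbs the relative abundance of
  all others (compositional coupling); enrichment tags name the habitat of
  highest mean rank, which for such secondary shifts may be less
  interpretable.
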