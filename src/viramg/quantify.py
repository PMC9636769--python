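"""FPKM abundances, vOTU-proxy AMG abundances, KO profiles and dataset variants.

Because most AMGs are host-derived, AMG abundance is represented by the FPKM
of the parent vOTU (fragments mapped to the vOTU catalogue), not by reads
mapped to the AMG itself; transcript FPKM, in contrast, is computed per AMG
gene from metatranscriptome counts.  KO abundance sums its member AMGs and
the KO expression level is total transcript FPKM over KO abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SampleTable, VirusGenome
from .amg import AMGCall
from .lifestyle import LifestyleCall


@dataclass
class FPKMMatrix:
    """Features x samples FPKM values with the lengths/totals that made them."""

    values: pd.DataFrame
    feature_lengths: pd.Series
    sample_totals: pd.Series

    def column(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]


@dataclass
class KOProfile:
    values: pd.DataFrame  # KO x sample
    provenance: dict[str, tuple[str, ...]]  # KO -> contributing AMG gene ids


def fpkm_column(sample: SampleTable, lengths: Mapping[str, int]) -> pd.Series:
    """FPKM for one sample: count / ((length/1e3) * (total_mapped/1e6))."""
    if sample.total_mapped <= 0:
        raise ValueError(f"sample {sample.sample_id!r}: total_mapped must be positive")
    out = {}
    for feature_id, count in sample.counts.items():
        if feature_id not in lengths:
            raise KeyError(f"no length for feature {feature_id!r}")
        length = lengths[feature_id]
        if length <= 0:
            raise ValueError(f"feature {feature_id!r} has non-positive length")
        if count < 0:
            raise ValueError(f"negative count for feature {feature_id!r}")
        out[feature_id] = count / ((length / 1e3) * (sample.total_mapped / 1e6))
    return pd.Series(out, name=sample.sample_id, dtype=float)


def fpkm_matrix(samples: Sequence[SampleTable], lengths: Mapping[str, int]) -> FPKMMatrix:
    """Stack per-sample FPKM columns over the union of features (absent = 0)."""
    columns = [fpkm_column(s, lengths) for s in samples]
    values = pd.concat(columns, axis=1).fillna(0.0)
    values = values.reindex(sorted(values.index))
    return FPKMMatrix(
        values=values,
        feature_lengths=pd.Series({f: lengths[f] for f in values.index}, dtype=int),
        sample_totals=pd.Series({s.sample_id: s.total_mapped for s in samples}, dtype=int),
    )


def amg_abundance(amg_calls: Iterable[AMGCall], votu_fpkm: FPKMMatrix) -> FPKMMatrix:
    """Each retained AMG inherits its parent vOTU's FPKM in every sample."""
    rows, lengths, index = [], [], []
    for call in amg_calls:
        if call.curation_status != "retained":
            continue
        if call.votu_id not in votu_fpkm.values.index:
            raise KeyError(
                f"AMG {call.gene_id!r}: parent vOTU {call.votu_id!r} has no abundance row"
            )
        rows.append(votu_fpkm.values.loc[call.votu_id])
        lengths.append(votu_fpkm.feature_lengths[call.votu_id])
        index.append(call.gene_id)
    values = pd.DataFrame(rows, index=index) if rows else pd.DataFrame(
        columns=votu_fpkm.values.columns
    )
    return FPKMMatrix(
        values=values,
        feature_lengths=pd.Series(lengths, index=index, dtype=int),
        sample_totals=votu_fpkm.sample_totals.copy(),
    )


def aggregate_ko(amg_abund: FPKMMatrix, amg_to_ko: Mapping[str, str]) -> KOProfile:
    """Sum member-AMG abundances per KO; AMGs without a KO are excluded."""
    members: dict[str, list[str]] = {}
    for gene_id in amg_abund.values.index:
        ko = amg_to_ko.get(gene_id, "")
        if ko:
            members.setdefault(ko, []).append(gene_id)
    data = {
        ko: amg_abund.values.loc[gene_ids].sum(axis=0)
        for ko, gene_ids in sorted(members.items())
    }
    values = pd.DataFrame(data).T if data else pd.DataFrame(columns=amg_abund.values.columns)
    return KOProfile(
        values=values,
        provenance={ko: tuple(g) for ko, g in sorted(members.items())},
    )


def ko_expression_level(
    transcript_fpkm: pd.DataFrame, ko_profile: KOProfile
) -> pd.DataFrame:
    """Per KO and sample: sum of member-AMG transcript FPKM / KO abundance.

    Undefined (NaN) exactly where the KO abundance is zero.  Samples are
    matched by id, so metatranscriptome columns must be named after their
    paired metagenome samples.
    """
    if (transcript_fpkm.values < 0).any():
        raise ValueError("transcript FPKM values must be non-negative")
    samples = [s for s in transcript_fpkm.columns if s in ko_profile.values.columns]
    out = pd.DataFrame(index=ko_profile.values.index, columns=samples, dtype=float)
    for ko in ko_profile.values.index:
        genes = [g for g in ko_profile.provenance.get(ko, ()) if g in transcript_fpkm.index]
        transcripts = (
            transcript_fpkm.loc[genes, samples].sum(axis=0)
            if genes
            else pd.Series(0.0, index=samples)
        )
        abund = ko_profile.values.loc[ko, samples]
        with np.errstate(divide="ignore", invalid="ignore"):
            level = transcripts / abund
        out.loc[ko] = level.where(abund > 0, np.nan)
    return out


# ---------------------------------------------------------------------------
# Dataset variants
# ---------------------------------------------------------------------------

VARIANT_NAMES = (
    "full",
    "rarefied",
    "completeness_filtered",
    "rarefied_completeness_filtered",
)


@dataclass(frozen=True)
class DatasetVariant:
    name: str
    votu_ids: frozenset[str]
    seed: int


def _rarefy(
    lytic: list[str], temperate: list[str], rng: np.random.Generator
) -> frozenset[str]:
    """All temperates plus an equal-size uniform subsample of lytics."""
    if len(lytic) < len(temperate):
        warnings.warn(
            "fewer lytic than temperate vOTUs; rarefaction keeps all lytic",
            stacklevel=3,
        )
        chosen = lytic
    else:
        chosen = list(rng.choice(lytic, size=len(temperate), replace=False))
    return frozenset(temperate) | frozenset(chosen)


def make_dataset_variants(
    genomes: Sequence[VirusGenome],
    lifestyles: Mapping[str, LifestyleCall],
    seed: int,
    completeness_min: float = 40.0,
) -> dict[str, DatasetVariant]:
    """Build the four analysis datasets.

    ``rarefied`` equalises lytic and temperate vOTU counts by a seeded
    uniform subsample of the lytic set (single draw, without replacement);
    ``completeness_filtered`` keeps vOTUs with completeness >= 40%;
    the last variant rarefies within the completeness-filtered set.
    """
    def split(ids: Iterable[str]) -> tuple[list[str], list[str]]:
        lytic = sorted(v for v in ids if lifestyles[v].lifestyle == "lytic")
        temperate = sorted(v for v in ids if lifestyles[v].lifestyle == "temperate")
        return lytic, temperate

    all_ids = [g.votu_id for g in genomes]
    complete_ids = [
        g.votu_id
        for g in genomes
        if g.completeness_pct is not None and g.completeness_pct >= completeness_min
    ]
    rng_full = np.random.default_rng(seed)
    rng_cf = np.random.default_rng(seed)

    lytic, temperate = split(all_ids)
    lytic_cf, temperate_cf = split(complete_ids)
    return {
        "full": DatasetVariant("full", frozenset(all_ids), seed),
        "rarefied": DatasetVariant("rarefied", _rarefy(lytic, temperate, rng_full), seed),
        "completeness_filtered": DatasetVariant(
            "completeness_filtered", frozenset(complete_ids), seed
        ),
        "rarefied_completeness_filtered": DatasetVariant(
            "rarefied_completeness_filtered", _rarefy(lytic_cf, temperate_cf, rng_cf), seed
        ),
    }
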