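"""Comparative statistics for community-wide AMG profiles.

Diversity (richness, Shannon with natural log), Bray-Curtis distances,
distance-based permutation tests (PERMANOVA after Anderson, Mantel), exact
Fisher occurrence-frequency enrichment, Kruskal-Wallis habitat enrichment,
and the rank tests used throughout (Mann-Whitney U, Spearman).

Permutation p-values follow the exact-permutation convention
p = (#{permuted statistic >= observed} + 1) / (n_permutations + 1),
so p is never 0 and its lower bound is 1/(n_permutations + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .amg import AMGCall


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "data", d)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.data[iu]


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    method: str
    r_squared: float | None = None


@dataclass(frozen=True)
class EnrichmentResult:
    unit: str
    group_a: str
    group_b: str
    group_a_count: int
    group_a_total: int
    group_b_count: int
    group_b_total: int
    p_value: float
    direction: str  # "a" | "b" | "none"

    @property
    def frequency_a(self) -> float:
        return self.group_a_count / self.group_a_total

    @property
    def frequency_b(self) -> float:
        return self.group_b_count / self.group_b_total


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    richness: int
    shannon: float


# ---------------------------------------------------------------------------
# Diversity and distance
# ---------------------------------------------------------------------------


def diversity(profile: pd.Series | np.ndarray, sample_id: str = "") -> DiversityResult:
    """Richness (positive features) and Shannon entropy (natural log)."""
    values = np.asarray(profile, dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    positive = values[values > 0]
    if positive.size == 0:
        return DiversityResult(sample_id, 0, 0.0)
    p = positive / positive.sum()
    return DiversityResult(sample_id, int(positive.size), float(-(p * np.log(p)).sum()))


def diversity_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-sample diversity of a feature x sample abundance matrix."""
    rows = [diversity(profiles[s], s) for s in profiles.columns]
    return pd.DataFrame(
        {"sample_id": [r.sample_id for r in rows],
         "richness": [r.richness for r in rows],
         "shannon": [r.shannon for r in rows]}
    ).set_index("sample_id")


def bray_curtis(profiles: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis distances between sample columns.

    A pair of all-zero samples is assigned distance 0 by convention.
    """
    x = profiles.to_numpy(dtype=float).T  # samples x features
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    with np.errstate(invalid="ignore"):
        condensed = pdist(x, metric="braycurtis")
    condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(tuple(profiles.columns), squareform(condensed))


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------


def _group_indices(groups: Sequence[str]) -> dict[str, np.ndarray]:
    labels = np.asarray(groups)
    return {g: np.flatnonzero(labels == g) for g in dict.fromkeys(groups)}


def _permanova_ss(d2: np.ndarray, idx_by_group: Iterable[np.ndarray]) -> float:
    """Within-group sum of squares from a squared distance matrix."""
    ss_w = 0.0
    for idx in idx_by_group:
        ss_w += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_w


def permanova(
    D: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """One-way PERMANOVA (Anderson) with label permutation.

    The total sum of squares comes from all squared distances, the
    within-group term from within-group squared distances; pseudo-F and R^2
    follow from the partition.  Significance is assessed by permuting group
    labels ``n_perm`` times.
    """
    n = len(D.labels)
    if len(groups) != n:
        raise ValueError("group labels do not match distance matrix")
    idx_by_group = _group_indices(groups)
    a = len(idx_by_group)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sizes = [len(ix) for ix in idx_by_group.values()]
    if min(sizes) < 2:
        raise ValueError("every group needs at least two samples")

    d2 = D.data ** 2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _permanova_ss(d2, idx_by_group.values())
    ss_among = ss_total - ss_within
    df_among, df_within = a - 1, n - a
    f_obs = (ss_among / df_among) / (ss_within / df_within)
    r2 = ss_among / ss_total

    rng = np.random.default_rng(seed)
    # Batched permutations: one (n_perm x n) index matrix, gathered per group.
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    ss_w_perm = np.zeros(n_perm)
    offset = 0
    for idx in idx_by_group.values():
        cols = perms[:, offset : offset + len(idx)]
        block = d2[cols[:, :, None], cols[:, None, :]]
        ss_w_perm += block.sum(axis=(1, 2)) / (2.0 * len(idx))
        offset += len(idx)
    # Permuting positions [0..n) and slicing contiguous blocks of the group
    # sizes is equivalent to permuting the labels themselves.
    ss_a_perm = ss_total - ss_w_perm
    f_perm = (ss_a_perm / df_among) / (ss_w_perm / df_within)
    p = (np.count_nonzero(f_perm >= f_obs) + 1) / (n_perm + 1)
    return PermutationTestResult(
        statistic=float(f_obs), p_value=float(p), n_permutations=n_perm,
        seed=seed, method="permanova", r_squared=float(r2),
    )


def mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> PermutationTestResult:
    """Mantel test: Pearson r of the two condensed distance vectors.

    The rows and columns of the second matrix are permuted simultaneously.
    ``alternative`` is "greater" (the convention of the ecology tooling this
    mirrors) or "two-sided".
    """
    if D1.labels != D2.labels:
        raise ValueError("distance matrices must share labels and order")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n = len(D1.labels)
    iu = np.triu_indices(n, k=1)
    v1, v2 = D1.data[iu], D2.data[iu]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("Mantel statistic undefined for a constant distance vector")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    v2_perm = D2.data[perms[:, iu[0]], perms[:, iu[1]]]  # (n_perm, n_pairs)
    v1c = v1 - v1.mean()
    v2c = v2_perm - v2_perm.mean(axis=1, keepdims=True)
    r_perm = (v2c @ v1c) / (
        np.sqrt((v2c ** 2).sum(axis=1)) * np.sqrt((v1c ** 2).sum())
    )
    if alternative == "greater":
        exceed = np.count_nonzero(r_perm >= r_obs)
    else:
        exceed = np.count_nonzero(np.abs(r_perm) >= abs(r_obs))
    p = (exceed + 1) / (n_perm + 1)
    return PermutationTestResult(
        statistic=r_obs, p_value=float(p), n_permutations=n_perm,
        seed=seed, method="mantel",
    )


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def fisher_enrichment(
    unit: str,
    group_a_count: int,
    group_a_total: int,
    group_b_count: int,
    group_b_total: int,
    group_a: str = "a",
    group_b: str = "b",
) -> EnrichmentResult:
    """Two-sided Fisher's exact test on carrier counts in two virus groups."""
    if group_a_total <= 0 or group_b_total <= 0:
        raise ValueError("group totals must be positive")
    if not (0 <= group_a_count <= group_a_total and 0 <= group_b_count <= group_b_total):
        raise ValueError("counts must lie within their totals")
    table = [
        [group_a_count, group_a_total - group_a_count],
        [group_b_count, group_b_total - group_b_count],
    ]
    _, p = sps.fisher_exact(table, alternative="two-sided")
    freq_a = group_a_count / group_a_total
    freq_b = group_b_count / group_b_total
    direction = "none" if freq_a == freq_b else ("a" if freq_a > freq_b else "b")
    return EnrichmentResult(
        unit=unit, group_a=group_a, group_b=group_b,
        group_a_count=group_a_count, group_a_total=group_a_total,
        group_b_count=group_b_count, group_b_total=group_b_total,
        p_value=float(p), direction=direction,
    )


def pathway_occurrence(
    group_of: Mapping[str, str],
    amg_calls: Iterable[AMGCall],
) -> list[EnrichmentResult]:
    """Occurrence-frequency enrichment of pathways between virus groups.

    The unit of counting is the virus, not the AMG: a virus carrying several
    AMGs of one pathway contributes one carrier.  With exactly two groups one
    result per pathway is returned; with more, each group is tested against
    the pooled others.  Pathways carried by no virus are omitted.
    """
    carriers: dict[str, dict[str, set[str]]] = {}
    groups = sorted(set(group_of.values()))
    totals = {g: sum(1 for v in group_of.values() if v == g) for g in groups}
    for call in amg_calls:
        if call.curation_status != "retained" or call.votu_id not in group_of:
            continue
        g = group_of[call.votu_id]
        for pathway in call.pathways:
            carriers.setdefault(pathway, {}).setdefault(g, set()).add(call.votu_id)

    results: list[EnrichmentResult] = []
    for pathway in sorted(carriers):
        by_group = carriers[pathway]
        if len(groups) == 2:
            a, b = groups
            results.append(
                fisher_enrichment(
                    pathway,
                    len(by_group.get(a, ())), totals[a],
                    len(by_group.get(b, ())), totals[b],
                    group_a=a, group_b=b,
                )
            )
        else:
            for g in groups:
                rest_count = sum(len(by_group.get(h, ())) for h in groups if h != g)
                rest_total = sum(totals[h] for h in groups if h != g)
                results.append(
                    fisher_enrichment(
                        pathway,
                        len(by_group.get(g, ())), totals[g],
                        rest_count, rest_total,
                        group_a=g, group_b="rest",
                    )
                )
    return results


def relative_abundance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-sample normalisation to column sums (all-zero columns stay zero)."""
    totals = profiles.sum(axis=0)
    safe = totals.replace(0, np.nan)
    return profiles.div(safe, axis=1).fillna(0.0)


def habitat_enrichment(
    ko_relative_abundance: pd.DataFrame,
    habitat_of: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis test per KO across habitats.

    Input is the per-sample relative abundance (KO / sample total).  KOs with
    p < alpha are tagged with the habitat of highest mean rank.
    """
    habitats = sorted(set(habitat_of[s] for s in ko_relative_abundance.columns))
    members = {
        h: [s for s in ko_relative_abundance.columns if habitat_of[s] == h]
        for h in habitats
    }
    for h, samples in members.items():
        if len(samples) < 2:
            raise ValueError(f"habitat {h!r} has fewer than two samples")

    rows = []
    for ko in ko_relative_abundance.index:
        groups = [ko_relative_abundance.loc[ko, members[h]].to_numpy(float) for h in habitats]
        flat = np.concatenate(groups)
        if np.ptp(flat) == 0:  # all values identical: no evidence of difference
            h_stat, p = 0.0, 1.0
        else:
            h_stat, p = sps.kruskal(*groups)
        enriched = ""
        if p < alpha:
            ranks = sps.rankdata(flat)
            bounds = np.cumsum([0] + [len(g) for g in groups])
            mean_ranks = [
                ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))
            ]
            enriched = habitats[int(np.argmax(mean_ranks))]
        rows.append({"ko_id": ko, "H": float(h_stat), "p_value": float(p),
                     "enriched_habitat": enriched})
    return pd.DataFrame(rows).set_index("ko_id")


# ---------------------------------------------------------------------------
# Rank tests and helpers
# ---------------------------------------------------------------------------


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact for small tie-free samples."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Optional BH adjustment for the enrichment tables (raw p is the default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]
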