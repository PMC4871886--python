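"""OTU-table processing and community statistics, from definitions.

Covers the full profile workflow: lineage-based cleaning of
non-protist OTUs, multiple rarefaction to a common depth, the
shared-OTU (present in every replicate of every group) filter,
relative-abundance profiles with <1%→'Others' lumping, and the
resemblance statistics: Bray–Curtis similarity (% scale), group-average
(UPGMA) hierarchical clustering with Newick export, one-sided
permutation ANOSIM on dissimilarity ranks, and the exact Mann–Whitney
U test (full enumeration for small samples, tie-corrected normal
approximation otherwise).

The statistics are implemented directly from their definitions so that
every choice (average-rank ties, permutation p-value convention,
lexicographic tie-breaks in the clustering) is explicit and testable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import OtuTable, ValidationError, logger

RANK_NAMES = ["domain", "phylum", "class", "order", "family", "genus", "species"]


# ---------------------------------------------------------------------------
# OTU table processing
# ---------------------------------------------------------------------------

def parse_lineage(lineage: str) -> list[str]:
    return [p.strip() for p in str(lineage).split(";") if p.strip()]


def clean_protist_table(table: OtuTable,
                        excluded_lineages: list[str]) -> OtuTable:
    """Drop OTUs whose lineage contains any excluded rank label
    (case-insensitive whole-rank match, e.g. Metazoa, Fungi)."""
    excluded = {e.lower() for e in excluded_lineages}
    keep = []
    removed = []
    for otu in table.otu_ids:
        parts = {p.lower() for p in parse_lineage(table.lineages[otu])}
        (removed if parts & excluded else keep).append(otu)
    if removed:
        logger.info("clean_protist_table: removed %d OTUs (%s...)",
                    len(removed), removed[:5])
    if not keep:
        logger.warning("clean_protist_table: all OTUs excluded")
    return table.subset(keep)


def rarefy(table: OtuTable, depth: int, repeats: int = 100,
           seed: int = 0) -> OtuTable:
    """Multiple rarefaction: each sample subsampled without replacement to
    exactly ``depth`` reads, ``repeats`` times; output counts are the
    per-OTU means over repeats, rounded half-up to integers."""
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    if depth < 0:
        raise ValidationError("depth must be >= 0")
    totals = table.counts.sum(axis=0)
    low = totals[totals < depth]
    if not low.empty:
        raise ValidationError(
            f"rarefaction depth {depth} exceeds total reads of sample {low.index[0]!r} "
            f"({int(low.iloc[0])})")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(0, index=table.counts.index, columns=table.counts.columns,
                       dtype=float)
    for col in table.counts.columns:
        colors = table.counts[col].to_numpy()
        acc = np.zeros(len(colors), dtype=float)
        for _ in range(repeats):
            acc += rng.multivariate_hypergeometric(colors, depth)
        out[col] = acc / repeats
    rounded = np.floor(out + 0.5).astype(int)   # round half-up
    logger.info("rarefy: depth=%d repeats=%d", depth, repeats)
    return OtuTable(rounded, table.lineages.copy(), list(table.samples))


def shared_otu_filter(table: OtuTable,
                      groups: dict[str, list[str]]) -> OtuTable:
    """Keep OTUs with count > 0 in every sample of every group.

    ``groups`` maps group name → sample_ids; every sample of the table
    must belong to exactly one group, and no group may be empty.
    """
    assigned: list[str] = []
    for name, members in groups.items():
        if not members:
            raise ValidationError(f"empty group {name!r}")
        assigned.extend(members)
    ids = [s.sample_id for s in table.samples]
    if sorted(assigned) != sorted(ids):
        raise ValidationError("groups must partition the samples exactly")
    present = (table.counts > 0).all(axis=1)
    keep = list(table.counts.index[present])
    logger.info("shared_otu_filter: %d/%d OTUs kept", len(keep), len(table.otu_ids))
    return table.subset(keep)


def lineage_at_rank(lineage: str, level: int | str) -> str:
    """Rank label of a lineage at the given level (index or rank name);
    unresolvable lineages map to 'Unclassified'."""
    if isinstance(level, str):
        try:
            level = RANK_NAMES.index(level.lower())
        except ValueError:
            raise ValidationError(f"unknown rank name {level!r}") from None
    parts = parse_lineage(lineage)
    if level < len(parts) and parts[level].lower() not in {"", "unclassified"}:
        return parts[level]
    return "Unclassified"


@dataclass
class CommunityProfile:
    """Relative-abundance profile (%) per sample with 'Others' lumping."""

    ra: pd.DataFrame   # categories × samples, columns sum to 100
    lumped: list[str]  # categories folded into 'Others'


def relative_abundance_profile(table: OtuTable, level: int | str,
                               threshold: float = 1.0) -> CommunityProfile:
    """Aggregate counts to a taxonomic rank, convert to % of sample total,
    and fold categories below ``threshold`` % in *all* samples into
    'Others'."""
    labels = table.lineages.map(lambda s: lineage_at_rank(s, level))
    agg = table.counts.groupby(labels.values).sum()
    totals = agg.sum(axis=0)
    zero = totals[totals == 0]
    if not zero.empty:
        raise ValidationError(f"sample {zero.index[0]!r} has zero total reads")
    ra = 100.0 * agg / totals
    minor = ra.index[(ra < threshold).all(axis=1)]
    lumped = sorted(minor)
    if lumped:
        others = ra.loc[minor].sum(axis=0)
        ra = ra.drop(index=minor)
        ra.loc["Others"] = others
    ra = ra.sort_index()
    return CommunityProfile(ra, lumped)


# ---------------------------------------------------------------------------
# Resemblance statistics
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity (%) with 100 on the diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValidationError("similarity matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValidationError("similarity matrix must be symmetric")
        if (v < -1e-9).any() or (v > 100 + 1e-9).any():
            raise ValidationError("similarities must lie in [0, 100]")
        self.values = v

    def dissimilarity(self) -> np.ndarray:
        return 100.0 - self.values

    def condensed_dissimilarity(self) -> np.ndarray:
        n = len(self.sample_ids)
        return np.array([100.0 - self.values[i, j]
                         for i in range(n) for j in range(i + 1, n)])


def bray_curtis(profiles: pd.DataFrame) -> SimilarityMatrix:
    """Bray–Curtis similarity (%) between sample columns:
    100·(1 − Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ))."""
    if profiles.shape[1] < 2:
        raise ValidationError("bray_curtis needs >= 2 samples")
    x = profiles.to_numpy(dtype=float)
    n = x.shape[1]
    sim = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            denom = (x[:, i] + x[:, j]).sum()
            if denom == 0:
                raise ValidationError(
                    f"Bray–Curtis undefined: samples {profiles.columns[i]!r} and "
                    f"{profiles.columns[j]!r} are both all-zero")
            s = 100.0 * (1.0 - np.abs(x[:, i] - x[:, j]).sum() / denom)
            sim[i, j] = sim[j, i] = s
    return SimilarityMatrix(list(profiles.columns), sim)


@dataclass
class Dendrogram:
    """Group-average agglomeration history on the similarity (%) scale."""

    leaves: list[str]
    merges: list[tuple[frozenset, frozenset, float]]  # (left members, right members, similarity)
    newick: str


def upgma(sim: SimilarityMatrix) -> Dendrogram:
    """Group-average (UPGMA) clustering on dissimilarity = 100 − similarity.

    Ties are broken deterministically by the lexicographically smallest
    member label of the candidate pair.  The Newick tree is ultrametric
    with node heights at half the merge dissimilarity.
    """
    labels = sim.sample_ids
    n = len(labels)
    diss = sim.dissimilarity()
    # active clusters: key -> (sorted member labels, member indices, newick, height)
    clusters: dict[int, tuple[list[str], list[int], str, float]] = {
        i: ([labels[i]], [i], labels[i], 0.0) for i in range(n)
    }
    merges: list[tuple[frozenset, frozenset, float]] = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            la, ia, _, _ = clusters[a]
            lb, ib, _, _ = clusters[b]
            d = float(np.mean([diss[i, j] for i in ia for j in ib]))
            sort_key = (round(d, 12), min(la[0], lb[0]), max(la[0], lb[0]))
            if best is None or sort_key < best[0]:
                best = (sort_key, a, b, d)
        _, a, b, d = best
        la, ia, na, ha = clusters[a]
        lb, ib, nb, hb = clusters[b]
        if lb[0] < la[0]:   # deterministic child order
            (la, ia, na, ha), (lb, ib, nb, hb) = (lb, ib, nb, hb), (la, ia, na, ha)
        height = d / 2.0
        merges.append((frozenset(la), frozenset(lb), 100.0 - d))
        newick = (f"({na}:{height - ha:.6g},{nb}:{height - hb:.6g})")
        del clusters[a], clusters[b]
        clusters[next_id] = (sorted(la + lb), ia + ib, newick, height)
        next_id += 1
    (_, _, newick, _), = clusters.values()
    return Dendrogram(list(labels), merges, newick + ";")


def _multiset_arrangements(uniq: list, counts: list[int], n: int):
    """All distinct assignments of a label multiset to n positions."""
    out = np.empty(n, dtype=object)

    def rec(avail: tuple[int, ...], gi: int):
        if gi == len(uniq) - 1:
            for p in avail:
                out[p] = uniq[gi]
            yield out
            return
        for chosen in itertools.combinations(avail, counts[gi]):
            rest = tuple(p for p in avail if p not in chosen)
            for p in chosen:
                out[p] = uniq[gi]
            yield from rec(rest, gi + 1)

    yield from rec(tuple(range(n)), 0)


def _anosim_r(rank_matrix: np.ndarray, labels: np.ndarray) -> float:
    """ANOSIM R from a square matrix of dissimilarity ranks and labels."""
    n = len(labels)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    within = rank_matrix[iu][same[iu]]
    between = rank_matrix[iu][~same[iu]]
    return float((between.mean() - within.mean()) / (n * (n - 1) / 4.0))


@dataclass
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int
    group_labels: list[str]
    exhaustive: bool


def anosim(sim: SimilarityMatrix, labels: list[str],
           n_permutations: int = 999, seed: int = 0) -> AnosimResult:
    """One-sided (large R) permutation ANOSIM on dissimilarity ranks.

    R = (mean between-group rank − mean within-group rank)/(n(n−1)/4)
    with average-rank ties on the pairwise dissimilarities.  The null
    distribution enumerates all distinct label arrangements when their
    number does not exceed ``n_permutations`` (p = #{R_perm ≥ R_obs}/N,
    identity included); otherwise it samples with the given seed
    (p = (1 + #{R_perm ≥ R_obs})/(1 + n_permutations)).
    """
    labels_arr = np.asarray(labels)
    if len(labels_arr) != len(sim.sample_ids):
        raise ValidationError("one label per sample required")
    uniq, counts = np.unique(labels_arr, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs >= 2 groups")
    if counts.min() < 2:
        raise ValidationError("every ANOSIM group needs >= 2 samples")
    n = len(labels_arr)
    condensed = sim.condensed_dissimilarity()
    ranks = rankdata(condensed)  # average-rank ties
    rank_matrix = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    rank_matrix[iu] = ranks
    rank_matrix = rank_matrix + rank_matrix.T

    r_obs = _anosim_r(rank_matrix, labels_arr)
    n_distinct = math.factorial(n) // math.prod(math.factorial(c) for c in counts)
    eps = 1e-12
    if n_distinct <= n_permutations:
        count = total = 0
        for perm in _multiset_arrangements(list(uniq), list(counts), n):
            total += 1
            if _anosim_r(rank_matrix, perm) >= r_obs - eps:
                count += 1
        p = count / total
        return AnosimResult(r_obs, p, total, list(uniq), True)
    rng = np.random.default_rng(seed)
    count = 0
    perm = labels_arr.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if _anosim_r(rank_matrix, perm) >= r_obs - eps:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return AnosimResult(r_obs, p, n_permutations, list(uniq), False)


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x, from rank sums with average-rank ties."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney(x, y, exact_limit: int = 16) -> tuple[float, float]:
    """Mann–Whitney U and two-sided p.

    Exact p by full enumeration of all C(m+n, m) group assignments of
    the pooled values when m+n ≤ ``exact_limit`` (counting arrangements
    at least as extreme as |U − mn/2|); tie-corrected normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    m, n = len(x), len(y)
    u_obs = _u_statistic(x, y)
    mu = m * n / 2.0
    dev = abs(u_obs - mu)
    if m + n <= exact_limit:
        pooled = np.concatenate([x, y])
        idx = range(m + n)
        total = 0
        extreme = 0
        eps = 1e-9
        for comb in itertools.combinations(idx, m):
            mask = np.zeros(m + n, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev - eps:
                extreme += 1
        return u_obs, extreme / total
    # normal approximation with tie correction
    pooled = np.concatenate([x, y])
    nt = m + n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (nt * (nt - 1))
    sigma2 = m * n / 12.0 * (nt + 1 - tie_term)
    if sigma2 == 0:
        return u_obs, 1.0
    from scipy.stats import norm
    z = (dev - 0.5) / math.sqrt(sigma2)
    return u_obs, float(2 * norm.sf(max(z, 0.0)))
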