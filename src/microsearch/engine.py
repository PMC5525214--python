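"""Search orchestration, contextualization and significance.

Two analysis types are offered.  Type I is the accurate, phylogeny-aware
path: each query runs a GNAT (or AESA) range search under weighted
UniFrac, the recorded comparisons select a context set M' of database
samples, and a complete distance matrix over M' and the queries N is
assembled block-wise — M'xM' from the pre-computed database store, M'xN
from the recorded search evaluations, NxN by calling the sparse
EMD-UniFrac kernel per pair.  PCoA and UPGMA clustering contextualize
the queries, and each match carries an empirical p-value relating its
distance to all database pair distances.

Type II is the coarse path: Bray-Curtis (not a metric, hence no index)
against up to 1000 representative samples chosen as medoids of an
average-linkage clustering of the database, optionally restricted to an
ecosystem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.linalg

from microsearch.distances import bray_curtis, emd_unifrac_sparse
from microsearch.errors import EmptyContextError, MissingDistanceError
from microsearch.metric_index import (
    AesaIndex,
    GnatIndex,
    SearchRecord,
    aesa_range_search,
    build_aesa,
    build_gnat,
    gnat_range_search,
)
from microsearch.phylo import PhyloTree
from microsearch.profiles import (
    AbundanceProfile,
    DistanceStore,
    SampleDatabase,
    TaxonomyTable,
    phyla_key,
    to_relative,
)

__all__ = [
    "DEFAULT_RADIUS",
    "DEFAULT_TOP_K",
    "DEFAULT_BINS",
    "DEFAULT_MAX_REPRESENTATIVES",
    "MAX_QUERIES_GNAT",
    "MAX_QUERIES_AESA",
    "SUPPORTED_RADII",
    "PvalueTable",
    "Match",
    "Ranking",
    "ContextSet",
    "AnalysisResult",
    "select_context",
    "assemble_matrix",
    "pcoa",
    "hierarchical_cluster",
    "build_pvalue_table",
    "empirical_pvalue",
    "select_representatives",
    "run_type1",
    "run_type2",
    "composition_comparison",
    "phyla_index_fn_table",
    "false_negative_percentage",
]

# defaults exposed by the web tool this engine mirrors
DEFAULT_RADIUS = 0.3
SUPPORTED_RADII = (0.1, 0.2, 0.3, 0.4)
DEFAULT_TOP_K = 20
DEFAULT_BINS = 10_000
DEFAULT_MAX_REPRESENTATIVES = 1000
MAX_QUERIES_GNAT = 10
MAX_QUERIES_AESA = 100

COMPARISON_RANKS = ("phylum", "class", "order", "family", "genus")


# ---------------------------------------------------------------------------
# context selection and matrix assembly


def select_context(records: list[SearchRecord], k: int = DEFAULT_TOP_K) -> list[str]:
    """Database samples forming the contextualization set M'.

    Only samples compared to *every* query qualify (the complete matrix
    needs all M'xN cells); of those, a sample is retained iff it ranks
    within the ``k`` smallest recorded distances of at least one query,
    ranking restricted to the qualifying intersection.
    """
    if not records:
        raise ValueError("select_context needs at least one search record")
    common = set(records[0].evaluated)
    for rec in records[1:]:
        common &= set(rec.evaluated)
    if not common:
        raise EmptyContextError(
            "no database sample was evaluated against every query"
        )
    keep: set[str] = set()
    for rec in records:
        ranked = sorted(common, key=lambda s: (rec.evaluated[s], s))
        keep.update(ranked[:k])
    return sorted(keep)


def assemble_matrix(
    context_ids: list[str],
    queries: list[AbundanceProfile],
    precalc: DistanceStore,
    records: list[SearchRecord],
    pairwise_user,
) -> pd.DataFrame:
    """Complete symmetric distance matrix over M' ∪ N, block-wise.

    M'xM' cells come from the pre-computed store, M'xN from the recorded
    search evaluations, NxN from direct metric calls.
    """
    rec_by_query = {r.query_id: r for r in records}
    qids = [q.sample_id for q in queries]
    ids = list(context_ids) + qids
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(context_ids):
        for b in context_ids[i + 1:]:
            if (a, b) not in precalc:
                raise MissingDistanceError(
                    f"pre-computed store lacks pair ({a}, {b})"
                )
            mat.loc[a, b] = mat.loc[b, a] = precalc.get(a, b)
    for q in queries:
        rec = rec_by_query.get(q.sample_id)
        for a in context_ids:
            if rec is None or a not in rec.evaluated:
                raise MissingDistanceError(
                    f"search record lacks pair ({a}, {q.sample_id})"
                )
            mat.loc[a, q.sample_id] = mat.loc[q.sample_id, a] = rec.evaluated[a]
    for i, qa in enumerate(queries):
        for qb in queries[i + 1:]:
            d = float(pairwise_user(qa, qb))
            mat.loc[qa.sample_id, qb.sample_id] = d
            mat.loc[qb.sample_id, qa.sample_id] = d
    return mat


# ---------------------------------------------------------------------------
# contextualization


def pcoa(matrix: pd.DataFrame, dims: int | None = None):
    """Classical scaling (principal coordinates analysis).

    Double-centers ``-D**2 / 2`` and eigendecomposes; axes with negative
    eigenvalues (non-Euclidean residue) are dropped with a warning.

    Returns
    -------
    coordinates : pd.DataFrame  (samples x retained axes, eigenvalue order)
    eigenvalues : np.ndarray
    """
    D = np.asarray(matrix, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("pcoa needs a square symmetric matrix")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = scipy.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    neg = eigvals < -1e-9 * max(1.0, abs(eigvals[0]) if n else 1.0)
    if neg.any():
        warnings.warn(
            f"dropping {int(neg.sum())} negative eigenvalue(s): matrix is "
            "not fully Euclidean-embeddable",
            UserWarning,
            stacklevel=2,
        )
    keep = eigvals > 1e-12 * max(1.0, abs(eigvals[0]) if n else 1.0)
    eigvals = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(eigvals)
    if dims is not None:
        coords = coords[:, :dims]
        eigvals = eigvals[:dims]
    index = matrix.index if isinstance(matrix, pd.DataFrame) else range(n)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=index, columns=cols), eigvals


def hierarchical_cluster(matrix: pd.DataFrame, linkage: str = "average") -> str:
    """UPGMA dendrogram over a distance matrix, as newick with heights.

    Branch lengths place each merge at half its linkage distance (the
    classical ultrametric convention), so two samples at distance d
    merge at height d/2.
    """
    if linkage != "average":
        raise ValueError("only average linkage (UPGMA) is supported")
    ids = list(matrix.index)
    D = np.asarray(matrix, dtype=float)
    if len(ids) == 1:
        return f"{ids[0]}:0;"
    iu = np.triu_indices(len(ids), k=1)
    Z = sch.average(D[iu])
    root = sch.to_tree(Z)

    def fmt(node) -> tuple[str, float]:
        if node.is_leaf():
            return ids[node.id], 0.0
        left, lh = fmt(node.left)
        right, rh = fmt(node.right)
        h = node.dist / 2.0
        return f"({left}:{h - lh:.10g},{right}:{h - rh:.10g})", h

    body, _ = fmt(root)
    return body + ";"


# ---------------------------------------------------------------------------
# empirical p-values


@dataclass
class PvalueTable:
    """Binned cumulative counts of all database pair distances.

    ``cumulative[i]`` counts pairs with distance strictly below
    ``bin_edges[i]``; p-values are the cumulative count at the lower
    edge of the bin containing the observed distance, a conservative
    (never anti-conservative) estimate accurate to one bin width.
    """

    bin_edges: np.ndarray
    cumulative: np.ndarray
    total_pairs: int


def build_pvalue_table(
    all_pair_distances: np.ndarray, bins: int = DEFAULT_BINS
) -> PvalueTable:
    d = np.asarray(all_pair_distances, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("no pair distances supplied")
    if (d < 0).any():
        raise ValueError("negative distances supplied")
    top = float(d.max())
    if top <= 0:
        top = 1.0  # degenerate all-identical database; any scale works
    # last edge strictly above the maximum so the final cumulative count
    # covers every pair (distances are counted strictly below each edge)
    top = float(np.nextafter(top, np.inf))
    edges = np.linspace(0.0, top, bins + 1)
    d_sorted = np.sort(d)
    cumulative = np.searchsorted(d_sorted, edges, side="left").astype(np.int64)
    return PvalueTable(edges, cumulative, int(d.size))


def empirical_pvalue(table: PvalueTable, d: float) -> float:
    """Fraction of database pairs closer than ``d`` (empirical p-value)."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    idx = int(np.searchsorted(table.bin_edges, d, side="right")) - 1
    idx = min(max(idx, 0), len(table.bin_edges) - 1)
    return float(table.cumulative[idx]) / table.total_pairs


# ---------------------------------------------------------------------------
# representatives (coarse search)


def select_representatives(
    db: SampleDatabase,
    ecosystem_filter: str = "All",
    max_n: int = DEFAULT_MAX_REPRESENTATIVES,
    seed: int = 0,
) -> list[str]:
    """Representative samples for the coarse search.

    The pool is the set of cluster medoids obtained by cutting an
    average-linkage clustering of the pre-computed distance matrix into
    ``max_n`` clusters, after restricting to the ecosystem filter
    ("All" keeps everything).  A pool that still exceeds ``max_n`` is
    down-sampled uniformly with the given seed.
    """
    if db.precalc is None:
        raise MissingDistanceError(
            "representative selection needs the pre-computed distance store"
        )
    if ecosystem_filter == "All":
        ids = sorted(db.sample_ids)
    else:
        ids = sorted(
            s for s in db.sample_ids if db.ecosystem(s) == ecosystem_filter
        )
    if len(ids) <= max_n:
        return ids
    pos = [db.precalc.ids.index(s) for s in ids]
    sub = db.precalc.matrix[np.ix_(pos, pos)]
    iu = np.triu_indices(len(ids), k=1)
    Z = sch.average(sub[iu])
    labels = sch.fcluster(Z, t=max_n, criterion="maxclust")
    pool: list[str] = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        # medoid: minimal summed distance to the rest of the cluster
        sums = sub[np.ix_(members, members)].sum(axis=1)
        best = members[int(np.argmin(sums))]  # argmin ties: lowest index/id
        pool.append(ids[best])
    pool.sort()
    if len(pool) <= max_n:
        return pool
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(pool, size=max_n, replace=False).tolist())


# ---------------------------------------------------------------------------
# rankings and analysis runs


@dataclass
class Match:
    sample_id: str
    distance: float
    p_value: float | None
    ecosystem: str
    annotations: list[str] = field(default_factory=list)
    composition: dict | None = None


@dataclass
class Ranking:
    """Per-query ordered matches (ascending distance, at most k)."""

    per_query: dict[str, list[Match]]


@dataclass
class ContextSet:
    context_ids: list[str]
    query_ids: list[str]
    full_matrix: pd.DataFrame


@dataclass
class AnalysisResult:
    ranking: Ranking
    context: ContextSet
    pcoa_coordinates: pd.DataFrame
    pcoa_eigenvalues: np.ndarray
    dendrogram: str
    records: list[SearchRecord]


def _rank(
    db: SampleDatabase,
    rec: SearchRecord,
    k: int,
    pvalues: PvalueTable | None,
    tax: TaxonomyTable | None,
    query: AbundanceProfile | None,
    candidates: set[str] | None = None,
) -> list[Match]:
    pool = rec.hits if candidates is None else [
        s for s in rec.hits if s in candidates
    ]
    ordered = sorted(pool, key=lambda s: (rec.evaluated[s], s))[:k]
    out = []
    for s in ordered:
        eco, notes = db.metadata.get(s, ("unknown", []))
        comp = None
        if tax is not None and query is not None:
            comp = composition_comparison(query, db[s], tax, ("phylum",))
        out.append(
            Match(
                s,
                rec.evaluated[s],
                empirical_pvalue(pvalues, rec.evaluated[s]) if pvalues else None,
                eco,
                list(notes),
                comp,
            )
        )
    return out


def run_type1(
    db: SampleDatabase,
    queries: list[AbundanceProfile],
    tree: PhyloTree,
    method: str = "gnat",
    radius: float = DEFAULT_RADIUS,
    k: int = DEFAULT_TOP_K,
    tax: TaxonomyTable | None = None,
    pvalues: PvalueTable | None = None,
    index: GnatIndex | AesaIndex | None = None,
    seed: int = 0,
    max_queries: int | None = None,
) -> AnalysisResult:
    """Analysis Type I: phylogeny-aware range search + contextualization.

    Queries must be relative-abundance profiles over the tree's leaves
    (apply copy-number correction / rarefaction upstream).  Query-count
    limits default to 10 for GNAT and 100 for AESA; pass ``max_queries``
    to override programmatically.
    """
    if method not in ("gnat", "aesa"):
        raise ValueError("method must be 'gnat' or 'aesa'")
    limit = max_queries if max_queries is not None else (
        MAX_QUERIES_GNAT if method == "gnat" else MAX_QUERIES_AESA
    )
    if not 1 <= len(queries) <= limit:
        raise ValueError(
            f"{method} accepts between 1 and {limit} query samples, "
            f"got {len(queries)}"
        )
    queries = [to_relative(q) for q in queries]

    # database profiles are stored as counts; the kernel wants relative
    # abundances, so normalize lazily and cache per sample id
    rel_cache: dict[str, AbundanceProfile] = {q.sample_id: q for q in queries}

    def _rel(p: AbundanceProfile) -> AbundanceProfile:
        cached = rel_cache.get(p.sample_id)
        if cached is None:
            cached = rel_cache[p.sample_id] = to_relative(p)
        return cached

    def metric(a: AbundanceProfile, b: AbundanceProfile) -> float:
        return emd_unifrac_sparse(tree, _rel(a), _rel(b)).value

    if index is None:
        if method == "gnat":
            index = build_gnat(db, metric, seed=seed)
        else:
            index = build_aesa(db, metric)
    records = []
    for q in queries:
        if method == "gnat":
            records.append(gnat_range_search(index, q, radius))
        else:
            records.append(aesa_range_search(index, q, radius, metric))

    context_ids = select_context(records, k)
    precalc = db.precalc if db.precalc is not None else (
        index.store if isinstance(index, AesaIndex) else None
    )
    if precalc is None:
        raise MissingDistanceError(
            "Type I contextualization needs a pre-computed database matrix "
            "(db.precalc) or an AESA index"
        )
    full = assemble_matrix(
        context_ids, queries, precalc, records,
        lambda a, b: emd_unifrac_sparse(tree, _rel(a), _rel(b)).value,
    )
    coords, eigvals = pcoa(full)
    dendro = hierarchical_cluster(full)
    ranking = Ranking(
        {
            q.sample_id: _rank(db, rec, k, pvalues, tax, q)
            for q, rec in zip(queries, records)
        }
    )
    context = ContextSet(context_ids, [q.sample_id for q in queries], full)
    return AnalysisResult(ranking, context, coords, eigvals, dendro, records)


def run_type2(
    db: SampleDatabase,
    queries: list[AbundanceProfile],
    ecosystem_filter: str = "All",
    k: int = DEFAULT_TOP_K,
    max_representatives: int = DEFAULT_MAX_REPRESENTATIVES,
    tax: TaxonomyTable | None = None,
    seed: int = 0,
) -> AnalysisResult:
    """Analysis Type II: coarse Bray-Curtis search against representatives.

    Bray-Curtis is not a metric (no triangle inequality), so no index is
    used; instead each query is compared to at most
    ``max_representatives`` representative samples and contextualized
    against all of them.
    """
    if not queries:
        raise ValueError("no query samples supplied")
    reps = select_representatives(db, ecosystem_filter, max_representatives, seed)
    if not reps:
        raise EmptyContextError(
            f"no database samples match ecosystem {ecosystem_filter!r}"
        )
    records = []
    for q in queries:
        rec = SearchRecord(q.sample_id, radius=1.0)
        for s in reps:
            rec.record(s, bray_curtis(q, db[s]))
        records.append(rec.finalize())

    qids = [q.sample_id for q in queries]
    ids = reps + qids
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(reps):
        for b in reps[i + 1:]:
            d = bray_curtis(db[a], db[b])
            mat.loc[a, b] = mat.loc[b, a] = d
    for q, rec in zip(queries, records):
        for s in reps:
            mat.loc[s, q.sample_id] = mat.loc[q.sample_id, s] = rec.evaluated[s]
    for i, qa in enumerate(queries):
        for qb in queries[i + 1:]:
            d = bray_curtis(qa, qb)
            mat.loc[qa.sample_id, qb.sample_id] = d
            mat.loc[qb.sample_id, qa.sample_id] = d

    coords, eigvals = pcoa(mat)
    dendro = hierarchical_cluster(mat)
    ranking = Ranking(
        {
            q.sample_id: _rank(db, rec, k, None, tax, q)
            for q, rec in zip(queries, records)
        }
    )
    context = ContextSet(reps, qids, mat)
    return AnalysisResult(ranking, context, coords, eigvals, dendro, records)


# ---------------------------------------------------------------------------
# composition comparison and key-index evaluation


def composition_comparison(
    query: AbundanceProfile,
    match: AbundanceProfile,
    tax: TaxonomyTable,
    ranks: tuple[str, ...] = ("phylum", "class", "order"),
) -> dict[str, list[tuple[str, float, float]]]:
    """Side-by-side taxonomic composition of a query and a match.

    For each requested rank (up to three of phylum..genus), taxa are
    ordered by descending fraction *in the query* (ties, and taxa absent
    from the query, lexicographically); the match's fractions are listed
    in that same order, 0.0 where the taxon is absent.  Fractions sum to
    1 per sample per rank.
    """
    if not 1 <= len(ranks) <= 3:
        raise ValueError("choose between one and three ranks")
    bad = [r for r in ranks if r not in COMPARISON_RANKS]
    if bad:
        raise ValueError(f"unsupported ranks {bad}; choose from {COMPARISON_RANKS}")
    q_rel = to_relative(query)
    m_rel = to_relative(match)
    out: dict[str, list[tuple[str, float, float]]] = {}
    for rank in ranks:
        q_tot: dict[str, float] = {}
        m_tot: dict[str, float] = {}
        for otu, v in q_rel.counts.items():
            name = tax.rank_of(otu, rank)
            q_tot[name] = q_tot.get(name, 0.0) + v
        for otu, v in m_rel.counts.items():
            name = tax.rank_of(otu, rank)
            m_tot[name] = m_tot.get(name, 0.0) + v
        names = sorted(
            set(q_tot) | set(m_tot),
            key=lambda t: (-q_tot.get(t, 0.0), t),
        )
        out[rank] = [
            (t, q_tot.get(t, 0.0), m_tot.get(t, 0.0)) for t in names
        ]
    return out


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def false_negative_percentage(total: int, differing: int) -> float | None:
    """Share of close pairs whose top-5-phyla keys differ, in percent.

    ``100 * differing / total`` rounded half-up to two decimals; None
    (undefined) when no pair falls below the threshold.
    """
    if total == 0:
        return None
    return _round2(100.0 * differing / total)


def phyla_index_fn_table(
    precalc: DistanceStore,
    keys: dict[str, tuple[str, ...]],
    thresholds: list[float],
) -> list[tuple[float, int, int, float | None]]:
    """False negatives of top-5-phyla key indexing, per distance threshold.

    A pair of samples closer than the threshold but carrying different
    ordered top-5-phyla keys would be missed by a key-based index; each
    row reports (threshold, pairs below threshold, pairs with differing
    keys, percentage).
    """
    ids = precalc.ids
    rows = []
    for t in thresholds:
        total = 0
        diff = 0
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if precalc.matrix[i, j] < t:
                    total += 1
                    if keys[ids[i]] != keys[ids[j]]:
                        diff += 1
        rows.append((t, total, diff, false_negative_percentage(total, diff)))
    return rows
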