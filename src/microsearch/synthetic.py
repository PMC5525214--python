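"""Self-contained synthetic fixtures for the search pipeline.

Real deployments run against a large curated database of 16S profiles
keyed to a reference phylogeny; this module generates statistically
analogous stand-ins so the whole pipeline is exercisable offline:
random coalescent-style phylogenies, ecosystem-structured sparse
abundance profiles, clade-derived taxonomies, per-OTU 16S copy numbers
and pre-computed all-vs-all distance stores.  Everything is a pure
function of its seed.

The generative model for profiles: each ecosystem owns a random leaf
subset of expected size sparsity * n_leaves with a Dirichlet center
over it; a sample draws a Dirichlet perturbation of its ecosystem's
center (concentration = ``separation``; larger means tighter, easier
ecosystems) and then multinomial counts at a Poisson-distributed
sequencing depth.  Samples from the same ecosystem therefore share
support and are closer in weighted UniFrac than samples from different
ecosystems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from microsearch.metric_index import save_aesa_matrix
from microsearch.phylo import PhyloTree, parse_newick
from microsearch.profiles import (
    RANKS,
    AbundanceProfile,
    CopyNumberTable,
    DistanceStore,
    SampleDatabase,
    TaxonomyTable,
)

__all__ = [
    "FixtureSpec",
    "random_tree",
    "random_profiles",
    "build_precalc",
    "random_taxonomy",
    "random_copy_numbers",
    "write_fixture",
]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic database."""

    n_leaves: int = 200
    n_samples: int = 60
    n_ecosystems: int = 3
    mean_depth: int = 500
    sparsity: float = 0.05  # expected fraction of leaves per sample
    separation: float = 50.0  # Dirichlet concentration around centers
    seed: int = 0

    def __post_init__(self):
        if min(self.n_leaves, self.n_samples, self.n_ecosystems, self.mean_depth) <= 0:
            raise ValueError("all fixture sizes must be positive")
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must be in (0, 1]")


def random_tree(n_leaves: int, seed: int = 0, mean_branch: float = 0.1) -> PhyloTree:
    """Random binary tree by coalescent-style pairwise merging.

    Branch lengths are exponential with the given mean, then rescaled so
    the mean root-to-leaf depth is 0.5 — weighted UniFrac distances
    between relative-abundance profiles then land in the unit band the
    configured search radii assume.  Leaves are labelled ``otu0001``...
    """
    if n_leaves < 1:
        raise ValueError("need at least one leaf")
    rng = np.random.default_rng(seed)
    labels = [f"otu{i + 1:04d}" for i in range(n_leaves)]
    if n_leaves == 1:
        return parse_newick(f"({labels[0]}:{0.5});")
    subtrees = {lab: f"{lab}:{rng.exponential(mean_branch):.12g}" for lab in labels}
    keys = list(subtrees)
    while len(keys) > 1:
        i, j = sorted(rng.choice(len(keys), size=2, replace=False))
        a, b = keys[i], keys[j]
        blen = rng.exponential(mean_branch)
        merged = f"({subtrees[a]},{subtrees[b]}):{blen:.12g}"
        subtrees[a] = merged
        del subtrees[b]
        keys = list(subtrees)
    body = next(iter(subtrees.values()))
    # strip the root's pendant length: the root has no parent branch
    tree = parse_newick(body[: body.rfind(":")] + ";")
    depths = []
    for leaf in tree.leaf_index.values():
        d, nid = 0.0, leaf
        while tree.nodes[nid].parent is not None:
            d += tree.nodes[nid].length
            nid = tree.nodes[nid].parent
        depths.append(d)
    scale = 0.5 / float(np.mean(depths))
    for node in tree.nodes:
        node.length *= scale
    return tree


def random_profiles(tree: PhyloTree, spec: FixtureSpec) -> SampleDatabase:
    """Ecosystem-structured sparse profiles over the tree's leaves."""
    rng = np.random.default_rng(spec.seed)
    leaves = tree.leaf_labels()
    support = max(2, round(spec.sparsity * len(leaves)))
    support = min(support, len(leaves))
    centers = []
    for _ in range(spec.n_ecosystems):
        subset = sorted(rng.choice(leaves, size=support, replace=False).tolist())
        weights = rng.dirichlet(np.ones(support))
        centers.append((subset, weights))
    profiles, metadata = [], {}
    for i in range(spec.n_samples):
        eco = i % spec.n_ecosystems
        subset, center = centers[eco]
        theta = rng.dirichlet(center * spec.separation + 1e-9)
        depth = max(1, int(rng.poisson(spec.mean_depth)))
        counts = rng.multinomial(depth, theta)
        sid = f"s{i + 1:04d}"
        profiles.append(
            AbundanceProfile(sid, {o: int(c) for o, c in zip(subset, counts) if c})
        )
        metadata[sid] = (f"eco{eco + 1}", [f"synthetic ecosystem {eco + 1}"])
    return SampleDatabase(profiles, metadata)


def random_taxonomy(tree: PhyloTree) -> TaxonomyTable:
    """Clade-cut taxonomy: rank r of a leaf is its ancestor at a depth
    proportional to r along its root-to-leaf path (species = the leaf)."""
    table = {}
    n_mid = len(RANKS) - 2  # ranks between kingdom and species
    for label in tree.leaf_labels():
        path = tree.ancestor_path(label)[::-1]  # root .. leaf
        lineage = ["k__root"]
        for r in range(1, n_mid + 1):
            pos = max(1, min(len(path) - 1, round(r * (len(path) - 1) / (n_mid + 1))))
            node = tree.nodes[path[pos]]
            lineage.append(f"{RANKS[r][0]}__n{path[pos]}")
        lineage.append(f"s__{label}")
        table[label] = tuple(lineage)
    return TaxonomyTable(table)


def random_copy_numbers(tree: PhyloTree, seed: int = 0) -> CopyNumberTable:
    """Per-OTU 16S operon copy numbers, uniform integers in 1..10."""
    rng = np.random.default_rng(seed)
    return CopyNumberTable(
        {lab: int(rng.integers(1, 11)) for lab in tree.leaf_labels()}
    )


def build_precalc(db: SampleDatabase, metric, path=None) -> DistanceStore:
    """All-vs-all distance store: C(|M|, 2) metric evaluations.

    When ``path`` is given the store is also written to disk (HDF5
    layout: dense float64 matrix + id vector) and round-trips
    bit-exactly.
    """
    ids = sorted(db.sample_ids)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = float(metric(db[ids[i]], db[ids[j]]))
    store = DistanceStore(ids, mat)
    if path is not None:
        save_aesa_matrix(store, path)
    return store


def write_fixture(out_dir, spec: FixtureSpec, tree: PhyloTree,
                  db: SampleDatabase, tax: TaxonomyTable,
                  copy_numbers: CopyNumberTable,
                  precalc: DistanceStore | None = None) -> dict:
    """Write a fixture in the formats the readers consume.

    newick tree, classic TSV OTU table, taxonomy TSV, copy-number TSV,
    metadata TSV and (optionally) the HDF5-layout distance matrix.
    Returns the path map.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": out / "tree.nwk",
        "otu_table": out / "otu_table.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "copy_numbers": out / "copy_numbers.tsv",
        "metadata": out / "metadata.tsv",
    }
    paths["tree"].write_text(tree.to_newick() + "\n")
    sample_ids = db.sample_ids
    otus = sorted({o for p in db.profiles for o in p.counts})
    with open(paths["otu_table"], "w") as fh:
        fh.write("#OTU ID\t" + "\t".join(sample_ids) + "\n")
        for o in otus:
            row = "\t".join(str(db[s].counts.get(o, 0)) for s in sample_ids)
            fh.write(f"{o}\t{row}\n")
    with open(paths["taxonomy"], "w") as fh:
        for o, lineage in sorted(tax.items()):
            fh.write(o + "\t" + "\t".join(lineage) + "\n")
    with open(paths["copy_numbers"], "w") as fh:
        for o, v in sorted(copy_numbers.items()):
            fh.write(f"{o}\t{v}\n")
    with open(paths["metadata"], "w") as fh:
        for s in sample_ids:
            eco, notes = db.metadata[s]
            fh.write("\t".join([s, eco, *notes]) + "\n")
    if precalc is not None:
        paths["precalc"] = out / "precalc.h5"
        save_aesa_matrix(precalc, paths["precalc"])
    return paths
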