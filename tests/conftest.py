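"""Shared fixtures: a tiny hand-traceable tree and a synthetic database."""

import numpy as np
import pytest

from microsearch import synthetic as syn
from microsearch.distances import emd_unifrac_sparse
from microsearch.phylo import parse_newick
from microsearch.profiles import AbundanceProfile, SampleDatabase, to_relative

TREE_A = "((A:1,B:1):1,(C:1,D:1):1):0;"


@pytest.fixture(scope="session")
def tree_a():
    return parse_newick(TREE_A)


def unifrac_metric(tree):
    """Metric over count profiles: normalize (cached) then EMD-UniFrac."""
    cache = {}  # id(profile) -> (profile, relative form); keyed by identity

    def rel(p):
        entry = cache.get(id(p))
        if entry is None or entry[0] is not p:
            entry = (p, p if abs(p.depth - 1) <= 1e-9 else to_relative(p))
            cache[id(p)] = entry
        return entry[1]

    def metric(a, b):
        return emd_unifrac_sparse(tree, rel(a), rel(b)).value

    return metric


@pytest.fixture(scope="session")
def small_world():
    """64-leaf tree, 45-sample / 3-ecosystem database with precalc."""
    spec = syn.FixtureSpec(
        n_leaves=64, n_samples=45, n_ecosystems=3, mean_depth=400,
        sparsity=0.15, separation=50.0, seed=11,
    )
    tree = syn.random_tree(spec.n_leaves, spec.seed)
    db = syn.random_profiles(tree, spec)
    metric = unifrac_metric(tree)
    store = syn.build_precalc(db, metric)
    db = SampleDatabase(db.profiles, db.metadata, store)
    tax = syn.random_taxonomy(tree)
    cn = syn.random_copy_numbers(tree, spec.seed)
    return {
        "spec": spec, "tree": tree, "db": db, "metric": metric,
        "tax": tax, "copy_numbers": cn,
    }


def random_profile_pair(tree, rng, max_support=None):
    """Two random relative-abundance profiles over a tree's leaves."""
    leaves = tree.leaf_labels()
    cap = max_support or len(leaves)
    out = []
    for name in ("p", "q"):
        k = int(rng.integers(1, min(cap, len(leaves)) + 1))
        chosen = rng.choice(leaves, size=k, replace=False)
        w = rng.dirichlet(np.ones(k))
        out.append(AbundanceProfile(name, dict(zip(chosen.tolist(), w))))
    return out
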