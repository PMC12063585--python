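"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd
import pytest

from cagesym.containers import lineages_per_bug_sampler

#: per-bug lineage-count distribution used across the community simulations
KDIST = {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.10, 5: 0.05}

POOL14 = [f"L{i:02d}" for i in range(1, 15)]
POOL3 = POOL14[:3]


def random_tree(n_tips: int, rng: np.random.Generator) -> dendropy.Tree:
    """A random rooted binary tree with uniform branch lengths, for oracles."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    if n_tips == 1:
        leaf = tree.seed_node.new_child(edge_length=float(rng.uniform(0.1, 1.0)))
        leaves = [leaf]
    else:
        a = tree.seed_node.new_child(edge_length=float(rng.uniform(0.1, 1.0)))
        b = tree.seed_node.new_child(edge_length=float(rng.uniform(0.1, 1.0)))
        leaves = [a, b]
        for _ in range(n_tips - 2):
            pick = leaves.pop(int(rng.integers(len(leaves))))
            c = pick.new_child(edge_length=float(rng.uniform(0.1, 1.0)))
            d = pick.new_child(edge_length=float(rng.uniform(0.1, 1.0)))
            leaves.extend([c, d])
    for i, leaf in enumerate(leaves):
        leaf.taxon = taxa.new_taxon(f"T{i:03d}")
    return tree


def brute_force_cophenetic(tree: dendropy.Tree) -> pd.DataFrame:
    """Tip-to-tip path sums computed by explicit root-path arithmetic."""
    def path_to_root(node):
        out = []
        while node.parent_node is not None:
            out.append(node)
            node = node.parent_node
        return out

    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = path_to_root(leaves[i])
            pj = path_to_root(leaves[j])
            shared = {id(x) for x in pi} & {id(x) for x in pj}
            dist = sum(e.edge.length for e in pi if id(e) not in shared)
            dist += sum(e.edge.length for e in pj if id(e) not in shared)
            d[i, j] = d[j, i] = dist
    return pd.DataFrame(d, index=labels, columns=labels)


def draw_presence_dataset(
    caged_pool: list[str],
    wild_pool: list[str],
    n_cages: int,
    cage_size: int,
    n_wild: int,
    rng: np.random.Generator,
    kdist: dict | None = None,
):
    """Binary per-bug lineage presence for a caged-vs-wild comparison.

    Every bug hosts k ~ kdist lineages drawn uniformly without replacement
    from its origin's pool.  Returns (presence matrix, cage->bug ids, wild ids).
    """
    ks, kp = lineages_per_bug_sampler(kdist or KDIST)
    labels = sorted(set(caged_pool) | set(wild_pool))
    rows, ids, cages = [], [], {}
    for c in range(n_cages):
        cage = f"c{c:02d}"
        cages[cage] = []
        for b in range(cage_size):
            bid = f"{cage}_b{b}"
            cages[cage].append(bid)
            k = min(int(rng.choice(ks, p=kp)), len(caged_pool))
            hosted = {caged_pool[i] for i in rng.choice(len(caged_pool), size=k, replace=False)}
            rows.append([int(lab in hosted) for lab in labels])
            ids.append(bid)
    wild_ids = []
    for w in range(n_wild):
        bid = f"w{w:02d}"
        wild_ids.append(bid)
        k = min(int(rng.choice(ks, p=kp)), len(wild_pool))
        hosted = {wild_pool[i] for i in rng.choice(len(wild_pool), size=k, replace=False)}
        rows.append([int(lab in hosted) for lab in labels])
        ids.append(bid)
    return pd.DataFrame(rows, index=ids, columns=labels), cages, wild_ids


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_tip_tree():
    return dendropy.Tree.get(data="(A:0.3,B:0.4);", schema="newick")
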