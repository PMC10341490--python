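import numpy as np
import pytest

import vhhscreen as v


@pytest.fixture(scope="session")
def small_cfg():
    """Error-free two-arm experiment, small enough for exact bookkeeping."""
    return v.PanningConfig(
        seed=11,
        n_clones=80,
        reads_per_round=4000,
        per_base_error_rate=0.0,
        cell_lines=("S1T", "HepG2"),
    )


@pytest.fixture(scope="session")
def small_repertoire(small_cfg):
    return v.generate_repertoire(small_cfg)


@pytest.fixture(scope="session")
def errorfree_fixtures(small_cfg, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim_errorfree")
    return v.make_fixtures(small_cfg, str(out), top_k=15)


@pytest.fixture(scope="session")
def noisy_cfg():
    """Small experiment with realistic sequencing error."""
    return v.PanningConfig(
        seed=19,
        n_clones=150,
        reads_per_round=15_000,
        per_base_error_rate=0.005,
        cell_lines=("S1T", "HepG2"),
        binder_fraction=0.04,
        cross_reactive_fraction=0.02,
    )


@pytest.fixture(scope="session")
def noisy_run(noisy_cfg, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim_noisy")
    fx = v.make_fixtures(noisy_cfg, str(out), top_k=30)
    result = v.run_pipeline(fx.run_config)
    return fx, result


def truth_aa_counts(repertoire, counts_by_clone):
    """Aggregate a per-clone count column into ground-truth aa_seq counts."""
    by_id = {c.clone_id: c.aa_seq for c in repertoire}
    out: dict[str, int] = {}
    for cid, n in counts_by_clone.items():
        n = int(n)
        if n:
            aa = by_id[cid]
            out[aa] = out.get(aa, 0) + n
    return out


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson-Foulds distance via dendropy (independent oracle)."""
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns,
                           rooting="force-unrooted")
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns,
                           rooting="force-unrooted")
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(treecompare.symmetric_difference(t1, t2))


def random_additive_tree(rng: np.random.Generator, n: int):
    """Random binary tree with positive branch lengths.

    Returns (newick, labels, distance matrix) where the matrix holds the
    exact leaf-to-leaf path lengths computed by brute-force accumulation,
    independently of any tree-building code.
    """
    labels = [f"T{i}" for i in range(n)]
    items = [(lbl, {lbl: 0.0}) for lbl in labels]
    dist: dict[tuple[str, str], float] = {}

    def join(i, j):
        (nwk_i, di) = items[i]
        (nwk_j, dj) = items[j]
        x, y = rng.uniform(0.1, 1.0, 2)
        for u, du in di.items():
            for w, dw in dj.items():
                dist[(u, w)] = dist[(w, u)] = du + x + dw + y
        merged_map = {u: du + x for u, du in di.items()}
        merged_map.update({w: dw + y for w, dw in dj.items()})
        return f"({nwk_i}:{x:.10f},{nwk_j}:{y:.10f})", merged_map

    while len(items) > 2:
        i, j = sorted(rng.choice(len(items), 2, replace=False))
        merged = join(i, j)
        del items[j], items[i]
        items.append(merged)
    nwk, _ = join(0, 1)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a != b:
                D[a, b] = dist[(labels[a], labels[b])]
    return nwk + ";", labels, D
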