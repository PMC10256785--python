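"""Native NJ, Fitch parsimony, GTR likelihood, and bootstrap."""

import itertools

import dendropy
import numpy as np
import pytest

import mitophylo as mp
from mitophylo.phylo import Phylogeny, patristic_distances
from mitophylo.treeinfer import (
    DistanceMatrix,
    FitchEngine,
    GTREngine,
    _node_splits,
)

from util import (
    brute_fitch,
    enumerate_unrooted_topologies,
    random_unrooted_tree,
    toy_matrix,
)


# --------------------------------------------------------------------- #
# distances
# --------------------------------------------------------------------- #

def test_pairwise_differences_basics():
    m = toy_matrix(["ACGT", "ACGT", "ACGA"])
    D = mp.pairwise_differences(m)
    assert D[("t0", "t1")] == 0
    assert D[("t0", "t2")] == 1


def test_pairwise_differences_ignores_gaps_ambiguity_and_mask():
    m = toy_matrix(["ACGTAA", "AC-TWA", "TCGTAT"])
    m.exclusion_mask[5] = True  # final column never counted
    D = mp.pairwise_differences(m)
    assert D[("t0", "t1")] == 0  # gap and W cells are missing data
    assert D[("t0", "t2")] == 1


def test_pairwise_differences_match_column_scan(small_matrix):
    D = mp.pairwise_differences(small_matrix)
    m = small_matrix
    cols = m.retained_columns({1, 2, 3})
    a, b = 3, 9
    count = 0
    for c in cols.tolist():
        x, y = bytes(m.data[a, c]), bytes(m.data[b, c])
        if x in b"ACGT" and y in b"ACGT" and len(x) and len(y) and x != y:
            count += 1
    assert D.values[a, b] == count


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))


# --------------------------------------------------------------------- #
# neighbor joining
# --------------------------------------------------------------------- #

def test_nj_three_taxa_closed_form():
    D = DistanceMatrix(["a", "b", "c"],
                       np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float))
    tree = mp.neighbor_joining(D)
    lengths = {lf.name: lf.length for lf in tree.leaves()}
    assert lengths["a"] == pytest.approx((5 + 9 - 8) / 2)
    assert lengths["b"] == pytest.approx((5 + 8 - 9) / 2)
    assert lengths["c"] == pytest.approx((9 + 8 - 5) / 2)


@pytest.mark.parametrize("n_taxa,seed", [(5, 0), (5, 1), (8, 2), (12, 3)])
def test_nj_recovers_additive_trees_exactly(n_taxa, seed):
    rng = np.random.default_rng(seed)
    names = [f"x{i}" for i in range(n_taxa)]
    truth = random_unrooted_tree(names, rng)
    dist = patristic_distances(truth)
    vals = np.array([[dist[(a, b)] for b in names] for a in names])
    tree = mp.neighbor_joining(DistanceMatrix(names, vals))
    assert tree.same_topology(truth)
    est = patristic_distances(tree)
    for a, b in itertools.combinations(names, 2):
        assert est[(a, b)] == pytest.approx(dist[(a, b)], abs=1e-9)


def test_nj_agrees_with_dendropy_oracle(small_matrix):
    D = mp.pairwise_differences(small_matrix)
    ours = mp.neighbor_joining(D)
    csv = "," + ",".join(D.taxa) + "\n"
    for name, row in zip(D.taxa, D.values):
        csv += name + "," + ",".join(str(v) for v in row) + "\n"
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=__import__("io").StringIO(csv))
    theirs = Phylogeny.from_newick(
        pdm.nj_tree().as_string(schema="newick").replace("[&U]", ""))
    assert ours.same_topology(theirs)


def test_nj_near_additive_matches_least_squares_over_quartets():
    rng = np.random.default_rng(7)
    names = ["A", "B", "C", "D"]
    pair_index = list(itertools.combinations(range(4), 2))
    topo_sides = {"AB|CD": (0, 1), "AC|BD": (0, 2), "AD|BC": (0, 3)}

    def ls_residual(d, split):
        # branches: 4 terminal + 1 internal; design over the 6 pair paths
        rows, y = [], []
        i, j = split
        others = [k for k in range(4) if k not in (i, j)]
        for (a, b) in pair_index:
            row = [0.0] * 5
            row[a] += 1
            row[b] += 1
            same = {a, b} in ({i, j}, set(others))
            if not same:
                row[4] = 1
            rows.append(row)
            y.append(d[a, b])
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        pred = np.array(rows) @ sol
        return float(((pred - np.array(y)) ** 2).sum())

    for _ in range(20):
        truth = random_unrooted_tree(names, rng)
        dist = patristic_distances(truth)
        d = np.array([[dist[(a, b)] for b in names] for a in names])
        noise = rng.normal(scale=0.01, size=d.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        d = np.abs(d + noise)
        d = (d + d.T) / 2
        tree = mp.neighbor_joining(DistanceMatrix(names, d))
        best = min(topo_sides, key=lambda k: ls_residual(d, topo_sides[k]))
        split = frozenset({names[topo_sides[best][0]], names[topo_sides[best][1]]})
        got = tree.splits()
        want = split if "A" not in split else frozenset(names) - split
        assert got == frozenset({want})


# --------------------------------------------------------------------- #
# Fitch parsimony
# --------------------------------------------------------------------- #

def test_fitch_constant_matrix_is_zero(small_matrix, preset_nj):
    m = toy_matrix(["AAAA"] * 4)
    tree = Phylogeny.from_newick("(t0,t1,(t2,t3));")
    assert mp.fitch_length(tree, m) == 0


def test_fitch_textbook_quartet():
    m = toy_matrix(["A", "A", "C", "C"])
    grouping = Phylogeny.from_newick("(t0,t1,(t2,t3));")
    split = Phylogeny.from_newick("(t0,t2,(t1,t3));")
    assert mp.fitch_length(grouping, m) == 1
    assert mp.fitch_length(split, m) == 2


def test_fitch_leaf_mismatch_raises(small_matrix):
    tree = Phylogeny.from_newick("(a,b,(c,d));")
    with pytest.raises(ValueError):
        mp.fitch_length(tree, small_matrix)


def test_fitch_branch_counts_sum_to_length(preset_matrix, preset_nj):
    engine = FitchEngine(preset_matrix)
    total = engine.length(preset_nj)
    tree = preset_nj.copy()
    assigned = engine.branch_lengths(tree)
    assert assigned == total
    assert sum(n.length for n in tree.postorder() if n is not tree.root) == total


def test_fitch_with_missing_data_matches_exhaustive_oracle(rng):
    names = ["t0", "t1", "t2", "t3", "t4"]
    for _ in range(10):
        rows = {
            n: "".join(rng.choice(list("ACGT-N"), size=12, p=[.22]*4+[.06,.06]))
            for n in names
        }
        tree = random_unrooted_tree(names, rng)
        m = toy_matrix([rows[n] for n in names])
        assert mp.fitch_length(tree, m) == brute_fitch(tree, rows)


def test_mp_search_matches_exhaustive_enumeration_small(rng):
    names = [f"t{i}" for i in range(6)]
    rows = ["".join(rng.choice(list("ACGT"), size=30)) for _ in names]
    m = toy_matrix(rows)
    engine = FitchEngine(m)
    best_exhaustive = min(
        engine.length(t) for t in enumerate_unrooted_topologies(names)
    )
    trees = mp.mp_search(m, n_starts=5, seed=0)
    assert engine.length(trees[0]) == best_exhaustive


def test_mp_search_recovers_generating_topology(small, small_matrix):
    _, _, truth = small
    trees = mp.mp_search(small_matrix, n_starts=3, seed=0)
    # truth tree (in Ka) has the same topology as any best MP tree
    assert any(t.same_topology(truth.tree) for t in trees)


def test_duplicate_taxon_attaches_as_zero_length_sister(small_matrix):
    m = small_matrix
    dup = mp.Supermatrix(
        list(m.taxa) + [("DUPX", "dup")],
        np.vstack([m.data, m.data[0:1]]),
        dict(m.partitions),
        m.exclusion_mask.copy(),
        m.codon_position.copy(),
    )
    trees = mp.mp_search(dup, n_starts=2, seed=0)
    tree = trees[0]
    leaf = tree.find_leaf("DUPX")
    siblings = [c for c in leaf.parent.children if c is not leaf]
    assert any(s.is_leaf and s.name == m.accessions[0] for s in siblings)
    assert leaf.length == 0


# --------------------------------------------------------------------- #
# GTR likelihood
# --------------------------------------------------------------------- #

def test_zero_branch_identical_taxa_closed_form():
    m = toy_matrix(["ACGT", "ACGT", "ACGT"])
    tree = Phylogeny.from_newick("(t0:0,t1:0,t2:0);")
    params = mp.GTRParams(freqs=np.array([0.4, 0.2, 0.1, 0.3]))
    ll = mp.gtr_log_likelihood(tree, m, params)
    expect = sum(np.log(params.freqs[i]) for i in (0, 1, 2, 3))
    assert ll == pytest.approx(expect)


def test_two_taxon_jc_closed_form():
    m = toy_matrix(["AAAA", "AAGA"])
    t = 0.3
    half = Phylogeny.from_newick(f"(t0:{t / 2},t1:{t / 2});")
    params = mp.GTRParams()  # JC: equal rates and frequencies
    ll = mp.gtr_log_likelihood(half, m, params)
    p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    p_diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
    expect = 3 * np.log(0.25 * p_same) + np.log(0.25 * p_diff)
    assert ll == pytest.approx(expect, rel=1e-9)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        mp.GTRParams(rates=np.array([1, 1, 1, 1, 1, -1.0]))
    with pytest.raises(ValueError):
        mp.GTRParams(freqs=np.array([0.5, 0.5, 0.2, -0.2]))
    with pytest.raises(ValueError):
        mp.GTRParams(p_inv=1.0)


def test_ml_trace_is_monotone_and_finite(small_ml):
    trace = small_ml.trace
    assert np.isfinite(small_ml.log_likelihood)
    assert all(b >= a - 1e-6 for a, b in zip(trace, trace[1:]))


def test_ml_fixed_point_keeps_optimal_start(small_matrix, small_ml):
    res = mp.ml_search(small_matrix, start=small_ml.tree, seed=0)
    assert res.tree.same_topology(small_ml.tree)
    assert res.log_likelihood >= small_ml.log_likelihood - 1e-3


def test_ml_recovers_known_eight_taxon_topology():
    cfg = mp.SimulationConfig(
        clade_names=("w", "x", "y", "z"),
        leaves_per_clade=2,
        backbone_ages_ka=(780.0, 540.0, 250.0),
        crown_age_ka=100.0,
    )
    genomes, truth = mp.simulate_dataset(cfg, seed=9)
    matrix = mp.build_supermatrix(genomes)
    res = mp.ml_search(matrix, seed=0)
    assert res.tree.same_topology(truth.tree)


# --------------------------------------------------------------------- #
# mask neutrality and patristic additivity
# --------------------------------------------------------------------- #

def test_masking_a_constant_column_changes_nothing(small_matrix, small_ml):
    m = small_matrix
    cls = mp.classify_sites(m)
    const_col = next(c for c, cat in cls.categories.items() if cat == "constant")
    masked = mp.Supermatrix(
        list(m.taxa), m.data.copy(), dict(m.partitions),
        m.exclusion_mask.copy(), m.codon_position.copy(),
    )
    masked.exclusion_mask[const_col] = True
    assert (mp.pairwise_differences(masked).values
            == mp.pairwise_differences(m).values).all()
    nj = mp.neighbor_joining(mp.pairwise_differences(m))
    assert mp.fitch_length(nj, masked) == mp.fitch_length(nj, m)
    # the likelihood drops by exactly the masked column's own contribution
    single = GTREngine(m, columns=np.array([const_col]))
    col_ll = single.log_likelihood(small_ml.tree, small_ml.params)
    assert mp.gtr_log_likelihood(small_ml.tree, masked, small_ml.params) == \
        pytest.approx(
            mp.gtr_log_likelihood(small_ml.tree, m, small_ml.params) - col_ll,
            rel=1e-9,
        )


def test_patristic_four_point_condition(rng):
    names = [f"t{i}" for i in range(8)]
    tree = random_unrooted_tree(names, rng)
    dist = patristic_distances(tree)
    for quad in itertools.combinations(names, 4):
        a, b, c, d = quad
        sums = sorted([
            dist[(a, b)] + dist[(c, d)],
            dist[(a, c)] + dist[(b, d)],
            dist[(a, d)] + dist[(b, c)],
        ])
        assert sums[1] == pytest.approx(sums[2], abs=1e-9)


# --------------------------------------------------------------------- #
# bootstrap
# --------------------------------------------------------------------- #

def test_bootstrap_single_pattern_gives_full_support():
    m = toy_matrix(["AAACCC", "AAACCC", "CCCAAA", "CCCAAA", "CCCTTT"])
    tree = mp.bootstrap(m, method="nj", B=1, seed=0)
    supports = [n.support for n in tree.postorder()
                if n.support is not None]
    assert supports and all(s == 100.0 for s in supports)


def test_bootstrap_high_support_for_separated_clades():
    cfg = mp.SimulationConfig(
        clade_names=("left", "right"), leaves_per_clade=3,
        backbone_ages_ka=(780.0,), crown_age_ka=100.0,
    )
    genomes, truth = mp.simulate_dataset(cfg, seed=5)
    matrix = mp.build_supermatrix(genomes)
    tree = mp.bootstrap(matrix, method="nj", B=100, seed=1)
    clade = frozenset(a for a, l in truth.labels.items() if l == "left")
    for node, split in _node_splits(tree).items():
        if split in (clade, frozenset(truth.labels) - clade):
            assert node.support >= 95.0
            break
    else:
        pytest.fail("true clade bipartition missing from the point tree")


def test_bootstrap_supports_invariant_to_taxon_order(small_matrix):
    m = small_matrix
    perm = np.arange(m.n_taxa)[::-1]
    reordered = mp.Supermatrix(
        [m.taxa[i] for i in perm], m.data[perm], dict(m.partitions),
        m.exclusion_mask.copy(), m.codon_position.copy(),
    )
    t1 = mp.bootstrap(m, method="nj", B=30, seed=4)
    t2 = mp.bootstrap(reordered, method="nj", B=30, seed=4)
    s1 = {split: n.support for n, split in _node_splits(t1).items()}
    s2 = {split: n.support for n, split in _node_splits(t2).items()}
    assert s1 == s2


def test_bootstrap_validates_arguments(small_matrix):
    with pytest.raises(ValueError):
        mp.bootstrap(small_matrix, B=0)
    with pytest.raises(ValueError):
        mp.bootstrap(small_matrix, method="bayes")


def test_mp_length_not_above_nj_topology_length(preset_matrix, preset_nj):
    engine = FitchEngine(preset_matrix)
    best = mp.mp_search(preset_matrix, n_starts=2, seed=0)
    assert engine.length(best[0]) <= engine.length(preset_nj)
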