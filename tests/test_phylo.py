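import itertools

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.linalg import expm
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from neuromine._jtt import AA_ORDER, FREQS, rate_matrix
from neuromine.phylo import (
    Msa,
    _bipartitions,
    annotate_by_clade,
    bootstrap_support,
    jtt_distance,
    leaf_distances,
    needleman_wunsch,
    neighbor_joining,
    p_distance,
    pair_counts,
    progressive_align,
    read_newick,
    write_newick,
)

AAs = list("ARNDCQEGHILKMFPSTWYV")


def _random_family(rng, n, length=120, rate=0.1):
    base = "".join(rng.choice(AAs, length))
    out = []
    for k in range(n):
        s = list(base)
        for i in range(length):
            if rng.random() < rate * (k + 1) / n:
                s[i] = rng.choice(AAs)
        out.append("".join(s))
    return out


# ---------------------------------------------------------------------------
# alignment


def test_identical_pair_aligns_without_gaps():
    msa = progressive_align([("a", "MKTAYIAK"), ("b", "MKTAYIAK")])
    assert msa.rows[0] == msa.rows[1] == "MKTAYIAK"


def test_single_gap_column_and_dp_oracle_score():
    score, o1, o2 = needleman_wunsch("ACDEF", "ACEF")
    assert (o1, o2) == ("ACDEF", "AC-EF")
    gap_columns = sum((x == "-") != (y == "-") for x, y in zip(o1, o2))
    assert gap_columns == 1


def test_nw_scores_match_pairwise_aligner_oracle(rng):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.5  # first gap residue: open 10 + extend 0.5
    aligner.extend_gap_score = -0.5
    for _ in range(15):
        a = "".join(rng.choice(AAs, rng.integers(5, 50)))
        b = "".join(rng.choice(AAs, rng.integers(5, 50)))
        score, o1, o2 = needleman_wunsch(a, b)
        assert score == pytest.approx(aligner.score(a, b))
        assert o1.replace("-", "") == a and o2.replace("-", "") == b


def test_degapping_recovers_inputs(rng):
    seqs = [(f"s{i}", s) for i, s in enumerate(_random_family(rng, 6, 60, 0.4))]
    msa = progressive_align(seqs)
    assert msa.degapped() == dict(seqs)
    assert len({len(r) for r in msa.rows}) == 1


def test_single_sequence_rejected():
    with pytest.raises(ValueError):
        progressive_align([("only", "MKT")])


# ---------------------------------------------------------------------------
# JTT distances


def test_identical_rows_distance_zero():
    msa = Msa(["a", "b"], ["MKTAYIAKQR", "MKTAYIAKQR"])
    assert jtt_distance(msa)[("a", "b")] == 0.0


def test_short_branch_limit_close_to_p_distance(rng):
    base = "".join(rng.choice(AAs, 400))
    mutated = list(base)
    for i in rng.choice(400, 12, replace=False):
        mutated[i] = rng.choice(AAs)
    msa = Msa(["a", "b"], [base, "".join(mutated)])
    d_jtt = jtt_distance(msa)[("a", "b")]
    d_p = p_distance(msa)[("a", "b")]
    assert d_p <= 0.05
    assert abs(d_jtt - d_p) / d_p < 0.10


def _grid_oracle(counts):
    """Independent likelihood maximisation: dense grid + matrix
    exponential (scipy expm, no spectral shortcut)."""
    Q = rate_matrix()
    ts = np.linspace(1e-4, 5.0, 2001)
    best_t, best_ll = None, -np.inf
    for t in ts:
        P = expm(Q * t)
        joint = FREQS[:, None] * P
        ll = float((counts * np.log(joint.clip(1e-300))).sum())
        if ll > best_ll:
            best_t, best_ll = t, ll
    return best_t


def test_distance_matches_grid_search_oracle(rng):
    for _ in range(5):
        base = "".join(rng.choice(AAs, 250))
        mutated = list(base)
        for i in range(250):
            if rng.random() < rng.uniform(0.05, 0.4):
                mutated[i] = rng.choice(AAs)
        counts = pair_counts(base, "".join(mutated))
        mine = jtt_distance(Msa(["a", "b"], [base, "".join(mutated)]))[("a", "b")]
        oracle = _grid_oracle(counts)
        assert abs(mine - oracle) < 1e-3 + 5.0 / 2000  # grid resolution slack


def test_no_shared_columns_flagged():
    msa = Msa(["a", "b", "c"], ["MK--", "--TA", "MKTA"])
    with pytest.warns(UserWarning, match="undefined"):
        jtt_distance(msa)


# ---------------------------------------------------------------------------
# neighbor joining


def test_three_taxa_closed_form():
    D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
    tree = neighbor_joining(DistanceMatrix(D, ids=list("ABC")))
    ld = leaf_distances(tree)
    assert ld[("A", "B")] == pytest.approx(5)
    assert ld[("A", "C")] == pytest.approx(9)
    assert ld[("B", "C")] == pytest.approx(10)


def _random_additive(n_leaves, rng):
    parent, blen = {}, {}
    active = list(range(n_leaves))
    nxt = n_leaves
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[j], active[i]
        for x in (a, b):
            parent[x] = nxt
            blen[x] = rng.uniform(0.5, 3.0)
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1

    def path(x):
        acc, d = {}, 0.0
        while x in parent:
            d += blen[x]
            x = parent[x]
            acc[x] = d
        return acc

    M = np.zeros((n_leaves, n_leaves))
    paths = [path(i) for i in range(n_leaves)]
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            common = set(paths[i]) & set(paths[j])
            M[i, j] = M[j, i] = min(paths[i][c] + paths[j][c] for c in common)
    return M


@pytest.mark.parametrize("n", [4, 5, 6])
def test_nj_exact_on_additive_matrices(n, rng):
    for _ in range(5):
        M = _random_additive(n, rng)
        ids = [f"t{i}" for i in range(n)]
        tree = neighbor_joining(DistanceMatrix(M, ids=ids))
        ld = leaf_distances(tree)
        err = max(
            abs(ld[tuple(sorted((ids[i], ids[j])))] - M[i, j])
            for i in range(n)
            for j in range(i + 1, n)
        )
        assert err < 1e-9


def test_nj_topology_matches_skbio_oracle(rng):
    for _ in range(5):
        n = 6
        M = _random_additive(n, rng) + rng.uniform(0, 0.05, (n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        ids = [f"t{i}" for i in range(n)]
        dm = DistanceMatrix(M, ids=ids)
        leaves = frozenset(ids)
        mine = set(_bipartitions(neighbor_joining(dm), leaves).values())
        ref = set(_bipartitions(skbio_nj(dm), leaves).values())
        assert mine == ref


def test_asymmetric_matrix_rejected():
    from skbio.stats.distance import DistanceMatrixError

    with pytest.raises(DistanceMatrixError):
        DistanceMatrix(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]), ids=list("abc"))


def test_negative_branch_lengths_clamped(rng):
    for _ in range(10):
        n = 5
        M = rng.uniform(0.5, 2.0, (n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        tree = neighbor_joining(DistanceMatrix(M, ids=[f"t{i}" for i in range(n)]))
        for node in tree.traverse(include_self=False):
            assert node.length >= 0


# ---------------------------------------------------------------------------
# bootstrap


def _toy_msa(rng):
    return Msa([f"x{i}" for i in range(5)], _random_family(rng, 5, 80, 0.5))


def test_duplicated_column_msa_gets_full_support():
    rows = ["AAAAACCCCC", "AAAAACCCCC", "CCCCCAAAAA", "CCCCCAAAAA", "CACACACACA"]
    msa = Msa([f"s{i}" for i in range(5)], rows)
    tree = bootstrap_support(msa, n_reps=20, seed=1, distance="p")
    supports = [
        float(n.name)
        for n in tree.postorder(include_self=False)
        if not n.is_tip() and n.name is not None
    ]
    assert supports and all(s == 100.0 for s in supports)


def test_single_replicate_supports_are_zero_or_hundred(rng):
    tree = bootstrap_support(_toy_msa(rng), n_reps=1, seed=3, distance="p")
    for node in tree.postorder(include_self=False):
        if not node.is_tip() and node.name is not None:
            assert float(node.name) in (0.0, 100.0)


def test_bootstrap_deterministic_under_fixed_seed(rng):
    msa = _toy_msa(rng)
    t1 = bootstrap_support(msa, n_reps=30, seed=7, distance="p")
    t2 = bootstrap_support(msa, n_reps=30, seed=7, distance="p")
    assert write_newick(t1) == write_newick(t2)


def test_supports_within_range_and_order_invariant(rng):
    msa = _toy_msa(rng)
    perm = [3, 1, 4, 0, 2]
    msa_perm = Msa([msa.ids[i] for i in perm], [msa.rows[i] for i in perm])

    def support_map(tree):
        out = {}
        leaves = frozenset(msa.ids)
        parts = _bipartitions(tree, leaves)
        for node in tree.postorder(include_self=False):
            if not node.is_tip() and id(node) in parts and node.name is not None:
                out[parts[id(node)]] = float(node.name)
        return out

    s1 = support_map(bootstrap_support(msa, n_reps=40, seed=11, distance="p"))
    s2 = support_map(bootstrap_support(msa_perm, n_reps=40, seed=11, distance="p"))
    assert set(s1) == set(s2)
    for part in s1:
        assert 0.0 <= s1[part] <= 100.0
        assert s1[part] == s2[part]


def test_newick_round_trip_is_byte_stable(rng):
    tree = bootstrap_support(_toy_msa(rng), n_reps=10, seed=2, distance="p")
    nw = write_newick(tree)
    assert write_newick(read_newick(nw)) == nw


# ---------------------------------------------------------------------------
# clade annotation


def _quartet_tree(support: str):
    return read_newick(f"((cand:0.1,refA:0.1){support}:0.2,(refB:0.1,other:0.1)90:0.2);")


def test_candidate_sister_to_reference_inherits_label():
    tree = _quartet_tree("100")
    result = annotate_by_clade(tree, {"refA": "RPCH receptor", "refB": "PDH receptor"})
    assert result["cand"] == ("RPCH receptor", "high")


def test_conflicting_labels_leave_unannotated():
    tree = read_newick("((cand:0.1,(refA:0.1,refB:0.1)95:0.05)99:0.2,(x:0.1,y:0.1)90:0.2);")
    result = annotate_by_clade(tree, {"refA": "L1", "refB": "L2"})
    assert result["cand"][0] == "unannotated"


def test_support_min_above_100_annotates_nothing():
    tree = _quartet_tree("100")
    result = annotate_by_clade(
        tree, {"refA": "L1", "refB": "L2"}, support_min=101
    )
    assert all(label == "unannotated" for label, _ in result.values())


def test_low_support_clade_blocks_transfer():
    tree = _quartet_tree("40")
    result = annotate_by_clade(tree, {"refA": "L1", "refB": "L2"}, support_min=70)
    assert result["cand"][0] == "unannotated"


def test_tree_without_references_rejected():
    with pytest.raises(ValueError):
        annotate_by_clade(_quartet_tree("90"), {"absent": "L"})
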