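"""Alignment, distances and neighbor-joining trees with bootstrap support.

Receptor (or peptide) candidates are annotated by phylogenetic placement:
candidates and reference sequences are aligned with a ClustalW-style
progressive aligner (pairwise global alignments → UPGMA guide tree →
profile-profile merges), pairwise distances are maximum-likelihood branch
lengths under the JTT amino-acid substitution model, trees come from the
canonical Saitou-Nei neighbor-joining agglomeration, and internal-edge
supports are bootstrap percentages over column-resampled replicates.
A candidate inherits a reference's annotation when the smallest
well-supported clade containing both carries no conflicting label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from io import StringIO

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from ._jtt import AA_ORDER, FREQS, rate_matrix

GAP = "-"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


# ---------------------------------------------------------------------------
# multiple sequence alignment


@dataclass
class Msa:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self) -> dict[str, str]:
        return {i: r.replace(GAP, "") for i, r in zip(self.ids, self.rows)}

    def resample_columns(self, rng: np.random.Generator) -> "Msa":
        cols = rng.integers(0, self.n_cols, self.n_cols)
        return Msa(list(self.ids), ["".join(r[c] for c in cols) for r in self.rows])

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{r}\n" for i, r in zip(self.ids, self.rows))


@lru_cache(maxsize=1)
def _blosum62() -> np.ndarray:
    """BLOSUM62 as a 21x21 array in AA_ORDER + gap (gap scores 0)."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((21, 21))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            out[i, j] = mat[a][b]
    return out


def _profile(rows: list[str]) -> np.ndarray:
    """Column residue frequencies over AA_ORDER + gap, rows normalised."""
    n_cols = len(rows[0])
    prof = np.zeros((n_cols, 21))
    for row in rows:
        for c, res in enumerate(row):
            prof[c, _AA_INDEX.get(res, 20)] += 1.0
    return prof / len(rows)


def _gotoh(S: np.ndarray, gap_open: float, gap_extend: float) -> tuple[float, list[str]]:
    """Global affine-gap alignment over a precomputed score matrix.

    A gap of length k costs ``gap_open + k * gap_extend``. Returns the
    optimal score and the column operations ('M' both, 'X' gap in the
    second profile, 'Y' gap in the first). Ties prefer M, then X, then Y.
    """
    n1, n2 = S.shape
    NEG = -1e30
    M = np.full((n1 + 1, n2 + 1), NEG)
    X = np.full((n1 + 1, n2 + 1), NEG)
    Y = np.full((n1 + 1, n2 + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n1 + 1):
        X[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, n2 + 1):
        Y[0, j] = -(gap_open + j * gap_extend)
    H = lambda i, j: max(M[i, j], X[i, j], Y[i, j])
    for i in range(1, n1 + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Hi1 = np.maximum(np.maximum(Mi1, Xi1), Yi1)
        Si = S[i - 1]
        Mrow, Xrow, Yrow = M[i], X[i], Y[i]
        for j in range(1, n2 + 1):
            Mrow[j] = Hi1[j - 1] + Si[j - 1]
            Xrow[j] = max(Hi1[j] - gap_open - gap_extend, Xi1[j] - gap_extend)
            Yrow[j] = max(
                max(Mrow[j - 1], Xrow[j - 1], Yrow[j - 1]) - gap_open - gap_extend,
                Yrow[j - 1] - gap_extend,
            )
    score = H(n1, n2)
    # traceback
    ops: list[str] = []
    i, j = n1, n2
    state = max(
        (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])), key=lambda kv: kv[1]
    )[0]
    while i > 0 or j > 0:
        if i == 0:
            ops.append("Y")
            j -= 1
            continue
        if j == 0:
            ops.append("X")
            i -= 1
            continue
        if state == "M":
            ops.append("M")
            i, j = i - 1, j - 1
            state = max(
                (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])), key=lambda kv: kv[1]
            )[0]
        elif state == "X":
            ops.append("X")
            cont = X[i - 1, j] - gap_extend
            i -= 1
            if X[i, j] == NEG or abs(X[i + 1, j] - cont) > 1e-9:
                state = max(
                    (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])), key=lambda kv: kv[1]
                )[0]
        else:
            ops.append("Y")
            cont = Y[i, j - 1] - gap_extend
            j -= 1
            if Y[i, j] == NEG or abs(Y[i, j + 1] - cont) > 1e-9:
                state = max(
                    (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])), key=lambda kv: kv[1]
                )[0]
    ops.reverse()
    return float(score), ops


def _merge(rows1: list[str], rows2: list[str], gap_open: float, gap_extend: float):
    p1, p2 = _profile(rows1), _profile(rows2)
    S = p1 @ _blosum62() @ p2.T
    score, ops = _gotoh(S, gap_open, gap_extend)
    out1, out2 = [], []
    for row in rows1:
        it = iter(row)
        out1.append("".join(next(it) if op in "MX" else GAP for op in ops))
    for row in rows2:
        it = iter(row)
        out2.append("".join(next(it) if op in "MY" else GAP for op in ops))
    return score, out1, out2


def needleman_wunsch(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> tuple[float, str, str]:
    """Global BLOSUM62 alignment of two sequences (length-k gap costs
    ``gap_open + k * gap_extend``)."""
    score, out1, out2 = _merge([a], [b], gap_open, gap_extend)
    return score, out1[0], out2[0]


def _guide_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def progressive_align(
    seqs: list[tuple[str, str]], gap_open: float = 10.0, gap_extend: float = 0.5
) -> Msa:
    """ClustalW-style progressive alignment.

    Pairwise global-alignment identities give distances, an average-
    linkage (UPGMA) guide tree orders profile-profile merges, each merge
    is an affine-gap alignment of column-frequency profiles under
    BLOSUM62. Deterministic; rows are returned in input order.
    """
    if len(seqs) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    ids = [i for i, _ in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    raw = {i: s for i, s in seqs}
    n = len(ids)
    if n == 2:
        _, o1, o2 = _merge([raw[ids[0]]], [raw[ids[1]]], gap_open, gap_extend)
        return Msa(list(ids), [o1[0], o2[0]])
    aligner = _guide_aligner(gap_open, gap_extend)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(raw[ids[i]], raw[ids[j]])[0]
            s1, s2 = str(aln[0]), str(aln[1])
            matches = sum(x == y and x != GAP for x, y in zip(s1, s2))
            dist[i, j] = dist[j, i] = 1.0 - matches / len(s1)
    Z = linkage(squareform(dist, checks=False), method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [raw[ids[i]]]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        _, out_a, out_b = _merge(rows_a, rows_b, gap_open, gap_extend)
        clusters[n + step] = (ids_a + ids_b, out_a + out_b)
    (merged_ids, merged_rows), = clusters.values()
    order = {i: k for k, i in enumerate(merged_ids)}
    rows = [merged_rows[order[i]] for i in ids]
    return Msa(list(ids), rows)


# ---------------------------------------------------------------------------
# JTT maximum-likelihood pairwise distances


class JttModel:
    """Spectral form of the JTT rate matrix for fast transition matrices."""

    def __init__(self) -> None:
        Q = rate_matrix()
        self.pi = FREQS
        sq = np.sqrt(self.pi)
        B = (Q * sq[:, None]) / sq[None, :]  # symmetric similarity transform
        lam, U = np.linalg.eigh((B + B.T) / 2)
        self.lam = lam
        self._U = U
        self._sq = sq
        self._grid_t = np.geomspace(1e-4, 20.0, 160)
        self._grid_logjoint = np.stack(
            [np.log(self.joint(t).clip(1e-300)) for t in self._grid_t]
        )

    def transition(self, t: float) -> np.ndarray:
        E = self._U * np.exp(self.lam * t)
        P = (E @ self._U.T) * (self._sq[None, :] / self._sq[:, None])
        return P

    def joint(self, t: float) -> np.ndarray:
        """P(a, b | t) = pi_a * P_ab(t)."""
        return self.pi[:, None] * self.transition(t)

    def loglik(self, counts: np.ndarray, t: float) -> float:
        return float((counts * np.log(self.joint(t).clip(1e-300))).sum())

    def distance(self, counts: np.ndarray) -> float:
        """ML time separating a pair, from their 20x20 site-pair counts."""
        total = counts.sum()
        if total == 0:
            return np.nan
        p_dist = 1.0 - np.trace(counts) / total
        if p_dist == 0:
            return 0.0
        flat = counts.reshape(-1)
        grid_ll = self._grid_logjoint.reshape(len(self._grid_t), -1) @ flat
        k = int(np.argmax(grid_ll))
        lo = self._grid_t[max(k - 1, 0)]
        hi = self._grid_t[min(k + 1, len(self._grid_t) - 1)]
        res = minimize_scalar(
            lambda t: -self.loglik(counts, t),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)


@lru_cache(maxsize=1)
def _default_model() -> JttModel:
    return JttModel()


def pair_counts(row1: str, row2: str) -> np.ndarray:
    """20x20 residue-pair counts over shared ungapped columns
    (pairwise deletion)."""
    counts = np.zeros((20, 20))
    for a, b in zip(row1, row2):
        ia, ib = _AA_INDEX.get(a), _AA_INDEX.get(b)
        if ia is not None and ib is not None:
            counts[ia, ib] += 1.0
    return counts


def jtt_distance(msa: Msa, model: JttModel | None = None) -> DistanceMatrix:
    """Pairwise ML distances under JTT (gamma off, pairwise deletion).

    Pairs with zero p-distance get distance 0; pairs sharing no ungapped
    columns are undefined — they are flagged with a warning and assigned
    twice the largest finite distance so the matrix stays usable.
    """
    if len(msa.ids) < 2:
        raise ValueError("need at least 2 rows")
    model = model or _default_model()
    n = len(msa.ids)
    D = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            d = model.distance(pair_counts(msa.rows[i], msa.rows[j]))
            if np.isnan(d):
                undefined.append((msa.ids[i], msa.ids[j]))
            D[i, j] = D[j, i] = d
    if undefined:
        warnings.warn(
            f"distance undefined (no shared ungapped columns) for pairs: {undefined}"
        )
        finite_max = np.nanmax(D) if np.isfinite(np.nanmax(D)) else 1.0
        D = np.nan_to_num(D, nan=2.0 * finite_max)
    return DistanceMatrix(D, ids=list(msa.ids))


def p_distance(msa: Msa) -> DistanceMatrix:
    """Plain proportion-of-differences distance (pairwise deletion)."""
    n = len(msa.ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = pair_counts(msa.rows[i], msa.rows[j])
            total = c.sum()
            D[i, j] = D[j, i] = 1.0 - np.trace(c) / total if total else 0.0
    return DistanceMatrix(D, ids=list(msa.ids))


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical Saitou-Nei agglomeration.

    Q-matrix ties break on the smallest (i, j) index pair in current
    matrix order; negative branch lengths are clamped to zero with the
    deficit shifted onto the sibling branch. The returned tree is rooted
    at the final join for serialization; path lengths between leaves
    reproduce an additive input exactly.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # canonical id order makes tie-breaking (and hence bootstrap supports)
    # independent of input row order
    ids = sorted(dm.ids)
    dm = dm.filter(ids)
    D = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    while len(nodes) > 2:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                if best is None or Q[i, j] < Q[best] - 1e-12:
                    best = (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
            li = max(li, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(li)
        child_j.length = float(lj)
        new = TreeNode(children=[child_i, child_j])
        d_new = 0.5 * (D[:, i] + D[:, j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[: len(keep), : len(keep)] = D[np.ix_(keep, keep)]
        D2[-1, : len(keep)] = D2[: len(keep), -1] = d_new[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
    a, b = nodes
    d = float(D[0, 1])
    a.length = d / 2.0
    b.length = d / 2.0
    return TreeNode(children=[a, b])


def leaf_distances(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Patristic (path-length) distances between all leaf pairs."""
    leaves = list(tree.tips())
    out = {}
    for i, x in enumerate(leaves):
        for y in leaves[i + 1 :]:
            d = x.distance(y)
            key = tuple(sorted((x.name, y.name)))
            out[key] = float(d)
    return out


# ---------------------------------------------------------------------------
# bootstrap


def _bipartitions(tree: TreeNode, all_leaves: frozenset[str]) -> dict[int, frozenset[str]]:
    """Canonical non-trivial bipartitions keyed by node id."""
    ref = min(all_leaves)
    out = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue
        if ref in side:
            side = all_leaves - side
        out[id(node)] = side
    return out


def bootstrap_support(
    msa: Msa,
    n_reps: int = 1000,
    seed: int = 0,
    distance: str = "jtt",
    model: JttModel | None = None,
) -> TreeNode:
    """NJ tree of the full alignment with bootstrap supports.

    Columns are resampled with replacement per replicate; each internal
    node's name is set to the percentage of replicate NJ trees containing
    its bipartition. Seeded and deterministic.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    dist_fn = {"jtt": lambda m: jtt_distance(m, model), "p": p_distance}[distance]
    tree = neighbor_joining(dist_fn(msa))
    all_leaves = frozenset(msa.ids)
    target = _bipartitions(tree, all_leaves)
    hits = {nid: 0 for nid in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep = msa.resample_columns(rng)
        rep_tree = neighbor_joining(dist_fn(rep))
        rep_parts = set(_bipartitions(rep_tree, all_leaves).values())
        for nid, part in target.items():
            if part in rep_parts:
                hits[nid] += 1
    for node in tree.postorder(include_self=False):
        if not node.is_tip() and id(node) in target:
            node.name = f"{100.0 * hits[id(node)] / n_reps:g}"
    return tree


def node_support(node: TreeNode) -> float:
    """Bootstrap support stored in an internal node's name (root: 100)."""
    if node.parent is None:
        return 100.0
    try:
        return float(node.name)
    except (TypeError, ValueError):
        return 100.0


def annotate_by_clade(
    tree: TreeNode,
    reference_labels: dict[str, str],
    support_min: float = 70.0,
) -> dict[str, tuple[str, str]]:
    """Transfer reference annotations to candidate leaves by clade.

    A candidate receives a reference's label when the smallest clade
    containing both has bootstrap support >= ``support_min`` and contains
    no conflicting reference label; otherwise it stays "unannotated".
    Confidence is "high" for support >= 70, else "low".
    """
    if not any(t.name in reference_labels for t in tree.tips()):
        raise ValueError("tree contains no labeled reference leaf")
    result: dict[str, tuple[str, str]] = {}
    for leaf in tree.tips():
        if leaf.name in reference_labels:
            continue
        node = leaf.parent
        label, confidence = "unannotated", ""
        while node is not None:
            ref_labels = {
                reference_labels[t.name]
                for t in node.tips()
                if t.name in reference_labels
            }
            if ref_labels:
                support = node_support(node)
                if len(ref_labels) == 1 and support >= support_min:
                    label = ref_labels.pop()
                    confidence = "high" if support >= 70.0 else "low"
                break
            node = node.parent
        result[leaf.name] = (label, confidence)
    return result


# ---------------------------------------------------------------------------
# newick io


def write_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf)
    return buf.getvalue()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(StringIO(text))
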