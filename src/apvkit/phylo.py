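"""Distance phylogenetics: K2P/TN93 distances, neighbor-joining, bootstrap.

The substitution models are the two used for the avian papillomavirus L1
trees: Kimura 2-parameter with gamma rate variation, and Tamura-Nei with
gamma rate variation plus an invariant-site fraction.  Gamma correction
follows the MEGA convention — each logarithmic term -c*ln(w) of the
closed-form distance becomes c*a*(w^(-1/a) - 1) for shape a; the
invariant-site correction rescales the observed mismatch proportions by
1/(1 - p_inv) and the resulting distance by (1 - p_inv).

Trees are built with Saitou-Nei neighbor joining (deterministic tie-breaks,
negative branch lengths clamped to zero with the deficit moved to the
sister branch) and assessed by nonparametric bootstrap over alignment
columns.  Maximum-likelihood inference is deliberately out of scope: the
trees here serve qualitative clade-composition (monophyly) queries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .taxonomy import Alignment, comparable_columns

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass
class DistanceModel:
    model: str = "K2P"  # {"p", "K2P", "TN93"}
    gamma_shape: float | None = None
    prop_invariant: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ("p", "K2P", "TN93"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.prop_invariant is not None:
            if not 0.0 <= self.prop_invariant < 1.0:
                raise ValueError("prop_invariant must be in [0, 1)")
            if self.model == "p":
                raise ValueError("prop_invariant requires K2P or TN93")


def _term(c: float, w: float, alpha: float | None) -> float:
    """One model term: -c*ln(w), or its gamma-corrected power transform."""
    if w <= 0.0:
        return math.inf  # saturation
    if alpha is None:
        return -c * math.log(w)
    return c * alpha * (w ** (-1.0 / alpha) - 1.0)


def model_distance(a: str, b: str, m: DistanceModel | None = None) -> float:
    """Model-corrected distance in substitutions/site between two gapped rows.

    Saturated comparisons (non-positive logarithm argument) return
    ``math.inf`` rather than NaN.
    """
    m = m or DistanceModel()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    a, b = a.upper(), b.upper()
    cols = comparable_columns(a, b)
    if not cols:
        raise ValueError("no comparable columns")
    n = len(cols)
    scale = 1.0 - (m.prop_invariant or 0.0)

    if m.model == "p":
        diff = sum(1 for i in cols if a[i] != b[i])
        return diff / n

    # mismatch proportions by class
    p1 = p2 = q = 0
    counts: dict[str, int] = {"A": 0, "C": 0, "G": 0, "T": 0}
    for i in cols:
        x, y = a[i], b[i]
        counts[x] += 1
        counts[y] += 1
        if x != y:
            if x in PURINES and y in PURINES:
                p1 += 1
            elif x in PYRIMIDINES and y in PYRIMIDINES:
                p2 += 1
            else:
                q += 1
    P1, P2, Q = p1 / n / scale, p2 / n / scale, q / n / scale
    alpha = m.gamma_shape

    if m.model == "K2P":
        P = P1 + P2
        d = _term(0.5, 1.0 - 2.0 * P - Q, alpha) + _term(0.25, 1.0 - 2.0 * Q, alpha)
        return scale * d

    # TN93: empirical base composition from the pair
    tot = 2.0 * n
    gA, gC, gG, gT = (counts[k] / tot for k in "ACGT")
    gR, gY = gA + gG, gC + gT
    if gA * gG == 0.0 or gT * gC == 0.0 or gR * gY == 0.0:
        # degenerate composition: fall back to K2P behaviour for absent classes
        if (gA * gG == 0.0 and P1 > 0) or (gT * gC == 0.0 and P2 > 0):
            return math.inf
        c3 = 2.0 * gR * gY
        d = _term(c3 if c3 else 0.0, 1.0 - (Q / c3 if c3 else 0.0), alpha) if Q else 0.0
        return scale * d
    c1 = 2.0 * gA * gG / gR
    c2 = 2.0 * gT * gC / gY
    c3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1.0 - gR * P1 / (2.0 * gA * gG) - Q / (2.0 * gR)
    w2 = 1.0 - gY * P2 / (2.0 * gT * gC) - Q / (2.0 * gY)
    w3 = 1.0 - Q / (2.0 * gR * gY)
    d = _term(c1, w1, alpha) + _term(c2, w2, alpha) + _term(c3, w3, alpha)
    return scale * d


def distance_matrix(aln: Alignment, m: DistanceModel | None = None) -> np.ndarray:
    n = len(aln.ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = model_distance(aln.rows[i], aln.rows[j], m)
    return D


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree held rooted at an internal (usually trifurcating) node."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def _sides(self) -> dict[frozenset, TreeNode]:
        """Leaf set below every non-root node (one side of each edge)."""
        sides: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                s = frozenset([node.name])
            else:
                s = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root:
                sides[s] = node
            return s

        walk(self.root)
        return sides

    def bipartitions(self) -> set[frozenset]:
        """Internal-edge bipartitions, canonicalized as the side not
        containing the alphabetically first leaf."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out = set()
        for side in self._sides():
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side if ref not in side else all_leaves - side)
        return out

    def newick(self, support_digits: int = 0) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if node.support is not None:
                label = f"{node.support:.{support_digits}f}" if support_digits else str(int(round(node.support)))
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def nj_tree(D: np.ndarray, labels: list[str]) -> Tree:
    """Saitou-Nei neighbor joining.

    Ties in the Q-criterion go to the smallest (i, j) pair in current node
    order; negative branch lengths are clamped to zero with the deficit
    moved to the sister branch.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise ValueError("bad distance matrix shape")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite entries")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    D = D.copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        k = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best, best_q = None, math.inf
        for ai in range(k):
            for aj in range(ai + 1, k):
                i, j = active[ai], active[aj]
                qv = (k - 2) * D[i, j] - r[i] - r[j]
                if qv < best_q - 1e-12:
                    best_q, best = qv, (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, lj)
        nodes[i].length, nodes[j].length = li, lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        # grow matrix with the new node's distances
        m = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for x in active:
            if x not in (i, j):
                D[m, x] = D[x, m] = 0.5 * (D[i, x] + D[j, x] - D[i, j])
        nodes.append(new)
        active = [x for x in active if x not in (i, j)] + [m]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        nodes[idx].length = max(ln, 0.0)
    return Tree(TreeNode(children=[nodes[a], nodes[b], nodes[c]]))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    n_replicates: int
    support: dict[frozenset, float]  # bipartition -> percent


def bootstrap(
    aln: Alignment,
    m: DistanceModel | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> tuple[Tree, BootstrapResult]:
    """Column-resampling bootstrap of the NJ tree.

    Support of each internal bipartition of the point-estimate tree is the
    percentage of replicate trees containing it.  Replicates whose resampled
    distance matrix saturates are redrawn (bounded).  Deterministic given
    the seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(aln.ids) < 4:
        raise ValueError("bootstrap support undefined for < 4 sequences")
    D = distance_matrix(aln, m)
    if not np.all(np.isfinite(D)):
        raise ValueError("saturated distances in the point estimate")
    point = nj_tree(D, aln.ids)
    splits = point.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    W = aln.width
    done = draws = 0
    while done < n_reps:
        draws += 1
        if draws > 100 * n_reps:
            raise RuntimeError("too many saturated bootstrap replicates")
        idx = rng.integers(0, W, size=W)
        rep = Alignment(list(aln.ids), ["".join(r[i] for i in idx) for r in aln.rows])
        try:
            Dr = distance_matrix(rep, m)
        except ValueError:
            continue
        if not np.all(np.isfinite(Dr)):
            continue
        rep_splits = nj_tree(Dr, rep.ids).bipartitions()
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
        done += 1
    support = {s: 100.0 * c / n_reps for s, c in counts.items()}
    # annotate the point tree
    all_leaves = frozenset(point.leaf_names())
    ref = min(all_leaves)
    for side, node in point._sides().items():
        if 2 <= len(side) <= len(all_leaves) - 2:
            key = side if ref not in side else all_leaves - side
            node.support = support[key]
    return point, BootstrapResult(n_reps, support)


# ---------------------------------------------------------------------------
# Monophyly
# ---------------------------------------------------------------------------

def is_monophyletic(
    t: Tree, leaves, outgroup: set | None = None
) -> bool:
    """True iff some edge of the unrooted tree bipartitions exactly ``leaves``.

    With an ``outgroup`` label set the test is rooted: the clade side must
    exclude the outgroup.
    """
    leaves = frozenset(leaves)
    all_leaves = frozenset(t.leaf_names())
    unknown = leaves - all_leaves
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    if not leaves or leaves == all_leaves:
        raise ValueError("subset must be nonempty and proper")
    if len(leaves) == 1:
        return True
    sides = set(t._sides().keys())
    # the root's child sides cover all edges incident to the root except one;
    # complement sides represent the same edges seen from the other end
    if outgroup is not None:
        if leaves & frozenset(outgroup):
            return False
        return leaves in sides or (all_leaves - leaves) in sides
    return leaves in sides or (all_leaves - leaves) in sides


def write_newick(t: Tree, path) -> None:
    text = t.newick() + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
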