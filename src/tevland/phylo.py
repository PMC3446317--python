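"""Strain phylogenetics from TEV presence/absence characters.

A TE insertion at an orthologous site is, for practical purposes, a unique
irreversible event: two strains sharing an insertion at the same position
share ancestry, and the insertion can subsequently be lost (deleted or
undetected) but not independently regained.  Presence/absence columns are
therefore scored under Dollo parsimony -- exactly one gain per character,
placed at the last common ancestor (LCA) of the carriers, plus as few
losses as the tree demands.

Trees are rooted; leaves are strains.  Internally a tree is a flat array of
nodes whose leaf sets are bitmasks over the strain list, which makes both
the Dollo scorer and majority-rule clade counting cheap.  Newick I/O goes
through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "infer_tree",
    "map_to_lca",
    "lineage_composition",
    "solo_ltr_fraction_by_node",
    "dollo_score",
]


# ---------------------------------------------------------------------------
# tree container
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    id: int
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    label: str | None = None       # strain name for leaves
    length: float | None = None    # branch length to parent (My)
    support: float | None = None   # bootstrap support in [0, 100]
    mask: int = 0                  # bitmask of descendant leaves

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted strain tree with optional branch lengths (My) and supports."""

    def __init__(self, nodes: list[_Node], taxa: list[str]):
        self.nodes = nodes
        self.taxa = list(taxa)
        self._leaf_index = {t: i for i, t in enumerate(taxa)}
        self._refresh_masks()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        taxa = sorted(lf.taxon.label for lf in dt.leaf_node_iter())
        nodes: list[_Node] = []

        def build(dn, parent):
            nid = len(nodes)
            n = _Node(id=nid, parent=parent)
            n.length = dn.edge.length
            if dn.is_leaf():
                n.label = dn.taxon.label
            nodes.append(n)
            for ch in dn.child_nodes():
                cid = build(ch, nid)
                nodes[nid].children.append(cid)
            return nid

        build(dt.seed_node, None)
        return cls(nodes, taxa)

    def _refresh_masks(self) -> None:
        for n in reversed(self.nodes):  # children are appended after parents
            if n.is_leaf:
                n.mask = 1 << self._leaf_index[n.label]
            else:
                n.mask = 0
                for c in n.children:
                    n.mask |= self.nodes[c].mask

    # -- queries -------------------------------------------------------------

    @property
    def root(self) -> _Node:
        return self.nodes[0]

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    def leaves(self):
        return [n for n in self.nodes if n.is_leaf]

    def postorder(self):
        order: list[int] = []

        def walk(i):
            for c in self.nodes[i].children:
                walk(c)
            order.append(i)

        walk(0)
        return order

    def depths(self) -> dict[int, float]:
        """Distance from the root to each node (0 for the root)."""
        d = {0: 0.0}
        for n in self.nodes[1:]:
            d[n.id] = d[n.parent] + (n.length or 0.0)
        return d

    def height(self) -> float:
        d = self.depths()
        return max(d[n.id] for n in self.leaves())

    def leaf_set(self, node_id: int) -> set[str]:
        mask = self.nodes[node_id].mask
        return {t for t, i in self._leaf_index.items() if mask >> i & 1}

    def lca(self, strains) -> int:
        """Node id of the last common ancestor of the given strains."""
        want = 0
        for s in strains:
            want |= 1 << self._leaf_index[s]
        if want == 0:
            raise ValueError("LCA of an empty strain set is undefined")
        best = 0
        # deepest node whose mask covers all carriers
        for n in self.nodes:
            if n.mask & want == want and n.mask <= self.nodes[best].mask:
                best = n.id
        return best

    def clades(self) -> dict[int, int]:
        """Map node id -> descendant-leaf bitmask for non-trivial clades."""
        full = (1 << self.n_leaves) - 1
        return {
            n.id: n.mask
            for n in self.nodes
            if not n.is_leaf and n.mask != full
        }

    # -- output --------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(i):
            n = self.nodes[i]
            if n.is_leaf:
                s = n.label
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if n.support is not None:
                    s += f"{n.support:g}"
            if n.length is not None:
                s += f":{n.length:g}"
            return s

        return fmt(0) + ";"


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------

def _score_masks(masks: np.ndarray, parents: np.ndarray,
                 carriers: np.ndarray, known: np.ndarray,
                 weights: np.ndarray) -> float:
    """Vectorized Dollo cost over characters for one topology.

    ``masks``/``parents`` describe the tree (root at index 0); characters
    are bitmask columns.  The gain sits at the LCA of the carriers; losses
    are children of gained-lineage nodes whose subtree holds no carrier but
    at least one observed (non-NA) leaf.
    """
    m = masks[:, None]
    c = carriers[None, :]
    inter = m & c
    nz = inter != 0
    covers = inter == c
    sentinel = np.int64(1) << np.int64(62)
    lca_mask = np.where(covers, m, sentinel).min(axis=0)
    in_sub = (m & ~lca_mask[None, :]) == 0
    parent_on = (nz & in_sub)[parents]
    loss = parent_on & ~nz & ((m & known[None, :]) != 0)
    loss[0, :] = False  # root has no parent edge
    per_char = loss.sum(axis=0)
    per_char = np.where(carriers == 0, 0, per_char)
    return float((per_char * weights).sum())


def _tree_arrays(tree: PhyloTree) -> tuple[np.ndarray, np.ndarray]:
    masks = np.array([n.mask for n in tree.nodes], dtype=np.int64)
    parents = np.array([n.parent if n.parent is not None else 0
                        for n in tree.nodes], dtype=np.intp)
    return masks, parents


def dollo_score(tree: PhyloTree, chars: list[tuple[int, int]],
                weights=None) -> float:
    """Total Dollo cost of binary characters on a rooted tree.

    Each character is ``(carrier_mask, known_mask)``; leaves outside
    ``known_mask`` are missing (NA) and do not constrain the fit.  The gain is
    placed at the LCA of the carriers and the cost is the number of loss
    events: maximal carrier-free subtrees hanging off the gained lineage.
    """
    if not chars:
        return 0.0
    if weights is None:
        weights = np.ones(len(chars))
    carriers = np.array([c for c, _ in chars], dtype=np.int64)
    known = np.array([k for _, k in chars], dtype=np.int64)
    masks, parents = _tree_arrays(tree)
    return _score_masks(masks, parents, carriers, known,
                        np.asarray(weights, dtype=float))


def _chars_from_matrix(matrix: pd.DataFrame, taxa: list[str]):
    """Rows of a {0,1,NA} presence matrix as (carrier, known) bitmask pairs."""
    idx = {t: i for i, t in enumerate(taxa)}
    chars = []
    vals = matrix[taxa].to_numpy(dtype=float)
    for row in vals:
        carriers = 0
        known = 0
        for t, v in zip(taxa, row):
            if np.isnan(v):
                continue
            known |= 1 << idx[t]
            if v:
                carriers |= 1 << idx[t]
        chars.append((carriers, known))
    return chars


def _random_resolved_tree(taxa, rng) -> PhyloTree:
    order = list(rng.permutation(len(taxa)))
    return _stepwise_tree(taxa, order, [], None)


def _build_tree_from_parents(taxa, topo) -> PhyloTree:
    """topo: list of (children tuple) nested structure."""
    nodes: list[_Node] = []

    def build(sub, parent):
        nid = len(nodes)
        nodes.append(_Node(id=nid, parent=parent))
        if isinstance(sub, int):
            nodes[nid].label = taxa[sub]
        else:
            for s in sub:
                cid = build(s, nid)
                nodes[nid].children.append(cid)
        return nid

    build(topo, None)
    return PhyloTree(nodes, sorted(taxa))


def _topo_arrays(topo, n_leaves: int) -> tuple[np.ndarray, np.ndarray]:
    """Masks/parents arrays for a nested-tuple topology (leaf = int index)."""
    masks: list[int] = []
    parents: list[int] = []

    def build(sub, parent):
        nid = len(masks)
        masks.append(0)
        parents.append(parent if parent is not None else 0)
        if isinstance(sub, int):
            masks[nid] = 1 << sub
        else:
            for s in sub:
                build(s, nid)
        if parent is not None:
            pass
        return nid

    build(topo, None)
    # fill internal masks bottom-up via parents
    m = np.zeros(len(masks), dtype=np.int64)
    for i in range(len(masks) - 1, -1, -1):
        if masks[i]:
            m[i] |= masks[i]
        if i > 0:
            m[parents[i]] |= m[i]
    return m, np.array(parents, dtype=np.intp)


def _topo_cost(topo, n_leaves, carriers, known, weights) -> float:
    m, p = _topo_arrays(topo, n_leaves)
    return _score_masks(m, p, carriers, known, weights)


def _insertions(t, leaf):
    out = [(t, leaf)]
    if not isinstance(t, int):
        a, b = t
        out += [(x, b) for x in _insertions(a, leaf)]
        out += [(a, x) for x in _insertions(b, leaf)]
    return out


def _stepwise_topo(n_leaves, order, carriers, known, weights):
    """Greedy stepwise-addition Dollo topology for the given leaf order."""
    topo = (order[0], order[1]) if len(order) > 1 else order[0]
    for leaf in order[2:]:
        best, best_cost = None, np.inf
        for cand in _insertions(topo, leaf):
            cost = _topo_cost(cand, n_leaves, carriers, known, weights)
            if cost < best_cost:
                best, best_cost = cand, cost
        topo = best
    return topo


def _nni_neighbours(topo):
    """Nearest-neighbour-interchange variants of a nested-tuple topology."""
    out = []

    def rec(t, path):
        if isinstance(t, int):
            return
        a, b = t
        # swap across the (a,b) edge where possible
        if not isinstance(a, int):
            a1, a2 = a
            out.append(_replace(topo, path, ((a1, b), a2)))
            out.append(_replace(topo, path, ((a2, b), a1)))
        if not isinstance(b, int):
            b1, b2 = b
            out.append(_replace(topo, path, (b2, (a, b1))))
            out.append(_replace(topo, path, (b1, (a, b2))))
        rec(a, path + (0,))
        rec(b, path + (1,))

    rec(topo, ())
    return out


def _replace(topo, path, new):
    if not path:
        return new
    a, b = topo
    if path[0] == 0:
        return (_replace(a, path[1:], new), b)
    return (a, _replace(b, path[1:], new))


def _search(n_leaves, carriers, known, weights, rng) -> tuple:
    order = [int(i) for i in rng.permutation(n_leaves)]
    topo = _stepwise_topo(n_leaves, order, carriers, known, weights)
    cost = _topo_cost(topo, n_leaves, carriers, known, weights)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbours(topo):
            c = _topo_cost(cand, n_leaves, carriers, known, weights)
            if c < cost - 1e-9:
                topo, cost = cand, c
                improved = True
                break
    return topo, cost


def _exhaustive_search(n_leaves, carriers, known, weights):
    """Score every rooted topology; the test oracle for <= 7 leaves."""
    if n_leaves > 7:
        raise ValueError("exhaustive search is limited to 7 leaves")
    topos = [0] if n_leaves == 1 else [(0, 1)]
    for leaf in range(2, n_leaves):
        topos = [t for topo in topos for t in _insertions(topo, leaf)]
    best, best_cost = None, np.inf
    for topo in topos:
        c = _topo_cost(topo, n_leaves, carriers, known, weights)
        if c < best_cost:
            best, best_cost = topo, c
    return best, best_cost


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def infer_tree(matrix: pd.DataFrame, n_bootstrap: int = 100,
               seed: int = 0, exhaustive: bool | None = None) -> PhyloTree:
    """Infer a rooted strain tree from a TEV presence/absence matrix.

    Characters (matrix rows) are scored under Dollo parsimony; tree search is
    stepwise addition followed by NNI hill climbing, or exhaustive enumeration
    for <= 7 strains.  With ``n_bootstrap > 0`` characters are resampled with
    replacement and the majority-rule consensus is returned with per-node
    supports on the 0-100 scale; with ``n_bootstrap = 0`` the single best tree
    is returned with supports unset.

    Raises ``ValueError`` if no character varies among the strains.
    """
    taxa = sorted(matrix.columns)
    if len(taxa) < 3:
        raise ValueError("need at least 3 strains")
    chars = _chars_from_matrix(matrix, taxa)
    informative = [
        (c, k) for c, k in chars if c != 0 and (k & ~c) != 0
    ]
    if not informative:
        raise ValueError("presence matrix carries no phylogenetic signal")
    if exhaustive is None:
        exhaustive = len(taxa) <= 7
    rng = np.random.default_rng(seed)
    n = len(taxa)

    # collapse identical presence patterns into weighted unique characters
    uniq: dict[tuple[int, int], int] = {}
    for ck in chars:
        uniq[ck] = uniq.get(ck, 0) + 1
    carriers = np.array([c for c, _ in uniq], dtype=np.int64)
    known = np.array([k for _, k in uniq], dtype=np.int64)
    base_w = np.array(list(uniq.values()), dtype=float)
    m = int(base_w.sum())

    def best_topo(weights, allow_exhaustive):
        if exhaustive and allow_exhaustive:
            topo, _ = _exhaustive_search(n, carriers, known, weights)
        else:
            topo, _ = _search(n, carriers, known, weights, rng)
        return topo

    point = _build_tree_from_parents(taxa, best_topo(base_w, True))
    if n_bootstrap <= 0:
        return point

    probs = base_w / m
    clade_hits: dict[int, int] = {}
    for _ in range(n_bootstrap):
        w = rng.multinomial(m, probs).astype(float)
        rep_topo = best_topo(w, False)  # heuristic inside replicates
        rep_masks, _ = _topo_arrays(rep_topo, n)
        full = (1 << n) - 1
        for mask in set(int(v) for v in rep_masks
                        if bin(int(v)).count("1") > 1 and int(v) != full):
            clade_hits[mask] = clade_hits.get(mask, 0) + 1

    # majority-rule consensus of replicate clades
    keep = {
        mask: 100.0 * hits / n_bootstrap
        for mask, hits in clade_hits.items()
        if hits / n_bootstrap > 0.5
    }
    return _consensus_from_clades(taxa, keep)


def _consensus_from_clades(taxa, clade_support: dict[int, float]) -> PhyloTree:
    full = (1 << len(taxa)) - 1
    masks = sorted(set(clade_support) | {full},
                   key=lambda m: -bin(m).count("1"))
    nodes: list[_Node] = []

    def build(mask, parent, members):
        nid = len(nodes)
        n = _Node(id=nid, parent=parent)
        if mask != full:
            n.support = clade_support.get(mask)
        nodes.append(n)
        inner = [m for m in masks if m != mask and m & mask == m]
        used = 0
        for m in inner:
            if m & used:
                continue
            cid = build(m, nid, m)
            nodes[nid].children.append(cid)
            used |= m
        for i in range(len(taxa)):
            bit = 1 << i
            if mask & bit and not used & bit:
                cid = len(nodes)
                nodes.append(_Node(id=cid, parent=nid, label=taxa[i]))
                nodes[nid].children.append(cid)
        return nid

    build(full, None, full)
    return PhyloTree(nodes, taxa)


def map_to_lca(presence_row, tree: PhyloTree) -> int:
    """Assign one TEV to the LCA node of its carrier strains.

    ``presence_row`` maps strain -> {0,1,NA}; NA strains do not vote.  A
    single-carrier TEV maps to that strain's terminal node (a private TEV).
    """
    carriers = [
        s for s, v in dict(presence_row).items()
        if not pd.isna(v) and int(v) == 1
    ]
    if not carriers:
        raise ValueError("TEV with zero carriers cannot be mapped")
    if len(carriers) == 1:
        for n in tree.leaves():
            if n.label == carriers[0]:
                return n.id
    return tree.lca(carriers)


def lineage_composition(assignments: dict[str, int],
                        records: pd.DataFrame) -> pd.DataFrame:
    """Per-branch TEV counts and proportions by class and ERV family.

    ``assignments`` maps tev_id -> node id; ``records`` must carry columns
    ``tev_id``, ``te_class`` and ``family``.  Proportions sum to 1 on every
    branch with at least one TEV; empty branches are absent from the output.
    """
    rec = records.set_index("tev_id")
    rows = []
    for tev, node in assignments.items():
        rows.append((node, rec.at[tev, "te_class"], rec.at[tev, "family"]))
    df = pd.DataFrame(rows, columns=["node", "te_class", "family"])
    out = []
    for node, grp in df.groupby("node"):
        n = len(grp)
        for cls, cnt in grp["te_class"].value_counts().items():
            out.append((node, "class", cls, int(cnt), cnt / n))
        erv = grp[grp["te_class"] == "ERV"]
        for fam, cnt in erv["family"].value_counts().items():
            out.append((node, "erv_family", fam, int(cnt),
                        cnt / len(erv)))
    return pd.DataFrame(
        out, columns=["node", "level", "label", "count", "proportion"])


def solo_ltr_fraction_by_node(assignments: dict[str, int],
                              records: pd.DataFrame) -> pd.Series:
    """Fraction of solo-LTR structures among ERV TEVs per tree node.

    Nodes without ERV TEVs are reported as NaN.  Feeds the solo-LTR
    half-life estimate downstream.
    """
    rec = records.set_index("tev_id")
    per_node: dict[int, list[int]] = {}
    for tev, node in assignments.items():
        if rec.at[tev, "te_class"] != "ERV":
            continue
        per_node.setdefault(node, []).append(
            1 if rec.at[tev, "structure"] == "solo_LTR" else 0)
    return pd.Series(
        {node: float(np.mean(v)) for node, v in per_node.items()},
        dtype=float,
    ).sort_index()
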