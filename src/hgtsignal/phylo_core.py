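"""Tree container, newick I/O, and the equal-rates Mk model.

This module is the numerical substrate for the delta phylogenetic-signal
statistic: a light rooted-tree class (polytomies allowed, bootstrap supports
carried as internal-node labels), Felsenstein pruning under the equal-rates
k-state Markov (Mk) model with a uniform root prior, maximum-likelihood rate
fitting, and marginal ancestral state reconstruction by up-down message
passing.

Newick reading/writing is delegated to dendropy; the wrapper enforces the
invariants the rest of the package relies on (unique non-empty tip labels,
finite non-negative branch lengths, a single root).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

#: The closed niche vocabulary used for trait tables in this package.
NICHE_CATEGORIES = (
    "Arthropod",
    "Plant",
    "Nematode",
    "Mammalian",
    "Aquatic",
    "Soil",
    "Other",
)

RATE_BOUNDS = (1e-8, 100.0)
RATE_XATOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed trees or trait tables."""


class ZeroLikelihoodError(ArithmeticError):
    """The tip configuration has probability zero under the model (e.g.
    conflicting states across zero-length branches)."""


@dataclass(eq=False)
class Node:
    """A node of a rooted tree.

    Tips have a unique non-empty ``label`` and no children; internal nodes
    have >= 2 children (polytomies allowed) and may carry a bootstrap
    ``support`` percentage in [0, 100] (``None`` = unknown, never 0).
    ``length`` is the branch length to the parent in substitutions/site
    (the root's length is ignored).
    """

    label: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: List["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class PhyloTree:
    """A rooted phylogeny with branch lengths and bootstrap supports."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # -- construction / validation ------------------------------------

    def validate(self) -> None:
        seen: set = set()
        for node in self.postorder():
            if node.is_tip:
                if not node.label:
                    raise TreeError("tip with empty label")
                if node.label in seen:
                    raise TreeError(f"duplicate tip label: {node.label!r}")
                seen.add(node.label)
            else:
                if len(node.children) < 2 and node is not self.root:
                    raise TreeError("internal node with a single child")
            if node is not self.root:
                if node.length is None or not math.isfinite(node.length):
                    raise TreeError(f"non-finite branch length at {node.label!r}")
                if node.length < 0:
                    raise TreeError(f"negative branch length: {node.length}")
            if node.support is not None and not (0 <= node.support <= 100):
                raise TreeError(f"support outside [0, 100]: {node.support}")
        if len(self.root.children) == 1 and not self.root.is_tip:
            raise TreeError("root with a single child")

    # -- traversal -----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_tip:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def tips(self) -> List[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> List[str]:
        return [n.label for n in self.tips()]

    def internal_nodes(self) -> List[Node]:
        return [n for n in self.postorder() if not n.is_tip]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(label=node.label, length=node.length, support=node.support)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root), validate=False)

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    def height(self) -> float:
        """Maximum root-to-tip path length."""
        depth = {self.root: 0.0}
        best = 0.0
        for node in self.preorder():
            if node is not self.root:
                depth[node] = depth[node.parent] + node.length
                if node.is_tip:
                    best = max(best, depth[node])
        return best

    def mrca(self, labels: Sequence[str]) -> Node:
        """Most recent common ancestor of the named tips."""
        want = set(labels)
        found = {}
        for node in self.postorder():
            if node.is_tip:
                found[node] = {node.label} & want
            else:
                found[node] = set().union(*(found[c] for c in node.children))
            if found[node] == want:
                return node
        raise TreeError(f"tips not on tree: {sorted(want)}")

    # -- I/O -----------------------------------------------------------

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_tips} tips>"


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        node = Node(label=None, length=float(length))
        if dnode.is_leaf():
            node.label = label
        else:
            # internal labels that parse as numbers in [0, 100] are bootstrap
            # supports; anything else is kept as a plain label
            if label is not None:
                try:
                    val = float(label)
                except ValueError:
                    node.label = label
                else:
                    if 0 <= val <= 100:
                        node.support = val
                    else:
                        node.label = label
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
        return node

    return PhyloTree(convert(dtree.seed_node))


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Internal-node labels that parse as numbers in [0, 100] are interpreted
    as bootstrap support percentages. Raises :class:`TreeError` on duplicate
    tip labels, unbalanced parentheses or negative branch lengths.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"malformed newick: {exc}") from exc
    return _from_dendropy(dtree)


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def _format_length(x: float) -> str:
    s = f"{x:.10g}"
    return s


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to newick; supports emitted as internal labels."""

    def fmt(node: Node, with_length: bool = True) -> str:
        if node.is_tip:
            label = node.label
            if any(c in label for c in "(),:; \t'"):
                label = "'" + label.replace("'", "''") + "'"
            core = label
        else:
            inner = ",".join(fmt(c) for c in node.children)
            tag = ""
            if node.support is not None:
                tag = _format_length(node.support)
            elif node.label:
                tag = node.label
            core = f"({inner}){tag}"
        if with_length and node.parent is not None:
            core += f":{_format_length(node.length)}"
        return core

    return fmt(tree.root) + ";"


def write_newick_file(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------
# Trait vectors
# ---------------------------------------------------------------------


def validate_traits(tree: PhyloTree, traits: Mapping[str, str]) -> None:
    """Check that a trait table covers exactly the tips of ``tree``."""
    tips = set(tree.tip_labels())
    dom = set(traits)
    if tips - dom:
        missing = sorted(tips - dom)[:5]
        raise TreeError(f"tips missing from trait table: {missing}")
    if dom - tips:
        extra = sorted(dom - tips)[:5]
        raise TreeError(f"trait table names unknown tips: {extra}")


def read_trait_tsv(path) -> Dict[str, str]:
    """Read a two-column ``tip_id<TAB>niche`` table (header optional)."""
    out: Dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TreeError(f"{path}:{i + 1}: expected 2 tab-separated columns")
            tip, cat = parts
            if i == 0 and tip.lower() in {"tip_id", "tip", "label"}:
                continue
            out[tip] = cat
    return out


def write_trait_tsv(traits: Mapping[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tip in traits:
            fh.write(f"{tip}\t{traits[tip]}\n")


def trait_states(traits: Mapping[str, str]) -> List[str]:
    """Sorted distinct categories observed in a trait table."""
    return sorted(set(traits.values()))


# ---------------------------------------------------------------------
# Equal-rates Mk model
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class MkModel:
    """Equal-rates k-state Markov model.

    Off-diagonal rate ``r`` for every ordered state pair; diagonal
    ``-(k-1) r``. Transition probabilities have the closed form

        P_same(t) = 1/k + (k-1)/k * exp(-k r t)
        P_diff(t) = 1/k -   1/k  * exp(-k r t)
    """

    k: int
    r: float

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("Mk model needs k >= 2 states")
        if not (self.r >= 0 and math.isfinite(self.r)):
            raise ValueError("rate must be finite and >= 0")

    def p_same(self, t: float) -> float:
        e = math.exp(-self.k * self.r * t)
        return 1.0 / self.k + (self.k - 1) / self.k * e

    def p_diff(self, t: float) -> float:
        e = math.exp(-self.k * self.r * t)
        return 1.0 / self.k - e / self.k


def mk_transition_matrix(r: float, t: float, k: int) -> np.ndarray:
    """k x k transition probability matrix of the equal-rates Mk model."""
    if not (math.isfinite(r) and math.isfinite(t)):
        raise ValueError("rate and time must be finite")
    if r < 0 or t < 0:
        raise ValueError("rate and time must be >= 0")
    model = MkModel(k=k, r=r)
    ps, pd = model.p_same(t), model.p_diff(t)
    mat = np.full((k, k), pd)
    np.fill_diagonal(mat, ps)
    return mat


class _FlatTree:
    """Postorder-indexed arrays for fast repeated pruning on one tree.

    Index convention: nodes numbered in postorder, tips first encountered in
    postorder keep their position; the root is the last index.
    """

    def __init__(self, tree: PhyloTree):
        self.nodes = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.lengths = np.array(
            [n.length if n.parent is not None else 0.0 for n in self.nodes]
        )
        self.is_tip = np.array([n.is_tip for n in self.nodes])
        self.children = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        self.tip_indices = {
            n.label: i for i, n in enumerate(self.nodes) if n.is_tip
        }
        self.root_index = len(self.nodes) - 1

    def tip_matrix(self, traits: Mapping[str, str], states: Sequence[str]) -> np.ndarray:
        k = len(states)
        state_index = {s: j for j, s in enumerate(states)}
        L = np.zeros((len(self.nodes), k))
        for label, i in self.tip_indices.items():
            try:
                L[i, state_index[traits[label]]] = 1.0
            except KeyError as exc:
                raise TreeError(f"tip {label!r} missing from trait table") from exc
        return L


def _edge_probs(flat: _FlatTree, r: float, k: int):
    """Per-edge (p_same - p_diff, p_diff) under the closed form."""
    e = np.exp(-k * r * flat.lengths)
    pd = (1.0 - e) / k
    coef = e  # p_same - p_diff = exp(-k r t)
    return coef, pd


def _upward(flat: _FlatTree, L_tips: np.ndarray, r: float, k: int):
    """Felsenstein pruning with per-node scaling.

    Returns (partials, up_messages, log_scale, log_likelihood) where
    ``up_messages[i]`` is M(t_i) @ partial_i, the message node i sends up
    its own edge.
    """
    coef, pd = _edge_probs(flat, r, k)
    partial = L_tips.copy()
    up = np.empty_like(partial)
    log_scale = 0.0
    for i, ch in enumerate(flat.children):
        if ch:
            prod = up[ch[0]].copy()
            for c in ch[1:]:
                prod *= up[c]
            s = prod.sum()
            if s <= 0 or not math.isfinite(s):
                raise ZeroLikelihoodError(
                    "tip states have probability zero under the model"
                )
            prod /= s
            log_scale += math.log(s)
            partial[i] = prod
        if i != flat.root_index:
            p = partial[i]
            up[i] = pd[i] * p.sum() + coef[i] * p
    root = partial[flat.root_index]
    lik = root.sum() / k
    return partial, up, log_scale, log_scale + math.log(lik)


def prune_log_likelihood(
    tree: PhyloTree, traits: Mapping[str, str], r: float
) -> float:
    """Log-likelihood of tip states under the equal-rates Mk model.

    Uses a uniform 1/k prior on the root state, where k is the number of
    distinct observed categories. Polytomies are handled natively.
    """
    if r < 0:
        raise ValueError("rate must be >= 0")
    validate_traits(tree, traits)
    states = trait_states(traits)
    if len(states) < 2:
        raise TreeError("constant trait: need >= 2 observed states")
    flat = _FlatTree(tree)
    L = flat.tip_matrix(traits, states)
    try:
        return _upward(flat, L, r, len(states))[3]
    except ZeroLikelihoodError:
        return -math.inf


def fit_rate(tree: PhyloTree, traits: Mapping[str, str]) -> float:
    """Maximum-likelihood transition rate of the equal-rates Mk model.

    Bounded scalar search on r in [1e-8, 100] to absolute tolerance 1e-6.
    Raises :class:`TreeError` for a constant trait, for which the rate (and
    hence delta) is undefined.
    """
    validate_traits(tree, traits)
    states = trait_states(traits)
    if len(states) < 2:
        raise TreeError(
            "constant trait (single observed state): phylogenetic signal "
            "(delta) is undefined; provide a trait with >= 2 categories"
        )
    flat = _FlatTree(tree)
    k = len(states)
    L = flat.tip_matrix(traits, states)

    def nll(r: float) -> float:
        try:
            return -_upward(flat, L, r, k)[3]
        except ZeroLikelihoodError:
            return math.inf

    res = minimize_scalar(
        nll, bounds=RATE_BOUNDS, method="bounded", options={"xatol": RATE_XATOL}
    )
    return float(res.x)


def marginal_ancestral(
    tree: PhyloTree, traits: Mapping[str, str], r: float
) -> Dict[int, np.ndarray]:
    """Marginal posterior state probabilities for every internal node.

    Up-down message passing under the equal-rates Mk model with a uniform
    root prior. Returns a mapping from internal-node postorder index to a
    probability vector over the sorted observed categories (each vector sums
    to 1). Postorder indices match :meth:`PhyloTree.postorder` over all
    nodes (tips included), so they are stable tree coordinates.
    """
    if r < 0:
        raise ValueError("rate must be >= 0")
    validate_traits(tree, traits)
    states = trait_states(traits)
    if len(states) < 2:
        raise TreeError("constant trait: need >= 2 observed states")
    k = len(states)
    flat = _FlatTree(tree)
    L = flat.tip_matrix(traits, states)
    partial, up, _, _ = _upward(flat, L, r, k)
    coef, pd = _edge_probs(flat, r, k)

    # downward messages: D[root] = uniform prior; for child c of v,
    # D[c] = M(t_c) @ (D[v] * prod_{siblings s} up[s])
    D = np.empty_like(partial)
    D[flat.root_index] = 1.0 / k
    out: Dict[int, np.ndarray] = {}
    for i in range(flat.root_index, -1, -1):  # preorder = reverse postorder
        ch = flat.children[i]
        if not ch:
            continue
        post = D[i] * partial[i]
        total = post.sum()
        out[i] = post / total
        for c in ch:
            sib = D[i].copy()
            for s in ch:
                if s != c:
                    sib *= up[s]
            msg = pd[c] * sib.sum() + coef[c] * sib
            m = msg.sum()
            D[c] = msg / m
    return out


def ancestral_state_table(
    tree: PhyloTree, traits: Mapping[str, str], r: float
) -> "np.ndarray":
    """Stacked marginal probabilities, one row per internal node."""
    anc = marginal_ancestral(tree, traits, r)
    return np.vstack([anc[i] for i in sorted(anc)])
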