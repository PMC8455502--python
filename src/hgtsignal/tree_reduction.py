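"""Display-tree collapse and congeneric-paralog trimming.

Two reductions of a gene tree:

* ``collapse_low_support`` contracts internal edges below a bootstrap
  threshold (default 50%) into polytomies, the usual preparation of a
  consensus tree for display.
* ``trim_to_hgt_only`` iteratively removes same-genus paralog tips so the
  remaining congeners reflect horizontal transfer rather than vertical
  descent: of a congeneric pair, one tip is dropped when the pair's MRCA is
  highly supported (rule A, default > 75%), or when one tip sits as a lone
  outgroup — no sister of its own — to the clade holding the other (rule
  B). Iteration continues until no congeneric sister pair remains. Trimming
  is blind to any trait data.

Genus grouping takes the first whitespace/underscore token of a binomial
label, except that tips of configured cecidomyiid species all collapse to
one pseudo-group "Cecidomyiidae" (transfers within the midge family are the
signal of interest, so the family is one unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

from .phylo_core import Node, PhyloTree, TreeError


@dataclass
class GenusMap:
    """Total mapping from tip label to genus group.

    ``pseudo_group_members`` lists species (by label or by genus token) that
    collapse into ``pseudo_group`` regardless of their own genus — e.g. all
    cecidomyiid tips grouped as "Cecidomyiidae".
    """

    explicit: Dict[str, str] = field(default_factory=dict)
    pseudo_group: str = "Cecidomyiidae"
    pseudo_group_members: Set[str] = field(default_factory=set)

    def group_of(self, tip_label: str) -> str:
        if tip_label in self.explicit:
            return self.explicit[tip_label]
        token = tip_label.replace("_", " ").split()[0]
        if tip_label in self.pseudo_group_members or token in self.pseudo_group_members:
            return self.pseudo_group
        return token

    def groups(self, labels: Sequence[str]) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for lbl in labels:
            out.setdefault(self.group_of(lbl), []).append(lbl)
        return out


def read_genus_tsv(path) -> GenusMap:
    """Read a ``tip_id<TAB>genus_group`` table into an explicit GenusMap."""
    explicit: Dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TreeError(f"{path}:{i + 1}: expected 2 columns")
            if i == 0 and parts[0].lower() in {"tip_id", "tip"}:
                continue
            explicit[parts[0]] = parts[1]
    return GenusMap(explicit=explicit)


# ---------------------------------------------------------------------
# Support collapse
# ---------------------------------------------------------------------


def collapse_low_support(tree: PhyloTree, threshold: float = 50.0) -> PhyloTree:
    """Contract internal edges whose child node has support < threshold.

    The children of a collapsed node are promoted to its parent (in place of
    the collapsed node, preserving order); the contracted edge's length is
    discarded and promoted children keep their own lengths. Nodes with
    absent support are left untouched (unknown is not zero). Idempotent.
    """
    out = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(out.postorder()):
            if node.is_tip or node.parent is None:
                continue
            if node.support is not None and node.support < threshold:
                parent = node.parent
                pos = parent.children.index(node)
                for c in node.children:
                    c.parent = parent
                parent.children[pos : pos + 1] = node.children
                changed = True
    out.validate()
    return out


# ---------------------------------------------------------------------
# Congeneric-paralog trimming
# ---------------------------------------------------------------------


def _drop_tip(tree: PhyloTree, label: str) -> None:
    """Remove a tip in place; a resulting single-child node is suppressed
    with its edge length added to the surviving child's."""
    tip = next(n for n in tree.postorder() if n.is_tip and n.label == label)
    parent = tip.parent
    if parent is None:
        raise TreeError("cannot drop the only node")
    parent.children.remove(tip)
    while parent is not None and len(parent.children) == 1 and not parent.is_tip:
        only = parent.children[0]
        grand = parent.parent
        if grand is None:
            # parent was the root: the surviving child becomes the root
            only.parent = None
            only.length = 0.0
            tree.root = only
        else:
            only.length += parent.length
            only.parent = grand
            grand.children[grand.children.index(parent)] = only
        parent = grand


def _lone_outgroup(tree: PhyloTree, tip_label: str, other_label: str) -> bool:
    """True if ``tip_label`` attaches as a lone child directly outside the
    clade containing ``other_label`` (it has no sister taxon of its own:
    its parent's other child subtrees jointly form the clade with the other
    tip, and the tip is the only other child)."""
    tip = next(n for n in tree.postorder() if n.is_tip and n.label == tip_label)
    parent = tip.parent
    if parent is None or len(parent.children) != 2:
        return False
    sibling = next(c for c in parent.children if c is not tip)
    # the sibling clade must contain the other congener
    stack = [sibling]
    while stack:
        n = stack.pop()
        if n.is_tip and n.label == other_label:
            return True
        stack.extend(n.children)
    return False


def trim_to_hgt_only(
    tree: PhyloTree,
    genera: GenusMap,
    support_threshold: float = 75.0,
) -> PhyloTree:
    """Iteratively remove congeneric paralog tips until none are sisters.

    Each pass visits genus groups and tip pairs in lexicographic order and
    applies rule A before rule B:

    * rule A — the pair's MRCA node has support strictly greater than
      ``support_threshold``: drop the lexicographically later tip (absent
      support does not exceed the threshold, so no removal);
    * rule B — one tip of the pair is a lone outgroup to the clade holding
      the other (no sister taxon of its own): drop the lone tip; for a
      sister pair of two tips both are lone, so the lexicographically later
      one is dropped.

    Passes repeat until a fixed point. The result never loses all tips of a
    group (removal needs a surviving partner) and is independent of any
    trait data.
    """
    out = tree.copy()
    for lbl in out.tip_labels():
        genera.group_of(lbl)  # raises on unmappable labels (empty label etc.)

    def one_removal() -> bool:
        labels = out.tip_labels()
        groups = genera.groups(labels)
        for group in sorted(g for g, members in groups.items() if len(members) >= 2):
            members = sorted(groups[group])
            # rule A over all pairs first, then rule B
            for x_i in range(len(members)):
                for y_i in range(x_i + 1, len(members)):
                    x, y = members[x_i], members[y_i]
                    mrca = out.mrca([x, y])
                    if mrca.support is not None and mrca.support > support_threshold:
                        _drop_tip(out, y)
                        return True
            for x_i in range(len(members)):
                for y_i in range(x_i + 1, len(members)):
                    x, y = members[x_i], members[y_i]
                    if _is_sister_pair(out, x, y):
                        _drop_tip(out, y)
                        return True
                    if _lone_outgroup(out, x, y):
                        _drop_tip(out, x)
                        return True
                    if _lone_outgroup(out, y, x):
                        _drop_tip(out, y)
                        return True
        return False

    while one_removal():
        pass
    out.validate()
    return out


def _is_sister_pair(tree: PhyloTree, a: str, b: str) -> bool:
    ta = next(n for n in tree.postorder() if n.is_tip and n.label == a)
    tb = next(n for n in tree.postorder() if n.is_tip and n.label == b)
    return ta.parent is tb.parent


def congeneric_sister_pairs(
    tree: PhyloTree, genera: GenusMap
) -> List[Tuple[str, str]]:
    """All sister tip pairs from the same genus group (empty after trimming)."""
    pairs: List[Tuple[str, str]] = []
    for node in tree.postorder():
        if node.is_tip:
            continue
        tips = sorted(c.label for c in node.children if c.is_tip)
        for i in range(len(tips)):
            for j in range(i + 1, len(tips)):
                if genera.group_of(tips[i]) == genera.group_of(tips[j]):
                    pairs.append((tips[i], tips[j]))
    return pairs
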