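"""Maximum-parsimony timing of horizontal acquisitions on a species tree.

Given presence/absence of each horizontally transferred gene across
species, plus two kinds of corroborating evidence — micro-synteny between
carrier pairs and whether the carriers' gene-tree sequences are
monophyletic — events are placed by three ordered rules:

1. synteny between carriers implies a single ancestral acquisition: one
   solid gain at the MRCA of the syntenic carriers (extended to every
   carrier inside that clade), with one loss per maximal non-carrier clade
   below the gain;
2. otherwise, if the carriers are resolved monophyletic in the gene tree, a
   single dashed gain at the carriers' MRCA with losses as needed (dashed:
   the gene tree alone cannot exclude several transfers from one donor
   lineage);
3. otherwise, one dashed gain on each carrier's terminal branch. At equal
   event counts and no synteny support, independent gains are preferred
   (rule 3), and when monophyly is simply unknown the scenario is flagged
   ambiguous rather than forced.

Solid ticks mean synteny-backed placements; dashed ticks mean the placement
rests on gene-tree evidence alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .phylo_core import Node, PhyloTree, TreeError


@dataclass
class GeneEvidence:
    """Evidence for one gene: carrier pairs with micro-synteny, and whether
    the carriers' sequences are monophyletic in the gene tree (True / False /
    None = unknown or untested)."""

    synteny_pairs: Set[Tuple[str, str]] = field(default_factory=set)
    carriers_monophyletic: Optional[bool] = None

    def normalized_pairs(self) -> Set[Tuple[str, str]]:
        return {tuple(sorted(p)) for p in self.synteny_pairs}


@dataclass
class Event:
    gene: str
    node_tips: Tuple[str, ...]  # clade identified by its tip set
    type: str  # "gain" | "loss"
    confidence: str  # "solid" | "dashed"


@dataclass
class AcquisitionScenario:
    gene: str
    events: List[Event]
    ambiguous: bool = False
    note: str = ""

    @property
    def n_gains(self) -> int:
        return sum(e.type == "gain" for e in self.events)

    @property
    def n_losses(self) -> int:
        return sum(e.type == "loss" for e in self.events)


def _clade_tips(node: Node) -> Tuple[str, ...]:
    tips = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_tip:
            tips.append(n.label)
        stack.extend(n.children)
    return tuple(sorted(tips))


def _max_noncarrier_clades(node: Node, carriers: Set[str]) -> List[Node]:
    """Maximal clades below ``node`` containing no carrier."""
    out: List[Node] = []

    def visit(n: Node) -> None:
        if not (set(_clade_tips(n)) & carriers):
            out.append(n)
            return
        for c in n.children:
            visit(c)

    for c in node.children:
        visit(c)
    return out


def infer_events(
    tree: PhyloTree,
    presence: Mapping[str, Mapping[str, int]],
    evidence: Mapping[str, GeneEvidence],
) -> Dict[str, AcquisitionScenario]:
    """Place gain/loss events for every gene in ``presence``.

    ``presence[gene][species]`` is the copy number on bona fide eukaryotic
    scaffolds (0 = absent); ``evidence[gene]`` may be omitted (treated as no
    synteny, monophyly unknown). Species named in the matrix must be tips of
    the species tree. A gene absent everywhere yields an empty event list.
    """
    tips = set(tree.tip_labels())
    scenarios: Dict[str, AcquisitionScenario] = {}
    for gene, row in presence.items():
        unknown = set(row) - tips
        if unknown:
            raise TreeError(f"species not on tree: {sorted(unknown)}")
        carriers = {sp for sp, n in row.items() if n > 0}
        ev = evidence.get(gene, GeneEvidence())
        bad = [p for p in ev.normalized_pairs() if not set(p) <= carriers]
        if bad:
            raise TreeError(f"synteny pair outside carrier set: {bad}")
        if not carriers:
            scenarios[gene] = AcquisitionScenario(gene=gene, events=[])
            continue
        syntenic: Set[str] = set()
        for a, b in ev.normalized_pairs():
            syntenic.update((a, b))

        events: List[Event] = []
        ambiguous = False
        note = ""
        if len(carriers) == 1:
            # single carrier: a terminal gain; synteny needs a pair, so the
            # placement rests on presence alone (dashed)
            (sp,) = carriers
            events.append(Event(gene, (sp,), "gain", "dashed"))
        elif syntenic:
            mrca = tree.mrca(sorted(syntenic))
            clade = set(_clade_tips(mrca))
            events.append(Event(gene, tuple(sorted(clade)), "gain", "solid"))
            for nc in _max_noncarrier_clades(mrca, carriers):
                events.append(Event(gene, _clade_tips(nc), "loss", "solid"))
            outside = carriers - clade
            if outside:
                # carriers outside the syntenic clade get their own gains
                for sp in sorted(outside):
                    events.append(Event(gene, (sp,), "gain", "dashed"))
        elif ev.carriers_monophyletic is True:
            mrca = tree.mrca(sorted(carriers))
            events.append(Event(gene, _clade_tips(mrca), "gain", "dashed"))
            for nc in _max_noncarrier_clades(mrca, carriers):
                events.append(Event(gene, _clade_tips(nc), "loss", "dashed"))
        else:
            for sp in sorted(carriers):
                events.append(Event(gene, (sp,), "gain", "dashed"))
            if ev.carriers_monophyletic is None:
                ambiguous = True
                note = (
                    "monophyly untested and no synteny: single ancestral "
                    "acquisition cannot be excluded"
                )
        scenarios[gene] = AcquisitionScenario(
            gene=gene, events=events, ambiguous=ambiguous, note=note
        )
    return scenarios


def implied_presence(
    tree: PhyloTree, scenario: AcquisitionScenario
) -> Dict[str, bool]:
    """Presence/absence per species implied by a scenario's events.

    A species carries the gene iff it lies inside at least one gain clade
    and inside no loss clade placed under that gain.
    """
    gains = [set(e.node_tips) for e in scenario.events if e.type == "gain"]
    losses = [set(e.node_tips) for e in scenario.events if e.type == "loss"]
    out = {}
    for sp in tree.tip_labels():
        has = any(sp in g for g in gains) and not any(sp in l for l in losses)
        out[sp] = has
    return out


def scenario_table(scenarios: Mapping[str, AcquisitionScenario]) -> pd.DataFrame:
    rows = []
    for gene in sorted(scenarios):
        sc = scenarios[gene]
        for e in sc.events:
            rows.append(
                {
                    "gene": gene,
                    "event": e.type,
                    "clade": "|".join(e.node_tips),
                    "confidence": e.confidence,
                    "ambiguous": sc.ambiguous,
                }
            )
        if not sc.events:
            rows.append(
                {"gene": gene, "event": "none", "clade": "", "confidence": "",
                 "ambiguous": False}
            )
    return pd.DataFrame(rows)


def annotate_tree_with_events(
    tree: PhyloTree, scenarios: Mapping[str, AcquisitionScenario]
) -> str:
    """Newick with per-node comment annotations listing tick marks.

    Each gain/loss is rendered as ``[&gene=...,event=gain,conf=solid]`` on
    the branch subtending the event's clade.
    """
    marks: Dict[Tuple[str, ...], List[str]] = {}
    for gene in sorted(scenarios):
        for e in scenarios[gene].events:
            marks.setdefault(e.node_tips, []).append(
                f"{e.gene}:{e.type}:{e.confidence}"
            )

    def fmt(node: Node) -> str:
        if node.is_tip:
            core = node.label
            key = (node.label,)
        else:
            core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.support is not None:
                core += f"{node.support:g}"
            key = _clade_tips(node)
        if key in marks:
            core += "[&" + ",".join(marks[key]) + "]"
        if node.parent is not None:
            core += f":{node.length:g}"
        return core

    return fmt(tree.root) + ";"


def enumerate_min_events(
    tree: PhyloTree, carriers: Set[str], single_gain: bool
) -> int:
    """Brute-force minimal event count over gain/loss labelings (oracle).

    Counts the minimum number of events needed to explain the carrier set
    when either (a) one gain at some node with losses below it
    (``single_gain``), or (b) independent terminal gains, is permitted.
    Intended for small (e.g. 5-taxon) trees in tests.
    """
    if not single_gain:
        return len(carriers)
    best = None
    for node in tree.postorder():
        clade = set(_clade_tips(node))
        if not carriers <= clade:
            continue
        losses = _max_noncarrier_clades(node, carriers)
        count = 1 + len(losses)
        if best is None or count < best:
            best = count
    return best if best is not None else len(carriers)
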