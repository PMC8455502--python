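"""Generators with known ground truth for every pipeline stage.

Three families of generators:

* Yule (pure-birth) trees with exponential waiting times, rescaled to unit
  height so simulated trait rates are comparable across replicates.
* Categorical traits evolved along a tree under the equal-rates Mk process
  (exact simulation: one transition-matrix draw per branch), with the rate
  acting as a signal-strength dial (low rate = strong phylogenetic signal).
* Genome-screening fixtures: tabular homology hits, scaffold/gene records,
  nucleotide sequences, and a read-depth table, with planted horizontally
  transferred genes (long scaffolds, eukaryotic neighbors, ordinary depth,
  introns, no Shine-Dalgarno motif) and planted contaminant-style records
  engineered so every stage of the screening cascade fires on at least one
  record.

Also houses the exhaustive-enumeration oracles (likelihood and marginal
posteriors) used to verify the pruning implementation on small trees.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .phylo_core import (
    NICHE_CATEGORIES,
    Node,
    PhyloTree,
    mk_transition_matrix,
    trait_states,
    validate_traits,
)
from .hgt_screen import BlastHit, Gene, ScaffoldRecord


# ---------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------


def simulate_yule(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    rescale_height: Optional[float] = 1.0,
) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_tips`` tips.

    Waiting times between birth events are exponential with rate
    ``birth_rate * n_lineages``; the lineage that splits is uniform. By
    default the tree is rescaled to height 1 (delta is invariant to overall
    scale once the Mk rate is refit, so units are arbitrary); pass
    ``rescale_height=None`` to keep raw time units.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    rng = np.random.default_rng(seed)
    root = Node()
    active: List[Node] = []
    for _ in range(2):
        active.append(root.add_child(Node(length=0.0)))
    while len(active) < n_tips:
        dt = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.length += dt
        i = rng.integers(len(active))
        parent = active.pop(int(i))
        for _ in range(2):
            active.append(parent.add_child(Node(length=0.0)))
    dt = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length += dt
    # deterministic tip naming in birth order
    for j, node in enumerate(active):
        node.label = f"t{j + 1}"
    tree = PhyloTree(root)
    if rescale_height is not None:
        h = tree.height()
        if h > 0:
            f = rescale_height / h
            for node in tree.postorder():
                if node is not tree.root:
                    node.length *= f
    return tree


def simulate_mk_trait(
    tree: PhyloTree,
    k: int,
    rate: float,
    seed: int = 0,
    root_state: Optional[int] = None,
    categories: Sequence[str] = NICHE_CATEGORIES,
) -> Dict[str, str]:
    """Evolve a k-state trait along ``tree`` under the equal-rates Mk model.

    Exact simulation: the state at each node is drawn from the closed-form
    transition matrix over the connecting branch. Root state is uniform
    unless ``root_state`` fixes it. States are reported using the first
    ``k`` niche ``categories`` so outputs look like real trait tables.
    """
    if k < 2 or k > len(categories):
        raise ValueError(f"k must be in [2, {len(categories)}]")
    rng = np.random.default_rng(seed)
    state: Dict[int, int] = {}
    if root_state is None:
        state[id(tree.root)] = int(rng.integers(k))
    else:
        state[id(tree.root)] = int(root_state)
    out: Dict[str, str] = {}
    for node in tree.preorder():
        if node is tree.root:
            pass
        else:
            P = mk_transition_matrix(rate, node.length, k)
            prev = state[id(node.parent)]
            state[id(node)] = int(rng.choice(k, p=P[prev]))
        if node.is_tip:
            out[node.label] = categories[state[id(node)]]
    return out


def expected_changes_rate(tree: PhyloTree, k: int, n_changes: float) -> float:
    """Mk rate giving an expected ``n_changes`` state changes on ``tree``.

    Total flux out of a state is (k-1) * r, so the expected number of
    changes is (k-1) * r * total branch length.
    """
    total = tree.total_length()
    return n_changes / ((k - 1) * total)


def conserved_trait_rate(tree: PhyloTree, k: int, changes_per_lineage: float) -> float:
    """Mk rate for a conserved ("strong-signal") trait.

    Sets the expected number of state changes along a root-to-tip lineage:
    (k-1) * r * height = changes_per_lineage. At <= 2 expected changes per
    lineage the trait stays phylogenetically clustered (neighboring tips
    share states) while remaining variable enough to carry signal; spreading
    the same budget over the whole tree instead mostly yields
    single-deviant-tip traits that no signal statistic can distinguish from
    their shuffles.
    """
    h = tree.height()
    return changes_per_lineage / ((k - 1) * h)


# ---------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------


def brute_force_likelihood(
    tree: PhyloTree, traits: Mapping[str, str], r: float
) -> float:
    """Exhaustive-enumeration Mk log-likelihood (test oracle).

    Sums over all k^(#internal) assignments of states to internal nodes,
    with a uniform root prior. Guarded to trees with <= 8 internal nodes.
    """
    validate_traits(tree, traits)
    states = trait_states(traits)
    k = len(states)
    if k < 2:
        raise ValueError("need >= 2 observed states")
    internals = tree.internal_nodes()
    if len(internals) > 8:
        raise ValueError("brute force guarded to <= 8 internal nodes")
    sidx = {s: j for j, s in enumerate(states)}
    tip_state = {id(n): sidx[traits[n.label]] for n in tree.tips()}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        amap.update(tip_state)
        p = 1.0 / k
        for node in tree.postorder():
            if node is tree.root:
                continue
            P = mk_transition_matrix(r, node.length, k)
            p *= P[amap[id(node.parent)], amap[id(node)]]
        total += p
    return math.log(total)


def brute_force_marginals(
    tree: PhyloTree, traits: Mapping[str, str], r: float
) -> Dict[int, np.ndarray]:
    """Marginal internal-node posteriors by enumerating the joint (oracle).

    Keys are postorder node indices, matching
    :func:`hgtsignal.phylo_core.marginal_ancestral`.
    """
    validate_traits(tree, traits)
    states = trait_states(traits)
    k = len(states)
    internals = tree.internal_nodes()
    if len(internals) > 8:
        raise ValueError("brute force guarded to <= 8 internal nodes")
    sidx = {s: j for j, s in enumerate(states)}
    tip_state = {id(n): sidx[traits[n.label]] for n in tree.tips()}
    postorder = list(tree.postorder())
    node_pos = {id(n): i for i, n in enumerate(postorder)}
    acc = {node_pos[id(n)]: np.zeros(k) for n in internals}
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        amap.update(tip_state)
        p = 1.0 / k
        for node in postorder:
            if node is tree.root:
                continue
            P = mk_transition_matrix(r, node.length, k)
            p *= P[amap[id(node.parent)], amap[id(node)]]
        for n, s in zip(internals, assign):
            acc[node_pos[id(n)]][s] += p
    for i in acc:
        acc[i] /= acc[i].sum()
    return acc


def random_tree(
    n_tips: int,
    seed: int,
    max_length: float = 2.0,
    polytomy_prob: float = 0.2,
) -> PhyloTree:
    """Random rooted tree with branch lengths in (0, max_length].

    Built by successive random attachment; with probability
    ``polytomy_prob`` a new tip is attached to an existing internal node
    (creating/extending a polytomy) instead of subdividing an edge.
    """
    rng = np.random.default_rng(seed)

    def blen() -> float:
        return float(rng.uniform(1e-3, max_length))

    root = Node()
    root.add_child(Node(label="s1", length=blen()))
    root.add_child(Node(label="s2", length=blen()))
    for i in range(3, n_tips + 1):
        tree_nodes = [n for n in PhyloTree(root, validate=False).postorder()]
        internals = [n for n in tree_nodes if not n.is_tip]
        if rng.random() < polytomy_prob:
            host = internals[int(rng.integers(len(internals)))]
            host.add_child(Node(label=f"s{i}", length=blen()))
        else:
            cands = [n for n in tree_nodes if n.parent is not None]
            edge_child = cands[int(rng.integers(len(cands)))]
            parent = edge_child.parent
            mid = Node(length=blen())
            pos = parent.children.index(edge_child)
            parent.children[pos] = mid
            mid.parent = parent
            mid.add_child(edge_child)
            mid.add_child(Node(label=f"s{i}", length=blen()))
    return PhyloTree(root)


# ---------------------------------------------------------------------
# Screening fixtures
# ---------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Knobs for the screening-fixture generator.

    Defaults are chosen to look like a midge-genome screen: true
    horizontally transferred genes sit on multi-kilobase scaffolds next to
    bona fide eukaryotic genes at ordinary read depth; contaminant-style
    records are planted so that each stage of the filter cascade removes at
    least one record.
    """

    n_tips: int = 40
    birth_rate: float = 1.0
    k: int = 4
    trait_rate: float = 0.5
    seed: int = 0
    n_true_htg: int = 12
    n_contaminants: int = 8
    n_background_scaffolds: int = 30
    scaffold_length_mean_bp: float = 200_000.0
    contaminant_scaffold_bp: int = 800
    depth_mean: float = 50.0
    depth_sd: float = 5.0
    contaminant_depth_factor: float = 10.0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k >= 2 required")
        for name in (
            "n_tips",
            "birth_rate",
            "trait_rate",
            "scaffold_length_mean_bp",
            "depth_mean",
            "depth_sd",
            "contaminant_depth_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FixtureTruth:
    """Ground truth for a generated screening fixture."""

    planted_htg_ids: List[str]
    planted_contaminant_ids: List[str]
    expected_verdicts: Dict[str, str]

    def __post_init__(self):
        overlap = set(self.planted_htg_ids) & set(self.planted_contaminant_ids)
        if overlap:
            raise ValueError(f"planted sets overlap: {sorted(overlap)}")


SD_MOTIF = "AGGAGG"

#: 1-based position of the start codon in every fixture sequence window.
#: Fixture sequences are ORF-centered upstream windows (60 nt of upstream
#: context, then the start codon), keyed by candidate id.
ORF_START_IN_WINDOW = 61

# cascade stages a planted contaminant-style record can fail, cycled so the
# default 8 contaminants cover all seven removal stages at least once
_FAIL_STAGES = (
    "evalue",
    "insect-tophit",
    "hsp-length",
    "redundancy",
    "scaffold-length",
    "canonical-fraction",
    "no-euk-scaffold",
    "scaffold-length",
)

_DONOR_PROTEINS = ("aip56", "cdtB", "lysozyme", "rhs", "sltxB")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def generate_screen_fixture(config: SimulationConfig):
    """Generate (hits, scaffolds, sequences, depths, truth) for the screen.

    * true records: unique coordinates on long scaffolds carrying >= 1 bona
      fide eukaryotic neighbor gene, genome-typical read depth, 0-3 introns,
      no Shine-Dalgarno motif upstream of the gene start;
    * contaminant-style records: each engineered to fail one specific
      cascade stage (E-value above threshold, canonical-insect top hits,
      short alignment, redundant duplicate, sub-kilobase scaffold, fraction
      of canonical length below 10%, or a 2-9 kb scaffold with no
      eukaryotic gene); contaminant scaffolds get inflated read depth and a
      planted AGGAGG motif upstream of the gene start.

    Returns hits (list of BlastHit), scaffolds (dict id -> ScaffoldRecord),
    sequences (dict candidate id -> ORF-centered upstream window, start
    codon at :data:`ORF_START_IN_WINDOW`), depths (dict scaffold id -> mean
    depth),
    insect_tophits (dict hit id -> count), canonical lengths
    (dict query id -> aa length), and a FixtureTruth.
    """
    rng = np.random.default_rng(config.seed)
    hits: List[BlastHit] = []
    scaffolds: Dict[str, ScaffoldRecord] = {}
    sequences: Dict[str, str] = {}
    depths: Dict[str, float] = {}
    insect_tophits: Dict[str, int] = {}
    # canonical proteins > 500 aa so a >= 50 aa fragment can still fall
    # below 10% of canonical length (the stage-6 contrast)
    canonical: Dict[str, int] = {q: int(rng.integers(550, 900)) for q in _DONOR_PROTEINS}
    truth = FixtureTruth([], [], {})

    def normal_depth() -> float:
        return float(rng.normal(config.depth_mean, config.depth_sd))

    for b in range(config.n_background_scaffolds):
        sid = f"bg_scaffold_{b + 1}"
        length = int(rng.exponential(config.scaffold_length_mean_bp)) + 20_000
        scaffolds[sid] = ScaffoldRecord(
            scaffold_id=sid,
            length_bp=length,
            mean_read_depth=normal_depth(),
            genes=[
                Gene(
                    gene_id=f"{sid}_g1",
                    start=1000,
                    end=3000,
                    strand="+",
                    is_bona_fide_eukaryotic=True,
                    intron_count=int(rng.integers(0, 5)),
                    transcribed=True,
                )
            ],
        )
        depths[sid] = scaffolds[sid].mean_read_depth

    # --- true horizontally transferred genes -------------------------
    for i in range(config.n_true_htg):
        sid = f"htg_scaffold_{i + 1}"
        length = int(rng.exponential(config.scaffold_length_mean_bp)) + 50_000
        query = _DONOR_PROTEINS[i % len(_DONOR_PROTEINS)]
        gene_start = int(rng.integers(5_000, 20_000))
        aa_len = int(canonical[query] * rng.uniform(0.5, 1.0))
        gene_end = gene_start + aa_len * 3 - 1
        hid = f"true_{i + 1}"
        genes = [
            Gene(
                gene_id=f"{sid}_euk1",
                start=max(1, gene_start - 4_000),
                end=gene_start - 1_000,
                strand="+",
                is_bona_fide_eukaryotic=True,
                intron_count=int(rng.integers(1, 6)),
                transcribed=True,
            ),
            Gene(
                gene_id=hid,
                start=gene_start,
                end=gene_end,
                strand="+",
                is_bona_fide_eukaryotic=False,
                intron_count=int(rng.integers(0, 4)),
                transcribed=bool(rng.random() < 0.8),
            ),
        ]
        scaffolds[sid] = ScaffoldRecord(
            scaffold_id=sid,
            length_bp=length,
            mean_read_depth=normal_depth(),
            genes=genes,
        )
        depths[sid] = scaffolds[sid].mean_read_depth
        # upstream window with a pyrimidine-only ribosome-binding region, so
        # no motif within one mismatch of AGGAGG can occur where it matters
        up = _random_seq(rng, 45) + "".join(rng.choice(list("CT"), size=15))
        sequences[hid] = up + "ATG" + _random_seq(rng, 30)
        hits.append(
            BlastHit(
                hit_id=hid,
                query_id=query,
                donor_strain=f"APSE-{1 + i % 3}",
                subject_scaffold=sid,
                subject_start=gene_start,
                subject_end=gene_end,
                frame=1,
                evalue=float(10.0 ** rng.uniform(-40, -5)),
                hsp_len_aa=aa_len,
                pct_identity=float(rng.uniform(40, 80)),
                bitscore=float(rng.uniform(100, 400)),
            )
        )
        insect_tophits[hid] = 0
        truth.planted_htg_ids.append(hid)
        truth.expected_verdicts[hid] = "retained"

    # --- contaminant-style records ------------------------------------
    for j in range(config.n_contaminants):
        stage = _FAIL_STAGES[j % len(_FAIL_STAGES)]
        hid = f"cont_{j + 1}"
        query = _DONOR_PROTEINS[j % len(_DONOR_PROTEINS)]
        if stage == "redundancy":
            # same gene hit again from a different donor strain at the same
            # coordinates as a retained true record: removed as redundant
            target = hits[j % config.n_true_htg]
            hits.append(
                BlastHit(
                    hit_id=hid,
                    query_id=target.query_id,
                    donor_strain="APSE-7",
                    subject_scaffold=target.subject_scaffold,
                    subject_start=target.subject_start,
                    subject_end=target.subject_end,
                    frame=target.frame,
                    evalue=target.evalue * 10,
                    hsp_len_aa=target.hsp_len_aa,
                    pct_identity=target.pct_identity,
                    bitscore=target.bitscore - 5,
                )
            )
            insect_tophits[hid] = 0
            truth.planted_contaminant_ids.append(hid)
            truth.expected_verdicts[hid] = "removed:redundancy"
            continue

        sid = f"cont_scaffold_{j + 1}"
        if stage == "scaffold-length":
            length = config.contaminant_scaffold_bp  # < 1 kb
            genes = []
        elif stage == "no-euk-scaffold":
            length = int(rng.integers(2_000, 9_000))  # < 10 kb, no euk gene
            genes = []
        else:
            length = int(rng.integers(30_000, 80_000))
            genes = [
                Gene(
                    gene_id=f"{sid}_euk1",
                    start=100,
                    end=600,
                    strand="+",
                    is_bona_fide_eukaryotic=True,
                    intron_count=1,
                    transcribed=True,
                )
            ]
        gene_start = int(rng.integers(200, max(300, length // 4)))
        if stage == "hsp-length":
            aa_len = int(rng.integers(15, 49))
        elif stage == "canonical-fraction":
            aa_len = max(50, int(canonical[query] * 0.05))
        else:
            aa_len = int(canonical[query] * rng.uniform(0.4, 0.9))
        gene_end = min(length, gene_start + aa_len * 3 - 1)
        genes.append(
            Gene(
                gene_id=hid,
                start=gene_start,
                end=gene_end,
                strand="+",
                is_bona_fide_eukaryotic=False,
                intron_count=0,
                transcribed=False,
            )
        )
        scaffolds[sid] = ScaffoldRecord(
            scaffold_id=sid,
            length_bp=length,
            mean_read_depth=normal_depth() * config.contaminant_depth_factor,
            genes=genes,
        )
        depths[sid] = scaffolds[sid].mean_read_depth
        # plant the ribosome-binding motif 8 nt upstream of the start codon
        up = _random_seq(rng, 46) + SD_MOTIF + _random_seq(rng, 8)
        sequences[hid] = up + "ATG" + _random_seq(rng, 30)
        hits.append(
            BlastHit(
                hit_id=hid,
                query_id=query,
                donor_strain=f"APSE-{1 + j % 3}",
                subject_scaffold=sid,
                subject_start=gene_start,
                subject_end=gene_end,
                frame=1,
                evalue=0.5 if stage == "evalue" else float(10.0 ** rng.uniform(-30, -5)),
                hsp_len_aa=aa_len,
                pct_identity=float(rng.uniform(40, 80)),
                bitscore=float(rng.uniform(50, 200)),
            )
        )
        insect_tophits[hid] = 3 if stage == "insect-tophit" else 0
        truth.planted_contaminant_ids.append(hid)
        truth.expected_verdicts[hid] = f"removed:{stage}"

    return hits, scaffolds, sequences, depths, insect_tophits, canonical, truth
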