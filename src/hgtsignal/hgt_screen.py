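"""HGT-candidate screening and contamination triage.

Implements the filter cascade used to separate genuine horizontally
transferred genes (HTGs) from microbial contamination in draft genome
assemblies, working entirely from offline tabular inputs:

1. E-value threshold on translated-search hits;
2. exclusion of hits whose top database matches are canonical insect genes
   (consumed as a precomputed count, keeping the package offline);
3. minimum aligned length (50 aa);
4. redundancy collapse (same gene recovered from several donor strains at
   the same genomic coordinates);
5. sub-kilobase scaffolds (classic contaminant real estate);
6. fragments under 10% of the canonical protein length;
7. scaffolds under 10 kb with no bona fide eukaryotic gene.

Every input hit gets one ledger row with a per-stage pass/fail/NA outcome
and a final verdict, mirroring the shape of a published screening table.
Separate QC operations cover duplicate-vs-misassembly classification,
Grubbs read-depth outlier testing, Shine-Dalgarno motif scanning, and
micro-synteny evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

CASCADE_STAGES = (
    "evalue",
    "insect-tophit",
    "hsp-length",
    "redundancy",
    "scaffold-length",
    "canonical-fraction",
    "no-euk-scaffold",
)

ANNOTATION_COLUMNS = ("depth-outlier", "shine-dalgarno", "introns", "transcribed")


class ScreenError(ValueError):
    pass


@dataclass
class BlastHit:
    """One translated-homology hit (tabular, 1-based inclusive coordinates)."""

    query_id: str
    donor_strain: str
    subject_scaffold: str
    subject_start: int
    subject_end: int
    frame: int
    evalue: float
    hsp_len_aa: int
    pct_identity: float
    bitscore: float
    hit_id: Optional[str] = None

    def __post_init__(self):
        if self.subject_start > self.subject_end:
            self.subject_start, self.subject_end = self.subject_end, self.subject_start
        if self.evalue < 0:
            raise ScreenError("negative E-value")
        if self.hit_id is None:
            self.hit_id = (
                f"{self.query_id}@{self.subject_scaffold}:"
                f"{self.subject_start}-{self.subject_end}/{self.donor_strain}"
            )


@dataclass
class Gene:
    gene_id: str
    start: int
    end: int
    strand: str = "+"
    is_bona_fide_eukaryotic: bool = False
    intron_count: Optional[int] = None
    transcribed: Optional[bool] = None


@dataclass
class ScaffoldRecord:
    scaffold_id: str
    length_bp: int
    mean_read_depth: Optional[float] = None
    genes: List[Gene] = field(default_factory=list)

    def __post_init__(self):
        for g in self.genes:
            if not (1 <= g.start <= g.end <= self.length_bp):
                raise ScreenError(
                    f"gene {g.gene_id} coordinates outside scaffold "
                    f"{self.scaffold_id} [1, {self.length_bp}]"
                )

    def has_eukaryotic_gene(self, excluding: Optional[str] = None) -> bool:
        return any(
            g.is_bona_fide_eukaryotic and g.gene_id != excluding for g in self.genes
        )


@dataclass
class ScreenParams:
    """Thresholds of the screening cascade (defaults: the published screen)."""

    evalue_max: float = 0.01
    min_hsp_aa: int = 50
    min_scaffold_bp: int = 1000
    min_fraction_of_canonical: float = 0.10
    min_scaffold_no_euk_bp: int = 10000
    identity_threshold: float = 0.90
    grubbs_alpha: float = 0.05
    insect_tophit_count: int = 2

    def __post_init__(self):
        for name in (
            "evalue_max",
            "min_hsp_aa",
            "min_scaffold_bp",
            "min_scaffold_no_euk_bp",
            "grubbs_alpha",
            "insect_tophit_count",
        ):
            if getattr(self, name) <= 0:
                raise ScreenError(f"{name} must be positive")
        for name in ("min_fraction_of_canonical", "identity_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ScreenError(f"{name} must be in (0, 1]")


# ---------------------------------------------------------------------
# Redundancy collapse
# ---------------------------------------------------------------------


def _reciprocal_overlap(a: BlastHit, b: BlastHit) -> float:
    lo = max(a.subject_start, b.subject_start)
    hi = min(a.subject_end, b.subject_end)
    if hi < lo:
        return 0.0
    inter = hi - lo + 1
    la = a.subject_end - a.subject_start + 1
    lb = b.subject_end - b.subject_start + 1
    return min(inter / la, inter / lb)


def dedupe_redundant(
    hits: Sequence[BlastHit], min_overlap: float = 0.5
) -> Tuple[List[BlastHit], Dict[str, str]]:
    """Collapse hits mapping to the same genomic coordinates.

    Hits on the same scaffold with reciprocal coordinate overlap >=
    ``min_overlap`` are grouped by single linkage; one representative per
    group is kept (lowest E-value, then highest bitscore, then
    lexicographically smallest query id). Returns the kept hits in input
    order and a mapping hit_id -> representative hit_id.
    """
    n = len(hits)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_scaffold: Dict[str, List[int]] = {}
    for i, h in enumerate(hits):
        by_scaffold.setdefault(h.subject_scaffold, []).append(i)
    for idxs in by_scaffold.values():
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1 :]:
                if _reciprocal_overlap(hits[i], hits[j]) >= min_overlap:
                    union(i, j)

    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    rep_of: Dict[str, str] = {}
    keep: set = set()
    for members in groups.values():
        rep = min(
            members,
            key=lambda i: (hits[i].evalue, -hits[i].bitscore, hits[i].query_id),
        )
        keep.add(rep)
        for i in members:
            rep_of[hits[i].hit_id] = hits[rep].hit_id
    return [h for i, h in enumerate(hits) if i in keep], rep_of


# ---------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------


def filter_hits(
    hits: Sequence[BlastHit],
    scaffolds: Mapping[str, ScaffoldRecord],
    canonical_lengths: Mapping[str, int],
    insect_tophits: Mapping[str, int],
    params: Optional[ScreenParams] = None,
) -> Tuple[List[BlastHit], pd.DataFrame]:
    """Run the screening cascade; return retained hits and the full ledger.

    The ledger has one row per input hit: per-stage outcomes (``pass`` /
    ``fail`` / ``NA`` for stages after the first failure or inapplicable
    checks) and a final ``verdict`` (``retained`` or ``removed:<stage>``).
    A hit with no canonical-length entry gets outcome NA at the
    canonical-fraction stage and is retained through it (with a warning
    column set).
    """
    params = params or ScreenParams()
    for h in hits:
        if h.subject_scaffold not in scaffolds:
            raise ScreenError(f"hit {h.hit_id} references unknown scaffold "
                              f"{h.subject_scaffold!r}")

    rows: Dict[str, Dict[str, object]] = {}
    for h in hits:
        rows[h.hit_id] = {
            "candidate_id": h.hit_id,
            "query_id": h.query_id,
            "scaffold_id": h.subject_scaffold,
            **{s: "NA" for s in CASCADE_STAGES},
            "warning": "",
            "verdict": None,
        }

    def fail(h: BlastHit, stage: str) -> None:
        rows[h.hit_id][stage] = "fail"
        rows[h.hit_id]["verdict"] = f"removed:{stage}"

    survivors: List[BlastHit] = []
    for h in hits:
        ok = h.evalue < params.evalue_max
        rows[h.hit_id]["evalue"] = "pass" if ok else "fail"
        if not ok:
            fail(h, "evalue")
            continue
        n_insect = insect_tophits.get(h.hit_id, 0)
        ok = n_insect < params.insect_tophit_count
        rows[h.hit_id]["insect-tophit"] = "pass" if ok else "fail"
        if not ok:
            fail(h, "insect-tophit")
            continue
        ok = h.hsp_len_aa >= params.min_hsp_aa
        rows[h.hit_id]["hsp-length"] = "pass" if ok else "fail"
        if not ok:
            fail(h, "hsp-length")
            continue
        survivors.append(h)

    kept, _rep = dedupe_redundant(survivors)
    kept_ids = {h.hit_id for h in kept}
    stage5in: List[BlastHit] = []
    for h in survivors:
        if h.hit_id in kept_ids:
            rows[h.hit_id]["redundancy"] = "pass"
            stage5in.append(h)
        else:
            fail(h, "redundancy")

    retained: List[BlastHit] = []
    for h in stage5in:
        scaf = scaffolds[h.subject_scaffold]
        ok = scaf.length_bp >= params.min_scaffold_bp
        rows[h.hit_id]["scaffold-length"] = "pass" if ok else "fail"
        if not ok:
            fail(h, "scaffold-length")
            continue
        canon = canonical_lengths.get(h.query_id)
        if canon is None:
            rows[h.hit_id]["canonical-fraction"] = "NA"
            rows[h.hit_id]["warning"] = "no canonical length for query"
        else:
            ok = h.hsp_len_aa >= params.min_fraction_of_canonical * canon
            rows[h.hit_id]["canonical-fraction"] = "pass" if ok else "fail"
            if not ok:
                fail(h, "canonical-fraction")
                continue
        small_and_bare = (
            scaf.length_bp < params.min_scaffold_no_euk_bp
            and not scaf.has_eukaryotic_gene(excluding=h.hit_id)
        )
        rows[h.hit_id]["no-euk-scaffold"] = "fail" if small_and_bare else "pass"
        if small_and_bare:
            fail(h, "no-euk-scaffold")
            continue
        rows[h.hit_id]["verdict"] = "retained"
        retained.append(h)

    ledger = pd.DataFrame([rows[h.hit_id] for h in hits])
    return retained, ledger


def annotate_ledger(
    ledger: pd.DataFrame,
    scaffolds: Mapping[str, ScaffoldRecord],
    depth_outlier_scaffolds: Iterable[str] = (),
    shine_dalgarno: Optional[Mapping[str, bool]] = None,
) -> pd.DataFrame:
    """Add the evidence columns (depth outlier, Shine-Dalgarno, introns,
    transcription) to a cascade ledger.

    ``depth_outlier_scaffolds`` is keyed by scaffold id;
    ``shine_dalgarno`` by candidate id. These mirror published evidence
    columns: they annotate, they do not remove candidates.
    """
    ledger = ledger.copy()
    outliers = set(depth_outlier_scaffolds)
    sd = shine_dalgarno or {}
    depth_col, sd_col, intron_col, tr_col = [], [], [], []
    for _, row in ledger.iterrows():
        sid = row["scaffold_id"]
        depth_col.append("yes" if sid in outliers else "no")
        sd_col.append({True: "yes", False: "no"}.get(sd.get(row["candidate_id"]), "NA"))
        scaf = scaffolds.get(sid)
        gene = None
        if scaf is not None:
            for g in scaf.genes:
                if g.gene_id == row["candidate_id"]:
                    gene = g
                    break
        intron_col.append("NA" if gene is None or gene.intron_count is None
                          else str(gene.intron_count))
        tr_col.append("NA" if gene is None or gene.transcribed is None
                      else ("yes" if gene.transcribed else "no"))
    ledger["depth-outlier"] = depth_col
    ledger["shine-dalgarno"] = sd_col
    ledger["introns"] = intron_col
    ledger["transcribed"] = tr_col
    return ledger


# ---------------------------------------------------------------------
# Duplicate vs misassembly
# ---------------------------------------------------------------------


def classify_duplicate_or_misassembly(
    scaffold_pair_nt_identity: Optional[float],
    same_scaffold_aa_ranges: Optional[Sequence[Tuple[object, float]]] = None,
    identity_threshold: float = 0.90,
) -> str:
    """Classify two gene copies as ``misassembly``, ``duplication`` or
    ``independent``.

    Misassembly: the two scaffolds align at > 90% nucleotide identity.
    Duplication: >= 2 ranges on the same scaffold share > 90% amino-acid
    identity. Otherwise independent. Raises if neither evidence source is
    provided.
    """
    ranges = same_scaffold_aa_ranges
    if scaffold_pair_nt_identity is None and ranges is None:
        raise ScreenError("no evidence provided (both sources NA)")
    if scaffold_pair_nt_identity is not None and \
            scaffold_pair_nt_identity > identity_threshold:
        return "misassembly"
    if ranges is not None:
        high = [rg for rg in ranges if rg[1] > identity_threshold]
        if len(high) >= 2:
            return "duplication"
    return "independent"


# ---------------------------------------------------------------------
# Grubbs read-depth outlier test
# ---------------------------------------------------------------------


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for a single outlier among n."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_outliers(
    depths: Sequence[float], alpha: float = 0.05
) -> Dict[str, object]:
    """Two-sided single-outlier Grubbs test on read depths.

    G = max_i |d_i - mean| / sd with the n-1 sample standard deviation,
    compared to the t-based critical value at level ``alpha``. Non-iterative:
    at most the single most extreme value is flagged. Returns a dict with
    ``outlier_indices`` (empty or one index), ``G`` and ``critical``.
    """
    d = np.asarray(depths, dtype=float)
    n = d.size
    if n < 3:
        raise ScreenError("Grubbs test needs n >= 3")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ScreenError("zero standard deviation: Grubbs test undefined")
    dev = np.abs(d - d.mean())
    i = int(dev.argmax())
    G = float(dev[i] / sd)
    crit = grubbs_critical_value(n, alpha)
    return {
        "outlier_indices": [i] if G > crit else [],
        "G": G,
        "critical": crit,
    }


def grubbs_outliers_iterative(
    depths: Sequence[float], alpha: float = 0.05, max_outliers: Optional[int] = None
) -> List[int]:
    """Repeatedly apply the single-outlier Grubbs test, removing the flagged
    value each round, until no outlier remains (or the sample gets too small
    or constant). Returns indices into the original sequence.

    Used by the screening pipeline to triage depth-anomalous scaffolds; note
    the single-outlier statistic is vulnerable to masking when a large
    fraction of the sample is anomalous.
    """
    d = list(enumerate(float(x) for x in depths))
    out: List[int] = []
    limit = max_outliers if max_outliers is not None else len(d)
    while len(d) >= 3 and len(out) < limit:
        vals = [v for _, v in d]
        if np.std(vals, ddof=1) == 0:
            break
        res = grubbs_outliers(vals, alpha)
        if not res["outlier_indices"]:
            break
        j = res["outlier_indices"][0]
        out.append(d[j][0])
        del d[j]
    return sorted(out)


# ---------------------------------------------------------------------
# Shine-Dalgarno scan
# ---------------------------------------------------------------------

SD_MOTIF = "AGGAGG"
SD_WINDOW = (3, 15)  # nt upstream of the start codon
SD_MAX_MISMATCH = 1


def shine_dalgarno_scan(
    sequence: str, orf_start: int
) -> Dict[str, object]:
    """Scan for a Shine-Dalgarno motif upstream of a start codon.

    Looks for AGGAGG with at most one mismatch anywhere in the window 3-15
    nt upstream of ``orf_start`` (1-based position of the first codon
    nucleotide) on the given (coding) strand; the window is truncated at the
    sequence start. ``N`` counts as a mismatch. Returns ``found``,
    ``position`` (1-based motif start or None) and ``motif`` (matched text).
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ScreenError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    if not (1 <= orf_start <= len(seq)):
        raise ScreenError("orf_start outside sequence")
    hi = orf_start - SD_WINDOW[0]  # last window position (1-based, inclusive)
    lo = max(1, orf_start - SD_WINDOW[1])
    m = len(SD_MOTIF)
    best = None
    for p in range(lo, hi - m + 2):  # motif must lie fully inside the window
        window = seq[p - 1 : p - 1 + m]
        if len(window) < m:
            break
        mism = sum(1 for a, b in zip(window, SD_MOTIF) if a != b)
        if mism <= SD_MAX_MISMATCH:
            if best is None or mism < best[2]:
                best = (p, window, mism)
    if best is None:
        return {"found": False, "position": None, "motif": None}
    return {"found": True, "position": best[0], "motif": best[1]}


# ---------------------------------------------------------------------
# Micro-synteny
# ---------------------------------------------------------------------


@dataclass
class SyntenyRecord:
    """Neighborhood of one HTG and where its pieces land in other species.

    ``neighbors`` lists flanking genes by signed offset (-n = n genes
    upstream, +n downstream). ``placements[species][gene_id]`` is the
    scaffold of that neighbor's homolog in ``species`` (None = no hit);
    ``htg_placement[species]`` is the scaffold of the HTG homolog itself.
    """

    htg_id: str
    neighbors: List[Tuple[int, str]]
    placements: Dict[str, Dict[str, Optional[str]]]
    htg_placement: Dict[str, Optional[str]]

    def __post_init__(self):
        offsets = [o for o, _ in self.neighbors]
        if 0 in offsets:
            raise ScreenError("neighbor offset 0 is the HTG itself")
        if len(set(offsets)) != len(offsets):
            raise ScreenError("duplicate neighbor offsets")


def microsynteny(record: SyntenyRecord, other_species: str) -> Dict[str, object]:
    """Micro-synteny evidence for one HTG against one other species.

    Evidence is positive iff at least one flanking gene's homolog lies on
    the same scaffold as the HTG homolog in ``other_species``; missing (NA)
    placements are ignored. Returns ``evidence`` and the offsets of the
    shared neighbors.
    """
    htg_scaf = record.htg_placement.get(other_species)
    shared: List[int] = []
    if htg_scaf is not None:
        placed = record.placements.get(other_species, {})
        for offset, gene_id in record.neighbors:
            scaf = placed.get(gene_id)
            if scaf is not None and scaf == htg_scaf:
                shared.append(offset)
    return {"evidence": bool(shared), "shared_neighbors": sorted(shared)}


# ---------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(path) -> List[BlastHit]:
    """Read BLAST tabular output (outfmt 6, 12 columns) into hits.

    The query id column is read as ``protein|strain`` or
    ``protein|strain|hit_id`` (pipe-composited ids are standard BLAST
    practice); the frame sign is inferred from subject coordinate
    orientation (tabular output carries no frame column).
    """
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    hits = []
    for _, r in df.iterrows():
        parts = str(r.qseqid).split("|")
        prot = parts[0]
        strain = parts[1] if len(parts) > 1 else ""
        hit_id = parts[2] if len(parts) > 2 else None
        frame = 1 if r.sstart <= r.send else -1
        hits.append(
            BlastHit(
                hit_id=hit_id,
                query_id=prot,
                donor_strain=strain or "unknown",
                subject_scaffold=str(r.sseqid),
                subject_start=int(min(r.sstart, r.send)),
                subject_end=int(max(r.sstart, r.send)),
                frame=frame,
                evalue=float(r.evalue),
                hsp_len_aa=int(r.length),
                pct_identity=float(r.pident),
                bitscore=float(r.bitscore),
            )
        )
    return hits


def write_blast_tab(hits: Sequence[BlastHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            q = f"{h.query_id}|{h.donor_strain}|{h.hit_id}"
            if h.frame >= 0:
                s, e = h.subject_start, h.subject_end
            else:
                s, e = h.subject_end, h.subject_start
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        q, h.subject_scaffold, f"{h.pct_identity:.2f}",
                        h.hsp_len_aa, 0, 0, 1, h.hsp_len_aa, s, e,
                        f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


def read_depth_tsv(path) -> Dict[str, float]:
    """Read a ``scaffold_id<TAB>mean_depth`` table."""
    df = pd.read_csv(path, sep="\t", names=["scaffold_id", "mean_depth"],
                     comment="#")
    if df["mean_depth"].dtype == object:  # header present
        df = df.iloc[1:]
    return {str(r.scaffold_id): float(r.mean_depth) for _, r in df.iterrows()}


def write_depth_tsv(depths: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        for sid, d in depths.items():
            fh.write(f"{sid}\t{d:.4f}\n")


def read_gff_scaffolds(path) -> Dict[str, ScaffoldRecord]:
    """Read a GFF3-subset annotation into scaffold records.

    Scaffold lengths come from ``##sequence-region`` pragmas; gene features
    carry the package's evidence flags in their attribute column
    (``bona_fide=1``, ``introns=N``, ``transcribed=1``).
    """
    lengths: Dict[str, int] = {}
    genes: Dict[str, List[Gene]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, sid, _start, end = line.split()
                lengths[sid] = int(end)
                genes.setdefault(sid, [])
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ScreenError(f"malformed GFF line: {line!r}")
            sid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            a = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            genes.setdefault(sid, []).append(
                Gene(
                    gene_id=a.get("ID", f"{sid}:{start}-{end}"),
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    is_bona_fide_eukaryotic=a.get("bona_fide") == "1",
                    intron_count=int(a["introns"]) if "introns" in a else None,
                    transcribed={"1": True, "0": False}.get(a.get("transcribed")),
                )
            )
    out = {}
    for sid, length in lengths.items():
        out[sid] = ScaffoldRecord(scaffold_id=sid, length_bp=length,
                                  genes=genes.get(sid, []))
    return out


def write_gff_scaffolds(scaffolds: Mapping[str, ScaffoldRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for sid, scaf in scaffolds.items():
            fh.write(f"##sequence-region {sid} 1 {scaf.length_bp}\n")
        for sid, scaf in scaffolds.items():
            for g in scaf.genes:
                attrs = [f"ID={g.gene_id}"]
                if g.is_bona_fide_eukaryotic:
                    attrs.append("bona_fide=1")
                if g.intron_count is not None:
                    attrs.append(f"introns={g.intron_count}")
                if g.transcribed is not None:
                    attrs.append(f"transcribed={int(g.transcribed)}")
                fh.write(
                    "\t".join(
                        [sid, "hgtsignal", "gene", str(g.start), str(g.end),
                         ".", g.strand, ".", ";".join(attrs)]
                    )
                    + "\n"
                )


def read_canonical_tsv(path) -> Dict[str, int]:
    """Read ``query_id<TAB>canonical_aa_length``."""
    out: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            q, n = line.split("\t")
            out[q] = int(n)
    return out


def write_ledger_tsv(ledger: pd.DataFrame, path) -> None:
    ledger.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
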