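"""tRNA gene repertoires: dual-predictor reconciliation and anticodon copy-number pools.

A genome's tRNA pool (tGCN: tRNA gene copy number per anticodon) can be built
either from annotated tRNA features or from the reconciled union of two
predictor outputs (a structure-aware predictor such as tRNAscan-SE, called the
P side here, and a second predictor such as Aragorn, the Q side).  The
reconciliation rules are:

(a) same anticodon, same strand, starts within ``window`` bp: the two calls
    collapse to one gene keeping the Q-side (Aragorn) record;
(b) exception to (a): for CAT-anticodon tRNAs (Met / Ile2 / fMet, whose
    isotype assignment needs structural evidence) the P-side call is kept;
(c) a P-side call with undetermined isotype that pairs positionally with a
    Q-side call is replaced by the Q-side call.  (c) outranks (b): an
    undetermined P call carries no isotype information worth keeping.

Unmatched calls from either side are retained.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

logger = logging.getLogger(__name__)

UNKNOWN = "UNKNOWN"
_RNA_TO_DNA = str.maketrans("Uu", "Tt")


def normalize_anticodon(ac: str | None) -> str:
    """Uppercase, RNA->DNA; anything not a clean 3-mer over ACGT becomes UNKNOWN."""
    if not ac:
        return UNKNOWN
    ac = ac.strip().upper().translate(_RNA_TO_DNA)
    if len(ac) == 3 and set(ac) <= set("ACGT"):
        return ac
    return UNKNOWN


@dataclass(frozen=True)
class TrnaGene:
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" | "-"
    anticodon: str = UNKNOWN  # DNA alphabet, 5'->3'
    isotype: str = "Undet"
    source: str = "annotation"
    pseudo: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"tRNA gene start {self.start} > end {self.end}")

    @property
    def undetermined(self) -> bool:
        return self.isotype == "Undet" or self.anticodon == UNKNOWN


@dataclass
class TgcnVector:
    """Anticodon -> gene copy number; the tRNA pool a gene is scored against."""

    copies: dict[str, int] = field(default_factory=dict)
    origin: str = ""

    def __getitem__(self, anticodon: str) -> int:
        return self.copies.get(anticodon, 0)

    @property
    def total(self) -> int:
        return sum(self.copies.values())

    def scaled(self, k: int) -> "TgcnVector":
        return TgcnVector({a: k * n for a, n in self.copies.items()}, origin=self.origin)


def merge_predictions(
    set_P: list[TrnaGene], set_Q: list[TrnaGene], window: int = 10
) -> list[TrnaGene]:
    """Reconcile two predictors' tRNA calls for one genome (rules in module docstring).

    Candidate P/Q pairs (same strand, |start_P - start_Q| <= window, and either
    identical anticodons or an undetermined P call) are matched greedily by
    smallest |delta start|, ties broken by leftmost start, so the result is
    deterministic.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    seq_ids = {g.seq_id for g in set_P} | {g.seq_id for g in set_Q}
    if len(seq_ids) > 1:
        raise ValueError(f"mixed seq_ids in merge input: {sorted(seq_ids)}")

    candidates = []
    for i, p in enumerate(set_P):
        for j, q in enumerate(set_Q):
            if p.strand != q.strand:
                continue
            delta = abs(p.start - q.start)
            if delta > window:
                continue
            if p.anticodon == q.anticodon or p.undetermined:
                # identical-anticodon matches outrank undetermined positional
                # matches at equal distance, so an undetermined call cannot
                # steal another call's exact partner
                priority = 0 if p.anticodon == q.anticodon else 1
                candidates.append((delta, priority, min(p.start, q.start), i, j))
    candidates.sort()

    used_p: set[int] = set()
    used_q: set[int] = set()
    merged: list[TrnaGene] = []
    for _delta, _prio, _pos, i, j in candidates:
        if i in used_p or j in used_q:
            continue
        used_p.add(i)
        used_q.add(j)
        p, q = set_P[i], set_Q[j]
        if p.undetermined:
            merged.append(q)  # rule (c); outranks (b)
        elif p.anticodon == "CAT":
            merged.append(p)  # rule (b)
        else:
            merged.append(q)  # rule (a): Q-side coordinates kept
    merged.extend(p for i, p in enumerate(set_P) if i not in used_p)
    merged.extend(q for j, q in enumerate(set_Q) if j not in used_q)
    merged.sort(key=lambda g: (g.start, g.end, g.strand, g.anticodon))
    return merged


def build_tgcn(
    genes: list[TrnaGene], origin: str = "", include_pseudo: bool = False
) -> TgcnVector:
    """Count genes per anticodon; unknown-anticodon (and, by default, pseudo) genes excluded."""
    counts: Counter[str] = Counter()
    n_unknown = n_pseudo = 0
    for g in genes:
        if g.pseudo and not include_pseudo:
            n_pseudo += 1
            continue
        if g.anticodon == UNKNOWN:
            n_unknown += 1
            continue
        counts[g.anticodon] += 1
    if n_unknown or n_pseudo:
        logger.info(
            "%s: excluded %d unknown-anticodon and %d pseudo tRNA gene(s) from pool",
            origin or "<pool>", n_unknown, n_pseudo,
        )
    return TgcnVector(dict(counts), origin=origin)


def combine_pools(a: TgcnVector, b: TgcnVector) -> TgcnVector:
    out = Counter(a.copies)
    out.update(b.copies)
    origin = "+".join(x for x in (a.origin, b.origin) if x)
    return TgcnVector(dict(out), origin=origin)


def pool_from_annotation(genome, include_pseudo: bool = False) -> TgcnVector:
    """Build a pool from a GenomeRecord's annotated tRNA features.

    The anticodon is taken from the ``anticodon`` qualifier when present
    (either a bare triplet or the GenBank ``(pos:..,aa:Xxx,seq:nnn)`` form,
    whose ``seq`` field is the anticodon read off the gene, 5'->3') or, as a
    fallback, from a ``tRNA-Xxx (NNN)`` style product string.
    """
    genes = [annotation_to_gene(genome.identifier, f) for f in genome.features if f.kind == "tRNA"]
    return build_tgcn(genes, origin=genome.identifier, include_pseudo=include_pseudo)


def annotation_to_gene(seq_id: str, feat) -> TrnaGene:
    quals = feat.qualifiers
    ac = UNKNOWN
    isotype = "Undet"
    raw = quals.get("anticodon", "")
    if raw:
        m = re.search(r"seq\s*:\s*([A-Za-z]{3})", raw)
        ac = normalize_anticodon(m.group(1) if m else raw)
        m_aa = re.search(r"aa\s*:\s*(\w+)", raw)
        if m_aa:
            isotype = m_aa.group(1)
    product = quals.get("product", "")
    if product:
        m = re.match(r"tRNA-(\w+)", product)
        if m and isotype == "Undet":
            isotype = m.group(1)
        if ac == UNKNOWN:
            m = re.search(r"\(([A-Za-z]{3})\)", product)
            if m:
                ac = normalize_anticodon(m.group(1))
    return TrnaGene(
        seq_id=seq_id, start=feat.start, end=feat.end, strand=feat.strand,
        anticodon=ac, isotype=isotype, source="annotation",
        pseudo="pseudo" in quals,
    )


# ---------------------------------------------------------------------------
# Predictor output parsers
# ---------------------------------------------------------------------------

def parse_trnascan(path, source: str = "tRNAscan-SE") -> list[TrnaGene]:
    """Parse tRNAscan-SE tabular output (the ``-o`` file with its 3 header lines).

    Columns: sequence name, tRNA #, begin, end, type, anticodon, intron begin,
    intron end, score[, ...].  Reverse-strand genes have begin > end.  "Undet"
    or "???" types and "???"/"NNN" anticodons become undetermined calls; a
    trailing "pseudo" note flags a pseudogene.
    """
    genes: list[TrnaGene] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lstrip().startswith(("Sequence", "Name", "--")):
            continue
        parts = re.split(r"\t|\s{2,}", line.strip())
        if len(parts) < 6:
            continue
        seq_id, _num, begin, end = parts[0], parts[1], int(parts[2]), int(parts[3])
        isotype, anticodon = parts[4], parts[5]
        strand = "+" if begin <= end else "-"
        start, stop = (begin, end) if begin <= end else (end, begin)
        iso = "Undet" if isotype in ("Undet", "???") else isotype
        ac = normalize_anticodon(anticodon) if anticodon not in ("???", "NNN") else UNKNOWN
        if iso == "Undet":
            ac = UNKNOWN
        pseudo = "pseudo" in line.lower()
        genes.append(TrnaGene(seq_id, start, stop, strand, ac, iso, source, pseudo))
    return genes


_ARAGORN_GENE = re.compile(
    r"tRNA-(?P<iso>\?|\w+)\s+(?P<comp>c?)\[(?P<start>\d+),(?P<end>\d+)\]"
    r".*?\((?P<ac>[a-zA-Z]{3})\)"
)


def parse_aragorn(path, source: str = "Aragorn") -> list[TrnaGene]:
    """Parse Aragorn batch output (``-w`` style listing).

    Lines look like ``1   tRNA-Phe   [100,175]  35  (gaa)`` with ``c[x,y]``
    marking complementary-strand genes; a ``>`` header names the sequence.
    tmRNA lines are ignored: they are not part of the translational tRNA pool.
    """
    genes: list[TrnaGene] = []
    seq_id = ""
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith(">"):
            seq_id = line[1:].split()[0]
            continue
        if "tmRNA" in line:
            continue
        m = _ARAGORN_GENE.search(line)
        if not m:
            continue
        iso = m.group("iso")
        genes.append(
            TrnaGene(
                seq_id=seq_id,
                start=int(m.group("start")),
                end=int(m.group("end")),
                strand="-" if m.group("comp") else "+",
                anticodon=normalize_anticodon(m.group("ac")),
                isotype="Undet" if iso == "?" else iso,
                source=source,
            )
        )
    return genes


_TSV_COLUMNS = ["seq_id", "source", "start", "end", "strand", "isotype", "anticodon", "pseudo"]


def parse_trna_tsv(path) -> list[TrnaGene]:
    """Parse the normalized TSV (seq_id, source, start, end, strand, isotype, anticodon, pseudo)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in _TSV_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    idx = {c: header.index(c) for c in _TSV_COLUMNS}
    genes = []
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        genes.append(
            TrnaGene(
                seq_id=f[idx["seq_id"]],
                start=int(f[idx["start"]]),
                end=int(f[idx["end"]]),
                strand=f[idx["strand"]],
                anticodon=normalize_anticodon(f[idx["anticodon"]]),
                isotype=f[idx["isotype"]] or "Undet",
                source=f[idx["source"]],
                pseudo=f[idx["pseudo"]].strip().lower() in ("1", "true", "yes"),
            )
        )
    return genes


def write_trna_tsv(genes: list[TrnaGene], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [g.seq_id, g.source, str(g.start), str(g.end), g.strand,
                     g.isotype, g.anticodon, "1" if g.pseudo else "0"]
                )
                + "\n"
            )
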