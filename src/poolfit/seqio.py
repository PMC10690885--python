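"""Genome I/O: read GenBank/FASTA records, extract coding sequences, count codons.

Coordinates are 1-based inclusive at the file boundary (GenBank convention)
and 0-based half-open internally; the conversion is confined to this module.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation

logger = logging.getLogger(__name__)

DNA_UNAMBIGUOUS = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in the named format."""


class EmptyInputError(ValueError):
    """Raised when a file or sequence holds no usable data."""


class FeatureSelectorError(LookupError):
    """Raised when a feature selector matches zero or multiple features."""


class FrameError(ValueError):
    """Raised when a coding sequence length is not a multiple of three."""


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated feature, 1-based inclusive coordinates as in the source file."""

    kind: str  # "CDS" | "tRNA" | other source feature key
    start: int
    end: int
    strand: str  # "+" | "-"
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"feature start {self.start} > end {self.end}")


@dataclass
class GenomeRecord:
    identifier: str
    sequence: str
    features: list[FeatureRecord] = field(default_factory=list)
    topology: str = "linear"
    #: declared length from the LOCUS line; equals len(sequence) when the
    #: record carries its sequence, and preserves the length for
    #: feature-table-only records (sequence == "").
    declared_length: int | None = None

    def __len__(self) -> int:
        if self.sequence:
            return len(self.sequence)
        if self.declared_length is not None:
            return self.declared_length
        return 0


def _strand_symbol(biopython_strand) -> str:
    return "-" if biopython_strand == -1 else "+"


def read_genome(path, format: str = "genbank") -> GenomeRecord:
    """Read the first record of a GenBank or FASTA file into a GenomeRecord.

    FASTA records yield an empty feature list.  GenBank records whose ORIGIN
    block was stripped (feature-table-only files) are accepted; their
    sequence is empty and ``declared_length`` carries the LOCUS length.
    """
    path = Path(path)
    if format not in ("genbank", "fasta"):
        raise ValueError(f"unknown format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path}: empty file")
    try:
        records = list(SeqIO.parse(str(path), format))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FormatError(f"{path}: cannot parse as {format}: {exc}") from exc
    if not records:
        raise EmptyInputError(f"{path}: no {format} records found")
    rec = records[0]
    try:
        seq = str(rec.seq).upper()
    except Exception:  # UndefinedSequenceError for sequence-less GenBank
        seq = ""
    features = []
    for f in getattr(rec, "features", []):
        if f.type == "source":
            continue
        if isinstance(f.location, CompoundLocation) and len({p.strand for p in f.location.parts}) > 1:
            raise FormatError(f"{path}: trans-spliced location in {f.type} feature is not supported")
        features.append(
            FeatureRecord(
                kind=f.type,
                start=int(f.location.start) + 1,
                end=int(f.location.end),
                strand=_strand_symbol(f.location.strand),
                qualifiers={k: v[0] if isinstance(v, list) and v else v for k, v in f.qualifiers.items()},
            )
        )
    topology = rec.annotations.get("topology", "linear") if hasattr(rec, "annotations") else "linear"
    declared = len(rec) if len(rec) else None
    return GenomeRecord(
        identifier=rec.id if rec.id and rec.id != "<unknown id>" else rec.name,
        sequence=seq,
        features=features,
        topology=topology,
        declared_length=declared,
    )


def read_genomes(paths: Iterable, format: str = "genbank") -> dict[str, GenomeRecord]:
    """Read several genomes, keyed by identifier; duplicate identifiers error."""
    out: dict[str, GenomeRecord] = {}
    for p in paths:
        g = read_genome(p, format=format)
        if g.identifier in out:
            raise ValueError(f"duplicate genome identifier {g.identifier!r}")
        out[g.identifier] = g
    return out


def gc_content(sequence: str) -> float:
    """Fraction of G+C (plus the S ambiguity code) over the full length.

    Other IUPAC ambiguity codes count toward the denominator only, so the
    value is exact on unambiguous sequences and conservative otherwise.
    """
    if not sequence:
        raise EmptyInputError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C") + s.count("S")
    return gc / len(s)


def _feature_matches(feat: FeatureRecord, selector: str) -> bool:
    quals = feat.qualifiers
    if quals.get("locus_tag") == selector or quals.get("gene") == selector:
        return True
    product = quals.get("product", "")
    return bool(product and re.search(selector, product, flags=re.IGNORECASE))


def find_cds(genome: GenomeRecord, selector: str) -> FeatureRecord:
    """Locate exactly one CDS by locus tag or product regular expression."""
    hits = [f for f in genome.features if f.kind == "CDS" and _feature_matches(f, selector)]
    if not hits:
        raise FeatureSelectorError(f"{genome.identifier}: no CDS matches selector {selector!r}")
    if len(hits) > 1:
        cands = ", ".join(f"{h.start}..{h.end} ({h.qualifiers.get('product', '?')})" for h in hits)
        raise FeatureSelectorError(
            f"{genome.identifier}: selector {selector!r} is ambiguous; candidates: {cands}"
        )
    return hits[0]


def extract_cds(genome: GenomeRecord, selector: str) -> str:
    """Return the spliced, strand-corrected (5'->3') coding sequence of one CDS."""
    feat = find_cds(genome, selector)
    if not genome.sequence:
        raise EmptyInputError(f"{genome.identifier}: record has no sequence to extract from")
    sub = genome.sequence[feat.start - 1 : feat.end]
    if feat.strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return sub


def to_seqrecord(genome: GenomeRecord):
    """Convert a GenomeRecord to a Biopython SeqRecord (for writing)."""
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.identifier,
        name=genome.identifier[:16].replace("|", "_"),
        description="",
        annotations={"molecule_type": "DNA", "topology": genome.topology},
    )
    for f in genome.features:
        loc = SimpleLocation(f.start - 1, f.end, strand=-1 if f.strand == "-" else 1)
        rec.features.append(
            SeqFeature(loc, type=f.kind, qualifiers={k: [v] for k, v in f.qualifiers.items()})
        )
    return rec


def write_genome(genome: GenomeRecord, path, format: str = "genbank") -> None:
    SeqIO.write([to_seqrecord(genome)], str(path), format)


@dataclass
class CodonCounts:
    counts: dict[str, int]
    gene_id: str = ""
    skipped: int = 0  # codons dropped for containing ambiguity codes

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def count_codons(cds: str, gene_id: str = "") -> CodonCounts:
    """Tally frame-0 triplets; triplets with ambiguity codes are skipped, not errored."""
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} is not a multiple of 3")
    if not cds:
        raise EmptyInputError("empty CDS")
    s = cds.upper()
    counts: dict[str, int] = {}
    skipped = 0
    for i in range(0, len(s), 3):
        codon = s[i : i + 3]
        if set(codon) <= DNA_UNAMBIGUOUS:
            counts[codon] = counts.get(codon, 0) + 1
        else:
            skipped += 1
    if skipped:
        logger.info("%s: skipped %d ambiguous codon(s)", gene_id or "<gene>", skipped)
    return CodonCounts(counts=counts, gene_id=gene_id, skipped=skipped)
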