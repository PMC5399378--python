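"""Coordinate model and readers/writers for the formats the pipeline touches.

Internal convention: 0-based, half-open intervals on the plus strand.  The
printed locus convention (1-based inclusive, minus-strand loci written
high-to-low, e.g. ``S648_2373-2295:-``) is handled only at parse/format
time.  BED is 0-based half-open; GFF3 is 1-based inclusive.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .rna_structure import FoldResult, reverse_complement

_LOCUS_RE = re.compile(r"^(?P<scaffold>.+)_(?P<a>\d+)-(?P<b>\d+):(?P<strand>[+-])$")


@dataclass(frozen=True)
class GenomeInterval:
    """A genomic span: 0-based half-open plus-strand coordinates."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold_id}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval", same_strand: bool = True) -> bool:
        if self.scaffold_id != other.scaffold_id:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomeInterval") -> int:
        if self.scaffold_id != other.scaffold_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def parse_locus(locus_string: str) -> GenomeInterval:
    """Parse a printed locus string ``<scaffold>_<a>-<b>:<strand>``.

    Printed coordinates are 1-based inclusive; minus-strand loci are printed
    high-to-low.  ``a == b`` denotes a single-base locus.  A high-to-low span
    with a ``+`` suffix is inconsistent and rejected.
    """
    m = _LOCUS_RE.match(locus_string)
    if not m:
        raise ValueError(f"malformed locus string: {locus_string!r}")
    a, b = int(m.group("a")), int(m.group("b"))
    if a == 0 or b == 0:
        raise ValueError(f"locus coordinates are 1-based, got zero in {locus_string!r}")
    strand = m.group("strand")
    if a > b and strand == "+":
        raise ValueError(
            f"inconsistent locus {locus_string!r}: high-to-low span printed as '+'")
    if a > b:
        strand = "-"
    lo, hi = min(a, b), max(a, b)
    return GenomeInterval(m.group("scaffold"), lo - 1, hi, strand)


def format_locus(interval: GenomeInterval) -> str:
    """Inverse of :func:`parse_locus`."""
    if interval.strand == "+":
        return f"{interval.scaffold_id}_{interval.start + 1}-{interval.end}:+"
    return f"{interval.scaffold_id}_{interval.end}-{interval.start + 1}:-"


def interval_length(interval: GenomeInterval) -> int:
    """Length in nt; equals |printed_a - printed_b| + 1."""
    return interval.length


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def as_rna(self) -> str:
        return self.sequence.upper().replace("T", "U")

    def as_dna(self) -> str:
        return self.sequence.upper().replace("U", "T")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PrecursorCandidate:
    """A candidate precursor locus with its fold and track provenance."""

    id: str
    interval: GenomeInterval
    sequence: str  # RNA, precursor-strand orientation
    fold: FoldResult | None = None
    tracks: set[str] = field(default_factory=set)
    mature: object | None = None  # MatureCall, attached downstream
    flags: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def mfe(self) -> float:
        if self.fold is None:
            raise ValueError(f"candidate {self.id} has not been folded")
        return self.fold.mfe

    def with_fold(self, fold: FoldResult) -> "PrecursorCandidate":
        new = replace(self)
        new.fold = fold
        return new


# ---------------------------------------------------------------------------
# sequence file I/O


def read_fasta(path) -> list[SequenceRecord]:
    return [SequenceRecord(r.id, str(r.seq), r.description)
            for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    SeqIO.write(
        (_BioSeqRecord(Seq(r.sequence), id=r.id,
                       description=r.description or "") for r in records),
        str(path), "fasta")


def read_fastq(path) -> list[SequenceRecord]:
    """Reads as records; qualities are ignored downstream."""
    return [SequenceRecord(r.id, str(r.seq), r.description)
            for r in SeqIO.parse(str(path), "fastq")]


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    def _conv():
        for r in records:
            br = _BioSeqRecord(Seq(r.sequence), id=r.id, description="")
            br.letter_annotations["phred_quality"] = [40] * len(r.sequence)
            yield br
    SeqIO.write(_conv(), str(path), "fastq")


def load_genome(path) -> dict[str, str]:
    """Scaffold id -> uppercase DNA sequence."""
    return {r.id: r.sequence.upper() for r in read_fasta(path)}


def fetch(genome: Mapping[str, str], interval: GenomeInterval,
          rna: bool = True) -> str:
    """Extract the sequence of an interval in its strand orientation."""
    scaffold = genome[interval.scaffold_id]
    if interval.end > len(scaffold):
        raise ValueError(
            f"interval {format_locus(interval)} out of scaffold bounds "
            f"(len {len(scaffold)})")
    seq = scaffold[interval.start:interval.end]
    if interval.strand == "-":
        seq = reverse_complement(seq)
        if not rna:
            seq = seq.replace("U", "T")
        return seq
    return seq.upper().replace("T", "U") if rna else seq


# ---------------------------------------------------------------------------
# interval file I/O


@dataclass(frozen=True)
class BedRecord:
    interval: GenomeInterval
    name: str = "."
    score: float | None = None


def read_bed(path) -> list[BedRecord]:
    out = []
    for ln, line in enumerate(open(path), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t") if "\t" in line else line.split()
        if len(f) < 3:
            raise ValueError(f"{path}:{ln}: BED line with fewer than 3 fields")
        strand = f[5] if len(f) > 5 else "+"
        score = None
        if len(f) > 4 and f[4] not in (".", ""):
            score = float(f[4])
        out.append(BedRecord(
            GenomeInterval(f[0], int(f[1]), int(f[2]), strand),
            f[3] if len(f) > 3 else ".", score))
    return out


def write_bed(records: Iterable[BedRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            score = "." if r.score is None else f"{r.score:g}"
            fh.write(f"{r.interval.scaffold_id}\t{r.interval.start}\t"
                     f"{r.interval.end}\t{r.name}\t{score}\t{r.interval.strand}\n")


@dataclass(frozen=True)
class Gff3Feature:
    interval: GenomeInterval
    type: str
    source: str = "."
    attributes: Mapping[str, str] = field(default_factory=dict)


def read_gff3(path) -> list[Gff3Feature]:
    feats = []
    for ln, line in enumerate(open(path), 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ValueError(f"{path}:{ln}: GFF3 line with {len(f)} fields")
        attrs = {}
        for item in f[8].split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                attrs[k.strip()] = v.strip()
        strand = f[6] if f[6] in "+-" else "+"
        feats.append(Gff3Feature(
            GenomeInterval(f[0], int(f[3]) - 1, int(f[4]), strand),
            f[2], f[1], attrs))
    return feats


def write_gff3(feats: Iterable[Gff3Feature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ft in feats:
            attrs = ";".join(f"{k}={v}" for k, v in ft.attributes.items()) or "."
            fh.write(f"{ft.interval.scaffold_id}\t{ft.source}\t{ft.type}\t"
                     f"{ft.interval.start + 1}\t{ft.interval.end}\t.\t"
                     f"{ft.interval.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# prediction report TSV

REPORT_COLUMNS = [
    "id", "locus", "tracks", "precursor_seq", "structure", "mfe",
    "filter_flags", "mature_5p", "mature_3p", "family_seed",
    "conservation_class",
]


def write_report(candidates: Iterable[PrecursorCandidate], path) -> None:
    """Stable TSV report; one row per candidate."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(REPORT_COLUMNS)
        for c in candidates:
            mature5 = mature3 = seed = ""
            if c.mature is not None:
                mature5 = "{}-{}".format(*c.mature.p5)
                mature3 = "{}-{}".format(*c.mature.p3)
                seed = c.meta.get("family_seed", "")
            w.writerow([
                c.id, format_locus(c.interval), ",".join(sorted(c.tracks)),
                c.sequence,
                c.fold.dotbracket if c.fold else "",
                f"{c.fold.mfe:.2f}" if c.fold else "",
                ",".join(c.flags), mature5, mature3, seed,
                c.meta.get("conservation_class", ""),
            ])


def read_tsv(path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
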