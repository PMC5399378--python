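"""Precursor discovery from small-RNA reads mapped onto the genome.

Reads are mapped ungapped, full length, with the printed cut-offs (identity
>= 90 %, aligned length >= 20, <= 2 mismatches, best hits only with ties
flagged multi-mapping).  Read loci +/- 100 bp are hairpin-scanned and the
mature is set from the read-matched segment; loci with mRNA coverage above
the expression cut-off are excluded.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._params import encode_sequence
from ._search import GenomeSearcher
from .core_io import (BedRecord, GenomeInterval, PrecursorCandidate,
                      SequenceRecord, format_locus)
from .denovo_track import shortest_passing_window
from .filtration import FilterCriteria
from .mature_strand_merge import MatureCall
from .rna_structure import hairpin_loop_runs, reverse_complement

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadHit:
    read_id: str
    interval: GenomeInterval
    mismatches: int
    aligned_length: int
    identity: float
    multi_mapping: bool = False


def map_reads(reads: Sequence[SequenceRecord],
              genome: Mapping[str, str],
              min_identity: float = 0.90,
              min_length: int = 20,
              max_mismatches: int = 2) -> list[ReadHit]:
    """Best-scoring ungapped hits per read (score = length - mismatches).

    Ties all kept and flagged multi-mapping; reads shorter than
    ``min_length`` are dropped with a logged count.
    """
    searcher = GenomeSearcher(genome)
    hits: list[ReadHit] = []
    n_short = 0
    for read in reads:
        seq = read.as_rna()
        if len(seq) < min_length:
            n_short += 1
            continue
        raw = searcher.find([seq], max_mismatches,
                            min_query_length=min_length)
        raw = [h for h in raw
               if (len(seq) - h.mismatches) / len(seq) >= min_identity]
        if not raw:
            continue
        best_mm = min(h.mismatches for h in raw)
        best = [h for h in raw if h.mismatches == best_mm]
        multi = len(best) > 1
        for h in best:
            hits.append(ReadHit(
                read.id,
                GenomeInterval(h.scaffold_id, h.start, h.start + len(seq),
                               h.strand),
                h.mismatches, len(seq), (len(seq) - h.mismatches) / len(seq),
                multi))
    if n_short:
        log.info("dropped %d reads shorter than %d nt", n_short, min_length)
    return hits


def loci_from_hits(hits: Sequence[ReadHit],
                   genome: Mapping[str, str],
                   flank: int = 100,
                   criteria: FilterCriteria = FilterCriteria(),
                   min_reads: int = 1) -> list[PrecursorCandidate]:
    """Fold read loci and keep those forming filter-passing hairpins.

    Overlapping same-strand hits are piled into one locus whose
    representative span is the modal read span; the hairpin window must
    contain that span and the mature is set from it (read-guided).
    """
    piles = _pile_hits(hits)
    out: list[PrecursorCandidate] = []
    for pile in piles:
        if len(pile) < min_reads:
            continue
        span_counts = Counter((h.interval.start, h.interval.end) for h in pile)
        (rep_start, rep_end), _ = span_counts.most_common(1)[0]
        sid = pile[0].interval.scaffold_id
        strand = pile[0].interval.strand
        scaffold = genome[sid]
        lo = max(0, rep_start - flank)
        hi = min(len(scaffold), rep_end + flank)
        flags = ["edge"] if (rep_start - flank < 0
                             or rep_end + flank > len(scaffold)) else []
        region = scaffold[lo:hi].upper().replace("T", "U")
        if "N" in region:
            continue
        if strand == "-":
            region = reverse_complement(region)
            span = (hi - rep_end, hi - rep_start)
        else:
            span = (rep_start - lo, rep_end - lo)
        win = shortest_passing_window(region, span, criteria)
        if win is None:
            continue
        ws, we, fr = win
        seq = region[ws:we]
        mature_rel = (span[0] - ws, span[1] - ws)
        if strand == "+":
            iv = GenomeInterval(sid, lo + ws, lo + we, "+")
        else:
            iv = GenomeInterval(sid, hi - we, hi - ws, "-")
        cand = PrecursorCandidate(
            f"sr_{format_locus(iv)}", iv, seq, fold=fr, tracks={"smallrna"},
            flags=flags,
            mature=_read_guided_mature(seq, fr, mature_rel),
            meta={"n_reads": len(pile),
                  "read_ids": sorted(h.read_id for h in pile)})
        out.append(cand)
    return sorted(out, key=lambda c: (c.interval.scaffold_id,
                                      c.interval.start))


def _pile_hits(hits: Sequence[ReadHit]) -> list[list[ReadHit]]:
    ordered = sorted(hits, key=lambda h: (h.interval.scaffold_id,
                                          h.interval.strand,
                                          h.interval.start))
    piles: list[list[ReadHit]] = []
    for h in ordered:
        if piles and piles[-1][0].interval.scaffold_id == h.interval.scaffold_id \
                and piles[-1][0].interval.strand == h.interval.strand \
                and h.interval.start < max(x.interval.end for x in piles[-1]):
            piles[-1].append(h)
        else:
            piles.append([h])
    return piles


def _read_guided_mature(seq: str, fr, read_span: tuple[int, int]) -> MatureCall:
    """Mature from the read-matched segment; star arm mirrored across the loop."""
    loops = hairpin_loop_runs(fr.dotbracket)
    if len(loops) != 1:
        return MatureCall(p5=read_span, p3=read_span, method="read_guided")
    ls, le = loops[0]
    n = read_span[1] - read_span[0]
    mid = (read_span[0] + read_span[1]) / 2
    if mid <= (ls + le) / 2:
        p5 = (max(0, read_span[0]), min(read_span[1], ls))
        p3 = (le, min(len(seq), le + n))
    else:
        p5 = (max(0, ls - n), ls)
        p3 = (max(read_span[0], le), min(read_span[1], len(seq)))
    return MatureCall(p5=p5, p3=p3, method="read_guided")


def exclude_expressed(candidates: Sequence[PrecursorCandidate],
                      mrna_coverage: Sequence[BedRecord],
                      max_reads: int = 10) -> list[PrecursorCandidate]:
    """Drop candidates with strictly more than ``max_reads`` mRNA reads.

    Coverage counts from any overlapping coverage interval are summed; loci
    without coverage count as zero.  Idempotent.
    """
    out = []
    for cand in candidates:
        count = sum(
            c.score or 0 for c in mrna_coverage
            if c.interval.overlaps(cand.interval, same_strand=False))
        if count > max_reads:
            cand.meta["mrna_reads"] = count
            continue
        out.append(cand)
    return out


def count_read_support(mature: str, reads: Sequence[SequenceRecord],
                       max_mismatches: int = 2) -> int:
    """Reads within Hamming distance of the mature (either orientation).

    For unequal lengths the shorter sequence slides ungapped along the
    longer; the best offset decides.
    """
    m_fwd = encode_sequence(mature.upper().replace("T", "U"))
    m_rev = encode_sequence(reverse_complement(mature))
    n = 0
    for read in reads:
        r = encode_sequence(read.as_rna())
        if _best_hamming(r, m_fwd) <= max_mismatches or \
           _best_hamming(r, m_rev) <= max_mismatches:
            n += 1
    return n


def _best_hamming(a: np.ndarray, b: np.ndarray) -> int:
    if len(a) < len(b):
        a, b = b, a
    best = len(b) + 1
    for off in range(len(a) - len(b) + 1):
        mm = int(np.count_nonzero(a[off:off + len(b)] != b))
        if mm < best:
            best = mm
    return best
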