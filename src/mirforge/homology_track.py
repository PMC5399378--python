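"""Candidate discovery by mismatch-limited matching of known matures.

A single exact Hamming scan (both strands, no indels) replaces the classic
word-seeded two-stage screen; it finds a superset of what word seeding can.
Each hit spawns two precursor window placements (mature on the 5' arm and on
the 3' arm), which are folded, end-trimmed and left for the filter battery
to adjudicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from ._search import GenomeSearcher
from .core_io import GenomeInterval, PrecursorCandidate, format_locus
from .filtration import FilterCriteria, evaluate
from .rna_structure import fold, reverse_complement, stem_spans_nested

log = logging.getLogger(__name__)

WINDOW_LENGTH = 110
WINDOW_EXTEND = 20
MIN_QUERY_LENGTH = 15
_MAX_TRIM_TRIES = 8


@dataclass(frozen=True)
class MatureQuery:
    id: str
    sequence: str  # RNA 18-27 nt
    family: str | None = None
    species: str | None = None

    def __post_init__(self):
        seq = self.sequence.upper().replace("T", "U")
        if not set(seq) <= set("ACGU"):
            raise ValueError(f"query {self.id}: invalid alphabet")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class MatureHit:
    query_id: str
    interval: GenomeInterval
    mismatches: int


def scan_for_matures(genome: Mapping[str, str],
                     queries: Sequence[MatureQuery],
                     max_mismatches: int = 2) -> list[MatureHit]:
    """Every genomic window within Hamming distance of any query, once."""
    searcher = GenomeSearcher(genome)
    raw = searcher.find([q.sequence for q in queries], max_mismatches,
                        min_query_length=MIN_QUERY_LENGTH)
    hits = []
    for h in raw:
        q = queries[h.query_index]
        iv = GenomeInterval(h.scaffold_id, h.start,
                            h.start + len(q.sequence), h.strand)
        hits.append(MatureHit(q.id, iv, h.mismatches))
    return sorted(hits, key=lambda h: (h.interval.scaffold_id,
                                       h.interval.start, h.interval.strand,
                                       h.query_id))


def build_precursor_candidates(
    hit: MatureHit,
    genome: Mapping[str, str],
    window_length: int = WINDOW_LENGTH,
    extend: int = WINDOW_EXTEND,
) -> list[PrecursorCandidate]:
    """Two window placements per hit: mature on the 5' arm and on the 3' arm.

    Each window is ``window_length + 2*extend`` nt before trimming of
    unpaired terminal runs.  Windows clipped at scaffold edges are flagged.
    """
    scaffold = genome[hit.interval.scaffold_id]
    total = window_length + 2 * extend
    placements = []
    if hit.interval.strand == "+":
        placements.append(("5p", hit.interval.start - extend))
        placements.append(("3p", hit.interval.end + extend - total))
    else:
        # 5'-of-mature is to the genomic right on the minus strand
        placements.append(("5p", hit.interval.end + extend - total))
        placements.append(("3p", hit.interval.start - extend))
    out = []
    for arm, start in placements:
        flags = []
        lo, hi = start, start + total
        if lo < 0 or hi > len(scaffold):
            lo, hi = max(0, lo), min(len(scaffold), hi)
            flags.append("edge")
        if hi - lo < 30:
            continue
        strand = hit.interval.strand
        seq = scaffold[lo:hi].upper().replace("T", "U")
        if strand == "-":
            seq = reverse_complement(seq)
        if "N" in seq:
            continue
        # mature span in window-oriented coordinates
        if strand == "+":
            mspan = (hit.interval.start - lo, hit.interval.end - lo)
        else:
            mspan = (hi - hit.interval.end, hi - hit.interval.start)
        fr = fold(seq)
        # trim to the stem-loop around the matched mature and refold;
        # over-extended stems (background swept in through small bulges) can
        # break GC or refold into branches, so nested sub-stems containing
        # the mature are tried from the outside in until one passes
        nested = stem_spans_nested(fr.dotbracket, mspan)
        spans = [s for s in nested
                 if s[0] <= mspan[0] and s[1] >= mspan[1]
                 and s[1] - s[0] >= 40]
        if not spans:
            spans = [s for s in nested[-1:] if s[1] - s[0] >= 30]
        if not spans:
            continue
        spans = spans[::-1][:_MAX_TRIM_TRIES]
        chosen = None
        for span in spans:
            seq2 = seq[span[0]:span[1]]
            fr2 = fold(seq2)
            cand2 = PrecursorCandidate(
                "t", GenomeInterval("_", 0, 1 + len(seq2)), seq2, fold=fr2)
            if evaluate(cand2, FilterCriteria()).pass_all:
                chosen = (span, seq2, fr2)
                break
        if chosen is None:
            span = spans[0]
            seq2 = seq[span[0]:span[1]]
            chosen = (span, seq2, fold(seq2))
        span, seq2, fr2 = chosen
        if strand == "+":
            iv = GenomeInterval(hit.interval.scaffold_id, lo + span[0],
                                lo + span[1], "+")
        else:
            iv = GenomeInterval(hit.interval.scaffold_id, hi - span[1],
                                hi - span[0], "-")
        mature_rel = (mspan[0] - span[0], mspan[1] - span[0])
        cand = PrecursorCandidate(
            f"hom_{hit.query_id}_{format_locus(iv)}_{arm}", iv, seq2,
            fold=fr2, tracks={"homology"}, flags=flags,
            meta={"query_id": hit.query_id, "mature_arm": arm,
                  "mismatches": hit.mismatches,
                  "mature_interval": hit.interval,
                  "mature_rel": mature_rel})
        out.append(cand)
    return out


def resolve_overlaps(
    candidates: Sequence[PrecursorCandidate],
) -> list[PrecursorCandidate]:
    """Greedy minimum-MFE selection among same-strand overlapping candidates.

    Candidates are visited by ascending MFE (ties: longer precursor, then
    lexicographically smallest locus string) and kept unless they overlap an
    already-kept candidate on the same strand.  The output is overlap-free.
    """
    ordered = sorted(candidates,
                     key=lambda c: (c.mfe, -c.interval.length,
                                    format_locus(c.interval)))
    kept: list[PrecursorCandidate] = []
    for c in ordered:
        if not any(c.interval.overlaps(k.interval) for k in kept):
            kept.append(c)
    return sorted(kept, key=lambda c: (c.interval.scaffold_id,
                                       c.interval.start))
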