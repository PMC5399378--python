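"""Structure-only hairpin discovery across a genome.

Windows anchored at each scanned position are folded in ascending length
order (default sweep 60..130 step 10) and the shortest window passing the
filter battery is emitted.  A cheap inverted-repeat prescreen (banded
complementarity score, numba) decides which anchors are worth folding at
all; it is calibrated to be permissive (low threshold) so that genuine
stem-loops are never skipped, and only saves the cost of folding plainly
unstructured background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from ._params import encode_sequence
from .core_io import BedRecord, GenomeInterval, PrecursorCandidate
from .filtration import FilterCriteria, evaluate
from .rna_structure import fold, reverse_complement, stem_span

DEFAULT_WINDOW_LENGTHS = tuple(range(60, 131, 10))


@dataclass(frozen=True)
class HairpinScanParams:
    window_lengths: tuple = DEFAULT_WINDOW_LENGTHS
    min_loop: int = 5
    allow_gu: bool = True
    step: int = 10
    min_stem_pairs: int = 16
    stride: int = 5
    prescreen_min_score: int = 15
    both_strands: bool = False  # hairpins mirror onto the minus strand;
    # strand is resolved downstream from expression/homology evidence

    def __post_init__(self):
        if list(self.window_lengths) != sorted(self.window_lengths):
            raise ValueError("window_lengths must be ascending")
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")


# complementarity scores for the prescreen: +1 match, -1.5 mismatch
_COMP = np.zeros((5, 5), np.float32)
for _a, _b in [(1, 4), (4, 1), (2, 3), (3, 2)]:
    _COMP[_a, _b] = 1.0
_GU = np.zeros((5, 5), np.float32)
_GU[:] = _COMP
_GU[3, 4] = _GU[4, 3] = 0.5


@njit(cache=False)
def _best_invrep_score(x, comp, min_loop):
    """Best contiguous complementarity run over all anti-diagonals."""
    W = len(x)
    best = 0.0
    for c in range(2 * min_loop, 2 * W - 3):
        run = 0.0
        peak = 0.0
        tmax = (c - min_loop) // 2
        for t in range(max(0, c - W + 1), tmax + 1):
            u = c - t
            if u >= W:
                continue
            sc = comp[x[t], x[u]]
            if sc > 0:
                run += sc
            else:
                run -= 1.5
                if run < 0:
                    run = 0.0
            if run > peak:
                peak = run
        if peak > best:
            best = peak
    return best


@njit(cache=False)
def _prescreen_positions(enc, stride, wmax, min_loop, comp, threshold):
    n = len(enc)
    out = np.zeros((n // stride + 1,), np.int64)
    cnt = 0
    for p in range(0, n - 50, stride):
        w = min(wmax, n - p)
        score = _best_invrep_score(enc[p:p + w], comp, min_loop)
        if score >= threshold:
            out[cnt] = p
            cnt += 1
    return out[:cnt]


def _stem_pairs(dotbracket: str) -> int:
    return dotbracket.count("(")


def shortest_passing_window(
    region: str,
    must_span: tuple[int, int] | None,
    criteria: FilterCriteria,
    window_lengths: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
    min_stem_pairs: int = 0,
    temperature: float = 37.0,
    placement_stride: int = 5,
    prescreen_min_score: float = 15.0,
):
    """Shortest window of ``region`` passing the filter battery.

    Windows are tried in ascending length; placements must contain
    ``must_span`` when given.  At the winning length the placement with the
    lowest MFE is returned as ``(start, end, FoldResult)``.  Regions without
    any inverted-repeat signal are rejected without folding.
    """
    L = len(region)
    if prescreen_min_score and "N" not in region:
        score = _best_invrep_score(encode_sequence(region), _GU, 5)
        if score < prescreen_min_score:
            return None
    for wl in window_lengths:
        if wl > L:
            break
        if must_span is not None:
            lo = max(0, must_span[1] - wl)
            hi = min(L - wl, must_span[0])
        else:
            lo, hi = 0, L - wl
        best = None
        starts = list(range(lo, hi + 1, placement_stride))
        if starts and starts[-1] != hi:
            starts.append(hi)
        for s in starts:
            window = region[s:s + wl]
            if "N" in window:
                continue
            fr = fold(window, temperature=temperature)
            if min_stem_pairs and _stem_pairs(fr.dotbracket) < min_stem_pairs:
                continue
            cand = PrecursorCandidate(
                "win", GenomeInterval("_", 1, 1 + wl), window, fold=fr)
            if not evaluate(cand, criteria).pass_all:
                continue
            if best is None or fr.mfe < best[2].mfe:
                best = (s, s + wl, fr)
        if best is not None:
            return best
    return None


def scan_hairpins(
    genome: Mapping[str, str],
    params: HairpinScanParams = HairpinScanParams(),
    criteria: FilterCriteria = FilterCriteria(),
    mask: Sequence[BedRecord] = (),
) -> list[PrecursorCandidate]:
    """Scan a genome for filter-passing hairpins on both strands.

    Deterministic; masked regions are excluded; per overlap component only
    the lowest-MFE candidate survives.
    """
    comp = _GU if params.allow_gu else _COMP
    wmax = max(params.window_lengths)
    candidates: list[PrecursorCandidate] = []
    mask_by_scaffold: dict[str, list[BedRecord]] = {}
    for m in mask:
        mask_by_scaffold.setdefault(m.interval.scaffold_id, []).append(m)

    strands = "+-" if params.both_strands else "+"
    for sid in sorted(genome):
        plus = genome[sid].upper().replace("T", "U")
        n = len(plus)
        for strand in strands:
            seq = plus if strand == "+" else reverse_complement(plus)
            enc = encode_sequence(seq)
            anchors = _prescreen_positions(
                enc, params.stride, wmax, params.min_loop, comp,
                float(params.prescreen_min_score))
            for p in anchors:
                region = seq[p:p + wmax]
                hit = _emit_shortest_at_anchor(region, params, criteria)
                if hit is None:
                    continue
                wl, fr = hit
                # trim to the stem-loop proper when it still passes
                win_seq, win_fr, off = region[:wl], fr, 0
                span = stem_span(fr.dotbracket)
                if span is not None and span[1] - span[0] >= 30:
                    seq2 = region[span[0]:span[1]]
                    fr2 = fold(seq2)
                    cand2 = PrecursorCandidate(
                        "t", GenomeInterval("_", 1, 2), seq2, fold=fr2)
                    if evaluate(cand2, criteria).pass_all:
                        win_seq, win_fr, off = seq2, fr2, span[0]
                wl2 = len(win_seq)
                if strand == "+":
                    iv = GenomeInterval(sid, int(p) + off,
                                        int(p) + off + wl2, "+")
                else:
                    iv = GenomeInterval(sid, n - int(p) - off - wl2,
                                        n - int(p) - off, "-")
                if _overlaps_mask(iv, mask_by_scaffold.get(sid, [])):
                    continue
                cand = PrecursorCandidate(
                    f"dn_{sid}_{iv.start}_{strand}", iv, win_seq,
                    fold=win_fr, tracks={"denovo"},
                    meta={"anchor": int(p), "anchor_strand": strand,
                          "window_length": wl})
                candidates.append(cand)
    return _dedupe_overlaps(candidates)


def _emit_shortest_at_anchor(region, params, criteria):
    comp = _GU if params.allow_gu else _COMP
    enc = None
    for wl in params.window_lengths:
        if wl > len(region):
            break
        window = region[:wl]
        if "N" in window:
            continue
        if enc is None:
            enc = encode_sequence(region)
        # window must itself contain the inverted repeat before folding
        if _best_invrep_score(enc[:wl], comp, params.min_loop) \
                < params.prescreen_min_score:
            continue
        fr = fold(window)
        if _stem_pairs(fr.dotbracket) < params.min_stem_pairs:
            continue
        cand = PrecursorCandidate(
            "win", GenomeInterval("_", 1, 1 + wl), window, fold=fr)
        if evaluate(cand, criteria).pass_all:
            return wl, fr
    return None


def _overlaps_mask(iv: GenomeInterval, mask: list[BedRecord]) -> bool:
    return any(iv.overlaps(m.interval, same_strand=False) for m in mask)


def _dedupe_overlaps(cands: list[PrecursorCandidate]) -> list[PrecursorCandidate]:
    """One representative (minimum MFE) per same-strand overlap component."""
    by_key = sorted(cands, key=lambda c: (c.interval.scaffold_id,
                                          c.interval.strand,
                                          c.interval.start))
    out: list[PrecursorCandidate] = []
    group: list[PrecursorCandidate] = []

    def flush():
        # the scan keeps the shortest passing hairpin at a locus; among
        # equal sweep lengths the lowest MFE wins
        if group:
            out.append(min(group, key=lambda c: (
                c.meta.get("window_length", 10**9), c.mfe,
                c.interval.start)))

    for c in by_key:
        if group and (c.interval.scaffold_id == group[-1].interval.scaffold_id
                      and c.interval.strand == group[-1].interval.strand
                      and c.interval.start < max(g.interval.end for g in group)):
            group.append(c)
        else:
            flush()
            group = [c]
    flush()
    return sorted(out, key=lambda c: (c.interval.scaffold_id,
                                      c.interval.start))


# ---------------------------------------------------------------------------
# redundancy clustering


def _ungapped_identity(a: str, b: str) -> float:
    """Best ungapped identity over the shorter sequence, all offsets."""
    if len(a) < len(b):
        a, b = b, a
    ea, eb = encode_sequence(a), encode_sequence(b)
    la, lb = len(ea), len(eb)
    best = 0
    for off in range(la - lb + 1):
        m = int(np.count_nonzero(ea[off:off + lb] == eb))
        if m > best:
            best = m
    return best / lb


def cluster_and_flag_repeats(
    candidates: Sequence[PrecursorCandidate],
    identity_threshold: float = 0.9,
    repeat_min_members: int = 3,
):
    """Greedy longest-first clustering; repeat-like clusters are excluded.

    Clusters with at least ``repeat_min_members`` members at distinct loci
    are flagged as repeats and dropped; each surviving cluster is represented
    by its longest member.  Returns ``(kept, excluded_clusters)``.
    """
    order = sorted(candidates, key=lambda c: (-len(c.sequence), c.id))
    reps: list[PrecursorCandidate] = []
    clusters: dict[str, list[PrecursorCandidate]] = {}
    for cand in order:
        home = None
        for rep in reps:
            if any(_ungapped_identity(m.sequence, cand.sequence)
                   >= identity_threshold for m in clusters[rep.id]):
                home = rep
                break
        if home is None:
            reps.append(cand)
            clusters[cand.id] = [cand]
        else:
            clusters[home.id].append(cand)
    kept, excluded = [], []
    for rep in reps:
        members = clusters[rep.id]
        loci = {(m.interval.scaffold_id, m.interval.start) for m in members}
        if len(members) >= repeat_min_members and len(loci) >= repeat_min_members:
            excluded.append(members)
            continue
        rep.meta["cluster_size"] = len(members)
        kept.append(rep)
    return sorted(kept, key=lambda c: (c.interval.scaffold_id,
                                       c.interval.start)), excluded
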