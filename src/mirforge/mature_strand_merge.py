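"""Mature 5p/3p arm inference, strand resolution, cross-track merging with
Venn accounting, seed-family assignment, conservation classes, and the
second-genome homolog rescan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._search import GenomeSearcher
from .core_io import GenomeInterval, PrecursorCandidate, SequenceRecord
from .filtration import FilterCriteria
from .rna_structure import FoldResult, hairpin_loop_runs, reverse_complement

PAIR_LEN_MIN, PAIR_LEN_MAX = 22, 27
PAIR_SEP_MIN, PAIR_SEP_MAX = 5, 50
PAIR_MAX_MISMATCH = 6
FALLBACK_ARM_LEN = 24

EVIDENCE_PRIORITY = ("reference_mature_hit", "est_hit", "smallrna_hit")


@dataclass(frozen=True)
class MatureCall:
    """Inferred mature arm spans, half-open and precursor-relative."""

    p5: tuple[int, int]
    p3: tuple[int, int]
    method: str  # read_guided | pair_pattern | fallback24 | planted
    pair_mismatches: int = 0


@dataclass(frozen=True)
class StrandEvidence:
    source: str  # one of EVIDENCE_PRIORITY
    strand: str
    score: float

    def __post_init__(self):
        if self.source not in EVIDENCE_PRIORITY:
            raise ValueError(f"unknown evidence source {self.source!r}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class StrandDecision:
    strand: str
    provenance: str
    tie: bool = False


def infer_mature(sequence: str, fold: FoldResult) -> MatureCall:
    """Infer paired 5p/3p arms from a single-loop fold.

    Searches 5'-arm segments of 22-27 nt whose reverse complement matches a
    3'-arm segment with at most 6 mismatches, separated by 5-50 nt; among
    valid pairs the one abutting the loop most closely wins.  Falls back to
    the 24-nt windows flanking the loop when no pair exists.
    """
    loops = hairpin_loop_runs(fold.dotbracket)
    if len(loops) != 1:
        raise ValueError(
            f"mature inference requires exactly one hairpin loop, "
            f"found {len(loops)}")
    loop_start, loop_end = loops[0]
    L = len(sequence)
    best = None  # (loop_distance, -length, start5, mismatches, call)
    for alen in range(PAIR_LEN_MIN, PAIR_LEN_MAX + 1):
        for end5 in range(min(loop_start, L - alen), alen - 1, -1):
            start5 = end5 - alen
            if start5 < 0:
                continue
            seg5 = sequence[start5:end5]
            target = reverse_complement(seg5)
            lo3 = max(loop_end, end5 + PAIR_SEP_MIN)
            hi3 = min(L - alen, end5 + PAIR_SEP_MAX)
            for start3 in range(lo3, hi3 + 1):
                seg3 = sequence[start3:start3 + alen]
                mm = sum(a != b for a, b in zip(target, seg3))
                if mm > PAIR_MAX_MISMATCH:
                    continue
                dist = (loop_start - end5) + (start3 - loop_end)
                key = (dist, -alen, start5, mm)
                if best is None or key < best[0]:
                    call = MatureCall(
                        p5=(start5, end5), p3=(start3, start3 + alen),
                        method="pair_pattern", pair_mismatches=mm)
                    best = (key, call)
    if best is not None:
        return best[1]
    p5 = (max(0, loop_start - FALLBACK_ARM_LEN), loop_start)
    p3 = (loop_end, min(L, loop_end + FALLBACK_ARM_LEN))
    return MatureCall(p5=p5, p3=p3, method="fallback24")


def infer_strand(candidate: PrecursorCandidate,
                 evidence: Sequence[StrandEvidence]) -> StrandDecision:
    """Resolve the template strand from prioritized evidence classes.

    The first non-empty class in reference > EST > small-RNA order decides;
    within it the best-scoring item wins, exact ties default to plus with a
    flag; no evidence at all defaults to plus.
    """
    for source in EVIDENCE_PRIORITY:
        items = [e for e in evidence if e.source == source]
        if not items:
            continue
        top = max(e.score for e in items)
        strands = {e.strand for e in items if e.score == top}
        if len(strands) == 1:
            return StrandDecision(strands.pop(), source)
        return StrandDecision("+", source, tie=True)
    return StrandDecision("+", "default_plus")


# ---------------------------------------------------------------------------
# merging


@dataclass
class MiRNACatalogEntry:
    id: str
    interval: GenomeInterval
    tracks: frozenset
    sequence: str
    mfe: float
    mature: MatureCall | None
    arm_seeds: dict = field(default_factory=dict)  # "5p"/"3p" -> 6-mer
    conservation_class: str | None = None

    def arm_ids(self) -> list[str]:
        return [f"{self.id}_5p", f"{self.id}_3p"]


VENN_REGIONS = ("homology_only", "denovo_only", "smallrna_only",
                "homology_denovo", "homology_smallrna", "denovo_smallrna",
                "all_three")


def merge_tracks(homology: Sequence[PrecursorCandidate],
                 denovo: Sequence[PrecursorCandidate],
                 smallrna: Sequence[PrecursorCandidate],
                 reciprocal_overlap: float = 0.5):
    """Unify per-track candidates into one catalog.

    Candidates whose precursor intervals overlap reciprocally by at least
    ``reciprocal_overlap`` on the same strand are one locus; the lowest-MFE
    member represents it.  Returns ``(catalog, venn_counts)`` where
    ``venn_counts`` maps the seven regions plus ``union``; the union obeys
    inclusion-exclusion by construction.
    """
    tagged: list[tuple[str, PrecursorCandidate]] = []
    for track, cands in (("homology", homology), ("denovo", denovo),
                         ("smallrna", smallrna)):
        for c in cands:
            tagged.append((track, c))
    n = len(tagged)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(n):
        for j in range(i + 1, n):
            a, b = tagged[i][1].interval, tagged[j][1].interval
            if not a.overlaps(b):
                continue
            ov = a.overlap_length(b)
            if ov >= reciprocal_overlap * a.length and \
               ov >= reciprocal_overlap * b.length:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    catalog: list[MiRNACatalogEntry] = []
    counts = dict.fromkeys(VENN_REGIONS, 0)
    for gi, (root, members) in enumerate(sorted(
            groups.items(), key=lambda kv: min(kv[1]))):
        cands = [tagged[i][1] for i in members]
        tracks = frozenset(tagged[i][0] for i in members)
        rep = min(cands, key=lambda c: (c.mfe, -c.interval.length,
                                        c.interval.start))
        region = _venn_region(tracks)
        counts[region] += 1
        seeds = {}
        if rep.mature is not None:
            for arm, span in (("5p", rep.mature.p5), ("3p", rep.mature.p3)):
                if span[1] - span[0] >= 7:
                    seeds[arm] = assign_family(rep.sequence[span[0]:span[1]])
        catalog.append(MiRNACatalogEntry(
            id=f"locus{gi:04d}", interval=rep.interval, tracks=tracks,
            sequence=rep.sequence, mfe=rep.mfe, mature=rep.mature,
            arm_seeds=seeds))
    counts["union"] = len(catalog)
    return catalog, counts


def _venn_region(tracks: frozenset) -> str:
    if len(tracks) == 3:
        return "all_three"
    if len(tracks) == 1:
        return f"{next(iter(tracks))}_only"
    return "_".join(t for t in ("homology", "denovo", "smallrna")
                    if t in tracks)


def assign_family(mature_sequence: str) -> str:
    """Family seed: mature nucleotides 2-7 (1-based)."""
    seq = mature_sequence.upper().replace("T", "U")
    if len(seq) < 7:
        raise ValueError(
            f"mature of {len(seq)} nt is too short for a 2-7 seed")
    return seq[1:7]


# ---------------------------------------------------------------------------
# conservation


@dataclass
class PresenceMatrix:
    """Family x species boolean presence table with clade annotations."""

    table: pd.DataFrame                    # bool, index=family, cols=species
    clades: Mapping[str, str]              # species -> tunicate|other_metazoan
    focal_species: str

    def __post_init__(self):
        if self.focal_species not in self.table.columns:
            raise ValueError(
                f"focal species {self.focal_species!r} missing from matrix")
        unknown = set(self.table.columns) - set(self.clades)
        if unknown:
            raise ValueError(f"species without clade annotation: {unknown}")

    @classmethod
    def from_tsv(cls, path, clade_row: str = "clade",
                 focal_species: str | None = None) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        clades = df.loc[clade_row].to_dict()
        table = df.drop(index=clade_row).astype(int).astype(bool)
        if focal_species is None:
            focal_species = df.columns[0]
        return cls(table, clades, focal_species)


CONSERVATION_CLASSES = ("widely_conserved", "tunicate_specific",
                        "species_specific")


def classify_conservation(families: Iterable[str],
                          matrix: PresenceMatrix) -> dict[str, tuple[str, bool]]:
    """Classify each family; returns family -> (class, matched_in_matrix)."""
    out = {}
    tunicate_cols = [c for c in matrix.table.columns
                     if matrix.clades[c] == "tunicate"]
    other_cols = [c for c in matrix.table.columns
                  if matrix.clades[c] != "tunicate"]
    for fam in families:
        if fam not in matrix.table.index:
            out[fam] = ("species_specific", False)
            continue
        row = matrix.table.loc[fam]
        if other_cols and bool(row[other_cols].any()):
            out[fam] = ("widely_conserved", True)
        elif int(row[tunicate_cols].sum()) >= 2:
            out[fam] = ("tunicate_specific", True)
        else:
            out[fam] = ("species_specific", True)
    return out


# ---------------------------------------------------------------------------
# homolog rescan against a second genome


@dataclass
class RescanResult:
    mature_id: str
    hit: bool
    best_mismatches: int | None
    canonical_stemloop: bool


def rescan_homologs(matures: Sequence[SequenceRecord],
                    other_genome: Mapping[str, str],
                    max_mismatches: int = 4,
                    min_length: int = 20,
                    refold_temperature: float = 18.0,
                    flank: int = 100,
                    criteria: FilterCriteria = FilterCriteria()):
    """Match each mature against a second genome and refold matched loci.

    Per mature: best full-length ungapped hit within ``max_mismatches``;
    matched loci +/- ``flank`` are hairpin-scanned at the given temperature
    with the full filter battery deciding "canonical".  Returns
    ``(results, summary)`` with summary fractions on the printed scale.
    """
    from .denovo_track import shortest_passing_window

    searcher = GenomeSearcher(other_genome)
    results: list[RescanResult] = []
    for rec in matures:
        seq = rec.as_rna()
        if len(seq) < min_length:
            results.append(RescanResult(rec.id, False, None, False))
            continue
        hits = searcher.find([seq], max_mismatches, min_query_length=min_length)
        if not hits:
            results.append(RescanResult(rec.id, False, None, False))
            continue
        best_mm = min(h.mismatches for h in hits)
        canonical = False
        for h in sorted(hits, key=lambda h: (h.mismatches, h.scaffold_id,
                                             h.start))[:5]:
            scaffold = other_genome[h.scaffold_id]
            lo = max(0, h.start - flank)
            hi = min(len(scaffold), h.start + len(seq) + flank)
            region = scaffold[lo:hi].upper().replace("T", "U")
            if "N" in region:
                continue
            if h.strand == "-":
                span = (len(region) - (h.start + len(seq) - lo),
                        len(region) - (h.start - lo))
                region = reverse_complement(region)
            else:
                span = (h.start - lo, h.start + len(seq) - lo)
            win = shortest_passing_window(
                region, span, criteria, temperature=refold_temperature)
            if win is not None:
                canonical = True
                break
        results.append(RescanResult(rec.id, True, best_mm, canonical))
    n = len(results)
    n_hit = sum(r.hit for r in results)
    n_canon = sum(r.canonical_stemloop for r in results)
    summary = {
        "n_matures": n,
        "n_hit": n_hit,
        "pct_hit": 100.0 * n_hit / n if n else 0.0,
        "n_canonical": n_canon,
        "pct_canonical_of_hits": 100.0 * n_canon / n_hit if n_hit else 0.0,
    }
    return results, summary
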