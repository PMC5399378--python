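"""Deterministic synthetic genomes with planted precursors and full truth.

Generates: an i.i.d. background genome at a configurable GC content, planted
single-loop stem-loop precursors (verified to pass the filter battery at
generation time), a palindromic repeat family, 26-nt reads sampled from the
planted matures with substitution errors, reference mature queries diverged
by an exact mismatch count, and simple gene models whose 3'UTRs may carry
planted perfect-complement target sites.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import (GenomeInterval, Gff3Feature, SequenceRecord,
                      fetch)
from .filtration import FilterCriteria, evaluate
from .rna_structure import fold, reverse_complement

ALL_TRACKS = frozenset({"homology", "denovo", "smallrna"})

_NTS = np.array(list("ACGU"))


class GenerationError(RuntimeError):
    """Requested parameters could not produce a filter-passing precursor."""


@dataclass(frozen=True)
class SyntheticConfig:
    genome_length: int = 200_000
    background_gc: float = 0.35
    n_precursors: int = 50
    stem_len_range: tuple[int, int] = (25, 40)
    loop_len_range: tuple[int, int] = (6, 12)
    stem_mismatch_range: tuple[int, int] = (0, 2)
    gu_fraction: float = 0.10
    n_repeat_copies: int = 0
    read_depth: int = 30
    read_error_rate: float = 0.01
    read_length: int = 26
    divergence_to_reference: int = 0
    n_genes: int = 0
    n_target_genes: int = 0
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.stem_len_range, self.loop_len_range,
                       self.stem_mismatch_range):
            if lo > hi:
                raise ValueError("empty range in config")
        if self.loop_len_range[0] < 5:
            raise ValueError("minimum hairpin loop length is 5")
        if not (0 <= self.background_gc <= 1 and 0 <= self.gu_fraction <= 1
                and 0 <= self.read_error_rate <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class TruthRecord:
    id: str
    precursor: GenomeInterval
    p5: GenomeInterval
    p3: GenomeInterval
    p5_rel: tuple[int, int]  # precursor-relative arm spans
    p3_rel: tuple[int, int]
    family_seed: str
    planted_in: frozenset = ALL_TRACKS
    is_repeat: bool = False
    target_genes: list = field(default_factory=list)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_NTS, size=n, p=p))


def make_precursor(stem_len: int, loop_len: int, n_mismatch: int,
                   gu_frac: float, rng: np.random.Generator,
                   criteria: FilterCriteria = FilterCriteria(),
                   max_tries: int = 60):
    """Build one canonical stem-loop precursor that passes the filter battery.

    Returns ``(sequence, p5_span, p3_span)`` with precursor-relative
    half-open mature arm spans.  Arm B is the reverse complement of arm A
    with ``n_mismatch`` substitutions plus a ``gu_frac`` share of pairs
    converted to G-U wobbles.
    """
    if loop_len < 5:
        raise ValueError("loop_len must be >= 5")
    if stem_len < 16:
        raise ValueError("stem_len must be >= 16")
    if n_mismatch > stem_len // 2:
        raise GenerationError(
            f"cannot place {n_mismatch} mismatches in a {stem_len} bp stem")
    from .core_io import PrecursorCandidate  # local import to avoid cycle noise
    from .mature_strand_merge import MatureCall

    mature_len = min(22, stem_len)
    for _ in range(max_tries):
        arm_a = _random_seq(rng, stem_len, 0.5)
        loop = _random_seq(rng, loop_len, 0.4)
        arm_b = list(reverse_complement(arm_a))
        # positions in arm_b paired with arm_a position i: stem_len-1-i
        editable = list(range(stem_len))
        rng.shuffle(editable)
        n_gu = int(round(gu_frac * stem_len))
        gu_sites = [i for i in editable if arm_a[i] in "GU"][:n_gu]
        for i in gu_sites:
            j = stem_len - 1 - i
            arm_b[j] = "U" if arm_a[i] == "G" else "G"
        mm_sites = [i for i in editable if i not in gu_sites][:n_mismatch]
        for i in mm_sites:
            j = stem_len - 1 - i
            comp = reverse_complement(arm_a[i])
            choices = [c for c in "ACGU"
                       if c != comp and not _pairs(arm_a[i], c)]
            arm_b[j] = rng.choice(choices)
        seq = arm_a + loop + "".join(arm_b)
        p5 = (stem_len - mature_len, stem_len)
        p3 = (stem_len + loop_len, stem_len + loop_len + mature_len)
        fr = fold(seq)
        cand = PrecursorCandidate(
            "gen", GenomeInterval("S1", 0, len(seq)), seq, fold=fr,
            mature=MatureCall(p5=p5, p3=p3, method="planted"))
        if evaluate(cand, criteria).pass_all:
            return seq, p5, p3
    raise GenerationError(
        f"no passing precursor after {max_tries} tries "
        f"(stem {stem_len}, loop {loop_len}, mm {n_mismatch})")


def _pairs(a: str, b: str) -> bool:
    return (a + b) in {"AU", "UA", "CG", "GC", "GU", "UG"}


def _seed_of(mature_rna: str) -> str:
    return mature_rna[1:7]


def plant_genome(config: SyntheticConfig):
    """Generate ``(genome, truth_records)`` for one scaffold genome."""
    rng = np.random.default_rng(config.seed)
    max_pre_len = 2 * config.stem_len_range[1] + config.loop_len_range[1]
    slot = max_pre_len + 200
    n_slots = config.n_precursors + config.n_repeat_copies
    if n_slots * slot + 200 > config.genome_length:
        raise ValueError(
            f"genome too small: need >= {n_slots * slot + 200} nt "
            f"for {n_slots} plantings")
    background = _random_seq(rng, config.genome_length, config.background_gc)
    genome = {"S1": background.replace("U", "T")}

    # choose non-overlapping slots
    gap = (config.genome_length - n_slots * slot) // (n_slots + 1)
    offsets = [gap + i * (slot + gap) for i in range(n_slots)]

    truth: list[TruthRecord] = []
    seqs_to_write: list[tuple[int, str]] = []

    repeat_seq = None
    if config.n_repeat_copies:
        repeat_seq, _, _ = make_precursor(
            int(rng.integers(*_incl(config.stem_len_range))),
            int(rng.integers(*_incl(config.loop_len_range))),
            0, config.gu_fraction, rng)

    for i in range(config.n_precursors):
        stem = int(rng.integers(*_incl(config.stem_len_range)))
        loop = int(rng.integers(*_incl(config.loop_len_range)))
        mm = int(rng.integers(*_incl(config.stem_mismatch_range)))
        seq, p5_rel, p3_rel = make_precursor(stem, loop, mm,
                                             config.gu_fraction, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        start = offsets[i] + int(rng.integers(0, 100))
        L = len(seq)
        pre_iv = GenomeInterval("S1", start, start + L, strand)
        p5_iv = _rel_to_genomic(pre_iv, p5_rel)
        p3_iv = _rel_to_genomic(pre_iv, p3_rel)
        planted = seq if strand == "+" else reverse_complement(seq)
        seqs_to_write.append((start, planted))
        mature_rna = seq[p5_rel[0]:p5_rel[1]]
        truth.append(TruthRecord(
            id=f"mir{i:03d}", precursor=pre_iv, p5=p5_iv, p3=p3_iv,
            p5_rel=p5_rel, p3_rel=p3_rel, family_seed=_seed_of(mature_rna)))

    for r in range(config.n_repeat_copies):
        start = offsets[config.n_precursors + r] + int(rng.integers(0, 100))
        pre_iv = GenomeInterval("S1", start, start + len(repeat_seq), "+")
        seqs_to_write.append((start, repeat_seq))
        truth.append(TruthRecord(
            id=f"rep{r:03d}", precursor=pre_iv, p5=pre_iv, p3=pre_iv,
            p5_rel=(0, 1), p3_rel=(0, 1), family_seed="",
            planted_in=frozenset(), is_repeat=True))

    chars = list(genome["S1"])
    for start, seq in seqs_to_write:
        chars[start:start + len(seq)] = list(seq.replace("U", "T"))
    genome["S1"] = "".join(chars)
    return genome, truth


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return rng_pair[0], rng_pair[1] + 1


def _rel_to_genomic(pre: GenomeInterval, rel: tuple[int, int]) -> GenomeInterval:
    if pre.strand == "+":
        return GenomeInterval(pre.scaffold_id, pre.start + rel[0],
                              pre.start + rel[1], "+")
    return GenomeInterval(pre.scaffold_id, pre.end - rel[1],
                          pre.end - rel[0], "-")


def make_reads(truth: list[TruthRecord], genome, depth: int,
               error_rate: float, rng: np.random.Generator,
               read_length: int = 26, jitter: int = 2,
               n_background: int = 0) -> list[SequenceRecord]:
    """Sample ~Poisson(depth) 26-nt reads per planted mature (5p arm).

    Reads start near the mature 5' end (uniform jitter), run into the
    precursor, and receive i.i.d. substitution errors.  Read ids encode their
    origin for truth evaluation.
    """
    reads: list[SequenceRecord] = []
    for rec in truth:
        if rec.is_repeat or "smallrna" not in rec.planted_in:
            continue
        pre_rna = fetch(genome, rec.precursor, rna=True)
        n = int(rng.poisson(depth))
        for r in range(n):
            off = int(rng.integers(-jitter, jitter + 1))
            start = min(max(0, rec.p5_rel[0] + off),
                        len(pre_rna) - read_length)
            read = _mutate(pre_rna[start:start + read_length], error_rate, rng)
            reads.append(SequenceRecord(
                f"read_{rec.id}_{r}", read.replace("U", "T")))
    scaffolds = sorted(genome)
    for b in range(n_background):
        sid = scaffolds[int(rng.integers(len(scaffolds)))]
        start = int(rng.integers(0, len(genome[sid]) - read_length))
        seq = genome[sid][start:start + read_length].upper().replace("T", "U")
        if "N" in seq:
            continue
        reads.append(SequenceRecord(f"read_bg_{b}", seq.replace("U", "T")))
    return reads


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < error_rate:
            out[i] = rng.choice([c for c in "ACGU" if c != out[i]])
    return "".join(out)


def make_reference_matures(truth: list[TruthRecord], genome, divergence: int,
                           rng: np.random.Generator) -> list[SequenceRecord]:
    """One reference query per planted mature (5p arm), diverged by exactly
    ``divergence`` substitutions placed outside the seed (positions 2-7)."""
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    records = []
    for rec in truth:
        if rec.is_repeat or "homology" not in rec.planted_in:
            continue
        mature = fetch(genome, rec.p5, rna=True)
        if divergence > len(mature) - 6:
            raise ValueError(
                f"divergence {divergence} exceeds non-seed positions "
                f"of a {len(mature)} nt mature")
        editable = [i for i in range(len(mature)) if not 1 <= i <= 6]
        pre = fetch(genome, rec.precursor, rna=True)
        for _ in range(50):
            sites = rng.choice(editable, size=divergence, replace=False)
            seq = list(mature)
            for i in sites:
                seq[i] = rng.choice([c for c in "ACGU" if c != seq[i]])
            query = "".join(seq)
            # the star arm or a shifted window must not sit closer than the
            # requested divergence, or the planted cutoff behavior breaks
            if _min_distance_to(query, pre) >= divergence:
                break
        records.append(SequenceRecord(f"ref_{rec.id}", query,
                                      f"reference mature for {rec.id}"))
    return records


def _min_distance_to(query: str, region: str) -> int:
    """Minimum sliding Hamming distance of query (either orientation)."""
    best = len(query)
    for q in (query, reverse_complement(query)):
        for off in range(len(region) - len(q) + 1):
            mm = sum(a != b for a, b in zip(region[off:off + len(q)], q))
            if mm < best:
                best = mm
    return best


def make_gene_models(truth: list[TruthRecord], genome,
                     n_genes: int, n_target_genes: int,
                     rng: np.random.Generator, utr_length: int = 400):
    """Plant CDS gene models in background regions; a subset of their 3'UTRs
    receives a perfect reverse-complement site for a planted mature.

    Mutates ``genome`` in place (writes target sites into UTRs); returns
    ``(gff_features, updated_truth)`` where target gene ids are appended to
    the donor truth records.
    """
    if n_target_genes > n_genes:
        raise ValueError("n_target_genes cannot exceed n_genes")
    sid = sorted(genome)[0]
    glen = len(genome[sid])
    occupied = sorted((r.precursor.start - 150, r.precursor.end + 150)
                      for r in truth)
    gene_len, span = 300, 300 + utr_length + 100
    free: list[tuple[int, int]] = []
    prev = 0
    for s, e in occupied + [(glen, glen)]:
        if s - prev >= span + 50:
            free.append((prev + 25, s - 25))
        prev = max(prev, e)
    slots = []
    for s, e in free:
        pos = s
        while pos + span <= e:
            slots.append(pos)
            pos += span
    if len(slots) < n_genes:
        raise ValueError(f"only {len(slots)} gene slots available")
    chosen = rng.choice(len(slots), size=n_genes, replace=False)
    feats, donors = [], [r for r in truth if not r.is_repeat]
    chars = list(genome[sid])
    for g, si in enumerate(sorted(int(c) for c in chosen)):
        start = slots[si]
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene{g:03d}"
        if strand == "+":
            cds = GenomeInterval(sid, start, start + gene_len, "+")
        else:
            cds = GenomeInterval(sid, start + utr_length,
                                 start + utr_length + gene_len, "-")
        feats.append(Gff3Feature(cds, "CDS", "mirforge_sim", {"ID": gene_id}))
        if g < n_target_genes and donors:
            donor = donors[int(rng.integers(len(donors)))]
            mature = fetch(genome, donor.p5, rna=True)
            site = reverse_complement(mature).replace("U", "T")
            off = int(rng.integers(30, utr_length - len(site) - 30))
            if strand == "+":
                pos = cds.end + off
                chars[pos:pos + len(site)] = list(site)
            else:
                pos = cds.start - off - len(site)
                chars[pos:pos + len(site)] = list(
                    reverse_complement(site).replace("U", "T"))
            donor.target_genes.append(gene_id)
    genome[sid] = "".join(chars)
    return feats, truth


def make_mrna_coverage(truth: list[TruthRecord], counts: dict[str, int]):
    """BED coverage records for exclude_expressed tests: id -> read count."""
    from .core_io import BedRecord
    return [BedRecord(rec.precursor, rec.id, float(counts.get(rec.id, 0)))
            for rec in truth]
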