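from collections import Counter
from itertools import combinations

import numpy as np
import pytest

from mirforge._params import (INF, PAIR_TYPE, encode_sequence,
                              params_for_temperature)
from mirforge.core_io import GenomeInterval, Gff3Feature, SequenceRecord
from mirforge.rna_structure import reverse_complement
from mirforge.target_scan import (HELIX_FRAMES, UTRRecord, dinucleotide_shuffle,
                                  duplex_energy, extract_utr3, fit_null,
                                  scan_targets)


# ---------------------------------------------------------------------------
# exhaustive oracle: enumerate every monotone pairing of miRNA positions to
# target positions and score it with the same printed energy tables


def oracle_duplex(mirna, window, frame, max_gap=10):
    p = params_for_temperature(37.0)
    mir = encode_sequence(mirna)
    tgt = encode_sequence(window)[::-1]
    a, b = frame[0] - 1, frame[1] - 1
    nm, nt = len(mir), len(tgt)
    rtype = [0, 2, 1, 4, 3, 6, 5]

    def pair_t(i, j):
        return int(PAIR_TYPE[mir[i], tgt[j]])

    best = None
    # enumerate matchings as increasing index sequences on both molecules
    def extend(pairs):
        nonlocal best
        if pairs:
            # score the complete matching if it satisfies the constraint
            covered = {i for i, _ in pairs}
            if all(i in covered for i in range(a, b + 1)):
                e = p.duplex_init
                t0 = pair_t(*pairs[0])
                tl = pair_t(*pairs[-1])
                if t0 > 2:
                    e += p.terminal_au
                if tl > 2:
                    e += p.terminal_au
                for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
                    n1, n2 = i2 - i1 - 1, j2 - j1 - 1
                    t1, t2 = pair_t(i1, j1), pair_t(i2, j2)
                    if n1 == 0 and n2 == 0:
                        e += p.stack[t1, rtype[t2]]
                    elif n1 == 0 or n2 == 0:
                        nl = n1 + n2
                        e += p.bulge[nl]
                        if nl == 1:
                            e += p.stack[t1, rtype[t2]]
                        else:
                            e += (p.terminal_au if t1 > 2 else 0)
                            e += (p.terminal_au if t2 > 2 else 0)
                    else:
                        e += p.internal[min(30, n1 + n2)]
                        e += min(p.ninio_max, abs(n1 - n2) * p.ninio)
                if best is None or e < best:
                    best = e
            li, lj = pairs[-1]
        else:
            li, lj = -1, -1
        i_hi = min(nm, li + max_gap + 2) if pairs else nm
        j_hi = min(nt, lj + max_gap + 2) if pairs else nt
        for i in range(li + 1, i_hi):
            for j in range(lj + 1, j_hi):
                if pair_t(i, j) > 0:
                    extend(pairs + [(i, j)])

    extend([])
    return None if best is None else best / 100.0


class TestDuplexEnergy:
    def test_perfect_complement_is_optimal(self, rng):
        mir = "UGAGGUAGUAGGUUGUAUAGUU"
        perfect = reverse_complement(mir)
        e_perfect = duplex_energy(mir, perfect, (2, 7))
        for _ in range(5):
            window = "".join(rng.choice(list("ACGU"), len(perfect)))
            e = duplex_energy(mir, window, (2, 7))
            if e is not None:
                assert e_perfect <= e

    def test_unsatisfiable_constraint(self):
        mir = "UGAGGUAGUAGGUUGUAUAGUU"
        assert duplex_energy(mir, "A" * 30, (2, 7)) is None

    @pytest.mark.parametrize("frame", [(1, 6), (2, 7), (3, 8)])
    def test_matches_exhaustive_oracle_toy(self, frame, rng):
        # toy scale (10-nt strand, small gap cap) keeps full enumeration of
        # constrained duplex alignments feasible; exercises the DP kernel
        from mirforge._params import RTYPE
        from mirforge.target_scan import _duplex_dp
        p = params_for_temperature(37.0)
        for trial in range(6):
            mir = "".join(rng.choice(list("ACGU"), 10, p=[.3, .2, .2, .3]))
            window = list(reverse_complement(mir))
            for i in rng.choice(10, size=2, replace=False):
                window[i] = rng.choice(list("ACGU"))
            window = "".join(window) + "".join(rng.choice(list("ACGU"), 2))
            a, b = frame[0] - 1, frame[1] - 1
            e, _ = _duplex_dp(
                encode_sequence(mir), encode_sequence(window)[::-1], a, b,
                p.stack, np.asarray([0, 2, 1, 4, 3, 6, 5], np.int32),
                p.bulge, p.internal, p.ninio, p.ninio_max, p.duplex_init,
                p.terminal_au, 3)
            got = None if e >= INF else e / 100.0
            want = oracle_duplex(mir, window, frame, max_gap=3)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=0.005)

    def test_forced_mismatch_never_lowers_energy(self, rng):
        mir = "UGAGGUAGUAGGUUGUAUAGUU"
        perfect = reverse_complement(mir)
        e0 = duplex_energy(mir, perfect, (2, 7))
        for pos in (3, 8, 15):
            corrupted = list(perfect)
            corrupted[pos] = {"A": "C", "C": "A", "G": "U", "U": "G"}[
                corrupted[pos]]
            e1 = duplex_energy(mir, "".join(corrupted), (2, 7))
            assert e1 is None or e1 >= e0

    def test_frame_outside_mirna_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            duplex_energy("ACGUACGUACGUACGUACGU", "ACGUACGU" * 3, (15, 25))


class TestExtractUtr3:
    def test_plus_strand(self):
        genome = {"S1": "A" * 1000 + "C" * 400 + "G" * 100}
        ft = Gff3Feature(GenomeInterval("S1", 500, 1000, "+"), "CDS",
                         attributes={"ID": "g1"})
        utr = extract_utr3([ft], genome)[0]
        assert utr.interval.start == 1000 and utr.interval.end == 1400
        assert utr.sequence == "C" * 400
        assert not utr.clipped

    def test_minus_strand_reverse_complemented(self):
        genome = {"S1": "A" * 400 + "G" * 500 + "T" * 100}
        ft = Gff3Feature(GenomeInterval("S1", 400, 900, "-"), "CDS",
                         attributes={"ID": "g2"})
        utr = extract_utr3([ft], genome)[0]
        assert utr.interval == GenomeInterval("S1", 0, 400, "-")
        assert utr.sequence == "U" * 400

    def test_clipped_at_scaffold_end(self):
        genome = {"S1": "A" * 500 + "C" * 150}
        ft = Gff3Feature(GenomeInterval("S1", 100, 500, "+"), "CDS",
                         attributes={"ID": "g3"})
        utr = extract_utr3([ft], genome)[0]
        assert len(utr.sequence) == 150 and utr.clipped

    def test_non_cds_skipped(self):
        genome = {"S1": "ACGT" * 300}
        ft = Gff3Feature(GenomeInterval("S1", 100, 400, "+"), "exon",
                         attributes={"ID": "g"})
        assert extract_utr3([ft], genome) == []


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), 150, p=[.3, .2, .2, .3]))
            sh = dinucleotide_shuffle(seq, rng)
            assert Counter(zip(seq, seq[1:])) == Counter(zip(sh, sh[1:]))
            assert sh[0] == seq[0] and sh[-1] == seq[-1]

    def test_produces_variation(self, rng):
        seq = "".join(rng.choice(list("ACGU"), 300))
        shuffles = {dinucleotide_shuffle(seq, rng) for _ in range(10)}
        assert len(shuffles) > 1


class TestScanTargets:
    def test_empty_utrs(self):
        mir = SequenceRecord("m", "UGAGGUAGUAGGUUGUAUAGUU")
        assert scan_targets([mir], []) == []

    def test_planted_perfect_site_recovered(self, rng):
        mir = SequenceRecord("m", "UGAGGUAGUAGGUUGUAUAGUU")
        utrs = []
        for k in range(25):
            seq = list("".join(rng.choice(list("ACGU"), 400,
                                          p=[.325, .175, .175, .325])))
            if k < 15:
                pos = int(rng.integers(30, 340))
                site = reverse_complement(mir.sequence)
                seq[pos:pos + len(site)] = list(site)
            utrs.append(UTRRecord(
                f"g{k}", GenomeInterval("S1", 1, 401), "".join(seq)))
        sites = scan_targets([mir], utrs, p_max=0.01, n_shuffles=150, seed=5)
        hit_genes = {s.gene_id for s in sites}
        planted = {f"g{k}" for k in range(15)}
        assert planted <= hit_genes
        # planted sites carry the lowest energies
        by_gene = {s.gene_id: s for s in sites}
        worst_planted = max(by_gene[g].duplex_energy for g in planted)
        for s in sites:
            if s.gene_id not in planted:
                assert s.duplex_energy >= worst_planted - 1e-9

    def test_p_values_monotone_in_energy(self, rng):
        mir = SequenceRecord("m", "UGAGGUAGUAGGUUGUAUAGUU")
        utrs = [UTRRecord(f"g{k}", GenomeInterval("S1", 1, 401),
                          "".join(rng.choice(list("ACGU"), 400)))
                for k in range(30)]
        sites = scan_targets([mir], utrs, p_max=1.0, n_shuffles=150, seed=2)
        ordered = sorted(sites, key=lambda s: s.duplex_energy)
        pvals = [s.p_value for s in ordered]
        assert pvals == sorted(pvals)

    def test_too_few_shuffles_rejected(self, rng):
        with pytest.raises(ValueError, match="shuffles"):
            fit_null("UGAGGUAGUAGGUUGUAUAGUU", ["ACGU" * 100], rng,
                     n_shuffles=10)

    def test_helix_frames_are_the_six_printed(self):
        assert HELIX_FRAMES == ((1, 6), (2, 7), (3, 8), (4, 9), (5, 10),
                                (6, 11))
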