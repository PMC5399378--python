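import numpy as np
import pandas as pd
import pytest

from mirforge.core_io import (GenomeInterval, PrecursorCandidate,
                              SequenceRecord, fetch)
from mirforge.mature_strand_merge import (MatureCall, PresenceMatrix,
                                          StrandEvidence, assign_family,
                                          classify_conservation, infer_mature,
                                          infer_strand, merge_tracks,
                                          rescan_homologs)
from mirforge.rna_structure import FoldResult, fold, reverse_complement
from mirforge.synthetic_data import make_precursor


class TestInferMature:
    def test_constructed_exact_pair(self, rng):
        # 24-nt arm, 8-nt loop, exact reverse-complement arm
        arm = "".join(rng.choice(list("ACGU"), 24, p=[.3, .2, .2, .3]))
        loop = "AACAAUAC"
        seq = arm + loop + reverse_complement(arm)
        fr = fold(seq)
        call = infer_mature(seq, fr)
        assert call.method == "pair_pattern"
        assert call.pair_mismatches <= 1
        # arms flank the loop and stay within their halves
        assert call.p5[1] <= 24 + 2
        assert call.p3[0] >= 24 + len(loop) - 2

    def test_planted_generator_truth(self, rng):
        seq, p5, p3 = make_precursor(30, 8, 1, 0.1, rng)
        call = infer_mature(seq, fold(seq))
        assert call.method == "pair_pattern"
        # inferred arms overlap the planted arms substantially
        for got, want in ((call.p5, p5), (call.p3, p3)):
            ov = max(0, min(got[1], want[1]) - max(got[0], want[0]))
            assert ov >= 15

    def test_multi_loop_errors(self):
        seq = "GGGGGGAAAACCCCCCAAAAAGAGAGAAAACUCUCU"
        with pytest.raises(ValueError, match="one hairpin loop"):
            infer_mature(seq, fold(seq))

    def test_closest_to_loop_wins(self, rng):
        seq, p5, p3 = make_precursor(35, 10, 0, 0.0, rng)
        call = infer_mature(seq, fold(seq))
        from mirforge.rna_structure import hairpin_loop_runs
        ls, le = hairpin_loop_runs(fold(seq).dotbracket)[0]
        # distance of the winning pair to the loop is minimal (0 or near)
        assert (ls - call.p5[1]) + (call.p3[0] - le) <= 4

    def test_fallback_when_no_pair(self):
        # hairpin too short for a 22-nt paired arm pattern
        arm = "GGCAGGCAGGCAGGCA"  # 16 nt
        seq = arm + "AAACAAA" + reverse_complement(arm)
        fr = fold(seq)
        call = infer_mature(seq, fr)
        assert call.method == "fallback24"
        assert call.p5[1] <= call.p3[0]

    def test_arms_respect_separation_bounds(self, rng):
        for _ in range(5):
            seq, *_ = make_precursor(int(rng.integers(25, 40)),
                                     int(rng.integers(6, 14)), 2, 0.1, rng)
            call = infer_mature(seq, fold(seq))
            if call.method == "pair_pattern":
                sep = call.p3[0] - call.p5[1]
                assert 5 <= sep <= 50
                assert 22 <= call.p5[1] - call.p5[0] <= 27


def _evidence(source, strand, score=1.0):
    return StrandEvidence(source=source, strand=strand, score=score)


class TestInferStrand:
    def _cand(self):
        return PrecursorCandidate("c", GenomeInterval("S1", 0, 80), "A" * 80)

    def test_no_evidence_default_plus(self):
        d = infer_strand(self._cand(), [])
        assert (d.strand, d.provenance) == ("+", "default_plus")

    def test_reference_beats_est(self):
        d = infer_strand(self._cand(), [
            _evidence("est_hit", "+", 99),
            _evidence("reference_mature_hit", "-", 1),
        ])
        assert d.strand == "-"
        assert d.provenance == "reference_mature_hit"

    def test_smallrna_only(self):
        d = infer_strand(self._cand(), [_evidence("smallrna_hit", "-")])
        assert d.strand == "-"

    def test_within_class_best_score(self):
        d = infer_strand(self._cand(), [
            _evidence("est_hit", "-", 5.0), _evidence("est_hit", "+", 2.0)])
        assert d.strand == "-" and not d.tie

    def test_exact_tie_flags_plus(self):
        d = infer_strand(self._cand(), [
            _evidence("est_hit", "-", 5.0), _evidence("est_hit", "+", 5.0)])
        assert d.strand == "+" and d.tie

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            StrandEvidence("blast_hit", "+", 1.0)


def _tcand(cid, start, end, mfe=-30.0, strand="+"):
    n = end - start
    return PrecursorCandidate(
        cid, GenomeInterval("S1", start, end, strand), "A" * n,
        fold=FoldResult("A" * n, "." * n, mfe))


class TestMergeTracks:
    def test_disjoint_sets(self):
        hom = [_tcand(f"h{i}", 1000 * i, 1000 * i + 80) for i in range(3)]
        den = [_tcand(f"d{i}", 10_000 + 1000 * i, 10_000 + 1000 * i + 80)
               for i in range(4)]
        srn = [_tcand(f"s{i}", 20_000 + 1000 * i, 20_000 + 1000 * i + 80)
               for i in range(5)]
        catalog, counts = merge_tracks(hom, den, srn)
        assert counts["union"] == 12
        assert counts["homology_only"] == 3
        assert counts["denovo_only"] == 4
        assert counts["smallrna_only"] == 5
        assert all(counts[k] == 0 for k in
                   ("homology_denovo", "homology_smallrna",
                    "denovo_smallrna", "all_three"))

    def test_identical_sets_inclusion_exclusion(self):
        a = [_tcand(f"a{i}", 1000 * i, 1000 * i + 80) for i in range(4)]
        b = [_tcand(f"b{i}", 1000 * i, 1000 * i + 80) for i in range(4)]
        c = [_tcand("c", 50_000, 50_080)]
        catalog, counts = merge_tracks(a, b, c)
        assert counts["union"] == 5  # |A u B u C| = |A| + |C| when A == B
        assert counts["homology_denovo"] == 4
        assert counts["smallrna_only"] == 1

    def test_inclusion_exclusion_randomized(self, rng):
        for trial in range(10):
            loci = [(int(s), int(s) + 80)
                    for s in rng.choice(10**6, size=12, replace=False) * 100]
            tracks = []
            membership = []
            for t in range(3):
                members = [i for i in range(12) if rng.random() < 0.5]
                membership.append(set(members))
                tracks.append([_tcand(f"t{t}_{i}", *loci[i]) for i in members])
            catalog, counts = merge_tracks(*tracks)
            union = len(membership[0] | membership[1] | membership[2])
            assert counts["union"] == union
            total = sum(counts[k] for k in counts if k != "union")
            assert total == union
            triple = len(membership[0] & membership[1] & membership[2])
            assert counts["all_three"] == triple

    def test_representative_lowest_mfe(self):
        a = [_tcand("a", 0, 80, mfe=-20.0)]
        b = [_tcand("b", 0, 80, mfe=-35.0)]
        catalog, _ = merge_tracks(a, b, [])
        assert catalog[0].mfe == -35.0
        assert catalog[0].tracks == frozenset({"homology", "denovo"})

    def test_commutative_in_track_order(self, rng):
        xs = [_tcand(f"x{i}", 500 * i, 500 * i + 80) for i in range(6)]
        ys = [_tcand(f"y{i}", 500 * i + 10, 500 * i + 90) for i in range(3)]
        _, c1 = merge_tracks(xs, ys, [])
        _, c2 = merge_tracks([], ys, xs)
        assert c1["union"] == c2["union"]
        assert c1["homology_denovo"] == c2["denovo_smallrna"]

    def test_reciprocal_overlap_required(self):
        # tiny overlap below 50 % reciprocal: not merged
        a = [_tcand("a", 0, 100)]
        b = [_tcand("b", 90, 190)]
        _, counts = merge_tracks(a, b, [])
        assert counts["union"] == 2


class TestAssignFamily:
    def test_let7_seed(self):
        assert assign_family("UGAGGUAGUAGGUUGUAUAGUUU") == "GAGGUA"

    def test_first_position_irrelevant(self):
        a = assign_family("UGAGGUAGUAGGUUGUAUAGUUU")
        b = assign_family("AGAGGUAGUAGGUUGUAUAGUUU")
        assert a == b

    def test_position_three_matters(self):
        a = assign_family("UGAGGUAGUAGGUUGUAUAGUUU")
        b = assign_family("UGCGGUAGUAGGUUGUAUAGUUU")
        assert a != b

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            assign_family("ACGUAC")

    def test_equivalence_relation(self, rng):
        seqs = ["".join(rng.choice(list("ACGU"), 22)) for _ in range(20)]
        fams = {s: assign_family(s) for s in seqs}
        for s1 in seqs:
            for s2 in seqs:
                same = fams[s1] == fams[s2]
                assert same == (s1[1:7] == s2[1:7])


def _matrix(rows, species, clades, focal="halro"):
    df = pd.DataFrame(rows, columns=species,
                      index=[f"fam{i}" for i in range(len(rows))])
    return PresenceMatrix(df.astype(bool), clades, focal)


CLADES = {"halro": "tunicate", "cirro": "tunicate", "human": "other_metazoan",
          "fly": "other_metazoan"}
SPECIES = ["halro", "cirro", "human", "fly"]


class TestClassifyConservation:
    def test_widely_conserved(self):
        m = _matrix([[1, 0, 1, 1]], SPECIES, CLADES)
        assert classify_conservation(["fam0"], m)["fam0"] == \
            ("widely_conserved", True)

    def test_tunicate_specific(self):
        m = _matrix([[1, 1, 0, 0]], SPECIES, CLADES)
        assert classify_conservation(["fam0"], m)["fam0"] == \
            ("tunicate_specific", True)

    def test_species_specific(self):
        m = _matrix([[1, 0, 0, 0]], SPECIES, CLADES)
        assert classify_conservation(["fam0"], m)["fam0"] == \
            ("species_specific", True)

    def test_unmatched_family_flagged(self):
        m = _matrix([[1, 0, 0, 0]], SPECIES, CLADES)
        assert classify_conservation(["nope"], m)["nope"] == \
            ("species_specific", False)

    def test_column_order_invariant(self):
        rows = [[1, 1, 0, 0], [1, 0, 1, 0], [1, 0, 0, 0]]
        m1 = _matrix(rows, SPECIES, CLADES)
        perm = ["fly", "halro", "human", "cirro"]
        df = m1.table[perm]
        m2 = PresenceMatrix(df, CLADES, "halro")
        fams = ["fam0", "fam1", "fam2"]
        assert classify_conservation(fams, m1) == classify_conservation(fams, m2)

    def test_duplicated_species_column_invariant(self):
        m1 = _matrix([[1, 1, 0, 0]], SPECIES, CLADES)
        df = m1.table.copy()
        df["human2"] = df["human"]
        clades = dict(CLADES, human2="other_metazoan")
        m2 = PresenceMatrix(df, clades, "halro")
        assert classify_conservation(["fam0"], m1)["fam0"] == \
            classify_conservation(["fam0"], m2)["fam0"]

    def test_missing_focal_rejected(self):
        with pytest.raises(ValueError, match="focal"):
            _matrix([[1, 0, 0, 0]], SPECIES, CLADES, focal="mouse")


class TestRescanHomologs:
    def test_mismatch_cutoffs(self, small_bundle, rng):
        cfg, genome, truth = small_bundle
        rec = truth[0]
        mature = fetch(genome, rec.p5)
        mut = list(mature)
        sites = rng.choice([i for i in range(len(mut))], size=4, replace=False)
        for i in sites:
            mut[i] = {"A": "C", "C": "G", "G": "U", "U": "A"}[mut[i]]
        q = SequenceRecord("m4", "".join(mut))
        res2, _ = rescan_homologs([q], genome, max_mismatches=2)
        res4, _ = rescan_homologs([q], genome, max_mismatches=4)
        assert not res2[0].hit
        assert res4[0].hit and res4[0].best_mismatches == 4

    def test_planted_homolog_canonical(self, small_bundle):
        cfg, genome, truth = small_bundle
        matures = [SequenceRecord(t.id, fetch(genome, t.p5)) for t in truth]
        results, summary = rescan_homologs(matures, genome, max_mismatches=2)
        assert summary["pct_hit"] == 100.0
        assert summary["pct_canonical_of_hits"] == 100.0
        # canonical structures judged at 18 C by the full battery
        assert all(r.canonical_stemloop for r in results)

    def test_empty_genome(self):
        q = SequenceRecord("m", "UGAGGUAGUAGGUUGUAUAGUU")
        results, summary = rescan_homologs([q], {"S1": "A" * 500})
        assert not results[0].hit
        assert summary["n_hit"] == 0
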