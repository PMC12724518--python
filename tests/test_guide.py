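"""Box C/D motif assignment, duplex scoring, the D+5 prediction rule, guide
scanning round-trips and the noncanonical best-duplex search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmscan._util import revcomp, revcomp_rna, spawn_rng
from nmscan.guide import (
    GuideMatch,
    SnoRNAModel,
    best_duplex_anywhere,
    duplex_score,
    extract_ases,
    find_boxes,
    mfe_windows,
    predict_nm_position,
    scan_targets,
    shuffled_ase_decoy,
)
from nmscan.simulate import Reference, build_reference, design_snornas


class Site:
    def __init__(self, contig, pos, strand):
        self.contig, self.pos, self.strand = contig, pos, strand


class TestFindBoxes:
    def test_c_at_start_d_at_end(self):
        seq = "AUGAUGA" + "C" * 20 + "CUGA"
        boxes = {b.kind: b for b in find_boxes(seq)}
        assert boxes["C"].start == 0
        assert boxes["D"].start == len(seq) - 4

    def test_two_cuga_instances_assign_dprime(self):
        seq = "AUGAUGA" + "CC" + "CUGA" + "C" * 15 + "CUGA"
        boxes = {b.kind: b for b in find_boxes(seq)}
        assert boxes["D"].start == len(seq) - 4
        assert boxes["Dprime"].start == 9

    def test_poly_a_has_no_boxes(self):
        with pytest.warns(UserWarning):
            assert find_boxes("A" * 60) == []

    def test_d_before_c_rejected(self):
        with pytest.warns(UserWarning):
            assert find_boxes("CUGA" + "C" * 20 + "AUGAUGA" + "CC") == []

    def test_t_read_as_u(self):
        seq = "ATGATGA" + "C" * 20 + "CTGA"
        assert {b.kind for b in find_boxes(seq)} == {"C", "D"}


class TestExtractAses:
    def _model(self, d_offset, length=80):
        seq = ["C"] * length
        seq[0:7] = "AUGAUGA"
        seq[d_offset : d_offset + 4] = "CUGA"
        m = SnoRNAModel("x", "".join(seq))
        m.boxes = find_boxes(m.seq)
        return m

    def test_ase_interval_upstream_of_d(self):
        m = extract_ases(self._model(60), ase_length=12)
        ase = [a for a in m.ases if a.box_kind == "D"][0]
        assert (ase.start, ase.end) == (48, 60)

    def test_no_room_upstream_means_no_ase(self):
        seq = "AUGAUGAC" + "CUGA" + "C" * 30  # D' candidate at offset 8
        m = SnoRNAModel("x", seq)
        m.boxes = find_boxes(m.seq)
        m = extract_ases(m)
        assert not any(a.box_kind == "Dprime" for a in m.ases)

    def test_both_d_and_dprime_get_ases(self):
        seq = "AUGAUGA" + "C" * 12 + "CUGA" + "C" * 15 + "CUGA" + "CC"
        m = SnoRNAModel("x", seq)
        m.boxes = find_boxes(m.seq)
        m = extract_ases(m, ase_length=12)
        assert {a.box_kind for a in m.ases} == {"D", "Dprime"}

    def test_invalid_ase_length_rejected(self):
        with pytest.raises(ValueError):
            extract_ases(self._model(60), ase_length=16)


class TestDuplexScore:
    def test_perfect_reverse_complement(self):
        ase = "ACGUACGUACGU"
        res = duplex_score(ase, revcomp_rna(ase))
        assert (res.n_pairs, res.n_gu_pairs, res.n_mismatches) == (12, 0, 0)
        assert res.score == 24

    def test_single_central_mismatch(self):
        ase = "ACGUACGUACGU"
        target = list(revcomp_rna(ase))
        target[6] = "C"  # pairs ase[5]='C': C:C mismatch
        res = duplex_score(ase, "".join(target))
        assert (res.n_pairs, res.n_mismatches) == (11, 1)
        assert res.score == 24 - 2 - 2

    def test_all_mismatch(self):
        res = duplex_score("A" * 12, "A" * 12)
        assert res.score == -24 and res.n_pairs == 0

    def test_gu_wobble_scores_one(self):
        res = duplex_score("G", "U")
        assert res.score == 1 and res.n_gu_pairs == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            duplex_score("ACGU", "ACG")

    @given(st.text(alphabet="ACGU", min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=60)
    def test_revcomp_always_scores_twice_length(self, seq):
        assert duplex_score(seq, revcomp_rna(seq)).score == 2 * len(seq)


class TestPredictNmPosition:
    def _match(self, pairing):
        return GuideMatch(
            "x", "D", "chr1", "+", 1000, 1012, pairing, len(pairing), 0, 0, 0, None
        )

    def test_worked_index_example(self):
        """ASE of length 12 ending at d pairs window [1000, 1012); snoRNA
        offset d-5 pairs target 1004."""
        d = 60
        pairing = {d - 1 - k: 1000 + k for k in range(12)}
        assert predict_nm_position(self._match(pairing), d) == 1004

    def test_uncovered_guide_offset_gives_no_prediction(self):
        d = 60
        pairing = {d - 1: 1000, d - 2: 1001, d - 3: 1002}
        assert predict_nm_position(self._match(pairing), d) is None


class TestScanTargets:
    def test_designed_guides_round_trip(self, study):
        sites = [Site(*m.target) for m in study.snornas]
        matches = scan_targets(study.snornas, sites, study.reference)
        exact = {
            (m.snorna_id, m.observed_pos)
            for m in matches
            if m.n_mismatches == 0 and m.predicted_nm_pos == m.observed_pos
        }
        for m in study.snornas:
            assert (m.id, m.target[1]) in exact

    def test_hundred_random_designs_round_trip(self):
        """find_boxes / extract_ases / the D+5 rule invert design exactly for
        100 random designs over both strands."""
        reference = build_reference((6000,), transcripts_per_contig=3, seed=5)
        rng = spawn_rng(5, 9)
        targets = [
            ("chr1", int(rng.integers(100, 5900)), "+-"[int(rng.integers(0, 2))])
            for _ in range(100)
        ]
        snornas = design_snornas(reference, 100, targets, seed=5)
        for model, target in zip(snornas, targets):
            matches = scan_targets([model], [Site(*target)], reference)
            assert any(
                m.snorna_id == model.id
                and m.n_mismatches == 0
                and m.predicted_nm_pos == target[1]
                for m in matches
            )

    def test_two_snornas_against_one_target_both_recovered(self):
        reference = build_reference((2000,), seed=3)
        target = ("chr1", 900, "+")
        pair = design_snornas(reference, 2, [target], seed=3)
        matches = scan_targets(pair, [Site(*target)], reference)
        assert {m.snorna_id for m in matches} >= {pair[0].id, pair[1].id}

    def test_zero_snornas_designed(self):
        reference = build_reference((2000,), seed=3)
        assert design_snornas(reference, 0, [("chr1", 900, "+")]) == []

    def test_shuffled_decoys_rarely_match(self, study):
        sites = [Site(*m.target) for m in study.snornas]
        rng = spawn_rng(99, 7)
        decoys = [
            shuffled_ase_decoy(study.snornas[i % len(study.snornas)], rng, f"d{i}")
            for i in range(100)
        ]
        false_hits = len({m.snorna_id for m in scan_targets(decoys, sites, study.reference)})
        assert false_hits <= 5

    def test_offset_violation_rejected_despite_perfect_duplex(self):
        """A perfect duplex whose geometry places the Nm four (not five)
        nucleotides upstream of box D is not a canonical match."""
        reference = build_reference((2000,), seed=3)
        model = design_snornas(reference, 1, [("chr1", 900, "+")], seed=3)[0]
        matches = scan_targets([model], [Site("chr1", 901, "+")], reference)
        assert not any(m.n_mismatches == 0 and m.duplex_score == 24 for m in matches)

    def test_strand_flip_symmetry(self):
        """Mirroring the reference maps matches to mirrored coordinates."""
        reference = build_reference((2000,), seed=8)
        L = 2000
        target = ("chr1", 700, "+")
        model = design_snornas(reference, 1, [target], seed=8)[0]
        flipped = Reference({"chr1": revcomp(reference.contigs["chr1"])})
        m_fwd = scan_targets([model], [Site("chr1", 700, "+")], reference)
        m_rev = scan_targets([model], [Site("chr1", L - 1 - 700, "-")], flipped)
        assert len(m_fwd) == len(m_rev) > 0
        for a, b in zip(m_fwd, m_rev):
            assert a.duplex_score == b.duplex_score
            assert b.predicted_nm_pos == L - 1 - a.predicted_nm_pos


class TestMfeWindows:
    def test_constructed_best_snorna_ranks_first(self):
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGT"))
        contig = "".join(bases[rng.integers(0, 4, 1000)])
        reference = Reference({"chr1": contig})
        site = Site("chr1", 500, "+")
        window = contig[493:508]  # the +-7 region
        planted = "CCCCC" + revcomp(window).replace("T", "U") + "CCCCC"
        decoy = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 25)])
        table = mfe_windows(
            [SnoRNAModel("hit", planted), SnoRNAModel("decoy", decoy)],
            [site],
            reference,
        )
        best = table.sort_values("best_score", ascending=False).iloc[0]
        assert best.snorna_id == "hit"
        assert best.best_score == 2 * 15

    def test_matches_bruteforce_enumeration(self):
        """The diagonal best-run search agrees with brute-force enumeration of
        every >=8 nt substring placement on 20 random pairs."""
        rng = np.random.default_rng(12)
        bases = "ACGU"
        for _ in range(20):
            sno = "".join(bases[i] for i in rng.integers(0, 4, 30))
            region = "".join(bases[i] for i in rng.integers(0, 4, 15))
            brute = None
            for m in range(8, len(region) + 1):
                for i in range(len(sno) - m + 1):
                    for j in range(len(region) - m + 1):
                        s = duplex_score(sno[i : i + m], region[j : j + m]).score
                        if brute is None or s > brute:
                            brute = s
            assert best_duplex_anywhere(sno, region) == brute

    def test_window_of_ns_skipped(self):
        reference = Reference({"chr1": "N" * 1000})
        table = mfe_windows([SnoRNAModel("x", "ACGU" * 10)], [Site("chr1", 500, "+")], reference)
        assert table.best_score.isna().all()
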