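import random

import pytest
from hypothesis import given, settings, strategies as st

from msapolish import (
    Move,
    RefinementLog,
    ace2_preset,
    apply_move,
    codon_preset,
    enumerate_moves,
    explain_conflict,
    greedy_refine,
    huntingtin_preset,
    pwmd,
    replay,
    sps,
)
from msapolish.alignment import AlignedSequence, Alignment
from msapolish.refine import MoveError

from conftest import random_alignment


class TestEnumerateMoves:
    def test_contains_the_two_site_repair(self):
        _, perturbed, truth = ace2_preset(0)
        assert truth[0] in enumerate_moves(perturbed)

    def test_gap_free_alignment_has_no_moves(self):
        aln = Alignment(tuple(
            AlignedSequence(f"s{i}", "ACDEF") for i in range(3)
        ))
        assert enumerate_moves(aln) == []

    def test_codon_frame_restricts_slides_to_triplets(self):
        aln = Alignment(
            (AlignedSequence("a", "ATG---GGA"), AlignedSequence("b", "ATGCCCGGA")),
            alphabet="codon",
        )
        moves = enumerate_moves(aln, frame_step=3)
        assert moves  # both ATG (right) and GGA (left) can slide
        assert all(m.slide % 3 == 0 and m.block_len % 3 == 0 for m in moves)

    def test_deterministic_order(self):
        aln = random_alignment(random.Random(3), n_seqs=4, n_cols=12)
        assert enumerate_moves(aln) == enumerate_moves(aln)

    def test_respects_max_block_and_max_slide(self):
        aln = Alignment(
            (AlignedSequence("a", "AAAA----"), AlignedSequence("b", "AAAAAAAA")),
        )
        moves = enumerate_moves(aln, max_block=2, max_slide=3)
        assert moves
        assert all(m.block_len <= 2 and m.slide <= 3 for m in moves)


class TestApplyMove:
    def test_two_site_repair(self):
        clean, perturbed, truth = ace2_preset(0)
        repaired = apply_move(perturbed, truth[0])
        assert repaired == clean
        for i, m in enumerate(perturbed.members):
            if i != truth[0].seq_index:
                assert repaired[i] == m

    def test_move_then_inverse_restores(self):
        aln = random_alignment(random.Random(4), n_seqs=4, n_cols=14)
        for m in enumerate_moves(aln)[:10]:
            assert apply_move(apply_move(aln, m), m.inverse()) == aln

    def test_degapped_content_preserved(self):
        aln = random_alignment(random.Random(5), n_seqs=4, n_cols=14)
        for m in enumerate_moves(aln)[:10]:
            moved = apply_move(aln, m)
            assert moved[m.seq_index].degapped() == aln[m.seq_index].degapped()

    def test_stale_move_rejected(self):
        aln = Alignment(
            (AlignedSequence("a", "AC-D"), AlignedSequence("b", "ACDD")),
        )
        with pytest.raises(MoveError, match="stale"):
            apply_move(aln, Move(0, 0, 1, 2, "right"))  # slide exceeds gap run

    def test_block_relocation_across_gap_run(self):
        aln = Alignment(
            (AlignedSequence("a", "PPP----AA"), AlignedSequence("b", "QQQQQQQAA")),
        )
        moved = apply_move(aln, Move(0, 0, 3, 4, "right"))
        assert moved[0].residues == "----PPPAA"


class TestGreedyRefine:
    def test_two_site_fixture_one_move_delta_24(self, linear_scheme):
        clean, perturbed, _ = ace2_preset(0)
        refined, log = greedy_refine(perturbed, "SPS", linear_scheme)
        assert refined == clean
        assert len(log.accepted) == 1
        assert log.accepted[0].delta == 24
        assert log.converged

    def test_already_optimal_is_fixed_point(self, linear_scheme):
        clean, _, _ = ace2_preset(0)
        refined, log = greedy_refine(clean, "SPS", linear_scheme)
        assert refined == clean
        assert log.accepted == []

    def test_codon_fixture_recovers_under_triplet_moves(self, nuc_scheme):
        clean, perturbed, _ = codon_preset(0)
        refined, log = greedy_refine(perturbed, "SPS", nuc_scheme, frame_step=3)
        assert refined == clean
        assert sps(clean, nuc_scheme) > sps(perturbed, nuc_scheme)

    def test_trajectory_non_decreasing(self, linear_scheme):
        _, perturbed, _ = huntingtin_preset(0)
        refined, log = greedy_refine(perturbed, "SPS", linear_scheme,
                                     max_block=4)
        assert all(e.delta > 0 for e in log.accepted)
        assert sps(refined, linear_scheme) >= sps(perturbed, linear_scheme)

    def test_deterministic(self, linear_scheme):
        _, perturbed, _ = huntingtin_preset(1)
        r1, l1 = greedy_refine(perturbed, "PWMD", max_block=4)
        r2, l2 = greedy_refine(perturbed, "PWMD", max_block=4)
        assert r1 == r2
        assert [e.move for e in l1.accepted] == [e.move for e in l2.accepted]

    def test_replay_reproduces_output(self):
        _, perturbed, _ = huntingtin_preset(2)
        refined, log = greedy_refine(perturbed, "PWMD", max_block=4)
        assert replay(log, perturbed) == refined

    def test_log_json_round_trip(self):
        _, perturbed, _ = huntingtin_preset(3)
        refined, log = greedy_refine(perturbed, "PWMD", max_block=4)
        restored = RefinementLog.from_json(log.to_json())
        assert replay(restored, perturbed) == refined
        assert restored.final_delta_total == pytest.approx(log.final_delta_total)

    def test_pwmd_total_gain_matches_log(self):
        """Σ accepted deltas equals the PWM-differential trajectory summed
        sweep by sweep (each sweep scored under its own pre-move PWM)."""
        _, perturbed, _ = huntingtin_preset(4)
        refined, log = greedy_refine(perturbed, "PWMD", max_block=4)
        state = perturbed
        total = 0.0
        for e in log.accepted:
            after = apply_move(state, e.move)
            total += pwmd(state, after, "before")
            state = after
            if e.columns_deleted:
                from msapolish.refine import _delete_columns
                state = _delete_columns(state, e.columns_deleted)
        assert state == refined
        assert total == pytest.approx(log.final_delta_total)

    def test_non_convergence_flagged(self, linear_scheme):
        _, perturbed, _ = huntingtin_preset(5)
        with pytest.warns(RuntimeWarning):
            _, log = greedy_refine(perturbed, "PWMD", max_block=4, max_sweeps=1)
        assert not log.converged

    def test_idempotent(self):
        _, perturbed, _ = huntingtin_preset(6)
        refined, _ = greedy_refine(perturbed, "PWMD", max_block=4)
        again, log = greedy_refine(refined, "PWMD", max_block=4)
        assert again == refined
        assert log.accepted == []

    def test_pai_refinement_matches_sps_refinement(self, linear_scheme):
        """Moves leave optimal pair scores untouched, so PAI-greedy and
        SPS-greedy take the same trajectory."""
        clean, perturbed, _ = ace2_preset(1)
        r_sps, _ = greedy_refine(perturbed, "SPS", linear_scheme)
        r_pai, _ = greedy_refine(perturbed, "PAI", linear_scheme)
        assert r_sps == r_pai == clean


class TestExplainConflict:
    def test_huntingtin_preset_shows_pwmd_sps_disagreement(self, affine_scheme):
        _, perturbed, _ = huntingtin_preset(0)
        report = explain_conflict(perturbed, affine_scheme)
        disagreeing = report[(report.pwmd_delta > 0) & (report.sps_delta < 0)]
        assert len(disagreeing) > 0
        assert disagreeing.conflict.all()

    def test_planted_p_relocation_is_a_conflict_move(self, affine_scheme):
        _, perturbed, truth = huntingtin_preset(0)
        report = explain_conflict(perturbed, affine_scheme)
        m = truth[0]
        row = report[
            (report.sequence == m.seq_index + 1)
            & (report.block_start == m.block_start + 1)
            & (report.block_len == m.block_len)
            & (report.slide == m.slide)
            & (report.direction == m.direction)
        ]
        assert len(row) == 1
        assert row.pwmd_delta.iloc[0] > 0
        assert row.sps_delta.iloc[0] < 0

    def test_two_site_fixture_criteria_agree(self, linear_scheme):
        _, perturbed, truth = ace2_preset(0)
        report = explain_conflict(perturbed, linear_scheme)
        m = truth[0]
        row = report[
            (report.sequence == m.seq_index + 1)
            & (report.block_start == m.block_start + 1)
            & (report.block_len == 1) & (report.slide == 1)
        ]
        assert (row.sps_delta > 0).all() and (row.pwmd_delta > 0).all()

    def test_gap_free_alignment_gives_empty_report(self, linear_scheme):
        aln = Alignment(tuple(
            AlignedSequence(f"s{i}", "ACDEF") for i in range(3)
        ))
        assert explain_conflict(aln, linear_scheme).empty
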