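"""Alignment scoring against an independent DP oracle, acceptance
thresholds, tally conventions, rates, replicate statistics and noise floor."""

import numpy as np
import pytest
from oracles import align_score_oracle

from polyrec.miscall import (AlignmentParams, MisincorporationTally,
                             accept_alignment, error_matrix, global_align,
                             noise_floor, rates, replicate_stats, tally,
                             tally_inserts, transition_matrix)
from polyrec.synthetic_data import (CationCondition, get_preset, get_template,
                                    make_titration_plate, revcomp)
from polyrec.pipeline import run_plate

TPL = get_template("original")
REF = TPL.product_ref


def mutate(seq, pos, base=None):
    old = seq[pos]
    new = base or ("A" if old != "A" else "C")
    return seq[:pos] + new + seq[pos + 1:]


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align(REF, REF)
        assert aln.score == 76 and not aln.has_indel

    def test_single_substitution(self):
        assert global_align(mutate(REF, 30), REF).score == 75

    def test_single_deletion(self):
        aln = global_align(REF[:9] + REF[10:], REF)
        assert aln.score == 65  # 75 matches - (10 gap open)
        assert aln.has_indel and accept_alignment(aln)

    @pytest.mark.parametrize("trial", range(4))
    def test_full_length_agrees_with_oracle(self, trial):
        rng = np.random.default_rng(90 + trial)
        q = list(REF)
        for pos in rng.choice(76, size=rng.integers(0, 25), replace=False):
            q[pos] = "ACGT"[rng.integers(4)]
        q = "".join(q)
        assert global_align(q, REF).score == align_score_oracle(q, REF)

    def test_random_12mers_agree_with_oracle(self):
        # exhaustive-DP agreement over 200 random 12-mer pairs
        rng = np.random.default_rng(1234)
        for _ in range(200):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, 12))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, 12))
            assert global_align(a, b).score == align_score_oracle(a, b)


class TestAcceptAlignment:
    def test_length_threshold_is_inclusive_70(self):
        aln = global_align(REF[:69], REF)
        assert not accept_alignment(aln)  # 69 < 70, regardless of score

    def test_score_threshold_is_strict_60(self):
        q60 = REF
        rng = np.random.default_rng(3)
        pos = rng.choice(76, size=16, replace=False)
        for p in pos:
            q60 = mutate(q60, p)
        aln = global_align(q60, REF)
        assert aln.score == 60 and not accept_alignment(aln)
        q61 = REF
        for p in pos[:15]:
            q61 = mutate(q61, p)
        aln61 = global_align(q61, REF)
        assert aln61.score == 61 and accept_alignment(aln61)

    def test_perfect_insert_accepted(self):
        assert accept_alignment(global_align(REF, REF))


class TestTally:
    def test_clean_reads(self):
        t = tally([global_align(REF, REF) for _ in range(10)], TPL)
        assert np.all(t.n_p == 0) and np.all(t.N_p == 10)
        assert t.check_conservation()

    def test_hand_placed_errors(self):
        # template-T position p: two reads carry a G there, two are clean ->
        # n_p = 2, N_p = 4, transition (template T -> dGTP) = 2
        p = TPL.bases_by_position.index("T")  # 0-based extension position
        assert REF[p] == "A"  # product base opposite template T
        bad = mutate(REF, p, "G")
        alns = [global_align(s, REF) for s in (bad, bad, REF, REF)]
        t = tally(alns, TPL)
        assert t.n_p[p] == 2 and t.N_p[p] == 4
        ti, gi = "ACGT".index("T"), "ACGT".index("G")
        assert t.transition_counts[ti, gi] == 2
        assert t.base_errors()[ti] == 2

    def test_deletion_column_not_counted(self):
        # the reference position spanned by a deletion contributes to
        # neither the error count nor the total at that position
        aln = global_align(REF[:9] + REF[10:], REF)
        gap_pos = set(range(76)) - set(aln.ref_idx[aln.qry_idx >= 0])
        assert len(gap_pos) == 1  # a single 1-base deletion
        g = gap_pos.pop()
        t = tally([aln, global_align(REF, REF)], TPL)
        assert t.N_p[g] == 1 and t.n_p[g] == 0
        others = np.delete(t.N_p, g)
        assert np.all(others == 2)

    def test_ambiguous_base_excluded(self):
        aln = global_align(mutate(REF, 20, "N"), REF)
        t = tally([aln], TPL)
        assert t.N_p[20] == 0 and t.n_p[20] == 0
        assert t.N_p.sum() == 75

    def test_fast_path_matches_generic_tally(self):
        rng = np.random.default_rng(8)
        inserts = []
        for _ in range(50):
            q = REF
            for p in rng.choice(76, size=rng.integers(0, 4), replace=False):
                q = mutate(q, p)
            inserts.append(q)
        fast = tally_inserts(inserts, TPL)
        slow = tally([global_align(q, REF) for q in inserts], TPL)
        assert np.array_equal(fast.n_p, slow.n_p)
        assert np.array_equal(fast.N_p, slow.N_p)
        assert np.array_equal(fast.transition_counts, slow.transition_counts)


class TestRates:
    def test_simple_ratio(self):
        t = MisincorporationTally.empty(TPL)
        t.n_p[4], t.N_p[4] = 2, 4
        r = rates(t)
        assert r.position["rate"].iloc[4] == 0.5

    def test_zero_denominator_flagged(self):
        t = MisincorporationTally.empty(TPL)
        r = rates(t)
        assert np.isnan(r.position["rate"]).all()
        assert np.isnan(r.mean_rate)

    def test_transition_row_normalisation(self):
        t = MisincorporationTally.empty(TPL)
        ti = "ACGT".index("T")
        # counts T->G: 30, T->A(correct): 960, T->C: 6, T->T: 4
        t.transition_counts[ti] = [960, 6, 30, 4]
        tm = transition_matrix(t)
        row = tm.loc["T"]
        assert row["G"] == pytest.approx(0.75)
        assert row["C"] == pytest.approx(0.15)
        assert row["T"] == pytest.approx(0.10)
        assert np.isnan(row["A"])  # correct incorporation masked
        assert row["G"] / max(row["C"], row["T"]) == pytest.approx(5.0)

    def test_mean_rate_is_unweighted_base_average(self):
        t = MisincorporationTally.empty(TPL)
        t.transition_counts[:] = 0
        for i in range(4):
            t.transition_counts[i, 3 - i] = 100  # correct cells
        t.transition_counts[0, 1] = 100  # template A: 50% errors
        r = rates(t)
        assert r.mean_rate == pytest.approx((0.5 + 0 + 0 + 0) / 4)


class TestReplicateStats:
    def test_duplicate_wells(self):
        est = replicate_stats([0.010, 0.012])
        assert est.rate == pytest.approx(0.011)
        assert est.sem == pytest.approx(0.001)
        assert est.n_replicates == 2

    def test_single_well_flagged(self):
        est = replicate_stats([0.42])
        assert est.rate == 0.42 and np.isnan(est.sem)

    def test_equal_wells_zero_sem(self):
        assert replicate_stats([0.2] * 4).sem == 0.0


class TestNoiseFloor:
    def test_zero_error_control(self):
        t = MisincorporationTally.empty(TPL)
        t.N_p[:] = 10
        for i in range(4):
            t.transition_counts[i, 3 - i] = 190
        nf = noise_floor([t, t])
        assert nf.mean_floor == 0.0 and nf.spatial_floor == 0.0

    def test_recovers_generator_noise_level(self, tmp_path):
        plate = make_titration_plate("mn", (800.0,), "phusion_control", 4000)
        res = run_plate(plate, "original", 17, "mn", noise_floor=1e-3)
        nf = noise_floor([w.tally for w in res.wells])
        assert nf.mean_floor == pytest.approx(1e-3, rel=0.35)
        assert nf.spatial_floor >= nf.mean_floor

    def test_invariant_to_well_order(self):
        rng = np.random.default_rng(5)
        tallies = []
        for _ in range(3):
            t = MisincorporationTally.empty(TPL)
            t.N_p[:] = 100
            t.n_p[:] = rng.integers(0, 5, TPL.length)
            for i in range(4):
                t.transition_counts[i, 3 - i] = 1900
            t.transition_counts[0, 1] = int(t.n_p.sum())
            tallies.append(t)
        a = noise_floor(tallies)
        b = noise_floor(tallies[::-1])
        assert a.mean_floor == pytest.approx(b.mean_floor, rel=1e-12)
        assert a.spatial_floor == pytest.approx(b.spatial_floor, rel=1e-12)


def test_error_matrix_uses_only_indel_free_reads():
    inserts = [REF, mutate(REF, 3), REF[:9] + REF[10:], REF[:60]]
    mat = error_matrix(inserts, TPL)
    assert mat.shape == (2, 70)  # deletion + short read excluded
    assert mat.sum() == 1
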