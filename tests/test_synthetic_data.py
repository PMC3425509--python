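"""Generator-level tests: templates, barcodes, the rate oracle, single-
molecule simulation, plate reproducibility and the toy structure profile."""

import dataclasses
import math

import numpy as np
import pytest
from oracles import levenshtein_oracle

import polyrec as pr
from polyrec.synthetic_data import (BASES, LEFT_PRIMER_BIND, BarcodeInfeasibleError,
                                    CationCondition, TemplateSpec, _RateParams,
                                    generate_barcodes, get_preset, get_template,
                                    rate_oracle, revcomp, simulate_extension,
                                    simulate_plate, simulate_well,
                                    toy_structure_profile, make_titration_plate)

STANDARD_TAIL = "TACAACAGCTATGACCATC"  # anneals the bundled primer 3' tail


def custom_template(ext_region: str, name: str = "custom") -> TemplateSpec:
    seq = ext_region + STANDARD_TAIL
    return TemplateSpec(name=name, template_seq=seq,
                        extension_end=len(ext_region))


class TestTemplates:
    @pytest.mark.parametrize("name", ["original", "swapped"])
    def test_bundled_template_invariants(self, name):
        t = get_template(name)
        assert t.length == 76
        assert t.product_ref == revcomp(t.extension_seq)
        assert len(t.template_seq) == 95
        # primer tail anneals perfectly to the template 3' end
        assert revcomp(t.template_seq[-t.primer_binding_len:]) == LEFT_PRIMER_BIND

    def test_extension_order_convention(self):
        t = get_template("original")
        # position 1 abuts the primer = template base just 5' of the tail
        assert t.bases_by_position[0] == t.template_seq[75]
        assert t.bases_by_position[-1] == t.template_seq[0]

    def test_non_annealing_template_rejected(self):
        with pytest.raises(ValueError):
            TemplateSpec(name="bad", template_seq="A" * 95)


class TestBarcodes:
    def test_full_plate_of_barcodes(self):
        bs = generate_barcodes(96, 5, 2, seed=11)
        assert len(bs) == 96
        assert len(set(bs.barcodes)) == 96
        dmin = min(levenshtein_oracle(a, b)
                   for i, a in enumerate(bs.barcodes)
                   for b in bs.barcodes[i + 1:])
        assert dmin >= 2

    def test_deterministic_given_seed(self):
        assert generate_barcodes(24, seed=5).barcodes == \
            generate_barcodes(24, seed=5).barcodes
        assert generate_barcodes(24, seed=5).barcodes != \
            generate_barcodes(24, seed=6).barcodes

    def test_singleton(self):
        bs = generate_barcodes(1, 5, 2, seed=0)
        assert len(bs) == 1 and len(bs.barcodes[0]) == 5

    def test_infeasible_request_raises(self):
        # any two distinct 1-mers are a single substitution apart, so no
        # five 1-mers can be pairwise >= 2 edits from each other
        with pytest.raises(BarcodeInfeasibleError, match="5 barcodes"):
            generate_barcodes(5, 1, 2, seed=0)


class TestRateOracle:
    def test_zero_rate_control(self):
        p = get_preset("phusion_control")
        for b in BASES:
            assert rate_oracle(p, b, CationCondition(mn_uM=800)) == 0.0

    def test_dpo4_calibration_points(self):
        p = get_preset("dpo4_paper")
        hi = rate_oracle(p, "T", CationCondition(mn_uM=800))
        lo = rate_oracle(p, "T", CationCondition(mn_uM=75))
        assert hi == pytest.approx(0.07, abs=0.002)
        assert lo == pytest.approx(0.0014, abs=0.0001)
        assert hi / lo == pytest.approx(50, rel=0.02)

    @pytest.mark.parametrize("preset", ["dpo4_paper", "klenow_paper"])
    def test_monotone_in_manganese(self, preset):
        p = get_preset(preset)
        for b in BASES:
            rates = [rate_oracle(p, b, CationCondition(mn_uM=c))
                     for c in (10, 25, 75, 200, 400, 800)]
            assert np.all(np.diff(rates) >= 0)

    def test_transition_rows_are_distributions(self):
        for name in pr.synthetic_data.available_presets():
            p = get_preset(name)
            for b in BASES:
                row = p.transition_rows[b]
                assert revcomp(b) not in row
                assert sum(row.values()) == pytest.approx(1.0, abs=1e-6)


class TestSimulateExtension:
    def test_error_free_limit(self):
        t = get_template("original")
        p = dataclasses.replace(get_preset("phusion_control"),
                                truncation_prob=0.0, indel_prob=0.0)
        rng = np.random.default_rng(0)
        product, truth = simulate_extension(t, p, CationCondition(), rng)
        assert product == t.product_ref
        assert truth.total_poly_errors() == 0

    def test_forced_transition(self):
        # rate 1 on template T with all mass on dGTP: every template T
        # yields a G in the product
        t = get_template("original")
        base = get_preset("phusion_control")
        params = dict(base.rate_params)
        params["T"] = _RateParams(r0=1.0)
        p = dataclasses.replace(base, rate_params=params, r_max=1.0,
                                truncation_prob=0.0, indel_prob=0.0,
                                transition_rows={**base.transition_rows,
                                                 "T": {"C": 0.0, "G": 1.0, "T": 0.0}})
        product, _ = simulate_extension(t, p, CationCondition(), np.random.default_rng(1))
        for pos, tb in enumerate(t.bases_by_position):
            assert product[pos] == ("G" if tb == "T" else revcomp(tb))

    def test_monte_carlo_matches_rate_oracle(self):
        # empirical per-base error frequencies over 10,000 molecules agree
        # with the analytic oracle to within 3 binomial standard errors
        t = get_template("original")
        p = get_preset("dpo4_paper")  # lag1_boost = 0, so positions are fair
        cond = CationCondition(mn_uM=400)
        truth = simulate_well(t, p, cond, 10000, np.random.default_rng(2),
                              noise_floor=0.0)
        tb = np.array(list(t.bases_by_position))
        for b in BASES:
            cols = tb == b
            n = truth.poly_errors[:, cols].size
            freq = truth.poly_errors[:, cols].mean()
            expect = rate_oracle(p, b, cond)
            se = math.sqrt(expect * (1 - expect) / n)
            assert abs(freq - expect) < 3 * se + 1e-9

    def test_truth_conservation(self):
        t = get_template("original")
        p = get_preset("klenow_paper")
        truth = simulate_well(t, p, CationCondition(mn_uM=800), 2000,
                              np.random.default_rng(3))
        assert truth.total_poly_errors() == truth.per_position_poly_errors().sum()


class TestSimulatePlate:
    def make_plate(self, reads=10):
        return make_titration_plate("mn", (75.0, 800.0), "dpo4_paper", reads,
                                    duplicates=1)

    def test_pair_counts_and_truth(self, tmp_path):
        plate = self.make_plate()
        sim = simulate_plate(plate, get_preset("dpo4_paper"),
                             get_template("original"), 4, tmp_path,
                             dimer_fraction=0.2)
        assert sim.n_pairs == 2 * (10 + 2)
        lines = sim.fwd_fastq.read_text().splitlines()
        assert len(lines) == 4 * sim.n_pairs

    def test_byte_identical_given_seed(self, tmp_path):
        plate = self.make_plate(50)
        p, t = get_preset("dpo4_paper"), get_template("original")
        s1 = simulate_plate(plate, p, t, 9, tmp_path / "a")
        s2 = simulate_plate(plate, p, t, 9, tmp_path / "b")
        assert s1.fwd_fastq.read_bytes() == s2.fwd_fastq.read_bytes()
        assert s1.rev_fastq.read_bytes() == s2.rev_fastq.read_bytes()
        s3 = simulate_plate(plate, p, t, 10, tmp_path / "c")
        assert s3.fwd_fastq.read_bytes() != s1.fwd_fastq.read_bytes()

    def test_control_preset_shows_only_noise(self, tmp_path):
        plate = make_titration_plate("mn", (800.0,), "phusion_control", 4000,
                                     duplicates=1)
        sim = simulate_plate(plate, get_preset("phusion_control"),
                             get_template("original"), 5, tmp_path,
                             noise_floor=1e-3)
        truth = sim.well_truths[plate.wells[0].well_id]
        assert truth.total_poly_errors() == 0
        noise_rate = truth.noise_errors.mean()
        assert noise_rate == pytest.approx(1e-3, rel=0.25)


class TestToyStructureProfile:
    def test_homopolymer_is_unpaired(self):
        assert np.all(toy_structure_profile("A" * 40) == 0.0)

    def test_hairpin_stem_beats_loop(self):
        stem = "GGCCGGCC"
        seq = stem + "AAAAAA" + revcomp(stem)
        s = toy_structure_profile(seq, window=5)
        stem_score = np.mean(np.r_[s[:8], s[-8:]])
        loop_score = np.mean(s[8:-8])
        assert stem_score > loop_score

    def test_length_and_range(self, original_template):
        s = toy_structure_profile(original_template)
        assert len(s) == original_template.length
        assert np.all((s >= 0) & (s <= 1))
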