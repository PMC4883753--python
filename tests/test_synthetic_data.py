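import dataclasses
import math

import numpy as np
import pytest

from cuticle_course.isoforms import detect_switches
from cuticle_course.composition import compose, screen_candidates
from cuticle_course.specificity import specificity_fractions
from cuticle_course.synthetic_data import (IsoformPlan, NoisePlan, ProteinPlan,
                                           ProteinSpec, QpcrPlan, SimConfig,
                                           ThicknessPlan, simulate_isoforms,
                                           simulate_proteins, simulate_qpcr,
                                           simulate_thickness,
                                           simulate_timecourse)
from cuticle_course.validation import (ratio_group_test,
                                       relative_quantification,
                                       thickness_ratios)


class TestTimecourse:
    def test_seed_determinism(self, small_config):
        m1, l1 = simulate_timecourse(small_config)
        m2, l2 = simulate_timecourse(small_config)
        np.testing.assert_array_equal(m1.fpkm, m2.fpkm)
        np.testing.assert_array_equal(m1.replicate_fpkm, m2.replicate_fpkm)
        assert l1 == l2

    def test_different_seed_different_data(self, small_config):
        m1, _ = simulate_timecourse(small_config)
        m2, _ = simulate_timecourse(dataclasses.replace(small_config, seed=8))
        assert not np.array_equal(m1.fpkm, m2.fpkm)

    def test_noiseless_spike_has_fraction_over_ninety_percent(self):
        cfg = SimConfig(seed=0, n_genes=10, noise_scale=0.0,
                        archetype_mix=(("spike", 1.0),))
        m, labels = simulate_timecourse(cfg)
        prof = specificity_fractions(m, universe=m.gene_ids)
        assert (prof.peak_fraction > 0.9).all()
        assert (prof.peak_time == 42).all()

    def test_flat_genes_vary_only_by_noise(self):
        cfg = SimConfig(seed=0, n_genes=10, noise_scale=0.0,
                        archetype_mix=(("flat", 1.0),))
        m, _ = simulate_timecourse(cfg)
        assert np.allclose(m.fpkm, m.fpkm[:, :1])

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(archetype_mix=(("spike", 0.5), ("flat", 0.4)))

    def test_replicate_cv2_decreases_with_expression(self):
        cfg = SimConfig(seed=3, n_genes=600, n_replicates=8,
                        archetype_mix=(("flat", 1.0),))
        m, _ = simulate_timecourse(cfg)
        reps = m.replicate_fpkm.reshape(-1, cfg.n_replicates)
        mean = reps.mean(axis=1)
        cv2 = reps.var(axis=1, ddof=1) / mean ** 2
        order = np.argsort(mean)
        lo = cv2[order[: len(order) // 4]].mean()
        hi = cv2[order[-len(order) // 4:]].mean()
        assert lo > hi  # variability falls as expression rises


class TestIsoforms:
    def test_seed_determinism(self, small_config):
        i1, p1 = simulate_isoforms(small_config)
        i2, p2 = simulate_isoforms(small_config)
        np.testing.assert_array_equal(i1.fpkm, i2.fpkm)
        assert p1 == p2

    def test_zero_noise_round_trip_is_exact(self):
        cfg = SimConfig(seed=0, isoforms=IsoformPlan(n_genes=10, n_switches=3,
                                                     noise_sigma=0.0))
        iso, planted = simulate_isoforms(cfg)
        events = detect_switches(iso)
        assert {(e.gene, e.time_pair) for e in events} == \
               {(p.gene, p.time_pair) for p in planted}

    def test_recall_and_precision_at_default_noise(self, small_config):
        iso, planted = simulate_isoforms(small_config)
        events = detect_switches(iso)
        det = {(e.gene, e.time_pair) for e in events}
        tru = {(p.gene, p.time_pair) for p in planted}
        recall = len(det & tru) / len(tru)
        precision = len(det & tru) / len(det) if det else 0.0
        assert recall >= 0.95 and precision >= 0.95

    def test_non_adjacent_switch_pair_rejected(self):
        cfg = SimConfig(isoforms=IsoformPlan(switch_pairs=(9,)))
        with pytest.raises(ValueError, match="adjacent"):
            simulate_isoforms(cfg)


class TestProteins:
    def test_seed_determinism(self, small_config):
        p1, t1 = simulate_proteins(small_config)
        p2, t2 = simulate_proteins(small_config)
        assert p1.records == p2.records and t1 == t2

    def test_pure_alanine_spec(self):
        cfg = SimConfig(proteins=ProteinPlan(
            specs=(ProteinSpec(50, absent=tuple(c for c in "CDEFGHIKLMNPQRSTVWY"),
                               high=()),)))
        proteins, _ = simulate_proteins(cfg)
        assert compose(proteins.records["prot000"]).fractions["A"] == 1.0

    def test_planted_flags_recovered_by_screen(self, small_config):
        proteins, truth = simulate_proteins(small_config)
        table, summary = screen_candidates(proteins)
        assert summary["lacking"]["Trp"] == \
            sum("W" in t["absent"] for t in truth.values())
        assert summary["n_short"] == sum(t["short"] for t in truth.values())
        by_id = table.set_index("protein_id")
        for pid, t in truth.items():
            rep = compose(proteins.records[pid])
            assert rep.length == t["length"]
            assert t["absent"] <= rep.absent_residues
            for res, frac in t["high"].items():
                assert rep.fractions[res] >= frac

    def test_infeasible_bias_rejected(self):
        cfg = SimConfig(proteins=ProteinPlan(
            specs=(ProteinSpec(100, absent=("A",), high=(("A", 0.25),)),)))
        with pytest.raises(ValueError, match="absent and enriched"):
            simulate_proteins(cfg)


class TestThickness:
    def test_seed_determinism(self, small_config):
        t1 = simulate_thickness(small_config)
        t2 = simulate_thickness(small_config)
        assert t1["wild_type"][1] == t2["wild_type"][1]

    def test_zero_jitter_recovers_drawn_ratios_exactly(self):
        cfg = SimConfig(thickness=ThicknessPlan(jitter=0.0, n_wings=5))
        groups = simulate_thickness(cfg)
        ts, drawn = groups["wild_type"]
        res = thickness_ratios(ts)
        for wing, ratio in drawn.items():
            assert math.isclose(res["ratios"][wing], ratio, rel_tol=1e-12)

    def test_group_separation_power_at_stated_parameters(self):
        # wild type 1.2 +/- 0.11 vs knockdown 2.1 +/- 0.43, 8 wings each:
        # the t-test should be significant in nearly every replicate draw
        hits = 0
        n_trials = 200
        for seed in range(n_trials):
            groups = simulate_thickness(SimConfig(seed=seed))
            wt = list(groups["wild_type"][1].values())
            kd = list(groups["knockdown"][1].values())
            if ratio_group_test(wt, kd)["p"] < 0.05:
                hits += 1
        assert hits / n_trials >= 0.95


class TestQpcr:
    def test_zero_noise_inverse_recovery(self):
        cfg = SimConfig(qpcr=QpcrPlan(noise_sd=0.0))
        true_rq = {"calibrator": 1.0, "s42": 4.0, "s52": 0.25, "s62": 1.0}
        plate = simulate_qpcr(cfg, true_rq)
        rq = relative_quantification(plate)["target"]
        for sample, expected in true_rq.items():
            assert math.isclose(rq[sample]["rq"], expected, rel_tol=1e-12)

    def test_rq_two_means_one_cycle_lower(self):
        cfg = SimConfig(qpcr=QpcrPlan(noise_sd=0.0))
        plate = simulate_qpcr(cfg, {"calibrator": 1.0, "s": 2.0})
        dct = {}
        for sample in ("calibrator", "s"):
            ct_t = np.mean(plate.ct(sample, "target"))
            ct_c = np.mean(plate.ct(sample, "Xbp1"))
            dct[sample] = ct_t - ct_c
        assert math.isclose(dct["s"] - dct["calibrator"], -1.0, abs_tol=1e-12)

    def test_noisy_recovery_within_three_sd(self, small_config):
        true_rq = {"calibrator": 1.0, "s42": 2.0}
        plate = simulate_qpcr(small_config, true_rq)
        rq = relative_quantification(plate)["target"]["s42"]
        assert abs(rq["rq"] - 2.0) <= 3 * max(rq["sd"], 1e-6)

    def test_calibrator_value_must_be_one(self, small_config):
        with pytest.raises(ValueError, match="calibrator"):
            simulate_qpcr(small_config, {"calibrator": 2.0, "s": 1.0})
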