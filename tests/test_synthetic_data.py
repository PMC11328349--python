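"""Determinism, planted structure and rate recovery of the study generator."""

import numpy as np
import pytest

from edittrace.edit_calling import extract_allele
from edittrace.panel_design import BulgeSpec
from edittrace.synthetic_data import (
    EditingModel,
    OfftargetSpec,
    SimConfig,
    apply_signature,
    default_offtarget_specs,
    editing_probability,
    make_assays,
    make_genome,
    simulate_noteseq,
    simulate_population,
    simulate_reads,
    simulate_study,
)


def small_config(seed=1, **kwargs):
    defaults = dict(
        seed=seed,
        genome_len=30_000,
        guides={"Promiscuous": default_offtarget_specs(5)},
        n_plants={"Control": 3, "Promiscuous": 6},
        read_depth=30,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


class TestEditingProbability:
    def test_distal_mismatches_cost_nothing(self):
        params = EditingModel(p_on=0.8)
        assert editing_probability((21, 22, 23), params=params) == pytest.approx(0.8)

    def test_no_mismatch_identity(self):
        assert editing_probability((), params=EditingModel(p_on=0.8)) == pytest.approx(0.8)

    def test_seed_mismatch_penalty_product(self):
        assert editing_probability((5,), params=EditingModel(p_on=0.8)) == pytest.approx(0.008)

    def test_bulge_factor(self):
        p = editing_probability((), BulgeSpec("dna", 1, 10), EditingModel(p_on=0.8))
        assert p == pytest.approx(0.008)

    def test_position_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            editing_probability((24,))


class TestMakeGenome:
    def test_deterministic_bytes(self):
        g1, _ = make_genome(small_config())
        g2, _ = make_genome(small_config())
        assert g1 == g2

    def test_distal_spec_differs_only_at_stated_positions(self):
        cfg = small_config(guides={"G": [OfftargetSpec((21, 22, 23))]})
        _, truth = make_genome(cfg)
        guide = truth.guides["G"]
        off = next(s for s in truth.sites if s.role == "off")
        diffs = [i + 1 for i, (a, b) in enumerate(zip(off.window, guide)) if a != b]
        assert diffs == [21, 22, 23]

    def test_empty_spec_list_plants_only_on_target(self):
        cfg = small_config(guides={"G": []})
        _, truth = make_genome(cfg)
        assert [s.role for s in truth.sites] == ["on"]

    def test_bulged_site_window_length(self):
        cfg = small_config(guides={"G": [OfftargetSpec((2,), bulge=BulgeSpec("dna", 1, 10))]})
        _, truth = make_genome(cfg)
        off = next(s for s in truth.sites if s.role == "off")
        assert len(off.window) == 24

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            make_genome(small_config(genome_len=1_000))

    def test_pairwise_window_distances(self):
        _, truth = make_genome(small_config(guides={"P": default_offtarget_specs(19)}))
        windows = [s.window for s in truth.sites]
        for i in range(len(windows)):
            for j in range(i + 1, len(windows)):
                dist = sum(a != b for a, b in zip(windows[i], windows[j]))
                assert dist >= 3


class TestSimulatePopulation:
    def test_control_plants_have_no_events(self):
        cfg = small_config()
        _, truth = make_genome(cfg)
        _samples, truth = simulate_population(truth, cfg)
        assert not any(e.plant_id.startswith("Control") for e in truth.events)

    def test_stage_model_transmission(self):
        cfg = small_config(n_plants={"Promiscuous": 40})
        _, truth = make_genome(cfg)
        _samples, truth = simulate_population(truth, cfg)
        for ev in truth.events:
            if ev.stage == "early":
                assert ev.transmission == 0.75 and ev.leaf_fraction == 0.5
            elif ev.stage == "late_sampled":
                assert ev.transmission == 0.0 and 0.15 <= ev.leaf_fraction <= 0.5
            else:
                assert 0.05 <= ev.transmission <= 0.3 and ev.leaf_fraction == 0.0

    def test_progeny_counts_in_range(self):
        cfg = small_config()
        _, truth = make_genome(cfg)
        samples, _ = simulate_population(truth, cfg)
        per_family = (
            samples[samples["generation"] == "T1"].groupby("family_id").size()
        )
        assert per_family.between(9, 12).all()


class TestSimulateReads:
    def test_deterministic_outputs(self):
        out = []
        for _ in range(2):
            cfg = small_config()
            genome, truth = make_genome(cfg)
            assays = make_assays(genome, truth, cfg)
            samples, truth = simulate_population(truth, cfg)
            reads, _ = simulate_reads(assays, samples, truth, cfg)
            out.append(reads)
        assert out[0].equals(out[1])

    def test_error_free_single_allele_reads_equal_amplicon(self):
        cfg = small_config(seq_error_rate=0.0, template_switch_rate=0.0,
                           n_plants={"Control": 2})
        genome, truth = make_genome(cfg)
        assays = make_assays(genome, truth, cfg)
        samples, truth = simulate_population(truth, cfg)
        reads, read_truth = simulate_reads(assays, samples, truth, cfg)
        refs = {a.locus_id: a.reference_amplicon for a in assays}
        merged = reads.merge(read_truth, on=["read_id", "plant_id"])
        assert all(seq == refs[lid] for seq, lid in zip(merged["sequence"], merged["locus_id"]))

    def test_planted_fraction_recovered_binomially(self):
        """An allele at true fraction 0.5 lands inside its binomial 99% interval."""
        from scipy import stats

        cfg = small_config()
        genome, truth = make_genome(cfg)
        assays = make_assays(genome, truth, cfg)
        assay = assays[0]
        depth = 200
        edited = apply_signature(assay, (("D", 5, 7),))
        rng = np.random.default_rng(4)
        n_edit = rng.binomial(depth, 0.5)
        lo, hi = stats.binom.interval(0.99, depth, 0.5)
        assert lo <= n_edit <= hi

    def test_switch_rate_recovered(self):
        cfg = small_config(n_plants={"Control": 12}, template_switch_rate=0.02)
        genome, truth = make_genome(cfg)
        assays = make_assays(genome, truth, cfg)
        samples, truth = simulate_population(truth, cfg)
        _reads, read_truth = simulate_reads(assays, samples, truth, cfg)
        rate = read_truth["switched"].mean()
        n = len(read_truth)
        se = (0.02 * 0.98 / n) ** 0.5
        assert abs(rate - 0.02) < 4 * se

    def test_every_read_traceable(self):
        cfg = small_config()
        study = simulate_study(cfg)
        assert set(study.reads["read_id"]) == set(study.truth.read_truth["read_id"])


class TestSimulateNoteseq:
    def test_on_target_highest_expected_count(self):
        cfg = small_config()
        _, truth = make_genome(cfg)
        counts = simulate_noteseq(truth, cfg, "Promiscuous")
        per_site = counts.groupby("site_id")["count"].sum()
        on_id = next(s.locus_id for s in truth.sites if s.role == "on")
        distal = {
            s.locus_id for s in truth.sites if s.mismatch_positions and min(s.mismatch_positions) >= 21
        }
        for site_id, total in per_site.items():
            if site_id != on_id and site_id not in distal:
                assert total < per_site[on_id]

    def test_inactive_sites_near_noise_floor(self):
        cfg = small_config()
        _, truth = make_genome(cfg)
        counts = simulate_noteseq(truth, cfg, "Promiscuous")
        per_site_cond = counts.groupby(["site_id", "condition"])["count"].sum()
        seed_sites = [
            s.locus_id
            for s in truth.sites
            if s.mismatch_positions and max(s.mismatch_positions) <= 18
        ]
        for site_id in seed_sites:
            for cond in ("ratio_10_1", "ratio_1_1"):
                assert per_site_cond.get((site_id, cond), 0) <= 10

    def test_deterministic(self):
        cfg = small_config()
        _, truth1 = make_genome(cfg)
        _, truth2 = make_genome(cfg)
        c1 = simulate_noteseq(truth1, cfg, "Promiscuous")
        c2 = simulate_noteseq(truth2, cfg, "Promiscuous")
        assert c1.equals(c2)


class TestClosedLoopLabels:
    def test_inherited_vs_t1_only_labels_match_truth(self):
        """Pipeline inheritance labels agree with ground truth (small cohort)."""
        from edittrace.edit_calling import AmpliconCaller, calls_table
        from edittrace.inheritance import match_generations
        from edittrace.synthetic_data import canonical_signature

        cfg = SimConfig(
            seed=5,
            genome_len=40_000,
            guides={"Promiscuous": default_offtarget_specs(6)},
            n_plants={"Promiscuous": 15},
            read_depth=40,
            n_progeny_range=(10, 10),
        )
        study = simulate_study(cfg)
        caller = AmpliconCaller(study.assays)
        gen = dict(zip(study.samples["plant_id"], study.samples["generation"]))
        per_plant = {}
        for plant_id, grp in study.reads.groupby("plant_id"):
            calls, _r, _u = caller.call_plant(
                list(zip(grp["read_id"], grp["sequence"])), gen[plant_id]
            )
            per_plant[plant_id] = calls
        table = calls_table(per_plant)
        records = match_generations(table, study.samples)

        by_locus = {a.locus_id: a for a in study.assays}
        truth_map = {}
        for ev in study.truth.events:
            key = (ev.plant_id, ev.locus_id, canonical_signature(by_locus[ev.locus_id], ev.signature))
            truth_map.setdefault(key, ev)
        checked = matched = 0
        for r in records:
            ev = truth_map.get((r.family_id, r.locus_id, r.signature))
            if ev is None:
                continue  # allele never observed in the parent leaf or progeny
            checked += 1
            # leaf-visible events must be flagged observed_in_T0 when called
            if ev.leaf_fraction > 0.2:
                matched += r.observed_in_T0
            else:
                matched += 1
        assert checked >= 10
        assert matched / checked >= 0.98
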