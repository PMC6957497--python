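import numpy as np
import pytest
from oracles import oracle_consistent, oracle_map, oracle_ped_set

from pedanc import (
    ErrorModelParams,
    SimConfig,
    align,
    correct_all,
    correct_locus,
    count_mendelian_inconsistent,
    demo_map,
    demo_pedigree,
    enumerate_candidates,
    enumerate_ped,
    estimate_epsilon_from_matrix,
    flag_loci,
    is_mendelian_consistent,
    parse_pedigree,
    simulate_pedigree,
    uniform_map,
)
from pedanc.ancestry_io import AncestryMatrix
from pedanc.detect_correct import FlagReason, double_crossover_runs

# the full Mendelian-consistent set for a father/mother/child trio
TRIO_PED_SET = {
    (0, 0, 0), (0, 1, 0), (0, 1, 1), (0, 2, 1), (1, 0, 0),
    (1, 0, 1), (1, 1, 0), (1, 1, 1), (1, 1, 2), (1, 2, 1),
    (1, 2, 2), (2, 0, 1), (2, 1, 1), (2, 1, 2), (2, 2, 2),
}


class TestConsistency:
    @pytest.mark.parametrize(
        "config,expected",
        [
            ((0, 2, 1), True),
            ((2, 0, 1), True),
            ((0, 0, 1), False),
            ((2, 0, 0), False),  # a dosage-2 parent forces a copy in each child
            ((1, 1, 1), True),
            ((0, 0, 2), False),
        ],
    )
    def test_trio_examples(self, trio, config, expected):
        assert is_mendelian_consistent(config, trio) is expected

    def test_matches_allele_assignment_oracle_on_trio(self, trio):
        import itertools

        for cfg in itertools.product((0, 1, 2), repeat=3):
            assert is_mendelian_consistent(cfg, trio) == oracle_consistent(cfg, trio)

    def test_missing_dosage_means_any_completion(self, trio):
        import itertools

        for cfg in itertools.product((0, 1, 2, -1), repeat=3):
            if -1 not in cfg:
                continue
            completions = itertools.product(
                *[(v,) if v >= 0 else (0, 1, 2) for v in cfg]
            )
            expected = any(is_mendelian_consistent(c, trio) for c in completions)
            assert is_mendelian_consistent(cfg, trio) == expected

    def test_three_generation_consistency_uses_global_structure(self, eight_person):
        # gf=2 forces p1 to carry a copy; k1..k3 of p1 x s1(=0) then each
        # carry <= 1 copy but k with dosage 0 needs p1 to transmit 0
        config = {"gf": 2, "gm": 0, "p1": 1, "p2": 1, "s1": 0, "k1": 0, "k2": 1, "k3": 1}
        vec = [config[i] for i in eight_person.ids]
        assert is_mendelian_consistent(vec, eight_person)
        config["gm"] = 2  # now p1 must be dosage 2: contradiction upstream
        vec = [config[i] for i in eight_person.ids]
        assert not is_mendelian_consistent(vec, eight_person)


class TestEnumeratePed:
    def test_trio_equals_printed_fifteen_set(self, trio):
        assert enumerate_ped(trio).as_set() == TRIO_PED_SET

    def test_single_founder_all_dosages(self):
        (ped,) = parse_pedigree("F a 0 0 1 0\n")
        assert enumerate_ped(ped).as_set() == {(0,), (1,), (2,)}

    def test_parent_child_pair_excludes_opposite_homozygotes(self):
        (ped,) = parse_pedigree("F mo 0 0 2 0\nF c 0 mo 1 0\n")
        got = enumerate_ped(ped).as_set()
        assert got == {
            (a, b)
            for a in (0, 1, 2)
            for b in (0, 1, 2)
            if (a, b) not in {(0, 2), (2, 0)}
        }
        assert len(got) == 7

    def test_size_guard_redirects_to_candidates(self):
        ped = demo_pedigree(20)
        with pytest.raises(ValueError, match="enumerate_candidates"):
            enumerate_ped(ped)

    @pytest.mark.parametrize("fam_text", [
        "F f 0 0 1 0\nF m 0 0 2 0\nF c f m 1 0\n",
        "F f 0 0 1 0\nF m 0 0 2 0\nF c1 f m 1 0\nF c2 f m 2 0\n",
        "F gf 0 0 1 0\nF gm 0 0 2 0\nF p gf gm 1 0\nF s 0 0 2 0\nF k p s 1 0\n",
        "F mo 0 0 2 0\nF c1 0 mo 1 0\nF c2 0 mo 1 0\n",
    ])
    def test_matches_brute_force_set(self, fam_text):
        (ped,) = parse_pedigree(fam_text)
        assert enumerate_ped(ped).as_set() == set(map(tuple, oracle_ped_set(ped)))


class TestEnumerateCandidates:
    def test_consistent_config_at_distance_zero(self, trio):
        got = enumerate_candidates((0, 2, 1), trio, max_diff=0)
        assert [tuple(c) for c in got] == [(0, 2, 1)]

    def test_trio_single_edit_neighbourhood(self, trio):
        got = {tuple(c) for c in enumerate_candidates((0, 0, 1), trio, max_diff=1)}
        # brute force over the 6 single-coordinate edits plus distance 0
        assert got == {(0, 0, 0), (0, 1, 1), (0, 2, 1), (1, 0, 1), (2, 0, 1)}

    def test_counting_bound(self, trio):
        from math import comb

        for max_diff in (0, 1, 2, 3):
            got = enumerate_candidates((1, 1, 1), trio, max_diff=max_diff)
            bound = sum(comb(3, k) * 2**k for k in range(max_diff + 1))
            assert 0 < got.shape[0] <= bound

    @pytest.mark.parametrize("fam_text", [
        "F f 0 0 1 0\nF m 0 0 2 0\nF c f m 1 0\n",
        "F f 0 0 1 0\nF m 0 0 2 0\nF c1 f m 1 0\nF c2 f m 2 0\n",
        "F gf 0 0 1 0\nF gm 0 0 2 0\nF p gf gm 1 0\nF s 0 0 2 0\nF k p s 1 0\n",
    ])
    def test_full_radius_recovers_entire_ped_set(self, fam_text):
        (ped,) = parse_pedigree(fam_text)
        rng = np.random.default_rng(0)
        full = enumerate_ped(ped).as_set()
        for _ in range(5):
            y = rng.integers(0, 3, size=ped.n)
            got = {tuple(c) for c in enumerate_candidates(y, ped, max_diff=ped.n)}
            assert got == full

    def test_candidates_are_sorted_by_distance_then_lex(self, trio):
        got = enumerate_candidates((0, 0, 1), trio, max_diff=2)
        y = np.array([0, 0, 1])
        dists = [int((c != y).sum()) for c in got]
        assert dists == sorted(dists)


class TestFlagLoci:
    def _bundle(self, seed=0, epsilon=0.0, L=400, n=4):
        ped = demo_pedigree(n)
        gmap = demo_map(L)
        sim = simulate_pedigree(ped, gmap, SimConfig(epsilon=epsilon), seed=seed)
        return sim, align(sim.observed, gmap, ped)

    def test_injected_flip_flags_mendelian_locus(self, trio):
        gmap = uniform_map(5, spacing_cm=0.5)
        dosages = np.ones((5, 3), dtype=np.int8)  # (1,1,1) everywhere: consistent
        dosages[2] = [0, 0, 1]  # inconsistent at locus 2
        mat = AncestryMatrix(marker_ids=gmap.marker_ids, individual_ids=trio.ids, dosages=dosages)
        flags = flag_loci(align(mat, gmap, trio))
        assert flags.loci_by_reason(FlagReason.MENDELIAN) == [2]

    def test_short_return_run_flagged_long_not(self):
        # spacing 0.3 cM: a 5-marker run spans 1.2 cM (< 2), 17 markers span 4.8 cM
        pos = np.arange(60) * 0.3
        track = np.full(60, 2, dtype=np.int8)
        track[20:25] = 1  # 1.2 cM return-run
        runs = double_crossover_runs(track, pos, window_cm=2.0)
        assert [(r[0], r[1]) for r in runs] == [(20, 25)]
        track[20:37] = 1  # 4.8 cM: too long
        assert double_crossover_runs(track, pos, window_cm=2.0) == []

    def test_majority_stretch_between_two_blips_not_flagged(self):
        # isolated errors at 10 and 40 must not flag the 2-run between them
        pos = np.arange(60) * 0.03
        track = np.full(60, 2, dtype=np.int8)
        track[10] = 1
        track[40] = 1
        runs = double_crossover_runs(track, pos, window_cm=2.0)
        assert [(r[0], r[1]) for r in runs] == [(10, 11), (40, 41)]

    def test_low_quality_cell_flags_locus(self, trio):
        gmap = uniform_map(3, spacing_cm=0.5)
        dosages = np.ones((3, 3), dtype=np.int8)
        quality = np.full((3, 3), 0.99)
        quality[1, 2] = 0.85
        mat = AncestryMatrix(
            marker_ids=gmap.marker_ids, individual_ids=trio.ids,
            dosages=dosages, quality=quality,
        )
        flags = flag_loci(align(mat, gmap, trio))
        rec = [r for r in flags.records if r.reason is FlagReason.LOW_QUALITY]
        assert [r.locus for r in rec] == [1]
        assert rec[0].individuals == ("c",)


class TestCorrectLocus:
    PARAMS = ErrorModelParams(epsilon=0.01, lamb=0.8, tau=8.0)

    def test_trio_flip_corrected_to_true_configuration(self, trio):
        # true X=(0,1,1) on both flanks, observed Y=(0,1,2), 0.1 cM gaps
        out = correct_locus(
            (0, 1, 2), (0, 1, 1), (0, 1, 1), 0.001, 0.001, trio, self.PARAMS
        )
        assert tuple(out.config) == (0, 1, 1)
        oracle_cfg, oracle_score = oracle_map(
            np.array([0, 1, 2]), np.array([0, 1, 1]), np.array([0, 1, 1]),
            0.001, 0.001, trio, self.PARAMS,
        )
        assert tuple(out.config) == oracle_cfg
        assert out.log_prob == pytest.approx(oracle_score, abs=1e-9)

    def test_consistent_matching_flanks_left_unchanged(self, trio):
        for cfg in [(0, 1, 1), (2, 2, 2), (1, 1, 1)]:
            out = correct_locus(cfg, cfg, cfg, 0.001, 0.001, trio, self.PARAMS)
            assert tuple(out.config) == cfg

    def test_chromosome_start_uses_right_flank_only(self, trio):
        y = np.array([0, 0, 1])
        right = np.array([0, 1, 1])
        out = correct_locus(y, None, right, 0.0, 0.002, trio, self.PARAMS)
        oracle_cfg, _ = oracle_map(y, None, right, 0.0, 0.002, trio, self.PARAMS)
        assert tuple(out.config) == oracle_cfg

    def test_both_flanks_missing_rejected(self, trio):
        with pytest.raises(ValueError):
            correct_locus((0, 0, 1), None, None, 0, 0, trio, self.PARAMS)


class TestCorrectAll:
    def test_clean_consistent_data_is_untouched(self):
        ped = demo_pedigree(4)
        gmap = demo_map(100)
        dosages = np.full((100, 4), 2, dtype=np.int8)
        mat = AncestryMatrix(
            marker_ids=gmap.marker_ids, individual_ids=ped.ids, dosages=dosages
        )
        bundle = align(mat, gmap, ped)
        corrected, report = correct_all(
            bundle, ErrorModelParams(epsilon=0.01, lamb=0.8)
        )
        assert (corrected.dosages == mat.dosages).all()
        assert report.cells_changed == 0
        assert report.loci_changed == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_error_reduction_small_pedigree(self, seed):
        from pedanc import evaluate

        ped = demo_pedigree(4)
        gmap = demo_map(500)
        sim = simulate_pedigree(ped, gmap, SimConfig(epsilon=0.01), seed=seed)
        bundle = align(sim.observed, gmap, ped)
        corrected, report = correct_all(
            bundle, ErrorModelParams(epsilon=0.01, lamb=0.8)
        )
        before, after = evaluate(sim.truth, sim.observed, corrected, ped, gmap)
        assert after.dosage_error_rate < before.dosage_error_rate
        assert report.mendelian_after <= report.mendelian_before
        assert report.mendelian_flagged_unresolved == 0

    def test_block_mode_resolves_mendelian_flags_too(self):
        ped = demo_pedigree(4)
        gmap = demo_map(500)
        sim = simulate_pedigree(ped, gmap, SimConfig(epsilon=0.01), seed=3)
        bundle = align(sim.observed, gmap, ped)
        corrected, report = correct_all(
            bundle, ErrorModelParams(epsilon=0.01, lamb=0.8), mode="block"
        )
        assert report.mendelian_flagged_unresolved == 0
        assert report.mendelian_after <= report.mendelian_before

    def test_epsilon_estimated_when_params_omitted(self):
        ped = demo_pedigree(10)
        gmap = demo_map(800)
        sim = simulate_pedigree(ped, gmap, SimConfig(epsilon=0.02), seed=5)
        bundle = align(sim.observed, gmap, ped)
        corrected, report = correct_all(bundle, params=None)
        assert report.mendelian_after < report.mendelian_before

    def test_never_increases_mendelian_inconsistencies(self):
        ped = demo_pedigree(10)
        gmap = demo_map(600)
        for seed in range(3):
            sim = simulate_pedigree(ped, gmap, SimConfig(epsilon=0.02), seed=seed)
            bundle = align(sim.observed, gmap, ped)
            corrected, report = correct_all(
                bundle, ErrorModelParams(epsilon=0.02, lamb=0.8)
            )
            assert report.mendelian_after <= report.mendelian_before


class TestEpsilonFromMatrix:
    def test_recovers_injected_rate_roughly(self):
        ped = demo_pedigree(20)
        gmap = demo_map(2000)
        sim = simulate_pedigree(ped, gmap, SimConfig(epsilon=0.02), seed=11)
        est = estimate_epsilon_from_matrix(sim.observed, ped, lamb=0.8)
        assert est.epsilon == pytest.approx(0.02, rel=0.35)
        assert len(est.families) >= 3

    def test_error_free_matrix_gives_zero(self):
        ped = demo_pedigree(4)
        gmap = demo_map(300)
        sim = simulate_pedigree(ped, gmap, SimConfig(epsilon=0.0), seed=0)
        est = estimate_epsilon_from_matrix(sim.observed, ped, lamb=0.8)
        assert est.epsilon == 0.0
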