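"""Connectivity matching, fragment enumeration (vs a networkx oracle),
reduced-chi2 scoring (vs brute-force enumeration) and result-list contracts."""

import itertools
import os

import networkx as nx
import numpy as np
import pytest

from bbassign import simgen
from bbassign.connect import (Fragment, MatchConfig, ScoringConfig,
                              SequenceArrays, analyze_all, best_ss_combination,
                              build_fragments, enumerate_placements,
                              fragment_observations, match_level,
                              parse_result_file, result_file_name,
                              score_placement, write_result_file, _edges)
from bbassign.formats import SS, ProteinSequence
from bbassign.shift_db import SS_CLASSES
from bbassign.spin_label import SpinSystem, build_spin_systems


def _system(sid, internal=None, sequential=None):
    return SpinSystem(sid, 118.0, 8.2, internal or {}, sequential or {})


class TestMatchLevel:
    CFG = MatchConfig(tol_ca=0.1, tol_cb=0.1, tol_co=0.1)

    def test_all_three_agree(self):
        pred = _system(1, internal={"CA": 56.2, "CB": 31.0, "CO": 176.0})
        succ = _system(2, sequential={"CA": 56.25, "CB": 31.05, "CO": 175.95})
        assert match_level(pred, succ, self.CFG) == 3

    def test_two_available_both_agree(self):
        pred = _system(1, internal={"CA": 56.2, "CO": 176.0})
        succ = _system(2, sequential={"CA": 56.25, "CO": 175.95, "CB": 31.0})
        assert match_level(pred, succ, self.CFG) == 2

    def test_conflicting_shared_nucleus_vetoes_the_link(self):
        # lower match levels cover missing shifts, not disagreeing ones
        pred = _system(1, internal={"CA": 56.2, "CB": 31.0, "CO": 176.0})
        succ = _system(2, sequential={"CA": 56.2, "CB": 36.0, "CO": 176.0})
        assert match_level(pred, succ, self.CFG) == 0

    def test_glycine_signature_promotes_to_three(self):
        pred = _system(1, internal={"CA": 45.1, "CO": 174.0})
        succ = _system(2, sequential={"CA": 45.1, "CO": 174.0})
        assert match_level(pred, succ, self.CFG) == 3

    def test_non_glycine_ca_window_is_not_promoted(self):
        pred = _system(1, internal={"CA": 56.1, "CO": 174.0})
        succ = _system(2, sequential={"CA": 56.1, "CO": 174.0})
        assert match_level(pred, succ, self.CFG) == 2

    def test_nothing_shared_is_unconnectable(self):
        pred = _system(1, internal={"CA": 56.2})
        succ = _system(2, sequential={"CB": 31.0})
        assert match_level(pred, succ, self.CFG) == 0


def _chain_systems(values):
    """Systems wired into a chain: system i+1's sequential = i's internal."""
    systems = []
    for i, v in enumerate(values):
        internal = {"CA": v, "CB": v + 10, "CO": v + 120}
        sequential = None
        if i > 0:
            w = values[i - 1]
            sequential = {"CA": w, "CB": w + 10, "CO": w + 120}
        systems.append(_system(i + 1, internal, sequential))
    return systems


class TestFragmentEnumeration:
    def test_line_graph_path_counts(self):
        systems = _chain_systems([50.0, 52.0, 54.0, 56.0, 58.0])
        build = build_fragments(systems, MatchConfig(max_fragment_size=5))
        for size, expect in ((2, 4), (3, 3), (4, 2), (5, 1)):
            assert len(build.groups[(size, 3)]) == expect
        chain = build.groups[(5, 3)][0]
        assert chain.system_ids == (1, 2, 3, 4, 5)

    def test_branch_emits_both_fragments(self):
        a = _system(1, internal={"CA": 50.0, "CB": 60.0, "CO": 170.0})
        b = _system(2, sequential={"CA": 50.0, "CB": 60.0, "CO": 170.0})
        c = _system(3, sequential={"CA": 50.0, "CB": 60.0, "CO": 170.0})
        build = build_fragments([a, b, c], MatchConfig())
        pairs = {f.system_ids for f in build.groups[(2, 3)]}
        assert pairs == {(1, 2), (1, 3)}

    def test_paths_match_networkx_enumeration(self):
        rng = np.random.default_rng(12)
        systems = []
        for sid in range(1, 9):
            internal = {"CA": float(rng.uniform(45, 65)),
                        "CO": float(rng.uniform(172, 179))}
            sequential = {"CA": float(rng.uniform(45, 65)),
                          "CO": float(rng.uniform(172, 179))}
            systems.append(_system(sid, internal, sequential))
        cfg = MatchConfig(tol_ca=3.0, tol_cb=3.0, tol_co=2.0,
                          max_fragment_size=6)
        edges = _edges(systems, cfg)
        for level in (1, 2, 3):
            g = nx.DiGraph()
            g.add_nodes_from(s.id for s in systems)
            g.add_edges_from(e for e, lvl in edges.items() if lvl >= level)
            want = set()
            for u, v in itertools.permutations(g.nodes, 2):
                for path in nx.all_simple_paths(g, u, v, cutoff=5):
                    want.add(tuple(path))
            build = build_fragments(systems, cfg)
            got = {f.system_ids
                   for size in range(2, 7)
                   for f in build.groups.get((size, level), [])}
            assert got == want

    def test_cap_triggers_backoff_and_floor_errors_out(self):
        # wholly degenerate shifts can never be separated by shrinking
        systems = [_system(i, {"CA": 50.0, "CB": 60.0, "CO": 170.0},
                           {"CA": 50.0, "CB": 60.0, "CO": 170.0})
                   for i in range(1, 12)]
        cfg = MatchConfig(fragment_cap=100)
        with pytest.raises(RuntimeError, match="clean"):
            build_fragments(systems, cfg)

    def test_backoff_resolves_moderate_degeneracy(self):
        # true chain at spacing 1.0 with decoy coincidences at 0.12 ppm:
        # shrinking the tolerances below 0.12 cuts the decoy edges
        values = [50.0 + i for i in range(8)]
        systems = _chain_systems(values)
        for i, s in enumerate(systems):
            if s.sequential:
                s.sequential = {k: v + (0.12 if i % 2 else -0.12)
                                for k, v in s.sequential.items()}
        cfg = MatchConfig(tol_ca=0.2, tol_cb=0.2, tol_co=0.2, fragment_cap=3)
        build = build_fragments(systems, cfg)
        assert build.backoff_rounds > 0
        assert all(len(v) <= 3 for v in build.groups.values())
        assert build.tol_ca < 0.2


@pytest.fixture(scope="module")
def coil_seqarr(tables):
    seq = ProteinSequence("MAGLSEKAFD")
    return SequenceArrays(seq, tables)


def _make_obs(tables, residues, seq, start, ss, jitter=0.0, rng=None):
    """Observations equal to consensus means (optionally jittered)."""
    obs = []
    from bbassign.connect import Observation
    for off, res_number in enumerate(range(start, start + residues)):
        res = seq.residue(res_number)
        for nuc in ("CA", "CB", "CO"):
            ent = tables.consensus.lookup(res, ss, nuc)
            if ent is None:
                continue
            v = ent[0]
            if rng is not None:
                v += jitter * ent[1] * rng.standard_normal()
            obs.append(Observation(off, nuc, v))
    return obs


class TestScoring:
    def test_exact_consensus_scores_zero(self, tables, coil_seqarr):
        seq = coil_seqarr.sequence
        obs = _make_obs(tables, 3, seq, 4, SS.COIL)
        ss = {r: SS.COIL for r in range(4, 7)}
        chi2, n = score_placement(obs, coil_seqarr, 4, ss)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert n == len(obs)

    def test_single_shift_one_sd_scores_scale_factor(self, tables, coil_seqarr):
        from bbassign.connect import Observation
        mean, sd = tables.consensus.lookup("L", SS.COIL, "CA")
        obs = [Observation(0, "CA", mean + sd)]
        chi2, n = score_placement(obs, coil_seqarr, 4, {4: SS.COIL})
        assert (chi2, n) == (pytest.approx(10.0), 1)

    def test_zero_compared_shifts_is_undefined(self, coil_seqarr):
        from bbassign.connect import Observation
        # a lone term probing before the sequence start compares nothing
        obs = [Observation(-2, "CA", 55.0)]
        with pytest.raises(ValueError, match="no shifts"):
            score_placement(obs, coil_seqarr, 2, {})

    def test_scale_factor_scales_chi2_linearly(self, tables, coil_seqarr):
        rng = np.random.default_rng(5)
        seq = coil_seqarr.sequence
        obs = _make_obs(tables, 3, seq, 4, SS.COIL, jitter=1.0, rng=rng)
        _, chi2_10, _ = best_ss_combination(obs, coil_seqarr, 4)
        _, chi2_20, _ = best_ss_combination(
            obs, coil_seqarr, 4, ScoringConfig(scale_factor=20.0))
        assert chi2_20 == pytest.approx(2 * chi2_10)

    def test_adding_an_exact_shift_never_increases_chi2(self, tables,
                                                        coil_seqarr):
        from bbassign.connect import Observation
        rng = np.random.default_rng(8)
        seq = coil_seqarr.sequence
        obs = _make_obs(tables, 2, seq, 4, SS.COIL, jitter=1.0, rng=rng)
        labels, chi2, _ = best_ss_combination(obs, coil_seqarr, 4)
        extra_res = seq.residue(5)
        mean, _ = tables.consensus.lookup(extra_res, labels[5], "CA")
        aug = obs + [Observation(1, "CA", mean)]
        _, chi2_aug, _ = best_ss_combination(aug, coil_seqarr, 4)
        assert chi2_aug <= chi2 + 1e-9

    @pytest.mark.parametrize("n_res", [2, 3, 4])
    def test_per_residue_minimum_equals_exhaustive_enumeration(
            self, tables, coil_seqarr, n_res):
        rng = np.random.default_rng(n_res)
        seq = coil_seqarr.sequence
        for trial in range(34):
            start = int(rng.integers(2, len(seq) - n_res + 1))
            ss_true = SS_CLASSES[int(rng.integers(3))]
            obs = _make_obs(tables, n_res, seq, start, ss_true,
                            jitter=1.5, rng=rng)
            labels, chi2, n = best_ss_combination(obs, coil_seqarr, start)
            best = min(
                score_placement(obs, coil_seqarr, start,
                                dict(zip(range(start, start + n_res), combo)))[0]
                for combo in itertools.product(SS_CLASSES, repeat=n_res))
            assert chi2 == pytest.approx(best, rel=1e-9)

    def test_helix_generated_shifts_recover_helix_labels(self, tables,
                                                         coil_seqarr):
        obs = _make_obs(tables, 4, coil_seqarr.sequence, 4, SS.HELIX)
        labels, chi2, _ = best_ss_combination(obs, coil_seqarr, 4)
        assert all(l is SS.HELIX for l in labels.values())
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_expected_ss_restriction_inactive_at_the_optimum(
            self, tables, coil_seqarr):
        seq = coil_seqarr.sequence
        obs = _make_obs(tables, 3, seq, 4, SS.COIL)
        expected = [SS.COIL] * len(seq)
        cfg = ScoringConfig(restrict_to_expected_ss=True)
        _, chi2_restricted, _ = best_ss_combination(obs, coil_seqarr, 4, cfg,
                                                    expected)
        _, chi2_free, _ = best_ss_combination(obs, coil_seqarr, 4)
        assert chi2_restricted == pytest.approx(chi2_free)


class TestPlacements:
    def test_list_contract_sorted_and_capped(self, noisy_run):
        for _, rl in noisy_run.analysis.all_lists():
            chis = [p.chi2 for p in rl.placements]
            assert len(chis) <= 20
            assert chis == sorted(chis)
            assert len({p.result_index for p in rl.placements}) == len(chis)

    def test_amides_avoid_prolines_and_first_residue(self, noisy_run):
        seq = noisy_run.dataset.sequence
        for _, rl in noisy_run.analysis.all_lists():
            for p in rl.placements:
                for r in p.amide_residues:
                    assert r != seq.first
                    assert seq.residue(r) != "P"

    def test_glycine_fragment_lands_on_the_glycine(self, tables):
        seq = ProteinSequence("MALSGEKAFD")  # single glycine at 5
        seqarr = SequenceArrays(seq, tables)
        sys1 = _system(1, internal={"CA": 45.1, "CO": 174.9})     # Gly-like
        sys2 = _system(2, internal={"CA": 56.6, "CB": 29.9, "CO": 176.6},
                       sequential={"CA": 45.1, "CO": 174.9})
        frag = Fragment((1, 2), 3)
        rl = enumerate_placements(frag, {1: sys1, 2: sys2}, seqarr)
        assert rl.placements[0].start_residue == 5
        # oracle: brute force over all starts and SS combinations
        obs = fragment_observations(frag, {1: sys1, 2: sys2})
        best = None
        for start in range(2, len(seq)):
            window = [seq.residue(r) for r in (start, start + 1)]
            if start + 1 > seq.last or "P" in window:
                continue
            for combo in itertools.product(SS_CLASSES, repeat=3):
                ss = dict(zip(range(start - 1, start + 2), combo))
                chi2, _ = score_placement(obs, seqarr, start, ss)
                if best is None or chi2 < best[0]:
                    best = (chi2, start)
        assert best[1] == 5
        assert rl.placements[0].chi2 == pytest.approx(best[0], rel=1e-9)

    def test_noise_free_fragments_rank_their_true_position_first(
            self, clean_dataset, tables):
        systems, _ = build_spin_systems(clean_dataset.peak_lists,
                                        simgen.PipelineConfig().label)
        build = build_fragments(systems, MatchConfig(tol_ca=0.3, tol_cb=0.3,
                                                     tol_co=0.3))
        seqarr = SequenceArrays(clean_dataset.sequence, tables)
        by_id = {s.id: s for s in systems}
        truth = {}
        for s in systems:
            refs = [clean_dataset.truth[ref] for ref in s.source_peaks]
            truth[s.id] = next(r for r, nuc, slot in refs if slot == "amide")
        checked = 0
        for frag in build.groups[(10, 3)] + build.groups[(3, 3)]:
            rl = enumerate_placements(frag, by_id, seqarr)
            want = truth[frag.system_ids[0]]
            if list(range(want, want + len(frag))) == \
                    [truth[s] for s in frag.system_ids]:
                assert rl.placements[0].start_residue == want
                checked += 1
        assert checked > 20

    def test_highlighting_marks_expected_ss_agreement(self, clean_dataset,
                                                      tables):
        systems, _ = build_spin_systems(clean_dataset.peak_lists,
                                        simgen.PipelineConfig().label)
        analysis = analyze_all(systems, clean_dataset.sequence, tables,
                               MatchConfig(tol_ca=0.3, tol_cb=0.3, tol_co=0.3),
                               expected_ss=clean_dataset.ss)
        tops = [rl.placements[0] for _, rl in analysis.all_lists()
                if rl.placements]
        assert any(p.highlighted for p in tops)
        for p in tops:
            if p.highlighted:
                for r, lab in p.ss_labels.items():
                    exp = clean_dataset.ss[r - clean_dataset.sequence.offset]
                    assert exp in (SS.UNKNOWN, lab)


class TestAnalyzeAll:
    def test_result_files_cover_sizes_two_to_ten(self, noisy_run, tmp_path,
                                                 tables):
        analysis = analyze_all(noisy_run.systems, noisy_run.dataset.sequence,
                               tables, simgen.PipelineConfig().match,
                               out_dir=str(tmp_path))
        for size in range(2, 11):
            assert (size, 3) in analysis.groups
            assert (tmp_path / result_file_name(size, 3)).exists()

    def test_empty_spin_system_set_is_an_explicit_error(self, tables,
                                                        default_sequence):
        with pytest.raises(ValueError, match="no spin systems"):
            analyze_all([], default_sequence, tables)

    def test_result_file_roundtrip(self, noisy_run):
        for key, rls in noisy_run.analysis.groups.items():
            text = write_result_file(rls)
            parsed = parse_result_file(text)
            flat = [p for rl in rls for p in rl.placements]
            assert len(parsed) == len(flat)
            for a, b in zip(flat, parsed):
                assert a.result_index == b.result_index
                assert a.fragment.system_ids == b.fragment.system_ids
                assert a.start_residue == b.start_residue
                assert b.chi2 == pytest.approx(a.chi2, abs=1e-5)
                assert a.ss_labels == b.ss_labels
                assert a.highlighted == b.highlighted
            break
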