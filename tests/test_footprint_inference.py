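"""Footprint calling and promoter occupancy-state classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from l1asp.footprint_inference import (
    ACCESSIBLE,
    MISSING,
    PROTECTED,
    AccessibilityVector,
    ClassifierParams,
    TRUTH_TO_STATE,
    accessibility_calls,
    call_footprints,
    classify_matrix,
    classify_promoter_state,
    iter_accessibility,
    occupancy_profile,
    promoter_windows,
    state_population_summary,
)
from l1asp.locus_model import DataError, GenomicInterval
from l1asp.methylation_analysis import CODE_METH, CODE_UNMETH, build_call_matrix, qc_clones
from l1asp.synthetic_data import SimulationConfig, simulate_dataset


def make_vec(positions, calls, molecule_id="m1"):
    return AccessibilityVector(
        molecule_id, tuple(positions), np.asarray(calls, dtype=np.int8)
    )


AMPLICON = GenomicInterval("loc", 1, 240)


class TestAccessibilityCalls:
    def test_methylated_gpc_is_accessible(self, clean_matrix):
        vec = accessibility_calls(clean_matrix, 0)
        gpc = clean_matrix.subset(site_class="gpc")
        expected = np.where(gpc.calls[0] == CODE_METH, ACCESSIBLE, PROTECTED)
        assert (vec.calls == expected).all()
        assert vec.positions == gpc.positions

    def test_round_trip_matches_simulator_truth(self, locus, clean_dataset, clean_matrix):
        # efficiency 1: accessible exactly where no footprint covers the site
        by_id = {m_id: mol for m_id, mol in zip(clean_dataset.clone_ids, clean_dataset.molecules)}
        for vec in iter_accessibility(clean_matrix):
            mol = by_id[vec.molecule_id]
            truth = np.array(
                [
                    PROTECTED
                    if any(fp.contains(p) for fp in mol.nucleosome_footprints)
                    else ACCESSIBLE
                    for p in vec.positions
                ],
                dtype=np.int8,
            )
            assert (vec.calls == truth).all()

    def test_matrix_without_gpc_columns_rejected(self, clean_matrix):
        cpg_only = clean_matrix.subset(site_class="cpg")
        with pytest.raises(DataError, match="GpC"):
            accessibility_calls(cpg_only, 0)

    def test_unknown_clone_id_rejected(self, clean_matrix):
        with pytest.raises(DataError):
            accessibility_calls(clean_matrix, "nonexistent")


class TestCallFootprints:
    def test_flanking_midpoint_span(self):
        # protected run 50..190 flanked by accessible sites at 30 and 210
        positions = [30] + list(range(50, 191, 20)) + [210]
        calls = [ACCESSIBLE] + [PROTECTED] * 8 + [ACCESSIBLE]
        fps = call_footprints(make_vec(positions, calls), AMPLICON)
        assert len(fps) == 1
        fp = fps[0]
        assert (fp.span.start, fp.span.end) == (40, 200)
        assert fp.span.length == 161
        assert fp.classification == "nucleosome"
        assert fp.n_protected_sites == 8

    def test_all_accessible_gives_no_footprint(self):
        fps = call_footprints(make_vec([10, 20, 30], [ACCESSIBLE] * 3), AMPLICON)
        assert fps == []

    def test_all_protected_spans_amplicon(self):
        fps = call_footprints(make_vec([10, 120, 230], [PROTECTED] * 3), AMPLICON)
        assert len(fps) == 1
        assert (fps[0].span.start, fps[0].span.end) == (AMPLICON.start, AMPLICON.end)
        assert fps[0].classification == "super-nucleosomal"

    def test_missing_calls_are_neutral(self):
        # missing neither breaks the run nor contributes protected sites
        positions = [10, 30, 50, 70, 90]
        calls = [ACCESSIBLE, PROTECTED, MISSING, PROTECTED, ACCESSIBLE]
        fps = call_footprints(make_vec(positions, calls), AMPLICON)
        assert len(fps) == 1
        assert fps[0].protected_sites == (30, 70)

    def test_smoothing_absorbs_isolated_accessible(self):
        positions = [10, 30, 50, 70, 90]
        calls = [ACCESSIBLE, PROTECTED, ACCESSIBLE, PROTECTED, ACCESSIBLE]
        assert len(call_footprints(make_vec(positions, calls), AMPLICON, k=0)) == 2
        merged = call_footprints(make_vec(positions, calls), AMPLICON, k=1)
        assert len(merged) == 1
        assert merged[0].protected_sites == (30, 70)

    def test_too_few_sites_rejected(self):
        with pytest.raises(DataError):
            call_footprints(make_vec([10], [PROTECTED]), AMPLICON)

    @given(
        calls=st.lists(
            st.sampled_from([ACCESSIBLE, PROTECTED, MISSING]), min_size=2, max_size=40
        ),
        k=st.integers(min_value=0, max_value=2),
    )
    def test_footprints_ordered_and_disjoint(self, calls, k):
        positions = [5 + 13 * i for i in range(len(calls))]
        amplicon = GenomicInterval("loc", 1, positions[-1] + 10)
        fps = call_footprints(make_vec(positions, calls), amplicon, k=k)
        for a, b in zip(fps, fps[1:]):
            assert a.span.end < b.span.start
        n_protected = sum(1 for c in calls if c == PROTECTED)
        assert sum(fp.n_protected_sites for fp in fps) == n_protected


class TestClassifyPromoterState:
    def _classify(self, locus, vec):
        fps = call_footprints(vec, locus.interval)
        return classify_promoter_state(fps, vec, locus)

    def _vec_from_truth(self, locus, footprints):
        gpc = locus.site_map.gpc_sites
        calls = [
            PROTECTED if any(fp.contains(p) for fp in footprints) else ACCESSIBLE
            for p in gpc
        ]
        return make_vec(gpc, calls)

    def test_fully_protected_molecule_is_tetranucleosomal(self, locus):
        vec = make_vec(locus.site_map.gpc_sites, [PROTECTED] * len(locus.site_map.gpc_sites))
        assert self._classify(locus, vec).state == "tetranucleosomal"

    def test_di_pattern_is_dinucleosomal(self, locus):
        from l1asp.synthetic_data import canonical_footprints

        vec = self._vec_from_truth(locus, canonical_footprints(locus, "di"))
        call = self._classify(locus, vec)
        assert call.state == "dinucleosomal"
        occ = call.evidence["occupied_windows"]
        assert occ["plus1_sense"] and occ["plus1_asp"]
        assert not occ["minus1_sense"] and not occ["minus1_asp"]

    def test_tetra_pattern_is_tetranucleosomal(self, locus):
        from l1asp.synthetic_data import canonical_footprints

        vec = self._vec_from_truth(locus, canonical_footprints(locus, "tetra"))
        assert self._classify(locus, vec).state == "tetranucleosomal"

    def test_no_protection_is_open(self, locus):
        vec = make_vec(locus.site_map.gpc_sites, [ACCESSIBLE] * len(locus.site_map.gpc_sites))
        assert self._classify(locus, vec).state == "open"

    def test_uninformative_window_gives_other(self, locus):
        gpc = locus.site_map.gpc_sites
        windows = promoter_windows(locus)
        calls = [
            MISSING if windows.minus1_sense.contains(p) else ACCESSIBLE for p in gpc
        ]
        call = self._classify(locus, make_vec(gpc, calls))
        assert call.state == "other"
        assert "uninformative" in call.evidence["reason"]


class TestOccupancyProfile:
    def test_all_tetra_frequency_one_under_footprints(self, locus):
        cfg = SimulationConfig(
            n_molecules=40, state_mixture={"tetra": 1.0},
            enzyme_efficiency=1.0, conversion_rate=1.0, seed=3,
        )
        ds = simulate_dataset(locus, cfg)
        matrix = build_call_matrix(list(zip(ds.clone_ids, ds.reads)), locus)
        prof = occupancy_profile(matrix)
        fps = ds.molecules[0].nucleosome_footprints
        for pos, freq in zip(prof.positions, prof.frequency):
            expected = 1.0 if any(fp.contains(pos) for fp in fps) else 0.0
            assert freq == expected

    def test_half_open_mixture_frequency_near_half(self, locus):
        n = 400
        cfg = SimulationConfig(
            n_molecules=n, state_mixture={"tetra": 0.5, "open": 0.5},
            enzyme_efficiency=1.0, conversion_rate=1.0, seed=9,
        )
        ds = simulate_dataset(locus, cfg)
        matrix = build_call_matrix(list(zip(ds.clone_ids, ds.reads)), locus)
        prof = occupancy_profile(matrix)
        fps = ds.molecules[[m.state_label for m in ds.molecules].index("tetra")].nucleosome_footprints
        sd = np.sqrt(0.25 / n)
        for pos, freq in zip(prof.positions, prof.frequency):
            if any(fp.contains(pos) for fp in fps):
                assert abs(freq - 0.5) <= 3 * sd

    def test_single_molecule_frequencies_binary(self, clean_matrix):
        prof = occupancy_profile(clean_matrix.select_clones([0]))
        assert set(np.unique(prof.frequency[~np.isnan(prof.frequency)])) <= {0.0, 1.0}


class TestStatePopulationSummary:
    def test_empty_input_all_zero(self):
        summary = state_population_summary([])
        assert (summary["count"] == 0).all()
        assert (summary["fraction"] == 0.0).all()

    def test_counts_sum_to_input_size(self, locus, noisy_matrix):
        calls, _ = classify_matrix(noisy_matrix, locus)
        summary = state_population_summary(calls)
        assert summary["count"].sum() == noisy_matrix.n_clones

    def test_all_open_simulation_is_fully_open(self, locus):
        cfg = SimulationConfig(
            n_molecules=50, state_mixture={"open": 1.0},
            enzyme_efficiency=1.0, conversion_rate=1.0, seed=4,
        )
        ds = simulate_dataset(locus, cfg)
        matrix = build_call_matrix(list(zip(ds.clone_ids, ds.reads)), locus)
        calls, _ = classify_matrix(matrix, locus)
        summary = state_population_summary(calls).set_index("state")
        assert summary.loc["open", "fraction"] == 1.0


class TestRecoveryProperties:
    def test_state_recovery_on_noisy_mixture(self, locus, noisy_dataset, noisy_matrix):
        truth = dict(zip(noisy_dataset.clone_ids, noisy_dataset.state_labels))
        calls, _ = classify_matrix(noisy_matrix, locus)
        acc = np.mean(
            [c.state == TRUTH_TO_STATE[truth[c.molecule_id]] for c in calls]
        )
        assert acc >= 0.95

    def test_nucleosome_footprints_localize_on_di_molecules(self, locus):
        # called nucleosome-class midpoints within one inter-GpC gap of truth
        cfg = SimulationConfig(
            n_molecules=200, state_mixture={"di": 1.0}, seed=21
        )
        ds = simulate_dataset(locus, cfg)
        matrix, _ = qc_clones(list(zip(ds.clone_ids, ds.reads)), locus)
        _, fps_per_mol = classify_matrix(matrix, locus)
        gap = np.diff(locus.site_map.gpc_sites).max()
        true_mids = [
            (fp.start + fp.end) / 2
            for fp in ds.molecules[0].nucleosome_footprints
        ]
        localized = 0
        with_nucleosome_call = 0
        for fps in fps_per_mol:
            nuc = [f for f in fps if f.classification == "nucleosome"]
            with_nucleosome_call += bool(nuc)
            localized += all(
                min(abs((f.span.start + f.span.end) / 2 - tm) for tm in true_mids) <= gap
                for f in nuc
            )
        n = len(fps_per_mol)
        # precision: every nucleosome-class call sits on a true nucleosome
        assert localized / n >= 0.9
        # sensitivity floor: merged +1/+1 patches (super-class) stay a minority
        assert with_nucleosome_call / n >= 0.7

    def test_accuracy_monotone_in_enzyme_efficiency(self, locus):
        accs = []
        for eff in (0.5, 0.7, 0.85, 1.0):
            cfg = SimulationConfig(n_molecules=400, seed=7, enzyme_efficiency=eff)
            ds = simulate_dataset(locus, cfg)
            matrix, _ = qc_clones(list(zip(ds.clone_ids, ds.reads)), locus)
            calls, _ = classify_matrix(matrix, locus)
            truth = dict(zip(ds.clone_ids, ds.state_labels))
            accs.append(
                np.mean([c.state == TRUTH_TO_STATE[truth[c.molecule_id]] for c in calls])
            )
        assert all(b >= a for a, b in zip(accs, accs[1:]))
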