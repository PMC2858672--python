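"""Ground-truth generator: molecules, enzyme marks, reads, cohorts, MNase."""

import itertools

import numpy as np
import pytest

from l1asp.locus_model import DataError, GenomicInterval, build_locus_model
from l1asp.synthetic_data import (
    CohortConfig,
    GroupSpec,
    MoleculeState,
    SimulationConfig,
    canonical_footprints,
    fragment_class_counts,
    make_synthetic_genome,
    simulate_bisulfite_reads,
    simulate_cohort,
    simulate_dataset,
    simulate_enzyme_treatment,
    simulate_mnase,
    simulate_molecules,
    synthetic_promoter_locus,
)


def _in_any(pos, footprints):
    return any(fp.contains(pos) for fp in footprints)


class TestSimulateMolecules:
    def test_pure_tetra_mixture(self, locus):
        cfg = SimulationConfig(
            n_molecules=20, state_mixture={"tetra": 1.0}, seed=0
        )
        for mol in simulate_molecules(locus, cfg):
            assert mol.state_label == "tetra"
            assert len(mol.nucleosome_footprints) == 4
            assert all(mol.endogenous_meth.values())  # fully CpG methylated

    def test_pure_di_mixture_leaves_nfrs_upstream_of_both_tss(self, locus):
        cfg = SimulationConfig(n_molecules=20, state_mixture={"di": 1.0}, seed=0)
        upstream_sense = GenomicInterval(
            locus.interval.chrom, locus.tss_sense - 147, locus.tss_sense - 1
        )
        upstream_asp = GenomicInterval(
            locus.interval.chrom, locus.tss_antisense + 1, locus.tss_antisense + 147
        )
        for mol in simulate_molecules(locus, cfg):
            assert len(mol.nucleosome_footprints) == 2
            assert not any(mol.endogenous_meth.values())
            for fp in mol.nucleosome_footprints:
                assert not fp.overlaps(upstream_sense)
                assert not fp.overlaps(upstream_asp)

    def test_mixture_fraction_within_binomial_bound(self, locus):
        n = 10_000
        cfg = SimulationConfig(
            n_molecules=n, state_mixture={"tetra": 0.5, "di": 0.5}, seed=11
        )
        mols = simulate_molecules(locus, cfg)
        frac = np.mean([m.state_label == "tetra" for m in mols])
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_locus_too_short_raises_with_required_span(self):
        tiny = build_locus_model(
            "ACGT" * 30,
            {
                "tss_sense": GenomicInterval("loc", 40, 40, "+"),
                "tss_antisense": GenomicInterval("loc", 80, 80, "-"),
                "l1": GenomicInterval("loc", 1, 120, "-"),
            },
        )
        with pytest.raises(DataError, match="bp"):
            simulate_molecules(tiny, SimulationConfig(n_molecules=1, seed=0))

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(DataError):
            SimulationConfig(state_mixture={"tetra": 0.5, "di": 0.4})

    def test_endogenous_mixture_override(self, locus):
        cfg = SimulationConfig(
            n_molecules=2000,
            state_mixture={"di": 1.0},
            endogenous_mixture=0.3,
            seed=5,
        )
        mols = simulate_molecules(locus, cfg)
        frac = np.mean([all(m.endogenous_meth.values()) for m in mols])
        assert abs(frac - 0.3) <= 3 * np.sqrt(0.3 * 0.7 / 2000)


class TestEnzymeTreatment:
    def test_full_efficiency_open_molecule_marks_every_gpc(self, locus):
        cfg = SimulationConfig(enzyme_efficiency=1.0, seed=0)
        mol = MoleculeState((), {p: False for p in locus.site_map.cpg_sites}, "open")
        marks = simulate_enzyme_treatment(mol, locus, cfg)
        assert all(marks[p] for p in locus.site_map.gpc_sites)

    def test_footprinted_gpcs_never_marked(self, locus):
        cfg = SimulationConfig(enzyme_efficiency=1.0, seed=0)
        fps = canonical_footprints(locus, "tetra")
        mol = MoleculeState(fps, {p: True for p in locus.site_map.cpg_sites}, "tetra")
        marks = simulate_enzyme_treatment(mol, locus, cfg)
        for p in locus.site_map.gpc_sites:
            if _in_any(p, fps):
                assert not marks[p]

    def test_marked_fraction_matches_efficiency(self, locus):
        cfg = SimulationConfig(enzyme_efficiency=0.8, seed=3)
        rng = np.random.default_rng(3)
        mol = MoleculeState((), {p: False for p in locus.site_map.cpg_sites}, "open")
        n_molecules, n_sites = 2000, len(locus.site_map.gpc_sites)
        marked = 0
        for _ in range(n_molecules):
            marks = simulate_enzyme_treatment(mol, locus, cfg, rng=rng)
            marked += sum(marks[p] for p in locus.site_map.gpc_sites)
        total = n_molecules * n_sites
        frac = marked / total
        assert abs(frac - 0.8) <= 3 * np.sqrt(0.8 * 0.2 / total)

    def test_cpg_states_copied_through(self, locus):
        cfg = SimulationConfig(seed=0)
        endo = {p: (i % 2 == 0) for i, p in enumerate(locus.site_map.cpg_sites)}
        mol = MoleculeState((), endo, "open")
        marks = simulate_enzyme_treatment(mol, locus, cfg)
        for p, v in endo.items():
            assert marks[p] == v


def _mini_locus(ref="AACGTT"):
    return build_locus_model(
        ref,
        {
            "tss_sense": GenomicInterval("m", 1, 1, "+"),
            "tss_antisense": GenomicInterval("m", len(ref), len(ref), "-"),
            "l1": GenomicInterval("m", 1, len(ref), "-"),
        },
    )


class TestBisulfiteReads:
    def test_methylated_cpg_protected_from_conversion(self):
        locus = _mini_locus("ACGT")
        mol = MoleculeState((), {2: True}, "open")
        cfg = SimulationConfig(conversion_rate=1.0, seed=0)
        assert simulate_bisulfite_reads(mol, {2: True}, locus, cfg) == "ACGT"

    def test_unmethylated_cpg_converted(self):
        locus = _mini_locus("ACGT")
        mol = MoleculeState((), {2: False}, "open")
        cfg = SimulationConfig(conversion_rate=1.0, seed=0)
        assert simulate_bisulfite_reads(mol, {2: False}, locus, cfg) == "ATGT"

    def test_full_conversion_leaves_no_unmarked_c(self, locus):
        cfg = SimulationConfig(conversion_rate=1.0, seed=0)
        mol = MoleculeState((), {p: False for p in locus.site_map.cpg_sites}, "open")
        read = simulate_bisulfite_reads(mol, {}, locus, cfg)
        assert "C" not in read

    def test_read_length_always_equals_reference(self, locus, noisy_dataset):
        assert all(len(r) == len(locus.reference) for r in noisy_dataset.reads)


class TestDeterminism:
    def test_same_seed_identical_dataset(self, locus):
        cfg = SimulationConfig(n_molecules=50, seed=99)
        a = simulate_dataset(locus, cfg)
        b = simulate_dataset(locus, cfg)
        assert a.reads == b.reads
        assert a.state_labels == b.state_labels
        assert all(x.endogenous_meth == y.endogenous_meth for x, y in zip(a.molecules, b.molecules))

    def test_different_seed_differs(self, locus):
        a = simulate_dataset(locus, SimulationConfig(n_molecules=50, seed=1))
        b = simulate_dataset(locus, SimulationConfig(n_molecules=50, seed=2))
        assert a.reads != b.reads

    def test_synthetic_genome_seed_determinism(self):
        r1, a1, m1 = make_synthetic_genome(4, 8, seed=5)
        r2, a2, m2 = make_synthetic_genome(4, 8, seed=5)
        assert r1 == r2
        assert a1.equals(a2)
        assert m1.equals(m2)


class TestSimulateCohort:
    def test_zero_sd_gives_group_means(self):
        cfg = CohortConfig(
            groups={
                "N": GroupSpec(5, 80.0, 0.0, 1.0, 0.0),
                "T": GroupSpec(5, 20.0, 0.0, 8.0, 0.0),
            },
            seed=0,
        )
        table = simulate_cohort(cfg)
        assert (table.loc[table["group"] == "N", "methylation"] == 80.0).all()
        assert (table.loc[table["group"] == "T", "expression"] == 8.0).all()

    def test_group_mean_ordering_recovered(self):
        cfg = CohortConfig(
            groups={
                "N": GroupSpec(30, 80.0, 8.0, 1.0, 0.5),
                "CN": GroupSpec(30, 50.0, 10.0, 4.0, 1.5),
                "T": GroupSpec(30, 20.0, 10.0, 8.0, 3.0),
            },
            seed=1,
        )
        means = simulate_cohort(cfg).groupby("group")["methylation"].mean()
        assert means["N"] > means["CN"] > means["T"]

    def test_negative_coupling_yields_negative_rank_correlation(self):
        from scipy.stats import spearmanr

        cfg = CohortConfig(
            groups={"N": GroupSpec(200, 50.0, 15.0, 5.0, 2.0)},
            coupling=-1.0,
            seed=2,
        )
        table = simulate_cohort(cfg)
        rho, _ = spearmanr(table["methylation"], table["expression"])
        assert rho < -0.9

    def test_values_within_bounds(self):
        cfg = CohortConfig(
            groups={"T": GroupSpec(500, 5.0, 30.0, 0.5, 2.0)}, seed=3
        )
        table = simulate_cohort(cfg)
        assert table["methylation"].between(0, 100).all()
        assert (table["expression"] >= 0).all()


def mnase_enumeration_oracle(n_nucleosomes, p_cut):
    """Exact fragment-class expectations by enumerating all cut patterns."""
    counts = {}
    total_weight = 0.0
    for pattern in itertools.product([0, 1], repeat=n_nucleosomes - 1):
        w = 1.0
        for c in pattern:
            w *= p_cut if c else (1 - p_cut)
        run = 1
        frags = []
        for c in pattern:
            if c:
                frags.append(run)
                run = 1
            else:
                run += 1
        frags.append(run)
        for f in frags:
            counts[f] = counts.get(f, 0.0) + w
        total_weight += w
    assert abs(total_weight - 1.0) < 1e-12
    return counts  # expected fragments of each class per molecule


class TestSimulateMnase:
    def _tetra(self, locus, n):
        fps = canonical_footprints(locus, "tetra")
        return [MoleculeState(fps, {}, "tetra") for _ in range(n)]

    def _di(self, locus, n):
        fps = canonical_footprints(locus, "di")
        return [MoleculeState(fps, {}, "di") for _ in range(n)]

    def test_full_digestion_gives_mononucleosomes(self, locus):
        frags = simulate_mnase(self._tetra(locus, 3), p_cut=1.0, rng=0)
        assert frags == [[1, 1, 1, 1]] * 3

    def test_no_digestion_keeps_dinucleosome(self, locus):
        frags = simulate_mnase(self._di(locus, 2), p_cut=0.0, rng=0)
        assert frags == [[2], [2]]

    def test_nucleosome_conservation(self, locus):
        mols = self._tetra(locus, 200) + self._di(locus, 200)
        frags = simulate_mnase(mols, p_cut=0.5, rng=1)
        assert sum(sum(f) for f in frags) == 200 * 4 + 200 * 2
        assert all(sum(f) == len(m.nucleosome_footprints) for f, m in zip(frags, mols) if f)

    def test_partial_digestion_matches_enumeration_oracle(self, locus):
        n = 10_000
        frags = simulate_mnase(self._tetra(locus, n), p_cut=0.5, rng=2)
        observed = fragment_class_counts(frags)
        expected = mnase_enumeration_oracle(4, 0.5)
        for cls, exp_per_mol in expected.items():
            obs = observed.get(cls, 0) / n
            # each molecule contributes a bounded count; binomial-style bound
            sd = np.sqrt(exp_per_mol / n)
            assert abs(obs - exp_per_mol) <= 3 * max(sd, 1e-3)

    def test_open_molecules_yield_no_fragments(self, locus):
        mol = MoleculeState((), {}, "open")
        assert simulate_mnase([mol], p_cut=0.5, rng=0) == [[]]


class TestMakeSyntheticGenome:
    def test_zero_repeats(self):
        _, annotations, manifest = make_synthetic_genome(3, 0, seed=0)
        assert manifest.empty
        assert (annotations["feature"] != "L1").all()

    def test_planted_candidates_flagged(self):
        _, _, manifest = make_synthetic_genome(5, 10, seed=1)
        # kinds cycle candidate, sense, short, exonic
        assert manifest["is_candidate"].sum() == 3
        assert set(manifest["kind"]) == {
            "candidate", "sense_decoy", "short_decoy", "exonic_decoy",
        }

    def test_counts_validated(self):
        with pytest.raises(DataError):
            make_synthetic_genome(-1, 0)
        with pytest.raises(DataError):
            make_synthetic_genome(0, 5)
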