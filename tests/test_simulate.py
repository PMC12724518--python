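"""The synthetic study: reference construction, truth planting, the RibOxi
generative model (trimming, masking, condition dependence) and the RiboMeth
cleavage model."""

import numpy as np
import pytest
from scipy import stats

from nmscan.caller import dedupe_umis, end3_coverage
from nmscan.simulate import (
    Reference,
    SimulationConfig,
    TruthDesign,
    TruthSet,
    TruthSite,
    build_reference,
    design_snornas,
    make_study,
    plant_truth,
    simulate_ribometh,
    simulate_riboxi,
)


class TestBuildReference:
    def test_deterministic_for_fixed_seed(self):
        a = build_reference((10_000,), 5, seed=1)
        b = build_reference((10_000,), 5, seed=1)
        assert a.contigs == b.contigs
        assert [t.exons for t in a.annotation] == [t.exons for t in b.annotation]

    def test_different_seed_differs(self):
        a = build_reference((10_000,), 5, seed=1)
        b = build_reference((10_000,), 5, seed=2)
        assert a.contigs != b.contigs

    def test_segment_lengths_track_requested_proportions(self):
        ref = build_reference((10_000,), 5, proportions=(0.05, 0.55, 0.40), seed=1)
        for tx in ref.annotation:
            u5, cds, u3 = tx.segment_lengths()
            L = tx.length
            assert abs(u5 - 0.05 * L) <= 1
            assert abs(cds - 0.55 * L) <= 1
            assert abs(u3 - 0.40 * L) <= 1

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            build_reference((10_000,), proportions=(0.5, 0.6, 0.4))

    def test_short_contig_rejected(self):
        with pytest.raises(ValueError):
            build_reference((500,))


class TestPlantTruth:
    def test_default_design_counts_and_genotype_matrix(self, study):
        truth = study.truth
        assert len(truth.sites) == 18
        by_dep = {}
        for s in truth.sites:
            by_dep.setdefault(s.dependency, []).append(s)
        assert len(by_dep["constitutive"]) == 10
        assert len(by_dep["SNORD116"]) == 4
        assert len(by_dep["SNORD113114"]) == 4
        # presence follows the deletion genotypes exactly
        for s in by_dep["SNORD116"]:
            pattern = [truth.effective_fraction(s, c) > 0 for c in truth.conditions]
            assert pattern == [True, False, True, False]
        for s in by_dep["SNORD113114"]:
            pattern = [truth.effective_fraction(s, c) > 0 for c in truth.conditions]
            assert pattern == [True, False, False, False]
        for s in by_dep["constitutive"]:
            assert all(truth.effective_fraction(s, c) > 0 for c in truth.conditions)

    def test_snord116_site_fraction_zero_in_deletion_line(self, study):
        site = next(s for s in study.truth.sites if s.dependency == "SNORD116")
        assert study.truth.effective_fraction(site, "CT2-smDEL") == 0.0

    def test_tandem_pair_flagged_and_adjacent(self, study):
        tandem = [s for s in study.truth.sites if s.tandem]
        assert len(tandem) == 2
        a, b = tandem
        assert a.contig == b.contig and a.strand == b.strand
        assert abs(a.pos - b.pos) == 1

    def test_more_dependent_sites_than_guides_rejected(self, study):
        design = TruthDesign(n_snord116=99)
        with pytest.raises(ValueError):
            plant_truth(study.reference, study.snornas, design)

    def test_guide_set_iff_snorna_dependency(self):
        with pytest.raises(ValueError):
            TruthSite("chr1", 5, "+", 0.5, "SNORD116", None)
        with pytest.raises(ValueError):
            TruthSite("chr1", 5, "+", 0.5, "constitutive", "SNORD116-1")


def _single_site_setup(fraction, length=5000, pos=2500, bg=0.0):
    reference = Reference({"chr1": "A" * length})
    truth = TruthSet(
        [TruthSite("chr1", pos, "+", fraction, "constitutive")], ("CT2",), {}
    )
    cfg = SimulationConfig(depth=50_000, background_end_rate=bg, seed=4)
    return reference, truth, cfg


class TestSimulateRiboxi:
    def test_reproducible_for_fixed_seed(self, study, ct2_records):
        again = simulate_riboxi(study.reference, study.truth, study.config, "CT2")
        assert again == ct2_records

    def test_fully_methylated_site_collects_all_ends(self):
        """With no background, every recorded 3' end sits exactly on the
        planted site: trimming from any terminus within the budget window
        stops there, and nothing else can ligate."""
        reference, truth, cfg = _single_site_setup(1.0)
        records = simulate_riboxi(reference, truth, cfg, "CT2")
        assert len(records) > 0
        assert {r.end3 for r in records} == {2500}

    def test_tandem_fully_methylated_masks_proximal(self):
        """Consecutive sites both at stoichiometry 1.0: the distal (3'-most)
        site intercepts every molecule, so the proximal site records nothing."""
        reference = Reference({"chr1": "A" * 5000})
        truth = TruthSet(
            [
                TruthSite("chr1", 2500, "+", 1.0, "constitutive", tandem=True),
                TruthSite("chr1", 2501, "+", 1.0, "constitutive", tandem=True),
            ],
            ("CT2",),
            {},
        )
        cfg = SimulationConfig(depth=50_000, background_end_rate=0.0, seed=4)
        records = simulate_riboxi(reference, truth, cfg, "CT2")
        ends = {r.end3 for r in records}
        assert 2501 in ends and 2500 not in ends

    def test_proximal_count_scales_with_distal_unmethylated_fraction(self):
        """Proximal record counts across a distal-stoichiometry grid follow
        count = C * (1 - f_dist): zero intercept, slope within 10% of the
        f_dist=0 count."""
        reference = Reference({"chr1": "A" * 5000})
        counts = []
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        for f_dist in grid:
            truth = TruthSet(
                [
                    TruthSite("chr1", 2500, "+", 1.0, "constitutive", tandem=True),
                    TruthSite("chr1", 2501, "+", f_dist, "constitutive", tandem=True),
                ],
                ("CT2",),
                {},
            )
            cfg = SimulationConfig(depth=100_000, background_end_rate=0.0, seed=4)
            records = simulate_riboxi(reference, truth, cfg, "CT2")
            counts.append(sum(1 for r in records if r.end3 == 2500))
        assert counts[-1] == 0
        slope, intercept = np.polyfit([1 - f for f in grid], counts, 1)
        assert slope == pytest.approx(counts[0], rel=0.10)

    def test_partially_methylated_distal_leaks_to_proximal(self):
        """With distal at 0.5 the proximal site receives roughly the half of
        molecules on which the distal site is unmethylated."""
        reference = Reference({"chr1": "A" * 5000})
        truth = TruthSet(
            [
                TruthSite("chr1", 2500, "+", 1.0, "constitutive", tandem=True),
                TruthSite("chr1", 2501, "+", 0.5, "constitutive", tandem=True),
            ],
            ("CT2",),
            {},
        )
        cfg = SimulationConfig(depth=100_000, background_end_rate=0.0, seed=4)
        records = simulate_riboxi(reference, truth, cfg, "CT2")
        prox = sum(1 for r in records if r.end3 == 2500)
        dist = sum(1 for r in records if r.end3 == 2501)
        assert prox > 0 and dist > 0
        assert prox / dist == pytest.approx(1.0, abs=0.25)  # both ~= C * 0.5

    def test_deletion_condition_signal_is_background(self, study):
        """At a SNORD116-guided site, the deletion line's record count is
        statistically indistinguishable from spurious ligation."""
        records = simulate_riboxi(study.reference, study.truth, study.config, "CT2-smDEL")
        cov = end3_coverage(dedupe_umis(records))
        cfg = study.config
        span = {}
        for tx in study.reference.annotation:
            span[tx.contig] = span.get(tx.contig, 0) + (tx.end - tx.start)
        for s in study.truth.sites:
            if s.dependency != "SNORD116":
                continue
            count = cov.get(s.contig, s.strand, s.pos)
            # under H0 the count is Binomial(termini per position, background rate)
            n_trials = max(1, round(cfg.depth / span[s.contig]))
            p = stats.binomtest(count, n_trials, cfg.background_end_rate).pvalue
            assert p > 0.01

    def test_unknown_condition_rejected(self, study):
        with pytest.raises(ValueError):
            simulate_riboxi(study.reference, study.truth, study.config, "K562")


class TestSimulateRibometh:
    def test_full_protection_gives_zero_end_sum(self):
        reference, truth, _ = _single_site_setup(1.0, length=2000, pos=1000)
        profiles = simulate_ribometh(reference, truth, depth=1000, replicates=1, seed=2)
        p = profiles[0]
        assert p.ends3.get(1000, 0) == 0 and p.ends5.get(1001, 0) == 0

    def test_background_poisson_moments(self):
        """With no methylation anywhere, per-position end sums are the sum of
        two Poisson(depth) draws; the empirical mean over 10 kb must land
        within 3 standard errors of 2*depth."""
        reference = Reference({"chr1": "A" * 10_000})
        truth = TruthSet([], ("CT2",), {})
        depth = 100
        p = simulate_ribometh(reference, truth, depth=depth, replicates=1, seed=3)[0]
        sums = np.array(
            [p.ends3.get(n, 0) + p.ends5.get(n + 1, 0) for n in range(10_000)]
        )
        se = np.sqrt(2 * depth / len(sums))
        assert abs(sums.mean() - 2 * depth) < 3 * se

    def test_replicates_distinct_but_reproducible(self):
        reference, truth, _ = _single_site_setup(0.5, length=2000, pos=1000)
        a = simulate_ribometh(reference, truth, depth=500, replicates=3, seed=9)
        b = simulate_ribometh(reference, truth, depth=500, replicates=3, seed=9)
        assert [p.ends3 for p in a] == [p.ends3 for p in b]
        assert a[0].ends3 != a[1].ends3


class TestSimulationConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"depth": 0},
            {"background_end_rate": 0.5},
            {"background_end_rate": -1e-5},
            {"trim_budget": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


def test_make_study_deterministic():
    a = make_study(seed=7, contig_lengths=(2000,), design=TruthDesign(4, 1, 1))
    b = make_study(seed=7, contig_lengths=(2000,), design=TruthDesign(4, 1, 1))
    assert [s.__dict__ for s in a.truth.sites] == [s.__dict__ for s in b.truth.sites]
    assert a.reference.contigs == b.reference.contigs
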