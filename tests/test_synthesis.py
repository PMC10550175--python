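"""Phantom construction, outcome simulation, series generation, cohorts."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from drillscore.scoring import dentist_score_from_counts, f1_score, select_essential_outcomes
from drillscore.study import GROUPS, learning_gain
from drillscore.synthesis import (
    CohortConfig,
    DrillPlan,
    PhantomConfig,
    build_tooth_phantom,
    generate_cohort,
    generate_outcome_series,
    simulate_outcome,
)
from drillscore.volume import classify_outcome


def score_outcome(phantom, actual):
    counts = classify_outcome(phantom.occupancy, phantom.ideal, actual)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return counts, dentist_score_from_counts(counts).value


class TestPhantom:
    def test_deterministic_per_seed(self):
        a = build_tooth_phantom(PhantomConfig.small(seed=7))
        b = build_tooth_phantom(PhantomConfig.small(seed=7))
        assert np.array_equal(a.occupancy.mask, b.occupancy.mask)
        assert np.array_equal(a.ideal_cavity.mask, b.ideal_cavity.mask)
        c = build_tooth_phantom(PhantomConfig.small(seed=8))
        assert not np.array_equal(a.occupancy.mask, c.occupancy.mask)

    def test_structural_invariants(self, small_phantom):
        ph = small_phantom
        assert ph.ideal_cavity.count() > 0
        # cavity and ideal partition the occupancy
        assert not np.any(ph.ideal.mask & ph.ideal_cavity.mask)
        assert np.array_equal(ph.ideal.mask | ph.ideal_cavity.mask, ph.occupancy.mask)
        # pulp region strictly enclosed by dentin: one-voxel dilation of the
        # pulp region stays inside dentin+pulp
        pulp, dentin = ph.tissue_masks["pulp"], ph.tissue_masks["dentin"]
        grown = ndimage.binary_dilation(pulp)
        assert np.all(~grown | pulp | dentin)

    def test_orifice_centers_inside_ideal_cavity(self, small_phantom):
        ph = small_phantom
        spacing = ph.occupancy.spacing
        for p in ph.orifice_centers:
            idx = tuple(int(round(p[a] / spacing[a])) for a in range(3))
            assert ph.ideal_cavity.mask[idx]

    def test_default_grid_builds_quickly(self, default_phantom):
        # the session fixture already built the default 90x135x90 phantom;
        # assert the advertised resolution and composition
        assert default_phantom.occupancy.shape == (90, 135, 90)
        assert default_phantom.occupancy.count() > 100_000
        labels = list(default_phantom.spheres.labels)
        assert {"enamel", "dentin", "pulp"} <= set(labels)

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(shape=(4, 4, 4))
        with pytest.raises(ValueError):
            PhantomConfig(spacing=-1.0)


class TestSimulateOutcome:
    def test_nominal_plan_reproduces_ideal(self, small_phantom):
        actual = simulate_outcome(small_phantom, DrillPlan())
        assert np.array_equal(actual.mask, small_phantom.ideal.mask)
        counts, d = score_outcome(small_phantom, actual)
        assert (counts.FP, counts.FN) == (0, 0)
        assert d == 0.0

    def test_full_underdrill_leaves_tooth_untouched(self, small_phantom):
        actual = simulate_outcome(small_phantom, DrillPlan(underdrill_fraction=1.0))
        assert np.array_equal(actual.mask, small_phantom.occupancy.mask)
        counts, _ = score_outcome(small_phantom, actual)
        assert counts.FN == 0

    def test_overdrill_sweep_monotone_in_fn_and_d(self, small_phantom):
        fns, ds = [], []
        for e in (0.0, 0.05, 0.1, 0.15):
            actual = simulate_outcome(small_phantom, DrillPlan(overdrill_extent=e))
            counts, d = score_outcome(small_phantom, actual)
            fns.append(counts.FN)
            ds.append(d)
        assert np.all(np.diff(fns) > 0)
        assert np.all(np.diff(ds) > 0)

    def test_actual_always_subset_of_initial(self, small_phantom, rng):
        for _ in range(5):
            plan = DrillPlan(
                overdrill_extent=rng.uniform(0, 0.2),
                underdrill_fraction=rng.uniform(0, 1),
                roughness=rng.uniform(0, 0.05),
                seed=int(rng.integers(1 << 30)),
            )
            actual = simulate_outcome(small_phantom, plan)
            assert not np.any(actual.mask & ~small_phantom.occupancy.mask)

    def test_explicit_path_carves_capsule(self, small_phantom):
        ph = small_phantom
        center = np.asarray(ph.occupancy.shape) * ph.occupancy.spacing / 2
        path = [center + [0, 0.3, 0], center - [0, 0.3, 0]]
        plan = DrillPlan(path=path, tool_radius=0.1)
        actual = simulate_outcome(ph, plan)
        assert actual.count() < ph.occupancy.count()

    def test_roughness_deterministic_per_seed(self, small_phantom):
        plan = DrillPlan(overdrill_extent=0.05, roughness=0.03, seed=11)
        a = simulate_outcome(small_phantom, plan)
        b = simulate_outcome(small_phantom, plan)
        assert np.array_equal(a.mask, b.mask)

    def test_invalid_plans_rejected(self):
        with pytest.raises(ValueError):
            DrillPlan(underdrill_fraction=1.5)
        with pytest.raises(ValueError):
            DrillPlan(overdrill_extent=-0.1)


class TestOutcomeSeries:
    def test_single_outcome_valid(self, small_phantom):
        recs = generate_outcome_series(small_phantom, 1, seed=5)
        assert len(recs) == 1
        assert recs[0].counts.total == small_phantom.occupancy.count()

    def test_seed_reproducibility(self, small_phantom):
        a = generate_outcome_series(small_phantom, 6, seed=9)
        b = generate_outcome_series(small_phantom, 6, seed=9)
        assert [r.dentist for r in a] == [r.dentist for r in b]
        assert [r.f1 for r in a] == [r.f1 for r in b]

    def test_scores_cover_empirical_windows(self, small_phantom):
        recs = generate_outcome_series(small_phantom, 40, seed=2)
        S = np.array([r.counts.TP / (r.counts.TP + r.counts.FN) for r in recs])
        P = np.array([r.counts.TP / (r.counts.TP + r.counts.FP) for r in recs])
        f1 = np.array([r.f1 for r in recs])
        assert S.min() < 0.45 and S.max() > 0.85  # sensitivity spreads wide
        assert P.min() > 0.95 and P.max() <= 1.0  # precision high and narrow
        assert f1.max() - f1.min() >= 0.35  # n=40; the 240-outcome series spans >= 0.5

    def test_uniform_target_spreads_f1(self, small_phantom):
        recs = generate_outcome_series(small_phantom, 30, seed=2, target="uniform")
        f1 = np.array([r.f1 for r in recs])
        assert f1.max() - f1.min() >= 0.35

    def test_essential_selection_on_series(self, small_phantom):
        recs = generate_outcome_series(small_phantom, 60, seed=4)
        scores = [r.dentist for r in recs]
        idx = select_essential_outcomes(scores, 12)
        assert len(idx) == len(set(idx)) == 12
        sel = np.asarray(scores)[idx]
        span = max(scores) - min(scores)
        assert sel.min() <= min(scores) + span / 12
        assert sel.max() >= max(scores) - span / 12

    def test_parameter_recovery_overdrill_monotone_in_d(self, small_phantom):
        """Noiseless sweep: the score strictly tracks the overdrill extent."""
        extents = np.linspace(0, 0.25, 8)
        ds = []
        for e in extents:
            actual = simulate_outcome(small_phantom, DrillPlan(overdrill_extent=float(e)))
            _, d = score_outcome(small_phantom, actual)
            ds.append(d)
        assert np.all(np.diff(ds) > 0)


class TestVirtualExpert:
    def test_dentist_correlates_with_threshold_rater(self, small_phantom):
        """A noiseless 'virtual expert' that rates five spatial surfaces by
        thresholding mis-drilled voxel counts must correlate positively with
        the automated score."""
        from drillscore.agreement import pearson_correlation

        ph = small_phantom
        nx, ny, nz = ph.occupancy.shape
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        # four wall quadrants around the grid axis plus the floor (lower third)
        floor = jj < ny // 3
        quads = [
            ~floor & (ii < nx // 2) & (kk < nz // 2),
            ~floor & (ii < nx // 2) & (kk >= nz // 2),
            ~floor & (ii >= nx // 2) & (kk < nz // 2),
            ~floor & (ii >= nx // 2) & (kk >= nz // 2),
        ]
        surfaces = quads + [floor]

        recs = generate_outcome_series(ph, 30, seed=6)
        totals, ds = [], []
        for rec in recs:
            mis = (rec.actual.mask ^ ph.ideal.mask) & ph.occupancy.mask
            total = 0
            for surf in surfaces:
                frac = mis[surf].sum() / max(ph.occupancy.mask[surf].sum(), 1)
                total += int(np.digitize(frac, [0.02, 0.1, 0.3]))  # 0..3
            totals.append(total)
            ds.append(rec.dentist)
        r, _ = pearson_correlation(ds, totals)
        assert r > 0


class TestCohort:
    def test_determinism_and_layout(self):
        a = generate_cohort(3, seed=42)
        b = generate_cohort(3, seed=42)
        assert [(r.group, r.e0, r.e1, r.trial_scores) for r in a] == [
            (r.group, r.e0, r.e1, r.trial_scores) for r in b
        ]
        assert len(a) == 12
        assert sorted({r.group for r in a}) == sorted(GROUPS)

    def test_null_config_has_no_mean_gain(self):
        gains = [
            learning_gain(r)
            for s in range(300)
            for r in generate_cohort(5, CohortConfig.null(), seed=s)
        ]
        se = np.std(gains, ddof=1) / np.sqrt(len(gains))
        assert abs(np.mean(gains)) < 4 * se

    def test_configured_pooled_gain_recovered(self):
        gains = [
            learning_gain(r) for s in range(300) for r in generate_cohort(10, seed=s)
        ]
        se = np.std(gains, ddof=1) / np.sqrt(len(gains))
        assert np.mean(gains) == pytest.approx(-0.375, abs=4 * se)

    def test_moments_match_study_scale(self):
        records = [r for s in range(100) for r in generate_cohort(10, seed=s)]
        e0 = np.array([r.e0 for r in records])
        assert e0.mean() == pytest.approx(2.77, abs=0.05)
        assert e0.std(ddof=1) == pytest.approx(1.19, abs=0.05)
        assert np.all(e0 >= 0)
        gains = np.array([learning_gain(r) for r in records])
        assert gains.std(ddof=1) == pytest.approx(1.95, abs=0.15)

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(1)
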