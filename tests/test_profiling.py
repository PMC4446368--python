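"""Inference core: regions, factor graph, loss, conditional solve, MAP."""

import numpy as np
import pytest

from nmrprofile import simulate as sim
from nmrprofile.model import (
    Cluster,
    CompoundSignature,
    InvalidParameterError,
    Peak,
    ProfileAssignment,
    SpectralLibrary,
    synthesize_mixture,
)
from nmrprofile.profiling import (
    INFLUENCE_EPS,
    InferenceConfig,
    build_factor_graph,
    fit_concentrations,
    gibbs_score,
    infer_map,
    influence_interval,
    partition_regions,
    region_loss,
)


class TestInfluenceInterval:
    def test_closed_form_single_peak(self):
        cl = Cluster("c", (Peak(1.0, 2.0, 0.02),), -0.025, 0.025)
        lo, hi = influence_interval(cl)
        reach = 0.01 * np.sqrt(1.0 / INFLUENCE_EPS - 1.0)
        assert lo == pytest.approx(2.0 - reach - 0.025)
        assert hi == pytest.approx(2.0 + reach + 0.025)
        assert (lo, hi) == pytest.approx((1.659, 2.341), abs=5e-3)
        # amplitude at the pre-window boundary equals eps * height
        from nmrprofile.model import eval_lorentzian

        val = eval_lorentzian(cl.peaks[0], 0.0, np.array([2.0 + reach]))[0]
        assert val == pytest.approx(INFLUENCE_EPS * 1.0, rel=1e-6)

    def test_half_amplitude_reach_is_half_width(self):
        cl = Cluster("c", (Peak(1.0, 2.0, 0.02),), 0.0, 0.0)
        lo, hi = influence_interval(cl, eps=0.5)
        assert hi - lo == pytest.approx(0.02)

    def test_multi_peak_envelope(self):
        peaks = (Peak(1.0, 2.0, 0.02), Peak(0.5, 2.3, 0.01))
        cl = Cluster("c", peaks, -0.025, 0.025)
        lo, hi = influence_interval(cl)
        for p in peaks:
            plo, phi = influence_interval(Cluster("x", (p,), -0.025, 0.025))
            assert lo <= plo and hi >= phi


class TestPartitionRegions:
    def test_disjoint_clusters_get_singleton_regions(self, axis):
        lib = SpectralLibrary(
            [
                CompoundSignature("A", (Cluster("a", (Peak(1.0, 2.0, 0.003),)),)),
                CompoundSignature("B", (Cluster("b", (Peak(1.0, 8.0, 0.003),)),)),
            ]
        )
        regions = partition_regions(lib, axis)
        labels = [r.cluster_ids for r in regions if r.cluster_ids]
        assert frozenset({"a"}) in labels and frozenset({"b"}) in labels
        assert all(len(l) == 1 for l in labels)

    def test_overlapping_clusters_share_a_region(self, axis):
        lib = SpectralLibrary(
            [
                CompoundSignature("A", (Cluster("a", (Peak(1.0, 5.0, 0.003),)),)),
                CompoundSignature("B", (Cluster("b", (Peak(1.0, 5.05, 0.003),)),)),
            ]
        )
        regions = partition_regions(lib, axis)
        assert any(r.cluster_ids == frozenset({"a", "b"}) for r in regions)

    def test_empty_library_single_empty_region(self, axis):
        regions = partition_regions(SpectralLibrary([]), axis)
        assert len(regions) == 1 and not regions[0].cluster_ids

    def test_partition_covers_axis_disjointly(self, axis):
        lib = sim.generate_library(10, seed=8)
        regions = partition_regions(lib, axis)
        bounds = sorted((r.lo, r.hi) for r in regions)
        assert bounds[0][0] == pytest.approx(axis[0])
        for (l1, h1), (l2, h2) in zip(bounds[:-1], bounds[1:]):
            assert h1 == pytest.approx(l2)

    def test_matches_brute_force_oracle(self):
        """Region labels equal the per-grid-point influence sets computed
        directly, for 100 random small libraries."""
        axis = sim.default_axis(2**12)
        rng = np.random.default_rng(0)
        for trial in range(100):
            lib = sim.generate_library(
                int(rng.integers(1, 5)), seed=trial, include_reference=False,
                params=sim.LibraryParams(clusters_range=(1, 3), peaks_range=(1, 3)),
            )
            intervals = {
                cl.cluster_id: influence_interval(cl) for _, cl in lib.clusters()
            }
            # oracle: per-point membership test
            oracle = {}
            for cid, (lo, hi) in intervals.items():
                oracle[cid] = (axis >= lo) & (axis < hi)
            regions = partition_regions(lib, axis)
            for r in regions:
                sel = (axis >= r.lo) & (axis < r.hi)
                if not sel.any():
                    continue
                for cid, member in oracle.items():
                    in_region = member[sel]
                    expected = cid in r.cluster_ids
                    assert in_region.all() == expected and in_region.any() == expected


class TestFactorGraph:
    def test_reachability_iff_interval_on_axis(self, axis):
        inside = CompoundSignature("IN", (Cluster("in0", (Peak(1.0, 5.0, 0.003),)),))
        outside = CompoundSignature("OUT", (Cluster("out0", (Peak(1.0, 40.0, 0.003),)),))
        lib = SpectralLibrary([inside, outside])
        fg = build_factor_graph(lib, axis)
        reachable = fg.reachable_variables()
        assert "IN" in reachable and "in0" in reachable
        assert "OUT" not in reachable and "out0" not in reachable

    def test_factor_variables_follow_region_labels(self, axis):
        lib = sim.generate_library(5, seed=4)
        owner = {cl.cluster_id: comp.name for comp, cl in lib.clusters()}
        fg = build_factor_graph(lib, axis)
        for region, svars, cvars in fg.factors:
            assert svars == region.cluster_ids
            assert cvars == frozenset(owner[c] for c in svars)


class TestRegionLossAndScore:
    def test_truth_loss_at_truncation_floor(self, small_mixture):
        # reconstruction is restricted to each region's clusters, so the truth
        # loss is not exactly zero but bounded by the influence cutoff
        # (eps = 1e-3 of apex) tail truncation, vanishing relative to signal
        lib, truth, axis = small_mixture
        spec = synthesize_mixture(lib, truth, axis)
        total = sum(region_loss(r, spec, lib, truth) for r in partition_regions(lib, axis))
        assert total < 1e-5 * float(spec.real @ spec.real)

    def test_quadratic_in_residual(self, small_mixture):
        lib, truth, axis = small_mixture
        spec = synthesize_mixture(lib, truth, axis)
        half = ProfileAssignment(
            {k: v / 2 for k, v in truth.concentrations.items()}, dict(truth.shifts)
        )
        quarter = ProfileAssignment(
            {k: 0.75 * v for k, v in truth.concentrations.items()}, dict(truth.shifts)
        )
        regions = partition_regions(lib, axis)
        l_half = sum(region_loss(r, spec, lib, half) for r in regions)
        l_quarter = sum(region_loss(r, spec, lib, quarter) for r in regions)
        # residual scale 0.5 vs 0.25 -> loss ratio 4 (up to tail truncation)
        assert l_half == pytest.approx(4 * l_quarter, rel=1e-3)

    def test_region_sum_equals_global_sse(self, small_mixture):
        lib, truth, axis = small_mixture
        spec = synthesize_mixture(lib, truth, axis)
        off = ProfileAssignment(
            {k: 0.9 * v for k, v in truth.concentrations.items()}, dict(truth.shifts)
        )
        regions = partition_regions(lib, axis)
        region_total = sum(region_loss(r, spec, lib, off) for r in regions)
        recon = synthesize_mixture(lib, off, axis)
        global_sse = float(((spec.real - recon.real) ** 2).sum())
        assert region_total == pytest.approx(global_sse, rel=1e-3)

    def test_gibbs_monotone_and_closed_form(self):
        assert gibbs_score(1.0, 2.0) > gibbs_score(5.0, 2.0)
        assert gibbs_score(0.0, 1.0) == 0.0
        sigma = 1.7
        assert gibbs_score(3.0, sigma) - gibbs_score(3.0 + 2 * sigma**2, sigma) == pytest.approx(1.0)
        with pytest.raises(InvalidParameterError):
            gibbs_score(1.0, 0.0)


class TestFitConcentrations:
    def test_single_compound_exact(self, single_peak_library, axis):
        truth = ProfileAssignment({"A": 123.0}, {"A:0": 0.004})
        spec = synthesize_mixture(single_peak_library, truth, axis)
        rho = fit_concentrations(spec, single_peak_library, truth.shifts)
        assert rho["A"] == pytest.approx(123.0, rel=1e-4)

    def test_absent_compound_zero(self, two_compound_library, axis):
        truth = ProfileAssignment({"A": 100.0}, {"A:0": 0.0, "A:1": 0.0, "B:0": 0.0})
        spec = synthesize_mixture(two_compound_library, truth, axis)
        rho = fit_concentrations(spec, two_compound_library, truth.shifts)
        assert rho["B"] == pytest.approx(0.0, abs=1e-8)

    def test_nonoverlapping_compounds_exact(self, axis):
        rng = np.random.default_rng(11)
        comps = [
            CompoundSignature(
                f"M{i}", (Cluster(f"M{i}:0", (Peak(1.0 + i * 0.1, 1.0 + i * 0.9, 0.003),)),)
            )
            for i in range(10)
        ]
        lib = SpectralLibrary(comps)
        truth = ProfileAssignment(
            {f"M{i}": float(rng.uniform(10, 1000)) for i in range(10)},
            {f"M{i}:0": 0.0 for i in range(10)},
        )
        spec = synthesize_mixture(lib, truth, axis)
        rho = fit_concentrations(spec, lib, truth.shifts)
        for name, val in truth.concentrations.items():
            assert rho[name] == pytest.approx(val, rel=1e-3)

    def test_duplicate_signatures_warn(self, axis):
        pk = (Peak(1.0, 3.0, 0.003),)
        lib = SpectralLibrary(
            [
                CompoundSignature("A", (Cluster("a", pk),)),
                CompoundSignature("B", (Cluster("b", pk),)),
            ]
        )
        truth = ProfileAssignment({"A": 50.0}, {"a": 0.0, "b": 0.0})
        spec = synthesize_mixture(lib, truth, axis)
        with pytest.warns(UserWarning, match="indistinguishable"):
            fit_concentrations(spec, lib, truth.shifts)


class TestInferMap:
    def test_single_compound_recovery(self, fine_axis):
        lib = SpectralLibrary(
            [CompoundSignature("A", (Cluster("A:0", (Peak(2.0, 3.0, 0.003),)),))]
        )
        truth = ProfileAssignment({"A": 100.0}, {"A:0": 0.015})
        spec = synthesize_mixture(lib, truth, fine_axis)
        spec.noise_sigma = 1e-4
        assign, diag = infer_map(spec, lib, InferenceConfig(seed=1))
        assert assign.shifts["A:0"] == pytest.approx(0.015, abs=spec.spacing)
        assert assign.concentrations["A"] == pytest.approx(100.0, rel=0.01)

    def test_empty_library(self, axis):
        spec = synthesize_mixture(SpectralLibrary([]), ProfileAssignment(), axis)
        spec.noise_sigma = 1.0
        assign, diag = infer_map(spec, SpectralLibrary([]))
        assert assign.concentrations == {} and diag.iterations == 0

    def test_frequency_mismatch_rejected(self, axis, single_peak_library):
        spec = synthesize_mixture(
            single_peak_library, ProfileAssignment({"A": 1.0}, {"A:0": 0.0}), axis
        )
        spec.frequency = 600.0
        spec.noise_sigma = 1.0
        with pytest.raises(InvalidParameterError, match="frequency"):
            infer_map(spec, single_peak_library)

    def test_best_loss_non_increasing(self, fine_axis):
        lib = sim.generate_library(6, seed=30, include_reference=False)
        truth = sim.sample_truth(lib, 1.0, (50, 500), seed=31)
        spec = synthesize_mixture(lib, truth, fine_axis, noise_sigma=2.0, seed=32)
        _, diag = infer_map(spec, lib, InferenceConfig(seed=33))
        trace = np.array(diag.loss_trace)
        assert (np.diff(trace) <= 1e-9 * trace[0]).all()

    def test_mixture_recovery_with_noise(self, fine_axis):
        """SNR >= 100 mixture: reconstruction SSE within the noise budget and
        all present concentrations within 10%."""
        lib = sim.generate_library(15, seed=40, include_reference=False)
        truth = sim.sample_truth(lib, 1.0, (200, 2000), seed=41)
        sigma = 10.0
        spec = synthesize_mixture(lib, truth, fine_axis, noise_sigma=sigma, seed=42)
        assign, diag = infer_map(spec, lib, InferenceConfig(seed=43))
        recon = synthesize_mixture(lib, assign, fine_axis)
        profiled = ~((fine_axis >= 4.6) & (fine_axis < 5.0))
        sse = float((((spec.real - recon.real) * profiled) ** 2).sum())
        assert sse < fine_axis.size * (2 * sigma) ** 2
        for name, rho in truth.concentrations.items():
            assert assign.concentrations[name] == pytest.approx(rho, rel=0.10)
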