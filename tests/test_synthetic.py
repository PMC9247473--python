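"""Buckle geometry, strain arithmetic and the sorting generator."""

import numpy as np
import pandas as pd
import pytest

from curvsort import (
    Composition,
    CompositionEntry,
    SortingModel,
    generate_trajectory,
    make_buckle_profile,
    sample_frame,
    strain,
)
from curvsort.errors import GeometryError, ModelInconsistencyError, ValidationError


class TestStrain:
    @pytest.mark.parametrize("X0,Xi,expected", [
        (40.0, 24.0, 0.4),
        (40.0, 40.0, 0.0),
        (40.0, 36.0, 0.1),
    ])
    def test_values(self, X0, Xi, expected):
        assert strain(X0, Xi) == pytest.approx(expected, abs=1e-12)

    def test_extension_rejected(self):
        with pytest.raises(GeometryError):
            strain(40.0, 44.0)


class TestBuckleProfile:
    def test_flat_limit(self):
        p = make_buckle_profile(40.0, 0.0)
        assert p.amplitude == 0.0
        x = np.linspace(0, p.Xi, 50)
        assert np.all(p.z(x) == 0.0)
        assert np.all(p.curvature(x) == 0.0)

    @pytest.mark.parametrize("gamma", [0.1, 0.2, 0.3, 0.4])
    def test_arc_length_conserved(self, gamma):
        p = make_buckle_profile(40.0, gamma)
        assert p.arc_length() == pytest.approx(40.0, abs=0.04)
        assert p.gamma == pytest.approx((p.X0 - p.Xi) / p.X0, abs=1e-12)

    def test_crest_curvature_closed_form(self):
        p = make_buckle_profile(40.0, 0.4)
        # extrema of A cos(kx): |C| = A k^2 exactly (slope vanishes)
        assert abs(p.curvature(0.0)) == pytest.approx(p.amplitude * p.k**2,
                                                      rel=1e-12)
        x = np.linspace(0, p.Xi, 2000)
        assert np.max(np.abs(p.curvature(x))) == pytest.approx(
            p.max_curvature, rel=1e-5)

    def test_periodic_endpoints(self):
        p = make_buckle_profile(40.0, 0.2)
        assert p.z(0.0) == pytest.approx(p.z(p.Xi), abs=1e-9)
        assert p.dz(0.0) == pytest.approx(p.dz(p.Xi), abs=1e-9)

    def test_gamma_out_of_range(self):
        with pytest.raises(ValidationError):
            make_buckle_profile(40.0, 0.6)


class TestSampleFrame:
    def test_null_model_honours_exact_counts(self, small_composition, registry):
        p = make_buckle_profile(40.0, 0.0)
        frame, truth = sample_frame(p, small_composition, SortingModel(),
                                    seed=3, headgroup_only=True)
        counts = truth.groupby(["leaflet", "species"], observed=True).size()
        for leaflet in ("outer", "inner"):
            for sp, expected in small_composition.counts(leaflet).items():
                assert counts[(leaflet, sp)] == expected

    def test_reference_leaflet_totals(self, profile_01, pm_composition):
        frame, truth = sample_frame(profile_01, pm_composition,
                                    SortingModel(), seed=1,
                                    headgroup_only=True)
        per_leaflet = truth.groupby("leaflet", observed=True).size()
        assert per_leaflet["outer"] == 1350
        assert per_leaflet["inner"] == 1348

    def test_outer_offset_too_large_raises(self, pm_composition):
        p = make_buckle_profile(40.0, 0.4)
        with pytest.raises(GeometryError):
            sample_frame(p, pm_composition, SortingModel(d_half=2.0), seed=0)

    def test_all_probabilities_clipped_raises(self, profile_01):
        comp = Composition(leaflets={
            "outer": (CompositionEntry(species="POPC", count=100),),
            "inner": (CompositionEntry(species="POPC", count=100),),
        })
        model = SortingModel(slopes={("inner", "POPC"): -50.0,
                                     ("outer", "POPC"): -50.0})
        with pytest.raises(ModelInconsistencyError):
            sample_frame(profile_01, comp, model, seed=0, headgroup_only=True)

    def test_signed_curvature_convention_at_crest(self, buckled_frame):
        # crest (x ~ 0 or Xi): convex seen from outside -> outer C > 0,
        # inner C < 0 after the outer-leaflet sign inversion
        _, truth = buckled_frame
        Xi = make_buckle_profile(40.0, 0.3).Xi
        near_crest = (truth.u < 1.0) | (truth.u > Xi - 1.0)
        crest = truth[near_crest]
        assert (crest.loc[crest.leaflet == "outer", "curvature_true"] > 0).all()
        assert (crest.loc[crest.leaflet == "inner", "curvature_true"] < 0).all()

    def test_uniform_arc_length_density(self, profile_03, small_composition):
        # the arc-length CDF of drawn positions must be uniform
        frame, truth = sample_frame(profile_03, small_composition,
                                    SortingModel(), seed=9,
                                    headgroup_only=True)
        for leaflet, t in (("outer", 2.0), ("inner", -2.0)):
            u = np.sort(truth.loc[truth.leaflet == leaflet, "u"].to_numpy())
            grid = np.linspace(0, profile_03.Xi, 2001)
            speed = profile_03.offset_speed(grid, t)
            cum = np.concatenate([[0.0], np.cumsum(
                (speed[1:] + speed[:-1]) / 2 * np.diff(grid))])
            q = np.interp(u, grid, cum / cum[-1])
            ks = np.max(np.abs(q - np.arange(1, q.size + 1) / q.size))
            assert ks < 1.63 / np.sqrt(q.size)  # KS 1% critical value

    def test_curvature_span_reaches_analytic_extremes(self, pm_composition):
        # gamma=0.4, d/2=1: the offset-surface curvature ranges over
        # [-kappa/(1-kappa), +kappa/(1+kappa)] with kappa = A k^2 ~ 0.6,
        # i.e. about [-1.5, +0.38]
        p = make_buckle_profile(40.0, 0.4)
        model = SortingModel(d_half=1.0)
        frame, truth = sample_frame(p, pm_composition, model, seed=2,
                                    headgroup_only=True)
        kap = p.max_curvature
        lo = -kap / (1.0 - model.d_half * kap)
        hi = kap / (1.0 + model.d_half * kap)
        assert truth.curvature_true.min() < 0.8 * lo
        assert truth.curvature_true.max() > 0.8 * hi
        assert truth.curvature_true.min() < -0.4


class TestGenerateTrajectory:
    def test_single_frame_matches_sample_frame(self, profile_01,
                                               small_composition):
        traj, truth = generate_trajectory(profile_01, small_composition,
                                          SortingModel(), 1, seed=7,
                                          headgroup_only=True)
        child = np.random.SeedSequence(7).spawn(1)[0]
        frame, _ = sample_frame(profile_01, small_composition, SortingModel(),
                                child, headgroup_only=True)
        np.testing.assert_array_equal(traj[0].positions, frame.positions)

    def test_determinism(self, profile_01, small_composition):
        a, _ = generate_trajectory(profile_01, small_composition,
                                   SortingModel(), 3, seed=13,
                                   headgroup_only=True)
        b, _ = generate_trajectory(profile_01, small_composition,
                                   SortingModel(), 3, seed=13,
                                   headgroup_only=True)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.positions, fb.positions)

    def test_zero_frames_rejected(self, profile_01, small_composition):
        with pytest.raises(ValidationError):
            generate_trajectory(profile_01, small_composition,
                                SortingModel(), 0, seed=1)


class TestSortingModelSemantics:
    def test_realized_share_slope_is_renormalized(self, registry):
        """With raw model parameter s on a species of fraction f, the
        realized in-bin share slope is s*(1-f) because the per-position
        renormalization removes the species' own contribution.  This is the
        basis of the share compensation used when imposing target slopes."""
        entries = (CompositionEntry(species="POPC", count=200),
                   CompositionEntry(species="DIPE", count=200))
        comp = Composition(leaflets={"outer": entries, "inner": entries})
        p = make_buckle_profile(40.0, 0.2)
        s_raw, f = -0.6, 0.5
        model = SortingModel(slopes={("inner", "POPC"): s_raw})
        truths = []
        for i in range(200):
            _, truth = sample_frame(p, comp, model, seed=500 + i,
                                    headgroup_only=True)
            truths.append(truth[truth.leaflet == "inner"])
        t = pd.concat(truths)
        bins = np.arange(-0.4, 0.45, 0.1)
        t = t.assign(b=pd.cut(t.curvature_true, bins))
        share = t.groupby("b", observed=True).apply(
            lambda g: (g.species == "POPC").mean(), include_groups=False)
        centers = np.array([iv.mid for iv in share.index])
        slope = np.polyfit(centers, share.to_numpy() / 0.5, 1)[0]
        # sampling SE of the fitted slope here is ~0.05; the raw parameter
        # (-0.6) and the renormalized prediction (-0.3) are ~6 SE apart
        assert slope == pytest.approx(s_raw * (1 - f), abs=0.12)
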