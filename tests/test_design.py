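import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hmmssf import (
    Formula,
    GammaRadial,
    Track,
    UniformDisc,
    build_design,
    importance_density,
    sample_controls,
    step_metrics,
)
from hmmssf.datasets import habitat_landscape
from hmmssf.design import build_step_table, pooled_length_moments


@pytest.fixture(scope="module")
def rw_track():
    rng = np.random.default_rng(12)
    n = 120
    steps = rng.gamma(2.0, 0.15, size=(n, 1)) * np.column_stack(
        [np.cos(a := rng.uniform(-np.pi, np.pi, n)), np.sin(a)]
    )
    xy = np.cumsum(np.vstack([[20.0, 20.0], steps]), axis=0)
    times = pd.date_range("2021-01-01", periods=n + 1, freq="30min")
    return Track("w", times, xy, np.ones(n + 1, bool))


class TestSchemes:
    def test_uniform_disc_within_radius(self, rw_track):
        ss = sample_controls([rw_track], n_controls=30,
                             scheme=UniformDisc(2.0), seed=1)
        anchors = ss.steps[["x0", "y0"]].to_numpy()[ss.usable]
        controls = ss.endpoints[ss.usable, 1:, :]
        d = np.linalg.norm(controls - anchors[:, None, :], axis=-1)
        assert (d <= 2.0).all()

    def test_gamma_radial_mean_matches_pooled(self):
        # large-sample check of the radial law against its moments
        rng = np.random.default_rng(3)
        sch = GammaRadial.from_moments(0.3, 0.2)
        pts = sch.sample(rng, np.zeros((1, 2)), np.zeros(1), 100_000)
        r = np.linalg.norm(pts[0], axis=-1)
        assert abs(r.mean() - 0.3) / 0.3 < 0.01
        assert abs(r.std() - 0.2) / 0.2 < 0.02

    def test_same_seed_identical(self, rw_track):
        a = sample_controls([rw_track], n_controls=10, seed=9)
        b = sample_controls([rw_track], n_controls=10, seed=9)
        np.testing.assert_array_equal(a.endpoints, b.endpoints)
        np.testing.assert_array_equal(a.h, b.h)

    def test_degenerate_moments_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            GammaRadial.from_moments(0.0, 0.1)

    def test_case_is_observed_endpoint(self, rw_track):
        ss = sample_controls([rw_track], n_controls=5, seed=2)
        sm = step_metrics(rw_track)
        usable = ss.usable
        np.testing.assert_allclose(
            ss.endpoints[usable, 0, :],
            sm.loc[usable, ["x1", "y1"]].to_numpy(),
        )

    def test_disc_too_small_raises(self, rw_track):
        with pytest.raises(ValueError, match="radius"):
            sample_controls([rw_track], n_controls=5,
                            scheme=UniformDisc(1e-4), seed=0)


class TestImportanceDensity:
    def test_uniform_disc_interior(self):
        val = importance_density(UniformDisc(2.0), (0.0, 0.0), [(0.5, 0.5)])
        assert val[0] == pytest.approx(1 / (4 * np.pi))

    def test_uniform_disc_exterior_zero(self):
        val = importance_density(UniformDisc(2.0), (0.0, 0.0), [(3.0, 0.0)])
        assert val[0] == 0.0

    def test_gamma_radial_histogram_oracle(self):
        # 2D histogram of samples must match h cell-by-cell
        rng = np.random.default_rng(7)
        sch = GammaRadial.from_moments(1.0, 0.5)
        n = 400_000
        pts = sch.sample(rng, np.zeros((1, 2)), np.zeros(1), n)[0]
        edges = np.linspace(-2.5, 2.5, 26)
        hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=(edges, edges))
        cw = edges[1] - edges[0]
        centres = (edges[:-1] + edges[1:]) / 2
        xx, yy = np.meshgrid(centres, centres, indexing="ij")
        dens = importance_density(
            sch, (0.0, 0.0), np.column_stack([xx.ravel(), yy.ravel()])
        ).reshape(xx.shape)
        emp = hist / (n * cw**2)
        # compare cells holding meaningful mass; binomial error ~3 sd
        mask = dens > 0.02
        err = np.abs(emp - dens)[mask]
        tol = 3 * np.sqrt(dens[mask] / (n * cw**2)) + 0.05 * dens[mask]
        assert (err < tol).mean() > 0.97

    def test_gamma_radial_integrates_to_one(self):
        sch = GammaRadial.from_moments(0.5, 0.3)
        # radial integral of f_gamma(r)/(2 pi r) * 2 pi r dr = 1
        from scipy.integrate import quad

        val, _ = quad(
            lambda r: importance_density(sch, (0, 0), [(r, 0.0)])[0] * 2 * np.pi * r,
            1e-9, 10.0,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_r_zero_raises(self):
        sch = GammaRadial.from_moments(0.5, 0.3)
        with pytest.raises(ValueError, match="r = 0"):
            importance_density(sch, (0.0, 0.0), [(0.0, 0.0)])


class TestBuildDesign:
    def test_habitat_plus_movement_columns(self, rw_track):
        land = habitat_landscape(seed=3)
        ss = sample_controls([rw_track], n_controls=10, seed=4)
        formula = Formula(habitat=["veg"])
        build_design(ss, land, formula)
        assert len(ss.colnames) == 6  # 3 indicators + 3 movement terms
        assert ss.colnames[:3] == [
            "veg_bushed_grassland", "veg_bushland", "veg_woodland"
        ]

    def test_case_row_reproduces_step_metrics(self, rw_track):
        land = habitat_landscape(seed=3)
        ss = sample_controls([rw_track], n_controls=10, seed=4)
        build_design(ss, land, Formula(habitat=["veg"]))
        sm = step_metrics(rw_track)
        usable = ss.usable
        i_len = ss.colnames.index("length")
        i_cos = ss.colnames.index("cos_angle")
        np.testing.assert_allclose(
            ss.covariates[usable, 0, i_len], sm.loc[usable, "length"]
        )
        np.testing.assert_allclose(
            ss.covariates[usable, 0, i_cos],
            np.cos(sm.loc[usable, "turn_angle"]),
            atol=1e-12,
        )

    def test_unknown_layer_raises(self, rw_track):
        land = habitat_landscape(seed=3)
        ss = sample_controls([rw_track], n_controls=5, seed=4)
        with pytest.raises(KeyError):
            build_design(ss, land, Formula(habitat=["nope"]))

    def test_outside_extent_flagged_invalid(self):
        # tiny landscape so many controls fall off the map
        land = habitat_landscape(seed=3, size=4.0)
        rng = np.random.default_rng(0)
        n = 40
        xy = np.cumsum(
            np.vstack([[2.0, 2.0], rng.normal(0, 0.4, size=(n, 2))]), axis=0
        )
        times = pd.date_range("2021-01-01", periods=n + 1, freq="30min")
        tr = Track("t", times, xy, np.ones(n + 1, bool))
        ss = sample_controls([tr], n_controls=20, seed=1)
        build_design(ss, land, Formula(habitat=["veg"]))
        usable = ss.usable
        assert (~ss.valid[usable]).any()
        # invalid rows are excluded via the per-step valid count
        assert (ss.valid[usable].sum(axis=1) <= 21).all()

    def test_interactions_are_products(self, rw_track):
        land = habitat_landscape(seed=3)
        ss = sample_controls([rw_track], n_controls=5, seed=4)
        f = Formula(habitat=["veg"], interactions=[("veg_bushland", "length")])
        build_design(ss, land, f)
        i_b = ss.colnames.index("veg_bushland")
        i_l = ss.colnames.index("length")
        i_int = ss.colnames.index("veg_bushland:length")
        u = ss.usable
        np.testing.assert_allclose(
            ss.covariates[u, :, i_int],
            ss.covariates[u, :, i_b] * ss.covariates[u, :, i_l],
        )

    def test_long_format_export(self, rw_track):
        land = habitat_landscape(seed=3)
        ss = sample_controls([rw_track], n_controls=5, seed=4)
        build_design(ss, land, Formula(habitat=["veg"]))
        df = ss.to_frame()
        assert {"track_id", "step", "endpoint", "case", "h", "valid"} <= set(df.columns)
        assert df["case"].sum() == ss.n_steps
        assert len(df) == ss.n_steps * 6


class TestEstimatorProperties:
    def test_uniform_importance_reduces_to_plain_mc(self, rw_track):
        """With a constant h the importance estimator equals plain Monte
        Carlo up to the disc-area constant, so the log densities differ by
        exactly log(pi R^2) at every step and state."""
        from hmmssf import log_state_densities

        land = habitat_landscape(seed=3)
        R = 3.0
        ss = sample_controls([rw_track], n_controls=50,
                             scheme=UniformDisc(R), seed=6)
        build_design(ss, land, Formula(habitat=["veg"]))
        beta = np.array([[0.4, -0.6, 0.2, -3.0, -0.4, 0.8]])
        ld_is = log_state_densities(ss, beta, use_importance=True)
        ld_mc = log_state_densities(ss, beta, use_importance=False)
        u = ss.usable
        diff = ld_is[u] - ld_mc[u]
        np.testing.assert_allclose(diff, -np.log(np.pi * R**2), atol=1e-10)

    def test_mc_denominator_converges_with_n(self, rw_track):
        """SD of the Monte Carlo denominator roughly halves per 4x N."""
        from hmmssf import log_state_densities

        land = habitat_landscape(seed=3)
        # step-length tail lighter than the importance kernel's, so the
        # weights have finite variance and the usual N^(-1/2) rate holds
        beta = np.array([[0.4, -0.6, 0.2, -9.0, -0.4, 0.8]])

        def denom_sd(n_controls, seeds):
            vals = []
            for s in seeds:
                ss = sample_controls([rw_track], n_controls=n_controls, seed=s)
                build_design(ss, land, Formula(habitat=["veg"]))
                ld = log_state_densities(ss, beta)
                vals.append(ld[ss.usable, 0])
            return np.std(np.array(vals), axis=0).mean()

        seeds = range(40, 52)
        sd_small = denom_sd(8, seeds)
        sd_big = denom_sd(32, seeds)
        ratio = sd_small / sd_big
        assert 1.5 < ratio < 3.0  # ~2 expected

    def test_pooled_moments(self, rw_track):
        table = build_step_table([rw_track])
        mean, sd = pooled_length_moments(table)
        sm = step_metrics(rw_track)
        assert mean == pytest.approx(sm["length"].mean())
        assert sd == pytest.approx(sm["length"].std())
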