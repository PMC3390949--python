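"""Log-normal volume models: fitting, p-values, regionalization, GOF."""

import numpy as np
import pytest
from scipy import integrate, stats

from pocketfrag.config import Config
from pocketfrag.mesh_core import MeshSolid
from pocketfrag.fragmenter import fragments_between
from pocketfrag.volumetric_stats import (
    FitError,
    RegionCube,
    VolumeModel,
    build_lattice,
    clip_fragment_volume,
    compare_distributions,
    evaluate_fragment,
    fit_lognormal,
    p_value,
    train_regional_model,
    train_standard_model,
    training_fragments,
)


class TestFitLognormal:
    def test_two_point(self):
        m = fit_lognormal([1.0, np.e**2])
        assert m.log_mean == pytest.approx(1.0)
        assert m.log_sd == pytest.approx(np.sqrt(2.0))
        assert m.n == 2

    def test_zero_spread_rejected(self):
        with pytest.raises(FitError):
            fit_lognormal([np.e, np.e, np.e])

    def test_too_few_rejected(self):
        with pytest.raises(FitError):
            fit_lognormal([1.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(FitError):
            fit_lognormal([1.0, -2.0, 3.0])

    def test_parameter_recovery(self):
        rng = np.random.default_rng(12)
        mu, sigma, n = 2.0, 0.7, 100_000
        draws = np.exp(rng.normal(mu, sigma, size=n))
        m = fit_lognormal(draws)
        se_mean = sigma / np.sqrt(n)
        se_sd = sigma / np.sqrt(2 * n)
        assert abs(m.log_mean - mu) < 3 * se_mean
        assert abs(m.log_sd - sigma) < 3 * se_sd

    def test_mle_variant(self):
        v = [1.0, np.e**2]
        m = fit_lognormal(v, unbiased=False)
        assert m.log_sd == pytest.approx(1.0)  # ddof=0: sqrt(mean sq dev)

    def test_json_round_trip(self):
        m = fit_lognormal([1.0, 2.0, 3.0])
        back = VolumeModel.from_json(m.to_json())
        assert back.log_mean == m.log_mean and back.log_sd == m.log_sd
        assert back.n == 3 and np.allclose(back.volumes, m.volumes)


class TestPValue:
    def test_median_is_half(self):
        m = fit_lognormal([1.0, 4.0, 9.0, 16.0])
        assert p_value(m, np.exp(m.log_mean)) == pytest.approx(0.5)

    def test_95th_percentile(self):
        m = fit_lognormal([1.0, 4.0, 9.0, 16.0])
        v = np.exp(m.log_mean + 1.6449 * m.log_sd)
        assert p_value(m, v) == pytest.approx(0.05, abs=1e-4)

    def test_matches_quadrature(self):
        """p equals the integral of the fitted log-normal density over [v, inf)."""
        m = fit_lognormal([0.5, 2.0, 5.0, 11.0, 0.8])
        dist = stats.lognorm(s=m.log_sd, scale=np.exp(m.log_mean))
        for v in (0.1, 0.5, 2.0, 10.0, 50.0):
            tail, _ = integrate.quad(dist.pdf, v, np.inf)
            assert p_value(m, v) == pytest.approx(tail, abs=1e-8)

    def test_strictly_decreasing_onto_unit_interval(self):
        m = fit_lognormal([1.0, 3.0, 7.0])
        vs = np.logspace(-2, 2, 200)
        ps = [p_value(m, v) for v in vs]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert p_value(m, 1e-9) > 1 - 1e-9 and p_value(m, 1e9) < 1e-9

    def test_nonpositive_volume_rejected(self):
        m = fit_lognormal([1.0, 2.0])
        with pytest.raises(ValueError):
            p_value(m, 0.0)


class TestStandardModel:
    def _bump_family(self):
        base = MeshSolid.box([0, 0, 0], [6, 6, 2])
        def with_bump(x, v):
            s = v ** (1 / 3)
            bump = MeshSolid.box([x, 2, 2], [x + s, 2 + s, 2 + s])
            from pocketfrag.csg_ops import union_all
            return union_all([base, bump]).solid
        return base, with_bump

    def test_identical_cavities_error(self, config):
        base = MeshSolid.box([0, 0, 0], [2, 2, 2])
        with pytest.raises(FitError):
            train_standard_model([base, MeshSolid.box([0, 0, 0], [2, 2, 2])], config)

    def test_bump_volumes_recovered(self, config):
        base, with_bump = self._bump_family()
        cavities = [base, with_bump(0.5, 1.0), with_bump(4.0, 1.3)]
        model = train_standard_model(cavities, config)
        # fragments: each bump appears once per pair against the other two
        assert model.n == 4
        expected = np.log([1.0, 1.0, 1.3, 1.3]).mean()
        assert model.log_mean == pytest.approx(expected, rel=1e-6)

    def test_pair_count_pooling(self, config):
        base, with_bump = self._bump_family()
        cavities = [with_bump(0.5, 1.0), with_bump(2.2, 1.2), with_bump(4.0, 1.4)]
        frags = training_fragments(cavities, config)
        # k=3 cavities -> 3 pairs, 2 one-bump fragments each
        assert len(frags) == 6
        assert len({fr.pair_id for fr in frags}) == 3


class TestLattice:
    def test_cube_counts(self):
        cavs = [MeshSolid.box([0, 0, 0], [10, 10, 10])]
        assert len(build_lattice(cavs, side=5.0, margin=0.0)) == 8

    def test_ceiling_per_axis(self):
        cavs = [MeshSolid.box([0, 0, 0], [12, 7, 7])]
        assert len(build_lattice(cavs, side=5.0, margin=0.0)) == 3 * 2 * 2

    def test_margin_monotone(self):
        cavs = [MeshSolid.box([0, 0, 0], [7, 7, 7])]
        counts = [len(build_lattice(cavs, side=5.0, margin=m)) for m in (0, 2, 5, 9)]
        assert counts == sorted(counts)

    def test_space_filling_clip_conservation(self, config):
        """Summed cube-clipped volumes reconstruct the fragment volume."""
        frag_mesh = MeshSolid.box([1.2, 0.7, 2.1], [7.8, 6.1, 6.9])
        cubes = build_lattice([MeshSolid.box([0, 0, 0], [9, 9, 9])], side=5.0, margin=1.0)
        total = sum(clip_fragment_volume(frag_mesh, c, config) for c in cubes)
        assert total == pytest.approx(6.6 * 5.4 * 4.8, rel=1e-9)


class TestRegionalModel:
    def _training(self, config):
        A = MeshSolid.box([0, 0, 0], [4, 4, 4])
        B = MeshSolid.box([0, 0, 0], [4, 4, 3])   # fragment: slab z in [3,4]
        C = MeshSolid.box([0, 0, 0], [4, 4, 3.5])
        return [A, B, C]

    def test_far_cube_empty(self, config):
        rm = train_regional_model(self._training(config), RegionCube((50, 50, 50), 5.0), config)
        assert rm.is_empty

    def test_enclosing_cube_equals_standard(self, config):
        cavs = self._training(config)
        frags = training_fragments(cavs, config)
        rm = train_regional_model(cavs, RegionCube((2, 2, 2), 40.0), config, fragments=frags)
        sm = train_standard_model(cavs, config, fragments=frags)
        assert rm.model.log_mean == pytest.approx(sm.log_mean, abs=1e-12)
        assert rm.model.log_sd == pytest.approx(sm.log_sd, abs=1e-12)

    def test_straddling_fragment_clipped(self, config):
        cavs = self._training(config)
        cube = RegionCube((2, 2, 3.25), 1.0)  # z in [2.75, 3.75]
        frags = training_fragments(cavs, config)
        clipped = [clip_fragment_volume(fr, cube, config) for fr in frags]
        # slab z in [3, 4] clipped to z in [3, 3.75] within 1 Å x-y window
        assert max(clipped) == pytest.approx(1 * 1 * 0.75, rel=1e-9)

    def test_empty_cube_categorical_call(self, config):
        rm = train_regional_model(self._training(config), RegionCube((50, 50, 50), 5.0), config)
        frag = _fake_fragment(MeshSolid.box([48, 48, 48], [50, 50, 50]), config)
        call = evaluate_fragment(rm, frag, config)
        assert call.categorical and call.significant and call.p_value == 0.0

    def test_empty_cube_untouched_fragment_no_call(self, config):
        rm = train_regional_model(self._training(config), RegionCube((50, 50, 50), 5.0), config)
        frag = _fake_fragment(MeshSolid.box([0, 0, 0], [1, 1, 1]), config)
        assert evaluate_fragment(rm, frag, config) is None

    def test_median_fragment_not_significant(self, config):
        m = fit_lognormal([2.0, 4.0, 8.0])
        call = evaluate_fragment(m, float(np.exp(m.log_mean)), config)
        assert call.p_value == pytest.approx(0.5) and not call.significant


class TestCompareDistributions:
    def test_lognormal_ranked_first(self):
        rng = np.random.default_rng(8)
        draws = np.exp(rng.normal(0, 1, size=10_000))
        reports = compare_distributions(draws)
        assert reports[0].family == "lognormal"
        assert reports[0].qq.shape == (10_000, 2)

    def test_gamma_beats_lognormal_on_gamma_data(self):
        rng = np.random.default_rng(9)
        draws = rng.gamma(shape=2.0, scale=1.0, size=10_000)
        reports = compare_distributions(draws)
        names = [r.family for r in reports]
        assert names.index("gamma") < names.index("lognormal")

    def test_constant_sample_all_flagged(self):
        reports = compare_distributions([3.0] * 25)
        assert all(r.failed for r in reports)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([1.0, 2.0])


def _fake_fragment(mesh, config):
    from pocketfrag.fragmenter import fragments_of

    [frag] = fragments_of(mesh, config)
    return frag
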