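"""Synthetic families and experiment drivers."""

import json

import numpy as np
import pytest

from pocketfrag.config import Config
from pocketfrag.mesh_core import MeshSolid, compute_volume
from pocketfrag.fragmenter import fragments_between
from pocketfrag.volumetric_stats import FitError
from pocketfrag.experiments import (
    Bump,
    SyntheticFamilySpec,
    apply_bumps,
    generate_family,
    leave_one_out,
    leave_two_out,
    make_base_box,
    regional_scan,
)


class TestGenerateFamily:
    def test_zero_bumps_identical_copies(self, config):
        spec = SyntheticFamilySpec(n_members=3, n_bumps=0, seed=1)
        fam = generate_family(spec, config)
        assert len(fam) == 3
        base_vol = np.prod(spec.base_dims)
        for m in fam:
            assert compute_volume(m) == pytest.approx(base_vol)

    def test_deterministic_given_seed(self, config):
        spec = SyntheticFamilySpec(seed=7)
        a = generate_family(spec, config)
        b = generate_family(spec, config)
        for x, y in zip(a, b):
            assert np.array_equal(x.vertices, y.vertices)
            assert np.array_equal(x.faces, y.faces)

    def test_carved_box_bump_volume(self, config):
        base = make_base_box((12.0, 12.0, 6.0))
        member = apply_bumps(base, [Bump(center=(6, 6), volume=8.0, mode="carve")], config)
        frags = fragments_between(base, member, config)
        assert len(frags) == 1
        assert frags[0].volume == pytest.approx(8.0, rel=1e-9)

    def test_carved_sphere_bump_half_ball(self, config):
        """A sphere bump centered on the face removes a half-ball of the
        nominal volume (within mesh/grid tolerance)."""
        base = make_base_box((12.0, 12.0, 6.0))
        member = apply_bumps(
            base, [Bump(center=(6, 6), volume=8.0, mode="carve", shape="sphere")], config
        )
        frags = fragments_between(base, member, config)
        assert len(frags) == 1
        assert frags[0].volume == pytest.approx(8.0, rel=0.08)

    def test_added_bump_direction(self, config):
        base = make_base_box((12.0, 12.0, 6.0))
        member = apply_bumps(base, [Bump(center=(6, 6), volume=8.0, mode="add")], config)
        frags = fragments_between(base, member, config)
        assert [f.direction for f in frags] == ["BA"]  # extra material on B

    def test_overflowing_bump_rejected(self, config):
        spec = SyntheticFamilySpec(bump_log_mean=np.log(5000.0), bump_log_sd=0.1, seed=2)
        with pytest.raises(ValueError):
            generate_family(spec, config)


class TestLeaveOneOut:
    def test_identical_family_training_error_surfaces(self, config):
        spec = SyntheticFamilySpec(n_members=3, n_bumps=0, seed=3)
        fam = generate_family(spec, config)
        with pytest.raises(FitError):
            leave_one_out(fam, [make_base_box(spec.base_dims)], config)

    def test_null_single_fragment_per_test(self, config):
        spec = SyntheticFamilySpec(seed=11)
        fam = generate_family(spec, config)
        rep = leave_one_out(fam, [make_base_box(spec.base_dims)], config)
        assert rep.n_tests == len(fam)
        assert rep.histogram.sum() == rep.n_tests
        assert not any(c.categorical for c in rep.calls)

    def test_huge_variant_always_significant(self, config):
        spec = SyntheticFamilySpec(seed=13)
        fam = generate_family(spec, config)
        big = float(np.exp(spec.bump_log_mean + 4 * spec.bump_log_sd))
        out_spec = SyntheticFamilySpec(n_members=1, n_bumps=0, variant_volume=big, seed=14)
        rep = leave_one_out(fam, generate_family(out_spec, config), config)
        assert rep.n_tests == len(fam)
        assert all(c.significant for c in rep.calls)

    def test_family_too_small(self, config):
        with pytest.raises(ValueError):
            leave_one_out([make_base_box()] * 2, [make_base_box()], config)


class TestLeaveTwoOut:
    def test_round_count(self, config):
        spec = SyntheticFamilySpec(n_members=5, seed=17)
        fam = generate_family(spec, config)
        rep = leave_two_out(fam, config)
        # every pair yields 2 one-dent fragments -> 2 * C(5,2) calls
        assert rep.n_tests == 2 * 10
        assert rep.histogram.sum() == rep.n_tests

    def test_null_pvalues_uniform(self, config):
        from scipy import stats

        spec = SyntheticFamilySpec(n_members=8, seed=77)
        fam = generate_family(spec, config)
        rep = leave_two_out(fam, config)
        ks = stats.kstest(rep.p_values, "uniform")
        assert ks.pvalue > 0.01

    def test_identical_pair_counts_empty_round(self, config):
        spec = SyntheticFamilySpec(n_members=4, seed=19)
        fam = generate_family(spec, config)
        fam.append(MeshSolid(fam[0].vertices.copy(), fam[0].faces.copy()))
        rep = leave_two_out(fam, config)
        assert rep.n_empty_rounds == 1


class TestRegionalScan:
    def test_identical_test_pair_no_calls(self, config):
        spec = SyntheticFamilySpec(n_members=4, seed=23)
        fam = generate_family(spec, config)
        rep = regional_scan(fam, (fam[0], fam[0]), config, side=8.0, margin=2.0)
        assert rep.n_tests == 0

    def test_outside_cubes_empty_no_calls(self, config):
        spec = SyntheticFamilySpec(n_members=4, seed=29)
        fam = generate_family(spec, config)
        rep = regional_scan(fam, (fam[0], make_base_box(spec.base_dims)), config,
                            side=8.0, margin=6.0)
        assert rep.extras["n_empty_cubes"] > 0
        # every call's cube really exists
        cube_ids = {c.cube_id for c in rep.calls}
        assert all(i is not None and 0 <= i < rep.extras["n_cubes"] for i in cube_ids)

    def test_single_cube_lattice_matches_standard_model(self, config):
        from pocketfrag.volumetric_stats import RegionCube, train_standard_model, p_value

        spec = SyntheticFamilySpec(n_members=5, seed=31)
        fam = generate_family(spec, config)
        test_pair = (fam[0], make_base_box(spec.base_dims))
        big_cube = RegionCube(center=(10.0, 10.0, 5.0), side=100.0, id=0)
        rep = regional_scan(fam[1:], test_pair, config, cubes=[big_cube])
        sm = train_standard_model(fam[1:], config)
        frags = fragments_between(*test_pair, config)
        assert rep.n_tests == len(frags)
        for call, fr in zip(rep.calls, frags):
            assert call.p_value == pytest.approx(p_value(sm, fr.volume), abs=1e-12)

    def test_low_vs_high_spread_cube_contrast(self, config):
        """A small fragment is significant where training cavities hardly
        vary, while an equal-volume fragment in a wildly varying region is
        not."""
        base = make_base_box((16.0, 8.0, 6.0))
        # site A (x≈4): tight dent volumes; site B (x≈12): wide spread
        tight = [1.9, 2.0, 2.1, 2.0, 1.95, 2.05]
        wide = [0.6, 1.1, 2.0, 3.6, 6.5, 5.0]
        fam = []
        for i in range(6):
            fam.append(
                apply_bumps(
                    base,
                    [
                        Bump(center=(2.0 + i * 0.7, 4.0), volume=tight[i], mode="carve"),
                        Bump(center=(10.0 + i * 0.9, 4.0), volume=wide[i], mode="carve"),
                    ],
                    config,
                )
            )
        test = apply_bumps(
            base,
            [
                Bump(center=(4.0, 6.5), volume=3.3, mode="carve"),
                Bump(center=(12.0, 6.5), volume=3.3, mode="carve"),
            ],
            config,
        )
        from pocketfrag.volumetric_stats import RegionCube

        cube_a = RegionCube(center=(4.0, 4.0, 4.0), side=8.0, id=0)
        cube_b = RegionCube(center=(12.0, 4.0, 4.0), side=8.0, id=1)
        rep = regional_scan(fam, (base, test), config, cubes=[cube_a, cube_b])
        calls = {c.cube_id: c for c in rep.calls}
        assert calls[0].significant and not calls[0].categorical
        assert not calls[1].significant

    def test_deterministic_report_json(self, config):
        spec = SyntheticFamilySpec(n_members=4, seed=37)
        fam = generate_family(spec, config)
        pair = (fam[0], make_base_box(spec.base_dims))
        a = regional_scan(fam[1:] + [fam[0]], pair, config, side=8.0, margin=2.0).to_json()
        b = regional_scan(fam[1:] + [fam[0]], pair, config, side=8.0, margin=2.0).to_json()
        assert a == b
        json.loads(a)  # valid JSON
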