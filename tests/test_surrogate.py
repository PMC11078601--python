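"""Surrogate landscape, dynamics and discretization."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wepath import surrogate as sg


class TestPresets:
    def test_barrier_ordering_encodes_substituent_series(self):
        b = {n: sg.make_surrogate(n).barrier_height for n in ("OCH3", "H", "CF3")}
        assert b["OCH3"] > b["H"] > b["CF3"] > 0

    def test_long_range_attraction_is_preset_independent(self):
        # the diffusional-encounter step does not depend on the substituent
        vals = {sg.make_surrogate(n).long_range_strength
                for n in ("OCH3", "H", "CF3")}
        assert len(vals) == 1

    def test_och3_wells_deeper_than_cf3(self):
        assert (sg.make_surrogate("OCH3").depths["O"]
                > sg.make_surrogate("CF3").depths["O"])

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            sg.make_surrogate("NO2")

    def test_threshold_violating_geometry_rejected(self):
        with pytest.raises(ValueError, match="r_product"):
            sg.make_surrogate("H", r_product=3.0)

    def test_duplicate_site_angles_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            sg.SurrogateParams(n_sites=2, site_angles=(0.0, 2 * math.pi),
                               site_labels=("O", "P"),
                               site_well_depth=(("O", 1.0), ("P", 1.0)))


class TestPotential:
    def test_asymptotic_reference_is_zero(self, h_params):
        for theta in (0.0, 1.0, 2.5):
            c = sg.Configuration(50.0, theta)
            assert abs(sg.potential(h_params, c)) < 1e-6

    def test_product_well_is_global_minimum_on_dense_grid(self, h_params):
        r = np.arange(0.0, 12.0, 0.01)
        th = np.arange(0.0, 2 * np.pi, 0.01)
        R, TH = np.meshgrid(r, th, indexing="ij")
        U = sg.potential_xy(h_params, R * np.cos(TH), R * np.sin(TH))
        i, j = np.unravel_index(np.argmin(U), U.shape)
        assert r[i] < h_params.r_product
        pmin = sg.product_minimum(h_params)
        assert U.min() >= sg.potential(h_params, pmin) - 1e-3

    def test_realized_activation_barrier_matches_request(self, h_params):
        # 2-D saddle search: lowest crossing of the barrier ring over theta
        r = np.arange(0.02, 5.5, 0.01)
        th = np.arange(0.0, 2 * np.pi, 0.005)
        R, TH = np.meshgrid(r, th, indexing="ij")
        U = sg.potential_xy(h_params, R * np.cos(TH), R * np.sin(TH))
        band = (R >= sg.R_ION_PAIR_INNER) & (R <= sg.R_ION_PAIR_OUTER)
        u_ip = U[band].min()
        ridge = (r > 0.9 * h_params.r_product) & (r < sg.R_ION_PAIR_INNER)
        saddle = U[ridge, :].max(axis=0).min()
        realized = saddle - u_ip
        assert realized == pytest.approx(h_params.barrier_height, rel=0.05)


class TestPropagation:
    def test_zero_temperature_is_stationary_at_product_minimum(self, h_params):
        cold = sg.make_surrogate(h_params, kT=0.0)
        start = sg.product_minimum(cold)
        end = sg.propagate(cold, start, 200, seed=0)
        assert np.hypot(*(end.xy - start.xy)) < 1e-6

    def test_same_seed_reproduces_trajectory_exactly(self, h_params):
        start = sg.Configuration(6.0, 1.0)
        a = sg.propagate(h_params, start, 500, seed=42)
        b = sg.propagate(h_params, start, 500, seed=42)
        assert a == b
        c = sg.propagate(h_params, start, 500, seed=43)
        assert a != c

    def test_free_diffusion_obeys_einstein_relation(self):
        # far outside every landscape feature the dynamics is free diffusion;
        # in 2-D, <|dx|^2> = 4 (kT/gamma) t
        p = sg.make_surrogate("H", wall_radius=1e6)
        n, steps = 2000, 10_000
        start = np.tile([1000.0, 0.0], (n, 1))
        rng = np.random.default_rng(7)
        end = sg.propagate_batch(p, start, steps, rng)
        msd = float(np.mean(((end - start) ** 2).sum(axis=1)))
        expected = 4.0 * (p.kT / p.gamma) * steps * p.dt
        assert msd == pytest.approx(expected, rel=0.05)

    def test_nonfinite_force_raises(self, h_params):
        with pytest.raises(ValueError):
            sg.Configuration(np.nan, 0.0)


class TestClassification:
    @pytest.mark.parametrize("r,expected", [
        (12.0, "unassociated"),
        (10.0, None),           # boundary: unassociated requires r > 10
        (5.0, "ion_pair"),
        (3.0, "ion_pair"),
        (2.25, "ion_pair"),
        (2.0, None),
        (1.61, None),
        (1.59, "product"),
    ])
    def test_state_definition_thresholds(self, r, expected):
        assert sg.classify_macrostate(sg.Configuration(r)) == expected

    @given(st.floats(min_value=0.0, max_value=60.0,
                     allow_nan=False, allow_infinity=False))
    def test_every_radius_gets_at_most_one_label(self, r):
        code = int(sg.classify_r(r))
        in_bands = [r > sg.R_UNASSOCIATED,
                    sg.R_ION_PAIR_INNER <= r <= sg.R_ION_PAIR_OUTER,
                    r < sg.R_PRODUCT]
        assert sum(in_bands) <= 1
        if code == -1:
            assert not any(in_bands)
        else:
            assert in_bands[code]


class TestNearestSite:
    def test_site_center_maps_to_its_label(self, h_params):
        for xy, lab in zip(h_params.site_xy, h_params.site_labels):
            c = sg.Configuration.from_xy(*xy)
            assert sg.nearest_site(h_params, c) == lab

    def test_center_maps_to_t(self, h_params):
        assert sg.nearest_site(h_params, sg.Configuration(0.0)) == "T"
        # anywhere inside the product radius is T regardless of angle
        assert sg.nearest_site(h_params, sg.Configuration(1.0, 2.0)) == "T"

    def test_exact_tie_goes_to_lower_site_index(self):
        p = sg.SurrogateParams(n_sites=2, site_angles=(math.pi / 3, -math.pi / 3),
                               site_labels=("O", "P"),
                               site_well_depth=(("O", 1.0), ("P", 1.0)))
        # a point on the x axis is exactly equidistant from the two sites
        assert sg.nearest_site(p, sg.Configuration(4.0, 0.0)) == "O"


class TestInitialPool:
    def test_pool_sits_on_the_restraint_ring(self, h_params):
        pool = sg.initial_pool(h_params, 50, seed=1)
        assert pool.shape == (50, 2)
        np.testing.assert_allclose(np.hypot(pool[:, 0], pool[:, 1]), 20.0)
        assert all(sg.classify_r(np.hypot(*p)) == 0 for p in pool)


class TestLabelSequences:
    def test_no_noise_gives_exact_copies(self):
        seqs, truth = sg.generate_label_sequences(["OOPT", "PT"], 3, 0.0, 0, seed=0)
        assert seqs == ["OOPT"] * 3 + ["PT"] * 3
        np.testing.assert_array_equal(truth, [0, 0, 0, 1, 1, 1])

    def test_same_seed_is_deterministic(self):
        a = sg.generate_label_sequences(["OOPT", "PT"], 10, 0.1, 2, seed=5)
        b = sg.generate_label_sequences(["OOPT", "PT"], 10, 0.1, 2, seed=5)
        assert a[0] == b[0]

    def test_invalid_mutation_rate_rejected(self):
        with pytest.raises(ValueError, match="mutation_rate"):
            sg.generate_label_sequences(["OT"], 2, 1.5, 0, seed=0)

    def test_classes_stay_separated_in_gestalt_distance(self):
        from wepath.pathways import pathway_distance
        seqs, truth = sg.generate_label_sequences(
            ["OOPT", "PT"], 20, 0.05, 1, seed=3)
        intra, inter = [], []
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                d = pathway_distance(seqs[i], seqs[j])
                (intra if truth[i] == truth[j] else inter).append(d)
        assert np.mean(intra) < np.mean(inter)


class TestForceConsistency:
    def test_analytic_force_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        for name in ("OCH3", "H", "CF3"):
            p = sg.make_surrogate(name)
            pts = np.column_stack([rng.uniform(-8, 8, 25),
                                   rng.uniform(-8, 8, 25)])
            analytic = sg.force_xy(p, pts)
            eps = 1e-6
            numeric = np.empty_like(analytic)
            for k in range(2):
                d = np.zeros(2)
                d[k] = eps
                numeric[:, k] = -(sg.potential_xy(p, *(pts + d).T)
                                  - sg.potential_xy(p, *(pts - d).T)) / (2 * eps)
            np.testing.assert_allclose(analytic, numeric, atol=1e-6)

    def test_landscape_identical_across_presets_outside_contact_shell(self):
        # the diffusional-approach region must not depend on the substituent
        th = np.linspace(0.0, 2 * np.pi, 200)
        for r in (5.0, 6.0, 9.0):
            vals = [sg.potential_xy(sg.make_surrogate(n),
                                    r * np.cos(th), r * np.sin(th))
                    for n in ("OCH3", "H", "CF3")]
            np.testing.assert_allclose(vals[0], vals[1], atol=5e-3)
            np.testing.assert_allclose(vals[0], vals[2], atol=5e-3)
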