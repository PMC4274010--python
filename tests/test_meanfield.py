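import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spatcoex as sx
from spatcoex.meanfield import boundary_segments, mf_jacobian


def _spec(b=(1.0, 1.0), d=(0.1, 0.1), c=((0.2, 0.2), (0.2, 0.2))):
    return sx.ModelSpec(
        species=(sx.SpeciesParams(b[0], 1.0, d[0]), sx.SpeciesParams(b[1], 1.0, d[1])),
        competition=sx.CompetitionParams(rate=c),
        lattice_side=50,
        initial_density=(0.3, 0.3),
    )


class TestRhs:
    def test_extinction_is_a_fixed_point(self, default_spec):
        assert np.allclose(sx.mf_rhs((0.0, 0.0), default_spec), 0.0)

    def test_single_species_closed_form_root(self):
        """b=1, d=0.2, c11=0.2: stationary density (b-d)/(b+c) = 2/3."""
        spec = _spec(d=(0.2, 0.2))
        rho_star = (1.0 - 0.2) / (1.0 + 0.2)
        assert rho_star == pytest.approx(2 / 3)
        assert np.allclose(sx.mf_rhs((rho_star, 0.0), spec), 0.0, atol=1e-15)
        # numerical integration settles on the same point
        _, y = sx.mf_integrate(spec, (0.05, 0.0), t_end=400.0)
        assert y[-1, 0] == pytest.approx(rho_star, abs=1e-8)

    def test_symmetric_parameters_give_symmetric_derivatives(self, default_spec):
        f = sx.mf_rhs((0.21, 0.21), default_spec)
        assert f[0] == pytest.approx(f[1])

    def test_spatial_rhs_reduces_to_mf_when_g_is_one(self, default_spec):
        ones = np.ones((2, 2))
        for rho in ((0.1, 0.2), (0.4, 0.3), (0.0, 0.5)):
            assert np.allclose(
                sx.spatial_mf_rhs(rho, ones, ones, default_spec),
                sx.mf_rhs(rho, default_spec),
            )

    def test_spatial_rhs_intra_crowding_shifts_root(self):
        """g_comp(1,1)=2 doubles the effective self-competition: the
        single-species root moves to (b-d)/(b+2c)."""
        spec = _spec()
        gb = np.ones((2, 2))
        gc = np.array([[2.0, 1.0], [1.0, 1.0]])
        root = (1.0 - 0.1) / (1.0 + 2 * 0.2)
        out = sx.spatial_mf_rhs((root, 0.0), gb, gc, spec)
        assert out[0] == pytest.approx(0.0, abs=1e-15)

    def test_doubling_enemy_factor_lowers_growth(self, default_spec):
        gb = np.ones((2, 2))
        gc1 = np.ones((2, 2))
        gc2 = np.ones((2, 2))
        gc2[1, 0] = 2.0  # species 1 kills species 2 more effectively
        rho = (0.25, 0.25)
        f1 = sx.spatial_mf_rhs(rho, gb, gc1, default_spec)
        f2 = sx.spatial_mf_rhs(rho, gb, gc2, default_spec)
        assert f2[1] < f1[1] and f2[0] == f1[0]


class TestFixedPoints:
    def test_symmetric_interior_point(self):
        spec = _spec(c=((0.3, 0.1), (0.1, 0.3)))
        pts = sx.mf_fixed_points(spec)
        interior = [p for p in pts if p[0] > 0 and p[1] > 0]
        assert len(interior) == 1
        r1, r2 = interior[0]
        assert r1 == pytest.approx(r2)
        assert np.allclose(sx.mf_rhs(interior[0], spec), 0.0, atol=1e-12)

    def test_all_fixed_points_have_zero_residual(self):
        spec = _spec(b=(1.2, 0.8), d=(0.1, 0.05), c=((0.25, 0.1), (0.15, 0.3)))
        for fp in sx.mf_fixed_points(spec):
            assert np.max(np.abs(sx.mf_rhs(fp, spec))) < 1e-12

    def test_nonviable_species_has_no_boundary_point(self):
        spec = _spec(d=(0.1, 1.5))
        pts = sx.mf_fixed_points(spec)
        assert not any(p[0] == 0 and p[1] > 0 for p in pts)

    def test_equivalent_species_yield_no_isolated_interior(self):
        # all rates equal: singular linear system, a line of equilibria
        pts = sx.mf_fixed_points(_spec())
        assert not any(p[0] > 0 and p[1] > 0 for p in pts)


class TestClassification:
    def test_intra_dominant_gives_stable_coexistence(self):
        spec = _spec(c=((0.3, 0.1), (0.1, 0.3)))
        res = sx.mf_classify(spec)
        assert res.classification == "stable_coexistence"
        interior = [p for p in res.fixed_points if p[0] > 0 and p[1] > 0][0]
        ev = res.eigenvalues[res.fixed_points.index(interior)]
        assert np.all(np.real(ev) < 0)

    def test_inter_dominant_gives_founder_control(self):
        spec = _spec(c=((0.1, 0.4), (0.4, 0.1)))
        res = sx.mf_classify(spec)
        assert res.classification == "founder_control"
        interior = [p for p in res.fixed_points if p[0] > 0 and p[1] > 0][0]
        ev = res.eigenvalues[res.fixed_points.index(interior)]
        assert np.max(np.real(ev)) > 0  # saddle
        # both boundary points are attractors
        for fp, e in zip(res.fixed_points, res.eigenvalues):
            if (fp[0] > 0) != (fp[1] > 0):
                assert np.all(np.real(e) < 0)

    def test_nonviable_competitor_means_exclusion(self):
        res = sx.mf_classify(_spec(d=(0.1, 1.5), c=((0.1, 0.9), (0.9, 0.1))))
        assert res.classification == "exclusion_sp1_wins"

    def test_identical_species_drift(self):
        assert sx.mf_classify(_spec()).classification == "ecological_drift"

    def test_classification_matches_forward_integration(self):
        """Random specs: the label agrees with long-time ODE integration
        from an interior initial condition (non-founder-control cases)."""
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 12:
            b = rng.uniform(0.5, 1.5, 2)
            d = rng.uniform(0.0, 0.4, 2)
            c = rng.uniform(0.0, 0.5, (2, 2))
            spec = _spec(b=tuple(b), d=tuple(d), c=tuple(map(tuple, c)))
            res = sx.mf_classify(spec)
            if res.classification in ("founder_control", "ecological_drift"):
                continue
            # skip near-degenerate draws whose transients outlast any
            # reasonable integration horizon
            rates = np.concatenate([np.real(e) for e in res.eigenvalues])
            if np.min(np.abs(rates)) < 0.02:
                continue
            _, y = sx.mf_integrate(spec, (0.2, 0.2), t_end=3000.0)
            final = y[-1]
            alive = final > 1e-6
            expect = {
                "stable_coexistence": (True, True),
                "exclusion_sp1_wins": (True, False),
                "exclusion_sp2_wins": (False, True),
                "both_extinct": (False, False),
            }[res.classification]
            assert tuple(alive) == expect, (spec, res.classification, final)
            checked += 1

    def test_founder_control_depends_on_initial_advantage(self):
        spec = _spec(c=((0.1, 0.4), (0.4, 0.1)))
        _, y1 = sx.mf_integrate(spec, (0.3, 0.1), t_end=2000.0)
        _, y2 = sx.mf_integrate(spec, (0.1, 0.3), t_end=2000.0)
        assert y1[-1, 0] > 0.1 and y1[-1, 1] < 1e-6
        assert y2[-1, 1] > 0.1 and y2[-1, 0] < 1e-6


@given(
    b=st.tuples(st.floats(0.5, 1.5), st.floats(0.5, 1.5)),
    d=st.tuples(st.floats(0.0, 0.4), st.floats(0.0, 0.4)),
    c=st.tuples(*[st.floats(0.01, 0.5)] * 4),
)
@settings(max_examples=40, deadline=None)
def test_stability_labels_consistent_with_eigenvalues(b, d, c):
    """Property: the reported interior_stable flag always matches the
    eigenvalues of the analytic Jacobian at the interior point."""
    spec = _spec(b=b, d=d, c=((c[0], c[1]), (c[2], c[3])))
    res = sx.mf_classify(spec)
    interior = [p for p in res.fixed_points if p[0] > 0 and p[1] > 0]
    if interior:
        ev = res.eigenvalues[res.fixed_points.index(interior[0])]
        assert res.interior_stable == bool(np.all(np.real(ev) < 0))
    # numerical Jacobian cross-check at a generic point
    rho = np.array([0.21, 0.13])
    J = mf_jacobian(rho, spec)
    eps = 1e-7
    for k in range(2):
        dr = np.zeros(2)
        dr[k] = eps
        num = (sx.mf_rhs(rho + dr, spec) - sx.mf_rhs(rho - dr, spec)) / (2 * eps)
        assert np.allclose(J[:, k], num, atol=1e-5)


class TestPhaseBoundary:
    def test_raising_d2_past_b2_excludes_species_2(self, default_spec):
        grid = sx.mf_phase_boundary(
            default_spec.with_param("c12", 0.1), "c12", "d2",
            [0.1], np.linspace(0.05, 1.2, 8),
        )
        high = grid[grid["param_y"] >= 1.0]
        assert (high["class"] == "exclusion_sp1_wins").all()

    def test_label_swap_symmetry(self, default_spec):
        """Swapping species labels and the swept parameters relabels the
        classification grid accordingly."""
        gx = np.linspace(0.05, 0.35, 4)
        gy = np.linspace(0.05, 0.35, 4)
        g12 = sx.mf_phase_boundary(default_spec, "c12", "c21", gx, gy)
        g21 = sx.mf_phase_boundary(default_spec, "c21", "c12", gx, gy)
        swap = {
            "exclusion_sp1_wins": "exclusion_sp2_wins",
            "exclusion_sp2_wins": "exclusion_sp1_wins",
        }
        for (_, r1), (_, r2) in zip(g12.iterrows(), g21.iterrows()):
            assert r2["class"] == swap.get(r1["class"], r1["class"])

    def test_grid_classes_agree_with_ode_oracle(self, default_spec):
        spec = default_spec.with_param("c11", 0.25).with_param("c22", 0.25)
        gx = np.linspace(0.05, 0.45, 5)
        gy = np.linspace(0.02, 0.4, 5)
        grid = sx.mf_phase_boundary(spec, "c12", "d2", gx, gy)
        for _, row in grid.iterrows():
            if row["class"] in ("founder_control", "ecological_drift"):
                continue
            s = spec.with_param("c12", row["param_x"]).with_param("d2", row["param_y"])
            res = sx.mf_classify(s)
            rates = np.concatenate([np.real(e) for e in res.eigenvalues])
            if np.min(np.abs(rates)) < 0.02:
                continue  # transient outlasts the integration horizon
            _, y = sx.mf_integrate(s, (0.2, 0.2), t_end=3000.0)
            alive = tuple(y[-1] > 1e-6)
            expect = {
                "stable_coexistence": (True, True),
                "exclusion_sp1_wins": (True, False),
                "exclusion_sp2_wins": (False, True),
                "both_extinct": (False, False),
            }[row["class"]]
            assert alive == expect

    def test_unknown_parameter_rejected(self, default_spec):
        with pytest.raises(sx.SpecError):
            sx.mf_phase_boundary(default_spec, "zz", "d2", [0.1], [0.1])

    def test_boundary_segments_on_known_grid(self, default_spec):
        spec = default_spec.with_param("c11", 0.25).with_param("c22", 0.25)
        grid = sx.mf_phase_boundary(
            spec, "c12", "d2", np.linspace(0.05, 0.45, 6), np.linspace(0.02, 0.4, 6)
        )
        segs = boundary_segments(grid)
        assert len(segs) > 0  # the grid straddles at least one transition
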