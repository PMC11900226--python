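import numpy as np
import pytest

from tdaforce.fixtures import (
    CROSSING_CONDUCTION_SHIFTS,
    diatomic_geometry,
    fixture,
)
from tdaforce.forces import (
    BseSettings,
    brute_force_force,
    e0_derivative,
    excited_force,
    make_context,
    omega_derivative_hf,
    optimize,
)
from tdaforce.model import ModelParams, scf_ground_state
from tdaforce.solver import solve_dense

BSE = BseSettings(n_states=4)


@pytest.fixture(scope="module")
def base(diatomic):
    geom, params = diatomic
    ctx = make_context(geom, params, BSE)
    return geom, params, ctx, solve_dense(ctx, 4)


class TestOmegaDerivative:
    def test_zero_step_rejected(self, base):
        geom, params, ctx, eset = base
        with pytest.raises(ValueError, match="delta_lambda"):
            omega_derivative_hf(eset[0], ctx, (2, 0), 0.0)

    def test_mirror_odd_coordinate_gives_zero_derivative(self, base):
        """Displacing an on-axis atom off the mirror plane is an antisymmetric
        coordinate: the derivative of any non-degenerate state vanishes."""
        geom, params, ctx, eset = base
        for s in range(3):
            assert omega_derivative_hf(eset[s], ctx, (2, 1), 0.05) == pytest.approx(0.0, abs=1e-8)
        assert e0_derivative(geom, params, (2, 1), 0.05) == pytest.approx(0.0, abs=1e-8)

    def test_agrees_with_tracked_energy_differences(self, base):
        """Hellmann-Feynman and tracked central differences of Omega agree
        within the validation bound, and agreement tightens with the step."""
        geom, params, ctx, eset = base
        devs = {}
        for dl in (0.1, 0.02):
            hf = excited_force(eset[0], ctx, dl, [(2, 0)], state_index=1)
            fd = brute_force_force(1, geom, params, BSE, dl, [(2, 0)])
            devs[dl] = abs(hf.forces[2, 0] - fd.forces[2, 0])
        assert devs[0.1] <= 0.01
        assert devs[0.02] < devs[0.1]

    def test_hf_estimator_is_second_order_in_step(self, base):
        """Richardson: halving delta_lambda shrinks the error against a
        delta_lambda = 1e-3 reference about fourfold."""
        geom, params, ctx, eset = base
        ref = omega_derivative_hf(eset[1], ctx, (2, 0), 1e-3)
        errs = [abs(omega_derivative_hf(eset[1], ctx, (2, 0), dl) - ref) for dl in (0.1, 0.05)]
        assert 3.0 <= errs[0] / errs[1] <= 5.0


class TestE0Derivative:
    def test_small_at_scan_minimum(self, diatomic):
        """|dE0/dx| at the grid argmin of the one-coordinate scan is limited
        by the grid spacing times the surface curvature."""
        geom, params = diatomic
        xs = np.arange(2.6, 2.7501, 0.001)
        es = [
            scf_ground_state(geom.displace(2, 0, float(x) - 2.4), params).e0 for x in xs
        ]
        x_min = xs[int(np.argmin(es))]
        g_min = geom.displace(2, 0, float(x_min) - 2.4)
        assert abs(e0_derivative(g_min, params, (2, 0), 0.01)) <= 2e-3

    def test_translational_invariance(self, diatomic):
        """The collective-translation derivative vanishes identically; the sum
        of per-atom central differences vanishes up to its O(step^2) bias."""
        from tdaforce.geometry import Geometry

        geom, params = diatomic
        d = 0.05
        shifted = {
            s: scf_ground_state(
                Geometry(labels=geom.labels, positions=geom.positions + [s * d, 0, 0]),
                params,
            ).e0
            for s in (+1, -1)
        }
        assert (shifted[1] - shifted[-1]) / (2 * d) == pytest.approx(0.0, abs=1e-10)
        total = sum(
            e0_derivative(geom, params, (a, 0), 0.002) for a in range(geom.n_atoms)
        )
        assert total == pytest.approx(0.0, abs=1e-6)

    def test_second_order_against_four_point_stencil(self, diatomic):
        geom, params = diatomic
        def e0(d):
            return scf_ground_state(geom.displace(2, 0, d), params).e0
        h = 0.05
        ref = (-e0(2 * h) + 8 * e0(h) - 8 * e0(-h) + e0(-2 * h)) / (12 * h)
        errs = [abs(e0_derivative(geom, params, (2, 0), dl) - ref) for dl in (0.1, 0.05)]
        assert errs[0] > errs[1]  # O(dl^2) central difference converges to the stencil


class TestExcitedForce:
    def test_forces_equal_minus_energy_derivative_sum(self, base):
        geom, params, ctx, eset = base
        rec = excited_force(eset[2], ctx, 0.1, [(2, 0), (3, 0)], state_index=3)
        for a, ax in rec.coordinates:
            assert rec.forces[a, ax] == pytest.approx(
                -(rec.omega_derivatives[a, ax] + rec.e0_derivatives[a, ax]), abs=1e-14
            )

    def test_newtons_third_law_on_two_site_molecule(self):
        geom, _ = fixture("diatomic", 2)
        params = ModelParams(n_electrons=2)
        ctx = make_context(geom, params, BseSettings(n_states=1))
        eset = solve_dense(ctx, 1)
        rec = excited_force(eset[0], ctx, 0.1, [(0, 0), (1, 0)], state_index=1)
        assert rec.forces[0, 0] == pytest.approx(-rec.forces[1, 0], abs=1e-6)

    def test_total_force_vanishes_by_translational_invariance(self, base):
        # small step keeps the O(step^2) finite-difference bias below the bound
        geom, params, ctx, eset = base
        rec = excited_force(eset[0], ctx, 0.002, state_index=1)
        np.testing.assert_allclose(np.sum(rec.forces, axis=0), 0.0, atol=1e-6)


class TestBruteForce:
    def test_ground_state_index_rejected(self, diatomic):
        geom, params = diatomic
        with pytest.raises(ValueError, match="1-based"):
            brute_force_force(0, geom, params, BSE, 0.1)

    def test_zero_step_rejected(self, diatomic):
        geom, params = diatomic
        with pytest.raises(ValueError, match="delta_lambda"):
            brute_force_force(1, geom, params, BSE, 0.0)

    def test_crossing_naive_fails_tracked_agrees(self, diatomic):
        """Near the engineered exact crossing, energy-ordered differencing
        deviates from Hellmann-Feynman while overlap tracking repairs it."""
        geom0, params = diatomic
        bse = BseSettings(conduction_shifts=dict(CROSSING_CONDUCTION_SHIFTS), n_states=4)
        g = geom0.displace(2, 0, 2.675 - 2.4)
        ctx = make_context(g, params, bse)
        eset = solve_dense(ctx, 4)
        coord = [(2, 0)]
        for s in (1, 2):
            hf = excited_force(eset[s - 1], ctx, 0.1, coord, state_index=s)
            tracked = brute_force_force(s, g, params, bse, 0.1, coord)
            naive = brute_force_force(s, g, params, bse, 0.1, coord, tracking=False)
            d_tracked = abs(tracked.forces[2, 0] - hf.forces[2, 0])
            d_naive = abs(naive.forces[2, 0] - hf.forces[2, 0])
            assert d_tracked <= 0.01
            assert d_naive > 0.05
            assert d_naive > d_tracked


class TestOptimize:
    COORD = [(2, 0)]
    STATE = 3  # surface with a deep interior minimum along the coordinate

    def fine_scan_argmin(self, geom, params):
        xs = np.arange(2.35, 2.751, 0.01)
        energies = []
        for x in xs:
            ctx = make_context(geom.displace(2, 0, float(x) - 2.4), params, BSE)
            eset = solve_dense(ctx, self.STATE)
            energies.append(ctx.mf.e0 + eset.omegas[self.STATE - 1])
        return float(xs[int(np.argmin(energies))])

    def test_relaxation_matches_fine_scan(self, diatomic):
        geom, params = diatomic
        x_ref = self.fine_scan_argmin(geom, params)
        results = {}
        for alg in ("bfgs", "sd"):
            trace = optimize(
                self.STATE, geom, params, BSE, algorithm=alg,
                coordinates=self.COORD, max_steps=40,
            )
            assert trace.converged
            assert trace.steps[-1].max_force < trace.fmax_threshold
            energies = [s.energy for s in trace.steps]
            assert np.all(np.diff(energies) <= 1e-12)
            results[alg] = trace.final_geometry.positions[2, 0]
            assert abs(results[alg] - x_ref) <= 0.011
        assert abs(results["bfgs"] - results["sd"]) <= 0.02

    def test_restart_from_minimum_converges_immediately(self, diatomic):
        geom, params = diatomic
        x_ref = self.fine_scan_argmin(geom, params)
        start = geom.displace(2, 0, x_ref - 2.4)
        trace = optimize(
            self.STATE, start, params, BSE, coordinates=self.COORD, max_steps=5
        )
        assert trace.converged and len(trace.steps) <= 2

    def test_final_forces_below_threshold(self, diatomic):
        geom, params = diatomic
        trace = optimize(
            self.STATE, geom, params, BSE, coordinates=self.COORD, max_steps=40
        )
        final = trace.final_geometry
        ctx = make_context(final, params, BSE)
        eset = solve_dense(ctx, self.STATE)
        rec = excited_force(eset[trace.steps[-1].state_index], ctx, 0.1, self.COORD)
        assert rec.max_force() < trace.fmax_threshold

    def test_invalid_inputs_rejected(self, diatomic):
        geom, params = diatomic
        with pytest.raises(ValueError):
            optimize(0, geom, params, BSE)
        with pytest.raises(ValueError):
            optimize(1, geom, params, BSE, fmax=-1.0)
        with pytest.raises(ValueError):
            optimize(1, geom, params, BSE, algorithm="nonsense")
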