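import numpy as np
import pytest

from conftest import random_exciton
from oracles import cis_singlet_matrix
from tdaforce.excitonic import (
    ExcitonicContext,
    QPCorrections,
    apply_diagonal,
    apply_direct,
    apply_exchange,
    apply_hexc,
    amplitudes_from_batches,
    batches_from_amplitudes,
    dense_matrix,
    project_conduction,
)
from tdaforce.fixtures import fixture
from tdaforce.forces import BseSettings, make_context
from tdaforce.kernels import InteractionKernels, bare_coulomb


def zero_kernel_ctx(ctx):
    n = ctx.mf.n_sites
    z = np.zeros((n, n))
    return ExcitonicContext(
        mf=ctx.mf,
        kernels=InteractionKernels(v=z, w=z.copy(), screening_mode="bare"),
        qp=ctx.qp,
        spin_channel=ctx.spin_channel,
    )


class TestConductionProjector:
    def test_annihilates_occupied_orbitals(self, ctx_chain6):
        for v in range(ctx_chain6.n_valence):
            out = project_conduction(ctx_chain6, ctx_chain6.mf.occupied[:, v])
            np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_preserves_conduction_orbitals(self, ctx_chain6):
        for c in range(ctx_chain6.n_conduction):
            phi = ctx_chain6.mf.virtual[:, c]
            np.testing.assert_allclose(project_conduction(ctx_chain6, phi), phi, atol=1e-12)

    def test_idempotent_on_random_vectors(self, ctx_ring6):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.standard_normal(ctx_ring6.mf.n_sites)
            once = project_conduction(ctx_ring6, x)
            np.testing.assert_allclose(project_conduction(ctx_ring6, once), once, atol=1e-12)


class TestDiagonalTerm:
    def test_eigenvector_batch(self, ctx_diatomic):
        """A batch equal to phi_c in slot v returns (eps_c - eps_v + Delta) phi_c."""
        mf = ctx_diatomic.mf
        delta = 0.3
        ctx = ExcitonicContext(mf=mf, kernels=ctx_diatomic.kernels,
                               qp=QPCorrections(scissor=delta), spin_channel="singlet")
        nv = mf.n_valence
        b = np.zeros((nv, mf.n_sites))
        b[0] = mf.virtual[:, 1]
        out = apply_diagonal(ctx, b)
        expected = (mf.energies[nv + 1] - mf.energies[0] + delta) * b[0]
        np.testing.assert_allclose(out[0], expected, atol=1e-12)
        np.testing.assert_allclose(out[1:], 0.0, atol=1e-12)

    def test_scissor_acts_linearly(self, ctx_diatomic):
        mf = ctx_diatomic.mf
        rng = np.random.default_rng(3)
        b = random_exciton(mf, rng).batches
        base = apply_diagonal(ctx_diatomic, b)
        ctx_shift = ExcitonicContext(mf=mf, kernels=ctx_diatomic.kernels,
                                     qp=QPCorrections(scissor=0.5), spin_channel="singlet")
        np.testing.assert_allclose(apply_diagonal(ctx_shift, b), base + 0.5 * b, atol=1e-12)

    def test_shift_index_out_of_range_rejected(self, ctx_diatomic):
        with pytest.raises(IndexError):
            ExcitonicContext(
                mf=ctx_diatomic.mf,
                kernels=ctx_diatomic.kernels,
                qp=QPCorrections(conduction_shifts={99: 0.1}),
                spin_channel="singlet",
            )

    def test_qp_shifts_enter_dense_diagonal(self, ctx_diatomic):
        mf = ctx_diatomic.mf
        nv = mf.n_valence
        qp = QPCorrections(scissor=0.2, valence_shifts={0: -0.05},
                           conduction_shifts={nv: 0.07})
        ctx = ExcitonicContext(mf=mf, kernels=ctx_diatomic.kernels, qp=qp,
                               spin_channel="singlet")
        base = ExcitonicContext(mf=mf, kernels=ctx_diatomic.kernels,
                                spin_channel="singlet")
        d = np.diag(dense_matrix(ctx)) - np.diag(dense_matrix(base))
        nc = ctx.n_conduction
        expected = np.full(nv * nc, 0.2)
        expected[0 * nc: 1 * nc] += 0.05          # deeper corrected valence level
        expected[0::nc] += 0.07                    # corrected lowest conduction level
        np.testing.assert_allclose(d, expected, atol=1e-12)


class TestKernelTerms:
    def test_triplet_exchange_vanishes(self, ctx_chain6):
        ctx = ExcitonicContext(mf=ctx_chain6.mf, kernels=ctx_chain6.kernels,
                               qp=ctx_chain6.qp, spin_channel="triplet")
        rng = np.random.default_rng(4)
        b = random_exciton(ctx.mf, rng).batches
        assert np.array_equal(apply_exchange(ctx, b), np.zeros_like(b))

    def test_zero_screened_interaction_kills_direct_term(self, ctx_chain6):
        n = ctx_chain6.mf.n_sites
        v = bare_coulomb(ctx_chain6.mf.geometry, ctx_chain6.mf.params)
        ctx = ExcitonicContext(
            mf=ctx_chain6.mf,
            kernels=InteractionKernels(v=v, w=np.zeros((n, n)), screening_mode="rpa"),
            spin_channel="singlet",
        )
        rng = np.random.default_rng(5)
        b = random_exciton(ctx.mf, rng).batches
        np.testing.assert_allclose(apply_direct(ctx, b), 0.0, atol=1e-15)

    def test_single_valence_direct_term_hand_expansion(self):
        """Two-site molecule, Nv = 1: the direct term reduces to a 1x1
        conduction block -<c| W(phi_v phi_v) phi_c |c> on the batch."""
        geom, _ = fixture("diatomic", 2)
        from tdaforce.model import ModelParams

        ctx = make_context(geom, ModelParams(n_electrons=2), BseSettings())
        mf = ctx.mf
        phi_v, phi_c = mf.occupied[:, 0], mf.virtual[:, 0]
        b = np.array([phi_c])
        out = apply_direct(ctx, b)
        expected = -float(phi_c @ ((ctx.kernels.w @ (phi_v * phi_v)) * phi_c)) * phi_c
        np.testing.assert_allclose(out[0], expected, atol=1e-12)


class TestBatchVsDense:
    @pytest.mark.parametrize("name", ["diatomic", "chain6", "ring6"])
    def test_each_term_matches_dense_blocks(self, all_contexts, name):
        ctx = all_contexts[name]
        mf = ctx.mf
        nv, nc = ctx.n_valence, ctx.n_conduction
        rng = np.random.default_rng(6)

        zero = zero_kernel_ctx(ctx)
        h_full = dense_matrix(ctx)
        h_diag = dense_matrix(zero)
        singlet_only = ExcitonicContext(
            mf=mf,
            kernels=InteractionKernels(v=ctx.kernels.v, w=np.zeros_like(ctx.kernels.w),
                                       screening_mode="rpa"),
            spin_channel="singlet",
        )
        h_x = dense_matrix(singlet_only) - h_diag
        h_d = h_full - h_diag - h_x

        for _ in range(10):
            amp = rng.standard_normal((nv, nc))
            b = batches_from_amplitudes(mf, amp)
            for op, h_block in [
                (apply_diagonal, h_diag),
                (apply_exchange, h_x),
                (apply_direct, h_d),
                (apply_hexc, h_full),
            ]:
                out = amplitudes_from_batches(mf, op(ctx, b)).reshape(-1)
                np.testing.assert_allclose(
                    out, h_block @ amp.reshape(-1), atol=1e-10,
                    err_msg=f"{op.__name__} vs dense block on {name}",
                )

    @pytest.mark.parametrize("name", ["diatomic", "chain6", "ring6"])
    def test_outputs_stay_in_conduction_subspace(self, all_contexts, name):
        ctx = all_contexts[name]
        rng = np.random.default_rng(7)
        b = random_exciton(ctx.mf, rng).batches
        out = apply_hexc(ctx, b)
        occ = ctx.mf.occupied
        np.testing.assert_allclose(out @ occ, 0.0, atol=1e-12)

    def test_sum_of_terms_is_full_application(self, ctx_diatomic):
        rng = np.random.default_rng(8)
        b = random_exciton(ctx_diatomic.mf, rng).batches
        total = (
            apply_diagonal(ctx_diatomic, b)
            + apply_exchange(ctx_diatomic, b)
            + apply_direct(ctx_diatomic, b)
        )
        assert np.array_equal(apply_hexc(ctx_diatomic, b), total)

    @pytest.mark.parametrize("name", ["diatomic", "chain6", "ring6"])
    def test_hermitian_as_quadratic_form(self, all_contexts, name):
        ctx = all_contexts[name]
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = random_exciton(ctx.mf, rng).batches
            b = random_exciton(ctx.mf, rng).batches
            lhs = np.sum(a * apply_hexc(ctx, b))
            rhs = np.sum(b * apply_hexc(ctx, a))
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_unit_amplitude_column_consistency(self, ctx_diatomic):
        """Dense column for (v, c) equals the batch application of phi_c in slot v."""
        mf = ctx_diatomic.mf
        nv, nc = ctx_diatomic.n_valence, ctx_diatomic.n_conduction
        h = dense_matrix(ctx_diatomic)
        for v in range(nv):
            for c in range(nc):
                amp = np.zeros((nv, nc))
                amp[v, c] = 1.0
                out = amplitudes_from_batches(
                    mf, apply_hexc(ctx_diatomic, batches_from_amplitudes(mf, amp))
                )
                np.testing.assert_allclose(out.reshape(-1), h[:, v * nc + c], atol=1e-10)


class TestCisOracle:
    @pytest.mark.parametrize("system,n", [("diatomic", 4), ("chain", 6), ("ring", 6)])
    def test_bare_hamiltonian_equals_slater_condon_cis(self, system, n):
        """With bare screening and zero scissor the excitonic Hamiltonian is
        exactly the singlet configuration-interaction-singles matrix."""
        geom, p = fixture(system, n)
        ctx = make_context(geom, p, BseSettings(screening="bare", scissor=0.0))
        h = dense_matrix(ctx)
        gamma = bare_coulomb(geom, p)
        h_ref = cis_singlet_matrix(ctx.mf, gamma)
        np.testing.assert_allclose(h, h_ref, atol=1e-10)
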