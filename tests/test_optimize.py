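import math

import numpy as np
import pytest
import scipy.optimize

import echt
from echt import adp
from echt.hierarchy import Level, LevelScheme
from echt.optimize import (
    EchtModel,
    OptimizerConfig,
    compute_weights,
    decay_weights,
    elastic_net_penalty,
    fit_echt,
    level_target,
    model_complexity,
    optimize_amplitudes,
    optimize_atomic_adps,
    optimize_tls_matrices,
    residual,
)
from echt.tls import TLSGroup, TLSMatrices, normalize_group, tls_uij

from conftest import SEQ, make_fixture


def diag(a, b, c):
    return np.array([a, b, c, 0.0, 0.0, 0.0])


class TestWeights:
    def test_two_atoms(self):
        u = np.stack([adp.iso_to_u(0.5 * adp.B_SCALE), adp.iso_to_u(1.0 * adp.B_SCALE)])
        np.testing.assert_allclose(compute_weights(u), [2 / 3, 1 / 3])

    def test_uniform(self):
        u = np.tile(diag(0.3, 0.3, 0.3), (5, 1))
        np.testing.assert_allclose(compute_weights(u), np.full(5, 0.2))

    def test_single_atom(self):
        np.testing.assert_allclose(compute_weights(diag(1, 1, 1)[None]), [1.0])

    def test_zero_trace_named(self):
        u = np.stack([diag(1, 1, 1), np.zeros(6)])
        with pytest.raises(ValueError, match=r"\[1\]"):
            compute_weights(u)


class TestLevelTarget:
    def test_all_other_levels_zero(self):
        u = np.random.default_rng(0).normal(size=(4, 6))
        contribs = np.zeros((3, 4, 6))
        np.testing.assert_allclose(level_target(u, contribs, 1), u)

    def test_exact_cancellation(self):
        u = np.tile(diag(1, 1, 1), (2, 1))
        contribs = np.zeros((2, 2, 6))
        contribs[1] = u
        np.testing.assert_allclose(level_target(u, contribs, 0), np.zeros((2, 6)))

    def test_elementwise_subtraction(self):
        u = diag(2, 2, 2)[None]
        contribs = np.zeros((2, 1, 6))
        contribs[1] = diag(0.5, 0.5, 0.5)[None]
        np.testing.assert_allclose(level_target(u, contribs, 0), diag(1.5, 1.5, 1.5)[None])


class TestResidual:
    def test_identical_is_zero(self):
        u = np.random.default_rng(1).normal(size=(3, 6))
        assert residual(u, u, np.full(3, 1 / 3)) == 0.0

    def test_diagonal_difference(self):
        assert residual(diag(1, 1, 1)[None], np.zeros((1, 6)), np.ones(1)) == pytest.approx(3.0)

    def test_off_diagonal_double_count(self):
        u = np.zeros((1, 6))
        u[0, 3] = 1.0  # u12
        assert residual(u, np.zeros((1, 6)), np.ones(1)) == pytest.approx(2.0)

    def test_isotropic_metric(self):
        t = diag(1.0, 1.0, 1.0)[None]
        c = np.zeros((1, 6))
        assert residual(t, c, np.ones(1), iso=np.array([True])) == pytest.approx(1.0)


class TestPenalty:
    def test_example(self):
        assert elastic_net_penalty(np.array([1.0, 2.0]), 0.1, 0.2) == pytest.approx(1.3)

    def test_pure_lasso_endpoint(self):
        gamma, gamma0 = 1.0, 0.5
        oa, ob = gamma * gamma0, (1 - gamma) * gamma0
        assert elastic_net_penalty(np.array([2.0]), oa, ob) == pytest.approx(1.0)

    def test_zero_weight(self):
        assert elastic_net_penalty(np.array([1.0, 5.0]), 0.0, 0.0) == 0.0


class TestDecay:
    def test_three_cycles(self):
        assert decay_weights(1.0, 0.8, 3) == pytest.approx(0.512)

    def test_zero_cycles(self):
        assert decay_weights(0.7, 0.8, 0) == pytest.approx(0.7)

    def test_default_matches_config(self):
        assert OptimizerConfig().delta == 0.8
        assert OptimizerConfig().gamma == 0.9

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            decay_weights(1.0, 1.5, 1)


class TestAtomicOptimization:
    def test_psd_target_copied(self):
        t = np.array([[0.3, 0.2, 0.1, 0.01, 0.0, 0.02]])
        uhat, amps = optimize_atomic_adps(t, np.ones(1), OptimizerConfig())
        np.testing.assert_allclose(amps[:, None] * uhat, t, atol=1e-12)

    def test_projection_matches_example(self):
        t = diag(1.0, 1.0, -0.5)[None]
        uhat, amps = optimize_atomic_adps(t, np.ones(1), OptimizerConfig())
        np.testing.assert_allclose(amps[:, None] * uhat, diag(1, 1, 0)[None], atol=1e-12)

    def test_projection_matches_cholesky_oracle(self):
        # independent oracle: unconstrained minimization over a Cholesky
        # factorization (PSD by construction) of the weighted LS objective
        rng = np.random.default_rng(4)
        t6 = rng.normal(size=6) * 0.5
        uhat, amps = optimize_atomic_adps(t6[None], np.ones(1), OptimizerConfig())
        ours = (amps[:, None] * uhat)[0]

        tm = adp.to_matrix(t6)

        def obj(x):
            l = np.zeros((3, 3))
            l[np.tril_indices(3)] = x
            p = l @ l.T
            return ((p - tm) ** 2).sum()

        best = min(
            (
                scipy.optimize.minimize(obj, rng.normal(size=6), method="Nelder-Mead",
                                        options={"maxiter": 4000, "fatol": 1e-15})
                for _ in range(4)
            ),
            key=lambda r: r.fun,
        )
        l = np.zeros((3, 3))
        l[np.tril_indices(3)] = best.x
        np.testing.assert_allclose(ours, adp.from_matrix(l @ l.T), atol=1e-4)

    def test_zero_target(self):
        uhat, amps = optimize_atomic_adps(np.zeros((2, 6)), np.ones(2), OptimizerConfig())
        assert np.all(amps == 0.0)

    def test_isotropic_atoms_stay_isotropic(self):
        t = np.array([[0.3, 0.1, 0.2, 0.05, 0.0, 0.0]])
        uhat, amps = optimize_atomic_adps(
            t, np.ones(1), OptimizerConfig(), iso=np.array([True])
        )
        u = amps[:, None] * uhat
        np.testing.assert_allclose(u[0], diag(0.2, 0.2, 0.2), atol=1e-12)


def _one_group_model(n_atoms, uhat_t, sel=None):
    positions = np.zeros((n_atoms, 3))
    sel = np.array([0] if sel is None else sel)
    g = TLSGroup(selection=sel, matrices=TLSMatrices(T=uhat_t), amplitude=0.0)
    scheme = LevelScheme([Level("g", [g]), Level("atomic", [], kind="atomic")])
    uhat0 = np.zeros((n_atoms, 6))
    uhat0[:, :3] = 1.0
    return EchtModel(
        scheme=scheme,
        atomic_uhat=uhat0,
        atomic_amp=np.zeros(n_atoms),
        positions=positions,
        fit_indices=list(range(n_atoms)),
        isotropic_atoms=np.zeros(n_atoms, dtype=bool),
    )


class TestAmplitudeOptimization:
    def test_exact_reproduction_without_penalty(self):
        model = _one_group_model(1, diag(1, 1, 1))
        target = diag(2, 2, 2)[None]
        x = optimize_amplitudes(model, target, np.ones(1), 0.0, 0.0)
        assert x.sum() == pytest.approx(2.0, abs=1e-8)
        # residual vanishes because the basis spans the target
        assert residual(target, x[0] * diag(1, 1, 1)[None] + x[1] * diag(1, 1, 1)[None],
                        np.ones(1)) < 1e-12

    def test_one_dimensional_lasso_closed_form(self):
        # minimizer of  w*||(1 - a) Uhat||^2 + oa*a  is  max(0, 1 - oa/(2 c)),
        # c = w * ||Uhat||^2; the group and atomic bases are degenerate for a
        # single isotropic atom, so the optimal total amplitude carries the
        # closed-form value
        w0, oa = 0.7, 0.9
        model = _one_group_model(2, diag(1, 1, 1))
        target = np.tile(diag(1, 1, 1), (2, 1))
        target[1] = 0.0
        weights = np.array([w0, 0.0])
        x = optimize_amplitudes(model, target, weights, oa, 0.0)
        c = w0 * 3.0
        expected = max(0.0, 1.0 - oa / (2 * c))
        assert x[0] + x[1] == pytest.approx(expected, abs=1e-6)

    def test_huge_penalty_zeroes_everything(self):
        model = _one_group_model(1, diag(1, 1, 1))
        target = diag(2, 2, 2)[None]
        x = optimize_amplitudes(model, target, np.ones(1), 1e6, 0.0)
        assert np.all(x == 0.0)

    def test_never_increases_objective(self):
        model = _one_group_model(1, diag(1, 1, 1))
        model.scheme.levels[0].groups[0].amplitude = 5.0  # bad start
        target = diag(0.1, 0.1, 0.1)[None]
        x = optimize_amplitudes(model, target, np.ones(1), 0.0, 0.0)
        assert x.sum() <= 5.0


class TestMatrixOptimization:
    def test_recovers_known_group(self):
        rng = np.random.default_rng(5)
        pos = rng.normal(scale=5.0, size=(12, 3))
        origin = pos.mean(axis=0)
        true = TLSMatrices(
            T=[0.05, 0.06, 0.04, 0.005, 0.0, 0.002],
            L=[0.003, 0.002, 0.004, 0.0005, 0.0, 0.0],
            S=np.zeros(8),
            origin=origin,
        )
        target = tls_uij(true, pos)
        amp0 = float(np.mean(target[:, :3].sum(axis=1)) / 3.0)
        g = TLSGroup(
            selection=np.arange(12),
            matrices=TLSMatrices(T=diag(1, 1, 1), origin=origin),
            amplitude=amp0,
        )
        cfg = OptimizerConfig(simplex_maxiter=500)
        w = np.full(12, 1 / 12)
        for _ in range(12):  # simplex restarts, as in the fit's microcycles
            m, _ = optimize_tls_matrices(g, target, w, pos, cfg)
            g.matrices = m
            gn = normalize_group(g, pos)
            g.matrices, g.amplitude = gn.matrices, gn.amplitude
        fitted = g.amplitude * tls_uij(g.matrices, pos)
        rmsd = math.sqrt(np.mean((fitted - target) ** 2))
        assert rmsd < 1e-3

    def test_result_never_worse_than_start(self):
        rng = np.random.default_rng(6)
        pos = rng.normal(scale=3.0, size=(5, 3))
        target = rng.normal(size=(5, 6)) * 0.1
        g = TLSGroup(
            selection=np.arange(5),
            matrices=TLSMatrices(T=diag(1, 1, 1), origin=pos.mean(axis=0)),
            amplitude=0.05,
        )
        w = np.full(5, 0.2)
        start = residual(target, g.amplitude * tls_uij(g.matrices, pos), w)
        m, _ = optimize_tls_matrices(g, target, w, pos, OptimizerConfig())
        end = residual(target, g.amplitude * tls_uij(m, pos), w)
        assert end <= start + 1e-12

    def test_single_atom_is_t_only(self):
        # a 1-atom group has zero lever arm: L and S cannot change the fit,
        # so the residual must reach the T-only optimum (zero for any target
        # reachable by a valid T)
        target = np.array([[0.2, 0.3, 0.25, 0.01, 0.0, 0.0]])
        g = TLSGroup(
            selection=np.array([0]),
            matrices=TLSMatrices(T=diag(1, 1, 1), origin=np.zeros(3)),
            amplitude=float(target[0, :3].sum() / 3.0),
        )
        pos = np.zeros((1, 3))
        cfg = OptimizerConfig(simplex_maxiter=400)
        for _ in range(6):
            m, _ = optimize_tls_matrices(g, target, np.ones(1), pos, cfg)
            g.matrices = m
            gn = normalize_group(g, pos)
            g.matrices, g.amplitude = gn.matrices, gn.amplitude
        end = residual(target, g.amplitude * tls_uij(g.matrices, pos), np.ones(1))
        assert end < 1e-8


class TestFitBehaviour:
    def test_deterministic(self):
        atoms, _ = make_fixture(
            [{"level": "chain", "group": "all", "b": 6.0}],
            n_residues=4,
            scheme_cfg={"levels": ["chain", "residue", "atomic"]},
        )
        cfg = OptimizerConfig(max_macrocycles=6, min_macrocycles=6)
        scheme = echt.parse_custom_levels({"levels": ["chain", "residue", "atomic"]}, atoms)
        _, tr1 = fit_echt(atoms, scheme, cfg)
        _, tr2 = fit_echt(atoms, scheme, cfg)
        assert len(tr1.records) == len(tr2.records)
        for r1, r2 in zip(tr1.records, tr2.records):
            assert r1.level_mean_b == r2.level_mean_b
            assert r1.micro_objectives == r2.micro_objectives

    def test_rmsd_cutoff_terminates(self):
        atoms, _ = make_fixture(
            [{"level": "chain", "group": "all", "b": 6.0}],
            n_residues=4,
            scheme_cfg={"levels": ["chain", "residue", "atomic"]},
        )
        scheme = echt.parse_custom_levels({"levels": ["chain", "residue", "atomic"]}, atoms)
        model, trace = fit_echt(
            atoms, scheme, OptimizerConfig(rmsd_cutoff=1.0, min_macrocycles=1)
        )
        assert trace.converged
        assert trace.final_rmsd <= 1.0
        assert len(trace.records) < 10

    def test_max_macrocycles_flagged(self):
        atoms, _ = make_fixture(
            [{"level": "chain", "group": "all", "b": 6.0}],
            n_residues=4,
            scheme_cfg={"levels": ["chain", "residue", "atomic"]},
        )
        scheme = echt.parse_custom_levels({"levels": ["chain", "residue", "atomic"]}, atoms)
        _, trace = fit_echt(atoms, scheme, OptimizerConfig(max_macrocycles=2))
        assert not trace.converged
        assert len(trace.records) == 2

    def test_input_reproduced_through_atomic_level(self):
        # with the atomic level present any PSD input can be absorbed
        atoms, _ = make_fixture(
            [{"level": "chain", "group": "all", "b": 6.0}],
            n_residues=4,
            scheme_cfg={"levels": ["chain", "residue", "atomic"]},
            noise_b=1.5,
            seed=3,
        )
        scheme = echt.parse_custom_levels({"levels": ["chain", "residue", "atomic"]}, atoms)
        model, trace = fit_echt(atoms, scheme, OptimizerConfig(rmsd_cutoff=0.05,
                                                               min_macrocycles=1,
                                                               max_macrocycles=40))
        assert trace.converged
        assert trace.final_rmsd <= 0.05

    def test_config_validation(self):
        with pytest.raises(ValueError):
            OptimizerConfig(gamma=1.5).validate()
        with pytest.raises(ValueError):
            OptimizerConfig(delta=1.0).validate()
        with pytest.raises(ValueError):
            OptimizerConfig(db_cutoff=-1.0).validate()


class TestComplexity:
    def test_zero_model(self):
        model = _one_group_model(6, diag(1, 1, 1))
        assert model_complexity(model) == (0.0, 0.0)

    def test_known_amplitudes(self):
        model = _one_group_model(6, diag(1, 1, 1))
        model.scheme.levels[0].groups[0].amplitude = 1.0
        model.atomic_amp[:] = [2.0, 3.0, 0.0, 0.0, 0.0, 0.0]
        total, per_atom = model_complexity(model)
        assert total == pytest.approx(6.0)
        assert per_atom == pytest.approx(1.0)

    def test_nonincreasing_with_penalty(self):
        atoms, _ = make_fixture(
            [{"level": "chain", "group": "all", "b": 6.0}],
            n_residues=4,
            scheme_cfg={"levels": ["chain", "residue", "atomic"]},
            noise_b=1.0,
            seed=9,
        )
        scheme = echt.parse_custom_levels({"levels": ["chain", "residue", "atomic"]}, atoms)
        cfg_lo = OptimizerConfig(omega0=0.01, max_macrocycles=8, min_macrocycles=8)
        cfg_hi = OptimizerConfig(omega0=0.5, max_macrocycles=8, min_macrocycles=8)
        m_lo, _ = fit_echt(atoms, scheme, cfg_lo)
        m_hi, _ = fit_echt(atoms, scheme, cfg_hi)
        assert m_hi.complexity()[0] <= m_lo.complexity()[0] + 1e-9
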