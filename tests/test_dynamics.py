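"""Equilibria, stability, continuation and regime structure of the ODE."""

import numpy as np
import pytest
import sympy as sp

from vaxperc.dynamics import (
    ModelParameters,
    classify_stability,
    continuation_branch,
    find_equilibria,
    fold_point,
    jacobian,
    model_rhs,
    phase_diagram,
    saturating_rate,
    simulate,
)


def _random_simplex(rng, n=1):
    return rng.dirichlet(np.ones(4), size=n)


def test_saturating_rate_shape():
    p = ModelParameters.reference()
    assert saturating_rate(0.0, p) == 0.0
    assert saturating_rate(p.b, p) == pytest.approx(p.c / 2)      # half-saturation
    assert saturating_rate(0.1, ModelParameters.reference(b=0.1, c=10)) \
        == pytest.approx(5.0)
    with pytest.raises(ValueError):
        ModelParameters.reference(b=0.0)


def test_rhs_conservation_identity(rng):
    p = ModelParameters.reference()
    for s in _random_simplex(rng, 20):
        assert model_rhs(s, p).sum() == pytest.approx(0.0, abs=1e-12)
    off = np.array([0.3, 0.2, 0.1, 0.1])   # off-simplex: sum = mu*(1-total)
    assert model_rhs(off, p).sum() == pytest.approx(p.mu * (1 - off.sum()),
                                                    abs=1e-12)


def test_rhs_pure_unwilling_state():
    p = ModelParameters.reference()
    d = model_rhs(np.array([1.0, 0.0, 0.0, 0.0]), p)
    np.testing.assert_allclose(d, [-p.k, p.k, 0.0, 0.0], atol=1e-15)
    with pytest.raises(ValueError):
        model_rhs(np.array([-0.1, 0.4, 0.4, 0.3]), p)


def test_rhs_matches_symbolic_oracle(rng):
    u, h, w, v = sp.symbols("u h w v")
    names = ("mu", "beta", "eta", "k", "g", "e", "f", "d", "r", "c", "b")
    syms = dict(zip(names, sp.symbols(" ".join(names))))
    gamma = syms["c"] * w / (syms["b"] + w)
    exprs = (
        syms["mu"] - syms["beta"] * u * w - syms["eta"] * u * v
        + syms["g"] * h - (syms["k"] + syms["mu"]) * u,
        syms["beta"] * u * w + syms["eta"] * u * v + syms["k"] * u
        + syms["d"] * w - syms["f"] * h * v
        - (syms["g"] + syms["e"] + syms["mu"]) * h,
        syms["f"] * h * v + syms["e"] * h
        - (syms["r"] + syms["d"] + syms["mu"]) * w - gamma,
        gamma + syms["r"] * w - syms["mu"] * v,
    )
    fn = sp.lambdify((u, h, w, v) + tuple(syms.values()), exprs)
    p = ModelParameters.reference()
    for s in _random_simplex(rng, 10):
        expected = fn(*s, *(getattr(p, n) for n in names))
        np.testing.assert_allclose(model_rhs(s, p), expected,
                                   rtol=1e-12, atol=1e-12)


def test_jacobian_columns_sum_to_minus_mu(rng):
    p = ModelParameters.reference()
    for s in _random_simplex(rng, 10):
        J = jacobian(s, p)
        np.testing.assert_allclose(J.sum(axis=0), -p.mu * np.ones(4),
                                   atol=1e-12)


def test_jacobian_matches_finite_differences(rng):
    """100 random (state, parameter) draws, relative tolerance 1e-6."""
    for _ in range(100):
        p = ModelParameters(**{n: float(x) for n, x in zip(
            ("mu", "beta", "eta", "k", "g", "e", "f", "d", "r", "c", "b"),
            rng.uniform(0.05, 3.0, 11))})
        s = _random_simplex(rng)[0]
        J = jacobian(s, p)
        eps = 1e-7
        for j in range(4):
            sp_ = s.copy()
            sm = s.copy()
            sp_[j] += eps
            sm[j] = max(sm[j] - eps, 0.0)
            fd = (model_rhs(sp_, p) - model_rhs(sm, p)) / (sp_[j] - sm[j])
            np.testing.assert_allclose(J[:, j], fd, rtol=1e-5, atol=1e-6)


def test_simulation_stays_on_simplex_and_holds_equilibria(graded_params):
    p = graded_params.replace(f=10.0)
    eqs = find_equilibria(p)
    stable = [e for e in eqs if e.stability == "stable"]
    assert len(stable) == 1
    traj = simulate(stable[0].state, p, t_end=100.0)
    assert np.abs(traj.states - stable[0].state).max() < 1e-6

    traj = simulate([0.97, 0.01, 0.01, 0.01], p, t_end=500.0)
    assert np.abs(traj.states.sum(axis=1) - 1.0).max() <= 1e-6
    assert np.abs(traj.terminal_state - stable[0].state).max() < 1e-5


def test_decoupled_limit_keeps_everyone_unwilling():
    p = ModelParameters(mu=0.2, beta=0, eta=0, k=0, g=0, e=0, f=0, d=0,
                        r=0, c=0, b=0.1)
    eqs = find_equilibria(p)
    states = np.array([e.state for e in eqs])
    assert any(np.abs(s - [1, 0, 0, 0]).max() < 1e-8 for s in states)


def test_bistable_point_has_three_equilibria(bistable_params):
    eqs = find_equilibria(bistable_params)
    stable = [e for e in eqs if e.stability == "stable"]
    unstable = [e for e in eqs if e.stability == "unstable"]
    assert len(eqs) == 3
    assert len(stable) == 2 and len(unstable) == 1
    low, high = sorted(e.v for e in stable)
    assert low < 0.5 < high
    # the saddle has exactly one eigenvalue with positive real part
    assert (unstable[0].eigenvalues.real > 0).sum() == 1


def test_stable_equilibria_attract_perturbations(bistable_params):
    for eq in find_equilibria(bistable_params):
        if eq.stability != "stable":
            continue
        bump = eq.state + np.array([1e-4, -1e-4, 0.0, 0.0])
        bump = np.clip(bump, 0, None)
        bump /= bump.sum()
        traj = simulate(bump, bistable_params, t_end=500.0)
        assert np.abs(traj.terminal_state - eq.state).max() < 1e-5


def test_classify_stability_contracts(bistable_params):
    eq = find_equilibria(bistable_params)[0]
    label, eig = classify_stability(eq.state, bistable_params)
    assert label == "stable" and len(eig) == 4
    label, _ = classify_stability(eq.state, bistable_params,
                                  margin=np.inf)
    assert label == "marginal"
    with pytest.raises(ValueError):
        classify_stability(np.array([0.4, 0.3, 0.2, 0.1]), bistable_params)


def test_random_starts_converge_to_catalogued_equilibria(bistable_params, rng):
    eqs = find_equilibria(bistable_params)
    catalog = np.array([e.state for e in eqs if e.stability == "stable"])
    for s0 in _random_simplex(rng, 20):
        traj = simulate(s0, bistable_params, t_end=2000.0)
        dists = np.abs(catalog - traj.terminal_state).max(axis=1)
        assert dists.min() < 1e-4


def test_graded_regime_single_monotone_branch(graded_params):
    grid = np.linspace(0.5, 20.0, 30)
    scans = continuation_branch(graded_params, "f", grid, direction="forward")
    scan = scans["forward"]
    assert all(reg == "monostable-low" for reg in scan.regimes)
    v_branch = [scan.stable_v(i)[0] for i in range(len(grid))]
    assert all(len(scan.stable_v(i)) == 1 for i in range(len(grid)))
    assert (np.diff(v_branch) >= -1e-10).all()


def test_hysteresis_loop_in_bistable_regime():
    p = ModelParameters.reference()        # eta = 1.2
    grid = np.linspace(6.0, 9.0, 31)
    scans = continuation_branch(p, "f", grid, direction="both",
                                fresh_multistarts=False)
    fwd, bwd = scans["forward"], scans["backward"]
    gaps = []
    for i in range(len(grid)):
        vf = fwd.stable_v(i)
        vb = bwd.stable_v(i)
        gaps.append(abs(vf[0] - vb[-1]))
    assert max(gaps) >= 0.1                # branches disagree somewhere
    # upper branch is monotone over the scanned range
    upper = [max(bwd.stable_v(i)) for i in range(len(grid))]
    assert (np.diff(upper) >= -1e-8).all()


def test_fold_location_near_transition_threshold():
    p = ModelParameters.reference()
    f_fold, state = fold_point(p, "f", x_start=6.0, x_max=10.0,
                               n_coarse=80, tol=1e-3)
    assert 7.0 < f_fold < 8.6
    assert state[3] < 0.5                   # the disappearing branch is the low one


def test_phase_diagram_regimes(bistable_params):
    frame = phase_diagram([0.2, 1.2], [2.0, 7.5],
                          ModelParameters.reference())
    get = lambda eta, f: frame[(frame.eta == eta)
                               & (frame.f == f)].regime.iloc[0]
    assert get(0.2, 2.0) == "monostable-low"
    assert get(1.2, 7.5) == "bistable"

    # degenerate supply: classification still defined with c = 0
    p0 = ModelParameters.reference(c=0.0, r=5.0)
    frame0 = phase_diagram([1.2], [7.5], p0)
    assert frame0.regime.iloc[0] in {"monostable-low", "bistable",
                                     "monostable-high"}


def test_unbounded_supply_empties_willing_queue():
    """As the throughput cap grows, willing people vaccinate immediately."""
    ws = []
    for c in (10.0, 100.0, 1000.0):
        p = ModelParameters.reference(c=c, f=9.0)
        eqs = find_equilibria(p)
        high = max((e for e in eqs if e.stability == "stable"),
                   key=lambda e: e.v)
        ws.append(high.w)
    assert ws[0] > ws[1] > ws[2]
    assert ws[2] < 1e-4


def test_parameter_yaml_round_trip(tmp_path):
    p = ModelParameters.reference(eta=0.7)
    path = tmp_path / "params.yaml"
    p.to_yaml(path)
    assert ModelParameters.from_yaml(path) == p
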