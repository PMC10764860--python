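"""Dynamics of the four-compartment vaccine-perception model.

State: population fractions (u, h, w, v) of the unwilling, hesitant,
willing and vaccinated compartments, with u + h + w + v = 1. The coupled
ODE system is

    u' = mu - beta*u*w - eta*u*v + g*h - (k + mu)*u
    h' = beta*u*w + eta*u*v + k*u + d*w - f*h*v - (g + e + mu)*h
    w' = f*h*v + e*h - (r + d + mu)*w - Gamma(w)
    v' = Gamma(w) + r*w - mu*v

where Gamma(w) = c*w / (b + w) is the saturating limited-supply vaccination
rate (throughput c, half-saturation b) and mu is the birth/death turnover.
The component sum is mu*(1 - u - h - w - v) identically, so the unit simplex
is invariant.

The module finds all equilibria by multi-start root finding on the reduced
(u, h, w) system with v eliminated through the conservation law, classifies
their stability from the analytic Jacobian's eigenvalues, continues
equilibrium branches along the peer-influence parameters f and eta (the
system undergoes a saddle-node bifurcation: a low- and a high-coverage
stable branch coexist in a bistable wedge, producing hysteresis), locates
the fold by bisection, and classifies the eta-f plane into monostable-low,
bistable and monostable-high regimes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "ModelParameters",
    "Equilibrium",
    "BifurcationScan",
    "saturating_rate",
    "model_rhs",
    "jacobian",
    "simulate",
    "find_equilibria",
    "classify_stability",
    "continuation_branch",
    "fold_point",
    "phase_diagram",
]

_PARAM_ORDER = ("mu", "beta", "eta", "k", "g", "e", "f", "d", "r", "c", "b")

#: Parameter set of the published bistable regime (eta = 1.2); the graded
#: regime uses the same values with eta = 0.2.
REFERENCE_PARAMETERS = dict(mu=0.2, beta=2.0, eta=1.2, k=0.01, g=0.5,
                            e=0.01, f=7.8, d=0.05, r=0.2, c=10.0, b=0.1)


@dataclass(frozen=True)
class ModelParameters:
    """Rates of the vaccine-perception ODE (per unit time, all >= 0).

    mu    birth/death turnover
    beta  willing-induced U->H contact rate
    eta   vaccinated-induced U->H contact rate
    k     autonomous U->H rate (campaigns, access restrictions)
    g     autonomous H->U relapse rate
    e     autonomous H->W rate
    f     vaccinated-induced (confirmatory) H->W contact rate
    d     autonomous W->H relapse rate
    r     smooth-supply W->V vaccination rate
    c     maximum limited-supply vaccination throughput
    b     half-saturation willing fraction of the limited-supply path
    """

    mu: float
    beta: float
    eta: float
    k: float
    g: float
    e: float
    f: float
    d: float
    r: float
    c: float
    b: float

    def __post_init__(self):
        for name in _PARAM_ORDER:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")
        if self.c > 0 and self.b <= 0:
            raise ValueError("b must be > 0 when c > 0 (singular supply term)")

    @classmethod
    def reference(cls, **overrides) -> "ModelParameters":
        return cls(**{**REFERENCE_PARAMETERS, **overrides})

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> Dict[str, float]:
        return {n: float(getattr(self, n)) for n in _PARAM_ORDER}

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**{n: float(data[n]) for n in _PARAM_ORDER})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def saturating_rate(w: float, params: ModelParameters) -> float:
    """Limited-supply vaccination flux Gamma(w) = c*w / (b + w).

    Zero at w = 0, strictly increasing, approaching the throughput cap c as
    the willing fraction grows.
    """
    if w < 0:
        raise ValueError("w must be >= 0")
    if params.b == 0 and params.c > 0:
        raise ValueError("singular supply term: b = 0 with c > 0")
    if params.c == 0:
        return 0.0
    return params.c * w / (params.b + w)


def model_rhs(state: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Time derivatives (u', h', w', v') of the perception dynamics."""
    state = np.asarray(state, float)
    if (state < -1e-12).any():
        raise ValueError(f"negative state component: {state}")
    u, h, w, v = state
    p = params
    gamma = saturating_rate(max(w, 0.0), p)
    du = p.mu - p.beta * u * w - p.eta * u * v + p.g * h - (p.k + p.mu) * u
    dh = (p.beta * u * w + p.eta * u * v + p.k * u + p.d * w
          - p.f * h * v - (p.g + p.e + p.mu) * h)
    dw = p.f * h * v + p.e * h - (p.r + p.d + p.mu) * w - gamma
    dv = gamma + p.r * w - p.mu * v
    return np.array([du, dh, dw, dv])


def jacobian(state: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Analytic 4x4 Jacobian of the right-hand side.

    Uses dGamma/dw = c*b / (b + w)^2. Every column sums to -mu, the
    differential form of the conservation identity.
    """
    u, h, w, v = np.asarray(state, float)
    p = params
    dgamma = p.c * p.b / (p.b + w) ** 2 if p.c > 0 else 0.0
    return np.array([
        [-p.beta * w - p.eta * v - (p.k + p.mu), p.g, -p.beta * u, -p.eta * u],
        [p.beta * w + p.eta * v + p.k, -p.f * v - (p.g + p.e + p.mu),
         p.beta * u + p.d, p.eta * u - p.f * h],
        [0.0, p.f * v + p.e, -(p.r + p.d + p.mu) - dgamma, p.f * h],
        [0.0, 0.0, dgamma + p.r, -p.mu],
    ])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    t: np.ndarray
    states: np.ndarray          # shape (len(t), 4)
    terminal_rhs_norm: float

    @property
    def terminal_state(self) -> np.ndarray:
        return self.states[-1]


def simulate(state0: Sequence[float], params: ModelParameters,
             t_end: float = 1000.0, rtol: float = 1e-8, atol: float = 1e-10,
             n_points: int = 200, method: str = "LSODA") -> Trajectory:
    """Integrate the dynamics from an admissible initial state.

    Stiff-capable (LSODA default). Raises if the solver fails or if the
    trajectory leaves the simplex by more than 1e-6.
    """
    s0 = np.asarray(state0, float)
    if (s0 < -1e-9).any() or abs(s0.sum() - 1.0) > 1e-6:
        raise ValueError(f"inadmissible initial state {s0}")
    sol = solve_ivp(lambda t, y: model_rhs(np.maximum(y, 0.0), params),
                    (0.0, t_end), s0, method=method,
                    t_eval=np.linspace(0.0, t_end, n_points),
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    states = sol.y.T
    drift = np.abs(states.sum(axis=1) - 1.0).max()
    if drift > 1e-6 or states.min() < -1e-6:
        raise RuntimeError(
            f"trajectory left the simplex (mass drift {drift:.2e}, "
            f"min component {states.min():.2e})")
    term_norm = float(np.linalg.norm(model_rhs(np.maximum(states[-1], 0.0),
                                               params)))
    return Trajectory(t=sol.t, states=states, terminal_rhs_norm=term_norm)


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------

@dataclass
class Equilibrium:
    state: np.ndarray
    residual_norm: float
    eigenvalues: np.ndarray
    stability: str               # "stable" | "unstable" | "marginal"
    branch_tag: str = ""         # "low" | "high" | "saddle"

    @property
    def u(self) -> float:
        return float(self.state[0])

    @property
    def h(self) -> float:
        return float(self.state[1])

    @property
    def w(self) -> float:
        return float(self.state[2])

    @property
    def v(self) -> float:
        return float(self.state[3])


def classify_stability(state: np.ndarray, params: ModelParameters,
                       margin: float = 1e-8,
                       root_tol: float = 1e-8) -> Tuple[str, np.ndarray]:
    """Stability label from the Jacobian spectrum at an equilibrium.

    stable if every eigenvalue real part < -margin, unstable if any
    > +margin, marginal otherwise. Raises when the input is not an
    equilibrium to ``root_tol``.
    """
    res = np.linalg.norm(model_rhs(np.maximum(state, 0.0), params))
    if res > root_tol:
        raise ValueError(f"not an equilibrium: |rhs| = {res:.3e}")
    eig = np.linalg.eigvals(jacobian(state, params))
    reals = eig.real
    if np.all(reals < -margin):
        label = "stable"
    elif np.any(reals > margin):
        label = "unstable"
    else:
        label = "marginal"
    return label, eig


def _default_starts(n_grid: int = 5) -> List[Tuple[float, float, float]]:
    """Lattice over the (u, h, w) simplex plus corners and small-w probes.

    The low-coverage branch lives at willing fractions of order 1e-6, far
    below any coarse lattice, so logarithmically spaced small-w starts are
    included as well.
    """
    starts = []
    grid = np.linspace(0.0, 1.0, n_grid)
    for u0 in grid:
        for h0 in grid:
            for w0 in grid:
                if u0 + h0 + w0 <= 1.0 + 1e-12:
                    starts.append((u0, h0, w0))
    for w0 in 10.0 ** np.arange(-8.0, -1.0):
        for u0 in (0.3, 0.6, 0.9, 0.98):
            starts.append((u0, min(0.02, 1 - u0), w0))
    return starts


def find_equilibria(params: ModelParameters,
                    starts: Optional[Iterable[Sequence[float]]] = None,
                    extra_random_starts: int = 0,
                    rng: Optional[np.random.Generator] = None,
                    root_tol: float = 1e-10,
                    merge_tol: float = 1e-6,
                    margin: float = 1e-8) -> List[Equilibrium]:
    """All admissible equilibria via multi-start Newton root finding.

    Roots are sought on the reduced (u, h, w) system with v = 1 - u - h - w
    (the conservation identity makes the fourth equation redundant), merged
    within ``merge_tol`` in max-norm, verified to ``root_tol`` on the full
    right-hand side and classified by Jacobian eigenvalues. Returned sorted
    by increasing v.
    """
    p = params

    def reduced(x):
        u0, h0, w0 = x
        s = np.array([u0, h0, w0, 1.0 - u0 - h0 - w0])
        return _rhs_unchecked(s, p)[:3]

    start_list = list(starts) if starts is not None else _default_starts()
    if extra_random_starts and rng is not None:
        raw = rng.dirichlet(np.ones(4), size=extra_random_starts)
        start_list.extend(tuple(row[:3]) for row in raw)

    found: List[np.ndarray] = []
    for x0 in start_list:
        # hybr occasionally reports failure with a fully converged residual,
        # so acceptance is by residual; lm is the fallback on true failures
        sol = root(reduced, x0, method="hybr", tol=1e-12)
        u0, h0, w0 = sol.x
        s = np.array([u0, h0, w0, 1.0 - u0 - h0 - w0])
        if np.abs(_rhs_unchecked(s, p)).max() > root_tol:
            sol = root(reduced, x0, method="lm", tol=1e-14)
            u0, h0, w0 = sol.x
            s = np.array([u0, h0, w0, 1.0 - u0 - h0 - w0])
        if (s < -1e-9).any():
            continue
        if np.abs(_rhs_unchecked(s, p)).max() > root_tol:
            continue
        if any(np.abs(s - q).max() < merge_tol for q in found):
            continue
        found.append(s)
    if not found:
        raise RuntimeError("no equilibrium found from any start")

    out = []
    for s in sorted(found, key=lambda q: q[3]):
        s = np.clip(s, 0.0, None)
        res = float(np.linalg.norm(_rhs_unchecked(s, p)))
        label, eig = classify_stability(s, p, margin=margin,
                                        root_tol=max(10 * root_tol, 1e-9))
        out.append(Equilibrium(state=s, residual_norm=res, eigenvalues=eig,
                               stability=label))
    _tag_branches(out)
    return out


def _rhs_unchecked(state: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Right-hand side without admissibility checks (Newton may probe
    slightly negative states)."""
    u, h, w, v = state
    gamma = p.c * w / (p.b + w) if p.c > 0 else 0.0
    du = p.mu - p.beta * u * w - p.eta * u * v + p.g * h - (p.k + p.mu) * u
    dh = (p.beta * u * w + p.eta * u * v + p.k * u + p.d * w
          - p.f * h * v - (p.g + p.e + p.mu) * h)
    dw = p.f * h * v + p.e * h - (p.r + p.d + p.mu) * w - gamma
    dv = gamma + p.r * w - p.mu * v
    return np.array([du, dh, dw, dv])


def _tag_branches(equilibria: List[Equilibrium],
                  v_split: float = 0.5) -> None:
    for eq in equilibria:
        if eq.stability == "unstable":
            eq.branch_tag = "saddle"
        else:
            eq.branch_tag = "high" if eq.v >= v_split else "low"


# ---------------------------------------------------------------------------
# continuation, fold location, phase diagram
# ---------------------------------------------------------------------------

@dataclass
class BifurcationScan:
    """Equilibria along a one-parameter sweep, with per-point regimes."""

    parameter: str
    grid: np.ndarray
    equilibria: List[List[Equilibrium]]
    direction: str                              # "forward" | "backward" | "both"
    regimes: List[str] = field(default_factory=list)
    v_split: float = 0.5

    def stable_v(self, i: int) -> List[float]:
        return sorted(eq.v for eq in self.equilibria[i]
                      if eq.stability == "stable")

    def classify(self) -> List[str]:
        self.regimes = []
        for i in range(len(self.grid)):
            vs = self.stable_v(i)
            high = [v for v in vs if v >= self.v_split]
            low = [v for v in vs if v < self.v_split]
            if high and low:
                self.regimes.append("bistable")
            elif high:
                self.regimes.append("monostable-high")
            else:
                self.regimes.append("monostable-low")
        return self.regimes

    def to_frame(self):
        import pandas as pd
        rows = []
        for x, eqs in zip(self.grid, self.equilibria):
            for eq in eqs:
                rows.append({self.parameter: x, "branch": eq.branch_tag,
                             "u": eq.u, "h": eq.h, "w": eq.w, "v": eq.v,
                             "stability": eq.stability})
        return pd.DataFrame(rows)


def _track(params: ModelParameters, parameter: str, grid: np.ndarray,
           fresh_multistarts: bool) -> List[List[Equilibrium]]:
    """Natural-parameter continuation: seed each point from the previous
    point's converged roots, plus (optionally) fresh lattice multi-starts to
    pick up coexisting branches."""
    results: List[List[Equilibrium]] = []
    prev_states: List[np.ndarray] = []
    lattice = _default_starts()
    for x in grid:
        p = params.replace(**{parameter: float(x)})
        starts = [tuple(s[:3]) for s in prev_states]
        if fresh_multistarts or not starts:
            starts += lattice
        eqs = find_equilibria(p, starts=starts)
        results.append(eqs)
        prev_states = [eq.state for eq in eqs]
    return results


def continuation_branch(params: ModelParameters, parameter: str,
                        grid: Sequence[float],
                        direction: str = "both",
                        fresh_multistarts: bool = True,
                        v_split: float = 0.5) -> Dict[str, BifurcationScan]:
    """Sweep a peer-influence parameter (f or eta) across a grid.

    Returns scans keyed by direction. In the bistable window the forward
    sweep (seeded from the low branch) and the backward sweep (seeded from
    the high branch) settle on different branches: hysteresis.
    """
    if parameter not in ("f", "eta"):
        raise ValueError("swept parameter must be 'f' or 'eta'")
    grid = np.asarray(grid, float)
    if not (np.diff(grid) > 0).all():
        raise ValueError("grid must be strictly increasing")
    out: Dict[str, BifurcationScan] = {}
    if direction in ("forward", "both"):
        scan = BifurcationScan(parameter, grid,
                               _track(params, parameter, grid,
                                      fresh_multistarts),
                               "forward", v_split=v_split)
        scan.classify()
        out["forward"] = scan
    if direction in ("backward", "both"):
        eqs = _track(params, parameter, grid[::-1], fresh_multistarts)
        scan = BifurcationScan(parameter, grid, eqs[::-1], "backward",
                               v_split=v_split)
        scan.classify()
        out["backward"] = scan
    return out


def _branch_exists(params: ModelParameters, parameter: str, x: float,
                   seed_state: np.ndarray, v_split: float = 0.5
                   ) -> Optional[np.ndarray]:
    """Root-find from ``seed_state``; return the root if it is a stable
    low-coverage equilibrium, else None."""
    p = params.replace(**{parameter: float(x)})
    try:
        eqs = find_equilibria(p, starts=[tuple(seed_state[:3])])
    except RuntimeError:
        return None
    for eq in eqs:
        if (eq.stability == "stable" and eq.v < v_split
                and np.abs(eq.state - seed_state).max() < 0.2):
            return eq.state
    return None


def fold_point(params: ModelParameters, parameter: str = "f",
               x_start: float = 1.0, x_max: float = 20.0,
               n_coarse: int = 400, tol: float = 1e-3,
               v_split: float = 0.5) -> Tuple[float, np.ndarray]:
    """Locate where the low-coverage stable branch disappears (saddle-node).

    Forward continuation on a coarse grid tracks the low branch until it
    ceases to exist; bisection between the last existing and first missing
    grid points refines the fold to ``tol`` in the swept parameter. Returns
    (fold location, last low-branch state).
    """
    grid = np.linspace(x_start, x_max, n_coarse)
    p0 = params.replace(**{parameter: float(grid[0])})
    eqs = find_equilibria(p0)
    lows = [eq for eq in eqs if eq.stability == "stable" and eq.v < v_split]
    if not lows:
        raise RuntimeError(
            f"no low-coverage stable branch at {parameter}={grid[0]}")
    state = lows[0].state
    x_last = grid[0]
    x_gone = None
    for x in grid[1:]:
        nxt = _branch_exists(params, parameter, x, state, v_split)
        if nxt is None:
            x_gone = x
            break
        state, x_last = nxt, x
    if x_gone is None:
        raise RuntimeError(
            f"low branch persists through {parameter}={x_max}; widen the scan")
    lo, hi = x_last, x_gone
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        nxt = _branch_exists(params, parameter, mid, state, v_split)
        if nxt is None:
            hi = mid
        else:
            state, lo = nxt, mid
    return 0.5 * (lo + hi), state


def phase_diagram(eta_grid: Sequence[float], f_grid: Sequence[float],
                  params: ModelParameters,
                  v_split: float = 0.5) -> "pd.DataFrame":
    """Regime classification over the eta-f plane.

    Each grid point is classified from its stable-equilibrium set:
    monostable-low, bistable, or monostable-high (high means a stable
    equilibrium with v >= v_split exists). Returns a tidy DataFrame with
    columns eta, f, regime, n_stable.
    """
    import pandas as pd
    eta_grid = np.asarray(eta_grid, float)
    f_grid = np.asarray(f_grid, float)
    for gname, gvals in (("eta", eta_grid), ("f", f_grid)):
        if not (np.diff(gvals) > 0).all():
            raise ValueError(f"{gname} grid must be strictly increasing")
    rows = []
    for eta in eta_grid:
        for fval in f_grid:
            p = params.replace(eta=float(eta), f=float(fval))
            eqs = find_equilibria(p)
            vs = [eq.v for eq in eqs if eq.stability == "stable"]
            high = any(v >= v_split for v in vs)
            low = any(v < v_split for v in vs)
            if high and low:
                regime = "bistable"
            elif high:
                regime = "monostable-high"
            else:
                regime = "monostable-low"
            rows.append({"eta": float(eta), "f": float(fval),
                         "regime": regime, "n_stable": len(vs)})
    return pd.DataFrame(rows)
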