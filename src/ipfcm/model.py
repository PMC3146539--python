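"""Mass-action kinetics of ZAP70 recruitment and phosphorylation at an
opposing-ITAM pair.

The model is a continuous-time Markov chain on the 28 symmetry-reduced pair
states (see :mod:`ipfcm.states`), written as a linear ODE for the occupancy
fractions x(t):

    dx/dt = (A_const + g(t) * A_deph) x,      sum(x) = 1,

where ``A_deph`` collects every dephosphorylation step (the rate constants
suppressed by pervanadate) and ``g(t)`` is the phosphatase-activity
multiplier.  Per-site reactions, each first-order with the active Lck and the
free-ZAP70 pools absorbed into the rate constants:

* ITAM phosphorylation by Lck: U → P1 at 2·k_itam_p, P1 → P2 at k_itam_p
  (the two ITAM tyrosines are identical and phosphorylated at random, hence
  the combinatorial factor 2); reverse dephosphorylation at k_itam_dp·g and
  2·k_itam_dp·g.
* ZAP70 binding to the doubly phosphorylated ITAM: P2 → Z at k_on; unbinding
  from any bound state (Z, Z319, Z319+493, Z493) → P2 at k_off, the leaving
  ZAP70 rejoining the constant (unphosphorylated) free pool.  k_off is not a
  dephosphorylation constant and is not modulated by g(t).
* Y319 (de)phosphorylation of bound ZAP70 by Lck: Z ↔ Z319 and
  Z493 ↔ Z319+493 at k_y319 / k_y319_dp·g.
* Y493 trans-autophosphorylation: Z319 → Z319+493 at k_y493, but only when
  the opposite ITAM also carries an opened (pY319) ZAP70 — this is the single
  pair-context-dependent reaction and the reason the model's unit is an ITAM
  pair.  Y493 dephosphorylation Z319+493 → Z319 and Z493 → Z at k_y493_dp·g.

Pervanadate is modelled as an instantaneous drop of g to ``f_min`` at each
dose, followed by exponential recovery with time constant ``tau_rec``
(phosphatase resynthesis).  Before the first dose the system sits in the
g ≡ 1 steady state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.integrate import odeint, solve_ivp

from .states import (
    N_PAIR,
    PAIR_INDEX,
    PAIR_STATES,
    PY319,
    PY493,
    ZAP_BOUND,
    ItamState,
    canonical_pair,
)

__all__ = [
    "RateParameters",
    "StimulationSchedule",
    "SimulationError",
    "phosphatase_activity",
    "build_rate_matrices",
    "derivative_field",
    "resting_steady_state",
    "simulate_timecourse",
    "compute_observables",
    "Trajectory",
]

#: Names of the free rate/scale parameters, in canonical order.
PARAM_NAMES = (
    "k_itam_p",
    "k_itam_dp",
    "k_on",
    "k_off",
    "k_y319",
    "k_y319_dp",
    "k_y493",
    "k_y493_dp",
    "f_min",
    "tau_rec",
    "s_Z",
    "s_pY",
)


class SimulationError(RuntimeError):
    """Raised when the ODE integrator or steady-state solver fails."""


@dataclass(frozen=True)
class RateParameters:
    """All rate constants of the ITAM-pair model (per minute) plus the
    pervanadate-inhibition and observable-scale parameters.

    Parameters
    ----------
    k_itam_p, k_itam_dp
        Per-site ITAM tyrosine phosphorylation (Lck activity absorbed) and
        dephosphorylation rates.
    k_on, k_off
        Pseudo-first-order ZAP70 binding (free-ZAP70 pool absorbed) and
        unbinding rates.
    k_y319, k_y319_dp
        Y319 phosphorylation by Lck and its dephosphorylation.
    k_y493, k_y493_dp
        Y493 trans-autophosphorylation (active only with an opened partner
        ZAP70) and its dephosphorylation.
    f_min
        Residual phosphatase activity fraction immediately after a
        pervanadate dose, in (0, 1].
    tau_rec
        Phosphatase-activity recovery time constant (minutes).
    s_Z, s_pY
        Scale factors mapping the bound-ZAP70 and bound-pY319 model fractions
        to arbitrary fluorescence-ratio units.

    The defaults are the package's reference parameter set, chosen to
    reproduce the characteristic pervanadate-response kinetics: bound ZAP70
    peaking near 10 min and its Y319 phosphorylation near 20 min, a transient
    early dip of the pY319/ZAP70 ratio below its resting value, and a small
    resting pool of phosphorylated bound ZAP70 (see docs/methods.md).
    """

    k_itam_p: float = 0.18
    k_itam_dp: float = 4.0
    k_on: float = 1.5
    k_off: float = 0.1
    k_y319: float = 0.035
    k_y319_dp: float = 0.15
    k_y493: float = 0.05
    k_y493_dp: float = 0.3
    f_min: float = 0.02
    tau_rec: float = 45.0
    s_Z: float = 1.0
    s_pY: float = 1.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES[:8]:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {v}")
        if not (0.0 < self.f_min <= 1.0):
            raise ValueError(f"f_min must lie in (0, 1], got {self.f_min}")
        if not self.tau_rec > 0:
            raise ValueError(f"tau_rec must be > 0, got {self.tau_rec}")
        if self.s_Z <= 0 or self.s_pY <= 0:
            raise ValueError("observable scales s_Z and s_pY must be > 0")

    def to_dict(self) -> Dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: Dict[str, float]) -> "RateParameters":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **changes: float) -> "RateParameters":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class StimulationSchedule:
    """Pervanadate dosing times (minutes) and the simulation horizon."""

    dose_times: Tuple[float, ...] = (0.0,)
    horizon: float = 60.0

    def __post_init__(self) -> None:
        doses = tuple(float(t) for t in self.dose_times)
        object.__setattr__(self, "dose_times", doses)
        if any(t < 0 for t in doses):
            raise ValueError("dose times must be non-negative")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("dose times must be strictly increasing")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")


def phosphatase_activity(
    t: float | np.ndarray,
    schedule: StimulationSchedule,
    f_min: float,
    tau_rec: float,
) -> float | np.ndarray:
    """Phosphatase-activity multiplier g(t) in (0, 1].

    Equals 1 before the first pervanadate dose.  At each dose the activity
    drops to ``f_min`` and then recovers exponentially,

        g(t) = f_min + (1 - f_min) * (1 - exp(-(t - t_dose)/tau_rec)),

    where ``t_dose`` is the most recent dose time; a later dose resets the
    recovery.
    """
    t_arr = np.asarray(t, dtype=float)
    g = np.ones_like(t_arr)
    for t_d in schedule.dose_times:
        after = t_arr >= t_d
        dt = t_arr - t_d
        g = np.where(after, f_min + (1.0 - f_min) * (-np.expm1(-dt / tau_rec)), g)
    return float(g) if np.isscalar(t) or t_arr.ndim == 0 else g


def _single_site_transitions(
    params: RateParameters,
) -> List[Tuple[ItamState, ItamState, float, bool]]:
    """Context-free per-site transitions as (src, dst, rate, is_dephos).

    The Y493 trans-autophosphorylation step (Z319 → Z319+493) is *not*
    listed here; it depends on the partner ITAM and is added at pair level.
    """
    p = params
    return [
        (ItamState.U, ItamState.P1, 2.0 * p.k_itam_p, False),
        (ItamState.P1, ItamState.U, 1.0 * p.k_itam_dp, True),
        (ItamState.P1, ItamState.P2, 1.0 * p.k_itam_p, False),
        (ItamState.P2, ItamState.P1, 2.0 * p.k_itam_dp, True),
        (ItamState.P2, ItamState.Z, p.k_on, False),
        (ItamState.Z, ItamState.P2, p.k_off, False),
        (ItamState.Z319, ItamState.P2, p.k_off, False),
        (ItamState.Z319_493, ItamState.P2, p.k_off, False),
        (ItamState.Z493, ItamState.P2, p.k_off, False),
        (ItamState.Z, ItamState.Z319, p.k_y319, False),
        (ItamState.Z319, ItamState.Z, p.k_y319_dp, True),
        (ItamState.Z493, ItamState.Z319_493, p.k_y319, False),
        (ItamState.Z319_493, ItamState.Z493, p.k_y319_dp, True),
        (ItamState.Z319_493, ItamState.Z319, p.k_y493_dp, True),
        (ItamState.Z493, ItamState.Z, p.k_y493_dp, True),
    ]


def build_rate_matrices(params: RateParameters) -> Tuple[np.ndarray, np.ndarray]:
    """Assemble the 28×28 generator split into its constant and
    phosphatase-modulated parts: A(t) = A_const + g(t)·A_deph.

    Within a pair state each ITAM reacts independently; a symmetric state
    (s, s) feeds (s', s) with a combinatorial factor 2 because either site
    can react.  The trans-autophosphorylation rate ``k_y493`` is applied to a
    site in Z319 only when its partner carries pY319 (Z319 or Z319+493).
    """
    a_const = np.zeros((N_PAIR, N_PAIR))
    a_deph = np.zeros((N_PAIR, N_PAIR))
    site_moves = _single_site_transitions(params)

    def add(mat: np.ndarray, i_src: int, i_dst: int, rate: float) -> None:
        mat[i_dst, i_src] += rate
        mat[i_src, i_src] -= rate

    for i, (s, t) in enumerate(PAIR_STATES):
        # reactions of each site; a symmetric state reacts once with factor 2
        if s == t:
            site_partner_mult = [(s, t, 2.0)]
        else:
            site_partner_mult = [(s, t, 1.0), (t, s, 1.0)]
        for site, partner, mult in site_partner_mult:
            for src, dst, rate, is_deph in site_moves:
                if site != src or rate == 0.0:
                    continue
                j = PAIR_INDEX[canonical_pair(dst, partner)]
                add(a_deph if is_deph else a_const, i, j, mult * rate)
            # pair-context reaction: Y493 trans-autophosphorylation
            if site == ItamState.Z319 and partner in PY319 and params.k_y493 > 0:
                j = PAIR_INDEX[canonical_pair(ItamState.Z319_493, partner)]
                add(a_const, i, j, mult * params.k_y493)
    return a_const, a_deph


def derivative_field(
    t: float,
    x: np.ndarray,
    params: RateParameters,
    schedule: StimulationSchedule,
    *,
    matrices: Tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-6,
) -> np.ndarray:
    """Time derivative dx/dt of the 28 pair-state occupancies.

    Raises
    ------
    ValueError
        If ``x`` has negative entries beyond ``tol`` or does not sum to 1
        within ``tol``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (N_PAIR,):
        raise ValueError(f"state vector must have {N_PAIR} entries, got {x.shape}")
    if np.min(x) < -tol:
        raise ValueError(f"negative occupancy {np.min(x):.3g} beyond tolerance {tol}")
    if abs(x.sum() - 1.0) > tol:
        raise ValueError(f"occupancies sum to {x.sum():.6f}, expected 1 ± {tol}")
    a_const, a_deph = matrices if matrices is not None else build_rate_matrices(params)
    g = phosphatase_activity(t, schedule, params.f_min, params.tau_rec)
    return (a_const + g * a_deph) @ x


def resting_steady_state(
    params: RateParameters,
    *,
    residual_tol: float = 1e-10,
) -> np.ndarray:
    """Occupancy vector of the unstimulated steady state (g ≡ 1).

    Solved as the normalized null vector of the full-activity generator;
    if the null space is not one-dimensional (degenerate rate sets) a
    long-time integration from the uniform distribution is used instead.

    Raises
    ------
    SimulationError
        If no probability vector with max-norm residual below
        ``residual_tol`` can be found.
    """
    a_const, a_deph = build_rate_matrices(params)
    a_full = a_const + a_deph
    x = None
    ns = linalg.null_space(a_full, rcond=1e-12)
    if ns.shape[1] == 1:
        v = ns[:, 0]
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        if v.sum() > 0:
            x = v / v.sum()
    if x is None or np.max(np.abs(a_full @ x)) > residual_tol:
        # degenerate or ill-conditioned: relax to equilibrium numerically
        x0 = np.full(N_PAIR, 1.0 / N_PAIR)
        sol = solve_ivp(
            lambda t, y: a_full @ y,
            (0.0, 1e6),
            x0,
            method="LSODA",
            jac=lambda t, y: a_full,
            rtol=1e-12,
            atol=1e-14,
        )
        if not sol.success:
            raise SimulationError(f"steady-state relaxation failed: {sol.message}")
        x = np.clip(sol.y[:, -1], 0.0, None)
        x = x / x.sum()
    residual = float(np.max(np.abs(a_full @ x)))
    if residual > residual_tol:
        raise SimulationError(
            f"steady state not converged: residual inf-norm {residual:.3e} "
            f"exceeds {residual_tol:.1e}"
        )
    return x


@dataclass(frozen=True)
class Trajectory:
    """Pair-state occupancies along a simulated time course."""

    times: np.ndarray  # minutes, shape (T,)
    states: np.ndarray  # occupancies, shape (T, 28)
    params: RateParameters
    schedule: StimulationSchedule
    #: largest |sum(x) - 1| seen before renormalization (conservation check)
    max_drift: float = 0.0

    def occupancy_frame(self) -> pd.DataFrame:
        """Long-format table (time_min, state, value)."""
        labels = [f"{s.name}|{t.name}" for s, t in PAIR_STATES]
        df = pd.DataFrame(self.states, columns=labels)
        df.insert(0, "time_min", self.times)
        return df.melt(id_vars="time_min", var_name="state", value_name="value")


def simulate_timecourse(
    params: RateParameters,
    schedule: StimulationSchedule,
    times: Sequence[float],
    *,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> Trajectory:
    """Integrate the pair-state ODE from the resting steady state.

    The integration restarts at every dose time (where g(t) is
    discontinuous), so stiff steps never straddle a dose.  Occupancies are
    renormalized only by clipping numerical negatives within tolerance.
    """
    t_eval = np.asarray(sorted(set(float(t) for t in times)), dtype=float)
    if t_eval.size == 0:
        raise ValueError("at least one output time is required")
    if np.any(t_eval < 0):
        raise ValueError("output times must be non-negative")

    a_const, a_deph = build_rate_matrices(params)
    x0 = resting_steady_state(params)

    # segment boundaries: 0, each dose, horizon end
    t_end = max(t_eval[-1], schedule.horizon)
    boundaries = [0.0] + [d for d in schedule.dose_times if 0.0 < d < t_end] + [t_end]

    def rhs(y: np.ndarray, t: float) -> np.ndarray:
        g = phosphatase_activity(t, schedule, params.f_min, params.tau_rec)
        return (a_const + g * a_deph) @ y

    def jac(y: np.ndarray, t: float) -> np.ndarray:
        g = phosphatase_activity(t, schedule, params.f_min, params.tau_rec)
        return a_const + g * a_deph

    out = np.empty((t_eval.size, N_PAIR))
    filled = np.zeros(t_eval.size, dtype=bool)
    # times exactly at segment starts take the incoming state
    x = x0
    for a, b in zip(boundaries, boundaries[1:]):
        at_start = np.isclose(t_eval, a) & ~filled
        out[at_start] = x
        filled |= at_start
        inside = (t_eval > a) & (t_eval <= b) & ~filled
        seg_times = t_eval[inside]
        eval_pts = np.unique(np.concatenate(([a], seg_times, [b])))
        with np.errstate(all="raise"):
            try:
                ys, info = odeint(
                    rhs,
                    x,
                    eval_pts,
                    Dfun=jac,
                    rtol=rtol,
                    atol=atol,
                    full_output=True,
                    mxstep=20000,
                )
            except FloatingPointError as exc:  # overflow inside lsoda
                raise SimulationError(f"integration failed on [{a}, {b}] min: {exc}")
        if info["message"] != "Integration successful.":
            raise SimulationError(
                f"integration failed on [{a}, {b}] min: {info['message']}"
            )
        for k, tt in zip(np.where(inside)[0], seg_times):
            out[k] = ys[np.searchsorted(eval_pts, tt)]
        filled[inside] = True
        x = ys[-1]
    out[~filled] = x  # times past the horizon (should not occur)

    drift = float(np.abs(out.sum(axis=1) - 1.0).max())
    if drift > 1e-6:
        raise SimulationError(f"probability drift {drift:.2e} exceeds tolerance")
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=1, keepdims=True)
    return Trajectory(
        times=t_eval, states=out, params=params, schedule=schedule, max_drift=drift
    )


def _pair_counts(members: frozenset) -> np.ndarray:
    """Expected ITAMs per pair state whose single-ITAM state is in ``members``."""
    return np.array(
        [(s in members) + (t in members) for s, t in PAIR_STATES], dtype=float
    )


_COUNT_BOUND = _pair_counts(ZAP_BOUND)
_COUNT_PY319 = _pair_counts(PY319)
_COUNT_PY493 = _pair_counts(PY493)


def compute_observables(trajectory: Trajectory) -> pd.DataFrame:
    """Experimental observables along a trajectory.

    Per time point (all "per ITAM pair" expectations):

    * ``bound_Z`` — ITAMs carrying ZAP70, scaled by ``s_Z`` (anti-ZAP70 stain
      normalized to CD3ε).
    * ``bound_pY319`` — ITAMs carrying pY319-ZAP70, scaled by ``s_pY``.
    * ``bound_pY493`` — ITAMs carrying pY493-ZAP70, unscaled (prediction
      channel; not measured in the fitting data).
    * ``ratio`` — bound_pY319 / bound_Z; NaN where bound_Z = 0.

    Returns a wide table with one row per time point.
    """
    p = trajectory.params
    z = trajectory.states @ _COUNT_BOUND
    py319 = trajectory.states @ _COUNT_PY319
    py493 = trajectory.states @ _COUNT_PY493
    bound_z = p.s_Z * z
    bound_py = p.s_pY * py319
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bound_z > 0, bound_py / bound_z, np.nan)
    return pd.DataFrame(
        {
            "time_min": trajectory.times,
            "bound_Z": bound_z,
            "bound_pY319": bound_py,
            "bound_pY493": py493,
            "ratio": ratio,
        }
    )
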