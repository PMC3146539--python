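"""Brute-force 49-ordered-state oracle for the opposing-ITAM pair model.

Deliberately independent of the package's 28-state implementation: states
are plain strings, the generator is assembled ordered-pair by ordered-pair
from the per-site reaction rules, and integration runs on the full 49-state
system.  Used to verify the symmetry-reduced model.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import odeint

SINGLE = ["U", "P1", "P2", "Z", "Z319", "Z3193", "Z493"]
ORDERED = [(a, b) for a in SINGLE for b in SINGLE]
IDX = {p: i for i, p in enumerate(ORDERED)}

BOUND = {"Z", "Z319", "Z3193", "Z493"}
HAS_PY319 = {"Z319", "Z3193"}
HAS_PY493 = {"Z3193", "Z493"}


def site_rates(state, partner, p):
    """(new_state, rate, needs_g) for one ITAM given its partner's state.

    ``p`` is a dict of rate constants; needs_g marks dephosphorylation steps
    multiplied by the phosphatase-activity function.
    """
    out = []
    if state == "U":
        out.append(("P1", 2.0 * p["k_itam_p"], False))
    elif state == "P1":
        out.append(("U", p["k_itam_dp"], True))
        out.append(("P2", p["k_itam_p"], False))
    elif state == "P2":
        out.append(("P1", 2.0 * p["k_itam_dp"], True))
        out.append(("Z", p["k_on"], False))
    elif state == "Z":
        out.append(("P2", p["k_off"], False))
        out.append(("Z319", p["k_y319"], False))
    elif state == "Z319":
        out.append(("P2", p["k_off"], False))
        out.append(("Z", p["k_y319_dp"], True))
        if partner in HAS_PY319:
            out.append(("Z3193", p["k_y493"], False))
    elif state == "Z3193":
        out.append(("P2", p["k_off"], False))
        out.append(("Z493", p["k_y319_dp"], True))
        out.append(("Z319", p["k_y493_dp"], True))
    elif state == "Z493":
        out.append(("P2", p["k_off"], False))
        out.append(("Z3193", p["k_y319"], False))
        out.append(("Z", p["k_y493_dp"], True))
    return out


def build_generators(p):
    """49x49 generator split into constant and g-modulated parts."""
    n = len(ORDERED)
    a_const = np.zeros((n, n))
    a_deph = np.zeros((n, n))
    for (a, b), i in IDX.items():
        for new_a, rate, needs_g in site_rates(a, b, p):
            j = IDX[(new_a, b)]
            m = a_deph if needs_g else a_const
            m[j, i] += rate
            m[i, i] -= rate
        for new_b, rate, needs_g in site_rates(b, a, p):
            j = IDX[(a, new_b)]
            m = a_deph if needs_g else a_const
            m[j, i] += rate
            m[i, i] -= rate
    return a_const, a_deph


def g_of_t(t, dose_times, f_min, tau_rec):
    g = 1.0
    for td in dose_times:
        if t >= td:
            g = f_min + (1.0 - f_min) * (1.0 - np.exp(-(t - td) / tau_rec))
    return g


def simulate_49(p, dose_times, times, x0_ordered, rtol=1e-10, atol=1e-13):
    """Integrate the ordered-pair system through each dosing segment."""
    a_const, a_deph = build_generators(p)

    def rhs(y, t):
        return (a_const + g_of_t(t, dose_times, p["f_min"], p["tau_rec"]) * a_deph) @ y

    def jac(y, t):
        return a_const + g_of_t(t, dose_times, p["f_min"], p["tau_rec"]) * a_deph

    times = np.asarray(sorted(set(times)), dtype=float)
    t_end = times[-1]
    bounds = [0.0] + [d for d in dose_times if 0.0 < d < t_end] + [t_end]
    out = np.empty((times.size, len(ORDERED)))
    x = np.asarray(x0_ordered, dtype=float)
    done = np.zeros(times.size, dtype=bool)
    for a, b in zip(bounds, bounds[1:]):
        sel = np.isclose(times, a) & ~done
        out[sel] = x
        done |= sel
        inside = (times > a) & (times <= b) & ~done
        pts = np.unique(np.concatenate(([a], times[inside], [b])))
        ys = odeint(rhs, x, pts, Dfun=jac, rtol=rtol, atol=atol, mxstep=50000)
        for k, tt in zip(np.where(inside)[0], times[inside]):
            out[k] = ys[np.searchsorted(pts, tt)]
        done[inside] = True
        x = ys[-1]
    out[~done] = x
    return times, out


def observables_49(states):
    """Expected bound-ZAP70 / pY319 / pY493 ITAM counts per pair."""
    z = np.array([(a in BOUND) + (b in BOUND) for a, b in ORDERED], float)
    p319 = np.array([(a in HAS_PY319) + (b in HAS_PY319) for a, b in ORDERED], float)
    p493 = np.array([(a in HAS_PY493) + (b in HAS_PY493) for a, b in ORDERED], float)
    return states @ z, states @ p319, states @ p493


def ordered_from_reduced(pairs, x_reduced):
    """Spread a 28-state occupancy onto ordered pairs (symmetric split)."""
    x49 = np.zeros(len(ORDERED))
    name = {"U": "U", "P1": "P1", "P2": "P2", "Z": "Z",
            "Z319": "Z319", "Z319_493": "Z3193", "Z493": "Z493"}
    for (s, t), v in zip(pairs, x_reduced):
        a, b = name[s.name], name[t.name]
        if a == b:
            x49[IDX[(a, b)]] += v
        else:
            x49[IDX[(a, b)]] += v / 2.0
            x49[IDX[(b, a)]] += v / 2.0
    return x49


def reduced_from_ordered(pairs, x49):
    """Aggregate ordered-pair occupancies onto the 28 unordered states."""
    name = {"U": "U", "P1": "P1", "P2": "P2", "Z": "Z",
            "Z319": "Z319", "Z319_493": "Z3193", "Z493": "Z493"}
    out = np.zeros(len(pairs))
    for i, (s, t) in enumerate(pairs):
        a, b = name[s.name], name[t.name]
        if a == b:
            out[i] = x49[IDX[(a, b)]]
        else:
            out[i] = x49[IDX[(a, b)]] + x49[IDX[(b, a)]]
    return out
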