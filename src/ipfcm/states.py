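"""State space of the opposing-ITAM pair.

Each ITAM (a CD3/ζ motif with two tyrosines) is in one of seven states that
record its own phosphorylation, ZAP70 occupancy and the modification state of
the bound ZAP70:

====== =======================================================================
state  meaning
====== =======================================================================
U      both ITAM tyrosines unphosphorylated
P1     exactly one ITAM tyrosine phosphorylated
P2     both ITAM tyrosines phosphorylated, no ZAP70 bound
Z      ZAP70 bound (tandem-SH2 docking requires the doubly phosphorylated
       ITAM), ZAP70 itself unphosphorylated
Z319   bound ZAP70 phosphorylated at Y319 (interdomain B, opened conformation)
Z3193  bound ZAP70 phosphorylated at both Y319 and Y493
Z493   bound ZAP70 phosphorylated at Y493 only (Y319 has been removed)
====== =======================================================================

The mechanistic unit is a *pair* of opposing ITAMs, because Y493
trans-autophosphorylation needs two juxtaposed, opened (pY319) ZAP70
molecules.  An ordered pair has 7 × 7 = 49 configurations; because the two
ITAMs are physically indistinguishable the dynamics close on the 28 unordered
pairs {(s, t): s ≤ t} = 7 + C(7, 2).
"""

from __future__ import annotations

import enum
import itertools
from typing import Dict, List, Tuple


class ItamState(enum.IntEnum):
    """The seven states of a single ITAM with respect to tyrosine
    phosphorylation, ZAP70 recruitment and ZAP70 modification."""

    U = 0
    P1 = 1
    P2 = 2
    Z = 3
    Z319 = 4
    Z319_493 = 5
    Z493 = 6


#: ITAM states that carry a bound ZAP70 molecule.
ZAP_BOUND = frozenset({ItamState.Z, ItamState.Z319, ItamState.Z319_493, ItamState.Z493})
#: Bound ZAP70 with phosphorylated Y319 (the "opened" conformation).
PY319 = frozenset({ItamState.Z319, ItamState.Z319_493})
#: Bound ZAP70 with phosphorylated Y493 (activation loop).
PY493 = frozenset({ItamState.Z319_493, ItamState.Z493})

N_SINGLE = len(ItamState)

PairKey = Tuple[ItamState, ItamState]


def canonical_pair(s: ItamState, t: ItamState) -> PairKey:
    """Unordered representative of an ordered ITAM pair (s, t)."""
    return (s, t) if s <= t else (t, s)


def enumerate_pair_states() -> Tuple[List[PairKey], Dict[PairKey, int]]:
    """Enumerate the symmetry-reduced pair state space.

    Returns
    -------
    pairs
        The 28 canonical unordered pairs ``{(s, t): s <= t}`` in a fixed
        deterministic order (lexicographic in the single-ITAM enumeration).
    ordered_index
        Mapping from each of the 49 ordered pairs to the index of its
        unordered representative in ``pairs``.
    """
    pairs = [
        (s, t)
        for s, t in itertools.combinations_with_replacement(ItamState, 2)
    ]
    pos = {p: i for i, p in enumerate(pairs)}
    ordered_index = {
        (s, t): pos[canonical_pair(s, t)]
        for s in ItamState
        for t in ItamState
    }
    return pairs, ordered_index


PAIR_STATES, ORDERED_TO_REDUCED = enumerate_pair_states()
N_PAIR = len(PAIR_STATES)
PAIR_INDEX: Dict[PairKey, int] = {p: i for i, p in enumerate(PAIR_STATES)}


def pair_label(pair: PairKey) -> str:
    """Human-readable label, e.g. ``'Z319|P2'``."""
    return f"{pair[0].name}|{pair[1].name}"
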