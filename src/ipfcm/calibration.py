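"""Absolute quantification with a PE calibration-bead ladder.

A ladder of beads carrying known numbers of PE fluorophores (the assay uses
515, 5956, 26653 and 69045 molecules per bead) yields a log–log standard
curve from measured MFI to molecules per bead.  With saturating one-PE-per-
antibody staining, molecules per bead equal stained protein copies per bead,
which converts relative fluorescence into absolute stoichiometries such as
ZAP70 molecules per TCR-CD3 complex (two CD3ε subunits per complex) and the
percentage of ZAP70 phosphorylated at Y319.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "StandardCurve",
    "CalibrationCurve",
    "MoleculeCount",
    "QUANTIBRITE_LADDER",
    "fit_standard_curve",
    "mfi_to_molecules",
    "molecules_per_complex",
    "phospho_fraction",
]

#: Nominal PE molecules per bead of the four-rung calibration ladder.
QUANTIBRITE_LADDER = (515, 5956, 26653, 69045)


@dataclass(frozen=True)
class MoleculeCount:
    """Absolute molecules per bead with a standard error."""

    molecules_per_bead: float
    sem: float = 0.0

    def __post_init__(self) -> None:
        if self.molecules_per_bead < 0 or self.sem < 0:
            raise ValueError("molecule counts and sems must be >= 0")

    def __float__(self) -> float:
        return float(self.molecules_per_bead)


@dataclass(frozen=True)
class Measurement:
    """A derived quantity with a delta-method propagated standard error."""

    value: float
    sem: float = 0.0
    flag: Optional[str] = None

    def __float__(self) -> float:
        return float(self.value)


class StandardCurve(RegressorMixin, BaseEstimator):
    """Log–log least-squares standard curve from MFI to molecules per bead.

    Ordinary least squares of log10(molecules) on log10(MFI) — i.e. the
    regression predicts molecules from a measured MFI.  Follows the sklearn
    estimator protocol: :meth:`fit` sets ``slope_``, ``intercept_``, ``r_``
    and ``n_points_``; :meth:`predict` maps net MFIs to molecule counts.

    Parameters
    ----------
    labelling_efficiency : float, default 1.0
        Fluorophores per staining antibody; predicted molecule counts are
        divided by this factor.
    """

    def __init__(self, labelling_efficiency: float = 1.0):
        self.labelling_efficiency = labelling_efficiency

    def fit(self, mfis: Sequence[float], molecules: Sequence[float]) -> "StandardCurve":
        if self.labelling_efficiency <= 0:
            raise ValueError("labelling_efficiency must be > 0")
        x = np.asarray(list(mfis), dtype=float)
        y = np.asarray(list(molecules), dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("ladder MFIs and molecule counts must be equal-length 1-d")
        if x.size < 2:
            raise ValueError("standard curve needs at least two ladder points")
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("ladder MFIs and molecule counts must all be > 0")
        lx, ly = np.log10(x), np.log10(y)
        if np.ptp(lx) == 0:
            raise ValueError("degenerate ladder: identical MFIs for different rungs")
        res = stats.linregress(lx, ly)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        # with exactly 2 points the line is exact by construction
        self.r_ = float(res.rvalue) if x.size > 2 else float(np.sign(res.slope))
        self.n_points_ = int(x.size)
        if self.slope_ <= 0:
            raise ValueError("invalid ladder: standard curve is not increasing")
        return self

    def predict(self, mfis: Union[float, Sequence[float]]) -> Union[float, np.ndarray]:
        """Molecules per bead for one or more net MFIs."""
        x = np.asarray(mfis, dtype=float)
        if np.any(x <= 0):
            raise ValueError("cannot calibrate non-positive net MFI")
        mol = 10.0 ** (self.slope_ * np.log10(x) + self.intercept_)
        mol = mol / self.labelling_efficiency
        return float(mol) if np.isscalar(mfis) else mol


#: Back-compat alias matching the domain name of the fitted object.
CalibrationCurve = StandardCurve


def fit_standard_curve(
    ladder_mfis: Sequence[float],
    ladder_molecules: Sequence[float] = QUANTIBRITE_LADDER,
) -> StandardCurve:
    """Fit the log–log standard curve (thin wrapper over StandardCurve)."""
    return StandardCurve().fit(ladder_mfis, ladder_molecules)


def mfi_to_molecules(
    curve: StandardCurve,
    net_mfi: float,
    sem: float = 0.0,
) -> MoleculeCount:
    """Convert a background-subtracted MFI to absolute molecules per bead.

    The MFI's standard error, when given, is propagated through the power-law
    curve by the delta method.
    """
    if net_mfi <= 0:
        raise ValueError("cannot calibrate a zero or negative net MFI")
    mol = curve.predict(net_mfi)
    # d(mol)/d(mfi) = slope * mol / mfi for the log-log line
    mol_sem = abs(curve.slope_) * mol / net_mfi * sem
    return MoleculeCount(molecules_per_bead=mol, sem=mol_sem)


def _as_count(x: Union[MoleculeCount, float]) -> MoleculeCount:
    return x if isinstance(x, MoleculeCount) else MoleculeCount(float(x))


def molecules_per_complex(
    target: Union[MoleculeCount, float],
    reference_subunit: Union[MoleculeCount, float],
    copies_per_complex: int = 2,
) -> Measurement:
    """Target molecules per receptor complex.

    The reference subunit count divided by its copies per complex estimates
    complexes per bead; the result is target / complexes.  With CD3ε as the
    reference and 2 copies per TCR-CD3, 5300 ZAP70 over 16000 CD3ε gives
    0.6625 ZAP70 per complex.
    """
    t, ref = _as_count(target), _as_count(reference_subunit)
    if copies_per_complex < 1:
        raise ValueError("copies_per_complex must be >= 1")
    if ref.molecules_per_bead <= 0:
        raise ValueError("reference subunit count must be > 0")
    value = t.molecules_per_bead / (ref.molecules_per_bead / copies_per_complex)
    if t.molecules_per_bead == 0:
        return Measurement(0.0, 0.0)
    rel = math.hypot(
        t.sem / t.molecules_per_bead, ref.sem / ref.molecules_per_bead
    )
    return Measurement(value=value, sem=value * rel)


def phospho_fraction(
    phospho: Union[MoleculeCount, float],
    total: Union[MoleculeCount, float],
) -> Measurement:
    """Percentage of target molecules carrying the phosphorylation.

    A phospho count exceeding the total is flagged (staining antibodies can
    differ in efficiency) but not fatal.
    """
    p, tot = _as_count(phospho), _as_count(total)
    if tot.molecules_per_bead <= 0:
        raise ValueError("total molecule count must be > 0")
    value = 100.0 * p.molecules_per_bead / tot.molecules_per_bead
    flag = "phospho exceeds total" if p.molecules_per_bead > tot.molecules_per_bead else None
    if p.molecules_per_bead == 0:
        return Measurement(0.0, 0.0, flag)
    rel = math.hypot(p.sem / p.molecules_per_bead, tot.sem / tot.molecules_per_bead)
    return Measurement(value=value, sem=value * rel, flag=flag)
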