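"""Synthetic bead-assay and kinetic data with known ground truth.

Emulates the inputs of the quantification pipeline: lognormal bead
fluorescence populations over an autofluorescent background, two-plex
mixtures of small and large beads separable by scatter, the four-rung PE
calibration ladder, and noisy kinetic time courses drawn from the ITAM-pair
model.  Every generator takes an explicit seed and is byte-reproducible.

The multiplicative replicate noise default (5 %cv) sits inside the 4.0–7.2
%cv range observed for the bead immunoassay; lognormal noise keeps the
strictly positive, scale-free character of fluorescence ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .fitting import TimeCourseDataset
from .model import RateParameters, StimulationSchedule, compute_observables, simulate_timecourse
from .quant import BeadEventTable

__all__ = [
    "BeadPopulationSpec",
    "KineticNoiseSpec",
    "DEFAULT_TIMES",
    "gen_bead_events",
    "gen_control_events",
    "gen_two_plex_events",
    "gen_quantibrite_set",
    "gen_kinetic_dataset",
]

#: Default sampling grid (minutes) for kinetic experiments.
DEFAULT_TIMES = (0.0, 2.0, 5.0, 10.0, 20.0, 60.0)


def _sigma_from_cv(cv: float) -> float:
    """Log-space sd of a lognormal with the given coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv))


@dataclass(frozen=True)
class BeadPopulationSpec:
    """One lognormal bead population.

    Fluorescence per channel is a background draw plus a signal draw, both
    lognormal; ``channel_geo_cv`` is the geometric coefficient of variation
    as a fraction (log-sd = sqrt(ln(1 + cv^2))).  Scatter is Gaussian around
    ``scatter_center`` with sd = ``scatter_cv`` × center.
    """

    n_events: int
    channel_geo_means: Mapping[str, float]
    channel_geo_cv: float = 0.3
    background_geo_mean: Union[float, Mapping[str, float]] = 0.0
    scatter_center: Tuple[float, float] = (200.0, 150.0)
    scatter_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if not self.channel_geo_means:
            raise ValueError("at least one fluorescence channel is required")
        for ch, m in self.channel_geo_means.items():
            if m <= 0:
                raise ValueError(f"geometric mean of channel {ch!r} must be > 0, got {m}")
        if self.channel_geo_cv < 0:
            raise ValueError("channel_geo_cv must be >= 0")
        for ch, b in self._backgrounds().items():
            if b < 0:
                raise ValueError(f"background of channel {ch!r} must be >= 0")
        if self.scatter_cv < 0:
            raise ValueError("scatter_cv must be >= 0")

    def _backgrounds(self) -> Dict[str, float]:
        if isinstance(self.background_geo_mean, Mapping):
            return {ch: float(self.background_geo_mean.get(ch, 0.0)) for ch in self.channel_geo_means}
        return {ch: float(self.background_geo_mean) for ch in self.channel_geo_means}

    def scatter_sd(self) -> Tuple[float, float]:
        return (
            self.scatter_cv * self.scatter_center[0],
            self.scatter_cv * self.scatter_center[1],
        )


@dataclass(frozen=True)
class KineticNoiseSpec:
    """Replicate structure and multiplicative noise of a kinetic dataset."""

    replicate_count: int = 3
    noise_cv_percent: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if self.noise_cv_percent < 0:
            raise ValueError("noise_cv_percent must be >= 0")


def _draw_population(spec: BeadPopulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_events
    sd_f, sd_s = spec.scatter_sd()
    cols: Dict[str, np.ndarray] = {
        "fsc": rng.normal(spec.scatter_center[0], sd_f, n),
        "ssc": rng.normal(spec.scatter_center[1], sd_s, n),
    }
    sigma = _sigma_from_cv(spec.channel_geo_cv)
    backgrounds = spec._backgrounds()
    for ch, m in spec.channel_geo_means.items():
        signal = m * np.exp(rng.normal(0.0, sigma, n)) if sigma > 0 else np.full(n, m)
        b = backgrounds[ch]
        if b > 0:
            bg = b * np.exp(rng.normal(0.0, sigma, n)) if sigma > 0 else np.full(n, b)
        else:
            bg = np.zeros(n)
        cols[ch] = signal + bg
    return pd.DataFrame(cols)


def gen_bead_events(spec: BeadPopulationSpec) -> BeadEventTable:
    """Generate one bead population as an event table.

    Each fluorescence value is a lognormal background draw plus a lognormal
    signal draw with the specified geometric parameters.
    """
    if spec.n_events < 1:
        raise ValueError("n_events must be >= 1 for a single population")
    rng = np.random.default_rng(spec.seed)
    return BeadEventTable(events=_draw_population(spec, rng), metadata={"seed": spec.seed})


def gen_control_events(spec: BeadPopulationSpec) -> BeadEventTable:
    """Matching uncoupled-bead control: autofluorescent background only.

    Channels whose background is zero get a degenerate near-zero floor so
    the control table remains a valid event table.
    """
    backgrounds = {ch: max(b, 1e-12) for ch, b in spec._backgrounds().items()}
    control = BeadPopulationSpec(
        n_events=spec.n_events,
        channel_geo_means=backgrounds,
        channel_geo_cv=spec.channel_geo_cv,
        background_geo_mean=0.0,
        scatter_center=spec.scatter_center,
        scatter_cv=spec.scatter_cv,
        seed=spec.seed + 1,
    )
    table = gen_bead_events(control)
    table.metadata["control"] = True
    return table


def gen_two_plex_events(
    spec_small: BeadPopulationSpec,
    spec_large: BeadPopulationSpec,
) -> BeadEventTable:
    """Mixture of two bead sizes with ground-truth population labels.

    The two populations must be separable by forward scatter; if the center
    separation is at most 4 combined scatter standard deviations a warning
    is recorded in the output metadata (``separation_warning``).
    """
    sep = abs(spec_small.scatter_center[0] - spec_large.scatter_center[0])
    combined_sd = spec_small.scatter_sd()[0] + spec_large.scatter_sd()[0]
    warn = sep <= 4.0 * combined_sd

    channels = sorted(set(spec_small.channel_geo_means) | set(spec_large.channel_geo_means))
    frames = []
    for label, spec in (("small", spec_small), ("large", spec_large)):
        if spec.n_events == 0:
            continue
        rng = np.random.default_rng(spec.seed)
        df = _draw_population(spec, rng)
        for ch in channels:
            if ch not in df.columns:
                df[ch] = 0.0
        df["population"] = label
        frames.append(df[["fsc", "ssc", *channels, "population"]])
    if not frames:
        raise ValueError("both populations are empty")
    events = pd.concat(frames, ignore_index=True)
    meta: Dict[str, object] = {"separation_sds": sep / combined_sd if combined_sd > 0 else math.inf}
    if warn:
        meta["separation_warning"] = (
            f"scatter separation {sep:.1f} is below 4 combined sds ({4 * combined_sd:.1f})"
        )
    return BeadEventTable(events=events, metadata=meta)


def gen_quantibrite_set(
    molecules_per_bead: Sequence[float] = (515, 5956, 26653, 69045),
    gain: float = 1.0,
    n_per_population: int = 2000,
    sigma: float = 0.3,
    seed: int = 0,
) -> BeadEventTable:
    """Calibration-bead ladder: one lognormal population per rung.

    Each rung's PE channel has geometric mean ``gain × molecules`` and
    log-space sd ``sigma``; rung labels are stored in the ``population``
    column as the nominal molecule count.
    """
    if len(molecules_per_bead) == 0:
        raise ValueError("calibration ladder must contain at least one rung")
    if any(m <= 0 for m in molecules_per_bead):
        raise ValueError("ladder molecule counts must be > 0")
    if gain <= 0:
        raise ValueError("gain must be > 0")
    if n_per_population < 1:
        raise ValueError("n_per_population must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for mol in molecules_per_bead:
        n = n_per_population
        geo = gain * mol
        pe = geo * np.exp(rng.normal(0.0, sigma, n)) if sigma > 0 else np.full(n, geo)
        frames.append(
            pd.DataFrame(
                {
                    "fsc": rng.normal(300.0, 9.0, n),
                    "ssc": rng.normal(200.0, 6.0, n),
                    "PE": pe,
                    "population": int(mol),
                }
            )
        )
    events = pd.concat(frames, ignore_index=True)
    return BeadEventTable(
        events=events,
        metadata={"ladder": tuple(molecules_per_bead), "gain": gain, "seed": seed},
    )


def gen_kinetic_dataset(
    true_params: RateParameters,
    schedule: StimulationSchedule = StimulationSchedule(),
    times: Sequence[float] = DEFAULT_TIMES,
    noise: KineticNoiseSpec = KineticNoiseSpec(),
) -> TimeCourseDataset:
    """Noisy replicated time course drawn from the ITAM-pair model.

    Observations are the scaled bound-ZAP70 and bound-pY319 observables
    multiplied by per-observation lognormal noise of the stated %cv.  The
    generating parameters are stored on the dataset as ground truth.
    """
    times = [float(t) for t in times]
    if any(t < 0 for t in times):
        raise ValueError("times must be non-negative")
    traj = simulate_timecourse(true_params, schedule, times)
    obs = compute_observables(traj)
    sigma = _sigma_from_cv(noise.noise_cv_percent / 100.0)
    rng = np.random.default_rng(noise.seed)
    rows = []
    for name in ("bound_Z", "bound_pY319"):
        for t, v in zip(obs["time_min"], obs[name]):
            for rep in range(1, noise.replicate_count + 1):
                factor = math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                rows.append((t, name, rep, v * factor))
    data = pd.DataFrame(rows, columns=["time_min", "observable", "replicate", "value"])
    return TimeCourseDataset(data=data, true_params=true_params, schedule=schedule)
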