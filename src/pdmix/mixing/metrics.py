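"""Danckwerts intensity-of-segregation mixing efficiency along the channel.

A cross-section normal to the main flow direction is sampled on a uniform
grid of points (50 by default, mirroring the cross-section grid used for the
3-D device model; in this planar solver the section is a line).  The mixing
efficiency at a station is

    ME = (1 - sigma^2 / sigma0^2) * 100%

where sigma^2 is the concentration variance over the section samples and
sigma0^2 is the fully-segregated reference variance.  The reference is the
variance of a binary (0/1) section with the same mean composition,
cbar (1 - cbar): this equals p (1 - p) with p = 1/(1 + FRR) downstream of
the inlet merge and guarantees ME in [0, 100] for any field bounded in
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .transport import TransportField

__all__ = [
    "MixingUndefinedError",
    "MixingProfile",
    "ThresholdCrossing",
    "mixing_profile",
    "distance_to_threshold",
    "transverse_nonuniformity",
]


class MixingUndefinedError(ValueError):
    """The segregated reference variance vanishes (single-stream inlet)."""


@dataclass
class MixingProfile:
    """Per-station mixing statistics.

    ``table`` columns: station (1-based), x_mm, mean_c, sigma2, sigma0_sq,
    me_percent.
    """

    table: pd.DataFrame
    n_samples: int
    frr: float

    @property
    def me(self) -> np.ndarray:
        return self.table["me_percent"].to_numpy()

    @property
    def x_mm(self) -> np.ndarray:
        return self.table["x_mm"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _section_samples(field: TransportField, i: int, n_samples: int) -> np.ndarray:
    """Concentration resampled at ``n_samples`` uniform points across the
    fluid extent of grid column ``i``."""
    grid = field.grid
    col = field.c[i]
    mask = grid.fluid[i]
    if not mask.any():
        raise ValueError(f"column {i} holds no fluid cells")
    y = grid.y[mask]
    c = col[mask]
    if len(c) == 1:
        return np.full(n_samples, c[0])
    ys = np.linspace(y[0], y[-1], n_samples)
    return np.interp(ys, y, c)


def mixing_profile(
    field: TransportField,
    n_stations: int = 10,
    n_samples: int = 50,
) -> MixingProfile:
    """Mixing efficiency at evenly spaced stations along the channel.

    Stations sit at fractions 1/S .. S/S of the channel length (the last
    station is the outlet column).  Raises
    :class:`MixingUndefinedError` when the nominal segregated variance
    p(1-p), p = 1/(1+FRR), vanishes.
    """
    grid = field.grid
    p = 1.0 / (1.0 + field.frr)
    if p * (1.0 - p) <= 0:
        raise MixingUndefinedError("segregated reference variance is zero")
    rows = []
    for s in range(1, n_stations + 1):
        i = min(int(round(s / n_stations * grid.nx)) - 1, grid.nx - 1)
        samples = _section_samples(field, i, n_samples)
        mean_c = float(samples.mean())
        sigma2 = float(samples.var())
        sigma0 = mean_c * (1.0 - mean_c)
        if sigma0 <= 0:
            # fully flushed single-composition section: call it fully mixed
            me = 100.0 if sigma2 == 0 else 0.0
        else:
            me = float(np.clip((1.0 - sigma2 / sigma0) * 100.0, 0.0, 100.0))
        rows.append((s, grid.x[i] * 1e3, mean_c, sigma2, sigma0, me))
    table = pd.DataFrame(
        rows,
        columns=["station", "x_mm", "mean_c", "sigma2", "sigma0_sq",
                 "me_percent"],
    )
    return MixingProfile(table=table, n_samples=n_samples, frr=field.frr)


class ThresholdCrossing(NamedTuple):
    distance_mm: float
    censored: bool


def distance_to_threshold(
    profile: MixingProfile, threshold: float = 90.0
) -> ThresholdCrossing:
    """Path distance at which the profile first reaches ``threshold`` % ME.

    Linear interpolation between the bracketing stations (or from the
    channel start, where ME is 0 for segregated inlets).  A profile that
    never reaches the threshold returns a censored result, not an error.
    """
    x = profile.x_mm
    me = profile.me
    above = np.nonzero(me >= threshold)[0]
    if len(above) == 0:
        return ThresholdCrossing(float(x[-1]), True)
    k = above[0]
    x0, me0 = (0.0, 0.0) if k == 0 else (x[k - 1], me[k - 1])
    if me[k] == me0:
        return ThresholdCrossing(float(x[k]), False)
    frac = (threshold - me0) / (me[k] - me0)
    return ThresholdCrossing(float(x0 + frac * (x[k] - x0)), False)


def transverse_nonuniformity(
    field: TransportField, station_x_mm: float, n_samples: int = 50
) -> float:
    """Coefficient of variation of the section samples at a given station.

    A scalar summary of how non-uniform the transverse concentration
    profile is; larger values mean a more skewed profile.
    """
    grid = field.grid
    i = int(np.clip(round(station_x_mm * 1e-3 / grid.h - 0.5), 0, grid.nx - 1))
    samples = _section_samples(field, i, n_samples)
    mean = samples.mean()
    if mean == 0:
        raise ValueError("mean concentration is zero at this station")
    return float(samples.std() / mean)
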