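"""Central-composite rotatable designs and inlet flow arithmetic.

The study design behind this package is a two-factor Central Composite
Rotatable design in the flow-rate ratio FRR (aqueous/organic, dimensionless)
and the total flow rate TFR (mL/h): 2^k factorial ("cube") points, 2k axial
points at coded distance alpha = (2^k)^(1/4) and a replicated centre point.
The stated factor extremes are interpreted as the *axial* positions, so cube
levels sit at ``centre +/- half_range / alpha``; this is the convention that
reproduces the packaged 29-run data set (cube FRR levels 2.6 and 10.4).

Natural factor settings are rounded to the pump-realizable resolution
(1 decimal by default) before they are stored, so all downstream fitting
uses the settings the pumps actually delivered.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignSpec",
    "FlowPair",
    "compute_alpha",
    "build_cccr_design",
    "coded_to_natural",
    "natural_to_coded",
    "split_flows",
    "flows_to_tfr_frr",
    "randomize_run_order",
    "default_study_design",
    "RESPONSE_COLUMNS",
]

#: Response columns carried by every run table (missing until measured).
RESPONSE_COLUMNS = ("z_average_nm", "pdi", "zeta_mv")


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its axial extremes in natural units."""

    name: str
    low_extreme: float
    high_extreme: float
    decimals: int = 1

    def __post_init__(self) -> None:
        if not self.low_extreme < self.high_extreme:
            raise ValueError(
                f"factor {self.name!r}: low_extreme must be < high_extreme"
            )
        if self.decimals < 0:
            raise ValueError(f"factor {self.name!r}: decimals must be >= 0")

    @property
    def center(self) -> float:
        return 0.5 * (self.low_extreme + self.high_extreme)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high_extreme - self.low_extreme)


@dataclass(frozen=True)
class DesignSpec:
    """Central composite rotatable design specification.

    ``alpha`` defaults to the rotatable value (2^k)^(1/4); it is kept at
    full precision internally and only rounded for display.
    """

    factors: tuple[FactorSpec, ...]
    alpha: float | None = None
    cube_reps: int = 1
    axial_reps: int = 1
    center_reps: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        if len(self.factors) < 1:
            raise ValueError("at least one factor required")
        for reps in (self.cube_reps, self.axial_reps, self.center_reps):
            if reps < 1:
                raise ValueError("replicate counts must be >= 1")
        if self.alpha is None:
            object.__setattr__(self, "alpha", compute_alpha(self.k))
        elif self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        k = self.k
        return 2 * k * self.axial_reps + 2**k * self.cube_reps + self.center_reps


@dataclass(frozen=True)
class FlowPair:
    """Aqueous / organic inlet flow rates (mL/h)."""

    q_as: float
    q_os: float

    @property
    def tfr(self) -> float:
        return self.q_as + self.q_os

    @property
    def frr(self) -> float:
        return self.q_as / self.q_os


def compute_alpha(k: int) -> float:
    """Coded axial distance of a rotatable central composite design.

    alpha = (2^k)^(1/4); for two factors this is sqrt(2) ~ 1.41.
    """
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool) or k < 1:
        raise ValueError(f"k must be an integer >= 1, got {k!r}")
    return float((2.0**k) ** 0.25)


def coded_to_natural(coded: Sequence[float], spec: DesignSpec) -> np.ndarray:
    """Map coded coordinates to natural units, rounded per factor.

    Natural = centre + coded * (half_axial_range / alpha): coded ``+/-alpha``
    lands exactly on the stated factor extremes.
    """
    coded = np.asarray(coded, dtype=float)
    out = np.empty_like(coded)
    for i, f in enumerate(spec.factors):
        scale = f.half_range / spec.alpha
        out[..., i] = np.round(f.center + coded[..., i] * scale, f.decimals)
    return out


def natural_to_coded(natural: Sequence[float], spec: DesignSpec) -> np.ndarray:
    """Exact inverse of the coded->natural map (before rounding)."""
    natural = np.asarray(natural, dtype=float)
    out = np.empty_like(natural)
    for i, f in enumerate(spec.factors):
        scale = f.half_range / spec.alpha
        out[..., i] = (natural[..., i] - f.center) / scale
    return out


def _design_points(spec: DesignSpec) -> np.ndarray:
    """Coded design points with replication, in build order."""
    k = spec.k
    rows: list[np.ndarray] = []
    for signs in itertools.product((-1.0, 1.0), repeat=k):
        rows.extend([np.array(signs)] * spec.cube_reps)
    for axis in range(k):
        for sign in (-1.0, 1.0):
            pt = np.zeros(k)
            pt[axis] = sign * spec.alpha
            rows.extend([pt] * spec.axial_reps)
    rows.extend([np.zeros(k)] * spec.center_reps)
    return np.vstack(rows)


def build_cccr_design(spec: DesignSpec) -> pd.DataFrame:
    """Build the replicated central composite design as a run table.

    Returns a DataFrame with columns ``run_order``, one natural and one
    ``<name>_coded`` column per factor, and empty response columns.  The run
    order is a seeded uniform random permutation (``spec.seed``); rows are
    returned sorted by run order.
    """
    coded = _design_points(spec)
    natural = coded_to_natural(coded, spec)
    n = len(coded)
    df = pd.DataFrame({"run_order": np.arange(1, n + 1)})
    for i, f in enumerate(spec.factors):
        df[f.name] = natural[:, i]
        df[f"{f.name}_coded"] = coded[:, i]
    for col in RESPONSE_COLUMNS:
        df[col] = np.nan
    return randomize_run_order(df, seed=spec.seed)


def randomize_run_order(table: pd.DataFrame, seed: int | None = None) -> pd.DataFrame:
    """Assign a fresh random run order (uniform permutation) and sort by it."""
    if len(table) == 0:
        raise ValueError("run table is empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table)) + 1
    out = table.copy()
    out["run_order"] = perm
    return out.sort_values("run_order", ignore_index=True)


def split_flows(tfr: float, frr: float) -> FlowPair:
    """Split a total flow rate into aqueous and organic inlet flows.

    Q_as = FRR*TFR/(1+FRR), Q_os = TFR/(1+FRR); the pair sums to TFR and
    has ratio Q_as/Q_os = FRR.
    """
    if tfr <= 0 or frr <= 0:
        raise ValueError("TFR and FRR must be positive")
    q_os = tfr / (1.0 + frr)
    return FlowPair(q_as=frr * q_os, q_os=q_os)


def flows_to_tfr_frr(flows: FlowPair) -> tuple[float, float]:
    """Inverse of :func:`split_flows`."""
    return flows.tfr, flows.frr


def default_study_design(seed: int | None = 0) -> DesignSpec:
    """The 29-run liposome study design shipped with this package.

    FRR spans 1.0-12.0 and TFR 3.0-18.0 mL/h (axial extremes), with 3
    replicates per cube and axial point and 5 centre replicates.
    """
    return DesignSpec(
        factors=(
            FactorSpec("frr", 1.0, 12.0, decimals=1),
            FactorSpec("tfr", 3.0, 18.0, decimals=1),
        ),
        cube_reps=3,
        axial_reps=3,
        center_reps=5,
        seed=seed,
    )
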