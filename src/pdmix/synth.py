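"""Synthetic run tables with the statistical structure of the liposome study.

Sizes are drawn from the reduced quadratic size surface
``Z = 236.3 - 26.95 FRR - 4.437 TFR + 1.573 FRR^2`` (nm) and PDI from
``0.0663 + 0.03181 FRR + 0.00319 TFR - 0.001905 FRR^2``, each plus i.i.d.
Gaussian replicate noise; zeta potential is factor-independent Gaussian.
Default noise levels sit inside the replicate spread observed in the study:
size SD 6 nm (the observed per-condition SDs range 0.43-11.48 nm), PDI SD
0.02, zeta -31.5 +/- 4 mV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import RESPONSE_COLUMNS

logger = logging.getLogger(__name__)

__all__ = ["TruthSpec", "generate_run_table", "generate_validation_sweep",
           "SIZE_COEFS", "PDI_COEFS"]

#: Generating coefficients for (1, frr, tfr, frr^2).
SIZE_COEFS: Mapping[str, float] = {
    "1": 236.3, "frr": -26.95, "tfr": -4.437, "frr^2": 1.573,
}
PDI_COEFS: Mapping[str, float] = {
    "1": 0.0663, "frr": 0.03181, "tfr": 0.00319, "frr^2": -0.001905,
}


def _eval_poly(coefs: Mapping[str, float], frr: np.ndarray,
               tfr: np.ndarray) -> np.ndarray:
    cols = {"1": np.ones_like(frr), "frr": frr, "tfr": tfr,
            "frr^2": frr**2, "tfr^2": tfr**2, "frr:tfr": frr * tfr}
    return sum(c * cols[t] for t, c in coefs.items())


@dataclass(frozen=True)
class TruthSpec:
    """Generating model and noise levels for synthetic responses."""

    size_coefs: Mapping[str, float] = field(default_factory=lambda: dict(SIZE_COEFS))
    pdi_coefs: Mapping[str, float] = field(default_factory=lambda: dict(PDI_COEFS))
    sd_size: float = 6.0
    sd_pdi: float = 0.02
    zeta_mean: float = -31.5
    zeta_sd: float = 4.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for sd in (self.sd_size, self.sd_pdi, self.zeta_sd):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")


def generate_run_table(
    design: pd.DataFrame,
    truth: TruthSpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fill a design's response columns from the generating model.

    PDI values are clipped to (0, 1); clip events are logged.  The result
    is deterministic for a fixed seed (``seed`` overrides ``truth.seed``).
    """
    truth = truth or TruthSpec()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    out = design.copy()
    frr = out["frr"].to_numpy(dtype=float)
    tfr = out["tfr"].to_numpy(dtype=float)
    n = len(out)
    size = _eval_poly(truth.size_coefs, frr, tfr)
    if truth.sd_size:
        size = size + rng.normal(0.0, truth.sd_size, n)
    out["z_average_nm"] = size
    pdi = _eval_poly(truth.pdi_coefs, frr, tfr)
    if truth.sd_pdi:
        pdi = pdi + rng.normal(0.0, truth.sd_pdi, n)
    n_clip = int(np.sum((pdi <= 0) | (pdi >= 1)))
    if n_clip:
        logger.info("clipped %d PDI values into (0, 1)", n_clip)
    out["pdi"] = np.clip(pdi, 1e-6, 1.0 - 1e-6)
    out["zeta_mv"] = rng.normal(truth.zeta_mean, truth.zeta_sd, n) \
        if truth.zeta_sd else np.full(n, truth.zeta_mean)
    return out


def generate_validation_sweep(
    frr_values: Sequence[float],
    tfr: float = 18.0,
    truth: TruthSpec | None = None,
    n_reps: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Triplicate (by default) runs over an FRR grid at fixed TFR.

    Mirrors the study's validation sweep at TFR = 18 mL/h.
    """
    frr = np.repeat(np.asarray(frr_values, dtype=float), n_reps)
    design = pd.DataFrame({
        "run_order": np.arange(1, len(frr) + 1),
        "frr": frr,
        "tfr": np.full(len(frr), float(tfr)),
    })
    for col in RESPONSE_COLUMNS:
        design[col] = np.nan
    return generate_run_table(design, truth, seed=seed)
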