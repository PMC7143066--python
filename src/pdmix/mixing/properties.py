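"""Water-ethanol mixture properties as polynomials of ethanol mass fraction.

The packaged 25 C table (density, dynamic viscosity, mutual diffusivity) is
fitted with order-5 polynomials at load time; users can supply their own
table or coefficients through the same interface.  All evaluated values are
SI: kg/m^3, Pa.s, m^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

__all__ = ["PropertyModel", "fit_property_polynomial", "load_property_table"]

_PACKAGED_TABLE = "ethanol_water_properties_25c.csv"


def load_property_table() -> pd.DataFrame:
    """The packaged 25 C water-ethanol property table.

    Columns: ``w`` (ethanol mass fraction), ``density_kg_m3``,
    ``viscosity_mpa_s``, ``diffusivity_1e9_m2_s``.
    """
    ref = resources.files("pdmix.data") / _PACKAGED_TABLE
    with ref.open("r") as fh:
        return pd.read_csv(fh, comment="#")


def fit_property_polynomial(
    c: np.ndarray, values: np.ndarray, order: int = 5
) -> tuple[Polynomial, np.ndarray]:
    """Least-squares polynomial fit of a property over mass fraction.

    Returns the polynomial (in the original variable, not the scaled
    domain) and the fit residuals.  Requires at least ``order + 1``
    distinct points; with exactly ``order + 1`` the fit interpolates.
    """
    c = np.asarray(c, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(np.unique(c)) < order + 1:
        raise ValueError(
            f"need at least {order + 1} distinct points for order {order}"
        )
    poly = Polynomial.fit(c, values, deg=order).convert()
    return poly, values - poly(c)


@dataclass(frozen=True)
class PropertyModel:
    """rho(c), mu(c), D(c) polynomials over ethanol mass fraction c in [0,1]."""

    rho: Polynomial  # kg/m^3
    mu: Polynomial   # Pa.s
    D: Polynomial    # m^2/s
    provenance: str = "user"

    def __post_init__(self) -> None:
        w = np.linspace(0.0, 1.0, 101)
        for name, poly in (("rho", self.rho), ("mu", self.mu), ("D", self.D)):
            if np.any(poly(w) <= 0):
                raise ValueError(f"{name}(c) must stay positive on [0, 1]")

    @classmethod
    def from_table(cls, table: pd.DataFrame, order: int = 5,
                   provenance: str = "table") -> "PropertyModel":
        w = table["w"].to_numpy()
        rho, _ = fit_property_polynomial(w, table["density_kg_m3"], order)
        mu, _ = fit_property_polynomial(
            w, table["viscosity_mpa_s"] * 1e-3, order)
        D, _ = fit_property_polynomial(
            w, table["diffusivity_1e9_m2_s"] * 1e-9, order)
        return cls(rho=rho, mu=mu, D=D, provenance=provenance)

    @classmethod
    def from_packaged(cls, order: int = 5) -> "PropertyModel":
        """Order-5 fits of the packaged 25 C water-ethanol table."""
        model = cls.from_table(load_property_table(), order,
                               provenance=f"packaged 25C table, order {order}")
        table = load_property_table()
        for col, poly, scale in (
            ("density_kg_m3", model.rho, 1.0),
            ("viscosity_mpa_s", model.mu, 1e-3),
            ("diffusivity_1e9_m2_s", model.D, 1e-9),
        ):
            for w_end in (0.0, 1.0):
                ref = float(table.loc[table.w == w_end, col].iloc[0]) * scale
                if abs(poly(w_end) - ref) > 0.01 * abs(ref):
                    raise ValueError(
                        f"{col} fit misses the pure-component entry at w={w_end}"
                    )
        return model
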