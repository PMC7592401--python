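"""Dual-energy image pair container and HU <-> attenuation conversion."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["DectImagePair", "hu_to_mu", "mu_to_hu", "WATER_MU"]

# linear attenuation of water (cm^-1) at the effective energies of 80 and
# 140 kVp spectra; matches the packaged library table
WATER_MU = {80.0: 0.222165, 140.0: 0.194703}


def hu_to_mu(image_hu: np.ndarray, mu_water: float) -> np.ndarray:
    """Convert CT numbers to linear attenuation: mu = mu_water*(1 + HU/1000),
    clipped below at zero."""
    if mu_water <= 0:
        raise ValueError("mu_water must be > 0")
    return np.clip(mu_water * (1.0 + np.asarray(image_hu, dtype=float) / 1000.0), 0.0, None)


def mu_to_hu(image_mu: np.ndarray, mu_water: float) -> np.ndarray:
    """Inverse of :func:`hu_to_mu` (without the clip)."""
    if mu_water <= 0:
        raise ValueError("mu_water must be > 0")
    return 1000.0 * (np.asarray(image_mu, dtype=float) / mu_water - 1.0)


@dataclass
class DectImagePair:
    """Two co-registered images of the same object at two tube voltages.

    ``units`` is ``"hu"`` for CT numbers or ``"mu"`` for linear attenuation
    (cm^-1); ``spacing_mm`` is the isotropic pixel spacing.  Optional
    ground-truth per-material volume-fraction maps (from a simulator) ride
    along for evaluation.
    """

    image_low: np.ndarray
    image_high: np.ndarray
    kvp_pair: tuple[float, float] = (80.0, 140.0)
    spacing_mm: float = 1.0
    units: str = "hu"
    truth_fractions: np.ndarray | None = None  # (H, W, n_materials)
    truth_materials: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image_low = np.asarray(self.image_low, dtype=float)
        self.image_high = np.asarray(self.image_high, dtype=float)
        if self.image_low.shape != self.image_high.shape:
            raise ValueError(
                f"image shapes differ: {self.image_low.shape} vs {self.image_high.shape}"
            )
        if self.spacing_mm <= 0:
            raise ValueError("pixel spacing must be > 0")
        if self.units not in ("hu", "mu"):
            raise ValueError("units must be 'hu' or 'mu'")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.image_low.shape

    def water_mu(self) -> tuple[float, float]:
        lo, hi = self.kvp_pair
        try:
            return WATER_MU[float(lo)], WATER_MU[float(hi)]
        except KeyError:
            raise ValueError(
                f"no water attenuation tabulated for kVp pair {self.kvp_pair}; "
                "convert to attenuation units upstream"
            ) from None

    def to_mu(self) -> "DectImagePair":
        """Return a copy in linear-attenuation units."""
        if self.units == "mu":
            return self
        wl, wh = self.water_mu()
        return replace(
            self,
            image_low=hu_to_mu(self.image_low, wl),
            image_high=hu_to_mu(self.image_high, wh),
            units="mu",
        )

    def to_hu(self) -> "DectImagePair":
        if self.units == "hu":
            return self
        wl, wh = self.water_mu()
        return replace(
            self,
            image_low=mu_to_hu(self.image_low, wl),
            image_high=mu_to_hu(self.image_high, wh),
            units="hu",
        )
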