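"""Regenerate the packaged material attenuation table.

Linear attenuation coefficients are tabulated at the effective energies of
typical 80 and 140 kVp CT spectra (taken as 52 and 69 keV).  Per-element
mass attenuation coefficients mu/rho (cm^2/g) are interpolated log-log from
standard photon cross-section tabulations at 40/50/60/80/100 keV, combined
by the elemental mass-weight mixture rule, and multiplied by mass density.

The output CSV is frozen into the package (src/dectmmd/data/); rerun this
script only when changing material definitions.

Usage:  python scripts/generate_attenuation_table.py
"""

from __future__ import annotations

import csv
import pathlib

import numpy as np

ENERGIES_KEV = np.array([40.0, 50.0, 60.0, 80.0, 100.0])

# mu/rho in cm^2/g at the energies above (photoelectric + coherent +
# incoherent), rounded standard tabulated values.
ELEMENT_MU_RHO = {
    "H": [0.3458, 0.3355, 0.3260, 0.3091, 0.2944],
    "C": [0.2076, 0.1871, 0.1753, 0.1610, 0.1514],
    "N": [0.2288, 0.1982, 0.1817, 0.1639, 0.1529],
    "O": [0.2585, 0.2132, 0.1907, 0.1678, 0.1551],
    "F": [0.2747, 0.2186, 0.1920, 0.1655, 0.1514],
    "P": [0.6162, 0.4041, 0.3106, 0.2251, 0.1880],
    "K": [0.8679, 0.5330, 0.3851, 0.2577, 0.2036],
    "Ca": [1.0190, 0.6578, 0.4571, 0.2953, 0.2281],
    "I": [12.09, 6.636, 4.101, 1.967, 1.137],
}

EFFECTIVE_KEV = {"low": 52.0, "high": 69.0}  # 80 kVp, 140 kVp

# name -> (density g/cm^3, {element: mass fraction}, group)
MATERIALS = {
    "air":      (0.0012, {"N": 0.755, "O": 0.232, "C": 0.013}, "default"),
    "water":    (1.000, {"H": 0.1119, "O": 0.8881}, "default"),
    "blood":    (1.060, {"H": 0.102, "C": 0.110, "N": 0.033, "O": 0.745,
                         "P": 0.001, "K": 0.002}, "default"),
    "fat":      (0.920, {"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.281}, "default"),
    "bone":     (1.920, {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435,
                         "P": 0.103, "Ca": 0.225}, "default"),
    "lexan":    (1.200, {"H": 0.0555, "C": 0.7557, "O": 0.1888}, "default"),
    "acrylic":  (1.190, {"H": 0.0805, "C": 0.5998, "O": 0.3196}, "default"),
    "teflon":   (2.160, {"C": 0.2402, "F": 0.7598}, "default"),
    # pure solutes used by the ideal-solution mixing helpers
    "koh_solid": (2.044, {"K": 0.6977, "O": 0.2852, "H": 0.0171}, "solute"),
    "iodine":    (4.933, {"I": 1.0}, "solute"),
}


def mu_rho_at(element: str, kev: float) -> float:
    """Log-log interpolated mass attenuation coefficient (cm^2/g)."""
    y = np.log(ELEMENT_MU_RHO[element])
    return float(np.exp(np.interp(np.log(kev), np.log(ENERGIES_KEV), y)))


def mixture_mu(density: float, weights: dict[str, float], kev: float) -> float:
    total = sum(weights.values())
    return density * sum(
        (w / total) * mu_rho_at(el, kev) for el, w in weights.items()
    )


def main() -> None:
    out = pathlib.Path(__file__).resolve().parents[1] / "src" / "dectmmd" / "data"
    out.mkdir(parents=True, exist_ok=True)
    path = out / "attenuation_80_140.csv"
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "density_g_cm3", "mu_low_cm1", "mu_high_cm1", "group"])
        for name, (rho, weights, group) in MATERIALS.items():
            mu_low = mixture_mu(rho, weights, EFFECTIVE_KEV["low"])
            mu_high = mixture_mu(rho, weights, EFFECTIVE_KEV["high"])
            writer.writerow([name, f"{rho:.4f}", f"{mu_low:.6f}", f"{mu_high:.6f}", group])
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
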