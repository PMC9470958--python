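"""Optical dielectric constant of the head/tail moieties by group contribution.

The Kramers-Kronig reconstruction needs the high-frequency anchor eps_inf,
the real permittivity left over above the computed band.  Lipids are
transparent from the near-infrared to the near-ultraviolet (kappa = 0), so
eps_inf is estimated optically:

1. Vogel group contributions: the moiety is decomposed into chemical units
   (CH3, CH2, COO, C, H, PO4, N) whose molar refractions R at 468.3, 589.3
   and 653.3 nm are tabulated; unit refractions add.
2. Lorentz-Lorenz: (n^2-1)/(n^2+2) = rho R / M gives the refractive index
   at those three wavelengths from the moiety's molecular weight M and mass
   density rho.
3. Cauchy dispersion n(lambda) = A + B/lambda^2 + C/lambda^4 is solved
   exactly through the three points and evaluated at the anchor frequency
   (300 THz by default, i.e. lambda ~ 999.3 nm); eps_inf = n^2 there.

The moiety densities are not a group-contribution output; the shipped
defaults (head 1.40 g/cm^3, tail 0.85 g/cm^3) are literature-typical values
for the phosphocholine headgroup region and a liquid alkane core, clearly
exposed as configuration, and every calibration result records the density
used.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units

__all__ = [
    "WAVELENGTHS_NM",
    "RefractionTable",
    "MoietyComposition",
    "CauchyModel",
    "epsilon_from_nk",
    "nk_from_epsilon",
    "sum_molar_refraction",
    "lorentz_lorenz_n",
    "fit_cauchy",
    "epsilon_infinity",
    "calibrate_region",
    "default_refraction_table",
    "head_composition",
    "tail_composition",
]

#: The three tabulated wavelengths of the group-contribution data (nm).
WAVELENGTHS_NM = (468.3, 589.3, 653.3)

#: Unit formula weights (g/mol), standard atomic masses.
UNIT_MASS = {
    "CH3": 15.035, "CH2": 14.027, "COO": 44.009, "C": 12.011,
    "H": 1.008, "PO4": 94.971, "N": 14.007,
}

#: Default moiety mass densities (g/cm^3).  Configuration, not measured
#: output: typical literature values for the hydrated phosphocholine
#: headgroup region and a liquid hydrocarbon core.
DEFAULT_DENSITY = {"head": 1.40, "tail": 0.85}

# Head: choline (3xCH3 + 2xCH2) + glycerol backbone (2xCH2 + CH) + two ester
# carbonyls + phosphate + nitrogen; tail: two myristoyl chains minus the
# carbonyl carbons.
HEAD_UNITS = {"CH3": 3, "CH2": 5, "COO": 2, "C": 1, "H": 1, "PO4": 1, "N": 1}
TAIL_UNITS = {"CH3": 2, "CH2": 23}


@dataclass
class RefractionTable:
    """Molar refraction (cm^3/mol) of each chemical unit at the 3 wavelengths."""

    values: dict[str, dict[float, float]]   # unit -> {wavelength_nm: R}

    def __post_init__(self) -> None:
        for unit, per_wl in self.values.items():
            if set(per_wl) != set(WAVELENGTHS_NM):
                raise ValueError(f"unit {unit!r} must tabulate exactly {WAVELENGTHS_NM}")
            if any(r <= 0 for r in per_wl.values()):
                raise ValueError(f"non-positive molar refraction for {unit!r}")

    def refraction(self, unit: str, wavelength_nm: float) -> float:
        if unit not in self.values:
            raise KeyError(f"unknown chemical unit {unit!r}")
        per_wl = self.values[unit]
        if wavelength_nm not in per_wl:
            raise KeyError(
                f"wavelength {wavelength_nm} nm not tabulated (have {WAVELENGTHS_NM})"
            )
        return per_wl[wavelength_nm]


def default_refraction_table() -> RefractionTable:
    """Load the packaged group-contribution table."""
    with importlib.resources.files("memdiel.data").joinpath("refraction_units.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    values = {
        str(r.unit): {wl: float(getattr(r, f"R_{str(wl).replace('.', '_')}"))
                      for wl in WAVELENGTHS_NM}
        for r in df.itertuples()
    }
    return RefractionTable(values=values)


@dataclass
class MoietyComposition:
    """Chemical-unit counts of one moiety plus its M (g/mol) and rho (g/cm^3)."""

    counts: dict[str, int]
    density_g_cm3: float
    molecular_weight: float | None = None   # computed from counts when omitted

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()) or not any(self.counts.values()):
            raise ValueError("unit counts must be non-negative and not all zero")
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")
        if self.molecular_weight is None:
            try:
                self.molecular_weight = sum(
                    n * UNIT_MASS[u] for u, n in self.counts.items()
                )
            except KeyError as exc:
                raise KeyError(f"no formula weight for unit {exc.args[0]!r}") from exc
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")


def head_composition(density_g_cm3: float | None = None) -> MoietyComposition:
    return MoietyComposition(dict(HEAD_UNITS),
                             density_g_cm3 or DEFAULT_DENSITY["head"])


def tail_composition(density_g_cm3: float | None = None) -> MoietyComposition:
    return MoietyComposition(dict(TAIL_UNITS),
                             density_g_cm3 or DEFAULT_DENSITY["tail"])


# ---------------------------------------------------------------------------
# optical <-> dielectric conversions
# ---------------------------------------------------------------------------

def epsilon_from_nk(n, kappa):
    """(n, kappa) -> (eps', eps'') via eps' = n^2 - kappa^2, eps'' = 2 n kappa."""
    n = np.asarray(n, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    return n * n - kappa * kappa, 2.0 * n * kappa


def nk_from_epsilon(eps_real, eps_imag):
    """(eps', eps'') -> (n, kappa), principal (physical) branch.

    ``n = sqrt((eps' + |eps|)/2)``; a transparent medium with eps' <= 0
    (n = 0, undefined kappa) is rejected as nonphysical.
    """
    eps_real = np.asarray(eps_real, dtype=float)
    eps_imag = np.asarray(eps_imag, dtype=float)
    if np.any(eps_imag < 0):
        raise ValueError("eps'' must be non-negative on the physical branch")
    mod = np.hypot(eps_real, eps_imag)
    n2 = 0.5 * (eps_real + mod)
    if np.any(n2 <= 0):
        raise ValueError("eps' <= 0 with eps'' = 0 has no physical optical constant")
    n = np.sqrt(n2)
    return n, eps_imag / (2.0 * n)


# ---------------------------------------------------------------------------
# Vogel -> Lorentz-Lorenz -> Cauchy
# ---------------------------------------------------------------------------

def sum_molar_refraction(
    composition: MoietyComposition,
    table: RefractionTable,
    wavelength_nm: float,
) -> float:
    """Additive molar refraction of the moiety (cm^3/mol)."""
    return sum(
        count * table.refraction(unit, wavelength_nm)
        for unit, count in composition.counts.items()
        if count
    )


def lorentz_lorenz_n(
    R: float, M: float, rho: float, literal_ratio: bool = False
) -> float:
    """Refractive index from molar refraction via Lorentz-Lorenz.

    Solves (n^2-1)/(n^2+2) = rho R / M for n, i.e.
    ``n = sqrt((M + 2 rho R)/(M - rho R))``.  ``literal_ratio=True`` returns
    the un-rooted ratio (M+2 rho R)/(M - rho R) instead; that variant lacks
    the vacuum limit n -> 1 and exists only for comparison.
    """
    if M <= 0 or rho <= 0 or R < 0:
        raise ValueError("M, rho must be positive and R non-negative")
    x = rho * R
    if x >= M:
        raise ValueError(
            f"rho*R = {x:.3f} >= M = {M:.3f}: Lorentz-Lorenz diverges "
            "(polarizability catastrophe)"
        )
    ratio = (M + 2.0 * x) / (M - x)
    return ratio if literal_ratio else math.sqrt(ratio)


@dataclass(frozen=True)
class CauchyModel:
    """n(lambda) = A + B/lambda^2 + C/lambda^4 (lambda in nm)."""

    A: float
    B: float   # nm^2
    C: float   # nm^4

    def refractive_index(self, wavelength_nm) -> np.ndarray | float:
        lam2 = np.asarray(wavelength_nm, dtype=float) ** 2
        return self.A + self.B / lam2 + self.C / lam2 ** 2


def fit_cauchy(points: list[tuple[float, float]]) -> CauchyModel:
    """Exact Cauchy model through three (wavelength nm, n) pairs."""
    if len(points) != 3:
        raise ValueError("exactly three (wavelength, n) pairs are required")
    lam = np.array([p[0] for p in points], dtype=float)
    n = np.array([p[1] for p in points], dtype=float)
    if len(set(lam.tolist())) != 3:
        raise np.linalg.LinAlgError("duplicate wavelengths make the system singular")
    A_mat = np.column_stack([np.ones(3), lam ** -2, lam ** -4])
    coeff = np.linalg.solve(A_mat, n)
    return CauchyModel(A=float(coeff[0]), B=float(coeff[1]), C=float(coeff[2]))


def epsilon_infinity(model: CauchyModel, f_anchor_thz: float = 300.0) -> float:
    """eps_inf = n(c/f)^2 at the anchor frequency (kappa = 0 there)."""
    if f_anchor_thz <= 0:
        raise ValueError("anchor frequency must be positive")
    lam_nm = units.wavelength_nm_from_thz(f_anchor_thz)
    n = float(model.refractive_index(lam_nm))
    return n * n


def calibrate_region(
    composition: MoietyComposition,
    table: RefractionTable | None = None,
    f_anchor_thz: float = 300.0,
) -> dict:
    """Full chain Vogel -> Lorentz-Lorenz -> Cauchy -> eps_inf for one moiety.

    Returns a JSON-ready record with the Cauchy coefficients, the anchor
    eps_inf and the (M, rho) actually used.
    """
    table = table or default_refraction_table()
    points = []
    for wl in WAVELENGTHS_NM:
        R = sum_molar_refraction(composition, table, wl)
        n = lorentz_lorenz_n(R, composition.molecular_weight, composition.density_g_cm3)
        points.append((wl, n))
    model = fit_cauchy(points)
    return {
        "A": model.A, "B": model.B, "C": model.C,
        "eps_inf": epsilon_infinity(model, f_anchor_thz),
        "anchor_THz": f_anchor_thz,
        "n_points": points,
        "M_used": composition.molecular_weight,
        "rho_used": composition.density_g_cm3,
    }
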