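"""Space-frequency dielectric landscape and waveguide-band search.

A multilamellar membrane can guide electromagnetic waves only in frequency
windows where (1) the band is continuous and reasonably broad, (2) the real
permittivity of the candidate core (the lipid head layers) exceeds that of
the surrounding water and of the tail layers, and (3) the core's imaginary
permittivity is small enough for low attenuation.  This module assembles the
per-slab spectra into an interpolated (z, f) landscape, pools slabs into
head/tail/water region means, applies those three criteria on a shared grid
and reports the maximal contiguous passing windows.

The thresholds are interpretations of qualitative criteria ("obviously
higher", "small enough") and are therefore configuration with documented
defaults, not measured constants.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .spectra import DielectricSpectrum

__all__ = [
    "Landscape",
    "BandThresholds",
    "BandWindow",
    "BandReport",
    "build_landscape",
    "region_aggregate",
    "waveguide_bands",
    "report",
]


@dataclass
class Landscape:
    """eps'(z, f) and eps''(z, f) matrices with bilinear interpolation."""

    z_centers_nm: np.ndarray      # (nz,)
    f_thz: np.ndarray             # (nf,)
    eps_imag: np.ndarray          # (nz, nf)
    eps_real: np.ndarray | None = None
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        nz, nf = len(self.z_centers_nm), len(self.f_thz)
        if self.eps_imag.shape != (nz, nf):
            raise ValueError("eps_imag matrix shape mismatch")
        if self.eps_real is not None and self.eps_real.shape != (nz, nf):
            raise ValueError("eps_real matrix shape mismatch")

    def interpolator(self, which: str = "imag") -> RegularGridInterpolator:
        mat = self.eps_imag if which == "imag" else self.eps_real
        if mat is None:
            raise ValueError(f"landscape lacks eps_{which}")
        return RegularGridInterpolator(
            (self.z_centers_nm, self.f_thz), mat, method="linear"
        )


def build_landscape(
    spectra: list[DielectricSpectrum],
    z_centers_nm: np.ndarray,
) -> Landscape:
    """Stack per-slab spectra into a bilinear (z, f) landscape.

    The interpolated surface passes exactly through the computed nodes; at
    least two slabs on one shared frequency grid are required.
    """
    if len(spectra) < 2:
        raise ValueError("need >= 2 slabs to interpolate a landscape")
    z = np.asarray(z_centers_nm, dtype=float)
    if len(z) != len(spectra):
        raise ValueError("one z centre per slab spectrum required")
    f = spectra[0].f_thz
    for s in spectra[1:]:
        if s.f_thz.shape != f.shape or not np.allclose(s.f_thz, f):
            raise ValueError("slab spectra are on mismatched frequency grids")
    order = np.argsort(z)
    eps_imag = np.stack([spectra[i].eps_imag for i in order])
    have_real = all(s.eps_real is not None for s in spectra)
    eps_real = np.stack([spectra[i].eps_real for i in order]) if have_real else None
    labels = [spectra[i].region or "" for i in order]
    return Landscape(z_centers_nm=z[order], f_thz=f, eps_imag=eps_imag,
                     eps_real=eps_real, region_labels=labels)


def region_aggregate(spectra: list[DielectricSpectrum]) -> dict[str, DielectricSpectrum]:
    """Arithmetic mean spectrum per region label, leaflets pooled.

    Every spectrum must carry a region label; an absent region is simply not
    in the result, but requesting the mean of zero spectra for a labelled
    region that exists cannot happen by construction.
    """
    if not spectra:
        raise ValueError("no spectra to aggregate")
    f = spectra[0].f_thz
    groups: dict[str, list[DielectricSpectrum]] = {}
    for s in spectra:
        if s.region is None:
            raise ValueError("spectrum without region label in aggregation")
        if s.f_thz.shape != f.shape or not np.allclose(s.f_thz, f):
            raise ValueError("region aggregation requires one shared grid")
        groups.setdefault(s.region, []).append(s)
    out = {}
    for region, members in groups.items():
        eps_imag = np.mean([m.eps_imag for m in members], axis=0)
        eps_real = (np.mean([m.eps_real for m in members], axis=0)
                    if all(m.eps_real is not None for m in members) else None)
        out[region] = DielectricSpectrum(
            f_thz=f.copy(), eps_imag=eps_imag, eps_real=eps_real, region=region,
            window_thz=members[0].window_thz,
        )
    return out


@dataclass(frozen=True)
class BandThresholds:
    """Quantitative reading of the three waveguide criteria."""

    margin_real: float = 0.0       # eps'_head must beat eps'_water by this
    max_imag: float = 0.5          # attenuation ceiling on eps''_head
    min_width_thz: float = 5.0     # discard narrower windows
    tol: float = 1e-9              # numeric slack on the strict inequalities


@dataclass(frozen=True)
class BandWindow:
    f_lo_thz: float
    f_hi_thz: float
    min_margin_over_water: float
    min_margin_over_tail: float
    max_head_imag: float

    @property
    def width_thz(self) -> float:
        return self.f_hi_thz - self.f_lo_thz


@dataclass
class BandReport:
    windows: list[BandWindow]
    thresholds: BandThresholds

    def to_dict(self) -> dict:
        return {"thresholds": asdict(self.thresholds),
                "windows": [asdict(w) for w in self.windows]}


def waveguide_bands(
    regions: dict[str, DielectricSpectrum],
    thresholds: BandThresholds | None = None,
) -> BandReport:
    """Apply the three waveguide criteria to the region mean spectra.

    A frequency passes iff eps'_head >= eps'_water + margin and
    eps'_head >= eps'_tail and eps''_head <= max_imag; maximal contiguous
    passing runs at least ``min_width_thz`` wide are reported, with the
    worst-case margins inside each window.  An empty report is a legitimate
    outcome.
    """
    thresholds = thresholds or BandThresholds()
    try:
        head, tail, water = regions["head"], regions["tail"], regions["water"]
    except KeyError as exc:
        raise ValueError(f"region {exc.args[0]!r} missing from the aggregate") from exc
    for r in (tail, water):
        if r.f_thz.shape != head.f_thz.shape or not np.allclose(r.f_thz, head.f_thz):
            raise ValueError("regions are on mismatched grids")
    if head.eps_real is None or tail.eps_real is None or water.eps_real is None:
        raise ValueError("waveguide criteria need eps_real (run the KK step first)")
    f = head.f_thz
    dvw = head.eps_real - water.eps_real
    dvt = head.eps_real - tail.eps_real
    ok = ((dvw >= thresholds.margin_real - thresholds.tol)
          & (dvt >= -thresholds.tol)
          & (head.eps_imag <= thresholds.max_imag + thresholds.tol))
    windows: list[BandWindow] = []
    i = 0
    n = len(f)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        if f[j] - f[i] >= thresholds.min_width_thz:
            windows.append(BandWindow(
                f_lo_thz=float(f[i]), f_hi_thz=float(f[j]),
                min_margin_over_water=float(dvw[i:j + 1].min()),
                min_margin_over_tail=float(dvt[i:j + 1].min()),
                max_head_imag=float(head.eps_imag[i:j + 1].max()),
            ))
        i = j + 1
    return BandReport(windows=windows, thresholds=thresholds)


def report(
    landscape: Landscape,
    bands: BandReport,
    calibration: dict | None = None,
    out_prefix: str | None = None,
    metadata: dict | None = None,
) -> dict:
    """Bundle landscape + bands (+ calibration, config, seeds) into a report.

    Returns the JSON-ready dict; when ``out_prefix`` is given, writes
    ``<prefix>_bands.json`` and a tidy ``<prefix>_landscape.csv``
    (columns z_nm, region, f_THz, eps_real, eps_imag).
    """
    from . import __version__

    doc = {
        "software": {"name": "memdiel", "version": __version__},
        "bands": bands.to_dict(),
        "calibration": calibration or {},
        "metadata": metadata or {},
        "landscape": {
            "z_centers_nm": landscape.z_centers_nm.tolist(),
            "f_thz_min": float(landscape.f_thz[0]),
            "f_thz_max": float(landscape.f_thz[-1]),
            "n_freq": int(len(landscape.f_thz)),
        },
    }
    if out_prefix is not None:
        with open(f"{out_prefix}_bands.json", "w") as fh:
            json.dump(doc, fh, indent=2)
        import pandas as pd

        nz, nf = landscape.eps_imag.shape
        frame = pd.DataFrame({
            "z_nm": np.repeat(landscape.z_centers_nm, nf),
            "region": np.repeat(
                landscape.region_labels or [""] * nz, nf),
            "f_THz": np.tile(landscape.f_thz, nz),
            "eps_real": (landscape.eps_real.ravel()
                         if landscape.eps_real is not None else np.nan),
            "eps_imag": landscape.eps_imag.ravel(),
        })
        frame.to_csv(f"{out_prefix}_landscape.csv", index=False)
    return doc
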