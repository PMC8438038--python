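"""Wavelength-resolved absorption models for the chromophores unmixed in
near-infrared photoacoustic (PA) imaging.

Four chromophores are packaged:

``hbo2`` / ``hhb``
    Oxy- and deoxyhemoglobin molar extinction curves (tabulated CSV asset).
``icg_monomer_water`` / ``icg_monomer_serum``
    Monomeric indocyanine green (ICG), peak ~790 nm in water shifting to
    ~810 nm when bound to serum albumin (parametric skew-normal band).
``patrace``
    The liposome-encapsulated ICG J-aggregate probe: peak ~890 nm
    (880-890 between batches), band narrowed to 30% of the monomer FWHM and
    ~3-fold more intense at equimolar dye concentration.

Optical density (OD) follows the Beer-Lambert convention at a 1 cm
reference path length: OD = eps(lambda) * c * L.
"""

from __future__ import annotations

import csv
import functools
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import skewnorm

from .exceptions import ValidationError

__all__ = [
    "Spectrum",
    "SpectralLibrary",
    "get_spectrum",
    "default_library",
    "blood_absorption",
    "mixture_spectrum",
    "peak_and_fwhm",
    "concentration_for_od",
    "water_absorption",
    "CHROMOPHORES",
]

WAVELENGTH_MIN_NM = 650.0
WAVELENGTH_MAX_NM = 1000.0

CHROMOPHORES = ("hbo2", "hhb", "icg_monomer_water", "icg_monomer_serum", "patrace")

#: Default evaluation grid for parametric probe models (1 nm steps).
DEFAULT_GRID_NM = np.arange(650.0, 1000.0 + 0.5, 1.0)


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed absorption curve.

    Parameters
    ----------
    name : str
        Chromophore identifier.
    wavelengths_nm : ndarray
        Strictly ascending grid within [650, 1000] nm.
    values : ndarray
        Molar absorption coefficient (cm^-1 M^-1) or normalized absorbance
        per unit OD concentration; all finite and >= 0.
    units : str
        ``"molar_extinction_cm_M"`` or ``"normalized"``.
    source : str
        ``"tabulated"`` or ``"parametric"``.
    """

    name: str
    wavelengths_nm: np.ndarray
    values: np.ndarray
    units: str = "molar_extinction_cm_M"
    source: str = "tabulated"

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)
        if wl.ndim != 1 or v.shape != wl.shape:
            raise ValidationError(f"{self.name}: wavelengths and values must be 1-D and matched")
        if wl.size < 1 or np.any(np.diff(wl) <= 0):
            raise ValidationError(f"{self.name}: wavelengths must be strictly ascending")
        if wl[0] < WAVELENGTH_MIN_NM - 1e-9 or wl[-1] > WAVELENGTH_MAX_NM + 1e-9:
            raise ValidationError(
                f"{self.name}: wavelengths must lie within "
                f"[{WAVELENGTH_MIN_NM:g}, {WAVELENGTH_MAX_NM:g}] nm"
            )
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValidationError(f"{self.name}: values must be finite and >= 0")

    def __call__(self, wavelengths_nm) -> np.ndarray:
        """Linear interpolation inside the grid; exact at grid nodes."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        if np.any(wl < self.wavelengths_nm[0] - 1e-9) or np.any(wl > self.wavelengths_nm[-1] + 1e-9):
            raise ValidationError(
                f"{self.name}: requested wavelength outside grid "
                f"[{self.wavelengths_nm[0]:g}, {self.wavelengths_nm[-1]:g}] nm"
            )
        return np.interp(wl, self.wavelengths_nm, self.values)

    def resampled(self, grid_nm) -> "Spectrum":
        grid = np.asarray(grid_nm, dtype=float)
        return replace(self, wavelengths_nm=grid, values=self(grid))

    def plot(self, ax=None, **kwargs):
        """Plot the curve (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.wavelengths_nm, self.values, label=self.name, **kwargs)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("absorption")
        return ax


@dataclass
class SpectralLibrary:
    """Mapping of chromophore name -> :class:`Spectrum` plus the OD
    convention (reference path length, default 1 cm)."""

    entries: Mapping[str, Spectrum] = field(default_factory=dict)
    reference_pathlength_cm: float = 1.0

    def __post_init__(self):
        if self.reference_pathlength_cm <= 0:
            raise ValidationError("reference path length must be positive")

    def __getitem__(self, name: str) -> Spectrum:
        try:
            return self.entries[name]
        except KeyError:
            raise KeyError(
                f"unknown chromophore {name!r}; known: {sorted(self.entries)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self):
        return list(self.entries)


# ---------------------------------------------------------------------------
# Packaged assets
# ---------------------------------------------------------------------------

def _read_packaged_csv(filename: str):
    rows = []
    with resources.files("paquant.data").joinpath(filename).open() as fh:
        for row in csv.reader(line for line in fh if not line.startswith("#")):
            if row and row[0] != "wavelength_nm":
                rows.append([float(x) for x in row])
    return np.asarray(rows)


@functools.lru_cache(maxsize=None)
def _hemoglobin_table():
    tab = _read_packaged_csv("hemoglobin_extinction_synthetic.csv")
    return tab[:, 0], tab[:, 1], tab[:, 2]


@functools.lru_cache(maxsize=None)
def _water_table():
    tab = _read_packaged_csv("water_absorption_synthetic.csv")
    return tab[:, 0], tab[:, 1]


@functools.lru_cache(maxsize=None)
def _probe_params() -> dict:
    with resources.files("paquant.data").joinpath("probe_models.yaml").open() as fh:
        return yaml.safe_load(fh)


def water_absorption(wavelengths_nm) -> np.ndarray:
    """Pure-water absorption coefficient (cm^-1), linearly interpolated."""
    wl_tab, mua = _water_table()
    return np.interp(np.asarray(wavelengths_nm, dtype=float), wl_tab, mua)


# ---------------------------------------------------------------------------
# Parametric skew-normal band
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def _skewnorm_shape_constants(skew: float):
    """Mode, peak density and FWHM of the *standard* skew-normal with shape
    ``skew``, computed numerically once per shape value."""
    pdf = lambda x: skewnorm.pdf(x, skew)
    res = minimize_scalar(lambda x: -pdf(x), bounds=(-4.0, 4.0), method="bounded",
                          options={"xatol": 1e-12})
    mode = float(res.x)
    fmax = pdf(mode)
    half = fmax / 2.0
    lo = brentq(lambda x: pdf(x) - half, mode - 20.0, mode, xtol=1e-12)
    hi = brentq(lambda x: pdf(x) - half, mode, mode + 20.0, xtol=1e-12)
    return mode, fmax, hi - lo


def _skewnorm_band(grid_nm, peak_nm: float, fwhm_nm: float, peak_value: float,
                   skew: float) -> np.ndarray:
    """Skew-normal absorption band with *exactly* the requested mode
    wavelength, FWHM and peak value."""
    mode, fmax, width = _skewnorm_shape_constants(skew)
    scale = fwhm_nm / width
    loc = peak_nm - mode * scale
    x = (np.asarray(grid_nm, dtype=float) - loc) / scale
    return peak_value * skewnorm.pdf(x, skew) / fmax


# ---------------------------------------------------------------------------
# Public constructors
# ---------------------------------------------------------------------------

def get_spectrum(name: str, *, peak_nm: float | None = None,
                 grid_nm=None) -> Spectrum:
    """Return a packaged chromophore spectrum.

    Parameters
    ----------
    name : str
        One of ``hbo2, hhb, icg_monomer_water, icg_monomer_serum, patrace``
        (``icg_monomer`` aliases the serum-bound form, the one relevant in
        blood).
    peak_nm : float, optional
        For ``patrace`` only: batch peak position, restricted to the
        documented 880-890 nm range.
    grid_nm : array-like, optional
        Evaluation grid for parametric models (default 1 nm, 650-1000 nm).
    """
    key = {"icg_monomer": "icg_monomer_serum"}.get(name, name)
    if key in ("hbo2", "hhb"):
        if peak_nm is not None:
            raise ValidationError(f"{name}: tabulated spectrum accepts no peak variant")
        wl, hbo2, hhb = _hemoglobin_table()
        return Spectrum(key, wl, hbo2 if key == "hbo2" else hhb, source="tabulated")
    if key not in CHROMOPHORES:
        raise KeyError(f"unknown chromophore {name!r}; known: {CHROMOPHORES}")

    params = dict(_probe_params()[key])
    if peak_nm is not None:
        lo, hi = params.get("peak_nm_range", (params["peak_nm"], params["peak_nm"]))
        if not lo <= peak_nm <= hi:
            raise ValidationError(
                f"{name}: peak {peak_nm:g} nm outside documented range [{lo:g}, {hi:g}] nm"
            )
        params["peak_nm"] = float(peak_nm)
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, dtype=float)
    values = _skewnorm_band(grid, params["peak_nm"], params["fwhm_nm"],
                            params["peak_eps"], params["skew"])
    return Spectrum(key, grid, values, source="parametric")


def default_library(*, patrace_peak_nm: float | None = None) -> SpectralLibrary:
    """The packaged four-chromophore library (1 cm OD path length)."""
    entries = {n: get_spectrum(n, peak_nm=patrace_peak_nm if n == "patrace" else None)
               for n in CHROMOPHORES}
    return SpectralLibrary(entries=entries, reference_pathlength_cm=1.0)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def blood_absorption(grid_nm, so2: float, thb: float = 1.0,
                     library: SpectralLibrary | None = None) -> Spectrum:
    """Molar absorption of blood: thb * [so2*eps_HbO2 + (1-so2)*eps_HHb].

    ``so2`` is the oxygen saturation fraction in [0, 1]; ``thb`` the total
    hemoglobin concentration (heme molarity, M).
    """
    if not 0.0 <= so2 <= 1.0:
        raise ValidationError(f"so2 must be in [0, 1], got {so2!r}")
    if thb <= 0:
        raise ValidationError(f"thb must be positive, got {thb!r}")
    lib = library if library is not None else default_library()
    grid = np.asarray(grid_nm, dtype=float)
    vals = thb * (so2 * lib["hbo2"](grid) + (1.0 - so2) * lib["hhb"](grid))
    return Spectrum(f"blood_so2={so2:g}", grid, vals, source="tabulated")


def mixture_spectrum(components: Mapping[str, float], grid_nm,
                     library: SpectralLibrary | None = None) -> Spectrum:
    """Linear superposition sum_i c_i * eps_i(lambda) on ``grid_nm``.

    Exactly linear in every concentration; an empty mapping yields the
    all-zero spectrum.
    """
    lib = library if library is not None else default_library()
    grid = np.asarray(grid_nm, dtype=float)
    vals = np.zeros_like(grid)
    for name, conc in components.items():
        if conc < 0:
            raise ValidationError(f"negative concentration for {name!r}: {conc!r}")
        vals = vals + conc * lib[name](grid)
    return Spectrum("mixture", grid, vals, source="tabulated")


def peak_and_fwhm(s: Spectrum) -> tuple[float, float]:
    """Peak wavelength (argmax, parabolic refinement on the grid) and full
    width at half maximum (linear interpolation of the two crossings).

    The grid must be at least 1 nm fine; a maximum at a grid end or a
    missing half-maximum crossing raises :class:`ValidationError`.
    """
    wl, v = s.wavelengths_nm, s.values
    if np.max(np.diff(wl)) > 1.0 + 1e-9:
        raise ValidationError("FWHM computation requires a grid no coarser than 1 nm")
    i = int(np.argmax(v))
    if i == 0 or i == v.size - 1:
        raise ValidationError(f"{s.name}: maximum lies at the grid boundary; peak not resolvable")
    # parabolic refinement through the three points around the discrete max
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom < 0:
        delta = 0.5 * (y0 - y2) / denom
        peak = wl[i] + delta * (wl[i + 1] - wl[i])
    else:  # flat top: stick to the node
        peak = wl[i]
    half = v[i] / 2.0
    below_l = np.nonzero(v[:i] < half)[0]
    below_r = np.nonzero(v[i:] < half)[0]
    if below_l.size == 0 or below_r.size == 0:
        raise ValidationError(f"{s.name}: no half-maximum crossing on one side of the peak")
    j = below_l[-1]  # last index below half on the left
    left = np.interp(half, [v[j], v[j + 1]], [wl[j], wl[j + 1]])
    k = i + below_r[0]  # first index below half on the right
    right = np.interp(half, [v[k], v[k - 1]], [wl[k], wl[k - 1]])
    return float(peak), float(right - left)


def concentration_for_od(s: Spectrum, od: float, wavelength_nm: float,
                         pathlength_cm: float = 1.0) -> float:
    """Concentration giving optical density ``od`` at ``wavelength_nm``:
    c = OD / (eps(lambda) * L). Inverse of OD evaluation."""
    if od < 0:
        raise ValidationError(f"od must be >= 0, got {od!r}")
    eps = float(s(wavelength_nm))
    if eps <= 0:
        raise ValidationError(
            f"{s.name}: zero absorption at {wavelength_nm:g} nm; concentration undefined"
        )
    return od / (eps * pathlength_cm)
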