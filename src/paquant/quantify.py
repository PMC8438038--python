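"""Contrast-enhancement (CE) statistics, circulation half-life fitting and
small group-comparison utilities.

CE of the probe image at a post-injection time-point is the voxel-wise
relative change over preinjection,

    CE = (probe_post - probe_pre) / probe_pre,

so a positive CE voxel carries more probe signal than before injection.
Because probe accumulation is sparse and focal, CE voxels indistinguishable
from acquisition noise are removed: the noise scale is measured as the mean
and SD of voxel-wise differences between spatially adjacent preinjection
slices within the ROI, and CE values inside [mean - SD, mean + SD] are
excluded before averaging.

Probe washout from circulation follows PA(t) = PA0 * exp(-lambda * t) with
half-life t_1/2 = ln(2) / lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .exceptions import NumericalError, ValidationError

__all__ = [
    "ce_image",
    "BaselineFilter",
    "baseline_filter",
    "CEResult",
    "ce_statistic",
    "ExponentialDecayModel",
    "DecayFit",
    "fit_halflife",
    "spectral_correlation",
    "loading_ratio",
    "compare_groups",
]

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# Contrast enhancement
# ---------------------------------------------------------------------------

def ce_image(post: np.ndarray, pre: np.ndarray) -> np.ndarray:
    """Voxel-wise (post - pre) / pre. Voxels whose preinjection value is at
    or below a machine-epsilon-scaled guard are invalid (NaN), not infinite."""
    post = np.asarray(post, dtype=float)
    pre = np.asarray(pre, dtype=float)
    if post.shape != pre.shape:
        raise ValidationError(f"shape mismatch: post {post.shape} vs pre {pre.shape}")
    finite_pre = pre[np.isfinite(pre)]
    guard = np.finfo(float).eps * (np.max(np.abs(finite_pre)) if finite_pre.size else 1.0)
    valid = np.isfinite(pre) & np.isfinite(post) & (pre > guard)
    out = np.full(pre.shape, np.nan)
    out[valid] = (post[valid] - pre[valid]) / pre[valid]
    return out


@dataclass(frozen=True)
class BaselineFilter:
    """Baseline (noise) variation of the preinjection probe image: CE values
    within the closed interval [mean - sd, mean + sd] are excluded."""

    mean: float
    sd: float
    n_differences: int

    def excludes(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (v >= self.mean - self.sd) & (v <= self.mean + self.sd)


def baseline_filter(pre_volume: np.ndarray, roi: np.ndarray) -> BaselineFilter:
    """Measure baseline variation from >= 2 spatially adjacent preinjection
    probe slices: voxel-wise differences between consecutive z-slices within
    the ROI, pooled over all adjacent pairs."""
    vol = np.asarray(pre_volume, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if vol.ndim != 3 or roi.shape != vol.shape:
        raise ValidationError("pre_volume and roi must be matched 3-D [slice, row, col]")
    slices = [s for s in range(vol.shape[0]) if roi[s].any()]
    if len(slices) < 2:
        raise ValidationError("baseline variation needs >= 2 adjacent slices in the ROI")
    diffs = []
    for a, b in zip(slices[:-1], slices[1:]):
        if b - a != 1:
            continue
        common = roi[a] & roi[b]
        if common.any():
            d = vol[b][common] - vol[a][common]
            diffs.append(d[np.isfinite(d)])
    if not diffs:
        raise ValidationError("ROI has no spatially adjacent slice pairs")
    pooled = np.concatenate(diffs)
    return BaselineFilter(mean=float(pooled.mean()),
                          sd=float(pooled.std(ddof=0)),
                          n_differences=int(pooled.size))


@dataclass(frozen=True)
class CEResult:
    """Scalar CE over an ROI after baseline filtering."""

    ce: float
    n_survivors: int
    n_valid: int
    n_roi: int
    filter: BaselineFilter | None
    time_label: str = ""

    def summary(self) -> str:
        kept = f"{self.n_survivors}/{self.n_valid} valid voxels kept"
        flt = ("no baseline filter" if self.filter is None else
               f"excluded band [{self.filter.mean - self.filter.sd:.4g}, "
               f"{self.filter.mean + self.filter.sd:.4g}]")
        return f"CE = {self.ce:.4g} ({kept}; {flt})"


def ce_statistic(ce_map: np.ndarray, roi: np.ndarray,
                 filter: BaselineFilter | None = None,
                 time_label: str = "") -> CEResult:
    """Mean of valid, non-excluded CE voxels within the ROI."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValidationError("empty ROI")
    vals = np.asarray(ce_map, dtype=float)[roi]
    valid = vals[np.isfinite(vals)]
    survivors = valid if filter is None else valid[~filter.excludes(valid)]
    if survivors.size == 0:
        raise ValidationError(
            f"no surviving CE voxels (ROI {int(roi.sum())}, valid {valid.size}, "
            f"filter {filter})"
        )
    return CEResult(ce=float(survivors.mean()), n_survivors=int(survivors.size),
                    n_valid=int(valid.size), n_roi=int(roi.sum()),
                    filter=filter, time_label=time_label)


# ---------------------------------------------------------------------------
# Circulation half-life
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayFit:
    """Exponential washout fit PA(t) = PA0 exp(-lambda t).

    ``half_life_min = ln(2) / lam`` exactly; the confidence interval on the
    half-life comes from the fit covariance by the delta method."""

    pa0: float
    lam: float
    residual_norm: float
    pa0_se: float
    lam_se: float
    n_samples: int

    @property
    def half_life_min(self) -> float:
        return LN2 / self.lam

    def half_life_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = LN2 * self.lam_se / self.lam ** 2
        return (self.half_life_min - z * se, self.half_life_min + z * se)

    def summary(self) -> str:
        lo, hi = self.half_life_ci()
        return ("Exponential decay fit (nonlinear least squares)\n"
                f"  PA0        : {self.pa0:.4g} +/- {self.pa0_se:.2g}\n"
                f"  lambda     : {self.lam:.4g} min^-1 +/- {self.lam_se:.2g}\n"
                f"  t_1/2      : {self.half_life_min:.4g} min "
                f"(95% CI {lo:.4g}-{hi:.4g})\n"
                f"  residual   : {self.residual_norm:.4g} over {self.n_samples} samples")


class ExponentialDecayModel:
    """Single-voxel washout model built from a (t, PA) series.

    The time origin is re-based to the sample of maximum PA (the moment of
    peak blood concentration); only samples from the peak onward enter the
    fit. ``fit()`` performs nonlinear least squares in linear space
    (matching additive acquisition noise); ``log_linear=True`` fits
    log(PA) ~ t instead.
    """

    def __init__(self, times_min, values):
        t = np.asarray(times_min, dtype=float)
        y = np.asarray(values, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValidationError("times and values must be matched 1-D arrays")
        i0 = int(np.argmax(y))
        self.times_min = t[i0:] - t[i0]
        self.values = y[i0:]
        if self.times_min.size < 4:
            raise ValidationError("need >= 4 samples after the peak")

    def fit(self, log_linear: bool = False) -> DecayFit:
        t, y = self.times_min, self.values
        if log_linear:
            if np.any(y <= 0):
                raise ValidationError("log-linear fit requires positive samples")
            slope, intercept = np.polyfit(t, np.log(y), 1)
            lam0, pa00 = -slope, math.exp(intercept)
        else:
            pos = y > 0
            if pos.sum() >= 2 and y[0] > 0:
                slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
                lam0, pa00 = max(-slope, 1e-6), y[0]
            else:
                lam0, pa00 = 0.1, max(y.max(), 1e-12)
        try:
            popt, pcov = curve_fit(lambda tt, a, lam: a * np.exp(-lam * tt),
                                   t, y, p0=(pa00, lam0), maxfev=10000)
        except RuntimeError as err:
            raise NumericalError(f"decay fit did not converge: {err}") from err
        pa0, lam = float(popt[0]), float(popt[1])
        if lam <= 0 or pa0 <= 0:
            raise NumericalError(
                f"non-decaying series: fitted PA0={pa0:.4g}, lambda={lam:.4g}"
            )
        se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
        resid = float(np.linalg.norm(y - pa0 * np.exp(-lam * t)))
        return DecayFit(pa0=pa0, lam=lam, residual_norm=resid,
                        pa0_se=float(se[0]), lam_se=float(se[1]), n_samples=t.size)

    def plot(self, fit: DecayFit | None = None, ax=None):
        """Data and (optionally refitted) exponential curve."""
        import matplotlib.pyplot as plt

        if fit is None:
            fit = self.fit()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times_min, self.values, "o", label="data")
        tt = np.linspace(0.0, float(self.times_min[-1]), 200)
        ax.plot(tt, fit.pa0 * np.exp(-fit.lam * tt), "-",
                label=f"fit: t1/2 = {fit.half_life_min:.3g} min")
        ax.set_xlabel("time from peak (min)")
        ax.set_ylabel("PA amplitude")
        ax.legend()
        return ax


def fit_halflife(times_min, values, log_linear: bool = False) -> DecayFit:
    """Functional form of :class:`ExponentialDecayModel` + ``fit``."""
    return ExponentialDecayModel(times_min, values).fit(log_linear=log_linear)


# ---------------------------------------------------------------------------
# Utilities
# ---------------------------------------------------------------------------

def spectral_correlation(measured, theoretical) -> float:
    """Pearson correlation between measured and theoretical spectrum samples
    on a shared wavelength support."""
    a = np.asarray(measured, dtype=float)
    b = np.asarray(theoretical, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValidationError("need two matched 1-D vectors of >= 3 samples")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("correlation undefined for a zero-variance spectrum")
    return float(stats.pearsonr(a, b).statistic)


def loading_ratio(molecules_per_ml: float, particles_per_ml: float) -> float:
    """Dye molecules per nanoparticle, to 3 significant figures."""
    if molecules_per_ml <= 0 or particles_per_ml <= 0:
        raise ValidationError("concentrations must be positive")
    q = molecules_per_ml / particles_per_ml
    return float(np.format_float_positional(q, precision=3, unique=False,
                                            fractional=False))


def compare_groups(a, b, tail: str = "two") -> tuple[float, float]:
    """Two-sample t-test (statistic, p-value).

    ``tail``: ``"two"`` (two-sided), ``"greater"``/``"one"`` (mean(a) >
    mean(b)) or ``"less"``. Utility only; no multiplicity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 observations")
    if np.std(a) == 0 and np.std(b) == 0:
        raise ValidationError("degenerate (zero-variance) groups")
    alt = {"two": "two-sided", "two-sided": "two-sided",
           "one": "greater", "greater": "greater", "less": "less"}.get(tail)
    if alt is None:
        raise ValidationError(f"unknown tail {tail!r}")
    res = stats.ttest_ind(a, b, alternative=alt)
    return float(res.statistic), float(res.pvalue)
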