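"""Per-voxel linear spectral unmixing and wavelength-subset scoring.

Multi-wavelength PA amplitude at a voxel is modeled as a linear combination
of chromophore absorption spectra sampled at the acquisition wavelengths
(the design matrix). Ordinary least squares per voxel recovers chromophore
coefficient maps, from which two ratio images follow:

    SO2 image         = HbO2 / (HbO2 + HHb)
    probe image       = probe / (HbO2 + HHb + probe)

Scalar estimates are spatial means of those images over an ROI. Wavelength
subsets are ranked by cost functions combining unmixing-accuracy terms with
a modest sqrt penalty on the number of wavelengths (faster acquisition).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import nnls

from .exceptions import NumericalError, ValidationError
from .spectra import SpectralLibrary
from .stacks import PAImageStack

__all__ = [
    "DesignMatrix",
    "build_design",
    "SpectralUnmixingModel",
    "UnmixResult",
    "unmix_stack",
    "derive_ratio_images",
    "auto_tube_roi",
    "roi_scalar",
    "WavelengthScore",
    "phantom_cost",
    "invivo_cost",
    "select_wavelengths",
    "DEFAULT_ALPHA",
]

#: Default weight of the sqrt(N) wavelength-count penalty. Chosen so the
#: penalty is "modest": it never overrides a >= 5-percentage-point
#: difference in the (fractional) error terms.
DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class DesignMatrix:
    """Extinction values sampled at the unmixing wavelengths
    (rows = wavelengths, cols = chromophores)."""

    wavelengths_nm: tuple
    chromophores: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "wavelengths_nm", tuple(float(w) for w in self.wavelengths_nm))
        object.__setattr__(self, "chromophores", tuple(self.chromophores))
        if m.shape != (len(self.wavelengths_nm), len(self.chromophores)):
            raise ValidationError("design matrix shape mismatch")
        if m.shape[0] < m.shape[1]:
            raise ValidationError(
                f"need >= as many wavelengths ({m.shape[0]}) as chromophores ({m.shape[1]})"
            )

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def build_design(library: SpectralLibrary, wavelengths_nm: Sequence[float],
                 chromophores: Sequence[str]) -> DesignMatrix:
    """Sample library spectra at the unmixing wavelengths and verify full
    column rank (naming the most collinear chromophore pair on failure)."""
    names = list(chromophores)
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"rank-deficient design: duplicated chromophore(s) {dup}")
    wl = [float(w) for w in wavelengths_nm]
    cols = [library[n](wl) for n in names]
    design = DesignMatrix(tuple(wl), tuple(names), np.column_stack(cols))
    if design.rank < len(names):
        # report the most collinear pair
        unit = design.matrix / np.linalg.norm(design.matrix, axis=0, keepdims=True)
        gram = np.abs(unit.T @ unit)
        np.fill_diagonal(gram, 0.0)
        i, j = np.unravel_index(np.argmax(gram), gram.shape)
        raise ValidationError(
            f"rank-deficient design on wavelengths {wl}: "
            f"{names[i]!r} and {names[j]!r} are collinear"
        )
    return design


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class SpectralUnmixingModel:
    """Per-voxel linear regression of a PA stack onto a chromophore design.

    Parameters
    ----------
    stack : PAImageStack
        Input images; its wavelengths must cover the design's (extra
        acquisition wavelengths are ignored).
    design : DesignMatrix
        Chromophore extinction sampled at the unmixing wavelengths.

    ``fit()`` returns an :class:`UnmixResult` with coefficient maps,
    residual norms, derived ratio images and ROI summaries.
    """

    def __init__(self, stack: PAImageStack, design: DesignMatrix):
        stack_wl = set(np.round(stack.wavelengths_nm, 6))
        missing = [w for w in design.wavelengths_nm if round(w, 6) not in stack_wl]
        if missing:
            raise ValidationError(f"stack lacks design wavelengths {missing}")
        self.stack = stack.subset(design.wavelengths_nm)
        self.design = design

    def fit(self, nonneg: bool = False) -> "UnmixResult":
        A = self.design.matrix
        y = self.stack.data  # [S, R, C, W]
        shape3 = y.shape[:3]
        Y = y.reshape(-1, A.shape[0])
        if nonneg:
            X = np.empty((Y.shape[0], A.shape[1]))
            for i in range(Y.shape[0]):
                X[i], _ = nnls(A, Y[i])
        else:
            X = Y @ np.linalg.pinv(A).T
        resid = np.linalg.norm(Y - X @ A.T, axis=1)
        coeffs = {name: X[:, k].reshape(shape3)
                  for k, name in enumerate(self.design.chromophores)}
        return UnmixResult(coefficients=coeffs,
                           residual_norm=resid.reshape(shape3),
                           design=self.design, nonneg=nonneg,
                           provenance=dict(self.stack.provenance))


@dataclass
class UnmixResult:
    """Chromophore coefficient maps + residuals from a spectral unmixing fit."""

    coefficients: dict
    residual_norm: np.ndarray
    design: DesignMatrix
    nonneg: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, m in self.coefficients.items():
            if not np.all(np.isfinite(m)):
                raise NumericalError(f"non-finite coefficients for {name!r}")
        if np.any(self.residual_norm < 0) or not np.all(np.isfinite(self.residual_norm)):
            raise NumericalError("invalid residual map")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.coefficients[name]

    def so2_image(self) -> np.ndarray:
        so2, _ = derive_ratio_images(self, probe_name=None)
        return so2

    def probe_fraction_image(self, probe_name: str) -> np.ndarray:
        _, frac = derive_ratio_images(self, probe_name)
        return frac

    def summary(self) -> str:
        lines = [
            "Spectral unmixing (per-voxel %s least squares)" %
            ("nonnegative" if self.nonneg else "ordinary"),
            f"  wavelengths (nm) : {list(self.design.wavelengths_nm)}",
            f"  chromophores     : {list(self.design.chromophores)}",
            f"  condition number : {self.design.condition_number:.3g}",
            f"  grid             : {self.residual_norm.shape}",
            f"  median residual  : {np.median(self.residual_norm):.4g}",
        ]
        for name, m in self.coefficients.items():
            lines.append(f"  {name:<18}: mean {m.mean():.4g}, max {m.max():.4g}")
        return "\n".join(lines)

    def plot(self, slice_index: int = 0, probe_name: str | None = None, axes=None):
        """SO2 (and probe-fraction) maps of one slice."""
        import matplotlib.pyplot as plt

        so2, frac = derive_ratio_images(
            self, probe_name if probe_name in self.coefficients else None)
        images = [("SO2", so2)] + ([("probe fraction", frac)] if frac is not None else [])
        if axes is None:
            _, axes = plt.subplots(1, len(images), squeeze=False)
            axes = axes[0]
        for ax, (title, img) in zip(axes, images):
            im = ax.imshow(img[slice_index], vmin=0, vmax=1)
            ax.set_title(title)
            plt.colorbar(im, ax=ax)
        return axes


def unmix_stack(stack: PAImageStack, design: DesignMatrix,
                nonneg: bool = False) -> UnmixResult:
    """Functional form of :class:`SpectralUnmixingModel` + ``fit``."""
    return SpectralUnmixingModel(stack, design).fit(nonneg=nonneg)


# ---------------------------------------------------------------------------
# Ratio images and ROIs
# ---------------------------------------------------------------------------

def derive_ratio_images(result: UnmixResult, probe_name: str | None):
    """SO2 and probe-fraction images from a fit.

    Negative coefficients are clipped to zero before forming the ratios, so
    both images lie in [0, 1]; voxels with a zero denominator are invalid
    (NaN), not zero. ``probe_name=None`` returns only the SO2 image (probe
    image is None).
    """
    coeffs = result.coefficients
    if "hbo2" not in coeffs or "hhb" not in coeffs:
        raise ValidationError("result lacks hemoglobin coefficients")
    hbo2 = np.clip(coeffs["hbo2"], 0.0, None)
    hhb = np.clip(coeffs["hhb"], 0.0, None)
    thb = hbo2 + hhb
    with np.errstate(invalid="ignore", divide="ignore"):
        so2 = np.where(thb > 0, hbo2 / np.where(thb > 0, thb, 1.0), np.nan)
    if probe_name is None:
        return so2, None
    if probe_name not in coeffs:
        raise ValidationError(f"probe {probe_name!r} absent from fit "
                              f"(have {list(coeffs)})")
    probe = np.clip(coeffs[probe_name], 0.0, None)
    total = thb + probe
    frac = np.where(total > 0, probe / np.where(total > 0, total, 1.0), np.nan)
    return so2, frac


def auto_tube_roi(stack: PAImageStack, anchor_wavelength_nm: float = 800.0,
                  half_size: int = 1) -> np.ndarray:
    """Automatic tube ROI: per slice, a (2*half_size+1)^2 window (3x3 by
    default) centered on the maximum-amplitude voxel of the anchor-wavelength
    image. Ties break to the first occurrence in row-major order; windows on
    the image border are clipped with a warning."""
    img = stack.plane(anchor_wavelength_nm)
    ns, nr, nc = img.shape
    roi = np.zeros(img.shape, dtype=bool)
    for s in range(ns):
        flat = int(np.argmax(img[s]))
        i, j = divmod(flat, nc)
        if i - half_size < 0 or i + half_size >= nr or j - half_size < 0 or j + half_size >= nc:
            warnings.warn(f"slice {s}: ROI window clipped at the image border",
                          stacklevel=2)
        roi[s, max(i - half_size, 0):i + half_size + 1,
            max(j - half_size, 0):j + half_size + 1] = True
    return roi


def roi_scalar(image: np.ndarray, roi: np.ndarray) -> float:
    """Arithmetic mean over valid (finite) ROI voxels."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValidationError("empty ROI")
    vals = np.asarray(image, dtype=float)[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError("all ROI voxels are invalid")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# Wavelength-subset cost functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavelengthScore:
    """A scored wavelength subset; ``total`` is the sum of the printed terms."""

    subset: tuple
    terms: dict
    penalty: float
    total: float

    def __post_init__(self):
        if len(self.subset) < 1:
            raise ValidationError("empty wavelength subset")
        s = sum(self.terms.values()) + self.penalty
        if not np.isclose(s, self.total):
            raise ValidationError("total must equal the sum of its terms")


def _score(subset, terms: dict, alpha: float) -> WavelengthScore:
    penalty = alpha * float(np.sqrt(len(subset)))
    return WavelengthScore(subset=tuple(float(w) for w in subset), terms=dict(terms),
                           penalty=penalty, total=sum(terms.values()) + penalty)


def phantom_cost(subset: Sequence[float], experiment, library: SpectralLibrary,
                 known_ratio: float = 3.0, alpha: float = DEFAULT_ALPHA,
                 nonneg: bool = False) -> WavelengthScore:
    """Phantom-experiment cost of a wavelength subset.

    ``experiment`` is a :class:`~paquant.workflows.PhantomExperiment`: tube
    stacks of blood-only controls and blood+probe mixtures at two probe
    concentrations. Terms (all dimensionless fractions):

    - ``so2_error``: mean |SO2(with probe) - SO2(blood-only)| over all
      SO2 x OD combinations;
    - ``ratio_error``: mean |recovered probe-signal ratio - R| / R for the
      known concentration ratio R (default threefold);
    - penalty ``alpha * sqrt(N)``.
    """
    if len(subset) < 3:
        raise ValidationError("subset must have >= 3 wavelengths (3 chromophores)")
    probe = experiment.probe_kind
    design = build_design(library, subset, ["hbo2", "hhb", probe])
    if not experiment.controls or not experiment.with_probe:
        raise ValidationError("phantom experiment lacks controls or probe acquisitions")

    def estimates(stack):
        res = unmix_stack(stack, design, nonneg=nonneg)
        roi = auto_tube_roi(stack, experiment.anchor_wavelength_nm)
        so2_img, frac_img = derive_ratio_images(res, probe)
        return roi_scalar(so2_img, roi), roi_scalar(frac_img, roi)

    so2_control = {so2: estimates(stk)[0] for so2, stk in experiment.controls.items()}
    so2_errs, probe_sig = [], {}
    for (so2, od), stk in experiment.with_probe.items():
        est_so2, est_frac = estimates(stk)
        so2_errs.append(abs(est_so2 - so2_control[so2]))
        probe_sig[(so2, od)] = est_frac
    ods = sorted({od for _, od in probe_sig})
    if len(ods) < 2:
        raise ValidationError("need two probe concentrations for the ratio term")
    lo, hi = ods[0], ods[-1]
    ratio_errs = []
    for so2 in sorted({s for s, _ in probe_sig}):
        if probe_sig[(so2, lo)] <= 0:
            ratio_errs.append(1.0)  # no recoverable low-concentration signal
            continue
        r = probe_sig[(so2, hi)] / probe_sig[(so2, lo)]
        ratio_errs.append(abs(r - known_ratio) / known_ratio)
    return _score(subset, {"so2_error": float(np.mean(so2_errs)),
                           "ratio_error": float(np.mean(ratio_errs))}, alpha)


def invivo_cost(subset: Sequence[float], pre: PAImageStack, post: PAImageStack,
                liver_roi: np.ndarray, library: SpectralLibrary,
                probe: str = "patrace", alpha: float = DEFAULT_ALPHA) -> WavelengthScore:
    """In-vivo cost of a wavelength subset.

    Minimizes (i) the preinjection probe signal in a superficial liver ROI
    (zero under perfect unmixing: no probe is present yet) and (ii) the
    change in the liver SO2 estimate from pre- to immediately-post-injection
    (liver SO2 is physiologically stable over that window, so any change is
    an unmixing artifact of the new chromophore), plus ``alpha * sqrt(N)``.
    """
    if len(subset) < 3:
        raise ValidationError("subset must have >= 3 wavelengths")
    if pre.data.shape[:3] != post.data.shape[:3]:
        raise ValidationError("pre/post stacks do not share a geometry")
    design = build_design(library, subset, ["hbo2", "hhb", probe])
    res_pre = unmix_stack(pre, design)
    res_post = unmix_stack(post, design)
    so2_pre, frac_pre = derive_ratio_images(res_pre, probe)
    so2_post, _ = derive_ratio_images(res_post, probe)
    delta = abs(roi_scalar(so2_pre, liver_roi) - roi_scalar(so2_post, liver_roi))
    pre_probe = roi_scalar(frac_pre, liver_roi)
    return _score(subset, {"delta_so2": float(delta),
                           "pre_probe": float(pre_probe)}, alpha)


def select_wavelengths(candidates: Sequence[float],
                       cost_function: Callable[[tuple], WavelengthScore],
                       min_size: int = 3,
                       constraint: Callable[[tuple], bool] | None = None) -> list:
    """Exhaustively score every subset of size >= ``min_size`` (optionally
    filtered by ``constraint``) and return scores ascending by total cost.
    Deterministic given the determinism of ``cost_function``."""
    cands = tuple(float(w) for w in candidates)
    if len(cands) > 12:
        raise ValidationError("exhaustive enumeration limited to <= 12 candidates")
    scores = []
    for n in range(min_size, len(cands) + 1):
        for subset in itertools.combinations(cands, n):
            if constraint is not None and not constraint(subset):
                continue
            scores.append(cost_function(subset))
    if not scores:
        raise ValidationError("no feasible wavelength subset")
    return sorted(scores, key=lambda s: (s.total, s.subset))
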