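"""Synthetic photoacoustic data with known ground truth.

Every input the analysis pipeline consumes can be generated here: tube
phantoms (blood + probe mixtures in a gelatin cylinder), longitudinal
in-vivo-like multi-organ studies imaged pre/post injection, serial probe
dilutions, and single-voxel washout time series. The forward model is the
standard PA generation law

    PA(x, lambda) = Gamma * Phi(x, lambda) * mu_a(x, lambda),

with Gamma a scalar PA-generation efficiency, Phi the optical fluence
(uniform unless a fluence field is supplied) and mu_a assembled from the
packaged chromophore spectra. Noise is multiplicative Gaussian
(pulse-energy fluctuation) plus an additive Gaussian floor. All randomness
flows through one seeded generator recorded in the stack provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError
from .spectra import SpectralLibrary, default_library
from .stacks import PAImageStack

__all__ = [
    "NoiseSpec",
    "Scene",
    "DecaySeries",
    "LongitudinalStudy",
    "make_phantom_scene",
    "render_stack",
    "make_longitudinal_study",
    "make_decay_series",
    "make_serial_dilution",
    "PHANTOM_WAVELENGTHS_NM",
    "INVIVO_WAVELENGTHS_NM",
]

LN10 = math.log(10.0)

#: The six phantom unmixing wavelengths.
PHANTOM_WAVELENGTHS_NM = (710.0, 734.0, 760.0, 800.0, 830.0, 870.0)
#: The seven in-vivo imaging wavelengths.
INVIVO_WAVELENGTHS_NM = (730.0, 760.0, 780.0, 800.0, 830.0, 890.0, 910.0)

#: Total heme molarity of whole blood (150 g/L Hb / 64500 g/mol x 4 hemes).
WHOLE_BLOOD_THB_M = 2.3e-3


@dataclass(frozen=True)
class NoiseSpec:
    """Acquisition noise: PA' = PA*(1+N(0,sigma_mult^2)) + N(0,sigma_add^2),
    with sigma_add expressed as a fraction of the noiseless stack maximum."""

    sigma_mult: float = 0.05
    sigma_add_frac: float = 0.005

    def __post_init__(self):
        if self.sigma_mult < 0 or self.sigma_add_frac < 0:
            raise ValidationError("noise fractions must be >= 0")


NOISELESS = NoiseSpec(0.0, 0.0)


@dataclass
class Scene:
    """Synthetic geometry with per-voxel ground truth.

    ``thb_map`` is heme molarity (M), ``so2_map`` a fraction in [0, 1],
    ``probe_od_map`` the probe optical density (1 cm path) per voxel.
    Background optics ``mua_background`` / ``musp_background`` are in m^-1;
    ``pa_efficiency`` is the dimensionless Gamma.
    """

    spacing_mm: tuple
    body_mask: np.ndarray
    rois: dict = field(default_factory=dict)
    thb_map: np.ndarray | None = None
    so2_map: np.ndarray | None = None
    probe_od_map: np.ndarray | None = None
    probe_kind: str = "patrace"
    mua_background: float = 10.0
    musp_background: float = 100.0
    pa_efficiency: float = 1.0
    library: SpectralLibrary | None = None

    def __post_init__(self):
        self.body_mask = np.asarray(self.body_mask, dtype=bool)
        shape = self.body_mask.shape
        if self.body_mask.ndim != 3:
            raise ValidationError("body_mask must be 3-D [slice, row, col]")
        for name in ("thb_map", "so2_map", "probe_od_map"):
            m = getattr(self, name)
            if m is None:
                m = np.zeros(shape)
            m = np.asarray(m, dtype=float)
            if m.shape != shape:
                raise ValidationError(f"{name} shape {m.shape} != body {shape}")
            setattr(self, name, m)
        if np.any(self.thb_map < 0) or np.any(self.probe_od_map < 0):
            raise ValidationError("concentration maps must be >= 0")
        perf = self.thb_map > 0
        if np.any((self.so2_map[perf] < 0) | (self.so2_map[perf] > 1)):
            raise ValidationError("so2_map must be within [0, 1] where thb > 0")
        for name, roi in self.rois.items():
            roi = np.asarray(roi, dtype=bool)
            if roi.shape != shape:
                raise ValidationError(f"ROI {name!r} shape mismatch")
            if np.any(roi & ~self.body_mask):
                raise ValidationError(f"ROI {name!r} extends outside the body mask")
            self.rois[name] = roi
        if self.mua_background <= 0 or self.musp_background <= 0:
            raise ValidationError("background optics must be positive")

    @property
    def shape(self):
        return self.body_mask.shape

    def _library(self) -> SpectralLibrary:
        if self.library is None:
            self.library = default_library()
        return self.library

    def absorption(self, wavelengths_nm) -> np.ndarray:
        """mu_a in m^-1, shape [slice, row, col, wavelength]."""
        lib = self._library()
        wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        eps_hbo2 = lib["hbo2"](wl)
        eps_hhb = lib["hhb"](wl)
        probe = lib[self.probe_kind]
        eps_probe = probe(wl)
        eps_probe_peak = float(np.max(probe.values))
        L = lib.reference_pathlength_cm
        # heme contribution (cm^-1 -> m^-1: x100); OD map -> molarity via peak eps
        hb = self.thb_map[..., None] * (
            self.so2_map[..., None] * eps_hbo2 + (1 - self.so2_map[..., None]) * eps_hhb
        )
        c_probe = self.probe_od_map / (eps_probe_peak * L)
        mua = 100.0 * LN10 * (hb + c_probe[..., None] * eps_probe)
        # background optics only where no chromophore lives (gelatin/bath);
        # chromophore-bearing voxels are described by the unmixing model
        background = self.body_mask & ~((self.thb_map > 0) | (self.probe_od_map > 0))
        mua += self.mua_background * background[..., None]
        return mua


def _cylinder_mask(shape, spacing_mm, diameter_mm, center_rc=None):
    _, nr, nc = shape
    rr, cc = np.mgrid[0:nr, 0:nc].astype(float)
    if center_rc is None:
        # voxel-centered so a small centered inclusion is grid-symmetric
        center_rc = (nr // 2, nc // 2)
    r2 = ((rr - center_rc[0]) * spacing_mm) ** 2 + ((cc - center_rc[1]) * spacing_mm) ** 2
    disk = r2 <= (diameter_mm / 2.0) ** 2
    return np.broadcast_to(disk, shape).copy()


def _disk_coverage(shape, spacing_mm, diameter_mm, oversample: int = 15):
    """Fractional sub-voxel coverage of a centered disk (partial-volume
    model for inclusions comparable to the voxel size)."""
    _, nr, nc = shape
    c_r, c_c = nr // 2, nc // 2
    sub = (np.arange(oversample) + 0.5) / oversample - 0.5
    rr, cc = np.mgrid[0:nr, 0:nc].astype(float)
    cov = np.zeros((nr, nc))
    rad2 = (diameter_mm / 2.0) ** 2
    for dr in sub:
        for dc in sub:
            r2 = (((rr + dr - c_r) * spacing_mm) ** 2
                  + ((cc + dc - c_c) * spacing_mm) ** 2)
            cov += r2 <= rad2
    cov /= oversample ** 2
    return np.broadcast_to(cov, shape).copy()


def make_phantom_scene(so2: float, probe_od: float, probe_kind: str = "patrace",
                       blood_fraction: float = 0.10, *,
                       shape=(12, 200, 200), spacing_mm: float = 0.1,
                       body_diameter_mm: float = 20.0,
                       tube_inner_diameter_mm: float = 0.4,
                       thb_whole_blood: float = WHOLE_BLOOD_THB_M,
                       library: SpectralLibrary | None = None) -> Scene:
    """Cylindrical gelatin phantom with a centered blood+probe-filled tube.

    The tube carries whole blood diluted to ``blood_fraction`` v/v (so thb is
    scaled by the fraction) at saturation ``so2``, co-mixed with probe at the
    stated optical density ``probe_od``. ``probe_od=0`` gives the blood-only
    control.
    """
    if not 0.0 <= so2 <= 1.0:
        raise ValidationError(f"so2 must be in [0, 1], got {so2!r}")
    if probe_od < 0:
        raise ValidationError("probe_od must be >= 0")
    if tube_inner_diameter_mm >= body_diameter_mm:
        raise ValidationError("tube does not fit inside the phantom body")
    body = _cylinder_mask(shape, spacing_mm, body_diameter_mm)
    coverage = _disk_coverage(shape, spacing_mm, tube_inner_diameter_mm)
    coverage[~body] = 0.0
    tube = coverage > 0
    if not tube.any():
        raise ValidationError("tube mask empty; refine the grid")
    # partial-volume tube: edge voxels hold proportionally less sample, and
    # the lumen displaces the gelatin background entirely
    thb = coverage * (blood_fraction * thb_whole_blood)
    so2_map = np.where(tube, so2, 0.0)
    od = coverage * probe_od
    return Scene(spacing_mm=(0.5, spacing_mm, spacing_mm), body_mask=body,
                 rois={"tube": tube}, thb_map=thb, so2_map=so2_map,
                 probe_od_map=od, probe_kind=probe_kind, library=library)


def render_stack(scene: Scene, wavelengths_nm: Sequence[float],
                 fluence=None, noise: NoiseSpec = NoiseSpec(),
                 seed: int | None = 0, *, time_label: str = "preinjection",
                 spectral_coloring: bool = False,
                 d_eff_mm: float = 0.2) -> PAImageStack:
    """Render a multi-wavelength PA stack from a scene.

    ``fluence`` may be None (uniform), a [S, R, C] field, or a
    [S, R, C, W] per-wavelength field. With ``spectral_coloring`` on, voxels
    containing blood are attenuated by exp(-mu_a(lambda) * d_eff): an
    effective in-vessel self-filtering path that emulates local spectral
    coloring (the mechanism by which real acquisitions bias unmixing).
    Identical seeds yield bitwise-identical stacks.
    """
    wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
    mua = scene.absorption(wl)
    pa = scene.pa_efficiency * mua
    if fluence is not None:
        phi = np.asarray(getattr(fluence, "values", fluence), dtype=float)
        if phi.ndim == 3:
            phi = phi[..., None]
        if phi.shape[:3] != scene.shape:
            raise ValidationError("fluence field shape does not match scene grid")
        pa = pa * phi
    if spectral_coloring:
        blood = scene.thb_map > 0
        atten = np.exp(-mua * (d_eff_mm * 1e-3))  # mua in 1/m, d_eff in m
        pa = np.where(blood[..., None], pa * atten, pa)
    prov = {"seed": seed, "noise": (noise.sigma_mult, noise.sigma_add_frac),
            "probe_kind": scene.probe_kind, "spectral_coloring": spectral_coloring}
    if noise.sigma_mult > 0 or noise.sigma_add_frac > 0:
        rng = np.random.default_rng(seed)
        scale = float(np.max(np.abs(pa))) if pa.size else 0.0
        if noise.sigma_mult > 0:
            pa = pa * (1.0 + rng.normal(0.0, noise.sigma_mult, pa.shape))
        if noise.sigma_add_frac > 0:
            pa = pa + rng.normal(0.0, noise.sigma_add_frac * scale, pa.shape)
    return PAImageStack(data=pa, wavelengths_nm=wl, spacing_mm=scene.spacing_mm,
                        time_label=time_label, provenance=prov)


# ---------------------------------------------------------------------------
# Longitudinal in-vivo-like study
# ---------------------------------------------------------------------------

def _ellipse_mask(shape, spacing_mm, center_rc_mm, semi_axes_mm, slices):
    ns, nr, nc = shape
    rr, cc = np.mgrid[0:nr, 0:nc].astype(float)
    d = (((rr * spacing_mm - center_rc_mm[0]) / semi_axes_mm[0]) ** 2
         + ((cc * spacing_mm - center_rc_mm[1]) / semi_axes_mm[1]) ** 2)
    disk = d <= 1.0
    out = np.zeros(shape, dtype=bool)
    for s in slices:
        if 0 <= s < ns:
            out[s] = disk
    return out


#: Organ blood content (heme M) and typical oxygen saturation.
_ORGAN_PHYSIOLOGY = {
    "liver": (0.25 * WHOLE_BLOOD_THB_M, 0.70),
    "spleen": (0.30 * WHOLE_BLOOD_THB_M, 0.75),
    "kidney": (0.20 * WHOLE_BLOOD_THB_M, 0.80),
    "tumor": (0.10 * WHOLE_BLOOD_THB_M, 0.55),
}


@dataclass
class LongitudinalStudy:
    """Stacks plus ground truth for a pre/post-injection imaging study."""

    stacks: list  # one PAImageStack per time-point
    scenes: list  # matched Scene per time-point
    timepoints_min: list
    truth_ce: dict  # roi name -> {t: true CE of the probe-fraction image}
    truth_so2: dict  # roi name -> true SO2
    rois: dict  # roi name -> boolean mask
    baseline_probe_fraction: float

    @property
    def preinjection(self) -> PAImageStack:
        return self.stacks[self.timepoints_min.index(0)]


def make_longitudinal_study(tumor_uptake: Mapping[float, float],
                            organ_uptake: Mapping[str, Mapping[float, float]] | None = None,
                            timepoints_min: Sequence[float] | None = None,
                            seed: int | None = 0, *,
                            shape=(12, 200, 200), spacing_mm: float = 0.1,
                            wavelengths_nm: Sequence[float] = INVIVO_WAVELENGTHS_NM,
                            noise: NoiseSpec = NoiseSpec(),
                            baseline_probe_fraction: float = 0.1,
                            probe_kind: str = "patrace",
                            library: SpectralLibrary | None = None) -> LongitudinalStudy:
    """Multi-slice body with liver/spleen/kidney/tumor ROIs imaged at several
    time-points sharing slice positions (co-registered by construction).

    ``tumor_uptake`` / ``organ_uptake`` give the *true* contrast enhancement
    of the probe-fraction image per ROI and time-point (CE >= -1). Because
    CE is a relative change, each ROI starts from a small preinjection
    baseline probe fraction f0 (default 0.1) and the probe concentration at
    time t is set so the noiseless fraction is exactly f0 * (1 + CE).
    """
    if timepoints_min is None:
        timepoints_min = sorted(tumor_uptake)
    timepoints_min = [float(t) for t in timepoints_min]
    if 0.0 not in timepoints_min:
        raise ValidationError("a preinjection time-point (t=0) is required")
    organ_uptake = dict(organ_uptake or {})
    uptake = {"tumor": dict(tumor_uptake), **{k: dict(v) for k, v in organ_uptake.items()}}
    for roi, prof in uptake.items():
        if any(v < -1 for v in prof.values()):
            raise ValidationError(f"uptake below -1 in ROI {roi!r}")

    ns, nr, nc = shape
    cy, cx = (nr - 1) / 2.0 * spacing_mm, (nc - 1) / 2.0 * spacing_mm
    body = _ellipse_mask(shape, spacing_mm, (cy, cx),
                         (0.45 * nr * spacing_mm, 0.45 * nc * spacing_mm), range(ns))
    third = max(1, ns // 3)
    rois = {
        "liver": _ellipse_mask(shape, spacing_mm, (cy - 0.2 * nr * spacing_mm, cx),
                               (2.5, 3.5), range(0, 2 * third)),
        "spleen": _ellipse_mask(shape, spacing_mm, (cy, cx - 0.25 * nc * spacing_mm),
                                (1.5, 2.0), range(third, max(2 * third, third + 2))),
        "kidney": _ellipse_mask(shape, spacing_mm, (cy, cx + 0.25 * nc * spacing_mm),
                                (1.5, 2.0), range(third, ns)),
        "tumor": _ellipse_mask(shape, spacing_mm, (cy + 0.22 * nr * spacing_mm, cx),
                               (2.0, 2.0), range(2 * third, ns)),
    }
    claimed = np.zeros(shape, dtype=bool)
    for name in rois:  # clip to the body and keep organs disjoint
        rois[name] &= body & ~claimed
        claimed |= rois[name]

    lib = library if library is not None else default_library()
    probe = lib[probe_kind]
    eps_peak = float(np.max(probe.values))

    thb = np.zeros(shape)
    so2 = np.zeros(shape)
    bg_thb, bg_so2 = 0.05 * WHOLE_BLOOD_THB_M, 0.65
    thb[body], so2[body] = bg_thb, bg_so2
    truth_so2 = {}
    for name, (o_thb, o_so2) in _ORGAN_PHYSIOLOGY.items():
        thb[rois[name]], so2[rois[name]] = o_thb, o_so2
        truth_so2[name] = o_so2

    f0 = baseline_probe_fraction
    if not 0 < f0 < 1:
        raise ValidationError("baseline_probe_fraction must be in (0, 1)")

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(timepoints_min))]

    stacks, scenes = [], []
    truth_ce = {name: {} for name in rois}
    for t, sub_seed in zip(timepoints_min, child_seeds):
        od = np.zeros(shape)
        for name, mask in rois.items():
            ce_t = 0.0 if t == 0.0 else uptake.get(name, {}).get(t, 0.0)
            frac = f0 * (1.0 + ce_t)
            if not 0 <= frac < 1:
                raise ValidationError(
                    f"CE {ce_t:g} in ROI {name!r} pushes probe fraction outside [0, 1)"
                )
            c_hb = thb[mask]
            c_probe = frac * c_hb / (1.0 - frac)
            od[mask] = c_probe * eps_peak * lib.reference_pathlength_cm
            truth_ce[name][t] = ce_t
        scene = Scene(spacing_mm=(0.5, spacing_mm, spacing_mm), body_mask=body,
                      rois=dict(rois), thb_map=thb, so2_map=so2, probe_od_map=od,
                      probe_kind=probe_kind, library=lib)
        label = "preinjection" if t == 0.0 else f"post_{t:g}min"
        stack = render_stack(scene, wavelengths_nm, noise=noise, seed=sub_seed,
                             time_label=label)
        stacks.append(stack.with_provenance(study_seed=seed, time_min=t))
        scenes.append(scene)
    return LongitudinalStudy(stacks=stacks, scenes=scenes,
                             timepoints_min=timepoints_min, truth_ce=truth_ce,
                             truth_so2=truth_so2, rois=rois,
                             baseline_probe_fraction=f0)


# ---------------------------------------------------------------------------
# Decay series and serial dilutions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecaySeries:
    """Single-voxel PA washout series with ground truth."""

    times_min: np.ndarray
    values: np.ndarray
    pa0: float
    half_life_min: float
    seed: int | None = None


def make_decay_series(pa0: float, half_life_min: float, times_min: Sequence[float],
                      noise_sd: float = 0.0, seed: int | None = 0) -> DecaySeries:
    """Exponential probe washout PA(t) = PA0 * exp(-ln2 * t / t_half) + noise,
    with the time origin at the signal maximum."""
    if half_life_min <= 0:
        raise ValidationError("half-life must be positive")
    t = np.asarray(times_min, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValidationError("times must be 1-D and strictly ascending")
    y = pa0 * np.exp(-math.log(2.0) * t / half_life_min)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, t.shape)
    return DecaySeries(times_min=t, values=y, pa0=pa0,
                       half_life_min=half_life_min, seed=seed)


def make_serial_dilution(probe_kind: str, ods: Sequence[float],
                         wavelengths_nm: Sequence[float], seed: int | None = 0,
                         noise: NoiseSpec = NOISELESS, *,
                         shape=(1, 60, 60), spacing_mm: float = 0.2,
                         library: SpectralLibrary | None = None) -> list:
    """One single-inclusion gelatin-phantom stack per OD. The noiseless
    peak-wavelength signal is exactly proportional to OD (concentration-
    dependent self-aggregation is deliberately not modeled)."""
    ods = [float(o) for o in ods]
    if any(o <= 0 for o in ods):
        raise ValidationError("ods must be positive")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(ods))]
    stacks = []
    for od, sub_seed in zip(ods, seeds):
        scene = make_phantom_scene(so2=0.0, probe_od=od, probe_kind=probe_kind,
                                   blood_fraction=0.0, shape=shape,
                                   spacing_mm=spacing_mm,
                                   body_diameter_mm=0.9 * shape[1] * spacing_mm,
                                   tube_inner_diameter_mm=2.0, library=library)
        stacks.append(render_stack(scene, wavelengths_nm, noise=noise, seed=sub_seed,
                                   time_label=f"od_{od:g}"))
    return stacks
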