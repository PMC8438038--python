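"""Surface-fluence model of a ring-illumination PA system and its smooth
propagation into the body.

The irradiation field of a ring of fiber-bundle pairs is modeled at the
body surface as a superposition over sources of (i) exponential attenuation
through the water coupling bath, exp(-mua_water(lambda) * d), and (ii) the
Green's function of the steady-state photon diffusion equation,
G(r) = exp(-mu_eff * r) / (4 pi D r), capturing beam divergence. Surface
values (normalized to max 1 per wavelength) are then propagated into the
volume by solving the homogeneous diffusion equation

    -div(D grad Phi) + mua * Phi = 0

on the voxel grid with Dirichlet data on the extracted surface, using
average tissue optics held constant across wavelength
(mua = 10 m^-1, mus' = 100 m^-1 by default). Dividing a PA stack by the
resulting field is the surface-fluence correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import splu

from .exceptions import NumericalError, ValidationError
from .spectra import water_absorption
from .stacks import PAImageStack

__all__ = [
    "IlluminationGeometry",
    "FluenceField",
    "extract_surface",
    "surface_fluence",
    "propagate_interior",
    "compute_fluence",
    "correct_stack",
]


@dataclass(frozen=True)
class IlluminationGeometry:
    """Ring illumination: ``n_fiber_pairs`` pairs of sources on a ring of
    ``ring_radius_mm`` centered on the grid, immersed in water. Tissue optics
    in m^-1."""

    ring_radius_mm: float = 40.0
    n_fiber_pairs: int = 5
    pair_half_angle_deg: float = 6.0
    mua_tissue: float = 10.0   # m^-1
    musp_tissue: float = 100.0  # m^-1

    def __post_init__(self):
        if self.mua_tissue <= 0 or self.musp_tissue <= 0:
            raise ValidationError("tissue optics must be positive")
        if self.ring_radius_mm <= 0 or self.n_fiber_pairs < 1:
            raise ValidationError("invalid ring geometry")

    @property
    def mu_eff(self) -> float:
        """Effective attenuation sqrt(3 * mua * (mua + mus')) in m^-1."""
        return math.sqrt(3.0 * self.mua_tissue * (self.mua_tissue + self.musp_tissue))

    @property
    def diffusion_mm(self) -> float:
        """Diffusion coefficient D = 1 / (3 (mua + mus')), in mm."""
        return 1000.0 / (3.0 * (self.mua_tissue + self.musp_tissue))

    def source_positions_mm(self) -> np.ndarray:
        """(2*n_fiber_pairs, 2) in-plane (y, x) positions on the ring,
        relative to the ring center."""
        base = np.arange(self.n_fiber_pairs) * (2 * math.pi / self.n_fiber_pairs)
        half = math.radians(self.pair_half_angle_deg)
        angles = np.concatenate([base - half, base + half])
        return self.ring_radius_mm * np.column_stack([np.sin(angles), np.cos(angles)])


@dataclass
class FluenceField:
    """Per-wavelength fluence on the scene grid, shape [S, R, C, W],
    normalized to max 1 per wavelength inside the body mask."""

    values: np.ndarray
    wavelengths_nm: np.ndarray
    body_mask: np.ndarray
    normalized: bool = True
    geometry: IlluminationGeometry | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths_nm = np.atleast_1d(np.asarray(self.wavelengths_nm, dtype=float))
        self.body_mask = np.asarray(self.body_mask, dtype=bool)
        if self.values.ndim != 4 or self.values.shape[-1] != self.wavelengths_nm.size:
            raise ValidationError("fluence values must be [S, R, C, W] matching wavelengths")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("fluence field contains non-finite values")
        inside = self.values[self.body_mask]
        if inside.size and np.any(inside <= 0):
            raise ValidationError("fluence must be strictly positive inside the body")


def extract_surface(body_mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: body voxels with >= 1 outside 4-neighbor per slice."""
    m = np.asarray(body_mask, dtype=bool)
    if m.ndim != 3:
        raise ValidationError("body mask must be 3-D [slice, row, col]")
    inside4 = np.ones_like(m)
    inside4[:, 1:, :] &= m[:, :-1, :]
    inside4[:, :-1, :] &= m[:, 1:, :]
    inside4[:, :, 1:] &= m[:, :, :-1]
    inside4[:, :, :-1] &= m[:, :, 1:]
    # voxels on the array edge count as having an outside neighbor
    inside4[:, 0, :] = inside4[:, -1, :] = False
    inside4[:, :, 0] = inside4[:, :, -1] = False
    return m & ~inside4


def surface_fluence(geometry: IlluminationGeometry, body_mask: np.ndarray,
                    wavelength_nm: float, spacing_mm: float = 0.1) -> np.ndarray:
    """Surface values on the extracted boundary, shape [S, R, C] (zero off
    the boundary), normalized to max 1.

    Each boundary point p receives
    sum_s exp(-mua_water(lambda) * |p - s|) * exp(-mu_eff |p - s|) / (4 pi D |p - s|),
    with the source-to-surface path taken as a straight line through the
    coupling bath.
    """
    surf = extract_surface(body_mask)
    if not surf.any():
        raise ValidationError("empty surface; check the body mask")
    ns, nr, nc = surf.shape
    cy, cx = (nr - 1) / 2.0, (nc - 1) / 2.0
    mua_w = float(water_absorption(wavelength_nm)) / 10.0  # cm^-1 -> mm^-1
    mu_eff = geometry.mu_eff / 1000.0  # m^-1 -> mm^-1
    D = geometry.diffusion_mm
    sources = geometry.source_positions_mm()
    out = np.zeros(surf.shape)
    sz, sy, sx = np.nonzero(surf)
    p = np.column_stack([(sy - cy) * spacing_mm, (sx - cx) * spacing_mm])
    r = np.sqrt(((p[:, None, :] - sources[None, :, :]) ** 2).sum(-1))
    if np.any(r < 1e-9):
        raise ValidationError("a boundary point coincides with a source (singular Green's function)")
    vals = (np.exp(-mua_w * r) * np.exp(-mu_eff * r) / (4.0 * math.pi * D * r)).sum(axis=1)
    out[sz, sy, sx] = vals / vals.max()
    return out


def _mask_key(m2d: np.ndarray) -> bytes:
    return m2d.tobytes()


def propagate_interior(surface_values: np.ndarray, body_mask: np.ndarray,
                       geometry: IlluminationGeometry, spacing_mm: float = 0.1,
                       tolerance: float = 1e-8) -> np.ndarray:
    """Solve -div(D grad Phi) + mua Phi = 0 inside the mask per slice with
    Dirichlet data on the surface; returns a [S, R, C] field (surface values
    on the boundary, zero outside the body).

    ``surface_values`` may carry a trailing wavelength axis, in which case
    a [S, R, C, W] array is returned (one sparse factorization per distinct
    slice mask, reused across wavelengths: tissue optics are wavelength-
    independent by design).
    """
    sv = np.asarray(surface_values, dtype=float)
    squeeze = sv.ndim == 3
    if squeeze:
        sv = sv[..., None]
    mask = np.asarray(body_mask, dtype=bool)
    surf = extract_surface(mask)
    if np.any(sv[surf] <= 0):
        raise ValidationError("surface values must be strictly positive")
    D = geometry.diffusion_mm
    mua = geometry.mua_tissue / 1000.0  # mm^-1
    h2 = spacing_mm ** 2
    ns = mask.shape[0]
    nw = sv.shape[-1]
    out = np.zeros(sv.shape)
    cache: dict[bytes, tuple] = {}
    for s in range(ns):
        m2, b2 = mask[s], surf[s]
        interior = m2 & ~b2
        out[s][b2] = sv[s][b2]
        if not interior.any():
            continue
        key = _mask_key(m2)
        if key not in cache:
            cache[key] = _factorize_slice(interior, D, mua, h2)
        lu, idx_map, neighbor_cols = cache[key]
        nun = int(interior.sum())
        for w in range(nw):
            rhs = np.zeros(nun)
            for (di, dj) in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                shifted = np.roll(b2, (di, dj), axis=(0, 1))
                sval = np.roll(sv[s, :, :, w], (di, dj), axis=(0, 1))
                contrib = np.where(shifted, sval, 0.0)[interior]
                rhs += (D / h2) * contrib
            phi = lu.solve(rhs)
            if not np.all(np.isfinite(phi)):
                raise NumericalError("interior diffusion solve produced non-finite values")
            plane = out[s, :, :, w]
            plane[interior] = phi
            out[s, :, :, w] = plane
    if squeeze:
        out = out[..., 0]
    return out


def _factorize_slice(interior: np.ndarray, D: float, mua: float, h2: float):
    """Sparse LU of the 5-point diffusion operator restricted to interior
    voxels of one slice (Dirichlet elimination of boundary neighbors)."""
    nr, nc = interior.shape
    idx_map = -np.ones(interior.shape, dtype=np.int64)
    ii, jj = np.nonzero(interior)
    n = ii.size
    idx_map[ii, jj] = np.arange(n)
    rows, cols, vals = [], [], []
    diag = np.full(n, 4.0 * D / h2 + mua)
    for (di, dj) in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ni, nj = ii + di, jj + dj
        ok = (ni >= 0) & (ni < nr) & (nj >= 0) & (nj < nc)
        nk = np.where(ok, idx_map[np.clip(ni, 0, nr - 1), np.clip(nj, 0, nc - 1)], -1)
        inside = nk >= 0
        rows.append(np.arange(n)[inside])
        cols.append(nk[inside])
        vals.append(np.full(int(inside.sum()), -D / h2))
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = csr_matrix((np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                   shape=(n, n))
    return splu(A.tocsc()), idx_map, None


def compute_fluence(geometry: IlluminationGeometry, body_mask: np.ndarray,
                    wavelengths_nm, spacing_mm: float = 0.1) -> FluenceField:
    """Surface model + interior propagation for every wavelength, normalized
    to max 1 per wavelength inside the body."""
    wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
    sv = np.stack([surface_fluence(geometry, body_mask, w, spacing_mm) for w in wl],
                  axis=-1)
    field = propagate_interior(sv, body_mask, geometry, spacing_mm)
    mask = np.asarray(body_mask, dtype=bool)
    for w in range(wl.size):
        peak = field[..., w][mask].max()
        field[..., w] /= peak
    return FluenceField(values=field, wavelengths_nm=wl, body_mask=mask,
                        normalized=True, geometry=geometry)


def correct_stack(stack: PAImageStack, field: FluenceField,
                  floor: float = 0.05) -> PAImageStack:
    """Divide a PA stack by the fluence field (surface-fluence correction).

    Each voxel inside the body becomes ``PA / max(Phi, floor * max(Phi))``;
    voxels outside the body mask are untouched. Raises on an already-
    corrected stack (the flag toggles exactly once per pipeline run).
    """
    if stack.fluence_corrected:
        raise ValidationError("stack is already fluence-corrected")
    if not 0 < floor < 1:
        raise ValidationError("floor must be a fraction in (0, 1)")
    if stack.data.shape[:3] != field.body_mask.shape:
        raise ValidationError("stack and fluence grids do not match")
    if (stack.wavelengths_nm.size != field.wavelengths_nm.size
            or not np.allclose(stack.wavelengths_nm, field.wavelengths_nm)):
        raise ValidationError("stack and fluence wavelengths do not match")
    out = stack.data.copy()
    mask = field.body_mask
    for w in range(field.wavelengths_nm.size):
        phi = field.values[..., w]
        clamp = np.maximum(phi, floor * phi[mask].max())
        out[..., w][mask] = stack.data[..., w][mask] / clamp[mask]
    corrected = PAImageStack(data=out, wavelengths_nm=stack.wavelengths_nm,
                             spacing_mm=stack.spacing_mm, time_label=stack.time_label,
                             fluence_corrected=True,
                             provenance=dict(stack.provenance))
    return corrected.with_provenance(fluence_floor=floor)
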