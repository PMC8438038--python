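"""Container for reconstructed multi-wavelength photoacoustic image stacks."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .exceptions import ValidationError

__all__ = ["PAImageStack"]


@dataclass
class PAImageStack:
    """A reconstructed PA image volume, indexed ``[slice, row, col, wavelength]``.

    Attributes
    ----------
    data : ndarray, shape (S, R, C, W)
        PA amplitude (arbitrary units), finite everywhere.
    wavelengths_nm : ndarray, shape (W,)
        Acquisition wavelengths.
    spacing_mm : tuple of 3 floats
        Voxel spacing (slice, row, col).
    time_label : str
        ``"preinjection"`` or ``"post_<t>min"`` (or any free label).
    fluence_corrected : bool
        Set exactly once along a pipeline run by the fluence correction.
    provenance : dict
        Seed, generator config, processing history.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    spacing_mm: tuple = (0.5, 0.1, 0.1)
    time_label: str = "preinjection"
    fluence_corrected: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError("stack data must be 4-D [slice, row, col, wavelength]")
        if self.data.shape[-1] != self.wavelengths_nm.size:
            raise ValidationError(
                f"wavelength axis length {self.data.shape[-1]} != "
                f"{self.wavelengths_nm.size} listed wavelengths"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("stack contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("spacing_mm must be 3 positive floats")

    @property
    def shape(self):
        return self.data.shape

    def plane(self, wavelength_nm: float) -> np.ndarray:
        """The [S, R, C] image at one acquisition wavelength."""
        idx = np.nonzero(np.isclose(self.wavelengths_nm, wavelength_nm))[0]
        if idx.size == 0:
            raise ValidationError(
                f"wavelength {wavelength_nm:g} nm not acquired; have {self.wavelengths_nm}"
            )
        return self.data[..., idx[0]]

    def subset(self, wavelengths_nm) -> "PAImageStack":
        """Restrict to a subset of the acquired wavelengths (order preserved
        as requested)."""
        wanted = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        cols = []
        for w in wanted:
            idx = np.nonzero(np.isclose(self.wavelengths_nm, w))[0]
            if idx.size == 0:
                raise ValidationError(f"wavelength {w:g} nm not in stack")
            cols.append(idx[0])
        return replace(self, data=self.data[..., cols], wavelengths_nm=wanted,
                       provenance=dict(self.provenance))

    def with_provenance(self, **kv: Any) -> "PAImageStack":
        prov = dict(self.provenance)
        prov.update(kv)
        return replace(self, provenance=prov)
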