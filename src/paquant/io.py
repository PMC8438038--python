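"""On-disk formats: PA stacks as NIfTI-1 or multi-page TIFF with a JSON
sidecar carrying wavelengths and acquisition metadata; run configuration as
YAML."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

from .exceptions import FormatError, ValidationError
from .stacks import PAImageStack

__all__ = ["read_stack", "write_stack", "sidecar_path", "RunConfig"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def sidecar_path(path: Path) -> Path:
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    raise FormatError(f"unsupported stack format: {path} (use .nii[.gz] or .tif[f])")


def write_stack(stack: PAImageStack, path) -> Path:
    """Write a stack (NIfTI-1 for .nii/.nii.gz, multi-page TIFF for
    .tif/.tiff) plus its JSON sidecar. Lossless for float64 data."""
    path = Path(path)
    side = sidecar_path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag([*stack.spacing_mm, 1.0])
        img = nib.Nifti1Image(stack.data, affine)
        img.header.set_data_dtype(np.float64)
        nib.save(img, str(path))
    else:
        tifffile.imwrite(path, stack.data, photometric="minisblack")
    meta = {
        "wavelengths_nm": stack.wavelengths_nm.tolist(),
        "spacing_mm": list(stack.spacing_mm),
        "time_label": stack.time_label,
        "fluence_corrected": stack.fluence_corrected,
        "provenance": _jsonable(stack.provenance),
    }
    side.write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path) -> PAImageStack:
    """Read a stack and its JSON sidecar; the sidecar's wavelength count
    must match the data's wavelength axis."""
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing JSON sidecar {side}")
    meta = json.loads(side.read_text())
    if "wavelengths_nm" not in meta:
        raise FormatError(f"sidecar {side} lacks 'wavelengths_nm'")
    if path.name.endswith((".nii", ".nii.gz")):
        data = np.asarray(nib.load(str(path)).get_fdata())
    else:
        data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 3:  # single-wavelength volume
        data = data[..., None]
    if data.shape[-1] != len(meta["wavelengths_nm"]):
        raise FormatError(
            f"{path}: {data.shape[-1]} wavelength planes but sidecar lists "
            f"{len(meta['wavelengths_nm'])}"
        )
    return PAImageStack(
        data=data,
        wavelengths_nm=np.asarray(meta["wavelengths_nm"], dtype=float),
        spacing_mm=tuple(meta.get("spacing_mm", (0.5, 0.1, 0.1))),
        time_label=meta.get("time_label", "preinjection"),
        fluence_corrected=bool(meta.get("fluence_corrected", False)),
        provenance=meta.get("provenance", {}),
    )


@dataclass
class RunConfig:
    """Serializable configuration of an end-to-end run: a run is
    reproducible from its config + seed alone."""

    seed: int = 0
    output_dir: str = "paquant_run"
    probe: str = "patrace"
    wavelengths_nm: tuple = (710.0, 734.0, 760.0, 800.0, 830.0, 870.0, 890.0, 900.0, 920.0)
    unmix_wavelengths_nm: tuple = (710.0, 734.0, 760.0, 800.0, 830.0, 870.0)
    so2_levels: tuple = (0.5, 0.7)
    probe_ods: tuple = (0.3, 0.9)
    blood_fraction: float = 0.1
    sigma_mult: float = 0.05
    sigma_add_frac: float = 0.005
    grid_shape: tuple = (12, 200, 200)
    spacing_mm: float = 0.1
    nonneg: bool = False
    alpha: float = 0.01
    fluence_correction: bool = False
    select_wavelengths: bool = False
    # longitudinal study settings
    timepoints_min: tuple = (0.0, 1.0, 30.0, 60.0)
    tumor_uptake: dict = field(default_factory=lambda: {0.0: 0.0, 1.0: 1.0, 30.0: 1.5, 60.0: 2.0})
    organ_uptake: dict = field(default_factory=lambda: {
        "liver": {1.0: 1.0, 30.0: 1.2, 60.0: 1.2},
        "spleen": {1.0: 0.8, 30.0: 1.0, 60.0: 1.0},
        "kidney": {1.0: 0.0, 30.0: 0.0, 60.0: 0.0},
    })
    invivo_wavelengths_nm: tuple = (730.0, 760.0, 780.0, 800.0, 830.0, 890.0, 910.0)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(_jsonable(dataclasses.asdict(self)),
                                       sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("wavelengths_nm", "unmix_wavelengths_nm", "so2_levels",
                    "probe_ods", "grid_shape", "timepoints_min", "invivo_wavelengths_nm"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)
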