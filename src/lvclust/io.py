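"""Domain types and readers/writers for left-ventricle segmentation stacks.

A segmentation stack is one patient's ordered short-axis slices, each a 2D
integer label map with four classes:

====  ====================  =======
code  region                palette
====  ====================  =======
0     background            black
1     compacted external    green
      layer (EL)
2     internal cavity (IC)  light blue
3     trabecular zone (TZ)  yellow
====  ====================  =======

Stacks travel either as a 3D NIfTI label volume (slice axis third) or as a
directory of paletted PNG slices named ``<patient>_s<index>.png`` with an
optional JSON sidecar for voxel geometry.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import nibabel as nib
import numpy as np
from PIL import Image

__all__ = [
    "BACKGROUND",
    "EL",
    "IC",
    "TZ",
    "CLASS_NAMES",
    "PALETTE",
    "ValidationError",
    "VoxelGeometry",
    "SegmentationStack",
    "validate_label_map",
    "read_stack",
    "write_stack",
]

BACKGROUND, EL, IC, TZ = 0, 1, 2, 3
CLASS_NAMES = {BACKGROUND: "background", EL: "EL", IC: "IC", TZ: "TZ"}
VALID_LABELS = frozenset((BACKGROUND, EL, IC, TZ))

# RGB palette for paletted-PNG output: green EL, light-blue IC, yellow TZ.
PALETTE = {
    BACKGROUND: (0, 0, 0),
    EL: (0, 160, 40),
    IC: (120, 200, 255),
    TZ: (255, 215, 0),
}

_PNG_NAME = re.compile(r"^(?P<patient>.+)_s(?P<index>\d+)\.png$")


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


def validate_label_map(pixels: np.ndarray, *, slice_index: Optional[int] = None) -> np.ndarray:
    """Check a 2D label map; returns it as a C-contiguous uint8 array.

    Raises :class:`ValidationError` naming the offending value (and slice,
    when given) if any pixel lies outside {0, 1, 2, 3}.
    """
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValidationError(f"label map must be non-empty 2D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.round(arr)):
            raise ValidationError("label map contains non-integer values")
        arr = arr.astype(np.int64)
    bad = np.setdiff1d(np.unique(arr), sorted(VALID_LABELS))
    if bad.size:
        where = f" in slice {slice_index}" if slice_index is not None else ""
        raise ValidationError(f"invalid label value(s) {bad.tolist()}{where}; expected 0..3")
    return np.ascontiguousarray(arr, dtype=np.uint8)


@dataclass(frozen=True)
class VoxelGeometry:
    """In-plane pixel spacing and through-plane slice geometry, in mm.

    The effective slice pitch is ``slice_thickness + slice_gap``; the default
    (1.5, 1.5, 8, 2) matches a typical 1.5 T cine short-axis protocol.
    """

    pixel_spacing_x: float = 1.5
    pixel_spacing_y: float = 1.5
    slice_thickness: float = 8.0
    slice_gap: float = 2.0

    def __post_init__(self) -> None:
        for name in ("pixel_spacing_x", "pixel_spacing_y", "slice_thickness", "slice_gap"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be strictly positive, got {v}")

    @property
    def slice_pitch(self) -> float:
        return self.slice_thickness + self.slice_gap

    @property
    def voxel_volume(self) -> float:
        """Volume in mm^3 attributed to one labelled pixel."""
        return self.pixel_spacing_x * self.pixel_spacing_y * self.slice_pitch

    def to_dict(self) -> dict:
        return {
            "pixel_spacing_x": self.pixel_spacing_x,
            "pixel_spacing_y": self.pixel_spacing_y,
            "slice_thickness": self.slice_thickness,
            "slice_gap": self.slice_gap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGeometry":
        return cls(**{k: float(d[k]) for k in ("pixel_spacing_x", "pixel_spacing_y",
                                               "slice_thickness", "slice_gap")})


class SegmentationStack:
    """One patient's ordered slices of class labels plus voxel geometry.

    Slices are stored as a (n_slices, height, width) uint8 array; slice order
    (apex-first or base-first) is whatever the source provided and is
    preserved exactly on round-trip. All algorithms downstream are symmetric
    in slice direction.
    """

    def __init__(
        self,
        patient_id: str,
        slices: Sequence[np.ndarray] | np.ndarray,
        geometry: Optional[VoxelGeometry] = None,
    ) -> None:
        if isinstance(slices, np.ndarray) and slices.ndim == 3:
            maps = [slices[i] for i in range(slices.shape[0])]
        else:
            maps = list(slices)
        if not maps:
            raise ValidationError("a stack needs at least one slice")
        checked = [validate_label_map(m, slice_index=i) for i, m in enumerate(maps)]
        shape = checked[0].shape
        for i, m in enumerate(checked):
            if m.shape != shape:
                raise ValidationError(
                    f"slice {i} has shape {m.shape}, expected {shape} (all slices must match)"
                )
        self.patient_id = str(patient_id)
        self.voxels = np.stack(checked, axis=0)
        self.geometry = geometry

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple:
        return self.voxels.shape[1:]

    @property
    def slices(self) -> List[np.ndarray]:
        return [self.voxels[i] for i in range(self.n_slices)]

    def __len__(self) -> int:
        return self.n_slices

    def __getitem__(self, i: int) -> np.ndarray:
        return self.voxels[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentationStack):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.voxels.shape == other.voxels.shape
            and bool(np.array_equal(self.voxels, other.voxels))
        )

    def with_voxels(self, voxels: np.ndarray) -> "SegmentationStack":
        """Same patient/geometry, new label data."""
        return SegmentationStack(self.patient_id, voxels, self.geometry)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _geometry_to_descrip(g: VoxelGeometry) -> bytes:
    return (
        f"sx={g.pixel_spacing_x:g};sy={g.pixel_spacing_y:g};"
        f"thk={g.slice_thickness:g};gap={g.slice_gap:g}"
    ).encode()


def _geometry_from_header(hdr) -> Optional[VoxelGeometry]:
    descrip = bytes(hdr["descrip"]).split(b"\x00", 1)[0].decode(errors="ignore")
    m = re.match(r"sx=([\d.eE+-]+);sy=([\d.eE+-]+);thk=([\d.eE+-]+);gap=([\d.eE+-]+)", descrip)
    if m:
        sx, sy, thk, gap = (float(x) for x in m.groups())
        return VoxelGeometry(sx, sy, thk, gap)
    zooms = hdr.get_zooms()[:3]
    if all(z > 0 for z in zooms) and tuple(zooms) != (1.0, 1.0, 1.0):
        # no gap information in a plain header: fold the pitch into thickness
        return VoxelGeometry(float(zooms[0]), float(zooms[1]), float(zooms[2]), 1e-9)
    return None


def _read_nifti(path: Path, patient_id: Optional[str]) -> SegmentationStack:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"expected 3D label volume, got {data.ndim}D")
    slices = [data[:, :, i] for i in range(data.shape[2])]
    pid = patient_id or re.sub(r"\.nii(\.gz)?$", "", path.name)
    return SegmentationStack(pid, slices, _geometry_from_header(img.header))


def _write_nifti(stack: SegmentationStack, path: Path) -> None:
    vol = np.moveaxis(stack.voxels, 0, 2).astype(np.uint8)
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    if stack.geometry is not None:
        g = stack.geometry
        img.header.set_zooms((g.pixel_spacing_x, g.pixel_spacing_y, g.slice_pitch))
        img.header["descrip"] = _geometry_to_descrip(g)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# PNG directory
# ---------------------------------------------------------------------------

def _flat_palette() -> list:
    pal = [0] * (256 * 3)
    for code, rgb in PALETTE.items():
        pal[3 * code: 3 * code + 3] = rgb
    return pal


def _read_png_dir(path: Path, patient_id: Optional[str]) -> SegmentationStack:
    entries = []
    for f in path.iterdir():
        m = _PNG_NAME.match(f.name)
        if m:
            entries.append((int(m.group("index")), m.group("patient"), f))
    if not entries:
        raise ValidationError(f"no '<patient>_s<index>.png' slices found in {path}")
    entries.sort(key=lambda e: e[0])
    pid = patient_id or entries[0][1]
    slices = []
    for i, (_, _, f) in enumerate(entries):
        arr = np.array(Image.open(f))
        slices.append(validate_label_map(arr, slice_index=i))
    geometry = None
    sidecar = path / "geometry.json"
    if sidecar.exists():
        geometry = VoxelGeometry.from_dict(json.loads(sidecar.read_text()))
    return SegmentationStack(pid, slices, geometry)


def _write_png_dir(stack: SegmentationStack, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    pal = _flat_palette()
    for i in range(stack.n_slices):
        img = Image.fromarray(stack.voxels[i], mode="P")
        img.putpalette(pal)
        img.save(path / f"{stack.patient_id}_s{i:02d}.png")
    if stack.geometry is not None:
        (path / "geometry.json").write_text(json.dumps(stack.geometry.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_stack(path, format: Optional[str] = None, patient_id: Optional[str] = None) -> SegmentationStack:
    """Read a segmentation stack from ``path``.

    ``format`` is ``"nifti"`` or ``"png_dir"``; when omitted it is inferred
    (directory → png_dir, ``.nii``/``.nii.gz`` → nifti).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file or directory: {p}")
    if format is None:
        format = "png_dir" if p.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(p, patient_id)
    if format == "png_dir":
        return _read_png_dir(p, patient_id)
    raise ValueError(f"unknown format {format!r}; expected 'nifti' or 'png_dir'")


def write_stack(stack: SegmentationStack, path, format: Optional[str] = None) -> None:
    """Write ``stack`` so that :func:`read_stack` reproduces it exactly."""
    p = Path(path)
    if format is None:
        format = "nifti" if p.suffix in (".nii", ".gz") or p.name.endswith(".nii.gz") else "png_dir"
    if format == "nifti":
        _write_nifti(stack, p)
    elif format == "png_dir":
        _write_png_dir(stack, p)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'nifti' or 'png_dir'")
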