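"""Canonical label volumes, landmarks and coverage masks.

Every measurement in this package runs on a :class:`LabelVolume` in a fixed
*canonical frame*:

* ``+x``: medial -> lateral
* ``+y``: inferior -> superior
* ``+z``: anterior -> posterior (the coronal slice index)

The frame is hemisphere-relative: a left-hemisphere volume is flipped along
x at load time so that "medial" always means "small x" downstream. Distances
between slices ``z1 < z2`` are ``(z2 - z1) * dz`` millimetres (inter-slice
distance, not an inclusive slice count).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, LandmarkError, OrientationError, SchemaError

REQUIRED_LABELS = ("SUB", "PrS", "PaS", "CA1", "CA2", "CA3", "DG", "SRLM")

#: Default label coding used by the phantom generator and the examples.
DEFAULT_SCHEMA_CODES = {
    "SUB": 1, "PrS": 2, "PaS": 3, "CA1": 4,
    "CA2": 5, "CA3": 6, "DG": 7, "SRLM": 8,
}


@dataclass(frozen=True)
class SubfieldSchema:
    """Mapping of subfield name to integer label code.

    Background is always code 0. Extra codes beyond the eight required
    subfields are allowed and ignored by all measurements.
    """

    codes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SCHEMA_CODES))

    def __post_init__(self) -> None:
        missing = [name for name in REQUIRED_LABELS if name not in self.codes]
        if missing:
            raise SchemaError(f"schema is missing required labels: {missing}")
        values = list(self.codes.values())
        if any((not isinstance(v, (int, np.integer))) or v < 0 for v in values):
            raise SchemaError("label codes must be non-negative integers")
        if 0 in values:
            raise SchemaError("code 0 is reserved for background")
        if len(set(values)) != len(values):
            raise SchemaError("label codes must be distinct")

    def code(self, label: str) -> int:
        if label not in self.codes:
            raise SchemaError(f"unknown label name: {label!r}")
        return int(self.codes[label])

    def known_codes(self) -> set[int]:
        return {0, *map(int, self.codes.values())}

    @classmethod
    def from_json(cls, path) -> "SubfieldSchema":
        with open(path) as fh:
            return cls({k: int(v) for k, v in json.load(fh).items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.codes, fh, indent=1)


@dataclass
class LabelVolume:
    """A canonically oriented 3D integer label map.

    ``voxels`` is indexed ``(x, y, z)`` in the canonical frame described in
    the module docstring. ``spacing`` is ``(dx, dy, dz)`` in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    hemisphere: str
    schema: SubfieldSchema
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if self.voxels.ndim != 3:
            raise FormatError("label volume must be 3-dimensional")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise FormatError("label volume must hold integer data")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        dx, dy, dz = self.spacing
        if not (np.isclose(dx, dy) and np.isclose(dy, dz)):
            warnings.warn(
                "anisotropic spacing: measurements assume isotropic voxels",
                stacklevel=2,
            )
        present = set(np.unique(self.voxels).tolist())
        unknown = sorted(present - self.schema.known_codes())
        if unknown:
            raise SchemaError(f"volume contains codes absent from schema: {unknown}")

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    @property
    def dz(self) -> float:
        return float(self.spacing[2])

    def mask(self, label: str) -> np.ndarray:
        """3D boolean mask of one label."""
        return self.voxels == self.schema.code(label)

    @classmethod
    def from_array(
        cls,
        voxels: np.ndarray,
        spacing=(0.2, 0.2, 0.2),
        hemisphere: str = "right",
        schema: SubfieldSchema | None = None,
        frame: str = "canonical",
    ) -> "LabelVolume":
        """Build a volume from an in-memory array.

        ``frame='canonical'`` takes the array as already medial->lateral in
        +x. ``frame='subject'`` takes +x as subject left->right (the on-disk
        convention), which is mirrored for left-hemisphere specimens.
        """
        if frame not in ("canonical", "subject"):
            raise ValueError("frame must be 'canonical' or 'subject'")
        arr = np.asarray(voxels)
        if frame == "subject" and hemisphere == "left":
            arr = arr[::-1, :, :]
        return cls(
            voxels=np.ascontiguousarray(arr),
            spacing=tuple(float(s) for s in spacing),
            hemisphere=hemisphere,
            schema=schema or SubfieldSchema(),
        )


def mirror(volume: LabelVolume) -> LabelVolume:
    """Anatomically mirror a volume into the opposite hemisphere.

    In subject (world) coordinates the x-axis is reversed and the
    hemisphere flag flipped; because the canonical frame is
    hemisphere-relative (x always runs medial -> lateral), the two
    reversals cancel and the *canonical* array of the mirrored specimen is
    unchanged - only the flag flips (the x-reversal reappears on save).
    ``mirror`` is an involution, preserves every label's voxel count, and
    leaves every canonical-frame measurement invariant.
    """
    flipped = "left" if volume.hemisphere == "right" else "right"
    subject_view = volume.voxels[::-1, :, :] if volume.hemisphere == "left" else volume.voxels
    return LabelVolume.from_array(
        subject_view[::-1, :, :],
        spacing=volume.spacing,
        hemisphere=flipped,
        schema=volume.schema,
        frame="subject",
    )


@dataclass(frozen=True)
class Landmarks:
    """Long-axis landmark slices (canonical z, 0-based).

    The anterior tip and uncal apex bound the hippocampal head; the
    posterior tip bounds the whole structure. Landmarks require visual
    identification of uncal tissue and are therefore always provided as a
    sidecar, never auto-detected.
    """

    anterior_tip_z: int
    uncal_apex_z: int
    posterior_tip_z: int | None = None
    posterior_tip_undeterminable: bool = False

    def __post_init__(self) -> None:
        if self.anterior_tip_z > self.uncal_apex_z:
            raise LandmarkError("anterior tip must not be posterior to the uncal apex")
        if self.posterior_tip_z is not None and self.uncal_apex_z > self.posterior_tip_z:
            raise LandmarkError("uncal apex must not be posterior to the posterior tip")

    def shifted(self, k: int) -> "Landmarks":
        return replace(
            self,
            anterior_tip_z=self.anterior_tip_z + k,
            uncal_apex_z=self.uncal_apex_z + k,
            posterior_tip_z=None if self.posterior_tip_z is None else self.posterior_tip_z + k,
        )

    @classmethod
    def from_json(cls, path) -> "Landmarks":
        with open(path) as fh:
            d = json.load(fh)
        post = d.get("posterior_tip_z")
        return cls(
            anterior_tip_z=int(d["anterior_tip_z"]),
            uncal_apex_z=int(d["uncal_apex_z"]),
            posterior_tip_z=None if post is None else int(post),
            posterior_tip_undeterminable=bool(d.get("posterior_tip_undeterminable", False)),
        )

    def to_json(self, path, hemisphere: str | None = None) -> None:
        d = {
            "anterior_tip_z": self.anterior_tip_z,
            "uncal_apex_z": self.uncal_apex_z,
            "posterior_tip_z": self.posterior_tip_z,
            "posterior_tip_undeterminable": self.posterior_tip_undeterminable,
        }
        if hemisphere is not None:
            d["hemisphere"] = hemisphere
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


class CoverageMask:
    """Per-slice indicator of sufficient segmentation coverage.

    Histology-derived segmentations can have gaps (missing sections, gaps
    between tissue blocks); slices falling in a gap are flagged uncovered.
    Defaults to all-covered when absent.
    """

    def __init__(self, covered: np.ndarray):
        self.covered = np.asarray(covered, dtype=bool)

    def __len__(self) -> int:
        return len(self.covered)

    def is_covered(self, z: int) -> bool:
        if z < 0 or z >= len(self.covered):
            return False
        return bool(self.covered[z])

    @classmethod
    def all_covered(cls, n_slices: int) -> "CoverageMask":
        return cls(np.ones(n_slices, dtype=bool))

    @classmethod
    def from_tsv(cls, path, n_slices: int | None = None) -> "CoverageMask":
        df = pd.read_csv(path, sep="\t")
        if not {"z", "covered"} <= set(df.columns):
            raise FormatError("coverage TSV needs columns 'z' and 'covered'")
        n = int(df["z"].max()) + 1 if n_slices is None else n_slices
        covered = np.ones(n, dtype=bool)
        covered[df["z"].to_numpy(dtype=int)] = df["covered"].to_numpy(dtype=bool)
        return cls(covered)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"z": np.arange(len(self.covered)), "covered": self.covered.astype(int)}
        ).to_csv(path, sep="\t", index=False)

    def longest_gap(self) -> int:
        """Length of the longest run of uncovered slices (QC statistic)."""
        longest = run = 0
        for c in self.covered:
            run = 0 if c else run + 1
            longest = max(longest, run)
        return longest


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _ras_to_canonical(arr: np.ndarray, zooms, hemisphere: str):
    """RAS-indexed (R, A, S) array -> canonical (x, y, z) = (lateral-for-right,
    superior, posterior); left hemispheres additionally mirrored in x."""
    # (R, A, S) -> (R, S, P): swap A and S axes, reverse the A axis
    arr = np.transpose(arr, (0, 2, 1))[:, :, ::-1]
    spacing = (float(zooms[0]), float(zooms[2]), float(zooms[1]))
    if hemisphere == "left":
        arr = arr[::-1, :, :]
    return np.ascontiguousarray(arr), spacing


def load_label_volume(path, schema: SubfieldSchema, hemisphere: str) -> LabelVolume:
    """Load a NIfTI label map into the canonical frame.

    Raises :class:`FormatError` for non-integer data, :class:`SchemaError`
    for label codes absent from the schema, and :class:`OrientationError`
    when the affine does not define three independent axes (in which case
    the caller must re-save the file with explicit orientation metadata).
    """
    img = nib.load(str(path))
    affine = img.affine
    if affine is None or not np.isfinite(affine).all() or np.linalg.matrix_rank(affine[:3, :3]) < 3:
        raise OrientationError(
            "ambiguous orientation metadata: affine does not define three axes; "
            "re-save the image with an explicit affine"
        )
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise FormatError(f"{path}: label map contains non-integer values")
        data = rounded.astype(np.int32)
    arr, spacing = _ras_to_canonical(data, img.header.get_zooms()[:3], hemisphere)
    return LabelVolume(
        voxels=arr.astype(np.int16, copy=False),
        spacing=spacing,
        hemisphere=hemisphere,
        schema=schema,
    )


def save_label_volume(volume: LabelVolume, path) -> None:
    """Write a canonical volume back to NIfTI (RAS affine); round-trips exactly."""
    arr = volume.voxels
    if volume.hemisphere == "left":
        arr = arr[::-1, :, :]
    # canonical (R, S, P) -> (R, A, S)
    arr = np.transpose(arr[:, :, ::-1], (0, 2, 1))
    dx, dy, dz = volume.spacing
    affine = np.diag([dx, dz, dy, 1.0])
    nib.save(nib.Nifti1Image(np.ascontiguousarray(arr), affine), str(path))


def slice_mask(volume: LabelVolume, z: int, label: str) -> np.ndarray:
    """2D boolean mask of ``label`` on coronal slice ``z`` (indexed x, y)."""
    if not 0 <= z < volume.n_slices:
        raise IndexError(f"slice {z} out of range [0, {volume.n_slices})")
    return volume.voxels[:, :, z] == volume.schema.code(label)
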