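"""Dynamic PET / mask I/O and geometric-temporal consistency checks.

All images are NIfTI-1/NIfTI-2 (via nibabel).  Frame timing arrives as a
sidecar table: either a two-column CSV of per-frame start/end seconds, or a
BIDS-style JSON carrying ``FrameTimesStart`` and ``FrameDuration``.  Times
are seconds internally, everywhere.

No resampling or registration happens here: masks must already live on the
PET grid, and any mismatch is an error, never a silent fix.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "MaskImage",
    "SubjectRecord",
    "read_dynamic",
    "read_mask",
    "read_schedule",
    "write_dynamic",
    "write_mask",
    "write_tac_csv",
    "check_alignment",
    "require_alignment",
    "AlignmentError",
    "ScheduleError",
]

Genotype = Literal["HAB", "MAB", "unknown"]


class ScheduleError(ValueError):
    """Raised for inconsistent or malformed frame timing."""


class AlignmentError(ValueError):
    """Raised when an image pair does not share a grid."""


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame acquisition intervals (seconds) shared by all TACs.

    Parameters
    ----------
    frame_start, frame_end
        1-D arrays of start/end times in seconds, sorted, non-overlapping.
    """

    frame_start: np.ndarray
    frame_end: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        end = np.asarray(self.frame_end, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_end", end)
        if start.ndim != 1 or end.ndim != 1 or start.size != end.size:
            raise ScheduleError("frame_start and frame_end must be 1-D and equal length")
        if start.size < 2:
            raise ScheduleError("a frame schedule needs at least 2 frames")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(end)):
            raise ScheduleError("non-finite frame times")
        if np.any(end <= start):
            raise ScheduleError("every frame must satisfy frame_end > frame_start")
        if np.any(np.diff(start) <= 0):
            raise ScheduleError("frames must be sorted by start time")
        if np.any(start[1:] < end[:-1] - 1e-9):
            raise ScheduleError("overlapping frames")

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def mid(self) -> np.ndarray:
        """Frame midpoints in seconds."""
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def duration(self) -> np.ndarray:
        """Frame durations in seconds."""
        return self.frame_end - self.frame_start

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return bool(
            np.array_equal(self.frame_start, other.frame_start)
            and np.array_equal(self.frame_end, other.frame_end)
        )

    def __hash__(self) -> int:
        return hash((self.frame_start.tobytes(), self.frame_end.tobytes()))

    def to_dict(self) -> dict:
        return {
            "frame_start_s": self.frame_start.tolist(),
            "frame_end_s": self.frame_end.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        return cls(np.asarray(d["frame_start_s"], float), np.asarray(d["frame_end_s"], float))


@dataclass
class DynamicImage:
    """4-D decay-corrected activity volume + schedule + geometry.

    ``voxels`` is indexed (x, y, z, frame) in activity-concentration units
    (e.g. kBq/mL); ``affine`` maps 0-based voxel indices to world mm.
    """

    voxels: np.ndarray
    schedule: FrameSchedule
    affine: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError(f"dynamic image must be 4-D, got {self.voxels.ndim}-D")
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise ScheduleError(
                f"frame count mismatch: image has {self.voxels.shape[3]} frames, "
                f"schedule has {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("dynamic image contains non-finite values")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class MaskImage:
    """3-D binary {0,1} or probability [0,1] mask on a PET grid."""

    voxels: np.ndarray
    affine: np.ndarray
    kind: Literal["binary", "probability"] = "binary"
    method: str = "unspecified"  # free-text provenance of how the mask was built

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3-D, got {self.voxels.ndim}-D")
        if self.voxels.min() < 0 or self.voxels.max() > 1:
            raise ValueError("mask values must lie in [0, 1]")
        if self.kind == "binary" and not np.all(np.isin(self.voxels, (0.0, 1.0))):
            raise ValueError("binary mask contains values other than 0 and 1")

    @property
    def as_bool(self) -> np.ndarray:
        if self.kind != "binary":
            raise ValueError("probability mask must be thresholded before boolean use")
        return self.voxels > 0.5

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.voxels)) if self.kind == "binary" else int(self.voxels.size)

    def provenance_hash(self) -> str:
        """Hash of the construction recipe (method + grid + kind), used to
        enforce that training and extraction used the same mask definition."""
        token = f"{self.kind}|{self.voxels.shape}|{self.method}"
        return hashlib.sha256(token.encode()).hexdigest()[:16]


@dataclass
class SubjectRecord:
    """One training/testing subject: dynamic PET plus co-registered masks."""

    subject_id: str
    pet: DynamicImage
    masks: dict[str, MaskImage]
    genotype: Genotype = "unknown"

    def __post_init__(self) -> None:
        if "brain" not in self.masks:
            raise ValueError(f"subject {self.subject_id}: brain mask is required")
        for name, m in self.masks.items():
            if not check_alignment(self.pet, m):
                raise AlignmentError(f"subject {self.subject_id}: mask '{name}' not on PET grid")


# ---------------------------------------------------------------------------
# readers / writers


def read_schedule(timing_path: str | Path) -> FrameSchedule:
    """Read a frame schedule from CSV (frame_start,frame_end seconds) or
    BIDS-style JSON (FrameTimesStart + FrameDuration)."""
    timing_path = Path(timing_path)
    if timing_path.suffix.lower() == ".json":
        with open(timing_path) as fh:
            d = json.load(fh)
        try:
            start = np.asarray(d["FrameTimesStart"], float)
            dur = np.asarray(d["FrameDuration"], float)
        except KeyError as exc:
            raise ScheduleError(f"timing JSON missing key: {exc}") from exc
        return FrameSchedule(start, start + dur)
    df = pd.read_csv(timing_path)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        start = df[cols["frame_start"]].to_numpy(float)
        end = df[cols["frame_end"]].to_numpy(float)
    except KeyError:
        raise ScheduleError(
            f"timing CSV must have columns frame_start,frame_end; got {list(df.columns)}"
        ) from None
    return FrameSchedule(start, end)


def write_schedule(schedule: FrameSchedule, path: str | Path) -> None:
    pd.DataFrame(
        {"frame_start": schedule.frame_start, "frame_end": schedule.frame_end}
    ).to_csv(path, index=False)


def read_dynamic(pet_path: str | Path, timing_path: str | Path) -> DynamicImage:
    """Load a 4-D NIfTI and its timing sidecar into a validated DynamicImage."""
    img = nib.load(str(pet_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{pet_path}: expected a 4-D image, got {data.ndim}-D")
    schedule = read_schedule(timing_path)
    if data.shape[3] != schedule.n_frames:
        raise ScheduleError(
            f"frame count mismatch: {pet_path} has {data.shape[3]} frames but "
            f"{timing_path} lists {schedule.n_frames}"
        )
    return DynamicImage(data, schedule, img.affine, meta={"source": str(pet_path)})


def read_mask(path: str | Path, kind: str | None = None, method: str = "unspecified") -> MaskImage:
    """Load a 3-D NIfTI mask; kind is auto-detected unless given."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if kind is None:
        kind = "binary" if np.all(np.isin(data, (0.0, 1.0))) else "probability"
    return MaskImage(data, img.affine, kind=kind, method=method)  # type: ignore[arg-type]


def write_dynamic(dyn: DynamicImage, pet_path: str | Path, timing_path: str | Path | None = None) -> None:
    nib.save(nib.Nifti1Image(dyn.voxels, dyn.affine), str(pet_path))
    if timing_path is not None:
        write_schedule(dyn.schedule, timing_path)


def write_mask(mask: MaskImage, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.voxels, mask.affine), str(path))


def write_tac_csv(values: np.ndarray, schedule: FrameSchedule, path: str | Path) -> None:
    """One row per frame: frame_mid_s, value."""
    pd.DataFrame({"frame_mid_s": schedule.mid, "value": np.asarray(values, float)}).to_csv(
        path, index=False
    )


def read_tac_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["frame_mid_s"].to_numpy(float), df["value"].to_numpy(float)


# ---------------------------------------------------------------------------
# geometry


def check_alignment(a: DynamicImage | MaskImage, b: DynamicImage | MaskImage, tol: float = 1e-3) -> bool:
    """True iff both images share the grid shape and affines agree within
    ``tol`` (mm) element-wise.  Pure predicate; never raises."""
    shape_a = a.voxels.shape[:3]
    shape_b = b.voxels.shape[:3]
    if shape_a != shape_b:
        return False
    return bool(np.all(np.abs(a.affine - b.affine) <= tol))


def require_alignment(a, b, tol: float = 1e-3, what: str = "images") -> None:
    if not check_alignment(a, b, tol):
        raise AlignmentError(f"{what} are not on the same grid (shape/affine mismatch)")
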