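"""Frame-wise z-normalization of dynamic PET within a brain mask.

Each frame is independently centred and scaled using the mean and the
*population* standard deviation of the in-mask voxels of that frame.  The
identical transform is used when building kinetic classes and when
extracting a reference region; out-of-mask voxels are set to NaN so they
can never leak into downstream averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .petio import DynamicImage, FrameSchedule, MaskImage, require_alignment

__all__ = ["NormalizedDynamic", "normalize_frames", "NormalizationError"]


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizedDynamic:
    """Unitless frame-normalized 4-D image.

    Out-of-mask voxels are NaN.  ``per_frame_mean``/``per_frame_sd`` are the
    statistics that were subtracted/divided, kept for audit.
    """

    voxels: np.ndarray
    schedule: FrameSchedule
    norm_mask: MaskImage
    per_frame_mean: np.ndarray
    per_frame_sd: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def mask_bool(self) -> np.ndarray:
        return self.norm_mask.as_bool


def normalize_frames(
    pet: DynamicImage,
    brain: MaskImage | None,
    *,
    sd_convention: str = "population",
) -> NormalizedDynamic:
    """Z-normalize every frame using in-mask statistics.

    Parameters
    ----------
    pet
        Dynamic PET image.
    brain
        Binary brain mask on the PET grid.  ``None`` reproduces the legacy
        whole-frame behaviour (statistics over the entire field of view).
    sd_convention
        "population" (divide by N, default) or "sample" (N-1).

    Raises
    ------
    NormalizationError
        On an empty mask or a frame whose in-mask SD is zero.
    """
    if brain is None:
        mask = np.ones(pet.shape3d, dtype=bool)
        norm_mask = MaskImage(mask.astype(float), pet.affine, kind="binary", method="whole-frame")
    else:
        if brain.kind != "binary":
            raise NormalizationError("brain mask must be binary; threshold probability maps first")
        require_alignment(pet, brain, what="PET and brain mask")
        mask = brain.as_bool
        norm_mask = brain
    n_in = int(mask.sum())
    if n_in < 2:
        raise NormalizationError("normalization mask must contain at least 2 voxels")

    ddof = 0 if sd_convention == "population" else 1
    inmask = pet.voxels[mask, :]  # (n_vox, n_frames)
    means = inmask.mean(axis=0)
    sds = inmask.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sds <= 0)
    if bad.size:
        raise NormalizationError(
            f"frame {bad[0]} has zero in-mask standard deviation (constant frame)"
        )

    out = np.full_like(pet.voxels, np.nan)
    out[mask, :] = (inmask - means) / sds
    return NormalizedDynamic(
        voxels=out,
        schedule=pet.schedule,
        norm_mask=norm_mask,
        per_frame_mean=means,
        per_frame_sd=sds,
        meta={"sd_convention": sd_convention, "n_mask_voxels": n_in},
    )
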