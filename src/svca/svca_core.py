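"""Per-voxel non-negative decomposition against the kinetic classes.

Each candidate voxel's normalized TAC is modelled as a non-negative linear
combination of the class curves, TAC_v = w1*K1 + ... + wn*Kn with all
wi >= 0, solved by non-negative least squares.  The reference ratio
w_lbgm / sum(w) is thresholded (strictly greater) to select reference
voxels; the reference TAC is then averaged from the RAW, un-normalized
dynamic PET over the selected voxels, simply or weighted by w_lbgm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .kinetic_classes import KineticClassSet
from .normalization import normalize_frames
from .petio import DynamicImage, MaskImage, require_alignment

__all__ = [
    "WeightVector",
    "RatioMap",
    "ReferenceRegionResult",
    "ExtractionError",
    "nnls_fit_voxel",
    "compute_ratio",
    "fit_candidates",
    "weight_maps",
    "extract_reference",
]


class ExtractionError(RuntimeError):
    """Raised when the algorithm fails to find a suitable reference region."""


@dataclass(frozen=True)
class WeightVector:
    """Non-negative class weights for one voxel plus the fit residual."""

    w: np.ndarray
    residual_ss: float

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if self.residual_ss < 0:
            raise ValueError("residual sum of squares must be >= 0")


@dataclass
class RatioMap:
    """3-D reference-class ratio per candidate voxel (NaN elsewhere)."""

    values: np.ndarray
    candidate_mask: MaskImage

    def __post_init__(self) -> None:
        inside = self.candidate_mask.as_bool
        v = self.values[inside]
        if v.size and (np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12):
            raise ValueError("ratio values must lie in [0, 1] inside the candidate mask")


@dataclass
class ReferenceRegionResult:
    selected_mask: MaskImage
    ref_tac: np.ndarray  # original activity units, one value per frame
    n_selected: int
    threshold: float
    averaging: str
    ratio_map: RatioMap
    diagnostics: dict = field(default_factory=dict)


def nnls_fit_voxel(tac_v: np.ndarray, K: np.ndarray) -> WeightVector:
    """Solve min ||K w - tac_v||^2 subject to w >= 0 for one voxel."""
    tac_v = np.asarray(tac_v, dtype=float)
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[1] < 2:
        raise ValueError("K must be 2-D with at least 2 class columns")
    if tac_v.shape != (K.shape[0],):
        raise ValueError(f"TAC length {tac_v.shape} does not match K rows {K.shape[0]}")
    if not (np.all(np.isfinite(tac_v)) and np.all(np.isfinite(K))):
        raise ValueError("non-finite input to NNLS")
    w, rnorm = _scipy_nnls(K, tac_v)
    return WeightVector(w=w, residual_ss=float(rnorm**2))


def compute_ratio(w: WeightVector | np.ndarray, lbgm_index: int) -> float:
    """Reference-class weight fraction w_lbgm / sum(w); 0 if all weights are 0
    (such a voxel can never be selected)."""
    vec = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    total = vec.sum()
    if total == 0:
        return 0.0
    return float(vec[lbgm_index] / total)


def _check_compatibility(
    pet: DynamicImage,
    brain: MaskImage,
    candidate: MaskImage,
    classes: KineticClassSet,
    genotype: str,
    force_mask_mismatch: bool,
) -> None:
    if classes.schedule != pet.schedule:
        raise ValueError("frame schedule of the PET scan does not match the class set")
    require_alignment(pet, brain, what="PET and brain mask")
    require_alignment(pet, candidate, what="PET and candidate mask")
    if not np.all(candidate.as_bool <= brain.as_bool):
        raise ValueError("candidate mask must be a subset of the brain mask")
    if classes.norm_mask_hash and classes.norm_mask_hash != brain.provenance_hash():
        msg = (
            "brain mask definition differs from the one used to build the kinetic "
            "classes (normalization mismatch between training and testing)"
        )
        if not force_mask_mismatch:
            raise ValueError(msg + "; pass force_mask_mismatch=True to override")
        warnings.warn(msg + " — proceeding because force_mask_mismatch is set", stacklevel=3)
    if classes.genotype not in ("ALL", "unknown"):
        if genotype == "unknown":
            warnings.warn(
                f"class set is genotype-specific ({classes.genotype}) but the subject "
                "genotype is unknown",
                stacklevel=3,
            )
        elif genotype != classes.genotype:
            raise ValueError(
                f"genotype mismatch: subject is {genotype}, class set is {classes.genotype}"
            )


def fit_candidates(
    pet: DynamicImage,
    brain: MaskImage,
    candidate: MaskImage,
    classes: KineticClassSet,
    *,
    genotype: str = "unknown",
    force_mask_mismatch: bool = False,
) -> tuple[np.ndarray, np.ndarray, RatioMap]:
    """Normalize and NNLS-fit every candidate voxel.

    Returns (weights_per_voxel [n_candidates x n_classes], residual_ss
    [n_candidates], RatioMap).  Candidate order is C-order linear index.
    """
    _check_compatibility(pet, brain, candidate, classes, genotype, force_mask_mismatch)
    norm = normalize_frames(pet, brain)
    sel = candidate.as_bool
    tacs = norm.voxels[sel, :]
    K = classes.K
    n = tacs.shape[0]
    W = np.empty((n, K.shape[1]))
    rss = np.empty(n)
    for i in range(n):
        fit = nnls_fit_voxel(tacs[i], K)
        W[i] = fit.w
        rss[i] = fit.residual_ss
    ratios = np.array([compute_ratio(W[i], classes.lbgm_index) for i in range(n)])
    ratio_vol = np.full(pet.shape3d, np.nan)
    ratio_vol[sel] = ratios
    return W, rss, RatioMap(ratio_vol, candidate)


def weight_maps(
    pet: DynamicImage,
    brain: MaskImage,
    candidate: MaskImage,
    classes: KineticClassSet,
    **kwargs,
) -> tuple[dict[str, np.ndarray], RatioMap]:
    """Per-class 3-D weight maps (NaN outside candidates) plus the ratio map,
    for visual inspection / NIfTI export."""
    W, _, ratio_map = fit_candidates(pet, brain, candidate, classes, **kwargs)
    sel = candidate.as_bool
    maps: dict[str, np.ndarray] = {}
    for j, name in enumerate(classes.class_names):
        vol = np.full(pet.shape3d, np.nan)
        vol[sel] = W[:, j]
        maps[name] = vol
    return maps, ratio_map


def extract_reference(
    pet: DynamicImage,
    brain: MaskImage,
    candidate: MaskImage,
    classes: KineticClassSet,
    threshold: float = 0.9,
    averaging: str = "simple",
    *,
    genotype: str = "unknown",
    force_mask_mismatch: bool = False,
    min_voxels_warn: int = 50,
) -> ReferenceRegionResult:
    """Select candidate voxels whose reference-class ratio is strictly above
    ``threshold`` and average their RAW time-activity curves.

    ``averaging`` is "simple" (unweighted mean) or "weighted" (weights are
    each voxel's reference-class NNLS weight).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    if averaging not in ("simple", "weighted"):
        raise ValueError("averaging must be 'simple' or 'weighted'")

    W, rss, ratio_map = fit_candidates(
        pet, brain, candidate, classes,
        genotype=genotype, force_mask_mismatch=force_mask_mismatch,
    )
    sel = candidate.as_bool
    cand_idx = np.flatnonzero(sel.ravel())
    ratios = ratio_map.values.ravel()[cand_idx]
    keep = ratios > threshold
    n_selected = int(keep.sum())
    if n_selected == 0:
        raise ExtractionError(
            f"SVCA failed to find a suitable reference region: no candidate voxel "
            f"has ratio > {threshold}"
        )
    if n_selected < min_voxels_warn:
        warnings.warn(
            f"only {n_selected} reference voxels selected (below warning floor "
            f"{min_voxels_warn}); treat results with caution",
            stacklevel=2,
        )

    mask_vol = np.zeros(pet.shape3d, dtype=float)
    mask_vol.ravel()[cand_idx[keep]] = 1.0
    selected_mask = MaskImage(mask_vol, pet.affine, kind="binary",
                              method=f"svca|ratio>{threshold}")

    raw = pet.voxels.reshape(-1, pet.schedule.n_frames)[cand_idx[keep], :]
    if averaging == "simple":
        ref_tac = raw.mean(axis=0)
    else:
        wl = W[keep, classes.lbgm_index]
        total = wl.sum()
        if total <= 0:
            raise ExtractionError("weighted averaging impossible: selected weights sum to 0")
        ref_tac = (raw * wl[:, None]).sum(axis=0) / total

    return ReferenceRegionResult(
        selected_mask=selected_mask,
        ref_tac=ref_tac,
        n_selected=n_selected,
        threshold=threshold,
        averaging=averaging,
        ratio_map=ratio_map,
        diagnostics={
            "n_candidates": int(cand_idx.size),
            "fraction_selected": n_selected / cand_idx.size,
            "median_residual_ss": float(np.median(rss)),
            "genotype": genotype,
            "class_set_genotype": classes.genotype,
        },
    )
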