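"""Build the kinetic-class set from a training cohort.

Pipeline per subject: threshold/erode tissue probability maps, derive the
blood mask from the hottest early-summed voxels, normalize the dynamic PET
within the brain mask, extract the per-class normalized TAC, then aggregate
across subjects (mean or median), optionally stratified by TSPO genotype.

Class order is fixed: low-binding grey matter (the reference class), white
matter, blood, high-binding grey matter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .normalization import NormalizedDynamic, normalize_frames
from .petio import (
    DynamicImage,
    FrameSchedule,
    MaskImage,
    SubjectRecord,
    require_alignment,
)

__all__ = [
    "CLASS_ORDER",
    "ClassTAC",
    "KineticClassSet",
    "ClassBuildConfig",
    "prepare_tissue_mask",
    "build_blood_mask",
    "extract_class_tac",
    "validate_blood_shape",
    "aggregate_classes",
    "extract_subject_class_tacs",
    "build_class_sets",
    "build_class_sets_loo",
]

CLASS_ORDER: tuple[str, ...] = ("lbgm", "wm", "blood", "hbgm")
REFERENCE_CLASS = "lbgm"

# 6-connected 3-D structuring element used for erosion/dilation
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class ClassTAC:
    """A single subject's normalized class time-activity curve."""

    class_name: str
    values: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"class TAC '{self.class_name}' ({self.subject_id}) not finite")


@dataclass
class KineticClassSet:
    """Aggregated class TAC matrix K (n_frames x n_classes) + provenance."""

    K: np.ndarray
    class_names: list[str]
    schedule: FrameSchedule
    genotype: str = "ALL"
    aggregation: str = "mean"
    norm_mask_hash: str = ""
    training_subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2:
            raise ValueError("K must be 2-D (n_frames x n_classes)")
        if self.K.shape[0] != self.schedule.n_frames:
            raise ValueError("K row count must equal the number of frames")
        if self.K.shape[1] != len(self.class_names):
            raise ValueError("K column count must equal the number of class names")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class names must be unique")
        if self.K.shape[1] < 2:
            raise ValueError("need at least 2 kinetic classes")
        if not np.all(np.isfinite(self.K)):
            raise ValueError("K contains non-finite values")
        if REFERENCE_CLASS not in self.class_names:
            raise ValueError(f"reference class '{REFERENCE_CLASS}' missing")

    @property
    def lbgm_index(self) -> int:
        return self.class_names.index(REFERENCE_CLASS)

    @property
    def n_classes(self) -> int:
        return self.K.shape[1]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "svca-kinetic-class-set",
            "version": 1,
            "class_names": list(self.class_names),
            "reference_class": REFERENCE_CLASS,
            "genotype": self.genotype,
            "aggregation": self.aggregation,
            "norm_mask_hash": self.norm_mask_hash,
            "training_subjects": list(self.training_subjects),
            "schedule": self.schedule.to_dict(),
            "K": [list(row) for row in self.K],  # row = frame
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticClassSet":
        return cls(
            K=np.asarray(d["K"], dtype=float),
            class_names=list(d["class_names"]),
            schedule=FrameSchedule.from_dict(d["schedule"]),
            genotype=d.get("genotype", "ALL"),
            aggregation=d.get("aggregation", "mean"),
            norm_mask_hash=d.get("norm_mask_hash", ""),
            training_subjects=list(d.get("training_subjects", [])),
        )

    def save(self, path: str | Path, csv_companion: bool = True) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        if csv_companion:
            df = pd.DataFrame(self.K, columns=self.class_names)
            df.insert(0, "frame_mid_s", self.schedule.mid)
            df.to_csv(path.with_suffix(".csv"), index=False)

    @classmethod
    def load(cls, path: str | Path) -> "KineticClassSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ClassBuildConfig:
    """Knobs for the class-building pipeline (defaults follow common practice)."""

    p_threshold: float = 0.9
    erode_binary: int = 1
    erode_probability: int = 0
    early_window_s: float = 180.0
    n_top_blood: int = 50
    aggregation: str = "mean"  # or "median"
    # where the high-binding class comes from: "high_binding" mask of the
    # subject record (patient lesion mask or a thalamus mask) — must exist.
    hbgm_mask_name: str = "high_binding"
    blood_search_dilate: int = 2
    min_subjects_warn: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.aggregation not in ("mean", "median"):
            raise ValueError("aggregation must be 'mean' or 'median'")
        if self.n_top_blood < 1:
            raise ValueError("n_top_blood must be >= 1")


# ---------------------------------------------------------------------------
# mask preparation


def prepare_tissue_mask(prob_map: MaskImage, p_threshold: float = 0.9, erode: int = 0) -> MaskImage:
    """Threshold a probability map (strictly ``> p_threshold``) and erode it
    ``erode`` times with a 6-connected structuring element.

    For an already-binary mask the threshold step is a no-op (1 > 0.9) and
    only the erosion applies — this is the partial-volume guard for
    non-probabilistic segmentations.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must be in (0, 1)")
    if erode < 0:
        raise ValueError("erode must be >= 0")
    binary = prob_map.voxels > p_threshold
    if erode > 0:
        binary = ndimage.binary_erosion(binary, structure=_STRUCT6, iterations=erode)
    if not binary.any():
        raise ValueError(
            "tissue mask is empty after thresholding/erosion; "
            "lower p_threshold or reduce erosion"
        )
    return MaskImage(
        binary.astype(float),
        prob_map.affine,
        kind="binary",
        method=f"{prob_map.method}|p>{p_threshold}|erode{erode}",
    )


def build_blood_mask(
    pet: DynamicImage,
    early_window_s: float = 180.0,
    n_top: int = 50,
    search_mask: MaskImage | None = None,
) -> MaskImage:
    """Select the ``n_top`` voxels with the highest raw PET signal summed over
    the early frames (frame midpoints <= ``early_window_s``), restricted to
    ``search_mask``.  Ties at the cutoff break by ascending linear index.
    """
    mid = pet.schedule.mid
    early = mid <= early_window_s
    if not early.any():
        raise ValueError(
            f"early window {early_window_s}s ends before the first frame midpoint ({mid[0]}s)"
        )
    if search_mask is None:
        region = np.ones(pet.shape3d, dtype=bool)
    else:
        require_alignment(pet, search_mask, what="PET and blood search mask")
        region = search_mask.as_bool
    if not region.any():
        raise ValueError("blood search mask is empty")
    if n_top < 1:
        raise ValueError("n_top must be >= 1")

    early_sum = pet.voxels[..., early].sum(axis=3)
    flat = early_sum.ravel()
    idx = np.flatnonzero(region.ravel())
    n_top = min(n_top, idx.size)
    # stable deterministic ranking: highest value first, lowest linear index on ties
    order = np.lexsort((idx, -flat[idx]))
    chosen = idx[order[:n_top]]
    out = np.zeros(pet.shape3d, dtype=float)
    out.ravel()[chosen] = 1.0
    return MaskImage(out, pet.affine, kind="binary",
                     method=f"blood|early{early_window_s}s|top{n_top}")


def dilate_mask(mask: MaskImage, iterations: int) -> MaskImage:
    if iterations <= 0:
        return mask
    grown = ndimage.binary_dilation(mask.as_bool, structure=_STRUCT6, iterations=iterations)
    return MaskImage(grown.astype(float), mask.affine, kind="binary",
                     method=f"{mask.method}|dilate{iterations}")


# ---------------------------------------------------------------------------
# TAC extraction & QC


def extract_class_tac(norm: NormalizedDynamic, mask: MaskImage, class_name: str,
                      subject_id: str = "") -> ClassTAC:
    """Per-frame unweighted mean of normalized values over the mask voxels."""
    require_alignment(norm.norm_mask, mask, what="normalized image and class mask")
    sel = mask.as_bool
    if not sel.any():
        raise ValueError(f"class mask '{class_name}' is empty")
    vals = norm.voxels[sel, :]
    if np.isnan(vals).any():
        raise ValueError(
            f"class mask '{class_name}' includes voxels outside the normalization mask"
        )
    return ClassTAC(class_name=class_name, values=vals.mean(axis=0), subject_id=subject_id)


def validate_blood_shape(tac: ClassTAC | np.ndarray, schedule: FrameSchedule) -> dict:
    """QC flag for the blood curve: the global peak must fall in the first
    third of frames and the final value must be below 50% of the peak.

    Never raises; returns a dict with ``passed``, ``peak_index`` and
    ``tail_to_peak`` evidence.
    """
    values = tac.values if isinstance(tac, ClassTAC) else np.asarray(tac, float)
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 frames to judge blood shape")
    peak_idx = int(np.argmax(values))
    peak = values[peak_idx]
    ratio = float(values[-1] / peak) if peak != 0 else np.inf
    passed = bool(peak_idx < n / 3 and peak > 0 and values[-1] < 0.5 * peak)
    return {"passed": passed, "peak_index": peak_idx, "tail_to_peak": ratio}


# ---------------------------------------------------------------------------
# aggregation


def aggregate_classes(
    per_subject: list[ClassTAC],
    method: str = "mean",
    genotype: str = "ALL",
    schedule: FrameSchedule | None = None,
    norm_mask_hash: str = "",
) -> KineticClassSet:
    """Aggregate per-subject class TACs into the K matrix (mean or median
    across subjects, per class, per frame)."""
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    if not per_subject:
        raise ValueError("no class TACs to aggregate")
    if schedule is None:
        raise ValueError("a schedule is required")
    n_frames = schedule.n_frames
    by_class: dict[str, list[ClassTAC]] = {c: [] for c in CLASS_ORDER}
    subjects: list[str] = []
    for tac in per_subject:
        if tac.class_name not in by_class:
            raise ValueError(f"unknown class '{tac.class_name}'")
        if tac.values.size != n_frames:
            raise ValueError(
                f"schedule mismatch: TAC '{tac.class_name}' of {tac.subject_id} has "
                f"{tac.values.size} frames, expected {n_frames}"
            )
        by_class[tac.class_name].append(tac)
        if tac.subject_id not in subjects:
            subjects.append(tac.subject_id)
    missing = [c for c, tacs in by_class.items() if not tacs]
    if missing:
        raise ValueError(f"missing class(es): {missing}")
    agg = np.mean if method == "mean" else np.median
    K = np.column_stack(
        [agg(np.stack([t.values for t in by_class[c]], axis=0), axis=0) for c in CLASS_ORDER]
    )
    return KineticClassSet(
        K=K,
        class_names=list(CLASS_ORDER),
        schedule=schedule,
        genotype=genotype,
        aggregation=method,
        norm_mask_hash=norm_mask_hash,
        training_subjects=subjects,
    )


# ---------------------------------------------------------------------------
# cohort pipeline


def extract_subject_class_tacs(
    subject: SubjectRecord, config: ClassBuildConfig
) -> list[ClassTAC]:
    """Run mask prep -> normalization -> class TAC extraction for one subject."""
    brain = subject.masks["brain"]
    if brain.kind != "binary":
        brain = prepare_tissue_mask(brain, 0.5, 0)

    def _binary(name: str) -> MaskImage:
        m = subject.masks[name]
        erode = config.erode_probability if m.kind == "probability" else config.erode_binary
        return prepare_tissue_mask(m, config.p_threshold, erode)

    if "gm_prob" not in subject.masks or "wm_prob" not in subject.masks:
        raise ValueError(f"subject {subject.subject_id}: gm_prob and wm_prob masks required")
    gm = _binary("gm_prob")
    wm = _binary("wm_prob")
    if config.hbgm_mask_name not in subject.masks:
        raise ValueError(
            f"subject {subject.subject_id}: high-binding mask "
            f"'{config.hbgm_mask_name}' required (lesion or thalamus mask)"
        )
    hb = _binary(config.hbgm_mask_name)
    # subtract the FULL (un-eroded) high-binding region from GM, otherwise the
    # eroded-away shell would leak high-binding voxels into the lbgm class
    hb_full = prepare_tissue_mask(subject.masks[config.hbgm_mask_name], config.p_threshold, 0)

    # low-binding GM = thresholded GM minus the high-binding region
    lbgm_vox = gm.as_bool & ~hb_full.as_bool
    if not lbgm_vox.any():
        raise ValueError(f"subject {subject.subject_id}: empty low-binding GM mask")
    lbgm = MaskImage(lbgm_vox.astype(float), gm.affine, kind="binary",
                     method=f"{gm.method}-minus-hbgm")

    if "blood" in subject.masks:
        blood = subject.masks["blood"]
        if blood.kind != "binary":
            blood = prepare_tissue_mask(blood, 0.5, 0)
    else:
        search = dilate_mask(brain, config.blood_search_dilate)
        blood = build_blood_mask(subject.pet, config.early_window_s, config.n_top_blood, search)
    # normalized values only exist inside the brain mask
    blood_in = blood.as_bool & brain.as_bool
    if not blood_in.any():
        raise ValueError(f"subject {subject.subject_id}: blood mask has no in-brain voxels")
    blood = MaskImage(blood_in.astype(float), blood.affine, kind="binary", method=blood.method)

    norm = normalize_frames(subject.pet, brain)
    sid = subject.subject_id
    return [
        extract_class_tac(norm, lbgm, "lbgm", sid),
        extract_class_tac(norm, wm, "wm", sid),
        extract_class_tac(norm, blood, "blood", sid),
        extract_class_tac(norm, hb, "hbgm", sid),
    ]


def build_class_sets(
    cohort: list[SubjectRecord],
    config: ClassBuildConfig | None = None,
    strata: tuple[str, ...] = ("ALL",),
) -> dict[str, KineticClassSet]:
    """Build one KineticClassSet per requested genotype stratum.

    Strata may be any of "ALL", "HAB", "MAB".  A stratum with fewer than
    ``config.min_subjects_warn`` subjects triggers a warning, not an error.
    A failing subject aborts with its id and the failing stage.
    """
    if not cohort:
        raise ValueError("empty training cohort")
    config = config or ClassBuildConfig()
    schedules = {s.pet.schedule for s in cohort}
    if len(schedules) > 1:
        raise ValueError("all training subjects must share one frame schedule")
    schedule = cohort[0].pet.schedule

    tacs_by_subject: dict[str, list[ClassTAC]] = {}
    for subject in cohort:
        try:
            tacs_by_subject[subject.subject_id] = extract_subject_class_tacs(subject, config)
        except Exception as exc:
            raise RuntimeError(
                f"class building failed for subject {subject.subject_id}: {exc}"
            ) from exc

    mask_hash = cohort[0].masks["brain"].provenance_hash()
    out: dict[str, KineticClassSet] = {}
    for stratum in strata:
        if stratum == "ALL":
            members = cohort
        else:
            members = [s for s in cohort if s.genotype == stratum]
        if not members:
            raise ValueError(f"stratum {stratum} has no subjects")
        if len(members) < config.min_subjects_warn:
            warnings.warn(
                f"stratum {stratum} has only {len(members)} subjects "
                f"(fewer than {config.min_subjects_warn} is discouraged)",
                stacklevel=2,
            )
        pooled = [t for s in members for t in tacs_by_subject[s.subject_id]]
        out[stratum] = aggregate_classes(
            pooled, method=config.aggregation, genotype=stratum,
            schedule=schedule, norm_mask_hash=mask_hash,
        )
    return out


def build_class_sets_loo(
    cohort: list[SubjectRecord],
    config: ClassBuildConfig | None = None,
    held_out: str = "",
    stratum: str = "ALL",
) -> KineticClassSet:
    """Leave-one-out class set: identical to ``build_class_sets`` on the
    cohort minus ``held_out``."""
    ids = [s.subject_id for s in cohort]
    if held_out not in ids:
        raise ValueError(f"held-out subject '{held_out}' not in cohort {ids}")
    rest = [s for s in cohort if s.subject_id != held_out]
    if not rest:
        raise ValueError("cohort must contain at least 2 subjects for leave-one-out")
    return build_class_sets(rest, config, strata=(stratum,))[stratum]
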