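"""Ground-truthed dynamic PET phantoms for end-to-end validation.

The generative model is deliberately simple and fully analytic: a
gamma-variate blood input function and one-tissue-compartment responses to
it (class-specific K1, k2), frame-averaged over the acquisition schedule.
Four tissue classes are laid out as labelled boxes (low-binding grey
matter, white matter, blood, high-binding grey matter) plus an optional
"mixed" compartment whose voxels carry Dirichlet-drawn convex mixtures of
the class kinetics.  Noise is additive Gaussian with a per-frame SD scaled
by 1/sqrt(frame duration), so longer frames are less noisy.

Everything is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetic_classes import CLASS_ORDER
from .petio import DynamicImage, FrameSchedule, MaskImage, SubjectRecord

__all__ = [
    "TracerProfile",
    "PhantomSpec",
    "PhantomTruth",
    "default_schedule",
    "make_class_templates",
    "generate_phantom",
    "generate_cohort",
]

LABELS = {"background": 0, "lbgm": 1, "wm": 2, "blood": 3, "hbgm": 4, "mixed": 5, "csf": 6}


def default_schedule() -> FrameSchedule:
    """20 frames over ~49 min: 6x30 s, 8x120 s, 6x300 s."""
    durations = np.array([30.0] * 6 + [120.0] * 8 + [300.0] * 6)
    end = np.cumsum(durations)
    return FrameSchedule(end - durations, end)


@dataclass(frozen=True)
class TracerProfile:
    """Kinetic parameters of the generative model.

    ``blood_amp`` is the peak of the gamma-variate input (activity units);
    ``blood_peak_s`` its peak time.  Per-class (K1 [1/s], k2 [1/s]) pairs
    drive the one-tissue responses; defaults give distinct shapes with
    late-time ordering hbgm > lbgm > wm and a blood peak well inside 60 s.
    """

    blood_amp: float = 100.0
    blood_peak_s: float = 30.0
    K1: dict = field(
        default_factory=lambda: {"lbgm": 1.8e-3, "wm": 1.2e-3, "hbgm": 2.0e-3}
    )
    k2: dict = field(
        default_factory=lambda: {"lbgm": 1.5e-3, "wm": 3.0e-3, "hbgm": 4.0e-4}
    )

    def __post_init__(self) -> None:
        if self.blood_amp <= 0 or self.blood_peak_s <= 0:
            raise ValueError("blood input parameters must be positive")
        for cls in ("lbgm", "wm", "hbgm"):
            if self.K1[cls] <= 0 or self.k2[cls] <= 0:
                raise ValueError(f"non-physical rate for class '{cls}'")


def _input_function(t: np.ndarray, profile: TracerProfile) -> np.ndarray:
    """Gamma-variate (alpha=1) blood input, peak value blood_amp at blood_peak_s."""
    tp = profile.blood_peak_s
    return profile.blood_amp * (t / tp) * np.exp(1.0 - t / tp)


def _tissue_response(t: np.ndarray, K1: float, k2: float, profile: TracerProfile) -> np.ndarray:
    """Analytic 1-tissue response K1 * (input (*) exp(-k2 t)) at times t."""
    tp = profile.blood_peak_s
    c = profile.blood_amp * np.e / tp  # input = c * t * exp(-t/tp)
    a = 1.0 / tp - k2
    t = np.asarray(t, float)
    if abs(a) > 1e-12:
        inner = (1.0 - np.exp(-a * t) * (1.0 + a * t)) / a**2
    else:
        inner = t**2 / 2.0
    return K1 * c * np.exp(-k2 * t) * inner


def _frame_average(fn, schedule: FrameSchedule, n_sub: int = 257) -> np.ndarray:
    """Average an analytic curve over each frame interval (trapezoid)."""
    out = np.empty(schedule.n_frames)
    for j in range(schedule.n_frames):
        tt = np.linspace(schedule.frame_start[j], schedule.frame_end[j], n_sub)
        out[j] = np.trapezoid(fn(tt), tt) / (schedule.frame_end[j] - schedule.frame_start[j])
    return out


def make_class_templates(
    schedule: FrameSchedule, profile: TracerProfile | None = None
) -> dict[str, np.ndarray]:
    """Raw (un-normalized) frame-averaged TAC per class, order-free dict keyed
    lbgm/wm/blood/hbgm."""
    profile = profile or TracerProfile()
    templates = {"blood": _frame_average(lambda t: _input_function(t, profile), schedule)}
    for cls in ("lbgm", "wm", "hbgm"):
        templates[cls] = _frame_average(
            lambda t, c=cls: _tissue_response(t, profile.K1[c], profile.k2[c], profile),
            schedule,
        )
    return templates


@dataclass
class PhantomSpec:
    """Everything needed to generate one phantom scan, reproducibly."""

    shape: tuple[int, int, int] = (24, 24, 24)
    schedule: FrameSchedule = field(default_factory=default_schedule)
    profile: TracerProfile = field(default_factory=TracerProfile)
    mixing: bool = True
    dirichlet_alpha: tuple[float, float, float] = (2.0, 1.0, 1.0)  # (lbgm, wm, hbgm)
    max_mixture_component: float = 0.88
    csf_blood_fraction: float = 0.06  # CSF TAC = this fraction of the blood curve
    noise_level: float = 0.1
    voxel_size_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if not (0 < self.max_mixture_component < 1):
            raise ValueError("max_mixture_component must be in (0, 1)")
        if min(self.shape) < 16:
            raise ValueError("phantom shape must be at least 16 voxels per axis")

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size_mm] * 3 + [1.0])


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    labels: np.ndarray  # 3-D int volume, LABELS coding
    weights: np.ndarray  # 4-D (x,y,z,class) true mixing weights, CLASS_ORDER
    templates: dict[str, np.ndarray]  # raw frame-averaged class TACs
    schedule: FrameSchedule

    @property
    def lbgm_template(self) -> np.ndarray:
        return self.templates["lbgm"]

    def region(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]


def _layout(shape: tuple[int, int, int]) -> np.ndarray:
    """Disjoint labelled boxes scaled to the grid."""
    nx, ny, nz = shape
    lab = np.zeros(shape, dtype=np.int8)

    def box(x0, x1, y0, y1, z0, z1):
        return (
            slice(int(x0 * nx), int(x1 * nx)),
            slice(int(y0 * ny), int(y1 * ny)),
            slice(int(z0 * nz), int(z1 * nz)),
        )

    lab[box(1 / 8, 11 / 24, 1 / 8, 7 / 8, 1 / 8, 7 / 8)] = LABELS["wm"]
    lab[box(1 / 2, 5 / 6, 1 / 8, 7 / 8, 1 / 8, 11 / 24)] = LABELS["lbgm"]
    lab[box(1 / 2, 5 / 6, 1 / 8, 11 / 24, 1 / 2, 5 / 6)] = LABELS["hbgm"]
    lab[box(1 / 2, 5 / 6, 1 / 2, 7 / 8, 1 / 2, 5 / 6)] = LABELS["mixed"]
    # CSF-like slab: in-brain tissue that belongs to NO kinetic class, as in a
    # real brain mask; without it the volume-weighted sum of the normalized
    # class curves is ~0 and the NNLS cone contains a degenerate null combo
    lab[box(5 / 6, 23 / 24, 1 / 8, 7 / 8, 1 / 8, 7 / 8)] = LABELS["csf"]
    lab[box(1 / 6, 1 / 3, 1 / 6, 1 / 3, 1 / 6, 1 / 3)] = LABELS["blood"]  # carved out of wm
    return lab


def generate_phantom(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[DynamicImage, PhantomTruth, dict[str, MaskImage]]:
    """Generate one phantom scan plus its ground truth and mask set.

    Mixed-compartment voxels draw convex weights over (lbgm, wm, hbgm) from
    a Dirichlet, rejection-sampled so no component exceeds
    ``max_mixture_component`` — mixed voxels are therefore genuinely mixed
    and distinguishable from pure ones by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    labels = _layout(spec.shape)
    templates = make_class_templates(spec.schedule, spec.profile)
    n_frames = spec.schedule.n_frames
    T = np.stack([templates[c] for c in CLASS_ORDER], axis=0)  # (4, n_frames)

    weights = np.zeros(spec.shape + (len(CLASS_ORDER),))
    for i, cls in enumerate(CLASS_ORDER):
        weights[labels == LABELS[cls], i] = 1.0

    mixed = labels == LABELS["mixed"]
    n_mixed = int(mixed.sum())
    if spec.mixing and n_mixed:
        tissue_idx = [CLASS_ORDER.index(c) for c in ("lbgm", "wm", "hbgm")]
        draws = np.empty((n_mixed, 3))
        filled = 0
        while filled < n_mixed:
            batch = rng.dirichlet(spec.dirichlet_alpha, size=n_mixed)
            ok = batch.max(axis=1) <= spec.max_mixture_component
            take = min(int(ok.sum()), n_mixed - filled)
            draws[filled : filled + take] = batch[ok][:take]
            filled += take
        w_mixed = np.zeros((n_mixed, len(CLASS_ORDER)))
        w_mixed[:, tissue_idx] = draws
        weights[mixed] = w_mixed
    elif n_mixed:
        weights[mixed, CLASS_ORDER.index("lbgm")] = 1.0  # mixing off: treat as pure lbgm

    brain = labels > 0
    voxels = np.zeros(spec.shape + (n_frames,))
    voxels[brain] = weights[brain] @ T
    # CSF-like voxels: partial-volume vascular signal only, no tissue class
    # membership (truth weights stay zero there)
    csf = labels == LABELS["csf"]
    voxels[csf] = spec.csf_blood_fraction * templates["blood"]

    if spec.noise_level > 0:
        tac_mean = voxels.mean(axis=3, keepdims=True)
        sd = spec.noise_level * tac_mean / np.sqrt(spec.schedule.duration)
        noise = rng.standard_normal(voxels.shape) * sd
        noise[~brain] = 0.0
        voxels = voxels + noise

    affine = spec.affine
    gm_prob = np.zeros(spec.shape)
    gm_prob[labels == LABELS["lbgm"]] = 0.95
    gm_prob[labels == LABELS["hbgm"]] = 0.95
    gm_prob[labels == LABELS["mixed"]] = 0.8
    gm_prob[labels == LABELS["wm"]] = 0.05
    gm_prob[labels == LABELS["blood"]] = 0.02
    wm_prob = np.zeros(spec.shape)
    wm_prob[labels == LABELS["wm"]] = 0.95
    wm_prob[labels == LABELS["lbgm"]] = 0.05
    wm_prob[labels == LABELS["mixed"]] = 0.1

    masks = {
        "brain": MaskImage(brain.astype(float), affine, kind="binary", method="phantom-brain"),
        "gm_prob": MaskImage(gm_prob, affine, kind="probability", method="phantom-gm"),
        "wm_prob": MaskImage(wm_prob, affine, kind="probability", method="phantom-wm"),
        "high_binding": MaskImage(
            (labels == LABELS["hbgm"]).astype(float), affine, kind="binary",
            method="phantom-hbgm",
        ),
    }
    pet = DynamicImage(voxels, spec.schedule, affine, meta={"phantom_seed": spec.seed})
    truth = PhantomTruth(labels=labels, weights=weights, templates=templates,
                         schedule=spec.schedule)
    return pet, truth, masks


def _jitter_profile(profile: TracerProfile, sigma: float, rng: np.random.Generator,
                    hbgm_scale: float = 1.0) -> TracerProfile:
    """Log-normal multiplicative jitter on every kinetic parameter."""
    def j() -> float:
        return float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0

    K1 = {c: profile.K1[c] * j() for c in profile.K1}
    k2 = {c: profile.k2[c] * j() for c in profile.k2}
    K1["hbgm"] *= hbgm_scale
    return replace(
        profile,
        blood_amp=profile.blood_amp * j(),
        blood_peak_s=profile.blood_peak_s * j(),
        K1=K1,
        k2=k2,
    )


def generate_cohort(
    n_subjects: int,
    spec: PhantomSpec | None = None,
    inter_subject_jitter: float = 0.03,
    genotypes: list[str] | None = None,
    mab_hbgm_scale: float = 0.6,
    seed: int | None = None,
) -> tuple[list[SubjectRecord], list[PhantomTruth]]:
    """Simulate a training cohort: per-subject log-normal kinetic jitter and
    independent noise realizations on a shared phantom layout.

    ``genotypes`` (optional) assigns HAB/MAB per subject; MAB subjects have
    their high-binding K1 scaled by ``mab_hbgm_scale``.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    spec = spec or PhantomSpec()
    if genotypes is not None and len(genotypes) != n_subjects:
        raise ValueError("genotypes must have one entry per subject")
    # one child stream per subject: cohorts with the same seed are identical
    # in kinetics and mixture layout regardless of the noise level
    children = np.random.SeedSequence(spec.seed if seed is None else seed).spawn(n_subjects)
    subjects: list[SubjectRecord] = []
    truths: list[PhantomTruth] = []
    for i in range(n_subjects):
        rng = np.random.default_rng(children[i])
        geno = genotypes[i] if genotypes is not None else "unknown"
        scale = mab_hbgm_scale if geno == "MAB" else 1.0
        prof = _jitter_profile(spec.profile, inter_subject_jitter, rng, hbgm_scale=scale)
        sub_spec = replace(spec, profile=prof)
        pet, truth, masks = generate_phantom(sub_spec, rng=rng)
        subjects.append(
            SubjectRecord(subject_id=f"s{i + 1:02d}", pet=pet, masks=masks, genotype=geno)
        )
        truths.append(truth)
    return subjects, truths
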