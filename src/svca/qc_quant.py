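"""Quality-control checks and a minimal Logan reference-region DVR.

Every check is pure, never raises on a bad result, and always reports the
numeric evidence alongside its verdict.  "Early" and "late" frames are
operationalized as the first and last third of the schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .kinetic_classes import CLASS_ORDER, ClassTAC
from .petio import FrameSchedule, MaskImage

__all__ = [
    "QCCheck",
    "QCReport",
    "DVRResult",
    "qc_class_curves",
    "qc_reference_vs_anatomical",
    "qc_selection_distribution",
    "logan_ref_dvr",
]


@dataclass
class QCCheck:
    name: str
    verdict: str  # pass | warn | fail
    evidence: dict


@dataclass
class QCReport:
    checks: list[QCCheck] = field(default_factory=list)

    @property
    def worst(self) -> str:
        order = {"pass": 0, "warn": 1, "fail": 2}
        return max((c.verdict for c in self.checks), key=order.get, default="pass")

    def to_dict(self) -> dict:
        return {
            "worst": self.worst,
            "checks": [
                {"name": c.name, "verdict": c.verdict, "evidence": c.evidence}
                for c in self.checks
            ],
        }


@dataclass
class DVRResult:
    dvr: float
    t_star: float
    fit_r2: float
    n_points: int


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    return float((a * b).sum() / denom) if denom > 0 else np.nan


def qc_class_curves(per_subject: list[ClassTAC], min_correlation: float = 0.7) -> QCReport:
    """Within each class, check that subjects' normalized curves agree.

    Computes all pairwise Pearson correlations over frames; warns when any
    pair falls below ``min_correlation``.  Flags the subject whose curve is
    farthest (L2) from the class median curve as the maximal outlier.
    """
    report = QCReport()
    for cls in CLASS_ORDER:
        tacs = [t for t in per_subject if t.class_name == cls]
        if len(tacs) < 2:
            continue
        curves = np.stack([t.values for t in tacs])
        ids = [t.subject_id for t in tacs]
        n = len(tacs)
        corrs = []
        min_pair = None
        for i in range(n):
            for j in range(i + 1, n):
                r = _pearson(curves[i], curves[j])
                corrs.append(r)
                if min_pair is None or r < min_pair[0]:
                    min_pair = (r, ids[i], ids[j])
        median_curve = np.median(curves, axis=0)
        dist = np.linalg.norm(curves - median_curve, axis=1)
        outlier = int(np.argmax(dist))
        min_r = float(np.min(corrs))
        report.checks.append(
            QCCheck(
                name=f"class_curve_agreement_{cls}",
                verdict="pass" if min_r >= min_correlation else "warn",
                evidence={
                    "min_pairwise_r": min_r,
                    "min_pair": list(min_pair[1:]),
                    "median_pairwise_r": float(np.median(corrs)),
                    "max_outlier_subject": ids[outlier],
                    "max_outlier_distance": float(dist[outlier]),
                },
            )
        )
    return report


def qc_reference_vs_anatomical(
    ref_tac: np.ndarray,
    anat_tac: np.ndarray,
    schedule: FrameSchedule,
    tol: float = 0.05,
) -> QCReport:
    """Compare the extracted reference TAC (raw units) against an anatomical
    reference TAC: the peak over the first third of frames must be comparable
    or higher, and the mean over the last third comparable or lower."""
    ref_tac = np.asarray(ref_tac, float)
    anat_tac = np.asarray(anat_tac, float)
    if ref_tac.size != schedule.n_frames or anat_tac.size != schedule.n_frames:
        raise ValueError("TAC length must match the schedule")
    n = schedule.n_frames
    early = slice(0, max(1, n // 3))
    late = slice(n - max(1, n // 3), n)
    early_ratio = float(ref_tac[early].max() / anat_tac[early].max())
    late_ratio = float(ref_tac[late].mean() / anat_tac[late].mean())
    early_ok = early_ratio >= 1.0 - tol
    late_ok = late_ratio <= 1.0 + tol
    report = QCReport()
    report.checks.append(
        QCCheck(
            name="reference_vs_anatomical",
            verdict="pass" if (early_ok and late_ok) else "fail",
            evidence={
                "early_peak_ratio": early_ratio,
                "late_mean_ratio": late_ratio,
                "tol": tol,
                "early_ok": early_ok,
                "late_ok": late_ok,
            },
        )
    )
    return report


def qc_selection_distribution(
    selected_mask: MaskImage,
    candidate_mask: MaskImage,
    max_octant_fraction: float = 0.5,
) -> QCReport:
    """Check that selected voxels are not concentrated in one corner of the
    candidate region: split space into octants at the candidate-mask centroid
    and warn if any octant holds more than ``max_octant_fraction`` of them."""
    sel = selected_mask.as_bool
    cand = candidate_mask.as_bool
    if not np.all(sel <= cand):
        raise ValueError("selected mask must be a subset of the candidate mask")
    n_selected = int(sel.sum())
    coords = np.argwhere(sel)
    centroid = np.argwhere(cand).mean(axis=0)
    octant = (coords >= centroid).astype(int) @ np.array([4, 2, 1])
    fractions = np.bincount(octant, minlength=8) / max(n_selected, 1)
    worst = float(fractions.max())
    report = QCReport()
    report.checks.append(
        QCCheck(
            name="selection_distribution",
            verdict="pass" if worst <= max_octant_fraction else "warn",
            evidence={
                "n_selected": n_selected,
                "fraction_of_candidates": n_selected / max(int(cand.sum()), 1),
                "octant_fractions": fractions.tolist(),
                "max_octant_fraction": worst,
            },
        )
    )
    return report


def logan_ref_dvr(
    target_tac: np.ndarray,
    ref_tac: np.ndarray,
    schedule: FrameSchedule,
    t_star: float,
    k2_ref: float | None = None,
) -> DVRResult:
    """Logan graphical analysis with a reference-region input.

    Ordinary least squares of y = int_0^t C_T / C_T(t) against
    x = [int_0^t C_R + C_R(t)/k2_ref] / C_T(t) over frames with midpoint
    >= ``t_star``; the slope is the distribution volume ratio.  The
    ``k2_ref`` term (1/min) is omitted when absent.  Integrals use the
    trapezoid rule on frame midpoints with C(0) = 0.
    """
    ct = np.asarray(target_tac, float)
    cr = np.asarray(ref_tac, float)
    t = schedule.mid
    if ct.size != t.size or cr.size != t.size:
        raise ValueError("TAC length must match the schedule")
    late = t >= t_star
    if late.sum() < 3:
        raise ValueError("need at least 3 frames with midpoint >= t_star")
    if np.any(ct[late] <= 0) or np.any(cr[late] <= 0):
        raise ValueError("TACs must be positive beyond t_star")

    t0 = np.concatenate([[0.0], t])
    int_ct = cumulative_trapezoid(np.concatenate([[0.0], ct]), t0)
    int_cr = cumulative_trapezoid(np.concatenate([[0.0], cr]), t0)
    num = int_cr if k2_ref is None else int_cr + cr / (k2_ref / 60.0)  # k2_ref is 1/min
    y = int_ct[late] / ct[late]
    x = num[late] / ct[late]

    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    yhat = A @ coef
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DVRResult(dvr=float(coef[0]), t_star=float(t_star), fit_r2=r2,
                     n_points=int(late.sum()))
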