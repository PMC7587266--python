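"""TSNIT profile statistics, repeatability and group comparisons.

Conventions follow the circumpapillary evaluation protocol: the mean RNFL
thickness of a subject is computed over the entire scan circle, while mean
retardation and birefringence are computed only over A-scans where the
RNFL is thicker than the threshold (and outside vessel shadows).  Because
of the differing masks, a subject's mean birefringence cannot be obtained
by dividing the tabulated mean retardation by the tabulated mean
thickness.

Group comparisons use the two-tailed t-test from per-group summary
statistics; the unequal-variance (Welch) variant is the default, a pooled
variant is provided.  No multiple-testing correction is applied (raw p
values, noted in the output metadata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .birefringence import BirefringenceProfile

__all__ = [
    "SubjectSummary",
    "GroupResult",
    "smooth_profile",
    "quadrant_labels",
    "subject_summary",
    "repeatability",
    "welch_ttest_summary",
    "pooled_ttest_summary",
    "group_compare",
]

QUADRANTS = ("T", "S", "N", "I")


@dataclass
class SubjectSummary:
    subject_id: str
    mean_thickness_um: float
    mean_retardation_deg: float
    mean_biref_quotient: float
    mean_biref_regression: float
    n_valid: int
    usable: bool = True

    def mean_biref(self, method: str = "regression") -> float:
        if method == "regression":
            return self.mean_biref_regression
        if method == "quotient":
            return self.mean_biref_quotient
        raise ValueError(f"unknown method {method!r}")


@dataclass
class GroupResult:
    label: str
    n: int
    mean: float
    sd: float
    comparisons: list = field(default_factory=list)  # (other, t, df, p)


def _circular_sliding_mean(values: np.ndarray, valid: np.ndarray,
                           width: int) -> np.ndarray:
    """Mean over a circular window, using valid samples only."""
    n = len(values)
    half = width // 2
    offs = np.arange(-half, width - half)
    idx = (np.arange(n)[None, :] + offs[:, None]) % n
    vals = np.where(valid, values, 0.0)[idx]
    cnts = valid.astype(float)[idx]
    num = vals.sum(axis=0)
    den = cnts.sum(axis=0)
    out = np.full(n, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def smooth_profile(values: np.ndarray, valid_mask: np.ndarray,
                   window: int = 10, loess_span: float = 0.05) -> np.ndarray:
    """Smooth a circumpapillary profile for display.

    A sliding average over ``window`` A-scans (circular, valid samples
    only) followed by a local linear regression with tricube weights over
    a circular neighborhood of ``loess_span`` of the circle.  Invalid
    A-scans (vessel gaps) remain NaN in the output.
    """
    values = np.asarray(values, dtype=float)
    valid = np.asarray(valid_mask, dtype=bool) & np.isfinite(values)
    n = len(values)
    if not valid.any():
        return np.full(n, np.nan)
    sm = _circular_sliding_mean(values, valid, window)

    half = max(2, int(round(loess_span * n / 2)))
    offs = np.arange(-half, half + 1)
    w_tri = (1.0 - (np.abs(offs) / (half + 1)) ** 3) ** 3
    out = np.full(n, np.nan)
    sm_ok = np.isfinite(sm)
    for i in range(n):
        if not valid[i]:
            continue
        idx = (i + offs) % n
        keep = sm_ok[idx]
        if keep.sum() < 3:
            out[i] = sm[i]
            continue
        x = offs[keep].astype(float)
        y = sm[idx][keep]
        w = w_tri[keep]
        # weighted local line evaluated at the center (x = 0)
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx <= 0:
            out[i] = ym
        else:
            b = (w * (x - xm) * (y - ym)).sum() / sxx
            out[i] = ym - b * xm
    return out


def quadrant_labels(n_ascans: int, eye: str = "OD") -> np.ndarray:
    """Per-A-scan quadrant labels in TSNIT order.

    Equal 90-degree quadrants centered at temporal 0, superior 90, nasal
    180, inferior 270 degrees.  For left eyes (OS) the temporal and nasal
    labels swap (lateral mirroring); superior/inferior are preserved.
    """
    if n_ascans < 4:
        raise ValueError("need at least 4 A-scans for quadrants")
    if eye not in ("OD", "OS"):
        raise ValueError("eye must be 'OD' or 'OS'")
    phi = np.arange(n_ascans) * (360.0 / n_ascans)
    sector = (np.floor((phi + 45.0) / 90.0) % 4).astype(int)
    labels = np.array(QUADRANTS)[sector]
    if eye == "OS":
        labels = np.where(labels == "T", "n",
                          np.where(labels == "N", "T", labels))
        labels = np.where(labels == "n", "N", labels)
    return labels


def subject_summary(profile: BirefringenceProfile,
                    subject_id: str = "subject") -> SubjectSummary:
    """Per-subject circumpapillary means.

    Thickness averages over all segmentation-valid A-scans (vessels
    included); retardation and birefringence average over the validity
    mask only (thickness above threshold, no vessel).
    """
    seg_ok = profile.seg_valid & np.isfinite(profile.thickness_um)
    valid = profile.valid_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        return SubjectSummary(subject_id, float(np.nanmean(
            np.where(seg_ok, profile.thickness_um, np.nan))),
            np.nan, np.nan, np.nan, 0, usable=False)

    def _mean(arr: np.ndarray, mask: np.ndarray) -> float:
        sel = mask & np.isfinite(arr)
        return float(arr[sel].mean()) if sel.any() else np.nan

    return SubjectSummary(
        subject_id=subject_id,
        mean_thickness_um=_mean(profile.thickness_um, seg_ok),
        mean_retardation_deg=_mean(profile.delta_pr_deg, valid),
        mean_biref_quotient=_mean(profile.biref_quotient, valid),
        mean_biref_regression=_mean(profile.biref_regression, valid),
        n_valid=n_valid)


def repeatability(summaries: list[SubjectSummary] | dict[str, list[SubjectSummary]]
                  ) -> dict:
    """Sample SDs (n-1 denominator) over repeated acquisitions.

    Given a list of repeats for one subject, returns per-quantity SDs.
    Given a mapping of subject -> repeats, additionally returns the
    across-subject mean of the per-subject SDs for each quantity.
    """
    if isinstance(summaries, dict):
        per_subject = {sid: repeatability(reps)
                       for sid, reps in summaries.items()}
        keys = ("thickness_um", "retardation_deg",
                "biref_quotient", "biref_regression")
        mean_sd = {k: float(np.mean([per_subject[s][k] for s in per_subject]))
                   for k in keys}
        return {"per_subject": per_subject, "mean_sd": mean_sd}

    if len(summaries) < 2:
        raise ValueError("repeatability requires at least 2 repeats")
    return {
        "thickness_um": float(np.std(
            [s.mean_thickness_um for s in summaries], ddof=1)),
        "retardation_deg": float(np.std(
            [s.mean_retardation_deg for s in summaries], ddof=1)),
        "biref_quotient": float(np.std(
            [s.mean_biref_quotient for s in summaries], ddof=1)),
        "biref_regression": float(np.std(
            [s.mean_biref_regression for s in summaries], ddof=1)),
        "n_repeats": len(summaries),
    }


def welch_ttest_summary(m1: float, s1: float, n1: int,
                        m2: float, s2: float, n2: int
                        ) -> tuple[float, float, float]:
    """Two-tailed unequal-variance t-test from summary statistics.

    Returns (t, Welch-Satterthwaite df, two-tailed p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be >= 0")
    if m1 == m2:
        return 0.0, float(n1 + n2 - 2), 1.0
    v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
    if v1 + v2 == 0:
        # degenerate: identical-variance-free difference
        return np.inf if m1 > m2 else -np.inf, float(n1 + n2 - 2), 0.0
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def pooled_ttest_summary(m1: float, s1: float, n1: int,
                         m2: float, s2: float, n2: int
                         ) -> tuple[float, float, float]:
    """Two-tailed pooled-variance (Student) t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if m1 == m2:
        return 0.0, float(n1 + n2 - 2), 1.0
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    if sp2 == 0:
        return np.inf if m1 > m2 else -np.inf, float(df), 0.0
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def group_compare(groups: dict[str, list[SubjectSummary]],
                  control: str = "healthy",
                  quantity: str = "biref_regression",
                  variant: str = "welch") -> list[GroupResult]:
    """Per-group mean/SD of a summary quantity plus pairwise two-tailed
    t-tests of every non-control group against the control group."""
    if control not in groups:
        raise ValueError(f"control group {control!r} missing from groups")
    test = welch_ttest_summary if variant == "welch" else pooled_ttest_summary

    attr = {"thickness_um": "mean_thickness_um",
            "retardation_deg": "mean_retardation_deg",
            "biref_quotient": "mean_biref_quotient",
            "biref_regression": "mean_biref_regression"}[quantity]

    stats: dict[str, tuple[float, float, int]] = {}
    for label, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"group {label!r} needs n >= 2")
        vals = np.array([getattr(s, attr) for s in members], dtype=float)
        keep = np.isfinite(vals)
        if not keep.all():
            # subjects without enough evaluable A-scans fail the
            # inclusion rule and drop out of the group statistics
            warnings.warn(f"group {label!r}: excluding "
                          f"{int((~keep).sum())} unusable subject(s)")
            vals = vals[keep]
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 usable "
                             "subjects")
        stats[label] = (float(vals.mean()), float(np.std(vals, ddof=1)),
                        len(vals))

    results = []
    cm, cs, cn = stats[control]
    for label, (m, s, n) in stats.items():
        res = GroupResult(label=label, n=n, mean=m, sd=s)
        if label != control:
            t, df, p = test(cm, cs, cn, m, s, n)
            res.comparisons.append((control, t, df, p))
        results.append(res)
    return results
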