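"""Quantitative CBV and blood-brain-barrier permeability screening.

QUTE-CE imaging with an intravascular iron-oxide contrast agent yields a
quantitative cerebral blood volume (qCBV) fraction per region,

    qCBV = (I'_M - I_M) / (I'_B - I_B),

the tissue intensity change after contrast normalised by the blood-pool
intensity change (primes denote post-injection).  With an intact
blood-brain barrier qCBV is constant over consecutive post-contrast scans;
contrast leaking into tissue makes apparent qCBV drift upward, so
permeability is screened per subject and region as a positive slope of
qCBV against scan time (one-tailed OLS t-test), with adaptive two-stage
false-discovery-rate control across regions within each subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import RegionTimecourse

__all__ = [
    "CbvTimecourse",
    "compute_qcbv",
    "regional_qcbv_table",
    "permeability_slope",
    "fdr_bky_two_stage",
    "subject_permeability_screen",
    "group_cbv_ttests",
]


@dataclass
class CbvTimecourse:
    """Regional qCBV values over post-contrast scan times for one subject."""

    subject_id: str
    label_id: int
    times_s: np.ndarray
    qcbv: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.qcbv = np.asarray(self.qcbv, dtype=float)
        if self.times_s.shape != self.qcbv.shape:
            raise ValueError("times and qCBV values must share length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("scan times must be strictly increasing")
        if not np.all(np.isfinite(self.qcbv)):
            raise ValueError("qCBV values must be finite")


def compute_qcbv(i_m_post, i_m_pre, i_b_post, i_b_pre, context: str = ""):
    """qCBV = (I'_M - I_M) / (I'_B - I_B); contrast must raise blood signal.

    Works elementwise, so it applies voxelwise for maps or regionwise for
    timecourses.  Invariant to a common additive offset and to a common
    scale of all four intensities.
    """
    i_m_post = np.asarray(i_m_post, dtype=float)
    i_m_pre = np.asarray(i_m_pre, dtype=float)
    denom = np.asarray(i_b_post, dtype=float) - np.asarray(i_b_pre, dtype=float)
    if np.any(denom <= 0):
        where = f" ({context})" if context else ""
        raise ValueError(
            f"blood intensity change must be positive{where}: contrast did "
            "not raise the blood-pool signal"
        )
    return (i_m_post - i_m_pre) / denom


def regional_qcbv_table(
    pre_series: list[RegionTimecourse],
    post_series: list[list[RegionTimecourse]],
    scan_times_s: np.ndarray,
    blood_label: int,
    subject_id: str | None = None,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Regional qCBV timecourse table from pre/post region summaries.

    ``post_series`` holds one list of region timecourses per post-contrast
    scan.  Blood intensities are the designated blood label's regional
    summary at each scan.  The regional mean feeds qCBV; the median-based
    value is retained as a QC column (mean - median flags skewed regions).
    """
    scan_times_s = np.asarray(scan_times_s, dtype=float)
    if len(post_series) != scan_times_s.size:
        raise ValueError("one post-contrast series per scan time required")
    if len(post_series) < 3:
        raise ValueError("need >= 3 post-contrast scans for a slope")

    def by_label(series: list[RegionTimecourse]) -> dict[int, RegionTimecourse]:
        return {tc.label_id: tc for tc in series}

    pre = by_label(pre_series)
    if blood_label not in pre:
        raise ValueError(f"blood label {blood_label} absent from pre-contrast series")
    sid = subject_id or pre_series[0].subject_id
    i_b_pre = float(pre[blood_label].mean_intensity[0])

    rows = []
    for k, series in enumerate(post_series):
        post = by_label(series)
        if blood_label not in post:
            raise ValueError(f"blood label {blood_label} absent from scan {k}")
        i_b_post = float(post[blood_label].mean_intensity[0])
        for label_id, tc_pre in pre.items():
            if label_id == blood_label or label_id not in post:
                continue
            tc_post = post[label_id]
            stat = {"mean": "mean_intensity", "median": "median_intensity"}[statistic]
            q = compute_qcbv(
                getattr(tc_post, stat)[0],
                getattr(tc_pre, stat)[0],
                i_b_post,
                i_b_pre,
                context=f"subject {sid}, scan {k}",
            )
            q_med = compute_qcbv(
                tc_post.median_intensity[0],
                tc_pre.median_intensity[0],
                i_b_post,
                i_b_pre,
                context=f"subject {sid}, scan {k}",
            )
            rows.append(
                {
                    "subject_id": sid,
                    "label_id": label_id,
                    "scan_index": k,
                    "time_s": scan_times_s[k],
                    "qcbv": float(q),
                    "qcbv_median": float(q_med),
                }
            )
    return pd.DataFrame(rows)


def permeability_slope(tc: CbvTimecourse) -> tuple[float, float]:
    """OLS slope of qCBV on time with a one-tailed p for slope > 0.

    Returns ``(slope, p)`` where p comes from the t distribution with
    n - 2 degrees of freedom.  A perfectly constant timecourse has slope 0
    and p = 0.5 (the exact null); an exact positive line has p -> 0.
    """
    t = tc.times_s
    y = tc.qcbv
    n = t.size
    if n < 3:
        raise ValueError("need >= 3 scans for a permeability slope")
    tc_ = t - t.mean()
    sxx = float(np.dot(tc_, tc_))
    if sxx == 0:
        raise ValueError("zero variance in scan times")
    yc = y - y.mean()  # exact zeros for a constant timecourse
    slope = float(np.dot(tc_, yc) / sxx)
    resid = yc - slope * tc_
    sse = float(np.dot(resid, resid))
    se = np.sqrt(sse / (n - 2) / sxx)
    if se == 0:
        p = 0.5 if slope == 0 else (0.0 if slope > 0 else 1.0)
    else:
        p = float(stats.t.sf(slope / se, df=n - 2))
    return slope, p


def fdr_bky_two_stage(pvalues, q: float = 0.1) -> np.ndarray:
    """Adaptive two-stage Benjamini-Krieger-Yekutieli FDR decisions.

    Stage 1 runs Benjamini-Hochberg at q' = q/(1+q); the number of
    rejections r1 estimates the null count m0 = m - r1.  If r1 = 0 nothing
    is rejected; if r1 = m everything is; otherwise stage 2 reruns BH at
    level q' * m / m0.  Returns a boolean rejection vector aligned with the
    input.  Decisions are monotone: lowering any p-value never shrinks the
    rejection set.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p-values must be a non-empty 1D vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    q1 = q / (1.0 + q)
    stage1 = _bh_reject(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    m0 = m - r1
    return _bh_reject(p, q1 * m / m0)


def _bh_reject(p: np.ndarray, level: float) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = level * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def subject_permeability_screen(
    qcbv_table: pd.DataFrame,
    q: float = 0.1,
    p_raw: float = 0.05,
    groups: pd.Series | dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject permeability calls with within-subject FDR control.

    For every subject, fits the qCBV-vs-time slope in each region and tests
    slope > 0 one-tailed; a region is *called* permeable when its raw
    p < ``p_raw`` AND it survives the two-stage BKY procedure at rate ``q``
    across that subject's regions (both printed constraints applied).

    Parameters
    ----------
    qcbv_table : long table with columns subject_id, label_id, time_s, qcbv
        (e.g. from :func:`regional_qcbv_table`), optionally ``group``.
    groups : optional subject -> group mapping used for the summary.

    Returns
    -------
    calls : one row per subject x region with slope, p, and decision.
    summary : per group, subjects with >= 1 call and mean regions called.
    """
    required = {"subject_id", "label_id", "time_s", "qcbv"}
    missing = required - set(qcbv_table.columns)
    if missing:
        raise ValueError(f"qCBV table missing columns {sorted(missing)}")
    subjects = qcbv_table["subject_id"].unique()
    region_sets = {
        s: frozenset(qcbv_table.loc[qcbv_table["subject_id"] == s, "label_id"])
        for s in subjects
    }
    full = max(region_sets.values(), key=len)
    rows = []
    for s in subjects:
        if region_sets[s] != full:
            warnings.warn(
                f"subject {s} missing regions "
                f"{sorted(full - region_sets[s])}; skipped",
                stacklevel=2,
            )
            continue
        sub = qcbv_table[qcbv_table["subject_id"] == s]
        labels, slopes, pvals, ns = [], [], [], []
        for label_id, reg in sub.groupby("label_id"):
            reg = reg.sort_values("time_s")
            slope, p = permeability_slope(
                CbvTimecourse(
                    subject_id=str(s),
                    label_id=int(label_id),
                    times_s=reg["time_s"].to_numpy(),
                    qcbv=reg["qcbv"].to_numpy(),
                )
            )
            labels.append(int(label_id))
            slopes.append(slope)
            pvals.append(p)
            ns.append(len(reg))
        fdr_pass = fdr_bky_two_stage(np.array(pvals), q=q)
        called = fdr_pass & (np.array(pvals) < p_raw)
        for lab, sl, p, n, c in zip(labels, slopes, pvals, ns, called):
            rows.append(
                {
                    "subject_id": s,
                    "label_id": lab,
                    "slope_per_s": sl,
                    "p_one_tailed": p,
                    "n_scans": n,
                    "permeable": bool(c),
                }
            )
    calls = pd.DataFrame(rows)
    if groups is not None:
        gmap = dict(groups) if not isinstance(groups, dict) else groups
        calls["group"] = calls["subject_id"].map(gmap)
    elif "group" in qcbv_table.columns:
        gmap = (
            qcbv_table[["subject_id", "group"]]
            .drop_duplicates()
            .set_index("subject_id")["group"]
            .to_dict()
        )
        calls["group"] = calls["subject_id"].map(gmap)
    else:
        calls["group"] = "all"
    per_subject = (
        calls.groupby(["group", "subject_id"])["permeable"].sum().rename("n_called")
    )
    summary = (
        per_subject.reset_index()
        .groupby("group")
        .agg(
            n_subjects=("subject_id", "nunique"),
            subjects_with_call=("n_called", lambda x: int((x > 0).sum())),
            mean_regions_called=("n_called", "mean"),
        )
        .reset_index()
    )
    return calls, summary


def group_cbv_ttests(
    qcbv_table: pd.DataFrame, q: float = 0.1, p_raw: float = 0.05
) -> pd.DataFrame:
    """Two-sample t-test of mean regional qCBV between groups, per region.

    Each subject contributes its scan-averaged qCBV per region; groups are
    compared with a pooled-variance t-test and decisions are controlled
    across regions with two-stage BKY at rate ``q`` plus the raw p < 0.05
    gate.  Regions with zero variance in both groups get p = 1 with a
    warning.
    """
    if "group" not in qcbv_table.columns:
        raise ValueError("qCBV table needs a 'group' column for group tests")
    groups = sorted(qcbv_table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    per_subj = (
        qcbv_table.groupby(["group", "subject_id", "label_id"])["qcbv"]
        .mean()
        .reset_index()
    )
    rows = []
    for label_id, reg in per_subj.groupby("label_id"):
        a = reg.loc[reg["group"] == groups[0], "qcbv"].to_numpy()
        b = reg.loc[reg["group"] == groups[1], "qcbv"].to_numpy()
        if a.size < 2 or b.size < 2:
            raise ValueError(f"region {label_id}: need >= 2 subjects per group")
        if np.var(a) == 0 and np.var(b) == 0:
            if np.mean(a) == np.mean(b):
                warnings.warn(
                    f"region {label_id}: zero variance in both groups; p = 1",
                    stacklevel=2,
                )
                t_stat, p = 0.0, 1.0
            else:
                t_stat = np.inf if np.mean(a) > np.mean(b) else -np.inf
                p = 0.0
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "label_id": int(label_id),
                "t": float(t_stat),
                "p": float(p),
                f"mean_{groups[0]}": float(np.mean(a)),
                f"mean_{groups[1]}": float(np.mean(b)),
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = fdr_bky_two_stage(out["p"].to_numpy(), q=q) & (
        out["p"].to_numpy() < p_raw
    )
    return out
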