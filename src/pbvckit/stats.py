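"""Scan-rescan reproducibility statistics.

Summaries follow the test-retest design: for each condition (two same-day
sessions on a 1.5T-like scanner, two on a 3T-like scanner, or one session
from each) the PBVC measured between the pair is the measurement error,
since the true change within a day is zero.  Reported are the median and
IQR of the absolute errors (the "median percentage error"), the signed
medians (the bias toward measuring positive or negative atrophy), a paired
Wilcoxon signed-rank comparison between the two methods, and Bland-Altman
agreement tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("intra_A", "intra_B", "inter")
METHODS = ("jacobian", "edge")
MEASURES = ("PV", "GM")


@dataclass
class ComparisonRecord:
    """One subject x condition x method x measure PBVC measurement."""

    subject_id: str
    condition: str
    method: str
    measure: str
    pbvc: float
    true_pbvc: float = 0.0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}")
        if not math.isfinite(self.pbvc):
            raise ValueError("pbvc must be finite")


@dataclass
class ErrorSummary:
    """Median/IQR of absolute and signed scan-rescan errors (percent)."""

    median_abs: float
    iqr_abs: float
    median_signed: float
    iqr_signed: float
    n: int

    def to_dict(self):
        return self.__dict__.copy()


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.quantile(x, [0.25, 0.75])  # linear interpolation
    return float(q3 - q1)


def summarize_errors(pbvcs) -> ErrorSummary:
    """Median and IQR of |pbvc| and signed pbvc (quartiles by linear
    interpolation between order statistics)."""
    x = np.asarray(list(pbvcs), dtype=float)
    if x.size == 0:
        raise ValueError("empty group")
    ax = np.abs(x)
    return ErrorSummary(
        median_abs=float(np.median(ax)), iqr_abs=_iqr(ax),
        median_signed=float(np.median(x)), iqr_signed=_iqr(x),
        n=int(x.size))


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


def _signed_ranks(d: np.ndarray):
    """Mid-ranks of |d| with zeros already removed."""
    ad = np.abs(d)
    order = np.argsort(ad, kind="mergesort")
    ranks = np.empty(len(d), dtype=float)
    sorted_ad = ad[order]
    i = 0
    r = 1
    while i < len(d):
        j = i
        while j + 1 < len(d) and sorted_ad[j + 1] == sorted_ad[i]:
            j += 1
        mid = 0.5 * (r + (r + (j - i)))
        ranks[order[i:j + 1]] = mid
        r += j - i + 1
        i = j + 1
    return ranks


def wilcoxon_signed_rank(a, b, zero_method: str = "wilcox") -> tuple:
    """Paired two-sided Wilcoxon signed-rank test of a - b.

    Zero differences are dropped (``zero_method="wilcox"``, the classic
    convention) or ranked with the rest and then discarded from the rank
    sum (``"pratt"``); ties are mid-ranked.  For effective n <= 12 the
    p-value is exact, from full enumeration of all 2^n sign assignments of
    the ranks; above that a normal approximation with continuity
    correction and tie correction is used.  Returns ``(W, p)`` with W the
    positive-rank sum.  If every difference is zero the test is degenerate
    and p = 1.
    """
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("a and b must be equal-length, non-empty")
    d = a - b
    if zero_method == "pratt":
        ranks_all = _signed_ranks(d)
        keep = d != 0
        ranks = ranks_all[keep]
        d = d[keep]
    else:
        d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    if zero_method == "wilcox":
        ranks = _signed_ranks(d)
    w_pos = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    if n <= 12:
        # exact: enumerate every sign assignment of the ranks
        stats = np.zeros(2 ** n)
        for bits in range(2 ** n):
            s = 0.0
            for k in range(n):
                if bits >> k & 1:
                    s += ranks[k]
            stats[bits] = s
        # two-sided on the distance from the mean rank sum
        dist = np.abs(stats - total / 2.0)
        p = float(np.mean(dist >= abs(w_pos - total / 2.0) - 1e-12))
        return w_pos, min(p, 1.0)
    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie = np.sum(counts**3 - counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie
    if var <= 0:
        return w_pos, 1.0
    z = (abs(w_pos - mean) - 0.5) / math.sqrt(var)
    p = math.erfc(z / math.sqrt(2.0))
    return w_pos, min(p, 1.0)


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass
class BlandAltman:
    """Paired-method agreement table for absolute measurement errors.

    Per pair: x = mean of the two methods, y = method1 - method2 (positive
    y = method2 had the smaller error).  ``bias`` is mean(y) and the limits
    of agreement are bias +- 1.96 sd(y); with fewer than 2 pairs the limits
    are undefined and flagged.
    """

    means: np.ndarray
    differences: np.ndarray
    bias: float
    loa_low: float
    loa_high: float
    limits_defined: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean": self.means,
            "difference": self.differences,
            "method2_smaller_error": self.differences > 0,
        })


def bland_altman(err_method1, err_method2) -> BlandAltman:
    m1 = np.asarray(list(err_method1), dtype=float)
    m2 = np.asarray(list(err_method2), dtype=float)
    if m1.shape != m2.shape or m1.size == 0:
        raise ValueError("inputs must be paired and non-empty")
    x = (m1 + m2) / 2.0
    y = m1 - m2
    bias = float(y.mean())
    if y.size >= 2:
        sd = float(y.std(ddof=1))
        return BlandAltman(x, y, bias, bias - 1.96 * sd, bias + 1.96 * sd,
                           True)
    return BlandAltman(x, y, bias, float("nan"), float("nan"), False)


# ---------------------------------------------------------------------------
# Synthetic cohort study


@dataclass
class CohortConfig:
    """Study conditions for the simulated test-retest cohort.

    Defaults emulate the source design at analysis scale: n subjects with
    MS-like lesion loads, two same-pose sessions per scanner preset with
    fresh noise (intra conditions), and a repositioned cross-preset pair
    (inter condition); zero true atrophy throughout, so every measured
    PBVC is error.
    """

    n_subjects: int = 10
    seed: int = 0
    scale: float = 3.0
    noise_sigma: float = 0.05
    bias_amplitude: float = 0.1
    lesions: bool = True
    atrophy_pct: float = 0.0  # true change between the paired sessions
    calibration_pairs: int = 5
    lesion_filling: bool = True


@dataclass
class StudyResult:
    records: pd.DataFrame
    summaries: dict  # condition -> method -> measure -> ErrorSummary dict
    wilcoxon_pv: dict  # condition -> {"W":..., "p":...}
    bland_altman_pv: dict  # condition -> BlandAltman
    calibration_c: float
    excluded_subjects: list


def records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def summarize_records(records: pd.DataFrame) -> StudyResult:
    """Tables-shaped summaries + per-condition method comparison for PV.

    The method comparison (Wilcoxon of absolute errors, Bland-Altman) is
    computed for PV only: the edge comparator measures no GM volume.
    """
    summaries = {}
    wilc = {}
    ba = {}
    for cond in sorted(records.condition.unique()):
        summaries[cond] = {}
        sub = records[records.condition == cond]
        for method in sorted(sub.method.unique()):
            summaries[cond][method] = {}
            for measure in sorted(sub[sub.method == method].measure.unique()):
                grp = sub[(sub.method == method) & (sub.measure == measure)]
                err = grp.pbvc - grp.true_pbvc
                summaries[cond][method][measure] = \
                    summarize_errors(err).to_dict()
        jac = sub[(sub.method == "jacobian") & (sub.measure == "PV")]
        edg = sub[(sub.method == "edge") & (sub.measure == "PV")]
        if len(jac) and len(jac) == len(edg):
            jac = jac.sort_values("subject_id")
            edg = edg.sort_values("subject_id")
            e1 = np.abs(jac.pbvc.values - jac.true_pbvc.values)
            e2 = np.abs(edg.pbvc.values - edg.true_pbvc.values)
            W, p = wilcoxon_signed_rank(e1, e2)
            wilc[cond] = {"W": W, "p": p}
            ba[cond] = bland_altman(e1, e2)
    return StudyResult(records=records, summaries=summaries, wilcoxon_pv=wilc,
                       bland_altman_pv=ba, calibration_c=float("nan"),
                       excluded_subjects=[])


def run_study(config: CohortConfig | None = None,
              progress: bool = False) -> StudyResult:
    """Simulate the three test-retest conditions and run both methods.

    Per subject, four sessions are rendered (two per scanner preset; the
    intra-scanner pairs share the pose, the 3T-like sessions are
    repositioned relative to the 1.5T-like ones) and each condition's pair
    is processed end-to-end: preprocessing, iterative lesion-aware
    segmentation, Jacobian-modulated symmetric PBVC, and the calibrated
    edge-displacement comparator.  Subjects whose pipeline fails are
    excluded and counted.
    """
    from . import phantom as ph
    from .pipeline import (PipelineConfig, calibrate_edge_method,
                           process_session, compare_sessions)

    config = config or CohortConfig()
    pcfg = PipelineConfig()
    pcfg.segment.fill_seed = config.seed + 101
    pcfg.lesion_filling = config.lesion_filling

    calib = calibrate_edge_method(scale=config.scale, seed=config.seed,
                                  n_pairs=config.calibration_pairs)
    pcfg.edge.calibration_c = calib

    specs_a = ph.cohort_specs(config.n_subjects, seed=config.seed,
                              preset="T15", scale=config.scale,
                              lesions=config.lesions,
                              noise_sigma=config.noise_sigma,
                              bias_amplitude=config.bias_amplitude)
    records = []
    excluded = []
    rng = np.random.default_rng(config.seed + 31)
    for i, spec_a1 in enumerate(specs_a):
        sid = f"S{i:02d}"
        try:
            import dataclasses as dc

            seeds = rng.integers(0, 2**31 - 1, size=5)
            # intra-scanner rescans share the scanner's shading field
            # (the subject is not repositioned) and redraw only the noise
            spec_a2 = dc.replace(spec_a1, rng_seed=int(seeds[0]),
                                 bias_seed=spec_a1.rng_seed)
            spec_b1 = dc.replace(spec_a1, contrast_preset="T30",
                                 rng_seed=int(seeds[1]))
            spec_b1 = ph.to_preset_grid(spec_b1, "T30", config.scale)
            spec_b2 = dc.replace(spec_b1, rng_seed=int(seeds[2]),
                                 bias_seed=spec_b1.rng_seed)
            if config.atrophy_pct:
                spec_a2 = ph.apply_atrophy(spec_a2, config.atrophy_pct)
                spec_b2 = ph.apply_atrophy(spec_b2, config.atrophy_pct)
            # pose: intra pairs share it; the B scanner is repositioned
            pose_b = ph.reposition_pose(int(seeds[3]))
            sessions = {}
            for key, spec, pose in (("A1", spec_a1, None),
                                    ("A2", spec_a2, None),
                                    ("B1", spec_b1, pose_b),
                                    ("B2", spec_b2, pose_b)):
                if pose is not None:
                    spec = dc.replace(spec, pose=pose)
                t1, flair, truth = ph.render_session(spec)
                sessions[key] = process_session(t1, flair, pcfg,
                                                template_spec=None)
            pairs = {"intra_A": ("A1", "A2"), "intra_B": ("B1", "B2"),
                     "inter": ("A1", "B1")}
            truths = {"intra_A": 0.0, "intra_B": 0.0, "inter": 0.0}
            if config.atrophy_pct:
                truths["intra_A"] = ph.true_pbvc(spec_a1, spec_a2)[0]
                truths["intra_B"] = ph.true_pbvc(spec_b1, spec_b2)[0]
            for cond, (ka, kb) in pairs.items():
                res = compare_sessions(sessions[ka], sessions[kb], pcfg)
                records.append(ComparisonRecord(
                    sid, cond, "jacobian", "PV", res["jacobian"].pbvc_pv,
                    truths[cond]))
                records.append(ComparisonRecord(
                    sid, cond, "jacobian", "GM", res["jacobian"].pbvc_gm,
                    truths[cond]))
                records.append(ComparisonRecord(
                    sid, cond, "edge", "PV", res["edge"].pbvc,
                    truths[cond]))
            if progress:
                print(f"subject {sid} done")
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            excluded.append((sid, str(exc)))
    if not records:
        raise RuntimeError(f"all subjects failed: {excluded}")
    frame = records_frame(records)
    result = summarize_records(frame)
    result.calibration_c = calib
    result.excluded_subjects = excluded
    return result
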