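"""External-validation metrics for time-to-event prediction models.

Discrimination: cumulative-case / dynamic-control time-dependent ROC and
AUC(t) with inverse-probability-of-censoring weights (IPCW) from the
Kaplan-Meier estimate of the censoring distribution, with standard errors
from the influence-function (iid) representation of the weighted
two-sample U-statistic.  Paired model comparison uses the joint influence
functions of two AUC estimates — the time-dependent analogue of the DeLong
paired test (to which it reduces exactly when there is no censoring; a
literal DeLong test is undefined under censoring).

Calibration at a fixed horizon: subjects are binned by deciles of predicted
risk, the observed risk per bin is 1 - KM(t), and slope/intercept come from
least squares of observed on predicted bin means.

Clinical utility: survival decision-curve analysis, net benefit
NB(p_t) = TPrate - FPrate * p_t / (1 - p_t) with the event probability
inside the treated set estimated by KM at t (censoring-aware).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class UndefinedAUCError(ValueError):
    """Raised when there are no cases or no controls at the horizon."""


class DegenerateCalibrationError(ValueError):
    """Raised when predictions carry no spread to calibrate against."""


def censoring_km(time, event):
    """Kaplan-Meier estimate G(t) of the censoring survival function."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(np.asarray(time, float), 1 - np.asarray(event, int))
    return km


def _ipcw_parts(marker, time, event, t):
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    G = censoring_km(time, event)

    case = (time <= t) & (event == 1)
    control = time > t
    if not case.any() or not control.any():
        raise UndefinedAUCError(f"no cases or no controls at t={t}")

    w = np.zeros(len(time))
    # G(T_i-) for cases, G(t) for controls
    g_case = G.survival_function_at_times(
        np.maximum(time[case] - 1e-9, 0.0)).to_numpy()
    g_t = float(G.survival_function_at_times(t).iloc[0])
    g_case = np.maximum(g_case, 1e-8)
    g_t = max(g_t, 1e-8)
    w[case] = 1.0 / g_case
    w[control] = 1.0 / g_t
    return marker, w, case, control


@dataclass
class TimeDependentROC:
    """ROC curve and IPCW AUC at one horizon."""

    t: float
    auc: float
    se: float
    curve: pd.DataFrame  # threshold, fpr, tpr
    influence: np.ndarray  # per-subject influence values (for pairing)

    @property
    def ci(self) -> tuple[float, float]:
        h = 1.959963984540054 * self.se
        return (max(self.auc - h, 0.0), min(self.auc + h, 1.0))


def time_dependent_roc(marker, time, event, t) -> TimeDependentROC:
    """Cumulative/dynamic IPCW ROC at horizon ``t``.

    Cases are subjects with an observed event by t, controls those still
    event-free at t; weights undo the sampling bias of censoring before t.
    The AUC standard error comes from the influence-function representation
    of the ratio of the two weighted V-statistics (treating the censoring
    weights as fixed).
    """
    marker, w, case, control = _ipcw_parts(marker, time, event, t)
    n = len(marker)
    a = np.where(case, w, 0.0)  # case weights
    b = np.where(control, w, 0.0)  # control weights

    order = np.argsort(marker, kind="mergesort")
    m_sorted = marker[order]

    # S = (1/n^2) sum_ij a_i b_j [1(m_i > m_j) + 0.5 * 1(m_i == m_j)]
    # computed by rank accumulation over the sorted marker values
    a_s, b_s = a[order], b[order]
    uniq, inv = np.unique(m_sorted, return_inverse=True)
    b_per_level = np.bincount(inv, weights=b_s)
    a_per_level = np.bincount(inv, weights=a_s)
    b_below = np.concatenate([[0.0], np.cumsum(b_per_level)[:-1]])
    # row sums for cases: sum_j b_j (1(m_i>m_j) + .5 eq) = b_below + .5*b_eq
    row_case = b_below[inv] + 0.5 * b_per_level[inv]  # per sorted subject
    a_above = np.cumsum(a_per_level[::-1])[::-1] - a_per_level
    col_ctrl = a_above[inv] + 0.5 * a_per_level[inv]

    S = float((a_s * row_case).sum()) / n**2
    D = float(a.sum() * b.sum()) / n**2
    auc = S / D

    # influence functions of the two V-statistics, then the ratio
    if_S = np.empty(n)
    if_S[order] = a_s * row_case / n + b_s * col_ctrl / n
    if_S -= 2.0 * S
    if_D = a * b.sum() / n + b * a.sum() / n - 2.0 * D
    infl = (if_S - auc * if_D) / D
    se = float(np.sqrt((infl**2).sum()) / n)

    thresholds = np.unique(marker)[::-1]
    tp = [(a * (marker >= thr)).sum() / a.sum() for thr in thresholds]
    fp = [(b * (marker >= thr)).sum() / b.sum() for thr in thresholds]
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fp, "tpr": tp})
    return TimeDependentROC(float(t), float(auc), se, curve, infl)


def compare_auc(marker_a, marker_b, time, event, t):
    """Paired comparison of two IPCW AUCs on the same subjects.

    Returns ``(z, p)`` from the joint influence-function covariance of the
    two AUC estimates (two-sided).  Identical or rank-equivalent markers
    give z = 0, p = 1.
    """
    ra = time_dependent_roc(marker_a, time, event, t)
    rb = time_dependent_roc(marker_b, time, event, t)
    n = len(ra.influence)
    diff = ra.auc - rb.auc
    var = float(((ra.influence - rb.influence) ** 2).sum()) / n**2
    if var <= 1e-16 or abs(diff) < 1e-12:
        return 0.0, 1.0
    z = diff / np.sqrt(var)
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def calibration_at_time(pred_risk, time, event, t, n_bins: int = 10):
    """Binned calibration of predicted vs observed risk at horizon ``t``.

    Returns ``(slope, intercept, curve)``; ``curve`` holds one row per bin
    with mean predicted and KM-observed risk.  Bins without at-risk
    subjects are merged into their neighbour (with a warning).
    """
    from lifelines import KaplanMeierFitter

    pred = np.asarray(pred_risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.ptp(pred) < 1e-12:
        raise DegenerateCalibrationError(
            "all predicted risks equal; calibration slope undefined"
        )
    qs = np.quantile(pred, np.linspace(0, 1, n_bins + 1))
    qs[0] -= 1e-9
    bins = np.clip(np.searchsorted(qs, pred, side="left") - 1, 0, n_bins - 1)

    rows = []
    pending_idx = np.array([], dtype=int)
    for k in range(n_bins):
        idx = np.concatenate([pending_idx, np.nonzero(bins == k)[0]])
        if len(idx) == 0:
            continue
        if event[idx].sum() == 0 and (time[idx] <= t).all():
            # nothing informative at t: merge into the next bin
            warnings.warn(f"calibration bin {k} merged into its neighbour")
            pending_idx = idx
            continue
        pending_idx = np.array([], dtype=int)
        km = KaplanMeierFitter().fit(time[idx], event[idx])
        obs = 1.0 - float(km.survival_function_at_times(t).iloc[0])
        rows.append({"bin": k, "n": len(idx),
                     "predicted": float(pred[idx].mean()), "observed": obs})
    curve = pd.DataFrame(rows)
    if len(curve) < 2:
        raise DegenerateCalibrationError("fewer than 2 usable calibration bins")
    slope, intercept = np.polyfit(curve["predicted"], curve["observed"], 1)
    return float(slope), float(intercept), curve


@dataclass
class NetBenefitCurve:
    """Decision-curve net benefit of a model vs treat-all / treat-none."""

    t: float
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray

    @property
    def nb_none(self) -> np.ndarray:
        return np.zeros_like(self.thresholds)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds, "nb_model": self.nb_model,
            "nb_all": self.nb_all, "nb_none": self.nb_none,
        })


def decision_curve(pred_risk, time, event, t,
                   thresholds=None) -> NetBenefitCurve:
    """Survival decision-curve analysis at horizon ``t``.

    At threshold p_t the treated set is {predicted risk >= p_t}; the event
    probability inside it is estimated by Kaplan-Meier at t, so censoring
    is handled without discarding subjects.  An empty treated set yields
    net benefit 0 at that threshold.
    """
    from lifelines import KaplanMeierFitter

    pred = np.asarray(pred_risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(pred)

    km_all = KaplanMeierFitter().fit(time, event)
    p_event_all = 1.0 - float(km_all.survival_function_at_times(t).iloc[0])

    nb_model = np.zeros_like(thresholds)
    nb_all = np.zeros_like(thresholds)
    for i, pt in enumerate(thresholds):
        odds = pt / (1.0 - pt)
        nb_all[i] = p_event_all - (1.0 - p_event_all) * odds
        pos = pred >= pt
        if not pos.any():
            nb_model[i] = 0.0
            continue
        km_pos = KaplanMeierFitter().fit(time[pos], event[pos])
        p_event_pos = 1.0 - float(km_pos.survival_function_at_times(t).iloc[0])
        frac_pos = pos.sum() / n
        tp = frac_pos * p_event_pos
        fp = frac_pos * (1.0 - p_event_pos)
        nb_model[i] = tp - fp * odds
    return NetBenefitCurve(float(t), thresholds, nb_model, nb_all)


def evaluate_models(risks_by_model: dict[str, np.ndarray], time, event,
                    times=(12.0, 15.0, 18.0),
                    reference: str | None = None) -> pd.DataFrame:
    """AUC/CI (and paired z, p vs a reference model) per model x horizon.

    ``risks_by_model`` maps model names to per-subject predicted risks (or
    any monotone risk marker) on one evaluation cohort.
    """
    rows = []
    for t in times:
        rocs = {m: time_dependent_roc(r, time, event, t)
                for m, r in risks_by_model.items()}
        for m, roc in rocs.items():
            row = {"model": m, "t": t, "auc": roc.auc, "auc_se": roc.se,
                   "auc_lower95": roc.ci[0], "auc_upper95": roc.ci[1]}
            if reference is not None and m != reference:
                z, p = compare_auc(risks_by_model[m],
                                   risks_by_model[reference], time, event, t)
                row["z_vs_reference"] = z
                row["p_vs_reference"] = p
            rows.append(row)
    return pd.DataFrame(rows)
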