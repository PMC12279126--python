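"""Radiomics score: LASSO-Cox signature selection and validation statistics.

The rad-score is a linear combination of the texture signatures selected by
an L1-penalized Cox regression on the development cohort, weighted by their
penalized coefficients (on the standardized feature scale, so scores are
unitless).  The penalty is chosen by k-fold cross-validated partial-
likelihood deviance (lambda at the minimum); patients are stratified into
high/low-risk groups at the cutpoint maximizing the log-rank chi-square, and
the split is validated with Kaplan-Meier curves, the G-rho (Harrington-
Fleming, rho = 1) weighted log-rank test and a univariate Cox model.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from . import coxph
from .coxph import ConvergenceError  # re-export for callers

__all__ = [
    "RadScoreCox", "RadScoreCoxResults", "lasso_cox_path", "cv_select_lambda",
    "rad_score", "optimal_cutpoint", "km_estimate", "grho_logrank",
    "univariate_cox",
]


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature passed to standardization")
    return (X - mean) / sd, mean, sd


def lasso_cox_path(X, time, event, lambda_grid=None, n_lambdas=50,
                   lambda_min_ratio=0.05):
    """L1-penalized Cox coefficient path on internally standardized features.

    Returns ``(lambdas, B)``; coefficients are on the standardized scale.
    """
    X = np.asarray(X, dtype=float)
    if np.asarray(event).sum() < 2:
        raise ValueError("need at least 2 events for a penalized Cox path")
    Xs, _, _ = _standardize(X)
    return coxph.lasso_cox_path(time, event, Xs, lambda_grid=lambda_grid,
                                n_lambdas=n_lambdas,
                                lambda_min_ratio=lambda_min_ratio)


def cv_select_lambda(X, time, event, k=10, seed=0, n_lambdas=50,
                     lambda_min_ratio=0.05, max_refolds=10):
    """Select lambda by k-fold cross-validated partial-likelihood deviance.

    Folds are stratified by the event indicator.  A fold without events is
    handled by refolding with a fresh seed (with a warning); if that keeps
    failing an error is raised.  Returns ``(lambda_star, curve)`` where
    ``curve`` is a DataFrame (lambda, mean_deviance, se_deviance) for a
    selection plot.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > event.sum():
        raise ValueError(
            f"k={k} folds exceed the {event.sum()} events; "
            "use fewer folds or more events"
        )
    Xs, _, _ = _standardize(X)
    lmax = coxph.lambda_max(time, event, Xs)
    lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambdas)

    for attempt in range(max_refolds):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(Xs, event))
        if all(event[tr].sum() >= 2 and event[te].sum() >= 1 for tr, te in folds):
            if attempt:
                warnings.warn(f"refolded {attempt} time(s) to avoid event-free folds")
            break
    else:
        raise ValueError("could not build folds with events in every part")

    dev = np.zeros((k, len(lambdas)))
    for f, (tr, te) in enumerate(folds):
        # KKT tolerance relaxed for the CV paths: deviance differences of
        # interest are orders of magnitude above 1e-5-level coefficient noise
        _, B = coxph.lasso_cox_path(time[tr], event[tr], Xs[tr],
                                    lambda_grid=lambdas, tol=1e-5)
        for i, beta in enumerate(B):
            # V&VH cross-validated deviance: full-data minus training pll
            pll_full = coxph.cox_loglik(beta, time, event, Xs, order=0)
            pll_tr = coxph.cox_loglik(beta, time[tr], event[tr], Xs[tr], order=0)
            dev[f, i] = -2.0 * (pll_full - pll_tr)
    mean = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(k)
    best = int(np.argmin(mean))
    # ties resolved toward the larger (more parsimonious) penalty
    best = int(np.nonzero(np.isclose(mean, mean[best], atol=1e-10))[0][0])
    curve = pd.DataFrame({"lambda": lambdas, "mean_deviance": mean,
                          "se_deviance": se})
    return float(lambdas[best]), curve


class RadScoreCox:
    """LASSO-Cox rad-score model over a texture feature table.

    Parameters
    ----------
    features : DataFrame
        Per-patient texture features (columns = feature names).  Constant
        and non-finite columns are dropped before fitting.
    time, event : array-like
        Right-censored healing outcome (months; 1 = healed, 0 = censored).
    """

    def __init__(self, features: pd.DataFrame, time, event):
        features = pd.DataFrame(features)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if len(features) != len(time) or len(time) != len(event):
            raise ValueError("features, time and event lengths differ")
        if event.sum() < 2:
            raise ValueError("need at least 2 events")
        usable = [
            c for c in features.columns
            if np.all(np.isfinite(features[c])) and features[c].std() > 0
        ]
        self.features = features[usable]
        self.dropped_columns = [c for c in features.columns if c not in usable]
        self.time = time
        self.event = event

    def fit(self, cv: int = 10, seed: int = 0, n_lambdas: int = 50,
            lambda_min_ratio: float = 0.05, lambda_: float | None = None
            ) -> "RadScoreCoxResults":
        """Fit the penalized path, select lambda by CV and build the score."""
        X = self.features.to_numpy(dtype=float)
        Xs, mean, sd = _standardize(X)
        if lambda_ is None:
            lambda_, curve = cv_select_lambda(
                X, self.time, self.event, k=cv, seed=seed,
                n_lambdas=n_lambdas, lambda_min_ratio=lambda_min_ratio,
            )
        else:
            curve = None
        beta = coxph.lasso_cox_fit(self.time, self.event, Xs, lambda_)
        sel = np.nonzero(beta != 0)[0]
        coef = pd.Series(beta[sel], index=self.features.columns[sel])
        standardization = pd.DataFrame(
            {"mean": mean, "sd": sd}, index=self.features.columns
        )
        return RadScoreCoxResults(
            model=self, coefficients=coef, lambda_=float(lambda_),
            standardization=standardization, cv_curve=curve,
        )


@dataclass
class RadScoreCoxResults:
    """Fitted rad-score: selected signatures, weights and scoring rule."""

    model: RadScoreCox | None
    coefficients: pd.Series  # nonzero coefficients only, standardized scale
    lambda_: float
    standardization: pd.DataFrame  # per-feature mean/sd over the fit cohort
    cv_curve: pd.DataFrame | None = None
    cutpoint: float | None = None

    @property
    def selected(self) -> list[str]:
        return list(self.coefficients.index)

    def score(self, X: pd.DataFrame) -> np.ndarray:
        """Rad-score: sum of standardized selected features times weights."""
        X = pd.DataFrame(X)
        missing = [c for c in self.selected if c not in X.columns]
        if missing:
            raise KeyError(f"missing selected feature(s): {missing}")
        if not self.selected:
            return np.zeros(len(X))
        z = np.zeros(len(X))
        for name, coef in self.coefficients.items():
            mu = self.standardization.loc[name, "mean"]
            sd = self.standardization.loc[name, "sd"]
            z += coef * (X[name].to_numpy(dtype=float) - mu) / sd
        return z

    def stratify(self, X: pd.DataFrame) -> np.ndarray:
        """High-risk indicator (score > cutpoint); requires a set cutpoint."""
        if self.cutpoint is None:
            raise ValueError("no cutpoint set; call set_cutpoint first")
        return (self.score(X) > self.cutpoint).astype(int)

    def set_cutpoint(self, min_group_frac: float = 0.1) -> float:
        """Determine the optimal log-rank cutpoint on the fit cohort."""
        scores = self.score(self.model.features)
        self.cutpoint, _, _ = optimal_cutpoint(
            scores, self.model.time, self.model.event,
            min_group_frac=min_group_frac,
        )
        return self.cutpoint

    def summary(self) -> str:
        lines = [
            "Rad-score (LASSO-Cox) results",
            f"  lambda: {self.lambda_:.4g}",
            f"  selected signatures: {len(self.selected)}",
        ]
        for name, c in self.coefficients.items():
            lines.append(f"    {name:40s} {c:+.4f}")
        if self.cutpoint is not None:
            lines.append(f"  risk cutpoint: {self.cutpoint:.4f}")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "selected": self.selected,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "lambda": self.lambda_,
            "standardization": {
                k: {"mean": float(self.standardization.loc[k, "mean"]),
                    "sd": float(self.standardization.loc[k, "sd"])}
                for k in self.selected
            },
            "cutpoint": self.cutpoint,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, src: str | Path) -> "RadScoreCoxResults":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        payload = json.loads(text)
        coef = pd.Series(payload["coefficients"])
        std = pd.DataFrame(payload["standardization"]).T
        return cls(model=None, coefficients=coef, lambda_=payload["lambda"],
                   standardization=std, cutpoint=payload.get("cutpoint"))


def rad_score(results: RadScoreCoxResults, X: pd.DataFrame) -> np.ndarray:
    """Functional alias for :meth:`RadScoreCoxResults.score`."""
    return results.score(X)


# ---------------------------------------------------------------------------
# Validation statistics
# ---------------------------------------------------------------------------

def _logrank_chi2(time, event, group, rho: float = 0.0):
    """Weighted (G-rho) log-rank chi-square for two groups.

    Weights w(t) = pooled-KM S(t-)**rho (Harrington-Fleming); rho = 0 is the
    standard log-rank, rho = 1 the Peto-Peto-style early-difference test.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    if event.sum() == 0:
        raise ValueError("weighted log-rank undefined: no events")
    uniq = np.unique(time[event == 1])
    s_pooled = 1.0  # S(t-) of the pooled sample, updated as we pass each time
    num = 0.0
    var = 0.0
    for t in uniq:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        w = s_pooled**rho
        num += w * (d1 - d * n1 / n)
        if n > 1:
            var += w**2 * d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        s_pooled *= 1.0 - d / n
    if var == 0:
        return 0.0, 1.0
    chi2 = num**2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def grho_logrank(time_a, event_a, time_b, event_b, rho: float = 1.0):
    """G-rho weighted log-rank test between two samples.

    Returns ``(chi2, p)``; identical samples give a statistic of 0 and
    rho = 0 reduces to the standard log-rank test.
    """
    if len(time_a) == 0 or len(time_b) == 0:
        raise ValueError("both groups must be non-empty")
    time = np.concatenate([np.asarray(time_a, float), np.asarray(time_b, float)])
    event = np.concatenate([np.asarray(event_a, int), np.asarray(event_b, int)])
    group = np.concatenate([np.zeros(len(time_a), int), np.ones(len(time_b), int)])
    return _logrank_chi2(time, event, group, rho=rho)


def optimal_cutpoint(score, time, event, min_group_frac: float = 0.1,
                     corrected_p: bool = True):
    """Exhaustive log-rank scan for the optimal risk cutpoint.

    Candidates are midpoints of adjacent unique scores whose induced groups
    both hold at least ``min_group_frac`` of the sample; returns
    ``(cutpoint, chi2, p)`` for the maximizing candidate, with the
    Miller-Siegmund minimum-p correction applied when ``corrected_p`` (the
    naive p-value of a maximally selected statistic is anti-conservative).
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(score)
    uniq = np.unique(score)
    if len(uniq) < 2:
        raise ValueError("no admissible cutpoint: fewer than 2 distinct scores")
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    best = None
    for cut in mids:
        hi = score > cut
        frac = hi.mean()
        if frac < min_group_frac or frac > 1 - min_group_frac:
            continue
        chi2, _ = _logrank_chi2(time, event, hi.astype(int), rho=0.0)
        if best is None or chi2 > best[1]:
            best = (float(cut), float(chi2))
    if best is None:
        raise ValueError(
            f"no admissible cutpoint with both groups >= {min_group_frac:.0%}"
        )
    cut, chi2 = best
    z = np.sqrt(chi2)
    if corrected_p:
        # Miller & Siegmund bound for a maximally selected chi-square over
        # the admissible quantile range (eps, 1 - eps)
        eps = min_group_frac
        phi = sps.norm.pdf(z)
        log_term = np.log((1 - eps) ** 2 / eps**2)
        p = phi * (z - 1.0 / z) * log_term + 4.0 * phi / z if z > 0 else 1.0
        p = float(min(max(p, sps.chi2.sf(chi2, 1)), 1.0))
    else:
        p = float(sps.chi2.sf(chi2, 1))
    return cut, chi2, p


def km_estimate(time, event, label: str | None = None):
    """Kaplan-Meier product-limit estimate with Greenwood confidence bands.

    Returns a fitted :class:`lifelines.KaplanMeierFitter`; its ``median_``
    attribute carries the median survival time when reached.
    """
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter(label=label)
    km.fit(np.asarray(time, float), np.asarray(event, int))
    return km


def km_to_frame(km) -> pd.DataFrame:
    """Export a fitted KM curve as (time, survival, ci_lower, ci_upper, at_risk)."""
    sf = km.survival_function_
    ci = km.confidence_interval_
    out = pd.DataFrame({
        "time": sf.index.to_numpy(dtype=float),
        "survival": sf.iloc[:, 0].to_numpy(),
        "ci_lower": ci.iloc[:, 0].to_numpy(),
        "ci_upper": ci.iloc[:, 1].to_numpy(),
    })
    out["at_risk"] = [
        int((np.asarray(km.durations) >= t).sum()) for t in out["time"]
    ]
    return out


def univariate_cox(x, time, event):
    """Univariate Cox fit: hazard ratio, Wald 95% CI and p-value."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("predictor must be finite")
    beta, cov, pll, trace = coxph.newton_cox(time, event, x[:, None])
    b = float(beta[0])
    se = float(np.sqrt(cov[0, 0]))
    z = b / se
    return {
        "beta": b,
        "se": se,
        "hr": float(np.exp(b)),
        "ci_lower": float(np.exp(b - 1.959963984540054 * se)),
        "ci_upper": float(np.exp(b + 1.959963984540054 * se)),
        "p": float(2.0 * sps.norm.sf(abs(z))),
        "loglik": pll,
        "iterations": len(trace) - 1,
    }
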