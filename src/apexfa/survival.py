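"""Multivariate Cox prognostic models for periapical healing.

A reference model uses the six clinical covariates (gender, age, diabetes,
lesion diameter, tooth position, tooth location — the three-level location
encoded as premolar/molar dummies against anterior teeth); the candidate
models add one ROI rad-score each.  Variable selection is backward stepwise
by AIC, internal validation is Harrell's optimism-corrected concordance via
bootstrap resampling.  Ties are handled by the Breslow convention and the
baseline hazard by the Breslow estimator, so a fitted model predicts the
absolute healing risk 1 - exp(-Lambda0(t) * exp(beta'z)) at any time t.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import coxph

#: encoded clinical covariate columns (see phantom.CLINICAL_TERMS)
CLINICAL_COVARIATES = (
    "gender", "age", "diabetes", "lesion_mm", "position",
    "loc_premolar", "loc_molar",
)


@dataclass(frozen=True)
class ModelSpec:
    """Named covariate list: the reference model or clinical + one rad-score."""

    name: str
    covariates: tuple[str, ...]

    @classmethod
    def reference(cls) -> "ModelSpec":
        return cls("reference", CLINICAL_COVARIATES)

    @classmethod
    def with_radscore(cls, k: int) -> "ModelSpec":
        """Clinical covariates + the S_k rad-score (k in 1..4)."""
        return cls(f"model{k}", CLINICAL_COVARIATES + (f"radscore_s{k}",))


class CoxModel:
    """Multivariate Cox proportional-hazards model on a patient table.

    Parameters
    ----------
    data : DataFrame
        One row per patient with covariate columns and the outcome columns.
    covariates : sequence of str
    duration_col, event_col : str
    """

    def __init__(self, data: pd.DataFrame, covariates,
                 duration_col: str = "time_months", event_col: str = "event"):
        self.data = pd.DataFrame(data).reset_index(drop=True)
        self.covariates = list(covariates)
        self.duration_col = duration_col
        self.event_col = event_col
        missing = [c for c in self.covariates if c not in self.data.columns]
        if missing:
            raise KeyError(f"covariates not in data: {missing}")
        n_events = int(self.data[event_col].sum())
        if n_events < 10 * len(self.covariates):
            warnings.warn(
                f"{n_events} events for {len(self.covariates)} covariates "
                "(fewer than 10 events per covariate)", stacklevel=2,
            )

    @classmethod
    def from_spec(cls, spec: ModelSpec, data: pd.DataFrame, **kw) -> "CoxModel":
        return cls(data, spec.covariates, **kw)

    def _xyz(self):
        X = self.data[self.covariates].to_numpy(dtype=float)
        t = self.data[self.duration_col].to_numpy(dtype=float)
        e = self.data[self.event_col].to_numpy(dtype=int)
        return t, e, X

    def fit(self) -> "CoxResults":
        t, e, X = self._xyz()
        # Cox models are translation-invariant, so constant or (centered)
        # collinear covariates make the information matrix exactly singular;
        # drop them with a warning (common in small resamples/subsets).
        from scipy.linalg import qr

        Xc = X - X.mean(axis=0)
        _, R, piv = qr(Xc, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        rank = int((diag > max(diag[0], 1.0) * 1e-9).sum()) if len(diag) else 0
        keep = sorted(piv[:rank])
        if len(keep) < len(self.covariates):
            dropped = [self.covariates[i] for i in range(len(self.covariates))
                       if i not in keep]
            warnings.warn(f"dropping degenerate covariate(s): {dropped}",
                          stacklevel=2)
        terms = [self.covariates[i] for i in keep]
        beta, cov, pll, trace = coxph.newton_cox(t, e, X[:, keep])
        baseline = coxph.breslow_baseline(t, e, X[:, keep], beta)
        fitted = CoxModel(self.data, terms, self.duration_col, self.event_col) \
            if terms != self.covariates else self
        return CoxResults(fitted, pd.Series(beta, index=terms),
                          cov, pll, baseline)


@dataclass
class CoxResults:
    """Fitted Cox model: coefficients, covariance, baseline hazard, summaries."""

    model: CoxModel
    params: pd.Series
    covariance: np.ndarray
    loglik: float
    baseline_cumhaz: coxph.BaselineCumHaz

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance)),
                         index=self.params.index)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.params)

    def hazard_ratios(self) -> pd.DataFrame:
        se = self.bse
        z = self.params / se
        return pd.DataFrame({
            "coef": self.params,
            "se": se,
            "HR": np.exp(self.params),
            "HR_lower95": np.exp(self.params - 1.959963984540054 * se),
            "HR_upper95": np.exp(self.params + 1.959963984540054 * se),
            "p": 2.0 * sps.norm.sf(np.abs(z)),
        })

    def linear_predictor(self, data: pd.DataFrame | None = None) -> np.ndarray:
        df = self.model.data if data is None else pd.DataFrame(data)
        X = df[list(self.params.index)].to_numpy(dtype=float)
        return X @ self.params.to_numpy()

    def predict_risk(self, t, data: pd.DataFrame | None = None) -> np.ndarray:
        """Absolute event risk by time t: 1 - exp(-Lambda0(t) e^lp)."""
        lp = self.linear_predictor(data)
        lam = self.baseline_cumhaz(t)
        return 1.0 - np.exp(-np.atleast_1d(lam)[..., None] * np.exp(lp)).squeeze()

    def concordance(self, data: pd.DataFrame | None = None) -> float:
        from lifelines.utils import concordance_index

        df = self.model.data if data is None else pd.DataFrame(data)
        lp = self.linear_predictor(df)
        return float(concordance_index(
            df[self.model.duration_col], -lp, df[self.model.event_col]
        ))

    def summary(self) -> str:
        hr = self.hazard_ratios()
        lines = [
            f"Cox PH model ({len(self.model.data)} subjects, "
            f"{int(self.model.data[self.model.event_col].sum())} events; "
            f"Breslow ties)",
            f"  log-likelihood {self.loglik:.2f}   AIC {self.aic:.2f}",
            f"  {'term':<16}{'coef':>9}{'HR':>8}{'95% CI':>18}{'p':>9}",
        ]
        for term, row in hr.iterrows():
            lines.append(
                f"  {term:<16}{row['coef']:>9.3f}{row['HR']:>8.3f}"
                f"   [{row['HR_lower95']:.3f}, {row['HR_upper95']:.3f}]"
                f"{row['p']:>9.4f}"
            )
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "terms": list(self.params.index),
            "beta": [float(b) for b in self.params],
            "covariance": self.covariance.tolist(),
            "loglik": self.loglik,
            "baseline_cumhaz": {
                "times": self.baseline_cumhaz.times.tolist(),
                "cumhaz": self.baseline_cumhaz.cumhaz.tolist(),
            },
        }


def fit_cox(spec: ModelSpec, data: pd.DataFrame, **kw) -> CoxResults:
    """Fit the Cox model named by ``spec`` on ``data``."""
    return CoxModel.from_spec(spec, data, **kw).fit()


def stepwise_select(results: CoxResults, criterion: str = "aic",
                    direction: str = "backward") -> CoxResults:
    """Backward stepwise selection by AIC.

    Iteratively removes the term whose removal most improves the criterion
    until no removal improves it; deterministic given the data.  Returns the
    input fit unchanged when it is already optimal.
    """
    if criterion != "aic" or direction != "backward":
        raise ValueError("only backward selection by AIC is supported")
    model = results.model
    current = results
    terms = list(current.params.index)
    while len(terms) > 1:
        best_candidate = None
        for drop in terms:
            reduced = list(t for t in terms if t != drop)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cand = CoxModel(model.data, reduced, model.duration_col,
                                model.event_col).fit()
            if cand.aic < current.aic - 1e-10 and (
                best_candidate is None or cand.aic < best_candidate.aic
            ):
                best_candidate = cand
        if best_candidate is None:
            break
        current = best_candidate
        terms = list(current.params.index)
    return current


def bootstrap_validate(spec: ModelSpec, data: pd.DataFrame, B: int = 200,
                       seed: int = 0, stepwise: bool = False,
                       duration_col: str = "time_months",
                       event_col: str = "event") -> dict:
    """Harrell optimism-corrected concordance by bootstrap.

    Refits the model (including stepwise selection when requested) on each
    bootstrap resample, measures the apparent-minus-test optimism against
    the original sample and subtracts its mean from the apparent
    concordance.  Resamples without events are redrawn with a warning.
    """
    if B < 1:
        raise ValueError("B must be >= 1 (use B >= 50 for stable estimates)")
    data = pd.DataFrame(data).reset_index(drop=True)
    rng = np.random.default_rng(seed)

    def _fit(df):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = CoxModel(df, spec.covariates, duration_col, event_col).fit()
            if stepwise:
                res = stepwise_select(res)
        return res

    full = _fit(data)
    apparent = full.concordance()
    optimisms = []
    n = len(data)
    for _ in range(B):
        for _try in range(100):
            idx = rng.integers(0, n, size=n)
            boot = data.iloc[idx].reset_index(drop=True)
            if boot[event_col].sum() >= max(2, len(spec.covariates)):
                break
        else:
            raise RuntimeError("could not draw a bootstrap sample with events")
        if boot[event_col].sum() < data[event_col].sum() * 0.1:
            warnings.warn("bootstrap resample nearly event-free; redrawn")
        try:
            bres = _fit(boot)
        except coxph.ConvergenceError:
            continue
        app_b = bres.concordance(boot)
        test_b = bres.concordance(data)
        optimisms.append(app_b - test_b)
    optimism = float(np.mean(optimisms)) if optimisms else 0.0
    return {
        "apparent": float(apparent),
        "optimism": optimism,
        "corrected": float(apparent - optimism),
        "B_effective": len(optimisms),
    }
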