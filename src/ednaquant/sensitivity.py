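"""Modeled limits of detection (LOD) and quantification (LOQ).

The LOD is the smallest copy number per reaction detected with a target
probability (default 95%). It is estimated by fitting monotone detection
curves to replicated dilution-series data by maximum binomial likelihood:

* ``poisson_cloglog`` — p(Q) = 1 - exp(-c*Q), the single-molecule Poisson
  sampling model (a binomial GLM with complementary log-log link and
  log-copies offset). With perfect per-molecule detection (c = 1) this gives
  the theoretical floor LOD = -ln(0.05) ~ 3 copies.
* ``logistic_log10`` — a logistic curve in log10 copies, covering assays
  whose detection falls off faster or slower than Poisson sampling predicts.

The lower-AIC model is selected and solved for p(Q) = probability.

The LOQ is the smallest copy number whose replicate-to-replicate coefficient
of variation (CV = sd/mean of back-calculated copies) stays below a
threshold (default 35%). Per-concentration CVs are fitted with three
candidate models — exponential decay ``a*exp(-b*Q)``, linear in log10 Q, and
quadratic in log10 Q — selected by AIC, and the fitted curve's first
downward crossing of the threshold within the standards' range is the LOQ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq, curve_fit
from sklearn.base import BaseEstimator

from .calibration import StandardCurve, cq_to_copies
from .records import SensitivityError

LOD_MODELS = ("poisson_cloglog", "logistic_log10")
LOQ_MODELS = ("exponential_decay", "linear", "polynomial2")


@dataclass(frozen=True)
class DetectionSummary:
    """Detection outcome at one standard concentration."""

    copies: float
    n_replicates: int
    n_detected: int

    def __post_init__(self):
        if self.n_detected > self.n_replicates:
            raise SensitivityError("n_detected cannot exceed n_replicates")


@dataclass(frozen=True)
class CvSummary:
    """Coefficient of variation of back-calculated copies at one concentration."""

    copies: float
    cv: float
    n_used: int


@dataclass(frozen=True)
class SensitivityResult:
    """Combined LOD/LOQ estimate for one assay."""

    lod_copies: float
    loq_copies: float
    lod_model: str
    loq_model: str
    lod_censored: bool
    loq_censored: bool
    fit_diagnostics: dict = field(default_factory=dict)
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "lod_copies": self.lod_copies,
            "loq_copies": self.loq_copies,
            "lod_model": self.lod_model,
            "loq_model": self.loq_model,
            "lod_censored": self.lod_censored,
            "loq_censored": self.loq_censored,
            "fit_diagnostics": self.fit_diagnostics,
            "notes": list(self.notes),
        }


def summarize_detections(standards: pd.DataFrame) -> pd.DataFrame:
    """Aggregate standard wells into per-concentration detection counts.

    Returns a frame with columns ``copies``, ``n_replicates``,
    ``n_detected`` (one row per distinct known concentration). A well counts
    as detected when its Cq is present.
    """
    df = standards
    if "reaction_type" in df.columns:
        df = df[df["reaction_type"] == "standard"]
    if df.empty:
        raise SensitivityError("no standard wells to summarize")
    out = (
        df.assign(detected=df["cq"].notna())
        .groupby("known_copies", sort=True)
        .agg(n_replicates=("detected", "size"), n_detected=("detected", "sum"))
        .reset_index()
        .rename(columns={"known_copies": "copies"})
    )
    out["n_detected"] = out["n_detected"].astype(int)
    return out


def summarize_cv(standards: pd.DataFrame, curve: StandardCurve) -> pd.DataFrame:
    """Per-concentration CV of back-calculated copies among detected wells.

    Concentrations with fewer than two detected replicates have no defined
    CV and are omitted. Columns: ``copies``, ``cv``, ``n_used``.
    """
    df = standards
    if "reaction_type" in df.columns:
        df = df[df["reaction_type"] == "standard"]
    df = df[df["cq"].notna()]
    rows = []
    for q, grp in df.groupby("known_copies", sort=True):
        est = cq_to_copies(grp["cq"].to_numpy(float), curve)
        if est.size < 2:
            continue
        rows.append(
            {"copies": float(q), "cv": float(np.std(est, ddof=1) / np.mean(est)), "n_used": int(est.size)}
        )
    return pd.DataFrame(rows, columns=["copies", "cv", "n_used"])


class LodEstimator(BaseEstimator):
    """Detection-probability curve fit yielding the limit of detection.

    Parameters
    ----------
    probability : float
        Target detection probability defining the LOD (default 0.95).

    Attributes
    ----------
    lod_ : float
        Estimated copies per reaction at the target probability.
    model_ : str
        Selected candidate, ``poisson_cloglog`` or ``logistic_log10``.
    censored_ : bool
        True when the lowest tested concentration already meets the target,
        so the LOD is only bounded above by it.
    aic_ : dict
        AIC of each successfully fitted candidate.
    params_ : dict
        Fitted coefficients of each candidate.
    """

    def __init__(self, probability: float = 0.95):
        self.probability = probability

    # -- candidate curves ------------------------------------------------
    def _fit_poisson(self, q, k, n):
        # binomial GLM, cloglog link, offset log(Q): eta = log(c) + log(Q)
        endog = np.column_stack([k, n - k])
        model = sm.GLM(
            endog,
            np.ones((len(q), 1)),
            family=sm.families.Binomial(link=sm.families.links.CLogLog()),
            offset=np.log(q),
        )
        res = model.fit()
        c = float(np.exp(res.params[0]))
        return {"c": c}, float(res.aic)

    def _fit_logistic(self, q, k, n):
        endog = np.column_stack([k, n - k])
        exog = sm.add_constant(np.log10(q))
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        b0, b1 = (float(v) for v in res.params)
        return {"b0": b0, "b1": b1}, float(res.aic)

    @staticmethod
    def _prob(model: str, params: dict, q):
        q = np.asarray(q, dtype=float)
        if model == "poisson_cloglog":
            return 1.0 - np.exp(-params["c"] * q)
        eta = params["b0"] + params["b1"] * np.log10(q)
        return 1.0 / (1.0 + np.exp(-eta))

    def _solve(self, model: str, params: dict) -> float:
        p = self.probability
        if model == "poisson_cloglog":
            return -np.log(1.0 - p) / params["c"]
        logit = np.log(p / (1.0 - p))
        return 10.0 ** ((logit - params["b0"]) / params["b1"])

    # --------------------------------------------------------------------
    def fit(self, X, y=None, n_replicates=None):
        """Fit the detection curve.

        Two input forms are accepted:

        * ``X`` = copies per well (shape (n_wells,)), ``y`` = 0/1 detection
          indicator per well;
        * ``X`` = distinct concentrations, ``y`` = detected counts,
          ``n_replicates`` = trials per concentration.
        """
        if not 0 < self.probability < 1:
            raise SensitivityError("probability must be in (0, 1)")
        x = np.asarray(X, dtype=float).reshape(-1)
        if n_replicates is None:
            det = np.asarray(y).reshape(-1).astype(int)
            q, inv = np.unique(x, return_inverse=True)
            n = np.bincount(inv)
            k = np.bincount(inv, weights=det).astype(int)
        else:
            q = x
            k = np.asarray(y, dtype=int).reshape(-1)
            n = np.asarray(n_replicates, dtype=int).reshape(-1)
        if np.any(q <= 0):
            raise SensitivityError("concentrations must be positive")
        if k.sum() == 0:
            raise SensitivityError("no detections at any concentration; LOD undefined")

        self.detections_ = pd.DataFrame(
            {"copies": q, "n_replicates": n, "n_detected": k}
        )
        self.warnings_: list[str] = []
        self.aic_: dict[str, float] = {}
        self.params_: dict[str, dict] = {}

        qmin = float(q.min())
        if np.all(k == n):
            # complete detection everywhere: the curve is unidentifiable and
            # the target is met at (at least) the lowest standard
            self.lod_ = qmin
            self.model_ = "poisson_cloglog"
            self.censored_ = True
            return self

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for name, fitter in (
                ("poisson_cloglog", self._fit_poisson),
                ("logistic_log10", self._fit_logistic),
            ):
                try:
                    params, aic = fitter(q, k, n)
                except Exception as exc:  # pragma: no cover - fit failure path
                    self.warnings_.append(f"{name} fit failed: {exc}")
                    continue
                monotone = name == "poisson_cloglog" and params["c"] > 0
                monotone |= name == "logistic_log10" and params.get("b1", 0) > 0
                if not monotone:
                    self.warnings_.append(
                        f"{name} fit is not increasing in copies; discarded"
                    )
                    continue
                self.params_[name] = params
                self.aic_[name] = aic
        if not self.params_:
            raise SensitivityError(
                "no monotone detection model could be fitted: "
                + "; ".join(self.warnings_)
            )
        self.model_ = min(self.aic_, key=self.aic_.get)
        params = self.params_[self.model_]
        if self._prob(self.model_, params, qmin) >= self.probability:
            self.lod_ = qmin
            self.censored_ = True
        else:
            self.lod_ = float(self._solve(self.model_, params))
            self.censored_ = False
        return self

    def detection_probability(self, copies):
        """Fitted detection probability at the given copy numbers."""
        return self._prob(self.model_, self.params_[self.model_], copies)


class LoqEstimator(BaseEstimator):
    """CV-curve fit with model selection yielding the limit of quantification.

    Parameters
    ----------
    cv_threshold : float
        Maximum acceptable coefficient of variation (default 0.35).

    Attributes
    ----------
    loq_ : float
    model_ : str
        Selected candidate: ``exponential_decay``, ``linear`` or
        ``polynomial2``.
    censored_ : bool
        True when the threshold is met at the lowest standard already, or is
        never met within the standards' range (then ``loq_`` is the highest
        standard and a warning is recorded).
    aic_ : dict
    """

    def __init__(self, cv_threshold: float = 0.35):
        self.cv_threshold = cv_threshold

    @staticmethod
    def _predictors(model: str, params, q):
        q = np.asarray(q, dtype=float)
        if model == "exponential_decay":
            a, b = params
            return a * np.exp(-b * q)
        return np.polyval(params, np.log10(q))

    def fit(self, X, y):
        """Fit CV against copies.

        ``X``: concentrations (copies/reaction), ``y``: CV at each.
        """
        if not 0 < self.cv_threshold:
            raise SensitivityError("cv_threshold must be positive")
        q = np.asarray(X, dtype=float).reshape(-1)
        cv = np.asarray(y, dtype=float).reshape(-1)
        mask = np.isfinite(q) & np.isfinite(cv)
        q, cv = q[mask], cv[mask]
        order = np.argsort(q)
        q, cv = q[order], cv[order]
        if q.size < 3:
            raise SensitivityError("need CV at >= 3 concentrations")
        n = q.size

        self.aic_: dict[str, float] = {}
        self.params_: dict[str, tuple] = {}
        self.warnings_: list[str] = []

        def register(name, params, k):
            resid = cv - self._predictors(name, params, q)
            rss = float(np.sum(resid**2))
            if n <= k:  # saturated fit carries no evidence
                return
            self.aic_[name] = n * np.log(max(rss, 1e-12) / n) + 2 * (k + 1)
            self.params_[name] = tuple(float(p) for p in params)

        # exponential decay a*exp(-b*Q), a,b > 0
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p0 = (max(cv.max(), 1e-3), 1.0 / max(np.median(q), 1e-9))
                popt, _ = curve_fit(
                    lambda x, a, b: a * np.exp(-b * x),
                    q,
                    cv,
                    p0=p0,
                    bounds=([0, 0], [np.inf, np.inf]),
                    maxfev=20000,
                )
            register("exponential_decay", popt, 2)
        except Exception as exc:
            self.warnings_.append(f"exponential_decay fit failed: {exc}")
        register("linear", np.polyfit(np.log10(q), cv, 1), 2)
        if n > 3:
            register("polynomial2", np.polyfit(np.log10(q), cv, 2), 3)
        if not self.aic_:
            raise SensitivityError("no CV model could be fitted")
        self.model_ = min(self.aic_, key=self.aic_.get)
        self.loq_, self.censored_ = self._crossing(q)
        return self

    def _crossing(self, q) -> tuple[float, bool]:
        """First downward crossing of the fitted CV through the threshold."""
        params = self.params_[self.model_]
        thr = self.cv_threshold
        f = lambda x: self._predictors(self.model_, params, x) - thr
        qmin, qmax = float(q.min()), float(q.max())
        if f(qmin) <= 0:
            return qmin, True
        grid = np.geomspace(qmin, qmax, 512)
        vals = f(grid)
        below = np.nonzero(vals <= 0)[0]
        if below.size == 0:
            self.warnings_.append(
                f"fitted CV never drops to {thr:g} within the standards' range; "
                "LOQ censored at the highest standard"
            )
            return qmax, True
        i = below[0]
        return float(brentq(f, grid[i - 1], grid[i])), False

    def predict(self, X):
        """Fitted CV at the given copy numbers."""
        return self._predictors(self.model_, self.params_[self.model_], X)


def estimate_lod(
    detections: pd.DataFrame, probability: float = 0.95
) -> tuple[float, str, bool]:
    """LOD from a per-concentration detection summary.

    ``detections`` has columns ``copies``, ``n_replicates``, ``n_detected``
    (as produced by :func:`summarize_detections`). Returns
    ``(lod_copies, model, censored)``.
    """
    est = LodEstimator(probability=probability)
    est.fit(
        detections["copies"].to_numpy(float),
        detections["n_detected"].to_numpy(int),
        n_replicates=detections["n_replicates"].to_numpy(int),
    )
    return est.lod_, est.model_, est.censored_


def estimate_loq(
    standards: pd.DataFrame,
    curve: StandardCurve,
    cv_threshold: float = 0.35,
) -> tuple[float, str, bool]:
    """LOQ from standard wells: back-calculate copies, fit the CV curve.

    Returns ``(loq_copies, model, censored)``.
    """
    cvs = summarize_cv(standards, curve)
    if cvs.empty:
        raise SensitivityError(
            "CV undefined at every concentration (need >= 2 detected replicates)"
        )
    est = LoqEstimator(cv_threshold=cv_threshold)
    est.fit(cvs["copies"].to_numpy(float), cvs["cv"].to_numpy(float))
    return est.loq_, est.model_, est.censored_


def assess_sensitivity(
    standards: pd.DataFrame,
    curve: StandardCurve,
    probability: float = 0.95,
    cv_threshold: float = 0.35,
) -> SensitivityResult:
    """Full LOD/LOQ assessment of one assay's dilution series.

    Enforces LOD <= LOQ in the report (quantification is never more
    sensitive than detection); when the raw fits disagree the LOQ is raised
    to the LOD with a diagnostic note.
    """
    det = summarize_detections(standards)
    lod_est = LodEstimator(probability=probability)
    lod_est.fit(
        det["copies"].to_numpy(float),
        det["n_detected"].to_numpy(int),
        n_replicates=det["n_replicates"].to_numpy(int),
    )
    cvs = summarize_cv(standards, curve)
    if cvs.empty:
        raise SensitivityError(
            "CV undefined at every concentration (need >= 2 detected replicates)"
        )
    loq_est = LoqEstimator(cv_threshold=cv_threshold)
    loq_est.fit(cvs["copies"].to_numpy(float), cvs["cv"].to_numpy(float))

    notes = list(getattr(lod_est, "warnings_", [])) + list(loq_est.warnings_)
    loq = loq_est.loq_
    if loq < lod_est.lod_:
        notes.append(
            f"fitted LOQ {loq:.3g} below LOD {lod_est.lod_:.3g}; reported LOQ "
            "raised to the LOD"
        )
        loq = lod_est.lod_
    diagnostics = {
        "lod_aic": dict(getattr(lod_est, "aic_", {})),
        "loq_aic": dict(loq_est.aic_),
        "detection_summary": det.to_dict(orient="records"),
        "cv_summary": cvs.to_dict(orient="records"),
    }
    return SensitivityResult(
        lod_copies=float(lod_est.lod_),
        loq_copies=float(loq),
        lod_model=lod_est.model_,
        loq_model=loq_est.model_,
        lod_censored=bool(lod_est.censored_),
        loq_censored=bool(loq_est.censored_),
        fit_diagnostics=diagnostics,
        notes=tuple(notes),
    )


def poisson_theoretical_lod(probability: float = 0.95) -> float:
    """Smallest mean copy number giving the target detection probability
    under pure Poisson sampling with perfect per-molecule detection:
    ``-ln(1 - probability)`` (~ 3 copies at 95%)."""
    if not 0 < probability < 1:
        raise SensitivityError("probability must be in (0, 1)")
    return float(-np.log(1.0 - probability))


def mean_lod(lods: Sequence[float], ndigits: int | None = None) -> float:
    """Reporting helper: mean of per-assay LODs, optionally rounded for
    display."""
    mean = float(np.mean(np.asarray(lods, dtype=float)))
    return mean if ndigits is None else round(mean, ndigits)
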