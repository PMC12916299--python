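"""Moderated regression of early weight gain on enrichment scores.

The outcome model regresses the 30-day change in BMI-SDS on age, baseline
BMI-SDS, one feature's per-subject enrichment score (speCT), and the
baseline x speCT interaction, with heteroskedasticity-consistent (HC3)
standard errors. The interaction is probed with the Johnson-Neyman
technique: the conditional slope of speCT, theta(w) = b3 + b4*w, is tested
across the baseline BMI-SDS axis w, and the significance boundaries are the
real roots of theta(w)^2 = t_crit^2 * Var(theta(w)).

Four control models swap in or add global mean CT to check that any effect
is tied to the spatial pattern rather than overall thinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MODEL_TERMS = {
    "main": ["age", "bmi_sds_baseline", "spect", "bmi_sds_baseline:spect"],
    "alt1": ["age", "bmi_sds_baseline", "global_ct", "bmi_sds_baseline:global_ct"],
    "alt2": ["age", "bmi_sds_baseline", "spect", "bmi_sds_baseline:spect",
             "global_ct"],
    "alt3": ["age", "bmi_sds_baseline", "spect", "bmi_sds_baseline:spect",
             "global_ct", "global_ct:spect"],
    "alt4": ["age", "bmi_sds_baseline", "spect", "bmi_sds_baseline:spect",
             "global_ct", "global_ct:spect", "global_ct:bmi_sds_baseline"],
}


def hc3_covariance(X: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    """HC3 sandwich: (X'X)^-1 X' diag(e_i^2/(1-h_ii)^2) X (X'X)^-1."""
    X = np.asarray(X, float)
    e = np.asarray(residuals, float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular design matrix: columns are collinear")
    xtx_inv = np.linalg.inv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("leverage h_ii = 1: HC3 undefined")
    w = (e / (1.0 - h)) ** 2
    meat = X.T @ (w[:, None] * X)
    return xtx_inv @ meat @ xtx_inv


class ModeratedOutcomeModel:
    """OLS with HC3 robust covariance, scikit-learn estimator style.

    ``fit(X, y)`` takes a DataFrame of named predictor columns (an intercept
    is added) and a response vector. Fitted attributes: ``params_`` (Series),
    ``cov_`` (DataFrame, HC3), ``bse_``, ``tvalues_``, ``pvalues_``, ``n_``,
    ``df_resid_``, ``residuals_``.
    """

    def __init__(self, add_intercept: bool = True):
        self.add_intercept = add_intercept

    def get_params(self, deep: bool = True) -> dict:
        return {"add_intercept": self.add_intercept}

    def set_params(self, **params) -> "ModeratedOutcomeModel":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y) -> "ModeratedOutcomeModel":
        X = pd.DataFrame(X)
        y = np.asarray(y, float)
        if self.add_intercept:
            X = X.copy()
            X.insert(0, "const", 1.0)
        names = list(X.columns)
        D = X.to_numpy(float)
        n, p = D.shape
        if n < p + 2:
            raise ValueError(f"need at least {p + 2} observations, got {n}")
        if np.linalg.matrix_rank(D) < p:
            raise ValueError(
                f"singular design matrix among columns {names}: "
                "some columns are collinear"
            )
        beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ beta
        cov = hc3_covariance(D, resid)
        se = np.sqrt(np.diag(cov))
        df = n - p
        t = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
        self.feature_names_in_ = names
        self.params_ = pd.Series(beta, index=names)
        self.cov_ = pd.DataFrame(cov, index=names, columns=names)
        self.bse_ = pd.Series(se, index=names)
        self.tvalues_ = pd.Series(t, index=names)
        self.pvalues_ = pd.Series(np.maximum(pvals, np.finfo(float).tiny),
                                  index=names)
        self.n_ = n
        self.df_resid_ = df
        self.residuals_ = resid
        self._X = D
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        if self.add_intercept:
            X = X.copy()
            X.insert(0, "const", 1.0)
        return X.to_numpy(float) @ self.params_.to_numpy()


@dataclass
class OutcomeFit:
    """Fitted outcome model with HC3 inference and provenance."""

    model: str
    feature: str
    estimator: ModeratedOutcomeModel
    moderator_range: tuple[float, float]

    @property
    def params(self) -> pd.Series:
        return self.estimator.params_

    @property
    def cov(self) -> pd.DataFrame:
        return self.estimator.cov_

    @property
    def pvalues(self) -> pd.Series:
        return self.estimator.pvalues_

    @property
    def n(self) -> int:
        return self.estimator.n_

    @property
    def df_resid(self) -> int:
        return self.estimator.df_resid_

    def to_frame(self) -> pd.DataFrame:
        est = self.estimator
        return pd.DataFrame({
            "model": self.model, "feature": self.feature,
            "term": est.params_.index,
            "estimate": est.params_.to_numpy(),
            "robust_se": est.bse_.to_numpy(),
            "t": est.tvalues_.to_numpy(),
            "p": est.pvalues_.to_numpy(),
            "n": est.n_,
        })


def _outcome_frame(clinical: pd.DataFrame, scores: pd.DataFrame, feature: str,
                   global_ct: pd.Series | np.ndarray | None) -> pd.DataFrame:
    clin = clinical.set_index("subject_id") if "subject_id" in clinical else clinical
    df = pd.DataFrame({
        "age": clin["age"],
        "bmi_sds_baseline": clin["bmi_sds_baseline"],
        "delta_bmi_sds": clin["bmi_sds_30d"] - clin["bmi_sds_baseline"],
        "group": clin["group"],
    })
    df["spect"] = scores[feature].reindex(df.index)
    if global_ct is not None:
        gct = pd.Series(np.asarray(global_ct, float), index=clin.index)
        df["global_ct"] = gct
    df = df[df["group"] == "AN"].drop(columns="group")
    return df.dropna()


def fit_outcome_model(
    clinical: pd.DataFrame,
    scores: pd.DataFrame,
    feature: str,
    model: str = "main",
    global_ct=None,
) -> OutcomeFit:
    """Fit the weight-gain model (or one of the four control variants).

    Uses AN subjects with non-missing 30-day follow-up (listwise deletion).
    ``scores`` is a subjects x features frame indexed by subject_id;
    ``global_ct`` (per-subject mean CT, aligned with ``clinical`` rows) is
    required for the control models.
    """
    if model not in MODEL_TERMS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODEL_TERMS)}")
    terms = MODEL_TERMS[model]
    if any("global_ct" in t for t in terms) and global_ct is None:
        raise ValueError(f"model {model!r} requires global_ct")
    data = _outcome_frame(clinical, scores, feature, global_ct)
    X = pd.DataFrame(index=data.index)
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            X[term] = data[a] * data[b]
        else:
            X[term] = data[term]
    est = ModeratedOutcomeModel().fit(X, data["delta_bmi_sds"])
    w = data["bmi_sds_baseline"]
    return OutcomeFit(model=model, feature=feature, estimator=est,
                      moderator_range=(float(w.min()), float(w.max())))


# ---------------------------------------------------------------------------
# Johnson-Neyman


@dataclass
class JNRegion:
    lower: float
    upper: float
    slope_sign: int
    extrapolated: bool


@dataclass
class JNInterval:
    """Significance regions of the conditional focal slope along the moderator."""

    moderator: str
    focal: str
    alpha: float
    t_crit: float
    regions: list[JNRegion] = field(default_factory=list)
    moderator_range: tuple[float, float] = (np.nan, np.nan)

    @property
    def boundaries(self) -> list[float]:
        out = []
        for r in self.regions:
            for b in (r.lower, r.upper):
                if np.isfinite(b):
                    out.append(b)
        return sorted(set(out))


def _slope_t(w, b3, b4, v33, v34, v44):
    theta = b3 + b4 * w
    var = v33 + 2.0 * w * v34 + w * w * v44
    return theta / np.sqrt(var)


def johnson_neyman(
    fit: OutcomeFit,
    moderator: str = "bmi_sds_baseline",
    focal: str = "spect",
    alpha: float = 0.05,
) -> JNInterval:
    """Closed-form Johnson-Neyman regions from the HC3 covariance.

    Solves theta(w)^2 = t_crit^2 Var(theta(w)) for w (a quadratic), then
    classifies each segment of the real line by testing an interior point.
    t_crit comes from the t distribution with df = n - p. Regions outside the
    observed moderator range are flagged as extrapolated.
    """
    inter = f"{moderator}:{focal}"
    if inter not in fit.params.index:
        inter_alt = f"{focal}:{moderator}"
        if inter_alt in fit.params.index:
            inter = inter_alt
        else:
            raise ValueError(f"fit has no {moderator} x {focal} interaction term")
    b3 = float(fit.params[focal])
    b4 = float(fit.params[inter])
    v33 = float(fit.cov.loc[focal, focal])
    v34 = float(fit.cov.loc[focal, inter])
    v44 = float(fit.cov.loc[inter, inter])
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, fit.df_resid))
    out = JNInterval(moderator=moderator, focal=focal, alpha=alpha,
                     t_crit=t_crit, moderator_range=fit.moderator_range)

    scale = max(abs(b3), abs(b4), np.sqrt(v33), np.sqrt(v44), 1e-300)
    a = b4 * b4 - t_crit ** 2 * v44
    b = 2.0 * (b3 * b4 - t_crit ** 2 * v34)
    c = b3 * b3 - t_crit ** 2 * v33
    eps = 1e-14 * scale ** 2

    # degenerate: no interaction and no interaction uncertainty -> the slope
    # is constant; significant everywhere or nowhere
    if abs(b4) < 1e-14 * scale and v44 < (1e-14 * scale) ** 2:
        if c > 0:
            out.regions = [_region(-np.inf, np.inf, b3, b4, fit.moderator_range)]
        return out

    if abs(a) < eps:
        if abs(b) < eps:
            if c > 0:
                out.regions = [_region(-np.inf, np.inf, b3, b4,
                                       fit.moderator_range)]
            return out
        root = -c / b
        lo, hi = ((-np.inf, root) if b < 0 else (root, np.inf))
        out.regions = [_region(lo, hi, b3, b4, fit.moderator_range)]
        return out

    disc = b * b - 4.0 * a * c
    if disc < 0:
        if a > 0:  # positive everywhere
            out.regions = [_region(-np.inf, np.inf, b3, b4, fit.moderator_range)]
        return out
    r1 = (-b - np.sqrt(disc)) / (2.0 * a)
    r2 = (-b + np.sqrt(disc)) / (2.0 * a)
    r1, r2 = min(r1, r2), max(r1, r2)
    if a > 0:
        out.regions = [_region(-np.inf, r1, b3, b4, fit.moderator_range),
                       _region(r2, np.inf, b3, b4, fit.moderator_range)]
    else:
        out.regions = [_region(r1, r2, b3, b4, fit.moderator_range)]
    return out


def _region(lo, hi, b3, b4, obs_range) -> JNRegion:
    if np.isfinite(lo) and np.isfinite(hi):
        w_rep = 0.5 * (lo + hi)
    elif np.isfinite(hi):
        w_rep = hi - 1.0
    elif np.isfinite(lo):
        w_rep = lo + 1.0
    else:
        w_rep = 0.0
    sign = int(np.sign(b3 + b4 * w_rep))
    extrapolated = hi < obs_range[0] or lo > obs_range[1]
    return JNRegion(lower=float(lo), upper=float(hi), slope_sign=sign,
                    extrapolated=bool(extrapolated))


def jn_table(jn: JNInterval) -> pd.DataFrame:
    return pd.DataFrame({
        "moderator": jn.moderator, "focal": jn.focal, "alpha": jn.alpha,
        "t_crit": jn.t_crit,
        "lower": [r.lower for r in jn.regions],
        "upper": [r.upper for r in jn.regions],
        "slope_sign": [r.slope_sign for r in jn.regions],
        "extrapolated": [r.extrapolated for r in jn.regions],
    })


# ---------------------------------------------------------------------------
# subsample control analyses

SUBSAMPLE_FILTERS = {
    "restrictive-only": lambda c: ~c["subtype_binge_purge"].astype(bool),
    "no-comorbidity": lambda c: ~c["comorbidity"].astype(bool),
    "no-antidepressant": lambda c: ~c["antidepressant"].astype(bool),
}


def subsample_refit(
    clinical: pd.DataFrame,
    scores: pd.DataFrame,
    feature: str,
    filters: dict | None = None,
) -> dict[str, OutcomeFit]:
    """Refit the main model on confound-excluding patient subsets."""
    if filters is None:
        filters = SUBSAMPLE_FILTERS
    fits = {}
    for name, pred in filters.items():
        sub = clinical[pred(clinical)]
        if len(sub) == 0 or (sub["group"] == "AN").sum() == 0:
            raise ValueError(f"subsample {name!r} is empty")
        try:
            fits[name] = fit_outcome_model(sub, scores, feature, model="main")
        except ValueError as err:
            raise ValueError(f"subsample {name!r}: {err}") from err
    return fits
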