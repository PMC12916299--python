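"""Covariate-adjusted rank correlations, FDR, and Welch group comparisons.

The symptom analysis correlates per-subject enrichment scores with clinical
scales within patients, partialling out age and (optionally) baseline
BMI-SDS. The adjusted Spearman coefficient is operationalized as partial
Pearson on average ranks: rank everything, residualize the x- and y-ranks on
the covariate ranks by OLS, and correlate the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PartialCorrelationResult:
    rho: float
    p: float
    n_effective: int
    covariates: tuple[str, ...] = ()


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def partial_spearman(
    x, y, covariates=(), covariate_names: tuple[str, ...] | None = None
) -> PartialCorrelationResult:
    """Spearman correlation of x and y adjusted for covariates.

    Complete cases only (listwise deletion). All variables get average ranks;
    x- and y-ranks are residualized on the covariate ranks (with intercept);
    rho is the Pearson correlation of the residuals and p comes from the t
    approximation with df = n - 2 - n_covariates.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    covs = [np.asarray(c, float) for c in covariates]
    ok = np.isfinite(x) & np.isfinite(y)
    for c in covs:
        ok &= np.isfinite(c)
    x, y = x[ok], y[ok]
    covs = [c[ok] for c in covs]
    n, k = len(x), len(covs)
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete cases, got {n}")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("correlation undefined: constant variable after ranking")
    Z = np.column_stack([np.ones(n)] + [stats.rankdata(c) for c in covs])
    ex = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    ey = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    denom = np.sqrt((ex @ ex) * (ey @ ey))
    if denom == 0:
        raise ValueError("correlation undefined: variable explained by covariates")
    rho = float(np.clip(ex @ ey / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho ** 2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    if covariate_names is None:
        covariate_names = tuple(f"c{i}" for i in range(k))
    return PartialCorrelationResult(rho=rho, p=max(p, np.finfo(float).tiny),
                                    n_effective=n, covariates=covariate_names)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def welch_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> WelchResult:
    """Welch two-sample t test from group summaries (t for group2 - group1).

    Degrees of freedom by Welch-Satterthwaite; two-sided p.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    if v1 + v2 == 0:
        raise ValueError("both group variances are zero: t undefined")
    t = (mean2 - mean1) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=p)


DEFAULT_SYMPTOMS = ["bdi_total", "edi_total", "edi_dt", "edi_bd", "edi_b"]


def correlate_enrichment_with_symptoms(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    symptoms: list[str] | None = None,
    covariates: tuple[str, ...] = ("age", "bmi_sds_baseline"),
    family: str = "per-symptom-across-features",
) -> pd.DataFrame:
    """Partial-Spearman grid of enrichment scores vs symptom scales.

    Computed within patients only. ``scores`` is a subjects x features frame
    indexed by subject_id (see :meth:`SubjectEnrichment.to_frame`). BH-FDR is
    applied within the configured family: across features for each symptom
    (default) or across symptoms for each feature.

    Returns a tidy frame with columns feature, symptom, rho, p, q, n,
    covariates, family.
    """
    if symptoms is None:
        symptoms = [s for s in DEFAULT_SYMPTOMS if s in clinical.columns]
    if family not in ("per-symptom-across-features", "per-feature-across-symptoms"):
        raise ValueError(f"unknown FDR family {family!r}")
    patients = clinical[clinical["group"] == "AN"].set_index("subject_id")
    if len(patients) == 0:
        raise ValueError("no patients (group == 'AN') in the clinical table")
    sc = scores.loc[scores.index.intersection(patients.index)]
    patients = patients.loc[sc.index]

    rows = []
    for feature in sc.columns:
        for symptom in symptoms:
            res = partial_spearman(
                sc[feature], patients[symptom],
                [patients[c] for c in covariates],
                covariate_names=tuple(covariates),
            )
            rows.append({"feature": feature, "symptom": symptom,
                         "rho": res.rho, "p": res.p, "n": res.n_effective})
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    if family == "per-symptom-across-features":
        for symptom, grp in table.groupby("symptom"):
            table.loc[grp.index, "q"] = bh_fdr(grp["p"].to_numpy())
    else:
        for feature, grp in table.groupby("feature"):
            table.loc[grp.index, "q"] = bh_fdr(grp["p"].to_numpy())
    table["covariates"] = "+".join(covariates) if covariates else "none"
    table["family"] = family
    return table
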