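"""Vertex-wise group GLM: CT = b0 + b1*age + b2*group + e.

Fit by ordinary least squares independently at each valid vertex, with the
design shared across vertices so the whole surface is solved in one pass.
Group is coded HC=0 / AN=1, so a negative group contrast means thinner cortex
in patients.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import CohortData
from .surfaces import VertexMap

GROUP_CODING = {"HC": 0.0, "AN": 1.0}


class VertexwiseGLM:
    """Per-vertex OLS of a subjects x vertices outcome on [1, age, group].

    scikit-learn-style estimator: ``fit(X, Y)`` with ``X`` a DataFrame holding
    ``age`` (years) and ``group`` ("AN"/"HC" or 0/1) columns and ``Y`` the
    subjects x vertices CT matrix (cm). Vertices outside ``valid_mask`` are
    skipped and carry NaN in all fitted maps.

    Attributes (after fit)
    ----------------------
    intercept_map_, age_slope_map_, group_contrast_map_ : (n_vertices,) arrays
        b0 (cm), b1 (cm/year) and the adjusted AN-minus-HC contrast b2 (cm).
    residuals_ : (n_subjects, n_vertices) array
        The per-subject deviation maps (term e).
    se_group_map_, t_group_map_ : (n_vertices,) arrays
    df_ : int
        n_subjects - 3.
    """

    def __init__(self, valid_mask: np.ndarray | None = None):
        self.valid_mask = valid_mask

    def get_params(self, deep: bool = True) -> dict:
        return {"valid_mask": self.valid_mask}

    def set_params(self, **params) -> "VertexwiseGLM":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    @staticmethod
    def _design(X: pd.DataFrame) -> np.ndarray:
        age = np.asarray(X["age"], dtype=float)
        group = X["group"]
        if group.dtype == object:
            group = group.map(GROUP_CODING)
            if group.isna().any():
                raise ValueError("group labels must be 'AN' or 'HC'")
        g = np.asarray(group, dtype=float)
        return np.column_stack([np.ones_like(age), age, g])

    def fit(self, X: pd.DataFrame, Y: np.ndarray) -> "VertexwiseGLM":
        Y = np.asarray(Y, dtype=float)
        D = self._design(X)
        n = len(D)
        if n < 3:
            raise ValueError("need at least 3 subjects")
        if len({*D[:, 2]}) < 2:
            raise ValueError("both groups must be present")
        if np.linalg.matrix_rank(D) < 3:
            raise ValueError(
                "rank-deficient design: age and group columns are collinear "
                "with the intercept (e.g. constant age or a single group)"
            )
        mask = (np.ones(Y.shape[1], bool) if self.valid_mask is None
                else np.asarray(self.valid_mask, bool))
        if np.isnan(Y[:, mask]).any():
            raise ValueError("NaN CT at a valid vertex")

        Yv = Y[:, mask]
        beta, _, _, _ = np.linalg.lstsq(D, Yv, rcond=None)
        resid_v = Yv - D @ beta
        df = n - 3
        sigma2 = (resid_v ** 2).sum(axis=0) / df
        xtx_inv = np.linalg.inv(D.T @ D)
        se2 = xtx_inv[2, 2] * sigma2

        V = Y.shape[1]
        full = lambda: np.full(V, np.nan)
        self.valid_mask_ = mask
        self.design_ = D
        self.ages_ = D[:, 1]
        self.df_ = df
        self.intercept_map_ = full(); self.intercept_map_[mask] = beta[0]
        self.age_slope_map_ = full(); self.age_slope_map_[mask] = beta[1]
        self.group_contrast_map_ = full(); self.group_contrast_map_[mask] = beta[2]
        self.se_group_map_ = full(); self.se_group_map_[mask] = np.sqrt(se2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[2] / np.sqrt(se2)
        self.t_group_map_ = full(); self.t_group_map_[mask] = t
        self.residuals_ = np.full(Y.shape, np.nan)
        self.residuals_[:, mask] = resid_v
        self._Y = Y
        return self

    def _check_fitted(self):
        if not hasattr(self, "residuals_"):
            raise RuntimeError("estimator is not fitted")

    def subject_residual_maps(self, mode: str = "full-model") -> np.ndarray:
        """Per-subject deviation maps.

        ``full-model`` returns the residual e of the three-term model;
        ``age-only`` refits without the group column and returns
        CT - (b0 + b1*age), i.e. deviation from age-predicted CT.
        """
        self._check_fitted()
        if mode == "full-model":
            return self.residuals_.copy()
        if mode == "age-only":
            D = self.design_[:, :2]
            mask = self.valid_mask_
            Yv = self._Y[:, mask]
            beta, _, _, _ = np.linalg.lstsq(D, Yv, rcond=None)
            out = np.full(self._Y.shape, np.nan)
            out[:, mask] = Yv - D @ beta
            return out
        raise ValueError(f"unknown residual mode {mode!r}")


def fit_vertexwise_glm(cohort: CohortData) -> VertexwiseGLM:
    """Fit the group GLM on a cohort (thin wrapper over :class:`VertexwiseGLM`)."""
    est = VertexwiseGLM(valid_mask=cohort.valid_mask)
    return est.fit(cohort.clinical[["age", "group"]], cohort.ct)


def group_contrast_map(fit: VertexwiseGLM, cohort: CohortData) -> VertexMap:
    """The adjusted AN-minus-HC contrast as a VertexMap on the cohort mesh."""
    fit._check_fitted()
    return VertexMap(np.nan_to_num(fit.group_contrast_map_, nan=0.0),
                     fit.valid_mask_, cohort.mesh)


def subject_residual_maps(fit: VertexwiseGLM, mode: str = "full-model") -> np.ndarray:
    return fit.subject_residual_maps(mode)


def global_mean_ct(cohort: CohortData) -> np.ndarray:
    """Mean CT over valid vertices, one scalar (cm) per subject."""
    return cohort.ct[:, cohort.valid_mask].mean(axis=1)
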