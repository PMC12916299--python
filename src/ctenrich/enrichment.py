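"""Spatial correlation, spin-rotation permutation nulls, and enrichment scores.

The spin test asks whether the spatial (Pearson) correlation between an
empirical surface map and a reference feature map exceeds what maps with the
same spatial autocorrelation would show by chance. The null is built by
rigidly rotating the reference map on the sphere: the empirical map stays
fixed, the feature map is rotated and resampled to the nearest original
vertex, and the correlation is recomputed per rotation.

Per-subject enrichment scores (speCT) are the same spatial correlation
computed between one subject's CT deviation map and each feature map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation as _ScipyRotation

from .clinical import bh_fdr
from .simulate import FeatureAtlas
from .surfaces import SphereMesh, VertexMap


def spatial_correlation(map_a: VertexMap, map_b: VertexMap) -> float:
    """Pearson correlation over jointly valid vertices.

    Raises if the maps live on different meshes, the joint mask has fewer
    than 3 vertices, or either map is constant on it.
    """
    if map_a.mesh is not map_b.mesh:
        raise ValueError("maps must share a mesh")
    joint = map_a.valid_mask & map_b.valid_mask
    return _pearson(map_a.values[joint], map_b.values[joint])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3:
        raise ValueError("need at least 3 jointly valid vertices")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0 or ny == 0:
        raise ValueError("correlation undefined: map constant on the joint mask")
    return float(np.clip((xc @ yc) / (nx * ny), -1.0, 1.0))


# ---------------------------------------------------------------------------
# rotations


def sample_rotation(seed) -> np.ndarray:
    """One uniform random 3x3 rotation matrix (quaternion method).

    ``seed`` may be an int or a numpy Generator.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return _ScipyRotation.random(random_state=rng).as_matrix()


def sample_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 3, 3) stack of independent uniform rotations."""
    return _ScipyRotation.random(n, random_state=rng).as_matrix()


def rotation_indices(mesh: SphereMesh, rotations: np.ndarray) -> np.ndarray:
    """Nearest-original-vertex source index per target vertex per rotation.

    The rotated map value at target vertex v is the original value at the
    vertex nearest to R^T v, so one index array encodes one rotation for every
    map on the mesh.
    """
    R = np.asarray(rotations)
    single = R.ndim == 2
    if single:
        R = R[None]
    pts = np.einsum("vj,rjk->rvk", mesh.vertices, R)  # rows are R^T v
    _, idx = mesh.kdtree.query(pts.reshape(-1, 3))
    idx = idx.reshape(len(R), mesh.n_vertices)
    return idx[0] if single else idx


def apply_rotation(mesh: SphereMesh, vmap: VertexMap, rotation: np.ndarray) -> VertexMap:
    """Resample a map under a rotation; invalidity propagates from the source
    vertex."""
    idx = rotation_indices(mesh, rotation)
    return VertexMap(vmap.values[idx], vmap.valid_mask[idx], mesh)


# ---------------------------------------------------------------------------
# spin test


@dataclass
class EnrichmentTest:
    """Observed spatial r for one feature plus its spin-null distribution."""

    feature: str
    r_observed: float
    null_r: np.ndarray
    p_spin: float
    n_perm: int
    seed: int
    q_fdr: float | None = None

    def __post_init__(self):
        assert abs(self.r_observed) <= 1.0
        assert 0.0 < self.p_spin <= 1.0


def _null_correlations(
    empirical: VertexMap, feature: VertexMap, idx: np.ndarray
) -> np.ndarray:
    """Null r for each rotation index row, with per-rotation pairwise deletion
    of vertices whose rotated source is invalid."""
    emp_mask = empirical.valid_mask
    fvals = feature.values
    fmask = feature.valid_mask
    if emp_mask.all() and fmask.all():
        e = empirical.values - empirical.values.mean()
        en = np.sqrt(e @ e)
        Fi = fvals[idx]
        Fi = Fi - Fi.mean(axis=1, keepdims=True)
        fn = np.sqrt((Fi ** 2).sum(axis=1))
        return np.clip(Fi @ e / (fn * en), -1.0, 1.0)
    out = np.empty(len(idx))
    for p, row in enumerate(idx):
        joint = emp_mask & fmask[row]
        out[p] = _pearson(empirical.values[joint], fvals[row][joint])
    return out


def spin_test(
    empirical_map: VertexMap,
    feature_map: VertexMap,
    n_perm: int = 5000,
    seed: int = 0,
) -> EnrichmentTest:
    """Two-sided spin-rotation permutation test for spatial correlation.

    p = (1 + #{|null r| >= |observed r|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    r_obs = spatial_correlation(empirical_map, feature_map)
    rng = np.random.default_rng(seed)
    idx = rotation_indices(empirical_map.mesh, sample_rotations(n_perm, rng))
    null_r = _null_correlations(empirical_map, feature_map, idx)
    p = (1.0 + np.sum(np.abs(null_r) >= abs(r_obs))) / (n_perm + 1.0)
    return EnrichmentTest(feature="", r_observed=r_obs, null_r=null_r,
                          p_spin=float(p), n_perm=n_perm, seed=seed)


def enrich_group_contrast(
    contrast: VertexMap,
    atlas: FeatureAtlas,
    n_perm: int = 5000,
    seed: int = 0,
) -> list[EnrichmentTest]:
    """Spin test of the group contrast against every atlas feature.

    One shared set of rotations is used for all features; Benjamini-Hochberg
    across the whole atlas fills ``q_fdr``. A feature whose correlation is
    undefined (constant on the joint mask) is reported with NaN statistics
    and a warning instead of aborting the others.
    """
    if atlas.n_features == 0:
        raise ValueError("atlas is empty")
    rng = np.random.default_rng(seed)
    idx = rotation_indices(contrast.mesh, sample_rotations(n_perm, rng))
    results: list[EnrichmentTest | None] = []
    pvals = []
    for name, fmap in zip(atlas.names, atlas.maps):
        try:
            r_obs = spatial_correlation(contrast, fmap)
            null_r = _null_correlations(contrast, fmap, idx)
        except ValueError as err:
            warnings.warn(f"feature {name!r} skipped: {err}")
            results.append(None)
            pvals.append(np.nan)
            continue
        p = (1.0 + np.sum(np.abs(null_r) >= abs(r_obs))) / (n_perm + 1.0)
        results.append(EnrichmentTest(feature=name, r_observed=r_obs,
                                      null_r=null_r, p_spin=float(p),
                                      n_perm=n_perm, seed=seed))
        pvals.append(float(p))
    ok = ~np.isnan(pvals)
    q = np.full(len(pvals), np.nan)
    if ok.any():
        q[ok] = bh_fdr(np.asarray(pvals)[ok])
    out = []
    for res, qi in zip(results, q):
        if res is not None:
            res.q_fdr = float(qi)
            out.append(res)
    return out


def enrichment_table(tests: list[EnrichmentTest]) -> pd.DataFrame:
    """Tidy per-feature summary (feature, r, p_spin, q_fdr, n_perm, seed)."""
    return pd.DataFrame({
        "feature": [t.feature for t in tests],
        "r": [t.r_observed for t in tests],
        "p_spin": [t.p_spin for t in tests],
        "q_fdr": [t.q_fdr for t in tests],
        "n_perm": [t.n_perm for t in tests],
        "seed": [t.seed for t in tests],
    })


# ---------------------------------------------------------------------------
# per-subject scores


@dataclass
class SubjectEnrichment:
    """speCT scores: subjects x features matrix of spatial correlations."""

    scores: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=self.feature_names,
                            index=pd.Index(self.subject_ids, name="subject_id"))


def subject_enrichment_scores(
    residuals: np.ndarray,
    atlas: FeatureAtlas,
    subject_ids: list[str] | None = None,
) -> SubjectEnrichment:
    """Correlate each subject's deviation map with each feature map.

    A subject whose deviation map is constant over the valid mask gets NaN
    scores and a warning (never a silent NaN from a zero variance).
    """
    mask = atlas.valid_mask
    R = np.asarray(residuals, float)[:, mask]
    F = atlas.matrix()[:, mask]
    Rc = R - R.mean(axis=1, keepdims=True)
    rn = np.sqrt((Rc ** 2).sum(axis=1))
    Fc = F - F.mean(axis=1, keepdims=True)
    fn = np.sqrt((Fc ** 2).sum(axis=1))
    bad = rn == 0
    if bad.any():
        warnings.warn(
            f"{bad.sum()} subject(s) with constant deviation maps: "
            "scores recorded as missing"
        )
    rn_safe = np.where(bad, np.nan, rn)
    scores = np.clip((Rc @ Fc.T) / np.outer(rn_safe, fn), -1.0, 1.0)
    if subject_ids is None:
        subject_ids = [f"S{i:04d}" for i in range(len(R))]
    return SubjectEnrichment(scores=scores, feature_names=list(atlas.names),
                             subject_ids=list(subject_ids))
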