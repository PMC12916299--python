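"""Synthetic surface cohorts with known ground truth.

Emulates the statistical structure the enrichment analysis assumes: a set of
smooth chemoarchitecture-like feature maps on a sphere, a case-control
cortical-thickness (CT) cohort whose group deficit is partially aligned with
chosen features, per-subject residual structure with known feature loadings,
and a clinical table (symptoms, baseline and 30-day BMI-SDS) generated from
those loadings with configurable effect sizes.

Everything is deterministic given the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .surfaces import SphereMesh, VertexMap, build_icosphere, smooth_map

#: the sixteen PET-derived reference features the group analysis screens
FEATURE_NAMES_16 = [
    "SERT", "HT1a", "AChN", "Glc",
    "AChM1", "DAT", "D1", "D2",
    "HT1b", "HT2a", "NET", "H3",
    "MOR", "CB1", "GABA", "Glut",
]


@dataclass
class FeatureAtlas:
    """Collection of z-scored smooth feature maps sharing one mesh and mask."""

    names: list[str]
    maps: list[VertexMap]
    smooth_iterations: int
    smooth_weight: float

    def __post_init__(self):
        if len(self.names) != len(self.maps):
            raise ValueError("names and maps length mismatch")
        mesh = self.maps[0].mesh
        mask = self.maps[0].valid_mask
        for m in self.maps:
            if m.mesh is not mesh:
                raise ValueError("all atlas maps must share one mesh")
            if not np.array_equal(m.valid_mask, mask):
                raise ValueError("all atlas maps must share one valid mask")
            if np.ptp(m.valid_values) == 0:
                raise ValueError("atlas map constant over valid vertices")

    @property
    def mesh(self) -> SphereMesh:
        return self.maps[0].mesh

    @property
    def valid_mask(self) -> np.ndarray:
        return self.maps[0].valid_mask

    @property
    def n_features(self) -> int:
        return len(self.names)

    def matrix(self) -> np.ndarray:
        """(n_features, n_vertices) value matrix (invalid vertices included)."""
        return np.vstack([m.values for m in self.maps])

    def __getitem__(self, name: str) -> VertexMap:
        return self.maps[self.names.index(name)]


def _smooth_unit_noise(mesh, mask, rng, iterations, weight):
    """Smoothed white noise, z-scored to mean 0 / SD 1 over valid vertices."""
    raw = VertexMap(rng.standard_normal(mesh.n_vertices), mask, mesh)
    sm = smooth_map(mesh, raw, iterations, weight)
    v = sm.values.copy()
    mu, sd = v[mask].mean(), v[mask].std()
    v = (v - mu) / sd
    return VertexMap(v, mask, mesh)


def generate_feature_atlas(
    mesh: SphereMesh,
    n_features: int = 16,
    smooth_iterations: int = 4,
    smooth_weight: float = 0.9,
    seed: int = 0,
    valid_mask: np.ndarray | None = None,
    names: list[str] | None = None,
    orthogonalize: bool = True,
) -> FeatureAtlas:
    """Smoothed standard-normal noise maps, z-scored over valid vertices.

    With ``orthogonalize`` (default) the maps are additionally decorrelated
    over the valid mask (Gram-Schmidt, then re-z-scored), so "aligned with
    feature k" is an identifiable ground-truth statement: smooth maps on a
    coarse sphere otherwise share sizeable chance correlations, which makes a
    deficit injected along one feature genuinely (not spuriously) aligned
    with others. Orthogonalized maps remain linear combinations of smooth
    maps, hence smooth.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if valid_mask is None:
        valid_mask = np.ones(mesh.n_vertices, bool)
    if orthogonalize and n_features > valid_mask.sum():
        raise ValueError("cannot orthogonalize more features than valid vertices")
    if names is None:
        names = (FEATURE_NAMES_16 + [f"F{i}" for i in range(16, n_features)])[:n_features]
    rng = np.random.default_rng(seed)
    maps = [
        _smooth_unit_noise(mesh, valid_mask, rng, smooth_iterations, smooth_weight)
        for _ in range(n_features)
    ]
    if orthogonalize and n_features > 1:
        V = np.vstack([m.values[valid_mask] for m in maps]).T  # (n_valid, K)
        V = V - V.mean(axis=0)
        Q, _ = np.linalg.qr(V)
        # keep each map's orientation aligned with its raw version
        sign = np.sign(np.einsum("vk,vk->k", Q, V))
        Q *= sign
        Q = (Q - Q.mean(axis=0)) / Q.std(axis=0)
        for m, col in zip(maps, Q.T):
            m.values[valid_mask] = col
    return FeatureAtlas(list(names), maps, smooth_iterations, smooth_weight)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortParams:
    """Generative settings for the CT cohort.

    CT for subject i at vertex v is
    ``b0_v + age_slope * age_i + [i in AN] * delta_v + sum_k a_ik F_kv + eta_iv``
    with ``delta_v = deficit_mean + sum_k gamma_k F_kv + remainder_v``.
    Units are cm throughout; feature maps are unit-SD, so ``gamma`` and
    ``tau`` are cm per feature-SD.
    """

    n_an: int = 114
    n_hc: int = 114
    age_range: tuple[float, float] = (12.0, 29.0)
    ct_baseline: float = 2.5            # mean CT level b0 (cm)
    ct_baseline_spatial_sd: float = 0.15  # smooth spatial variation of b0 (cm)
    age_slope: float = -0.01            # b1 (cm / year), constant over vertices
    deficit_mean: float = -0.10         # uniform component of the AN deficit (cm)
    gamma: dict[str, float] = field(
        default_factory=lambda: {"SERT": 0.05, "HT1a": 0.042,
                                 "AChN": -0.047, "Glc": -0.053}
    )
    delta_remainder_sd: float = 0.03    # smooth non-feature part of the deficit (cm)
    tau: float = 0.02                   # SD of subject loadings a_ik (cm)
    loading_an_shift: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.02              # smooth per-subject residual noise (cm)
    noise_smooth_iterations: int = 4
    subject_intercept_sd: float = 0.05  # global per-subject CT offset (cm)
    # baseline BMI-SDS (Table-1-like moments); AN truncated below 0
    bmi_an_mean: float = -3.20
    bmi_an_sd: float = 1.27
    bmi_hc_mean: float = -0.085
    bmi_hc_sd: float = 0.67
    # subtype / comorbidity / medication rates within AN
    binge_purge_rate: float = 12 / 114
    comorbidity_rate: float = 18 / 114
    antidepressant_rate: float = 4 / 114

    def gamma_vector(self, names: list[str]) -> np.ndarray:
        unknown = set(self.gamma) - set(names)
        if unknown:
            raise ValueError(f"gamma names not in atlas: {sorted(unknown)}")
        return np.array([self.gamma.get(n, 0.0) for n in names])

    def tau_vector(self, names: list[str]) -> np.ndarray:
        if np.isscalar(self.tau):
            return np.full(len(names), float(self.tau))
        tau = np.asarray(self.tau, float)
        if tau.shape != (len(names),):
            raise ValueError("tau length mismatch with atlas")
        return tau


@dataclass
class GroundTruth:
    """True generative quantities recorded alongside a synthetic cohort."""

    delta_map: VertexMap
    gamma: np.ndarray
    loadings: np.ndarray            # subjects x features
    b0_map: np.ndarray
    age_slope_map: np.ndarray
    tau: np.ndarray
    noise_sd: float
    seed: int
    feature_names: list[str]
    symptom_coeffs: dict = field(default_factory=dict)
    outcome_coeffs: dict = field(default_factory=dict)

    def standardized_loadings(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.loadings / np.where(self.tau > 0, self.tau, np.nan)


@dataclass
class CohortData:
    """Subjects x vertices CT matrix plus clinical table and provenance."""

    ct: np.ndarray
    clinical: pd.DataFrame
    mesh: SphereMesh
    atlas: FeatureAtlas
    ground_truth: GroundTruth | None = None

    def __post_init__(self):
        if self.ct.shape[0] != len(self.clinical):
            raise ValueError("ct rows must match clinical rows")
        if self.ct.shape[1] != self.mesh.n_vertices:
            raise ValueError("ct columns must match mesh.n_vertices")
        groups = set(self.clinical["group"])
        if not {"AN", "HC"} <= groups:
            raise ValueError("both groups (AN, HC) must be present")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.atlas.valid_mask

    def patients(self) -> pd.DataFrame:
        return self.clinical[self.clinical["group"] == "AN"]


def _truncated_normal(rng, mean, sd, upper, size):
    b = (upper - mean) / sd
    return stats.truncnorm.rvs(-np.inf, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(
    mesh: SphereMesh,
    atlas: FeatureAtlas,
    params: CohortParams | None = None,
    seed: int = 0,
) -> CohortData:
    """Draw a case-control CT cohort with known ground truth."""
    p = params or CohortParams()
    if p.n_an <= 0 or p.n_hc <= 0:
        raise ValueError("group sizes must be positive")
    rng = np.random.default_rng(seed)
    mask = atlas.valid_mask
    names = atlas.names
    F = atlas.matrix()                         # (K, V)
    K, V = F.shape
    gamma = p.gamma_vector(names)
    tau = p.tau_vector(names)

    n = p.n_an + p.n_hc
    group = np.array(["AN"] * p.n_an + ["HC"] * p.n_hc)
    is_an = (group == "AN").astype(float)
    age = rng.uniform(*p.age_range, size=n)

    b0_spatial = _smooth_unit_noise(mesh, mask, rng, atlas.smooth_iterations,
                                    atlas.smooth_weight).values
    b0_map = p.ct_baseline + p.ct_baseline_spatial_sd * b0_spatial
    age_slope_map = np.full(V, p.age_slope)

    remainder = np.zeros(V)
    if p.delta_remainder_sd > 0:
        remainder = p.delta_remainder_sd * _smooth_unit_noise(
            mesh, mask, rng, atlas.smooth_iterations, atlas.smooth_weight).values
    delta = p.deficit_mean + gamma @ F + remainder

    loadings = rng.standard_normal((n, K)) * tau
    shift = np.array([p.loading_an_shift.get(nm, 0.0) for nm in names])
    loadings += is_an[:, None] * shift

    eta = np.zeros((n, V))
    if p.noise_sd > 0:
        for i in range(n):
            eta[i] = p.noise_sd * _smooth_unit_noise(
                mesh, mask, rng, p.noise_smooth_iterations, 0.9).values

    subject_offset = p.subject_intercept_sd * rng.standard_normal(n)
    ct = (b0_map
          + age[:, None] * age_slope_map
          + is_an[:, None] * delta
          + loadings @ F
          + eta
          + subject_offset[:, None])

    bmi0 = np.empty(n)
    bmi0[: p.n_an] = _truncated_normal(rng, p.bmi_an_mean, p.bmi_an_sd, 0.0, p.n_an)
    bmi0[p.n_an:] = rng.normal(p.bmi_hc_mean, p.bmi_hc_sd, p.n_hc)

    clinical = pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "group": group,
        "age": age,
        "bmi_sds_baseline": bmi0,
        "bmi_sds_30d": np.nan,
        "subtype_binge_purge": np.r_[rng.random(p.n_an) < p.binge_purge_rate,
                                     np.zeros(p.n_hc, bool)],
        "comorbidity": np.r_[rng.random(p.n_an) < p.comorbidity_rate,
                             np.zeros(p.n_hc, bool)],
        "antidepressant": np.r_[rng.random(p.n_an) < p.antidepressant_rate,
                                np.zeros(p.n_hc, bool)],
    })
    gt = GroundTruth(
        delta_map=VertexMap(delta, mask, mesh),
        gamma=gamma, loadings=loadings, b0_map=b0_map,
        age_slope_map=age_slope_map, tau=tau, noise_sd=p.noise_sd,
        seed=seed, feature_names=list(names),
    )
    return CohortData(ct=ct, clinical=clinical, mesh=mesh, atlas=atlas,
                      ground_truth=gt)


# ---------------------------------------------------------------------------
# clinical outcomes


@dataclass
class SymptomSpec:
    """One symptom scale: group means, total SD, and feature links.

    ``links`` maps feature name -> target correlation between the symptom and
    the subject's standardized loading on that feature (within patients).
    """

    mean_an: float
    mean_hc: float
    sd: float
    links: dict[str, float] = field(default_factory=dict)
    age_beta: float = 0.0


@dataclass
class OutcomeSpec:
    """Early weight-gain model: dBMI-SDS = d0 + d1*age + d2*bmi0 + d3*z +
    d4*bmi0*z + noise, where z is the standardized loading on ``feature``."""

    feature: str = "SERT"
    d0: float = 1.85
    d1: float = 0.0
    d2: float = 0.25
    d3: float = -0.45
    d4: float = -0.15
    noise_sd: float = 0.5
    missing_rate: float = 21 / 114


@dataclass
class ClinicalEffectParams:
    symptoms: dict[str, SymptomSpec] = field(default_factory=lambda: {
        # Table-1-like moments; BDI linked to HT1a (-) and Glc (+),
        # body dissatisfaction to SERT (-), mirroring the studied effects
        "bdi_total": SymptomSpec(22.76, 5.51, 11.0,
                                 links={"HT1a": -0.35, "Glc": 0.32}),
        "edi_dt": SymptomSpec(28.99, 13.67, 9.1),
        "edi_bd": SymptomSpec(37.21, 23.27, 10.5, links={"SERT": -0.30}),
        "edi_b": SymptomSpec(11.11, 9.78, 4.9),
        "edi_total": SymptomSpec(210.57, 140.35, 45.0),
    })
    outcome: OutcomeSpec = field(default_factory=OutcomeSpec)


def generate_clinical_outcomes(
    cohort: CohortData,
    effect_params: ClinicalEffectParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Complete the clinical table with symptoms and 30-day follow-up.

    Symptoms are drawn for both groups around their group means; the linked
    part is driven by the subject's standardized feature loadings. Follow-up
    BMI-SDS exists only for AN and is masked missing at the configured rate.
    Returns the completed table (also stored on ``cohort.clinical``) and
    extends the cohort's ground truth with the effect coefficients.
    """
    ep = effect_params or ClinicalEffectParams()
    out = ep.outcome
    if not (0.0 <= out.missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    gt = cohort.ground_truth
    if gt is None:
        raise ValueError("clinical outcome generation requires a synthetic cohort")
    rng = np.random.default_rng(seed)
    clin = cohort.clinical
    n = len(clin)
    is_an = (clin["group"] == "AN").to_numpy()
    age = clin["age"].to_numpy()
    z = gt.standardized_loadings()
    names = gt.feature_names

    sym_coeffs = {}
    for sym, spec in ep.symptoms.items():
        rhos = np.array([spec.links.get(nm, 0.0) for nm in names])
        rss = float(rhos @ rhos)
        if rss >= 1.0:
            raise ValueError(f"symptom {sym}: sum of squared link rhos must be < 1")
        signal = z @ rhos
        eps = rng.standard_normal(n)
        values = (np.where(is_an, spec.mean_an, spec.mean_hc)
                  + spec.sd * (signal + np.sqrt(1.0 - rss) * eps)
                  + spec.age_beta * (age - age.mean()))
        clin[sym] = values
        sym_coeffs[sym] = {"links": dict(spec.links), "sd": spec.sd,
                           "age_beta": spec.age_beta}

    k = names.index(out.feature)
    z_t = z[:, k]
    bmi0 = clin["bmi_sds_baseline"].to_numpy()
    delta_bmi = (out.d0 + out.d1 * age + out.d2 * bmi0
                 + out.d3 * z_t + out.d4 * bmi0 * z_t
                 + out.noise_sd * rng.standard_normal(n))
    bmi30 = np.where(is_an, bmi0 + delta_bmi, np.nan)
    lost = rng.random(n) < out.missing_rate
    bmi30 = np.where(is_an & ~lost, bmi30, np.nan)
    clin["bmi_sds_30d"] = bmi30

    gt.symptom_coeffs = sym_coeffs
    gt.outcome_coeffs = {"feature": out.feature, "d0": out.d0, "d1": out.d1,
                         "d2": out.d2, "d3": out.d3, "d4": out.d4,
                         "noise_sd": out.noise_sd,
                         "missing_rate": out.missing_rate}
    return clin


def generate_full_cohort(
    mesh: SphereMesh | None = None,
    atlas: FeatureAtlas | None = None,
    params: CohortParams | None = None,
    effect_params: ClinicalEffectParams | None = None,
    seed: int = 0,
    mesh_subdivisions: int = 3,
    n_features: int = 16,
) -> CohortData:
    """Convenience one-call generator (mesh -> atlas -> cohort -> clinical)."""
    ss = np.random.SeedSequence(seed)
    s_atlas, s_cohort, s_clin = (int(s.generate_state(1)[0] % (2**31))
                                 for s in ss.spawn(3))
    if mesh is None:
        mesh = build_icosphere(mesh_subdivisions)
    if atlas is None:
        atlas = generate_feature_atlas(mesh, n_features=n_features, seed=s_atlas)
    cohort = generate_cohort(mesh, atlas, params, seed=s_cohort)
    generate_clinical_outcomes(cohort, effect_params, seed=s_clin)
    return cohort


def simulate_outcome_table(
    n_an: int = 114,
    outcome: OutcomeSpec | None = None,
    params: CohortParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Patients-only table for studying the weight-gain regression alone.

    Draws age, truncated-normal baseline BMI-SDS and a standard-normal
    enrichment score z directly (no surface stage), generates
    ``delta_bmi_sds`` from the outcome coefficients, and applies follow-up
    missingness. Rows with missing follow-up carry NaN in ``delta_bmi_sds``.
    """
    out = outcome or OutcomeSpec()
    p = params or CohortParams()
    rng = np.random.default_rng(seed)
    age = rng.uniform(*p.age_range, size=n_an)
    bmi0 = _truncated_normal(rng, p.bmi_an_mean, p.bmi_an_sd, 0.0, n_an)
    z = rng.standard_normal(n_an)
    dbmi = (out.d0 + out.d1 * age + out.d2 * bmi0 + out.d3 * z
            + out.d4 * bmi0 * z + out.noise_sd * rng.standard_normal(n_an))
    lost = rng.random(n_an) < out.missing_rate
    dbmi = np.where(lost, np.nan, dbmi)
    return pd.DataFrame({"age": age, "bmi_sds_baseline": bmi0, "spect": z,
                         "delta_bmi_sds": dbmi})


# ---------------------------------------------------------------------------
# export / import


def save_cohort(cohort: CohortData, outdir) -> None:
    """Write CT matrix, clinical table, atlas and ground truth as text files."""
    import os

    os.makedirs(outdir, exist_ok=True)
    pd.DataFrame(cohort.ct).to_csv(os.path.join(outdir, "ct.csv"), index=False,
                                   float_format="%.17g")
    cohort.clinical.to_csv(os.path.join(outdir, "clinical.csv"), index=False,
                           float_format="%.17g")
    atlas_df = pd.DataFrame(cohort.atlas.matrix().T, columns=cohort.atlas.names)
    atlas_df["valid"] = cohort.atlas.valid_mask.astype(int)
    atlas_df.to_csv(os.path.join(outdir, "atlas.csv"), index=False,
                    float_format="%.17g")
    gt = cohort.ground_truth
    if gt is not None:
        payload = {
            "delta_map": gt.delta_map.values.tolist(),
            "gamma": gt.gamma.tolist(),
            "loadings": gt.loadings.tolist(),
            "b0_map": gt.b0_map.tolist(),
            "age_slope_map": gt.age_slope_map.tolist(),
            "tau": gt.tau.tolist(),
            "noise_sd": gt.noise_sd,
            "seed": gt.seed,
            "feature_names": gt.feature_names,
            "symptom_coeffs": gt.symptom_coeffs,
            "outcome_coeffs": gt.outcome_coeffs,
        }
        with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
            json.dump(payload, fh)


def load_cohort(indir, mesh: SphereMesh) -> CohortData:
    import os

    ct = pd.read_csv(os.path.join(indir, "ct.csv"),
                     float_precision="round_trip").to_numpy()
    clinical = pd.read_csv(os.path.join(indir, "clinical.csv"),
                           float_precision="round_trip")
    atlas_df = pd.read_csv(os.path.join(indir, "atlas.csv"),
                           float_precision="round_trip")
    mask = atlas_df.pop("valid").to_numpy().astype(bool)
    maps = [VertexMap(atlas_df[c].to_numpy(), mask, mesh) for c in atlas_df.columns]
    atlas = FeatureAtlas(list(atlas_df.columns), maps, -1, 1.0)
    gt = None
    gt_path = os.path.join(indir, "ground_truth.json")
    if os.path.exists(gt_path):
        with open(gt_path) as fh:
            d = json.load(fh)
        gt = GroundTruth(
            delta_map=VertexMap(np.array(d["delta_map"]), mask, mesh),
            gamma=np.array(d["gamma"]),
            loadings=np.array(d["loadings"]),
            b0_map=np.array(d["b0_map"]),
            age_slope_map=np.array(d["age_slope_map"]),
            tau=np.array(d["tau"]),
            noise_sd=d["noise_sd"], seed=d["seed"],
            feature_names=d["feature_names"],
            symptom_coeffs=d["symptom_coeffs"],
            outcome_coeffs=d["outcome_coeffs"],
        )
    return CohortData(ct=ct, clinical=clinical, mesh=mesh, atlas=atlas,
                      ground_truth=gt)
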