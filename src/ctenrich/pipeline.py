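"""End-to-end orchestration: simulate -> GLM -> enrichment -> scores ->
clinical correlations -> outcome models, with named sub-seeds and CSV reports.

Every stochastic stage draws its seed by hashing the master seed together
with a fixed stage name, so adding or reordering stages never perturbs the
randomness of the others, and a saved config reproduces a run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import correlate_enrichment_with_symptoms
from .enrichment import (EnrichmentTest, enrich_group_contrast,
                         enrichment_table, spatial_correlation,
                         subject_enrichment_scores)
from .glm import fit_vertexwise_glm, global_mean_ct, group_contrast_map
from .outcome import (OutcomeFit, fit_outcome_model, jn_table, johnson_neyman,
                      subsample_refit)
from .simulate import (ClinicalEffectParams, CohortData, CohortParams,
                       FeatureAtlas, generate_clinical_outcomes,
                       generate_cohort, generate_feature_atlas)
from .surfaces import VertexMap, build_icosphere, connected_clusters

logger = logging.getLogger("ctenrich")


def derive_seed(master_seed: int, name: str) -> int:
    """Deterministic named sub-seed (< 2**31) from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run."""

    seed: int = 0
    mesh_subdivisions: int = 3
    n_features: int = 16
    atlas_smooth_iterations: int = 4
    atlas_smooth_weight: float = 0.9
    cohort: CohortParams = field(default_factory=CohortParams)
    effects: ClinicalEffectParams = field(default_factory=ClinicalEffectParams)
    n_perm: int = 1000
    alpha: float = 0.05
    residual_mode: str = "full-model"
    symptom_covariates: tuple[str, ...] = ("age", "bmi_sds_baseline")
    symptom_fdr_family: str = "per-symptom-across-features"
    gate_rule: str = "fdr"          # "fdr" (q < alpha) or "all"
    outcome_feature: str = "SERT"   # feature for control models / JN probing
    contrast_threshold: float = 0.1  # cm, intersection display threshold
    feature_sd_threshold: float = 1.0
    min_cluster: int = 15

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            ch = dict(d["cohort"])
            if "age_range" in ch:
                ch["age_range"] = tuple(ch["age_range"])
            d["cohort"] = CohortParams(**ch)
        if "effects" in d and isinstance(d["effects"], dict):
            from .simulate import OutcomeSpec, SymptomSpec
            ef = dict(d["effects"])
            if "symptoms" in ef:
                ef["symptoms"] = {k: SymptomSpec(**v)
                                  for k, v in ef["symptoms"].items()}
            if "outcome" in ef:
                ef["outcome"] = OutcomeSpec(**ef["outcome"])
            d["effects"] = ClinicalEffectParams(**ef)
        if "symptom_covariates" in d:
            d["symptom_covariates"] = tuple(d["symptom_covariates"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All tables produced by one pipeline run."""

    config: RunConfig
    cohort: CohortData
    contrast_summary: pd.DataFrame
    enrichment: pd.DataFrame
    enrichment_tests: list[EnrichmentTest]
    gated_features: list[str]
    intersections: pd.DataFrame
    symptom_correlations: pd.DataFrame
    outcome_models: pd.DataFrame
    jn_regions: pd.DataFrame
    outcome_fits: dict[str, OutcomeFit]
    provenance: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "contrast_summary": self.contrast_summary,
            "enrichment": self.enrichment,
            "intersections": self.intersections,
            "symptom_correlations": self.symptom_correlations,
            "outcome_models": self.outcome_models,
            "jn_regions": self.jn_regions,
        }

    def save(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(os.path.join(outdir, f"{name}.csv"), index=False,
                      float_format="%.12g")
        with open(os.path.join(outdir, "provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)


def _stage(name):
    logger.info("stage %s", name)
    return time.time()


def run_full_pipeline(config: RunConfig, outdir=None,
                      cohort: CohortData | None = None,
                      atlas: FeatureAtlas | None = None) -> RunReport:
    """Run every stage in order and return (and optionally save) the report.

    A pre-built cohort (user-supplied data) or atlas can be passed in; by
    default both are generated synthetically from the config seeds.
    """
    provenance = {"config_hash": config.hash(), "version": __version__,
                  "master_seed": config.seed, "stage_seconds": {},
                  "stage_seeds": {}}
    timings = provenance["stage_seconds"]

    def finish(name, t0):
        timings[name] = round(time.time() - t0, 3)

    # --- simulate -----------------------------------------------------------
    t0 = _stage("simulate")
    try:
        if cohort is None:
            mesh = build_icosphere(config.mesh_subdivisions)
            if atlas is None:
                s_atlas = derive_seed(config.seed, "atlas")
                provenance["stage_seeds"]["atlas"] = s_atlas
                atlas = generate_feature_atlas(
                    mesh, n_features=config.n_features,
                    smooth_iterations=config.atlas_smooth_iterations,
                    smooth_weight=config.atlas_smooth_weight, seed=s_atlas)
            s_cohort = derive_seed(config.seed, "cohort")
            s_clin = derive_seed(config.seed, "clinical")
            provenance["stage_seeds"].update(cohort=s_cohort, clinical=s_clin)
            cohort = generate_cohort(atlas.mesh, atlas, config.cohort,
                                     seed=s_cohort)
            generate_clinical_outcomes(cohort, config.effects, seed=s_clin)
    except Exception as err:
        raise RuntimeError(f"stage 'simulate' failed: {err}") from err
    finish("simulate", t0)

    # --- vertex-wise GLM ----------------------------------------------------
    t0 = _stage("glm")
    try:
        fit = fit_vertexwise_glm(cohort)
        contrast = group_contrast_map(fit, cohort)
        residuals = fit.subject_residual_maps(config.residual_mode)
        gct = global_mean_ct(cohort)
        mask = cohort.valid_mask
        contrast_summary = pd.DataFrame([{
            "n_an": int((cohort.clinical["group"] == "AN").sum()),
            "n_hc": int((cohort.clinical["group"] == "HC").sum()),
            "n_valid_vertices": int(mask.sum()),
            "contrast_mean": contrast.valid_values.mean(),
            "contrast_min": contrast.valid_values.min(),
            "contrast_max": contrast.valid_values.max(),
            "global_ct_an": gct[cohort.clinical["group"] == "AN"].mean(),
            "global_ct_hc": gct[cohort.clinical["group"] == "HC"].mean(),
        }])
    except Exception as err:
        raise RuntimeError(f"stage 'glm' failed: {err}") from err
    finish("glm", t0)

    # --- group-level enrichment + gating -----------------------------------
    t0 = _stage("enrich")
    try:
        s_spin = derive_seed(config.seed, "spin")
        provenance["stage_seeds"]["spin"] = s_spin
        tests = enrich_group_contrast(contrast, cohort.atlas,
                                      n_perm=config.n_perm, seed=s_spin)
        enr = enrichment_table(tests)
        if config.gate_rule == "all":
            gated = list(enr["feature"])
        else:
            gated = list(enr.loc[enr["q_fdr"] < config.alpha, "feature"])
    except Exception as err:
        raise RuntimeError(f"stage 'enrich' failed: {err}") from err
    finish("enrich", t0)

    # --- intersection display table ----------------------------------------
    t0 = _stage("intersect")
    try:
        inter = intersection_table(contrast, cohort.atlas,
                                   config.contrast_threshold,
                                   config.feature_sd_threshold,
                                   config.min_cluster,
                                   features=gated)
    except Exception as err:
        raise RuntimeError(f"stage 'intersect' failed: {err}") from err
    finish("intersect", t0)

    # --- subject scores -----------------------------------------------------
    t0 = _stage("scores")
    try:
        scores_all = subject_enrichment_scores(
            residuals, cohort.atlas,
            subject_ids=list(cohort.clinical["subject_id"]))
        scores = scores_all.to_frame()[gated] if gated else scores_all.to_frame().iloc[:, :0]
    except Exception as err:
        raise RuntimeError(f"stage 'scores' failed: {err}") from err
    finish("scores", t0)

    # --- clinical correlations ---------------------------------------------
    t0 = _stage("clinical")
    try:
        if gated:
            sym = correlate_enrichment_with_symptoms(
                scores, cohort.clinical,
                covariates=config.symptom_covariates,
                family=config.symptom_fdr_family)
        else:
            sym = pd.DataFrame(columns=["feature", "symptom", "rho", "p", "n",
                                        "q", "covariates", "family"])
    except Exception as err:
        raise RuntimeError(f"stage 'clinical' failed: {err}") from err
    finish("clinical", t0)

    # --- outcome models -----------------------------------------------------
    t0 = _stage("outcome")
    try:
        gct_series = pd.Series(gct, index=cohort.clinical["subject_id"])
        outcome_frames, jn_frames = [], []
        outcome_fits: dict[str, OutcomeFit] = {}
        for feat in gated:
            ofit = fit_outcome_model(cohort.clinical, scores, feat,
                                     model="main")
            outcome_fits[feat] = ofit
            outcome_frames.append(ofit.to_frame())
            inter_term = "bmi_sds_baseline:spect"
            if ofit.pvalues[inter_term] < config.alpha:
                jn = johnson_neyman(ofit, alpha=config.alpha)
                jf = jn_table(jn)
                jf.insert(0, "feature", feat)
                jn_frames.append(jf)
        if config.outcome_feature in gated:
            feat = config.outcome_feature
            for model in ("alt1", "alt2", "alt3", "alt4"):
                afit = fit_outcome_model(cohort.clinical, scores, feat,
                                         model=model, global_ct=gct_series)
                outcome_fits[f"{feat}:{model}"] = afit
                outcome_frames.append(afit.to_frame())
            for name, sfit in subsample_refit(cohort.clinical, scores,
                                              feat).items():
                frame = sfit.to_frame()
                frame["model"] = f"main[{name}]"
                outcome_fits[f"{feat}:{name}"] = sfit
                outcome_frames.append(frame)
        outcome_models = (pd.concat(outcome_frames, ignore_index=True)
                          if outcome_frames else
                          pd.DataFrame(columns=["model", "feature", "term",
                                                "estimate", "robust_se", "t",
                                                "p", "n"]))
        jn_regions = (pd.concat(jn_frames, ignore_index=True) if jn_frames else
                      pd.DataFrame(columns=["feature", "moderator", "focal",
                                            "alpha", "t_crit", "lower",
                                            "upper", "slope_sign",
                                            "extrapolated"]))
    except Exception as err:
        raise RuntimeError(f"stage 'outcome' failed: {err}") from err
    finish("outcome", t0)

    report = RunReport(config=config, cohort=cohort,
                       contrast_summary=contrast_summary,
                       enrichment=enr, enrichment_tests=tests,
                       gated_features=gated, intersections=inter,
                       symptom_correlations=sym,
                       outcome_models=outcome_models, jn_regions=jn_regions,
                       outcome_fits=outcome_fits, provenance=provenance)
    if outdir is not None:
        report.save(outdir)
    return report


def intersection_table(
    contrast: VertexMap,
    atlas: FeatureAtlas,
    contrast_threshold: float,
    feature_sd_threshold: float,
    min_cluster: int,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Clusters where a strong group difference overlaps a feature extreme.

    The contrast is binarized at |value| >= contrast_threshold; each feature
    at mean +/- feature_sd_threshold * SD (both tails). Tail pairing follows
    the sign of the feature's spatial correlation with the contrast (r > 0
    pairs same-sign tails, r < 0 opposite-sign). Surviving connected clusters
    (>= min_cluster vertices) are listed per feature with size and the
    contrast sign inside the cluster.
    """
    if contrast_threshold <= 0 or feature_sd_threshold <= 0:
        raise ValueError("thresholds must be positive")
    mesh = contrast.mesh
    rows = []
    names = features if features is not None else atlas.names
    for name in names:
        fmap = atlas[name]
        joint = contrast.valid_mask & fmap.valid_mask
        r = spatial_correlation(contrast, fmap)
        fv = fmap.values
        mu, sd = fv[joint].mean(), fv[joint].std()
        hi = joint & (fv >= mu + feature_sd_threshold * sd)
        lo = joint & (fv <= mu - feature_sd_threshold * sd)
        cpos = joint & (contrast.values >= contrast_threshold)
        cneg = joint & (contrast.values <= -contrast_threshold)
        if r >= 0:
            mask = (cpos & hi) | (cneg & lo)
        else:
            mask = (cpos & lo) | (cneg & hi)
        labels = connected_clusters(mesh, mask, min_cluster)
        for lab in range(1, labels.max() + 1):
            members = labels == lab
            sign = int(np.sign(contrast.values[members].mean()))
            rows.append({"feature": name, "cluster": lab,
                         "size": int(members.sum()),
                         "contrast_sign": sign, "spatial_r": r})
    return pd.DataFrame(rows, columns=["feature", "cluster", "size",
                                       "contrast_sign", "spatial_r"])


def run_replication(
    config_primary: RunConfig,
    config_replication: RunConfig,
    outdir=None,
) -> tuple[RunReport, RunReport, pd.DataFrame]:
    """Run two cohorts against one shared atlas and tabulate concordance.

    The atlas is built from the primary config (shared reference maps, as
    when two sites compare against the same PET-derived annotations); each
    cohort uses its own config/seed. The concordance table lists, per
    feature, the sign agreement of the group-level spatial r and whether both
    runs pass the FDR gate.
    """
    mesh = build_icosphere(config_primary.mesh_subdivisions)
    atlas = generate_feature_atlas(
        mesh, n_features=config_primary.n_features,
        smooth_iterations=config_primary.atlas_smooth_iterations,
        smooth_weight=config_primary.atlas_smooth_weight,
        seed=derive_seed(config_primary.seed, "atlas"))
    rep1 = run_full_pipeline(config_primary, atlas=atlas,
                             outdir=None if outdir is None
                             else os.path.join(outdir, "primary"))
    rep2 = run_full_pipeline(config_replication, atlas=atlas,
                             outdir=None if outdir is None
                             else os.path.join(outdir, "replication"))
    e1 = rep1.enrichment.set_index("feature")
    e2 = rep2.enrichment.set_index("feature")
    alpha = config_primary.alpha
    conc = pd.DataFrame({
        "feature": e1.index,
        "r_primary": e1["r"].to_numpy(),
        "r_replication": e2.loc[e1.index, "r"].to_numpy(),
    })
    conc["sign_agrees"] = np.sign(conc["r_primary"]) == np.sign(conc["r_replication"])
    conc["significant_primary"] = (e1["q_fdr"] < alpha).to_numpy()
    conc["significant_replication"] = (e2.loc[e1.index, "q_fdr"] < alpha).to_numpy()
    conc["jointly_significant"] = (conc["significant_primary"]
                                   & conc["significant_replication"])
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        conc.to_csv(os.path.join(outdir, "concordance.csv"), index=False,
                    float_format="%.12g")
    return rep1, rep2, conc
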