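"""End-to-end analysis pipeline.

Chains the stages: simulate (or read) a cohort, apply the two-distinct-bin
inclusion rule, fit the parallel-process growth mixture at a fixed K or
enumerate candidate K, order classes by severity, then run the three-step
covariate regressions (one covariate at a time, age-adjusted, grand-mean
centred, family-clustered, classification-error corrected) with multiple
imputation and Rubin's-rules pooling.  Emits four report CSVs and a
structured JSON run log.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from . import io as tio
from .impute import impute_covariates, rubin_pool
from .model import ModelSpec, multi_start_fit, order_classes, severity_score
from .selection import enumerate_classes, entropy
from .synthetic import (BIN_LABELS, CLASS_NAMES, IMPUTABLE_COLS, N_BINS,
                        PRS_COLS, GeneratorConfig, apply_inclusion_filter,
                        default_true_params, simulate_cohort, summarize_by_class)
from .threestep import (MultinomialFit, corrected_multinomial_fit,
                        grand_mean_center, modal_assign)

logger = logging.getLogger(__name__)

# pre-specified contrasts in canonical label space: (severe combined stable
# vs severe combined decreasing), (severe inattentive stable vs severe
# combined decreasing), (severe combined stable vs severe inattentive
# stable), (moderate combined increasing vs moderate combined decreasing)
DEFAULT_CONTRAST_LABELS = (
    ("severe combined stable", "severe combined decreasing"),
    ("severe inattentive stable", "severe combined decreasing"),
    ("severe combined stable", "severe inattentive stable"),
    ("moderate combined increasing", "moderate combined decreasing"),
)


def label_classes(params) -> list[str]:
    """Attach the seven canonical trajectory labels to a 7-class fit.

    Estimated per-class growth factors (both domains) are matched one-to-one
    to the canonical archetype profiles by minimum total squared distance,
    so labelling is deterministic and permutation-invariant.  Only defined
    for K = 7.
    """
    if params.n_classes != 7:
        raise ValueError("canonical labels are defined for K = 7 only")
    ref = default_true_params()
    est = np.column_stack([params.intercept[0], params.slope[0],
                           params.intercept[1], params.slope[1]])
    arche = np.column_stack([ref.intercept[0], ref.slope[0],
                             ref.intercept[1], ref.slope[1]])
    cost = ((est[:, None, :] - arche[None, :, :]) ** 2).sum(axis=2)
    _, cols = linear_sum_assignment(cost)
    return [CLASS_NAMES[j] for j in cols]


@dataclass
class RunConfig:
    """Configuration for one pipeline run; all randomness flows from seeds."""

    generator: GeneratorConfig | None = None
    observations_path: str | None = None
    covariates_path: str | None = None
    n_classes: int | None = 7          # fixed K; None -> enumerate
    k_min: int = 1
    k_max: int = 8
    n_initial_starts: int = 100
    n_final_starts: int = 20
    m_imputations: int = 10
    covariates: tuple = IMPUTABLE_COLS + PRS_COLS + ("mean_age",)
    ancestry_adjusters: tuple = ()     # extra adjusters for polygenic scores
    contrast_labels: tuple = DEFAULT_CONTRAST_LABELS
    fit_seed: int = 0
    imputation_seed: int = 0
    outdir: str = "trajmix_out"

    def validate(self) -> None:
        if self.generator is None and self.observations_path is None:
            raise ValueError("either a generator config or input paths required")
        if self.observations_path is not None:
            for p in (self.observations_path, self.covariates_path):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)


def _class_weight_pct(posteriors: np.ndarray) -> np.ndarray:
    return 100.0 * posteriors.mean(axis=0)


def pooled_contrast_rows(per_imp_fits: list[MultinomialFit], covariate: str,
                         contrasts: list[tuple[int, int]],
                         labels: list[str] | None) -> list[dict]:
    """Pool log-odds contrasts across imputations with Rubin's rules."""
    rows = []
    for a, b in contrasts:
        ests, vars_ = [], []
        for fit in per_imp_fits:
            d, se = fit.contrast(a, b)
            if np.isnan(d):
                continue
            ests.append(d)
            vars_.append(se ** 2)
        if not ests:
            rows.append({"covariate": covariate, "class_a": a, "class_b": b,
                         "odds_ratio": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan,
                         "df": np.nan, "m": 0})
            continue
        pooled = rubin_pool(ests, vars_)
        q = (stats.t.ppf(0.975, pooled.df) if np.isfinite(pooled.df)
             else stats.norm.ppf(0.975))
        rows.append({
            "covariate": covariate, "class_a": a, "class_b": b,
            "odds_ratio": float(np.exp(pooled.estimate)),
            "ci_low": float(np.exp(pooled.estimate - q * pooled.se)),
            "ci_high": float(np.exp(pooled.estimate + q * pooled.se)),
            "p_value": pooled.p_value, "df": pooled.df, "m": pooled.m,
        })
    if labels is not None:
        for r in rows:
            r["contrast"] = f"{labels[r['class_a']]} vs {labels[r['class_b']]}"
    return rows


def analyze_covariates(assignment, covariates: pd.DataFrame, pids: np.ndarray,
                       family_ids: np.ndarray, config: RunConfig,
                       contrasts: list[tuple[int, int]],
                       labels: list[str] | None) -> pd.DataFrame:
    """Three-step regressions for every covariate, pooled over imputations.

    Imputable covariates are analyzed on each of the m completed tables and
    pooled; polygenic scores use complete cases only (with any configured
    ancestry adjusters); mean age itself is analyzed unadjusted.
    """
    cov = covariates.loc[pids]
    imps = impute_covariates(cov, m=config.m_imputations,
                             seed=config.imputation_seed)
    all_rows: list[dict] = []
    for name in config.covariates:
        if name not in cov.columns:
            continue
        if name == "mean_age":
            adjusters: list[str] = []
        elif name in PRS_COLS:
            adjusters = ["mean_age", *config.ancestry_adjusters]
        else:
            adjusters = ["mean_age"]
        if name in PRS_COLS or not cov[name].isna().any():
            tables = [cov]          # complete cases, no imputation
        else:
            tables = imps.tables
        fits = []
        for table in tables:
            pred = pd.DataFrame(index=table.index)
            pred[name] = grand_mean_center(table[name])
            for adj in adjusters:
                pred[adj] = grand_mean_center(table[adj])
            fits.append(corrected_multinomial_fit(
                assignment.modal, assignment.D, pred, family_ids=family_ids))
        all_rows.extend(pooled_contrast_rows(fits, name, contrasts, labels))
    out = pd.DataFrame(all_rows)
    cols = ["covariate"] + (["contrast"] if labels is not None else []) + \
        ["class_a", "class_b", "odds_ratio", "ci_low", "ci_high",
         "p_value", "df", "m"]
    return out[cols]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the report bundle as a dict of frames.

    On a stage failure the partial outputs written so far remain on disk and
    ``error.json`` records the stage and traceback.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": [], "warnings": []}
    bundle: dict = {}
    stage = "setup"
    try:
        stage = "data"
        if config.generator is not None:
            dataset, covariates = simulate_cohort(config.generator)
            log["generator_seed"] = config.generator.seed
        else:
            dataset = tio.read_long_observations(config.observations_path)
            covariates = (tio.read_covariates(config.covariates_path)
                          if config.covariates_path else None)
        included = apply_inclusion_filter(dataset)
        Y, pids = included.to_wide()
        log["n_total"] = dataset.n_participants
        log["n_included"] = included.n_participants
        log["stages"].append("data")

        stage = "fit"
        if config.n_classes is None:
            enum = enumerate_classes(Y, config.k_min, config.k_max,
                                     n_initial=config.n_initial_starts,
                                     n_final=config.n_final_starts,
                                     seed=config.fit_seed)
            enum.table.to_csv(outdir / "enumeration.csv", index=False,
                              float_format="%.4f")
            bundle["enumeration"] = enum.table
            if enum.selected_k is None:
                raise RuntimeError("no admissible class count in enumeration")
            log["selected_k"] = enum.selected_k
            fit = enum.fits[enum.selected_k]
        else:
            spec = ModelSpec(n_classes=config.n_classes, n_bins=Y.shape[2])
            fit = multi_start_fit(Y, spec, n_initial=config.n_initial_starts,
                                  n_final=config.n_final_starts,
                                  seed=config.fit_seed)
        fit = order_classes(fit)
        K = fit.params.n_classes
        log["loglik"] = fit.loglik
        log["converged"] = fit.converged
        log["top_start_logliks"] = [round(x, 4) for x in
                                    (fit.start_logliks or [])[:10]]
        log["entropy"] = entropy(fit.posteriors) if K >= 2 else None
        log["class_weights_pct"] = [round(x, 2) for x in
                                    _class_weight_pct(fit.posteriors)]
        log["fit_seed"] = config.fit_seed
        log["stages"].append("fit")

        labels = None
        if K == 7:
            labels = label_classes(fit.params)
        log["class_labels"] = labels

        stage = "trajectory_table"
        mu = fit.params.means()
        rows = []
        for k in range(K):
            for d, dom in enumerate(("ia", "hi")):
                for t in range(N_BINS):
                    rows.append({
                        "class": k + 1,
                        "label": labels[k] if labels else f"class {k + 1}",
                        "weight_pct": round(100 * float(fit.params.pi[k]), 2),
                        "domain": dom, "bin": t, "bin_label": BIN_LABELS[t],
                        "mean_score": round(float(mu[d, k, t]), 4),
                    })
        traj = pd.DataFrame(rows)
        traj.to_csv(outdir / "trajectory_means.csv", index=False)
        bundle["trajectories"] = traj
        log["stages"].append("trajectory_table")

        assignment = modal_assign(fit.posteriors)
        modal_series = pd.Series(assignment.modal, index=pids)

        if covariates is not None:
            stage = "class_profiles"
            profiles = summarize_by_class(included, covariates.loc[pids],
                                          modal_series)
            profiles.to_csv(outdir / "class_profiles.csv",
                            float_format="%.4f")
            bundle["class_profiles"] = profiles
            log["stages"].append("class_profiles")

            stage = "bin_descriptives"
            desc = _bin_descriptives(included, covariates, modal_series, labels)
            desc.to_csv(outdir / "bin_descriptives.csv", index=False,
                        float_format="%.4f")
            bundle["bin_descriptives"] = desc
            log["stages"].append("bin_descriptives")

            stage = "contrasts"
            contrasts = _resolve_contrasts(config, labels, K)
            if contrasts:
                fam = included.family_ids(pids)
                ct = analyze_covariates(assignment, covariates, pids, fam,
                                        config, contrasts, labels)
                ct.to_csv(outdir / "contrasts.csv", index=False,
                          float_format="%.4f")
                bundle["contrasts"] = ct
                log["imputation_seed"] = config.imputation_seed
                log["m_imputations"] = config.m_imputations
                log["stages"].append("contrasts")
            else:
                log["warnings"].append(
                    "no contrasts resolvable for this class count; skipped")
    except Exception as exc:
        manifest = {"stage": stage, "error": str(exc),
                    "traceback": traceback.format_exc()}
        (outdir / "error.json").write_text(json.dumps(manifest, indent=1))
        (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
        raise
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    bundle["log"] = log
    bundle["fit"] = fit
    return bundle


def _resolve_contrasts(config: RunConfig, labels: list[str] | None,
                       K: int) -> list[tuple[int, int]]:
    pairs = []
    for a, b in config.contrast_labels:
        if isinstance(a, str):
            if labels is None or a not in labels or b not in labels:
                continue
            pairs.append((labels.index(a), labels.index(b)))
        else:
            if a < K and b < K:
                pairs.append((a, b))
    return pairs


def _bin_descriptives(included, covariates, modal_series, labels) -> pd.DataFrame:
    """Per class and age bin: sample size, symptom means, diagnosis and
    impairment summaries among participants observed in that bin."""
    obs = included.obs.copy()
    obs = obs.drop_duplicates(subset=["pid", "bin"], keep="first")
    obs["class"] = obs["pid"].map(modal_series)
    cov = covariates
    rows = []
    for (k, t), grp in obs.groupby(["class", "bin"]):
        members = grp["pid"]
        sub = cov.loc[cov.index.intersection(members)]
        rows.append({
            "class": int(k) + 1,
            "label": labels[int(k)] if labels else f"class {int(k) + 1}",
            "bin": int(t), "bin_label": BIN_LABELS[int(t)],
            "n_obs": len(grp),
            "ia_mean": grp["ia"].mean(), "hi_mean": grp["hi"].mean(),
            "diagnosis_pct": 100 * sub["lifetime_diagnosis"].mean()
            if "lifetime_diagnosis" in sub else np.nan,
            "parent_impairment_mean": sub["parent_impairment"].mean()
            if "parent_impairment" in sub else np.nan,
        })
    return pd.DataFrame(rows).sort_values(["class", "bin"]).reset_index(drop=True)
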