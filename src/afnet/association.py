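"""Per-feature association of expression with AF status and medications.

Prevalent AF (and medication use) is modelled cross-sectionally: log2
expression is regressed on the binary exposure plus covariates, with a
Gaussian random intercept per pedigree to absorb familial correlation
(cluster-robust OLS is the logged fallback if the mixed fit fails).
Incident AF is modelled with Cox proportional hazards on expression as a
continuous predictor, with robust sandwich standard errors clustered by
pedigree.  Multiple testing is controlled with Benjamini-Hochberg step-up
adjusted values; the testing universe m is always the number of features in
the run, never a constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import RandomInterceptModel
from .simulate import COVARIATE_COLUMNS

logger = logging.getLogger(__name__)

COVARIATE_SETS = {
    "age_sex": ["age", "sex"],
    "full_risk_factors": ["age", "sex"] + COVARIATE_COLUMNS,
    "none": [],
}


@dataclass
class ModelSpec:
    """What to regress on what.

    exposure: ``"prevalent_af"``, ``"incident_af"`` or a medication flag name.
    covariate_set: ``"age_sex"`` (primary) or ``"full_risk_factors"``
    (secondary adjustment), or ``"none"``.
    include_incident_in_referent: whether incident cases may serve as
    referents in the prevalent contrast (default: excluded — referents are
    participants who never developed AF).
    """

    exposure: str = "prevalent_af"
    covariate_set: str = "age_sex"
    clustering: str = "pedigree_id"
    include_incident_in_referent: bool = False
    min_events: int = 10
    extra_covariates: Sequence[str] = field(default_factory=tuple)

    def covariates(self) -> list:
        if self.covariate_set not in COVARIATE_SETS:
            raise ValueError(f"unknown covariate_set {self.covariate_set!r}")
        return COVARIATE_SETS[self.covariate_set] + list(self.extra_covariates)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1, returned in the
    input order.  All p must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D collection")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    # p*(m/j) at j=m can round one ulp below p; mathematically q >= p always.
    return np.maximum(q, p)


def _design(samples: pd.DataFrame, exposure_col: str, covariates: Sequence[str]):
    """Complete-case design matrix [1, exposure, covariates...] plus groups."""
    df = samples.copy()
    if "sex" in covariates:
        df["sex"] = df["sex"].map({"female": 0, "male": 1, 0: 0, 1: 1})
    used = [exposure_col] + list(covariates) + ["pedigree_id"]
    missing_cols = [c for c in used if c not in df.columns]
    if missing_cols:
        raise ValueError(f"unknown covariate name(s): {missing_cols}")
    n0 = len(df)
    df = df.dropna(subset=[c for c in used if c != "pedigree_id"])
    if len(df) < n0:
        logger.info("complete-case filtering removed %d of %d samples", n0 - len(df), n0)
    X = np.column_stack(
        [np.ones(len(df)), df[exposure_col].to_numpy(dtype=float)]
        + [df[c].to_numpy(dtype=float) for c in covariates]
    )
    return df, X


def _lmm_association(
    expr: pd.DataFrame, samples: pd.DataFrame, exposure_col: str,
    covariates: Sequence[str],
) -> pd.DataFrame:
    """Shared engine for the prevalent-AF and medication models."""
    df, X = _design(samples, exposure_col, covariates)
    expr = expr[df["sample_id"].tolist()]
    groups = df["pedigree_id"].to_numpy()

    try:
        model = RandomInterceptModel(X, groups)
    except Exception as exc:  # singular design for every feature
        raise ValueError(f"design matrix unusable: {exc}") from exc

    records = []
    n_failed = 0
    for feature_id, y in expr.iterrows():
        yv = y.to_numpy(dtype=float)
        if np.ptp(yv) == 0.0:
            records.append((feature_id, 0.0, np.nan, 1.0, "constant"))
            continue
        try:
            fit = model.fit(yv)
            records.append((feature_id, fit.beta[1], fit.se[1], fit.wald_p(1), "ok"))
        except Exception:
            # Cluster-robust OLS fallback, mirroring the mixed model's
            # fixed-effect part.
            try:
                import statsmodels.api as sm

                res = sm.OLS(yv, X).fit(cov_type="cluster",
                                        cov_kwds={"groups": groups})
                records.append((feature_id, res.params[1], res.bse[1],
                                float(res.pvalues[1]), "ols_fallback"))
                n_failed += 1
            except Exception:
                records.append((feature_id, np.nan, np.nan, np.nan, "failed"))
                n_failed += 1
    if n_failed:
        logger.warning("%d feature(s) required fallback or failed", n_failed)
    out = pd.DataFrame(records, columns=["feature_id", "effect", "se", "p", "status"])
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    return out[["feature_id", "effect", "se", "p", "q", "status"]]


def fit_prevalent(
    expr: pd.DataFrame, samples: pd.DataFrame, spec: Optional[ModelSpec] = None
) -> pd.DataFrame:
    """Association of each feature with prevalent AF.

    Linear mixed model per feature: expression ~ AF + covariates with a
    pedigree random intercept; effect is the AF coefficient, p a two-sided
    Wald test.  Referents are AF-free participants; incident cases are
    excluded from the contrast unless the spec says otherwise.
    """
    spec = spec or ModelSpec(exposure="prevalent_af")
    keep = samples["af_group"].isin(
        ["prevalent", "none", "incident"] if spec.include_incident_in_referent
        else ["prevalent", "none"]
    )
    sub = samples[keep].copy()
    sub["prevalent_af"] = (sub["af_group"] == "prevalent").astype(int)
    counts = sub["prevalent_af"].value_counts()
    if counts.get(1, 0) < 2 or counts.get(0, 0) < 2:
        raise ValueError(
            f"need >=2 samples per AF group, got {counts.get(1, 0)} prevalent / "
            f"{counts.get(0, 0)} referent"
        )
    logger.info("prevalent-AF model: %d cases, %d referents",
                counts.get(1, 0), counts.get(0, 0))
    return _lmm_association(expr, sub, "prevalent_af", spec.covariates())


def fit_medication(
    expr: pd.DataFrame, samples: pd.DataFrame, medication: str,
    spec: Optional[ModelSpec] = None,
) -> pd.DataFrame:
    """Association of each feature with use of one medication.

    Same model family and covariates as the prevalent-AF fit, with the
    dichotomous medication flag as the independent variable.
    """
    spec = spec or ModelSpec(exposure=medication)
    if medication not in samples.columns:
        raise ValueError(f"medication flag {medication!r} not in sample table")
    users = samples[medication].sum()
    if users == 0 or users == len(samples):
        raise ValueError(f"medication {medication!r} has no contrast "
                         f"({int(users)} users of {len(samples)})")
    return _lmm_association(expr, samples, medication, spec.covariates())


def fit_incident(
    expr: pd.DataFrame, samples: pd.DataFrame, spec: Optional[ModelSpec] = None
) -> pd.DataFrame:
    """Cox proportional-hazards association of each feature with incident AF.

    Expression enters as a continuous predictor; standard errors are robust
    sandwich estimates clustered by pedigree; prevalent cases are excluded;
    censoring is at the recorded follow-up time.  Effect is the log hazard
    ratio per log2 expression unit.
    """
    from lifelines import CoxPHFitter

    spec = spec or ModelSpec(exposure="incident_af")
    sub = samples[samples["af_group"] != "prevalent"].copy()
    covariates = spec.covariates()
    if "sex" in covariates:
        sub["sex"] = sub["sex"].map({"female": 0, "male": 1, 0: 0, 1: 1})
    sub = sub.dropna(subset=["followup_time", "event"] + covariates)
    n_events = int(sub["event"].sum())
    if n_events < spec.min_events:
        raise ValueError(f"insufficient events: {n_events} < {spec.min_events}")
    logger.info("incident-AF model: %d events among %d samples", n_events, len(sub))

    base = sub[["followup_time", "event", "pedigree_id"] + covariates].reset_index(drop=True)
    expr = expr[sub["sample_id"].tolist()]
    records = []
    for feature_id, y in expr.iterrows():
        yv = y.to_numpy(dtype=float)
        if np.ptp(yv) == 0.0:
            records.append((feature_id, 0.0, np.nan, 1.0, "constant"))
            continue
        df = base.copy()
        df["expression"] = yv
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="followup_time", event_col="event",
                    cluster_col="pedigree_id", robust=True, show_progress=False)
            coef = float(cph.params_["expression"])
            se = float(cph.standard_errors_["expression"])
            p = float(2.0 * stats.norm.sf(abs(coef / se)))
            records.append((feature_id, coef, se, p, "ok"))
        except Exception:
            records.append((feature_id, np.nan, np.nan, np.nan, "failed"))
    out = pd.DataFrame(records, columns=["feature_id", "effect", "se", "p", "status"])
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    return out[["feature_id", "effect", "se", "p", "q", "status"]]
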