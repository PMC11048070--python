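"""Standardized disc-metric scores and the spondylolisthesis index.

Scores
------
* z score: (metric − normal mean) / normal SD, level-specific.
* robust normalized score: (metric − Hodges–Lehmann location) / Qn scale.
* SpondyIndex: (observed SPO − regression-predicted normal SPO) / per-level
  residual SD.  The prediction is an OLS fit of ASPO (or PSPO) on endplate
  width ratio, anterior and posterior disc heights, and level indicators,
  trained on radiographically normal levels from wide-angle flexion/
  extension exams; one pass of studentized-residual trimming at 3 precedes
  the final fit.  Disc angle is deliberately not a predictor: the two disc
  heights carry the same information.  The shoelace disc area is also
  excluded by default (config-selectable): it is an exact function of the
  same four corners that define the offsets, so at nonzero disc angle
  {area, heights, EPWR} algebraically encode the offset being predicted —
  including area makes the "normal SPO" prediction partially circular and
  masks true listhesis in wide-angle exams.

The exponential age model z = b0·exp(b1·age) describes the age trend of the
standardized average disc height.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .types import LEVEL_NAMES, METRIC_COLUMNS

SPONDY_PREDICTORS = ("epwr", "adh", "pdh")


def z_score(value, ref_mean, ref_sd):
    """Level-specific standardized score (metric − normal mean)/normal SD."""
    ref_sd = np.asarray(ref_sd, dtype=float)
    if np.any(ref_sd <= 0):
        raise ValueError("z_score: reference sd must be > 0")
    return (np.asarray(value, dtype=float) - ref_mean) / ref_sd


def robust_score(value, hl_location, qn):
    """Robust analogue of the z score using Hodges–Lehmann location and Qn."""
    qn = np.asarray(qn, dtype=float)
    if np.any(qn <= 0):
        raise ValueError("robust_score: Qn scale must be > 0")
    return (np.asarray(value, dtype=float) - hl_location) / qn


def score_table(metrics: pd.DataFrame, reference: pd.DataFrame, kind: str = "z",
                params: str = "norm") -> pd.DataFrame:
    """Wide per-level score table: one z_<metric> column per reference metric.

    kind="z" uses Gaussian location/scale — the truncation-consistent
    (mu_norm, sigma_norm) pair when params="norm" (default) or the raw
    post-trim (mean, sd) when params="raw".  kind="robust" uses
    (hl_location, qn_scale).  Rows whose level is absent from the reference
    get NaN scores.
    """
    if kind == "z":
        loc_col, sca_col = ("mu_norm", "sigma_norm") if params == "norm" else ("mean", "sd")
    elif kind == "robust":
        loc_col, sca_col = "hl_location", "qn_scale"
    else:
        raise ValueError(f"kind must be 'z' or 'robust', got {kind!r}")

    out = metrics[[c for c in ("subject_id", "level_name") if c in metrics.columns]].copy()
    ref = reference.set_index(["level_name", "metric"])
    lv = metrics["level_name"]
    for m in METRIC_COLUMNS:
        if m not in metrics.columns:
            continue
        pairs = [(l, m) for l in lv]
        present = [p in ref.index for p in pairs]
        if not any(present):
            continue
        loc = np.array([ref.at[p, loc_col] if ok else np.nan
                        for p, ok in zip(pairs, present)])
        sca = np.array([ref.at[p, sca_col] if ok else np.nan
                        for p, ok in zip(pairs, present)])
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"z_{m}"] = (metrics[m].to_numpy(dtype=float) - loc) / sca
    return out


def classify_prevalence(scores: pd.DataFrame, thresholds=(2.0, 3.0)) -> pd.DataFrame:
    """Fraction of levels beyond each score threshold, per level and metric.

    Reports the absolute-value prevalence (default interpretation) and the
    one-sided high/low tails separately.  A pooled "ALL" row per metric is
    appended.
    """
    zcols = [c for c in scores.columns if c.startswith("z_")]
    rows = []
    groups = list(scores.groupby("level_name")) if "level_name" in scores.columns else []
    groups.append(("ALL", scores))
    for lv, grp in groups:
        for c in zcols:
            z = grp[c].to_numpy(dtype=float)
            z = z[np.isfinite(z)]
            row = {"level_name": lv, "metric": c[2:], "n": int(z.size)}
            for t in thresholds:
                tt = f"{t:g}"
                row[f"abs_gt{tt}"] = float(np.mean(np.abs(z) > t)) if z.size else np.nan
                row[f"pos_gt{tt}"] = float(np.mean(z > t)) if z.size else np.nan
                row[f"neg_lt{tt}"] = float(np.mean(z < -t)) if z.size else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exponential age model for standardized average disc height

@dataclass
class AgeModel:
    """z(avg disc height) = b0 · exp(b1 · age)."""

    b0: float
    b1: float


def age_model_eval(age, model: AgeModel):
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    return model.b0 * np.exp(model.b1 * age)


def fit_age_model(ages, z_values) -> AgeModel:
    """Nonlinear least squares fit of the exponential age model."""
    ages = np.asarray(ages, dtype=float)
    z = np.asarray(z_values, dtype=float)
    ok = np.isfinite(ages) & np.isfinite(z)
    ages, z = ages[ok], z[ok]
    if ages.size < 10:
        raise ValueError("fit_age_model needs >= 10 points")
    b0_init = float(np.sign(np.mean(z)) or 1.0) * 0.001
    try:
        popt, _ = optimize.curve_fit(
            lambda a, b0, b1: b0 * np.exp(b1 * a), ages, z,
            p0=[b0_init, 0.05], maxfev=20000)
    except RuntimeError as e:
        raise RuntimeError(f"age model fit did not converge: {e}") from e
    return AgeModel(b0=float(popt[0]), b1=float(popt[1]))


# ---------------------------------------------------------------------------
# SpondyIndex

class UnseenLevelError(KeyError):
    """A level absent from the training data cannot be scored."""


@dataclass
class SpondyModel:
    """OLS prediction of normal SPO plus per-level residual scales."""

    target: str                       # "aspo" or "pspo"
    coefficients: dict[str, float]    # predictors + one intercept per level
    residual_sd: dict[str, float]
    provenance: dict = field(default_factory=dict)
    degenerate: bool = False

    SCHEMA_VERSION = 1

    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": self.SCHEMA_VERSION,
            "target": self.target,
            "coefficients": self.coefficients,
            "residual_sd": self.residual_sd,
            "provenance": self.provenance,
            "degenerate": self.degenerate,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SpondyModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        if payload.get("schema_version") != cls.SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {payload.get('schema_version')}")
        return cls(target=payload["target"],
                   coefficients={k: float(v) for k, v in payload["coefficients"].items()},
                   residual_sd={k: float(v) for k, v in payload["residual_sd"].items()},
                   provenance=payload.get("provenance", {}),
                   degenerate=bool(payload.get("degenerate", False)))


def _design(df: pd.DataFrame, predictors, levels) -> np.ndarray:
    cols = [df[p].to_numpy(dtype=float) for p in predictors]
    lv = df["level_name"].to_numpy()
    for name in levels:
        cols.append((lv == name).astype(float))
    return np.column_stack(cols)


def train_spondy_index(training: pd.DataFrame, target: str = "aspo",
                       predictors=SPONDY_PREDICTORS, outlier_sigma: float = 3.0,
                       seed: int | None = None) -> SpondyModel:
    """Fit the SpondyIndex regression on radiographically normal levels.

    OLS of the target SPO on the predictors plus one indicator per level
    (no global intercept), one pass of |studentized residual| > outlier_sigma
    exclusion, refit, then per-level residual SDs.
    """
    target = target.lower()
    if target not in ("aspo", "pspo"):
        raise ValueError("target must be 'aspo' or 'pspo'")
    needed = {"level_name", target, *predictors}
    missing = needed - set(training.columns)
    if missing:
        raise ValueError(f"training table missing columns: {sorted(missing)}")
    df = training.dropna(subset=[target, *predictors]).reset_index(drop=True)
    levels = [lv for lv in LEVEL_NAMES if lv in set(df["level_name"])]
    names = [*predictors, *[f"level_{lv}" for lv in levels]]
    X = _design(df, predictors, levels)
    if len(df) <= X.shape[1]:
        raise np.linalg.LinAlgError(
            f"n={len(df)} rows cannot identify {X.shape[1]} coefficients")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"most collinear pair: {names[i]} ~ {names[j]}")

    y = df[target].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    stud = fit.get_influence().resid_studentized_internal
    inliers = np.abs(stud) <= outlier_sigma
    n_out = int((~inliers).sum())
    df2, X2, y2 = df.loc[inliers], X[inliers], y[inliers]
    fit2 = sm.OLS(y2, X2).fit()

    resid = y2 - fit2.predict(X2)
    residual_sd, degenerate = {}, False
    for lv in levels:
        r = resid[(df2["level_name"] == lv).to_numpy()]
        s = float(np.std(r, ddof=1)) if r.size > 1 else 0.0
        residual_sd[lv] = s
        if s <= 1e-10:
            degenerate = True

    model = SpondyModel(
        target=target,
        coefficients=dict(zip(names, (float(c) for c in fit2.params))),
        residual_sd=residual_sd,
        provenance={
            "n_training": int(len(df2)), "n_outliers_removed": n_out,
            "positions": sorted(map(str, set(df.get("position", pd.Series([])).dropna()))),
            "seed": seed, "r_squared": float(fit2.rsquared),
        },
        degenerate=degenerate,
    )
    model.results_ = fit2          # diagnostics only; not serialized
    model.predictor_names_ = names
    return model


def spondy_predict(metrics: pd.DataFrame, model: SpondyModel) -> np.ndarray:
    """Predicted normal SPO for each row of a metrics table."""
    predictors = [k for k in model.coefficients if not k.startswith("level_")]
    levels = [k[len("level_"):] for k in model.coefficients if k.startswith("level_")]
    unseen = set(metrics["level_name"]) - set(levels)
    if unseen:
        raise UnseenLevelError(f"levels not present in training data: {sorted(unseen)}")
    X = _design(metrics, predictors, levels)
    beta = np.array([model.coefficients[k] for k in (*predictors,
                                                     *[f"level_{lv}" for lv in levels])])
    return X @ beta


def spondy_index(metrics: pd.DataFrame, model: SpondyModel) -> pd.Series:
    """(observed − predicted normal SPO) / per-level residual SD."""
    pred = spondy_predict(metrics, model)
    lv = metrics["level_name"].to_numpy()
    sd = np.array([model.residual_sd[l] for l in lv])
    if np.any(sd <= 0):
        bad = sorted(set(lv[sd <= 0]))
        raise ValueError(f"non-positive residual sd for levels {bad}")
    obs = metrics[model.target].to_numpy(dtype=float)
    name = "ant_si" if model.target == "aspo" else "pst_si"
    return pd.Series((obs - pred) / sd, index=metrics.index, name=name)


def spine_summary(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-subject extrema: max AntSI, max PstSI, min z(avg disc height).

    Expects per-level rows with subject_id and any of ant_si, pst_si,
    z_avg_dh; missing levels are simply absent from the extrema.
    """
    if "subject_id" not in scored.columns:
        raise ValueError("spine_summary needs a subject_id column")
    agg = {}
    if "ant_si" in scored.columns:
        agg["max_ant_si"] = ("ant_si", "max")
    if "pst_si" in scored.columns:
        agg["max_pst_si"] = ("pst_si", "max")
    if "z_avg_dh" in scored.columns:
        agg["min_z_avg_dh"] = ("z_avg_dh", "min")
    if not agg:
        raise ValueError("no score columns (ant_si/pst_si/z_avg_dh) to summarize")
    return scored.groupby("subject_id").agg(**agg).reset_index()


def outcome_association(summaries: pd.DataFrame, back_pain) -> pd.DataFrame:
    """Univariable logistic regression of back pain on each spine summary.

    Returns odds ratio per unit, Wald p-value and McFadden pseudo-R² for each
    summary column.  Degenerate outcomes (single class) and perfect
    separation raise.
    """
    y = np.asarray(back_pain, dtype=float)
    if len(y) != len(summaries):
        raise ValueError("back_pain length mismatch")
    if len(y) < 50:
        raise ValueError("outcome_association needs n >= 50")
    if y.min() == y.max():
        raise ValueError("back pain outcome has a single class; association undefined")
    rows = []
    for col in summaries.columns:
        if col == "subject_id":
            continue
        x = summaries[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        X = sm.add_constant(x[ok])
        try:
            fit = sm.Logit(y[ok], X).fit(disp=0)
        except Exception as e:  # PerfectSeparation and kin
            raise RuntimeError(
                f"logistic fit failed for {col} ({e}); a penalized fit would be "
                "needed for separated data") from e
        rows.append({
            "summary": col,
            "odds_ratio": float(np.exp(fit.params[1])),
            "p_value": float(fit.pvalues[1]),
            "mcfadden_r2": float(1.0 - fit.llf / fit.llnull),
            "n": int(ok.sum()),
        })
    return pd.DataFrame(rows)
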