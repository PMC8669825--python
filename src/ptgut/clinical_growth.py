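"""Feeding categories, growth-velocity models, and clinical statistics.

Weekly milk volumes map each sample-week onto one of six feeding
categories (human milk vs formula predominance, crossed with fortifier
use).  Growth is summarised as weight-gain velocity (g/d) between
consecutive weighings and modelled as a linear mixed model on corrected
gestational age with per-infant random intercepts and slopes, optionally
restricted to weeks on a given fortifier.  Fisher exact and Spearman
utilities back the contingency and correlation analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .io_tables import CohortMetadata, ValidationError

__all__ = [
    "FEEDING_CATEGORIES",
    "assign_feeding_category",
    "feeding_categories",
    "weight_gain_velocity",
    "velocity_table",
    "GrowthFit",
    "fit_growth_model",
    "fisher_exact",
    "spearman",
    "correlate_velocity_abundance",
]

FEEDING_CATEGORIES = (
    "Human milk - none",
    "Human milk + HMF",
    "Human milk + BMF",
    "Human milk + both",
    "Formula + BMF",
    "Formula",
)

_HM_BY_FORTIFIER = {
    "none": "Human milk - none",
    "HMF": "Human milk + HMF",
    "BMF": "Human milk + BMF",
    "both": "Human milk + both",
}


def assign_feeding_category(vol_mom: float, vol_dhm: float, vol_formula: float,
                            fortifier: str) -> str:
    """Map one week's milk volumes and fortifier to a feeding category.

    Mother's own and donor milk are pooled as human milk (HM); the HM
    branch applies iff the HM volume fraction strictly exceeds 0.5 (an
    exact 50/50 split is predominantly-formula).  Formula-branch weeks can
    only carry a bovine fortifier or none: human-milk-based fortifier is
    added to HM, so HMF with formula predominance is a data error.
    """
    vols = np.array([vol_mom, vol_dhm, vol_formula], dtype=float)
    if (vols < 0).any():
        raise ValueError("negative milk volume")
    total = vols.sum()
    if total <= 0:
        raise ValueError("zero total milk volume")
    hm_frac = (vols[0] + vols[1]) / total
    if fortifier not in _HM_BY_FORTIFIER:
        raise ValidationError(f"unknown fortifier {fortifier!r}")
    if hm_frac > 0.5:
        return _HM_BY_FORTIFIER[fortifier]
    if fortifier in ("HMF", "both"):
        raise ValidationError(
            f"fortifier {fortifier!r} with predominant formula feeding has no "
            "defined category"
        )
    return "Formula + BMF" if fortifier == "BMF" else "Formula"


def feeding_categories(meta: CohortMetadata) -> pd.DataFrame:
    """Per-sample feeding category from the metadata volume columns.

    Samples with missing volumes or fortifier get a missing category.
    """
    rows = []
    for _, r in meta.samples.iterrows():
        try:
            cat = assign_feeding_category(
                r["vol_mom"], r["vol_dhm"], r["vol_formula"], r["fortifier"]
            )
        except (ValueError, ValidationError, TypeError):
            cat = np.nan
        rows.append({"sample_id": r["sample_id"], "feeding_category": cat})
    return pd.DataFrame(rows)


def weight_gain_velocity(weights, times_days) -> np.ndarray:
    """Consecutive-pair growth velocities (g/d) from a timed weight series."""
    w = np.asarray(weights, dtype=float)
    t = np.asarray(times_days, dtype=float)
    if w.shape != t.shape:
        raise ValueError("weights and times must align")
    if len(w) < 2:
        return np.empty(0)
    dt = np.diff(t)
    if (dt <= 0).any():
        raise ValueError("times must be strictly increasing")
    return np.diff(w) / dt


def velocity_table(meta: CohortMetadata, include_birth: bool = True
                   ) -> pd.DataFrame:
    """Per-interval growth velocities for the whole cohort.

    Each infant's weighed samples are ordered by postnatal age; every
    consecutive pair yields one velocity, attributed to the *later* sample
    (so the interval inherits that week's fortifier and feeding category).
    With ``include_birth`` the birth weight anchors a week-0 observation,
    adding the birth-to-first-weighing interval.
    """
    out = []
    cols = ["sample_id", "infant_id", "postnatal_age", "corrected_ga",
            "weight", "fortifier"]
    df = meta.samples[cols].dropna(subset=["postnatal_age", "weight"])
    birth = meta.infants.set_index("infant_id")["birth_weight"]
    for infant, grp in df.groupby("infant_id", sort=True):
        grp = grp.sort_values(["postnatal_age", "sample_id"], kind="stable")
        weights = grp["weight"].to_numpy()
        times = grp["postnatal_age"].to_numpy() * 7.0
        first = 1
        if include_birth and pd.notna(birth.get(infant)) and times.min() > 0:
            weights = np.concatenate([[birth[infant]], weights])
            times = np.concatenate([[0.0], times])
            first = 0
        if len(weights) < 2:
            continue
        vel = weight_gain_velocity(weights, times)
        for i, v in enumerate(vel, start=first):
            r = grp.iloc[i]
            out.append({
                "sample_id": r["sample_id"], "infant_id": infant,
                "corrected_ga": r["corrected_ga"], "velocity": v,
                "fortifier": r["fortifier"],
            })
    return pd.DataFrame(out, columns=["sample_id", "infant_id", "corrected_ga",
                                      "velocity", "fortifier"])


@dataclass
class GrowthFit:
    """Linear mixed-model fit of growth velocity on corrected GA."""

    stratum: str
    intercept: float          # g/d at ga_center weeks corrected GA
    slope: float              # g/d per week corrected GA
    slope_se: float
    slope_ci: tuple[float, float]
    intercept_se: float
    var_random_intercept: float
    var_random_slope: float
    var_residual: float
    ga_center: float
    n_obs: int
    n_infants: int
    infant_effects: pd.DataFrame  # per-infant predicted random deviations

    def predict(self, corrected_ga) -> np.ndarray:
        ga = np.asarray(corrected_ga, dtype=float)
        return self.intercept + self.slope * (ga - self.ga_center)


def fit_growth_model(velocities: pd.DataFrame, stratum: str | None = None,
                     ga_center: float | None = None) -> GrowthFit:
    """Fit velocity = b0 + b1 (cGA - center) + per-infant random
    intercept/slope + noise, by REML.

    Parameters
    ----------
    velocities : output of :func:`velocity_table` (columns infant_id,
        corrected_ga, velocity, fortifier).
    stratum : restrict to intervals on this fortifier (``"HMF"``/``"BMF"``);
        ``None`` fits all intervals.
    ga_center : centre of the corrected-GA axis; defaults to the sample
        mean (centering only shifts the intercept, for conditioning).
    """
    df = velocities.dropna(subset=["corrected_ga", "velocity"]).copy()
    if stratum is not None:
        df = df[df["fortifier"] == stratum]
    counts = df.groupby("infant_id").size()
    keep = counts[counts >= 2].index
    df = df[df["infant_id"].isin(keep)]
    if df["infant_id"].nunique() < 2:
        raise ValueError("need >= 2 infants with >= 2 velocity observations")
    if ga_center is None:
        ga_center = float(df["corrected_ga"].mean())
    df["ga_c"] = df["corrected_ga"] - ga_center

    # degenerate case: an exact common line (zero residual variance) breaks
    # REML at the boundary; ordinary least squares is then the exact answer
    x = np.column_stack([np.ones(len(df)), df["ga_c"].to_numpy()])
    y = df["velocity"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    if np.max(np.abs(resid)) < 1e-10 * max(1.0, np.max(np.abs(y))):
        return GrowthFit(
            stratum=stratum or "overall", intercept=float(beta[0]),
            slope=float(beta[1]), slope_se=0.0,
            slope_ci=(float(beta[1]), float(beta[1])),
            intercept_se=0.0, var_random_intercept=0.0, var_random_slope=0.0,
            var_residual=0.0, ga_center=ga_center, n_obs=len(df),
            n_infants=int(df["infant_id"].nunique()),
            infant_effects=pd.DataFrame(
                {"infant_id": sorted(df["infant_id"].unique())}),
        )

    # random intercept and random slope as independent variance components:
    # the model specifies their variances, not a covariance, and the
    # uncorrelated parameterisation is far better conditioned on short
    # per-infant series
    model = MixedLM.from_formula(
        "velocity ~ ga_c", groups="infant_id", re_formula="1",
        vc_formula={"ga_slope": "0 + ga_c"}, data=df,
    )
    res = None
    last = None
    for method in ("lbfgs", "bfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cand = model.fit(reml=True, method=method, disp=False)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last = str(exc)
            continue
        if np.isfinite(cand.fe_params).all() and np.isfinite(cand.bse_fe).all():
            res = cand
            break
        last = (f"non-finite estimates (variance trace: "
                f"cov_re={cand.cov_re.values.tolist()}, "
                f"vcomp={cand.vcomp.tolist()}, scale={cand.scale})")
    if res is None:
        raise RuntimeError(f"growth model failed to converge: {last}")
    slope = float(res.fe_params["ga_c"])
    se = float(res.bse_fe["ga_c"])
    ci = (slope - 1.959963984540054 * se, slope + 1.959963984540054 * se)
    ranef = pd.DataFrame(
        [{"infant_id": g, **dict(v)} for g, v in res.random_effects.items()]
    )
    return GrowthFit(
        stratum=stratum or "overall",
        intercept=float(res.fe_params["Intercept"]),
        slope=slope,
        slope_se=se,
        slope_ci=ci,
        intercept_se=float(res.bse_fe["Intercept"]),
        var_random_intercept=float(res.cov_re.iloc[0, 0]),
        var_random_slope=float(res.vcomp[0]) if len(res.vcomp) else 0.0,
        var_residual=float(res.scale),
        ga_center=ga_center,
        n_obs=len(df),
        n_infants=int(df["infant_id"].nunique()),
        infant_effects=ranef,
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sided by the probability-mass rule: the sum of hypergeometric
    probabilities of all tables (with the observed margins) no more likely
    than the observed one.  Both margins must be positive.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if not np.all(np.equal(np.mod(t, 1), 0)) or (t < 0).any():
            raise ValueError("table must hold non-negative integers")
        t = t.astype(np.int64)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation and large-sample p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rho undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def correlate_velocity_abundance(relab, velocities: pd.DataFrame,
                                 taxa=None, stratum: str | None = None
                                 ) -> pd.DataFrame:
    """Spearman correlation of taxon abundance with growth velocity.

    Joins the relative-abundance table to the velocity table on sample id
    (each velocity interval already carries its week's fortifier), restricts
    to ``stratum`` if given, and reports rho/p per taxon.
    """
    frame = relab.to_dataframe() if hasattr(relab, "to_dataframe") else relab
    df = velocities.dropna(subset=["velocity"])
    if stratum is not None:
        df = df[df["fortifier"] == stratum]
    df = df[df["sample_id"].isin(frame.index)]
    if taxa is None:
        taxa = list(frame.columns)
    rows = []
    for taxon in taxa:
        ab = frame.loc[df["sample_id"], taxon].to_numpy()
        vel = df["velocity"].to_numpy()
        try:
            rho, p = spearman(ab, vel)
        except ValueError:
            rho, p = np.nan, np.nan
        rows.append({"taxon": taxon, "stratum": stratum or "overall",
                     "rho": rho, "p": p, "n": len(df)})
    return pd.DataFrame(rows)
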