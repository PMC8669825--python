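"""Differential abundance: LDA effect size and per-taxon mixed models.

Two complementary analyses of which genera track a covariate:

* :func:`lda_effect_size` — a two-stage biomarker screen in the LefSe
  style: a Kruskal-Wallis class test per taxon, then a one-dimensional
  linear-discriminant effect size on the log10 scale, averaged over
  bootstrap resamples, reported above a threshold (default 2.0 on
  abundances scaled by 1e6).  The subclass (Wilcoxon) stage of the original
  tool is deliberately omitted: the two-enterotype design has no subclass
  structure.

* :func:`per_taxon_lmm` — per-taxon linear mixed models of the
  arcsine-square-root-transformed abundance on perinatal, anthropometric
  and dietary fixed effects with a per-infant random intercept (REML),
  Wald tests per term, and Benjamini-Hochberg correction across taxa
  within each term.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .diversity import RelAbundanceTable

__all__ = [
    "kruskal_wallis",
    "bh_fdr",
    "lda_effect_size",
    "per_taxon_lmm",
    "FEEDING_REFERENCE",
]

log = logging.getLogger("ptgut.differential")

#: Reference level for the six-level feeding factor (unfortified human milk).
FEEDING_REFERENCE = "Human milk - none"

#: LefSe-convention scale applied to relative abundances before the
#: discriminant step, so the default score threshold of 2.0 is meaningful.
LDA_ABUNDANCE_SCALE = 1e6


def kruskal_wallis(groups) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with tie correction and chi-square p.

    ``groups`` is a sequence of >= 2 one-dimensional samples.  If every
    value across all groups is identical the statistic is 0 and p = 1 by
    convention (scipy would raise on the 0/0 tie correction).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} (m p_(j) / j) over the sorted p-values, mapped back
    to input order; monotone non-decreasing in p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def lda_effect_size(relab: RelAbundanceTable | pd.DataFrame, classes,
                    alpha: float = 0.05, lda_threshold: float = 2.0,
                    n_boot: int = 30, seed: int = 0) -> pd.DataFrame:
    """Class-discriminating taxa by Kruskal-Wallis + LDA effect size.

    Stage 1 keeps taxa whose two-class Kruskal-Wallis p < ``alpha``.
    Stage 2 scores each survivor with the absolute projected class-mean
    difference of its (abundance x 1e6) values along the one-dimensional
    Fisher discriminant — for a single feature the discriminant axis is the
    feature itself, so the projection reduces to the scaled class-mean
    difference — averaged over ``n_boot`` within-class bootstrap resamples;
    the effect size is log10(max(difference, 1)).  Rows with effect size
    >= ``lda_threshold`` are reported, tagged with the class of higher mean.
    """
    if isinstance(relab, RelAbundanceTable):
        frame = relab.to_dataframe()
    else:
        frame = relab
    classes = np.asarray(classes)
    if len(classes) != frame.shape[0]:
        raise ValueError("classes must align with samples")
    uniq = np.unique(classes)
    if len(uniq) != 2:
        raise ValueError(f"exactly 2 classes required, got {len(uniq)}")
    masks = {c: classes == c for c in uniq}
    if any(m.sum() < 3 for m in masks.values()):
        raise ValueError("each class needs >= 3 samples")

    x = frame.to_numpy(dtype=float)
    # each class's bootstrap stream is keyed by its sample-membership mask,
    # so swapping the class labels swaps the streams with them and the
    # scores are exactly invariant
    import zlib

    def class_rng(mask, j):
        key = zlib.crc32(np.packbits(mask).tobytes())
        return np.random.default_rng(np.random.SeedSequence([seed, j, key]))

    rows = []
    for j, taxon in enumerate(frame.columns):
        g0, g1 = x[masks[uniq[0]], j], x[masks[uniq[1]], j]
        _, p = kruskal_wallis([g0, g1])
        if p >= alpha:
            continue
        rng0 = class_rng(masks[uniq[0]], j)
        rng1 = class_rng(masks[uniq[1]], j)
        m0 = np.array([rng0.choice(g0, size=len(g0), replace=True).mean()
                       for _ in range(n_boot)])
        m1 = np.array([rng1.choice(g1, size=len(g1), replace=True).mean()
                       for _ in range(n_boot)])
        diffs = np.abs(m0 - m1) * LDA_ABUNDANCE_SCALE
        score = float(np.log10(max(diffs.mean(), 1.0)))
        if score < lda_threshold:
            continue
        enriched = uniq[0] if g0.mean() >= g1.mean() else uniq[1]
        rows.append({
            "taxon": taxon, "enriched_class": enriched,
            "lda_score": score, "kw_p": p,
        })
    out = pd.DataFrame(rows, columns=["taxon", "enriched_class", "lda_score", "kw_p"])
    return out.sort_values("lda_score", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Per-taxon linear mixed models
# ---------------------------------------------------------------------------

def _formula_term(term: str, data: pd.DataFrame) -> str:
    col = data[term]
    if pd.api.types.is_numeric_dtype(col):
        return term
    levels = set(col.dropna().astype(str))
    if FEEDING_REFERENCE in levels:
        return f"C(Q('{term}'), Treatment('{FEEDING_REFERENCE}'))"
    return f"C(Q('{term}'))"


def per_taxon_lmm(transformed: pd.DataFrame, meta: pd.DataFrame,
                  fixed_terms: list[str], group_col: str = "infant_id",
                  ) -> tuple[pd.DataFrame, list[dict]]:
    """Per-taxon linear mixed model with a random intercept per infant.

    Parameters
    ----------
    transformed : DataFrame, samples x taxa, arcsine-sqrt scale, indexed by
        sample id (or with a ``sample_id`` column).
    meta : per-sample covariates including ``group_col`` and every term in
        ``fixed_terms``; aligned to ``transformed`` by sample id.
    fixed_terms : covariate names entering as fixed effects.  Categorical
        terms are treatment-coded; the feeding factor uses
        ``"Human milk - none"`` as reference when present.

    Returns
    -------
    associations : tidy frame (taxon, term, coef, p, q) with q from
        Benjamini-Hochberg across taxa within each term.
    flagged : list of {taxon, reason} for zero-variance or non-converged
        taxa, which are excluded from the FDR family.
    """
    if "sample_id" in transformed.columns:
        transformed = transformed.set_index("sample_id")
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    meta = meta.loc[transformed.index]

    data = meta[[group_col] + list(fixed_terms)].copy()
    complete = data.notna().all(axis=1)
    if complete.sum() < 4:
        raise ValueError("too few complete observations")
    data = data[complete]
    y_all = transformed.loc[complete.to_numpy()]
    groups = data[group_col].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 infants")

    rhs = " + ".join(_formula_term(t, data) for t in fixed_terms)
    formula = f"__y__ ~ {rhs}"

    # pre-flight design check on the full data; rank deficiency is a user
    # error (aliased terms), not a per-taxon condition
    probe = data.copy()
    probe["__y__"] = 0.0
    from patsy import dmatrices
    _, exog = dmatrices(formula, probe, return_type="dataframe")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {exog.shape[1]}): check for "
            f"aliased terms among {fixed_terms}"
        )

    # standardise numeric covariates for optimizer conditioning; report
    # coefficients back on the covariate's original units
    scales: dict[str, float] = {}
    for term in fixed_terms:
        col = data[term]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            sd = float(col.std())
            if sd > 0:
                data[term] = (col - col.mean()) / sd
                scales[term] = sd

    rows = []
    flagged: list[dict] = []
    for taxon in y_all.columns:
        y = y_all[taxon].to_numpy(dtype=float)
        if np.allclose(y.var(), 0):
            flagged.append({"taxon": taxon, "reason": "zero variance"})
            continue
        frame = data.copy()
        frame["__y__"] = y
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM.from_formula(formula, groups=group_col, data=frame)
                try:
                    res = model.fit(reml=True, method="lbfgs", disp=False)
                except np.linalg.LinAlgError:
                    # lbfgs can hit a singular Hessian near the variance
                    # boundary; the default optimizer cascade is more robust
                    res = model.fit(reml=True, disp=False)
            ok = (np.isfinite(res.fe_params).all()
                  and np.isfinite(res.bse_fe).all()
                  and (res.bse_fe.drop("Intercept", errors="ignore") > 0).all())
            if not ok:
                raise np.linalg.LinAlgError("non-finite standard errors")
        except (np.linalg.LinAlgError, ValueError) as exc:
            log.info("taxon %r: mixed model not converged (%s)", taxon, exc)
            flagged.append({"taxon": taxon, "reason": f"not converged: {exc}"})
            continue
        for name in res.fe_params.index:
            if name == "Intercept":
                continue
            scale = scales.get(name, 1.0)
            rows.append({
                "taxon": taxon, "term": name,
                "coef": float(res.fe_params[name]) / scale,
                "p": float(res.pvalues[name]),
            })

    assoc = pd.DataFrame(rows, columns=["taxon", "term", "coef", "p"])
    if len(assoc):
        assoc["q"] = np.nan
        for term, idx in assoc.groupby("term").groups.items():
            assoc.loc[idx, "q"] = bh_fdr(assoc.loc[idx, "p"].to_numpy())
    else:
        assoc["q"] = []
    return assoc, flagged
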