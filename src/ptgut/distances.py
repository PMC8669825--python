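"""Beta diversity: Jensen-Shannon distance, UniFrac, and PERMANOVA.

The enterotype workflow clusters samples on the Jensen-Shannon distance,
d(a, b) = sqrt(JS(a, b)) with natural logarithms, which is a metric bounded
by sqrt(ln 2).  Phylogenetic dissimilarity uses unweighted and weighted
UniFrac on a rooted tree (scikit-bio backend).  Community-covariate
association uses PERMANOVA with sequential (Type-I) sums of squares in the
style of vegan's ``adonis``, with free permutation of sample labels and the
small-sample ``+1`` p-value correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import skbio
from numpy.linalg import matrix_rank, pinv
from scipy.spatial.distance import cdist
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity

from .diversity import RelAbundanceTable
from .io_tables import TaxaCountTable, ValidationError, check_tree_covers_taxa

__all__ = [
    "jsd_matrix",
    "unweighted_unifrac",
    "weighted_unifrac",
    "permanova",
    "pcoa_coordinates",
    "MAX_JS_DISTANCE",
]

#: Upper bound of the Jensen-Shannon distance with natural logarithms.
MAX_JS_DISTANCE = float(np.sqrt(np.log(2.0)))


def _entropy_nats(p: np.ndarray) -> np.ndarray:
    """Row-wise Shannon entropy in nats with the 0 log 0 := 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return -plogp.sum(axis=-1)


def jsd_matrix(relab: RelAbundanceTable) -> DistanceMatrix:
    """Pairwise Jensen-Shannon distance sqrt(JS) between all samples.

    JS(a, b) = H(m) - (H(a) + H(b)) / 2 with m = (a + b)/2, equivalent to
    the symmetrised Kullback-Leibler form (1/2)KL(a||m) + (1/2)KL(b||m).
    """
    p = relab.proportions
    n = p.shape[0]
    h = _entropy_nats(p)
    # pairwise mixture entropies via broadcasting; fine at cohort scale
    m = 0.5 * (p[:, None, :] + p[None, :, :])
    hm = _entropy_nats(m)
    js = hm - 0.5 * (h[:, None] + h[None, :])
    js = np.clip(js, 0.0, None)
    d = np.sqrt(js)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # remove floating-point asymmetry
    return DistanceMatrix(d, ids=relab.sample_ids)


def _rooted_bifurcating(tree: skbio.TreeNode) -> skbio.TreeNode:
    """Copy of ``tree`` with multifurcations resolved by zero-length
    branches.  The inserted branches have length 0, so both UniFrac
    variants are unchanged; this fixes a root for branch enumeration."""
    if all(len(n.children) <= 2 for n in tree.traverse(include_self=True)):
        return tree
    out = tree.copy()
    out.bifurcate(insert_length=0.0)
    return out


def unweighted_unifrac(table: TaxaCountTable, tree: skbio.TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: unshared / total branch length of present taxa."""
    check_tree_covers_taxa(tree, table.taxon_ids)
    return beta_diversity(
        "unweighted_unifrac",
        table.counts,
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=_rooted_bifurcating(tree),
    )


def _branch_table(tree: skbio.TreeNode, taxon_ids) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and branch x taxon descendant-indicator matrix."""
    col = {t: j for j, t in enumerate(taxon_ids)}
    lengths, indicators = [], []
    for node in tree.postorder(include_self=False):
        length = node.length or 0.0
        mask = np.zeros(len(taxon_ids), dtype=bool)
        for tip in ([node] if node.is_tip() else node.tips()):
            if tip.name in col:
                mask[col[tip.name]] = True
        lengths.append(length)
        indicators.append(mask)
    return np.asarray(lengths, dtype=float), np.asarray(indicators)


def weighted_unifrac(relab: RelAbundanceTable, tree: skbio.TreeNode,
                     normalized: bool = True) -> DistanceMatrix:
    """Weighted UniFrac on relative abundances.

    Raw value is sum over branches of length x |A_b - B_b| where A_b is the
    fraction of sample A descending from the branch; the normalized variant
    divides by sum of length x (A_b + B_b) and lies in [0, 1].  Computed
    directly on float proportions (branch-mass tally), so no precision is
    lost to integer counts.
    """
    check_tree_covers_taxa(tree, relab.taxon_ids)
    lengths, indic = _branch_table(tree, relab.taxon_ids)
    # branch mass per sample, pre-scaled by branch length: w-weighted L1
    # distance equals plain L1 on the scaled coordinates
    mass = relab.proportions @ indic.T          # (n_samples, n_branches)
    scaled = mass * lengths[None, :]
    raw = cdist(scaled, scaled, metric="cityblock")
    if normalized:
        s = scaled.sum(axis=1)
        denom = s[:, None] + s[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, raw / denom, 0.0)
    else:
        d = raw
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(d, ids=relab.sample_ids)


# ---------------------------------------------------------------------------
# PERMANOVA (adonis-style, sequential SS)
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = a.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def _design_columns(values: pd.Series) -> np.ndarray:
    """Design-matrix columns for one term: dummies for factors, the column
    itself for numeric covariates."""
    if pd.api.types.is_numeric_dtype(values) and values.nunique() > 2:
        return values.to_numpy(dtype=float)[:, None]
    dummies = pd.get_dummies(values.astype("category"), drop_first=True)
    return dummies.to_numpy(dtype=float)


def permanova(dist: DistanceMatrix, covariates: pd.DataFrame,
              terms: list[str] | None = None, n_perm: int = 999,
              seed: int = 0) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a distance matrix.

    Terms enter sequentially in the given order (Type-I sums of squares), so
    each term's R^2 is conditional on the terms before it, matching the
    reference ``adonis`` behaviour for multi-factor models.  Labels are
    permuted freely (no strata); p = (1 + #{F* >= F}) / (1 + n_perm).

    Parameters
    ----------
    dist : skbio.DistanceMatrix
    covariates : DataFrame indexed or ordered like ``dist.ids`` (a
        ``sample_id`` column is used to align when present).  Samples with a
        missing value in any requested term are dropped listwise.
    terms : covariate column names, in entry order (default: all columns).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cov = covariates.copy()
    if "sample_id" in cov.columns:
        cov = cov.set_index("sample_id")
    if not cov.index.equals(pd.Index(dist.ids)):
        cov = cov.loc[list(dist.ids)]
    if terms is None:
        terms = list(cov.columns)
    cov = cov[terms]
    keep = cov.notna().all(axis=1).to_numpy()
    if keep.sum() < 3:
        raise ValueError("fewer than 3 samples with complete covariates")
    if not keep.all():
        dist = dist.filter(np.asarray(dist.ids)[keep])
        cov = cov.loc[keep]
    n = len(dist.ids)
    d = dist.data
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances")

    g = _gower_center(d)
    ss_total = float(np.trace(g))
    if ss_total <= 0:
        raise ValueError("degenerate distance matrix: zero total sum of squares")

    # nested projections: H_0 (intercept) up to H_q (all terms)
    ones = np.ones((n, 1))
    x = ones
    hats = [x @ pinv(x.T @ x) @ x.T]
    ranks = [1]
    for term in terms:
        col = cov[term]
        if col.nunique(dropna=True) < 2:
            raise ValueError(f"term {term!r} is constant")
        x = np.hstack([x, _design_columns(col)])
        hats.append(x @ pinv(x.T @ x) @ x.T)
        ranks.append(matrix_rank(x))
    df_terms = np.diff(ranks)
    if (df_terms == 0).any():
        bad = terms[int(np.argmax(df_terms == 0))]
        raise ValueError(f"term {bad!r} is aliased with preceding terms")
    df_res = n - ranks[-1]
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")

    # per-term contrast matrices M_j = H_j - H_{j-1}; residual M = I - H_q
    contrasts = [hats[j + 1] - hats[j] for j in range(len(terms))]
    m_res = np.eye(n) - hats[-1]

    def stats(gmat: np.ndarray):
        ss = np.array([float(np.sum(c * gmat)) for c in contrasts])
        ss_res = float(np.sum(m_res * gmat))
        f = (ss / df_terms) / (ss_res / df_res)
        return ss, ss_res, f

    ss_obs, ss_res_obs, f_obs = stats(g)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms), dtype=np.int64)
    chunk = max(1, min(n_perm, int(2e7 / (n * n))))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.array([rng.permutation(n) for _ in range(b)])
        gp = g[perms[:, :, None], perms[:, None, :]]  # (b, n, n)
        ss_p = np.stack([np.einsum("pij,ij->p", gp, c) for c in contrasts])
        ss_res_p = np.einsum("pij,ij->p", gp, m_res)
        f_p = (ss_p / df_terms[:, None]) / (ss_res_p / df_res)
        exceed += (f_p >= f_obs[:, None] - 1e-12).sum(axis=1)
        done += b
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for j, term in enumerate(terms):
        rows.append({
            "term": term, "df": int(df_terms[j]), "ss": ss_obs[j],
            "pseudo_F": f_obs[j], "R2": ss_obs[j] / ss_total,
            "p": pvals[j], "n_perm": n_perm,
        })
    rows.append({
        "term": "Residual", "df": int(df_res), "ss": ss_res_obs,
        "pseudo_F": np.nan, "R2": ss_res_obs / ss_total,
        "p": np.nan, "n_perm": n_perm,
    })
    rows.append({
        "term": "Total", "df": n - 1, "ss": ss_total, "pseudo_F": np.nan,
        "R2": 1.0, "p": np.nan, "n_perm": n_perm,
    })
    return pd.DataFrame(rows)


def pcoa_coordinates(dist: DistanceMatrix, n_axes: int = 3) -> pd.DataFrame:
    """Principal-coordinate axes of the distance matrix (for ordination
    plots); returns the leading ``n_axes`` coordinates per sample."""
    from skbio.stats.ordination import pcoa

    res = pcoa(dist, number_of_dimensions=n_axes)
    coords = res.samples.iloc[:, :n_axes].copy()
    coords.columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    coords.insert(0, "sample_id", list(dist.ids))
    return coords.reset_index(drop=True)
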