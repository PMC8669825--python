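"""Enterotype discovery and longitudinal transition analysis.

Samples are clustered on the Jensen-Shannon distance with Partitioning
Around Medoids (PAM).  The number of clusters is chosen by maximising a
Calinski-Harabasz index formulated directly on the distance matrix (no
coordinates are available for a non-Euclidean dissimilarity), and the
chosen k is sanity-checked with the mean silhouette width.  Fitted labels
are then ordered in time per infant to classify infants as stable or
enterotype "changers" and to tabulate covariates before and after each
switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .diversity import RelAbundanceTable
from .distances import jsd_matrix
from .io_tables import CohortMetadata, ValidationError

__all__ = [
    "pam",
    "calinski_harabasz",
    "silhouette",
    "EnterotypeFit",
    "fit_enterotypes",
    "detect_transitions",
    "compare_enterotypes",
    "WEAK_STRUCTURE_SILHOUETTE",
]

#: Mean silhouette below which a clustering is flagged as weak structure.
WEAK_STRUCTURE_SILHOUETTE = 0.25

_ESCHERICHIA = "Escherichia-Shigella"


def _as_matrix(dist) -> np.ndarray:
    d = dist.data if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances")
    return d


# ---------------------------------------------------------------------------
# PAM (k-medoids, BUILD + SWAP)
# ---------------------------------------------------------------------------

def pam(dist, k: int, seed: int = 0) -> tuple[np.ndarray, list[int]]:
    """Classic PAM on a distance matrix.

    BUILD greedily seeds ``k`` medoids minimising total point-to-nearest-
    medoid distance; SWAP then exchanges a medoid with a non-medoid while
    the total cost strictly decreases.  Fully deterministic: ties are
    broken toward the lowest sample index (``seed`` is accepted for
    interface uniformity but unused).

    Returns
    -------
    labels : ndarray of int in [0, k), aligned to the distance-matrix order.
    medoids : sorted list of medoid row indices.
    """
    d = _as_matrix(dist)
    n = d.shape[0]
    if not (2 <= k <= n - 1):
        raise ValueError(f"k={k} outside [2, n-1] for n={n}")

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=0)))]
    d1 = d[:, medoids[0]].copy()  # distance to nearest medoid
    while len(medoids) < k:
        gains = np.maximum(d1[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        cand = int(np.argmax(gains))  # argmax takes the lowest index on ties
        medoids.append(cand)
        d1 = np.minimum(d1, d[:, cand])

    medoids = sorted(medoids)

    # SWAP
    while True:
        med = np.array(medoids)
        dm = d[:, med]                    # (n, k)
        order = np.argsort(dm, axis=1, kind="stable")
        nearest = order[:, 0]
        d1 = dm[np.arange(n), nearest]
        d2 = dm[np.arange(n), order[:, 1]]

        best = (0.0, None, None)
        non_med = np.setdiff1d(np.arange(n), med)
        for mi, m in enumerate(med):
            in_m = nearest == mi
            # points losing medoid m: reassigned to min(second-nearest, h)
            loss = np.minimum(d[in_m][:, non_med], d2[in_m, None]).sum(axis=0) \
                - d1[in_m].sum()
            # points keeping their medoid may defect to h if closer
            gain = np.minimum(d[~in_m][:, non_med] - d1[~in_m, None], 0.0).sum(axis=0)
            delta = loss + gain
            j = int(np.argmin(delta))
            if delta[j] < best[0] - 1e-12:
                best = (float(delta[j]), int(m), int(non_med[j]))
        if best[1] is None:
            break
        medoids.remove(best[1])
        medoids.append(best[2])
        medoids = sorted(medoids)

    med = np.array(medoids)
    labels = np.argmin(d[:, med], axis=1)
    return labels, medoids


def total_cost(dist, medoids) -> float:
    """Total distance of every point to its nearest medoid."""
    d = _as_matrix(dist)
    return float(d[:, np.asarray(medoids)].min(axis=1).sum())


# ---------------------------------------------------------------------------
# Internal cluster-quality indices on a pure distance matrix
# ---------------------------------------------------------------------------

def _cluster_medoid(d: np.ndarray, members: np.ndarray) -> int:
    """Member minimising the summed squared distance to the other members."""
    sub = d[np.ix_(members, members)] ** 2
    return int(members[np.argmin(sub.sum(axis=1))])


def calinski_harabasz(dist, labels) -> float:
    """Calinski-Harabasz index from a distance matrix alone.

    W = sum over clusters of squared distances to the cluster medoid;
    B = sum over clusters of n_c x squared distance from the cluster medoid
    to the pseudo-global medoid (the sample minimising total squared
    distance to all samples); CH = (B / (k-1)) / (W / (n-k)).
    """
    d = _as_matrix(dist)
    labels = np.asarray(labels)
    n = d.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("need >= 2 clusters")
    if n == k:
        raise ValueError("all clusters are singletons")
    global_medoid = int(np.argmin((d ** 2).sum(axis=1)))
    w = 0.0
    b = 0.0
    for c in uniq:
        members = np.flatnonzero(labels == c)
        med = _cluster_medoid(d, members)
        w += float((d[members, med] ** 2).sum())
        b += len(members) * float(d[med, global_medoid] ** 2)
    if w == 0:
        return np.inf if b > 0 else 0.0
    return (b / (k - 1)) / (w / (n - k))


def silhouette(dist, labels) -> tuple[np.ndarray, float]:
    """Per-sample silhouette widths s(i) and their mean.

    s(i) = (b - a) / max(a, b) with a = mean within-cluster distance
    (excluding self) and b = minimum over foreign clusters of the mean
    distance to that cluster; members of singleton clusters score 0.
    """
    d = _as_matrix(dist)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires >= 2 clusters")
    n = d.shape[0]
    s = np.zeros(n)
    masks = {c: labels == c for c in uniq}
    for i in range(n):
        own = masks[labels[i]]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, masks[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


# ---------------------------------------------------------------------------
# Enterotype fitting
# ---------------------------------------------------------------------------

@dataclass
class EnterotypeFit:
    """Result of enterotype discovery.

    Clusters are numbered 1..k in decreasing size; ``names`` maps cluster
    number to an enterotype letter ("A", "B", ...).  For k = 2 the cluster
    with the higher mean Escherichia-Shigella abundance is named "A",
    following the convention that enterotype A is the
    Escherichia-Shigella-dominated state.
    """

    k: int
    sample_ids: list[str]
    labels: np.ndarray              # int, 1..k, size-ordered
    medoid_ids: list[str]
    ch_profile: dict[int, float]
    silhouette_profile: dict[int, float]
    names: dict[int, str]
    cluster_profiles: pd.DataFrame  # cluster x taxon mean relative abundance
    weak_structure: bool
    distances: DistanceMatrix = field(repr=False, default=None)

    def assignments(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "cluster": self.labels,
            "enterotype": [self.names[c] for c in self.labels],
        })

    def cluster_sizes(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in sorted(self.names)}


def fit_enterotypes(relab: RelAbundanceTable, k_range=range(2, 11),
                    seed: int = 0) -> EnterotypeFit:
    """Cluster samples on Jensen-Shannon distance and select k by CH index.

    Runs PAM for every k in ``k_range``, selects the k maximising the
    Calinski-Harabasz index (ties toward smaller k), and reports the
    silhouette profile; a mean silhouette below
    ``WEAK_STRUCTURE_SILHOUETTE`` at the chosen k sets ``weak_structure``.
    """
    n = len(relab.sample_ids)
    if n < 4:
        raise ValueError("need >= 4 samples to fit enterotypes")
    dist = jsd_matrix(relab)
    if np.allclose(dist.data, 0):
        raise ValueError("degenerate distances: all samples identical")
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range has no feasible values")

    ch_profile: dict[int, float] = {}
    sil_profile: dict[int, float] = {}
    fits: dict[int, tuple[np.ndarray, list[int]]] = {}
    for k in ks:
        labels, medoids = pam(dist, k, seed=seed)
        fits[k] = (labels, medoids)
        ch_profile[k] = calinski_harabasz(dist, labels)
        sil_profile[k] = silhouette(dist, labels)[1]

    best_k = max(ks, key=lambda k: (ch_profile[k], -k))
    labels0, medoids = fits[best_k]

    # renumber clusters 1..k in decreasing size (stable on ties)
    sizes = [( -(labels0 == c).sum(), c) for c in range(best_k)]
    order = [c for _, c in sorted(sizes)]
    renumber = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([renumber[c] for c in labels0])
    medoid_ids = [relab.sample_ids[medoids[old]] for old in order]

    profiles = pd.DataFrame(
        [relab.proportions[labels == c].mean(axis=0) for c in range(1, best_k + 1)],
        index=pd.Index(range(1, best_k + 1), name="cluster"),
        columns=relab.taxon_ids,
    )
    names = _name_clusters(profiles)
    return EnterotypeFit(
        k=best_k,
        sample_ids=list(relab.sample_ids),
        labels=labels,
        medoid_ids=medoid_ids,
        ch_profile=ch_profile,
        silhouette_profile=sil_profile,
        names=names,
        cluster_profiles=profiles,
        weak_structure=sil_profile[best_k] < WEAK_STRUCTURE_SILHOUETTE,
        distances=dist,
    )


def _name_clusters(profiles: pd.DataFrame) -> dict[int, str]:
    k = profiles.shape[0]
    letters = [chr(ord("A") + i) for i in range(k)]
    if k == 2 and _ESCHERICHIA in profiles.columns:
        es = profiles[_ESCHERICHIA]
        a_cluster = int(es.idxmax())
        b_cluster = int(es.idxmin())
        if a_cluster != b_cluster:
            return {a_cluster: "A", b_cluster: "B"}
    return {c: letters[i] for i, c in enumerate(profiles.index)}


# ---------------------------------------------------------------------------
# Longitudinal transitions
# ---------------------------------------------------------------------------

def detect_transitions(fit: EnterotypeFit, meta: CohortMetadata,
                       feeding: pd.DataFrame | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Order each infant's samples in time and record enterotype switches.

    Returns ``(transitions, infant_classes)``.  ``transitions`` has one row
    per consecutive sample pair with differing enterotypes, carrying the
    covariate snapshot before and after the switch (corrected GA, weight,
    antibiotic flag, and feeding category when ``feeding`` — a
    sample_id -> category frame — is given).  ``infant_classes`` classifies
    every infant as ``exclusively-<E>`` or ``changer``.
    """
    assign = fit.assignments()
    joined = meta.for_samples(fit.sample_ids)
    df = assign.merge(
        joined[["sample_id", "infant_id", "corrected_ga", "weight", "antibiotic"]],
        on="sample_id",
    )
    if df["corrected_ga"].isna().any():
        bad = df.loc[df["corrected_ga"].isna(), "sample_id"].tolist()
        raise ValidationError(f"samples without a time stamp: {bad[:5]}")
    if feeding is not None:
        feed_map = feeding.set_index("sample_id")["feeding_category"]
        df["feeding_category"] = df["sample_id"].map(feed_map)
    else:
        df["feeding_category"] = np.nan

    trans_rows = []
    class_rows = []
    for infant, grp in df.groupby("infant_id", sort=True):
        grp = grp.sort_values(["corrected_ga", "sample_id"], kind="stable")
        ents = grp["enterotype"].to_numpy()
        n_switch = 0
        for a, b in zip(range(len(grp) - 1), range(1, len(grp))):
            if ents[a] == ents[b]:
                continue
            n_switch += 1
            before, after = grp.iloc[a], grp.iloc[b]
            trans_rows.append({
                "infant_id": infant,
                "sample_before": before["sample_id"],
                "sample_after": after["sample_id"],
                "from_enterotype": before["enterotype"],
                "to_enterotype": after["enterotype"],
                "corrected_ga_before": before["corrected_ga"],
                "corrected_ga_after": after["corrected_ga"],
                "weight_before": before["weight"],
                "weight_after": after["weight"],
                "antibiotic_before": before["antibiotic"],
                "antibiotic_after": after["antibiotic"],
                "feeding_before": before["feeding_category"],
                "feeding_after": after["feeding_category"],
            })
        if n_switch:
            cls = "changer"
        else:
            cls = f"exclusively-{ents[0]}"
        class_rows.append({
            "infant_id": infant, "n_samples": len(grp),
            "n_transitions": n_switch, "class": cls,
        })
    transitions = pd.DataFrame(trans_rows, columns=[
        "infant_id", "sample_before", "sample_after", "from_enterotype",
        "to_enterotype", "corrected_ga_before", "corrected_ga_after",
        "weight_before", "weight_after", "antibiotic_before",
        "antibiotic_after", "feeding_before", "feeding_after"])
    classes = pd.DataFrame(class_rows)
    return transitions, classes


def transition_summary(transitions: pd.DataFrame,
                       classes: pd.DataFrame) -> dict:
    """Headline shares: fraction of changer infants and per-direction counts."""
    n_inf = len(classes)
    n_changer = int((classes["class"] == "changer").sum())
    directions = (
        transitions.groupby(["from_enterotype", "to_enterotype"]).size().to_dict()
        if len(transitions) else {}
    )
    return {
        "n_infants": n_inf,
        "n_changers": n_changer,
        "changer_share": n_changer / n_inf if n_inf else np.nan,
        "class_counts": classes["class"].value_counts().to_dict(),
        "transition_counts": directions,
    }


# ---------------------------------------------------------------------------
# Enterotype vs covariate comparison (contingency / rank tests)
# ---------------------------------------------------------------------------

_CATEGORICAL_VARS = ("maternal_race", "chorioamnionitis", "prom", "sex",
                     "delivery_mode", "antibiotic", "fortifier")
_NUMERIC_VARS = ("corrected_ga", "weight")


def compare_enterotypes(fit: EnterotypeFit, meta: CohortMetadata,
                        classes: pd.DataFrame | None = None,
                        categorical=_CATEGORICAL_VARS,
                        numeric=_NUMERIC_VARS) -> pd.DataFrame:
    """Per-covariate comparison between enterotypes, contingency style.

    Categorical covariates get a per-level one-vs-rest Fisher exact test on
    the level x enterotype 2x2 table; numeric covariates get Kruskal-Wallis
    across enterotypes.  When ``classes`` (from :func:`detect_transitions`)
    is given, two labelled "change enterotype" rows are added: samples that
    immediately precede a switch, and all samples of changer infants — the
    two readings of a per-sample change count.
    """
    import logging

    from .clinical_growth import fisher_exact
    from .differential import kruskal_wallis

    logger = logging.getLogger("ptgut.enterotyping")
    assign = fit.assignments()
    joined = meta.for_samples(fit.sample_ids)
    df = assign.merge(joined, on="sample_id")
    ents = sorted(assign["enterotype"].unique())

    rows = []

    def add_categorical(var: str, series: pd.Series):
        sub = df[["enterotype"]].copy()
        sub["v"] = series.to_numpy()
        sub = sub.dropna()
        levels = sorted(sub["v"].unique(), key=str)
        for level in levels:
            in_level = sub["v"] == level
            cells = {e: int(((sub["enterotype"] == e) & in_level).sum())
                     for e in ents}
            totals = {e: int((sub["enterotype"] == e).sum()) for e in ents}
            if len(ents) == 2 and all(totals.values()):
                a, b = ents
                table = [[cells[a], totals[a] - cells[a]],
                         [cells[b], totals[b] - cells[b]]]
                try:
                    p = fisher_exact(table)
                except ValueError:
                    p = np.nan
            else:
                p = np.nan
            rows.append({
                "variable": var, "level": str(level), "test": "fisher",
                **{f"n_{e}": cells[e] for e in ents},
                **{f"total_{e}": totals[e] for e in ents},
                "p": p,
            })

    for var in categorical:
        if var not in df.columns:
            logger.info("covariate %r absent; skipped", var)
            continue
        add_categorical(var, df[var])

    for var in numeric:
        if var not in df.columns:
            logger.info("covariate %r absent; skipped", var)
            continue
        sub = df[["enterotype", var]].dropna()
        groups = [sub.loc[sub["enterotype"] == e, var].to_numpy() for e in ents]
        if all(len(g) for g in groups):
            _, p = kruskal_wallis(groups)
        else:
            p = np.nan
        rows.append({
            "variable": var, "level": "", "test": "kruskal-wallis",
            **{f"n_{e}": len(g) for e, g in zip(ents, groups)},
            **{f"total_{e}": len(g) for e, g in zip(ents, groups)},
            "p": p,
        })

    if classes is not None:
        changer_ids = set(classes.loc[classes["class"] == "changer", "infant_id"])
        sample_infant = meta.for_samples(fit.sample_ids)["infant_id"]
        # definition 1: sample immediately precedes a switch
        precedes = _precedes_switch(fit, meta)
        add_categorical("change_enterotype_precedes_switch", precedes)
        # definition 2: any sample of a changer infant
        add_categorical("change_enterotype_changer_infant",
                        sample_infant.isin(changer_ids))

    return pd.DataFrame(rows)


def _precedes_switch(fit: EnterotypeFit, meta: CohortMetadata) -> pd.Series:
    assign = fit.assignments()
    joined = meta.for_samples(fit.sample_ids)
    df = assign.merge(joined[["sample_id", "infant_id", "corrected_ga"]],
                      on="sample_id")
    flags = pd.Series(False, index=df.index)
    for _, grp in df.groupby("infant_id"):
        grp = grp.sort_values(["corrected_ga", "sample_id"], kind="stable")
        ents = grp["enterotype"].to_numpy()
        idx = grp.index.to_numpy()
        for a in range(len(grp) - 1):
            if ents[a] != ents[a + 1]:
                flags.loc[idx[a]] = True
    return flags
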