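"""Rarefaction, abundance transforms, and alpha diversity.

Counts are rarefied to an even depth (the study convention for diversity
metrics), converted to relative abundances, and optionally variance-
stabilised with the arcsine square-root transform before model fitting.
Alpha diversity reports observed richness and the Shannon index (base-2
logarithm by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import TaxaCountTable, ValidationError

__all__ = [
    "RelAbundanceTable",
    "rarefy",
    "relative_abundance",
    "arcsine_sqrt",
    "alpha_diversity",
    "DEFAULT_RAREFACTION_DEPTH",
]

log = logging.getLogger("ptgut.diversity")

#: Even sampling depth used for the study cohort; synthetic fixtures use less.
DEFAULT_RAREFACTION_DEPTH = 23_098


@dataclass
class RelAbundanceTable:
    """Sample x taxon matrix of relative abundances (rows sum to 1)."""

    sample_ids: list[str]
    taxon_ids: list[str]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError("proportion matrix shape mismatch")
        if self.proportions.size:
            if self.proportions.min() < -1e-12 or self.proportions.max() > 1 + 1e-12:
                raise ValidationError("proportions outside [0, 1]")
            rs = self.proportions.sum(axis=1)
            if np.abs(rs - 1).max() > 1e-9:
                i = int(np.argmax(np.abs(rs - 1)))
                raise ValidationError(
                    f"row for sample {self.sample_ids[i]!r} sums to {rs[i]}, not 1"
                )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.taxon_ids,
        )


def rarefy(table: TaxaCountTable, depth: int, seed: int) -> TaxaCountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (logged); a sample
    with total exactly ``depth`` is returned unchanged.  The draw is
    multivariate hypergeometric, so expected proportions equal the input
    proportions.  Deterministic for a given ``seed``.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    totals = table.row_sums()
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        log.info(
            "rarefaction to depth %d drops %d/%d samples: %s",
            depth, len(dropped), table.n_samples,
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    if not keep.any():
        raise ValueError(f"nothing survives rarefaction at depth {depth}")
    sub = table.select_samples(keep)
    rng = np.random.default_rng(seed)
    out = np.empty_like(sub.counts)
    for i in range(sub.n_samples):
        row = sub.counts[i]
        total = int(row.sum())
        if total == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return TaxaCountTable(sub.sample_ids, sub.taxon_ids, out)


def relative_abundance(table: TaxaCountTable) -> RelAbundanceTable:
    """Divide each row by its total read count."""
    totals = table.row_sums()
    if (totals == 0).any():
        i = int(np.argmax(totals == 0))
        raise ValueError(f"sample {table.sample_ids[i]!r} has zero total count")
    props = table.counts / totals[:, None]
    return RelAbundanceTable(list(table.sample_ids), list(table.taxon_ids), props)


def arcsine_sqrt(relab: RelAbundanceTable | np.ndarray) -> np.ndarray:
    """Variance-stabilising transform y = asin(sqrt(p)), range [0, pi/2]."""
    p = relab.proportions if isinstance(relab, RelAbundanceTable) else np.asarray(relab, dtype=float)
    if p.size and (p.min() < -1e-12 or p.max() > 1 + 1e-12):
        raise ValueError("arcsine-sqrt input outside [0, 1]")
    return np.arcsin(np.sqrt(np.clip(p, 0.0, 1.0)))


def alpha_diversity(table: TaxaCountTable, log_base: float = 2.0) -> pd.DataFrame:
    """Observed richness and Shannon index per sample.

    Shannon H = -sum p_i log_base(p_i) over taxa with positive count; H is
    0 for a single-taxon sample and log_base(richness) for a perfectly even
    one.
    """
    totals = table.row_sums()
    if (totals == 0).any():
        i = int(np.argmax(totals == 0))
        raise ValueError(f"sample {table.sample_ids[i]!r} is empty")
    props = table.counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(props > 0, props * np.log(props), 0.0)
    shannon = -plogp.sum(axis=1) / np.log(log_base)
    shannon = np.maximum(shannon, 0.0)  # clip -0.0 from exact single-taxon rows
    richness = (table.counts > 0).sum(axis=1)
    return pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "observed_richness": richness.astype(int),
            "shannon": shannon,
        }
    )
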