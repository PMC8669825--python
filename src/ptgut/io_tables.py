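"""Tabular and tree I/O for the preterm gut-microbiota pipeline.

The pipeline's entry point is a genus-level sample x taxon count table,
accompanied by two metadata tables (per-sample and per-infant) and a rooted
phylogenetic tree over the taxa (for UniFrac).  All tables are tab-separated
UTF-8 text with a header row; taxon labels may contain spaces (genus names
such as ``Clostridium sensu stricto 1``), so tabs are the only field
separator.  Lines starting with ``#`` are provenance comments and ignored on
read.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "ParseError",
    "ValidationError",
    "TaxaCountTable",
    "CohortMetadata",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
    "provenance_header",
]


class ParseError(ValueError):
    """A file could not be parsed into the expected structure."""


class ValidationError(ValueError):
    """Parsed data violate a structural invariant."""


#: Column sets the metadata readers require.
SAMPLE_COLUMNS = (
    "sample_id",
    "infant_id",
    "corrected_ga",
    "postnatal_age",
    "weight",
    "antibiotic",
    "mech_vent",
    "vol_mom",
    "vol_dhm",
    "vol_formula",
    "fortifier",
)
INFANT_COLUMNS = (
    "infant_id",
    "maternal_race",
    "chorioamnionitis",
    "prom",
    "sex",
    "delivery_mode",
    "ga_birth",
    "birth_weight",
)

FORTIFIER_LEVELS = ("none", "HMF", "BMF", "both")
SEX_LEVELS = ("female", "male")
DELIVERY_LEVELS = ("vaginal", "c-section")
RACE_LEVELS = ("black", "white", "other")

_VOCABULARIES = {
    "fortifier": FORTIFIER_LEVELS,
    "sex": SEX_LEVELS,
    "delivery_mode": DELIVERY_LEVELS,
    "maternal_race": RACE_LEVELS,
}


def provenance_header(seed: int | None = None) -> str:
    """One-line ``#`` comment recording pipeline version and seed."""
    from ptgut import __version__

    seed_part = "" if seed is None else f" seed={seed}"
    return f"# ptgut {__version__}{seed_part}"


@dataclass
class TaxaCountTable:
    """Sample x taxon matrix of sequence read counts.

    Attributes
    ----------
    sample_ids : list of str
        Ordered, unique sample identifiers (rows).
    taxon_ids : list of str
        Ordered, unique genus labels (columns).
    counts : ndarray of int64, shape (n_samples, n_taxa)
        Non-negative read counts.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.counts = np.asarray(self.counts)
        self.validate()

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            dup = _first_duplicate(self.taxon_ids)
            raise ValidationError(f"duplicate taxon id: {dup!r}")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count for sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.taxon_ids,
        )

    def select_samples(self, keep: np.ndarray | list) -> "TaxaCountTable":
        """Subset rows, preserving order of ``keep``."""
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return TaxaCountTable(
            [self.sample_ids[i] for i in idx],
            list(self.taxon_ids),
            self.counts[idx],
        )


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)


def read_count_table(path) -> TaxaCountTable:
    """Read a TSV count table (first column sample id, header = taxon ids)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no samples in count table")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: count table needs a sample-id column and at least one taxon")
    sample_ids = df.iloc[:, 0].tolist()
    taxon_ids = list(df.columns[1:])
    raw = df.iloc[:, 1:].to_numpy()
    counts = np.empty(raw.shape, dtype=np.int64)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: cell for sample {sample_ids[i]!r}, taxon "
                    f"{taxon_ids[j]!r} is not an integer: {cell!r}"
                ) from None
            if v < 0:
                raise ParseError(
                    f"{path}: negative count for sample {sample_ids[i]!r}, "
                    f"taxon {taxon_ids[j]!r}"
                )
            counts[i, j] = v
    return TaxaCountTable(sample_ids, taxon_ids, counts)


def write_count_table(table: TaxaCountTable, path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(provenance_header(seed) + "\n")
        table.to_dataframe().to_csv(fh, sep="\t")


@dataclass
class CohortMetadata:
    """Per-sample and per-infant covariates, cross-referenced.

    ``samples`` carries one row per stool sample (time-varying covariates:
    corrected gestational age, postnatal age, weight, antibiotic and
    ventilation flags, weekly milk volumes by source, fortifier in use).
    ``infants`` carries one row per infant (perinatal covariates).  Missing
    cells are ``NaN`` and excluded listwise by downstream analyses.
    """

    samples: pd.DataFrame
    infants: pd.DataFrame
    ga_tolerance: float = field(default=1e-6, repr=False)

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.infants = self.infants.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValidationError(f"sample metadata missing column {col!r}")
        for col in INFANT_COLUMNS:
            if col not in self.infants.columns:
                raise ValidationError(f"infant metadata missing column {col!r}")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if self.infants["infant_id"].duplicated().any():
            dup = self.infants["infant_id"][self.infants["infant_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate infant id: {dup!r}")
        known = set(self.infants["infant_id"])
        orphans = set(self.samples["infant_id"]) - known
        if orphans:
            raise ValidationError(
                f"samples reference unknown infants: {sorted(orphans)}"
            )
        for col, levels in _VOCABULARIES.items():
            frame = self.samples if col in self.samples.columns else self.infants
            vals = frame[col].dropna()
            vals = vals[vals.astype(str) != ""]
            bad = set(vals) - set(levels)
            if bad:
                raise ValidationError(
                    f"column {col!r} contains values outside {levels}: {sorted(bad)}"
                )
        for col in ("vol_mom", "vol_dhm", "vol_formula"):
            v = pd.to_numeric(self.samples[col], errors="coerce")
            if (v.dropna() < 0).any():
                raise ValidationError(f"negative volume in column {col!r}")
        self._check_corrected_ga()

    def _check_corrected_ga(self) -> None:
        merged = self.samples.merge(
            self.infants[["infant_id", "ga_birth"]], on="infant_id", how="left"
        )
        expected = merged["ga_birth"] + merged["postnatal_age"]
        got = merged["corrected_ga"]
        mask = got.notna() & expected.notna()
        bad = mask & ((got - expected).abs() > self.ga_tolerance)
        if bad.any():
            row = merged[bad].iloc[0]
            raise ValidationError(
                f"sample {row['sample_id']!r}: corrected_ga {row['corrected_ga']} "
                f"!= ga_birth + postnatal_age = {row['ga_birth'] + row['postnatal_age']}"
            )

    def joined(self) -> pd.DataFrame:
        """Sample table left-joined with the infant covariates."""
        return self.samples.merge(self.infants, on="infant_id", how="left")

    def for_samples(self, sample_ids) -> pd.DataFrame:
        """Joined covariates re-ordered to match ``sample_ids``."""
        df = self.joined().set_index("sample_id")
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise ValidationError(f"no metadata for samples: {missing[:5]}")
        return df.loc[list(sample_ids)].reset_index()


_NUMERIC_SAMPLE_COLS = (
    "corrected_ga", "postnatal_age", "weight",
    "vol_mom", "vol_dhm", "vol_formula",
)
_NUMERIC_INFANT_COLS = ("ga_birth", "birth_weight")
_FLAG_COLS = ("antibiotic", "mech_vent", "chorioamnionitis", "prom")


def read_metadata(sample_path, infant_path, ga_tolerance: float = 1e-6) -> CohortMetadata:
    """Read and cross-validate the sample/infant metadata TSV pair.

    Empty cells become ``NaN`` (missing).  ``corrected_ga`` is recomputed
    from ``ga_birth + postnatal_age`` and checked against any supplied
    column within ``ga_tolerance`` weeks.
    """
    samples = pd.read_csv(sample_path, sep="\t", comment="#", dtype=str,
                          keep_default_na=False)
    infants = pd.read_csv(infant_path, sep="\t", comment="#", dtype=str,
                          keep_default_na=False)
    samples = samples.where(samples != "", other=np.nan)
    infants = infants.where(infants != "", other=np.nan)
    for col in _NUMERIC_SAMPLE_COLS:
        if col in samples.columns:
            samples[col] = pd.to_numeric(samples[col], errors="raise")
    for col in _NUMERIC_INFANT_COLS:
        if col in infants.columns:
            infants[col] = pd.to_numeric(infants[col], errors="raise")
    for col in _FLAG_COLS:
        for frame in (samples, infants):
            if col in frame.columns:
                frame[col] = pd.to_numeric(frame[col], errors="raise")
    return CohortMetadata(samples, infants, ga_tolerance=ga_tolerance)


def write_metadata(meta: CohortMetadata, sample_path, infant_path,
                   seed: int | None = None) -> None:
    for frame, path in ((meta.samples, sample_path), (meta.infants, infant_path)):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(provenance_header(seed) + "\n")
            frame.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------

def read_newick(source) -> skbio.TreeNode:
    """Read a rooted Newick tree with branch lengths.

    ``source`` is a path or a Newick string.  Leaves must be uniquely
    labelled; branch lengths must be finite and non-negative (``None``
    lengths are treated as 0, as for an unlengthed root).
    """
    if isinstance(source, str) and ("(" in source or ";" in source):
        handle = io.StringIO(source)
    else:
        handle = source
    try:
        tree = skbio.TreeNode.read(handle, format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise ParseError(f"could not parse Newick tree: {exc}") from None
    tips = [t.name for t in tree.tips()]
    if len(tips) == 0:
        raise ParseError("tree has no leaves")
    if len(set(tips)) != len(tips):
        raise ValidationError(f"duplicate leaf label: {_first_duplicate(tips)!r}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if not np.isfinite(node.length) or node.length < 0:
            raise ValidationError(
                f"branch above {node.name or '<internal>'} has invalid length "
                f"{node.length}"
            )
    return tree


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(path, format="newick")


def check_tree_covers_taxa(tree: skbio.TreeNode, taxon_ids) -> None:
    """Raise if any taxon is not a leaf of ``tree``."""
    tips = {t.name for t in tree.tips()}
    missing = [t for t in taxon_ids if t not in tips]
    if missing:
        raise ValidationError(f"taxa absent from tree: {missing}")
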