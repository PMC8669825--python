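"""End-to-end orchestration of the cohort analysis.

``run_pipeline`` executes the stages in method order — rarefaction,
relative abundance and arcsine-sqrt transform, alpha diversity, distance
matrices, PERMANOVA, enterotype discovery and transition analysis, LDA
effect size, per-taxon mixed models, feeding categories, growth models and
growth-taxa correlations — writing every artifact as TSV with a
provenance header and a JSON run manifest (versions, seeds, sample
drop-outs, content checksums).

One master seed fans out to per-stage seeds by stable hashing of the
stage name, so adding or reordering stages does not perturb the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical_growth import (correlate_velocity_abundance, feeding_categories,
                              fit_growth_model, velocity_table)
from .differential import lda_effect_size, per_taxon_lmm
from .distances import jsd_matrix, pcoa_coordinates, permanova, \
    unweighted_unifrac, weighted_unifrac
from .diversity import alpha_diversity, arcsine_sqrt, rarefy, \
    relative_abundance
from .enterotyping import compare_enterotypes, detect_transitions, \
    fit_enterotypes, transition_summary
from .io_tables import provenance_header, read_count_table, read_metadata, \
    read_newick

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("ptgut.pipeline")

DEFAULT_PERMANOVA_TERMS = ("chorioamnionitis", "prom", "sex",
                           "delivery_mode", "corrected_ga")
DEFAULT_LMM_TERMS = ("sex", "chorioamnionitis", "mech_vent", "antibiotic",
                     "corrected_ga", "weight", "feeding_category")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the master seed and stage name."""
    return (int(master_seed) ^ zlib.crc32(stage.encode("utf-8"))) % (2 ** 31)


@dataclass
class PipelineConfig:
    count_table: str
    sample_metadata: str
    infant_metadata: str
    tree: str | None = None
    use_unifrac: bool = False
    out_dir: str = "ptgut_out"
    rarefaction_depth: int = 23_098
    k_min: int = 2
    k_max: int = 10
    n_perm: int = 999
    lefse_alpha: float = 0.05
    lda_threshold: float = 2.0
    lefse_n_boot: int = 30
    permanova_terms: tuple = DEFAULT_PERMANOVA_TERMS
    lmm_fixed_terms: tuple = DEFAULT_LMM_TERMS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("permanova_terms", "lmm_fixed_terms"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def preflight(self) -> None:
        for name in ("count_table", "sample_metadata", "infant_metadata"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")
        if self.use_unifrac:
            if self.tree is None:
                raise ValueError("UniFrac requested but no tree configured")
            if not Path(self.tree).exists():
                raise FileNotFoundError(f"tree: {self.tree} does not exist")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, index=False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(provenance_header(seed) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def _write_matrix(dm, path: Path, seed: int) -> None:
    df = pd.DataFrame(dm.data, index=pd.Index(dm.ids, name="sample_id"),
                      columns=dm.ids)
    _write_tsv(df, path, seed, index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage; returns the result bundle in memory.

    Artifacts are written under ``config.out_dir``.  A stage failure
    aborts with the stage name; artifacts of completed stages remain on
    disk.
    """
    config.preflight()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    bundle: dict = {}
    manifest = {
        "ptgut_version": __version__,
        "master_seed": seed,
        "stage_seeds": {},
        "stages": [],
        "dropped_samples": {},
    }

    stage = "load"
    try:
        table = read_count_table(config.count_table)
        meta = read_metadata(config.sample_metadata, config.infant_metadata)
        tree = read_newick(config.tree) if config.tree else None

        stage = "rarefy"
        s = stage_seed(seed, stage)
        manifest["stage_seeds"][stage] = s
        rare = rarefy(table, config.rarefaction_depth, seed=s)
        dropped = sorted(set(table.sample_ids) - set(rare.sample_ids))
        manifest["dropped_samples"]["rarefaction"] = dropped
        bundle["rarefied"] = rare

        stage = "alpha"
        alpha = alpha_diversity(rare)
        _write_tsv(alpha, out / "alpha_diversity.tsv", seed)
        bundle["alpha"] = alpha

        stage = "transform"
        relab = relative_abundance(rare)
        transformed = pd.DataFrame(
            arcsine_sqrt(relab),
            index=pd.Index(relab.sample_ids, name="sample_id"),
            columns=relab.taxon_ids)
        bundle["relab"], bundle["transformed"] = relab, transformed

        stage = "distances"
        jsd = jsd_matrix(relab)
        _write_matrix(jsd, out / "distance_jsd.tsv", seed)
        bundle["jsd"] = jsd
        meta_aligned = meta.for_samples(relab.sample_ids)
        if tree is not None and config.use_unifrac:
            uu = unweighted_unifrac(rare, tree)
            wu = weighted_unifrac(relab, tree, normalized=True)
            _write_matrix(uu, out / "distance_unweighted_unifrac.tsv", seed)
            _write_matrix(wu, out / "distance_weighted_unifrac.tsv", seed)
            bundle["unweighted_unifrac"], bundle["weighted_unifrac"] = uu, wu
            _write_tsv(pcoa_coordinates(uu), out / "pcoa_unweighted_unifrac.tsv", seed)

        stage = "permanova"
        s = stage_seed(seed, stage)
        manifest["stage_seeds"][stage] = s
        terms = [t for t in config.permanova_terms if t in meta_aligned.columns]
        perm_frames = []
        targets = {"jsd": jsd}
        if "unweighted_unifrac" in bundle:
            targets["unweighted_unifrac"] = bundle["unweighted_unifrac"]
            targets["weighted_unifrac"] = bundle["weighted_unifrac"]
        for metric, dm in targets.items():
            res = permanova(dm, meta_aligned, terms,
                            n_perm=config.n_perm, seed=s)
            res.insert(0, "metric", metric)
            perm_frames.append(res)
        perm_all = pd.concat(perm_frames, ignore_index=True)
        _write_tsv(perm_all, out / "permanova.tsv", seed)
        bundle["permanova"] = perm_all

        stage = "enterotypes"
        s = stage_seed(seed, stage)
        manifest["stage_seeds"][stage] = s
        fit = fit_enterotypes(relab, range(config.k_min, config.k_max + 1),
                              seed=s)
        _write_tsv(fit.assignments(), out / "enterotype_labels.tsv", seed)
        profile = pd.DataFrame({
            "k": sorted(fit.ch_profile),
            "calinski_harabasz": [fit.ch_profile[k] for k in sorted(fit.ch_profile)],
            "mean_silhouette": [fit.silhouette_profile[k]
                                for k in sorted(fit.ch_profile)],
        })
        _write_tsv(profile, out / "enterotype_model_selection.tsv", seed)
        bundle["enterotypes"] = fit

        # enterotype as a PERMANOVA term (variance explained by clustering)
        ent_cov = fit.assignments()[["sample_id", "enterotype"]]
        ent_frames = []
        for metric, dm in targets.items():
            res = permanova(dm, ent_cov, ["enterotype"],
                            n_perm=config.n_perm, seed=s)
            res.insert(0, "metric", metric)
            ent_frames.append(res)
        ent_perm = pd.concat(ent_frames, ignore_index=True)
        _write_tsv(ent_perm, out / "permanova_enterotype.tsv", seed)
        bundle["permanova_enterotype"] = ent_perm

        stage = "feeding"
        feeding = feeding_categories(meta)
        _write_tsv(feeding, out / "feeding_categories.tsv", seed)
        bundle["feeding"] = feeding

        stage = "transitions"
        transitions, classes = detect_transitions(fit, meta, feeding)
        _write_tsv(transitions, out / "enterotype_transitions.tsv", seed)
        _write_tsv(classes, out / "infant_enterotype_classes.tsv", seed)
        bundle["transitions"], bundle["infant_classes"] = transitions, classes
        bundle["transition_summary"] = transition_summary(transitions, classes)

        stage = "enterotype_comparison"
        comparison = compare_enterotypes(fit, meta, classes=classes)
        _write_tsv(comparison, out / "enterotype_comparison.tsv", seed)
        bundle["comparison"] = comparison

        stage = "lefse"
        s = stage_seed(seed, stage)
        manifest["stage_seeds"][stage] = s
        lda = lda_effect_size(relab, fit.assignments()["enterotype"].to_numpy(),
                              alpha=config.lefse_alpha,
                              lda_threshold=config.lda_threshold,
                              n_boot=config.lefse_n_boot, seed=s)
        _write_tsv(lda, out / "lefse_enterotype.tsv", seed)
        bundle["lefse"] = lda

        stage = "associations"
        lmm_meta = meta_aligned.merge(feeding, on="sample_id", how="left")
        terms = [t for t in config.lmm_fixed_terms if t in lmm_meta.columns]
        assoc, flagged = per_taxon_lmm(transformed, lmm_meta, terms)
        _write_tsv(assoc, out / "taxon_associations.tsv", seed)
        bundle["associations"], bundle["associations_flagged"] = assoc, flagged
        manifest["dropped_samples"]["lmm_flagged_taxa"] = [
            f["taxon"] for f in flagged]

        stage = "growth"
        velocities = velocity_table(meta)
        _write_tsv(velocities, out / "growth_velocities.tsv", seed)
        growth_rows = []
        growth_fits = {}
        for stratum in (None, "HMF", "BMF"):
            try:
                gf = fit_growth_model(velocities, stratum=stratum)
            except (ValueError, RuntimeError) as exc:
                log.warning("growth model (%s): %s", stratum or "overall", exc)
                continue
            growth_fits[gf.stratum] = gf
            growth_rows.append({
                "stratum": gf.stratum, "intercept": gf.intercept,
                "slope": gf.slope, "slope_se": gf.slope_se,
                "slope_ci_low": gf.slope_ci[0], "slope_ci_high": gf.slope_ci[1],
                "var_rand_intercept": gf.var_random_intercept,
                "var_rand_slope": gf.var_random_slope,
                "var_residual": gf.var_residual, "ga_center": gf.ga_center,
                "n_obs": gf.n_obs, "n_infants": gf.n_infants,
            })
        _write_tsv(pd.DataFrame(growth_rows), out / "growth_models.tsv", seed)
        bundle["growth"] = growth_fits
        bundle["velocities"] = velocities

        stage = "growth_correlations"
        corr_frames = [
            correlate_velocity_abundance(relab, velocities, stratum=st)
            for st in ("HMF", "BMF")
        ]
        corr = pd.concat(corr_frames, ignore_index=True)
        _write_tsv(corr, out / "growth_taxa_correlations.tsv", seed)
        bundle["growth_correlations"] = corr
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["stages"] = [
        "rarefy", "alpha", "transform", "distances", "permanova",
        "enterotypes", "feeding", "transitions", "enterotype_comparison",
        "lefse", "associations", "growth", "growth_correlations"]
    manifest["checksums"] = {
        p.name: hashlib.md5(p.read_bytes()).hexdigest()
        for p in sorted(out.glob("*.tsv"))
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
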