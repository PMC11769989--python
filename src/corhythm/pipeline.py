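"""End-to-end orchestration: preprocess → fit → compare → overlap → enrich.

`run_pipeline` drives the whole analysis from a single
:class:`PipelineConfig` (loadable from YAML): per-species filtering and
normalization, per-group cosinor fits, the conserved-panel phase
comparison with random-effects pooling, pairwise mouse–human rhythmic
overlap and RRHO maps per sex, and (when a GMT collection is supplied)
over-representation analysis with the top-10 cross-group rule.

All stage outputs are TSVs with stable column order, written under the
output directory together with a JSON run manifest (config echo,
package version, seed), so identical inputs + config + seed give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cosinor import RhythmResults, fit_group
from .datasets import CLOCK_PANEL
from .enrichment import cross_group_top10, run_collection
from .errors import ValidationError
from .io import (
    ExpressionMatrix,
    SampleTable,
    read_counts,
    read_gene_annotations,
    read_gmt,
    read_metadata,
)
from .overlap import overlap_stats, rrho_map
from .phase import (
    active_phase_fraction,
    build_phase_table,
    peak_histogram,
    pool_phase_shift,
)
from .preprocess import preprocess_species

log = logging.getLogger("corhythm")

_HEADER = (
    "# corhythm results: times in hours after ZT0 (mouse) / sunrise (human); "
    "rhythmic = strict p < alpha\n"
)


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run."""

    counts: str = ""
    metadata: str = ""
    gene_annotations: str | None = None
    gmt: str | None = None
    output_dir: str = "results"
    filter_threshold: float = 1.0
    filter_frac: float = 0.5
    group_by: tuple[str, ...] = ("species", "sex", "region")
    period: float = 24.0
    alpha: float = 0.05
    alpha_stringent: float = 0.01
    phase_genes: tuple[str, ...] = CLOCK_PANEL
    rrho_steps: int = 100
    enrich_min_size: int = 15
    enrich_top_k: int = 10
    enrich_threshold: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.alpha, self.alpha_stringent):
            if not 0.0 < a < 1.0:
                raise ValidationError(f"alpha must be in (0, 1), got {a}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("group_by", "phase_genes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("counts", "metadata"):
            p = getattr(self, name)
            if not p:
                raise ValidationError(f"config missing required path: {name}")
            if not Path(p).exists():
                raise ValidationError(f"{name} path does not exist: {p}")
        for name in ("gmt", "gene_annotations"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise ValidationError(f"{name} path does not exist: {p}")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, sep="\t", index=index)


def summarize_counts(
    results_by_group: dict[str, RhythmResults], alphas=(0.05, 0.01)
) -> pd.DataFrame:
    """Rhythmic-transcript count and percentage per group × alpha."""
    rows = []
    for group in sorted(results_by_group):
        res = results_by_group[group]
        total = len(res.frame)
        for a in alphas:
            n_r = int((res.frame["p_value"] < a).sum())
            rows.append(
                {
                    "group": group,
                    "alpha": a,
                    "n_genes": total,
                    "n_rhythmic": n_r,
                    "pct_rhythmic": 100.0 * n_r / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the in-memory report bundle.

    The bundle maps stage names to DataFrames/objects; everything is
    also written as TSV under ``config.output_dir``.
    """
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    counts = read_counts(config.counts)
    if config.gene_annotations:
        counts = ExpressionMatrix(
            counts.values, counts.value_kind,
            read_gene_annotations(config.gene_annotations),
        )
    samples = read_metadata(config.metadata)
    missing = set(samples.sample_ids) - set(counts.sample_ids)
    if missing:
        raise ValidationError(f"metadata samples absent from counts: {sorted(missing)[:5]}")

    bundle: dict = {}
    results: dict[str, RhythmResults] = {}
    kept_by_species: dict[str, list[str]] = {}
    species_list = sorted(samples.frame["species"].unique())
    for species in species_list:
        sub_samples = samples.select(species=species)
        sub_counts = counts.subset_samples(sub_samples.sample_ids)
        n_in = len(sub_counts.gene_ids)
        norm, kept = preprocess_species(
            sub_counts, sub_samples,
            threshold=config.filter_threshold, frac=config.filter_frac,
            group_by=config.group_by,
        )
        log.info("%s: %d/%d genes pass the expression filter", species, len(kept), n_in)
        kept_by_species[species] = kept
        pd.DataFrame({"gene_id": kept}).pipe(
            _write_tsv, out / f"kept_genes_{species}.tsv"
        )
        norm.values.round(6).pipe(
            lambda df: _write_tsv(df, out / f"normalized_{species}.tsv", index=True)
        )
        for group in sub_samples.groups():
            results[group] = fit_group(norm, sub_samples, group, period=config.period)
            _write_tsv(
                results[group].frame.round(6).reset_index(),
                out / f"cosinor_{group}.tsv",
            )
    bundle["results"] = results
    bundle["kept_genes"] = kept_by_species

    summary = summarize_counts(results, alphas=(config.alpha, config.alpha_stringent))
    _write_tsv(summary, out / "rhythmic_summary.tsv")
    bundle["summary"] = summary

    # peak-time distributions and active-phase fractions
    hist_rows, active_rows = [], []
    for group, res in sorted(results.items()):
        species = group.split("_")[0]
        hist = peak_histogram(res, alpha=config.alpha)
        for iv, pct in hist.items():
            hist_rows.append({"group": group, "bin_start_h": iv.left, "pct": pct})
        if (res.frame["p_value"] < config.alpha).any():
            active_rows.append(
                {
                    "group": group,
                    "active_fraction": active_phase_fraction(res, species, config.alpha),
                }
            )
    bundle["peak_histograms"] = pd.DataFrame(hist_rows)
    bundle["active_fractions"] = pd.DataFrame(active_rows)
    _write_tsv(bundle["peak_histograms"], out / "peak_histograms.tsv")
    _write_tsv(bundle["active_fractions"], out / "active_fractions.tsv")

    # cross-species stages need both species
    if {"mouse", "human"} <= set(species_list):
        mouse_groups = {g for g in results if g.startswith("mouse_")}
        human_groups = {g for g in results if g.startswith("human_")}
        mouse_by_sex = {g.split("_")[1]: results[g] for g in sorted(mouse_groups)}
        human_by_rs = {
            (g.split("_", 2)[2], g.split("_")[1]): results[g]
            for g in sorted(human_groups)
        }
        panel = [
            g
            for g in config.phase_genes
            if all(g in r.frame.index for r in results.values())
        ]
        if len(panel) >= 2:
            table = build_phase_table(mouse_by_sex, human_by_rs, genes=panel)
            pooled = pool_phase_shift(table)
            _write_tsv(table.round(6), out / "phase_differences.tsv")
            pooled_rows = [
                {"sex": sex, **{k: v for k, v in d.items()}}
                for sex, d in pooled.by_sex.items()
            ]
            pooled_df = pd.DataFrame(pooled_rows)
            pooled_df["contrast_h"] = pooled.contrast_h
            pooled_df["contrast_p"] = pooled.contrast_p
            _write_tsv(pooled_df.round(6), out / "pooled_phase_shift.tsv")
            bundle["phase_table"] = table
            bundle["pooled_shift"] = pooled
        else:
            log.warning("phase panel not fitted in all groups; skipping pooling")

        # thresholded overlap + RRHO per sex, mouse vs each human region
        overlap_rows = []
        rrho_maps = {}
        for sex, mres in mouse_by_sex.items():
            for (region, hsex), hres in human_by_rs.items():
                if hsex != sex:
                    continue
                universe = sorted(set(mres.gene_ids) & set(hres.gene_ids))
                if not universe:
                    continue
                a = mres.rhythmic_set(config.alpha) & set(universe)
                b = hres.rhythmic_set(config.alpha) & set(universe)
                ov = overlap_stats(a, b, universe)
                overlap_rows.append(
                    {"sex": sex, "human_region": region, **ov.as_dict()}
                )
                rrho_maps[(sex, region)] = rrho_map(
                    mres.p_values(), hres.p_values(), steps=config.rrho_steps
                )
                np.savetxt(
                    out / f"rrho_{sex}_{region}.tsv",
                    rrho_maps[(sex, region)].matrix,
                    delimiter="\t", fmt="%.6g",
                )
                pd.DataFrame(
                    {
                        "cutoff_mouse": rrho_maps[(sex, region)].cutoffs_a,
                        "cutoff_human": rrho_maps[(sex, region)].cutoffs_b,
                    }
                ).pipe(_write_tsv, out / f"rrho_{sex}_{region}_grid.tsv")
        bundle["overlaps"] = pd.DataFrame(overlap_rows)
        bundle["rrho"] = rrho_maps
        _write_tsv(bundle["overlaps"], out / "overlaps.tsv")

    # enrichment
    if config.gmt:
        collection = read_gmt(config.gmt)
        enr: dict[str, pd.DataFrame] = {}
        for group, res in sorted(results.items()):
            species = group.split("_")[0]
            background = kept_by_species[species]
            query = res.rhythmic_set(config.alpha)
            enr[group] = run_collection(
                query, collection, background, min_size=config.enrich_min_size
            )
            _write_tsv(enr[group].round(6), out / f"enrichment_{group}.tsv")
        bundle["enrichment"] = enr
        cross_rows = []
        for sex in ("M", "F"):
            for ga in sorted(g for g in enr if g.startswith(f"mouse_{sex}")):
                for gb in sorted(g for g in enr if g.startswith(f"human_{sex}")):
                    rep = cross_group_top10(
                        enr[ga], enr[gb],
                        k=config.enrich_top_k,
                        threshold_neg_log10=config.enrich_threshold,
                        label_a=ga, label_b=gb,
                    )
                    cross_rows.append(rep)
        if cross_rows:
            bundle["cross_group"] = pd.concat(cross_rows, ignore_index=True)
            _write_tsv(bundle["cross_group"], out / "cross_group_pathways.tsv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
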