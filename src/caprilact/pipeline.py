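"""End-to-end pipeline: records -> curves -> shapes -> haplotype ANOVA.

Stages: read or simulate test-day records; build lactations and
standardized 210-day yields; fit the configured lactation-curve model per
trait per lactation (or run model selection over the registry); extract
peak/persistency shape parameters; group animals by casein haplotype
variant; run the one-way Bayesian ANOVA (F/p, JZS BF10, group posteriors)
for each trait level and each curve-shape parameter.

Trait levels are analysed per test-day record; curve-shape parameters are
analysed one value per lactation (the unit that generated them).  All
randomness flows from a single root seed and identical config + seed
produce byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import bayes_anova
from .curves import fit_lactation, get_model, registry
from .errors import (
    CapriLactError,
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
)
from .haplotypes import group_by_haplotype, parse_haplotypes
from .records import build_lactations, read_records
from .selection import aggregate_criteria, select_best
from .shape import shape_ali_schaeffer, shape_pyd
from .simulate import AS_TRAITS, SCC_TRAIT, SimConfig, simulate_herd

log = logging.getLogger("caprilact")

#: Reproduction model choices: Ali–Schaeffer for milk and components,
#: parabolic yield-density for somatic cell count.
DEFAULT_MODELS = {
    "milk_kg": "ali_schaeffer",
    "fat_pct": "ali_schaeffer",
    "protein_pct": "ali_schaeffer",
    "dry_matter_pct": "ali_schaeffer",
    "lactose_pct": "ali_schaeffer",
    "scc": "parabolic_yield_density",
}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Provide either ``records_path``/``haplotypes_path`` or a ``simulate``
    block, not neither.  ``models`` maps trait -> model id or "select".
    """

    records_path: str | None = None
    haplotypes_path: str | None = None
    simulate: SimConfig | None = None
    traits: tuple = AS_TRAITS + (SCC_TRAIT,)
    models: dict = field(default_factory=lambda: dict(DEFAULT_MODELS))
    horizon: int = 210
    rscale: float = 1.0
    ci_level: float = 0.95
    homozygous_only: bool = False
    outdir: str = "caprilact_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        has_paths = self.records_path is not None and self.haplotypes_path is not None
        if not has_paths and self.simulate is None:
            raise ConfigurationError(
                "config needs input paths (records + haplotypes) or a simulate block"
            )
        for trait in self.traits:
            if trait not in self.models:
                raise ConfigurationError(f"no model configured for trait {trait!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in _CONFIG_FIELDS})
        if sim is not None:
            cfg.simulate = SimConfig(**sim)
        if "traits" in raw:
            cfg.traits = tuple(raw["traits"])
        return cfg


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def _shape_rows(trait, model_id, series_list, fits, horizon):
    rows = []
    for series, fit in zip(series_list, fits):
        if fit is None or not fit.converged:
            continue
        if model_id == "parabolic_yield_density":
            try:
                s = shape_pyd(fit.b, days=horizon, trait=trait)
            except CapriLactError:
                continue
        else:
            s = shape_ali_schaeffer(fit.b, trait=trait)
        rows.append(
            {
                "animal_id": series.animal_id,
                "lactation_no": series.lactation_no,
                "trait": trait,
                "model_id": model_id,
                "peak": s.peak,
                "persistency_b1": s.persistency_b1,
                "persistency_b2": s.persistency_b2,
                "persistency_scalar": s.persistency_scalar,
            }
        )
    return rows


def _anova_rows(result):
    base = {"trait": result.trait, "parameter": result.parameter}
    return [
        {
            **base,
            "source": "Between",
            "ss": result.ss_between,
            "df": result.df_between,
            "ms": result.ms_between,
            "f": result.f,
            "p": result.p,
            "bf10": result.bf10,
        },
        {
            **base,
            "source": "Within",
            "ss": result.ss_within,
            "df": result.df_within,
            "ms": result.ms_within,
            "f": np.nan,
            "p": np.nan,
            "bf10": np.nan,
        },
    ]


def _audit_anova_table(df: pd.DataFrame) -> None:
    # self-consistency: ms = ss/df and f = ms ratio in every row pair
    for (_, _), sub in df.groupby(["trait", "parameter"], sort=False):
        b = sub[sub["source"] == "Between"].iloc[0]
        w = sub[sub["source"] == "Within"].iloc[0]
        assert np.isclose(b["ms"], b["ss"] / b["df"], rtol=1e-12)
        assert np.isclose(w["ms"], w["ss"] / w["df"], rtol=1e-12)
        assert np.isclose(b["f"], b["ms"] / w["ms"], rtol=1e-12)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a machine-readable run report."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"outputs": {}, "stages": {}}

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        return lambda: report["stages"].update(
            {name: round(time.perf_counter() - t0, 3)}
        )

    done = stage("input")
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        dataset = simulate_herd(sim)
        records, assignments = dataset.records, dataset.assignments
        dataset.write(outdir / "records.csv", outdir / "haplotypes.csv")
        report["outputs"]["records"] = str(outdir / "records.csv")
        report["outputs"]["haplotypes"] = str(outdir / "haplotypes.csv")
    else:
        records = read_records(config.records_path)
        assignments = parse_haplotypes(config.haplotypes_path)
    done()

    done = stage("lactations")
    series_list = build_lactations(records)
    yields = pd.DataFrame(
        [
            {
                "animal_id": s.animal_id,
                "lactation_no": s.lactation_no,
                "d1": s.d1,
                "n_controls": len(s.records),
                "total_yield_210": s.total_yield_210,
            }
            for s in series_list
        ]
    ).sort_values(["animal_id", "lactation_no"])
    _write_csv(yields, outdir / "yields.csv")
    report["outputs"]["yields"] = str(outdir / "yields.csv")
    done()

    done = stage("fit")
    fits: dict[str, list] = {}
    selection_tables = []
    for trait in config.traits:
        choice = config.models[trait]
        if choice == "select":
            by_model = {}
            for model in registry():
                mfits = []
                for s in series_list:
                    try:
                        mfits.append(
                            fit_lactation(s.dims, s.values(trait), model)
                        )
                    except InsufficientDataError:
                        continue
                by_model[model.model_id] = mfits
            table = aggregate_criteria(by_model)
            ranked = select_best(table)
            ranked.insert(0, "trait", trait)
            selection_tables.append(ranked)
            choice = ranked.iloc[0]["model_id"]
            log.info("selected %s for %s", choice, trait)
        model = get_model(choice)
        trait_fits = []
        for s in series_list:
            try:
                trait_fits.append(fit_lactation(s.dims, s.values(trait), model))
            except InsufficientDataError:
                trait_fits.append(None)
        fits[trait] = (model.model_id, trait_fits)
    if selection_tables:
        _write_csv(pd.concat(selection_tables), outdir / "model_ranking.csv")
        report["outputs"]["model_ranking"] = str(outdir / "model_ranking.csv")
    done()

    done = stage("shapes")
    shape_rows = []
    for trait, (model_id, trait_fits) in fits.items():
        shape_rows.extend(
            _shape_rows(trait, model_id, series_list, trait_fits, config.horizon)
        )
    shapes = pd.DataFrame(shape_rows).sort_values(
        ["trait", "animal_id", "lactation_no"]
    )
    _write_csv(shapes, outdir / "shapes.csv")
    report["outputs"]["shapes"] = str(outdir / "shapes.csv")
    done()

    done = stage("grouping")
    grouping = group_by_haplotype(
        assignments, homozygous_only=config.homozygous_only
    )
    animal_groups: dict[str, list[str]] = {}
    for key, animals in grouping.groups.items():
        for a in animals:
            animal_groups.setdefault(a, []).append(key)
    report["n_haplotypes"] = grouping.n_haplotypes
    report["n_animals"] = grouping.n_animals
    report["animals_per_haplotype"] = round(grouping.animals_per_haplotype, 2)
    done()

    done = stage("anova")
    anova_rows = []
    posterior_rows = []
    for trait in config.traits:
        model_id, trait_fits = fits[trait]
        # level analysis: one value per test-day record
        level_groups: dict[str, list[float]] = {}
        for rec in records:
            for key in animal_groups.get(rec.animal_id, ()):
                level_groups.setdefault(key, []).append(getattr(rec, trait))
        analyses = [("level", level_groups)]
        # shape analysis: one value per lactation
        sub = shapes[shapes["trait"] == trait]
        if model_id == "parabolic_yield_density":
            shape_params = ["peak", "persistency_scalar"]
        else:
            shape_params = ["peak", "persistency_b1", "persistency_b2"]
        for param in shape_params:
            groups: dict[str, list[float]] = {}
            for _, row in sub.iterrows():
                for key in animal_groups.get(row["animal_id"], ()):
                    groups.setdefault(key, []).append(row[param])
            analyses.append((param, groups))
        for param, groups in analyses:
            try:
                res = bayes_anova(
                    groups,
                    trait=trait,
                    parameter=param,
                    rscale=config.rscale,
                    ci=config.ci_level,
                )
            except (CapriLactError, ValueError) as exc:
                log.warning("anova %s/%s skipped: %s", trait, param, exc)
                continue
            anova_rows.extend(_anova_rows(res))
            for gp in res.group_posteriors:
                posterior_rows.append(
                    {
                        "trait": trait,
                        "parameter": param,
                        "haplotype": gp.label,
                        "n": gp.n,
                        "mean": gp.mean,
                        "deviation": gp.deviation,
                        "sd": gp.sd,
                        "ci_low": gp.ci_low,
                        "ci_high": gp.ci_high,
                        "significant": gp.significant,
                    }
                )
    anova_df = pd.DataFrame(anova_rows)
    _audit_anova_table(anova_df)
    _write_csv(anova_df, outdir / "anova.csv")
    _write_csv(pd.DataFrame(posterior_rows), outdir / "posteriors.csv")
    report["outputs"]["anova"] = str(outdir / "anova.csv")
    report["outputs"]["posteriors"] = str(outdir / "posteriors.csv")
    done()

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "outputs": report["outputs"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    report["outputs"]["manifest"] = str(outdir / "manifest.json")
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    sim = d.get("simulate")
    if sim is not None:
        # haplotype sequence inventories are bulky; manifest keeps counts only
        if sim.get("haplotype_seqs"):
            sim["haplotype_seqs"] = f"<{len(sim['haplotype_seqs'])} sequences>"
        if sim.get("haplotype_freqs"):
            sim["haplotype_freqs"] = f"<{len(sim['haplotype_freqs'])} frequencies>"
    return d
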