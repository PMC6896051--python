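"""Full-workflow orchestration: simulate/ingest -> QC -> weights -> scores
-> associations -> power -> report, with a run manifest for reproducibility.

Every stage writes plain-text tables (TSV/CSV) into the run directory; the
manifest records the configuration snapshot, seed, stage timings and output
checksums so a rerun with identical inputs can be verified byte-for-byte
(timings aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import association_grid_frame, run_association_suite, two_sample_t
from .cohort_io import (
    Cohort,
    assemble_cohort,
    complete_case_filter,
    read_genotypes_table,
    read_genotypes_vcf,
    read_phenotypes,
    write_genotypes_table,
)
from .effect_weights import derive_weights, pool_study_table
from .panel import SnpPanel, load_default_panel
from .power_calc import power_table
from .qc_popgen import qc_report
from .risk_scores import score_cohorts
from .synthetic_cohort import GeneratorConfig, generate_two_populations, load_preset

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    seed: int
    package_version: str = __version__
    stages: list = field(default_factory=list)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def record_stage(self, name: str, seconds: float, **info) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 3), **info})

    def record_output(self, path: Path) -> None:
        self.outputs[path.name] = _sha256(path)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resolve_cohort(spec: dict, panel: SnpPanel, label_default: str) -> Cohort:
    """Build a cohort from a config block: either file paths or a preset
    marker (presets are materialised by the caller, not here)."""
    label = spec.get("label", label_default)
    pheno = read_phenotypes(spec["phenotypes"])
    fmt = spec.get("format", "table")
    if fmt == "vcf":
        gm = read_genotypes_vcf(spec["genotypes"], panel)
    elif fmt == "table":
        gm = read_genotypes_table(spec["genotypes"], panel)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    return assemble_cohort(gm, pheno, label)


def load_run_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    for key in ("general", "roma"):
        if key not in config:
            raise ValueError(f"run config missing required section {key!r}")
        block = config[key]
        if "preset" not in block and not (
            "genotypes" in block and "phenotypes" in block
        ):
            raise ValueError(
                f"section {key!r} needs either a preset or genotype+phenotype paths"
            )
    return config


def run_pipeline(
    config: dict | str | Path,
    seed: int | None = None,
    skip_power: bool = False,
    output_dir: str | Path | None = None,
) -> RunManifest:
    """Execute the full workflow described by a run config.

    ``config`` is a dict or a YAML path with ``general`` and ``roma`` input
    sections (generator preset or file paths), an optional ``seed`` and
    ``output_dir``, and an optional ``power`` section (n, case_fraction,
    alpha). Stage errors abort the run with the failing stage named.
    """
    if not isinstance(config, dict):
        config = load_run_config(config)
    seed = int(seed if seed is not None else config.get("seed", 0))
    outdir = Path(output_dir or config.get("output_dir", "grspipe_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    panel = load_default_panel()
    manifest = RunManifest(config=config, seed=seed)

    stage = "ingest"
    try:
        t0 = time.perf_counter()
        need_general = "preset" in config["general"]
        need_roma = "preset" in config["roma"]
        if need_general != need_roma:
            raise ValueError("mixing a preset with file inputs is not supported")
        if need_general:
            cfg_g = load_preset(config["general"]["preset"])
            cfg_r = load_preset(config["roma"]["preset"])
            if "n" in config["general"]:
                cfg_g = GeneratorConfig(**{**cfg_g.__dict__, "n": config["general"]["n"]})
            if "n" in config["roma"]:
                cfg_r = GeneratorConfig(**{**cfg_r.__dict__, "n": config["roma"]["n"]})
            general, roma = generate_two_populations(cfg_g, cfg_r, seed, panel)
        else:
            general = _resolve_cohort(config["general"], panel, "General")
            roma = _resolve_cohort(config["roma"], panel, "Roma")
        enrolled = {general.label: general.n_samples, roma.label: roma.n_samples}
        manifest.record_stage(stage, time.perf_counter() - t0, enrolled=enrolled)

        stage = "complete_case_filter"
        t0 = time.perf_counter()
        general = complete_case_filter(general)
        roma = complete_case_filter(roma)
        analysed = {general.label: general.n_samples, roma.label: roma.n_samples}
        logger.info("analysis Ns: %s", analysed)
        manifest.record_stage(stage, time.perf_counter() - t0, analysed=analysed)

        stage = "qc"
        t0 = time.perf_counter()
        snp_table, ld_table = qc_report(general, roma)
        snp_table.to_csv(outdir / "qc_snps.tsv", sep="\t", index=False)
        ld_table.to_csv(outdir / "qc_ld.tsv", sep="\t", index=False)
        manifest.record_stage(stage, time.perf_counter() - t0)

        stage = "weights"
        t0 = time.perf_counter()
        if "study_effects" in config:
            pooled = pool_study_table(pd.read_csv(config["study_effects"]))
            weights = derive_weights(panel, pooled)
        else:
            weights = derive_weights(panel)
        weights.to_frame().to_csv(outdir / "weights.csv", index=False)
        manifest.record_stage(stage, time.perf_counter() - t0)

        stage = "score"
        t0 = time.perf_counter()
        scores = score_cohorts([general, roma], weights)
        scores.scores.to_csv(outdir / "scores.csv", index=False)
        scores.summary().to_csv(outdir / "score_summary.tsv", sep="\t", index=False)
        scores.histogram().to_csv(outdir / "grs_histogram.tsv", sep="\t", index=False)
        sc = scores.scores
        ttests = {
            name: two_sample_t(
                sc.loc[sc.population == general.label, name],
                sc.loc[sc.population == roma.label, name],
            )
            for name in ("grs", "wgrs")
        }
        manifest.record_stage(stage, time.perf_counter() - t0)

        stage = "associate"
        t0 = time.perf_counter()
        results = run_association_suite(general, roma, scores)
        grid = association_grid_frame(results)
        grid.to_csv(outdir / "associations.tsv", sep="\t", index=False)
        manifest.record_stage(stage, time.perf_counter() - t0, n_models=len(results))

        if skip_power or config.get("skip_power", False):
            manifest.record_stage("power", 0.0, skipped=True)
            power = None
        else:
            stage = "power"
            t0 = time.perf_counter()
            pcfg = config.get("power", {})
            freqs = {
                e.rsid: snp_table.loc[
                    snp_table.rsid == e.rsid, f"freq_{general.label}"
                ].iloc[0]
                for e in panel
            }
            frame = build_status_frame(general, roma)
            case_fraction = pcfg.get(
                "case_fraction", float(frame["t2dm_status"].mean())
            )
            power = power_table(
                panel,
                freqs,
                n=pcfg.get("n", general.n_samples),
                case_fraction=case_fraction,
                alpha=pcfg.get("alpha", 0.05),
            )
            power.to_csv(outdir / "power.tsv", sep="\t", index=False)
            manifest.record_stage(stage, time.perf_counter() - t0)

        stage = "report"
        t0 = time.perf_counter()
        report = write_report(
            outdir / "report.md",
            general=general,
            roma=roma,
            snp_table=snp_table,
            ld_table=ld_table,
            weights=weights,
            scores=scores,
            ttests=ttests,
            grid=grid,
            power=power,
            enrolled=enrolled,
        )
        manifest.record_stage(stage, time.perf_counter() - t0)
        for f in sorted(outdir.iterdir()):
            if f.name != "manifest.json" and f.is_file():
                manifest.record_output(f)
        manifest.write(outdir / "manifest.json")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def build_status_frame(*cohorts: Cohort) -> pd.DataFrame:
    from .association import classify_glycemic_status

    rows = []
    for cohort in cohorts:
        ph = cohort.phenotypes
        for fg, tr in zip(ph["fasting_glucose"], ph["on_treatment"]):
            rows.append(
                {
                    "population": cohort.label,
                    "t2dm_status": int(
                        classify_glycemic_status(fg, bool(tr)).binary_outcome
                    ),
                }
            )
    return pd.DataFrame(rows)


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.4g}") -> str:
    show = df.copy()
    for col in show.columns:
        if pd.api.types.is_float_dtype(show[col]):
            show[col] = show[col].map(lambda v: floatfmt.format(v))
    header = "| " + " | ".join(show.columns) + " |"
    sep = "|" + "|".join(["---"] * len(show.columns)) + "|"
    rows = ["| " + " | ".join(str(v) for v in row) + " |"
            for row in show.itertuples(index=False)]
    return "\n".join([header, sep, *rows])


def write_report(path, *, general, roma, snp_table, ld_table, weights, scores,
                 ttests, grid, power, enrolled) -> str:
    """Render the human-readable Markdown run report (deterministic bytes)."""
    sc = scores.summary()
    parts = [
        "# Genetic risk score pipeline report",
        "",
        "## Study populations",
        "",
        f"- {general.label}: {enrolled[general.label]} enrolled, "
        f"{general.n_samples} complete cases analysed",
        f"- {roma.label}: {enrolled[roma.label]} enrolled, "
        f"{roma.n_samples} complete cases analysed",
        "",
        "## Allele frequencies and Hardy-Weinberg equilibrium",
        "",
        _md_table(snp_table),
        "",
        "## Linkage disequilibrium",
        "",
        f"Pairs tested per cohort: {len(ld_table) // 2}. "
        f"Max r2 = {ld_table['r2'].max():.4f}; "
        f"pairs with D' = 1 and LOD >= 2: "
        f"{int(((ld_table['Dprime'] > 0.999) & (ld_table['lod'] >= 2)).sum())}.",
        "",
        "## wGRS weights",
        "",
        _md_table(weights.to_frame()),
        "",
        "## Risk score distributions",
        "",
        _md_table(sc),
        "",
        f"Student's t-test GRS {general.label} vs {roma.label}: "
        f"t = {ttests['grs']['t']:.3f}, p = {ttests['grs']['p']:.3g}; "
        f"wGRS: t = {ttests['wgrs']['t']:.3f}, p = {ttests['wgrs']['p']:.3g}.",
        "",
        "## Association models",
        "",
        _md_table(grid),
        "",
    ]
    if power is not None:
        parts += ["## Per-SNP power", "", _md_table(power), ""]
    text = "\n".join(parts)
    Path(path).write_text(text)
    return text


def export_cohort(cohort: Cohort, outdir: Path, prefix: str) -> None:
    """Write a cohort in the dosage-table + phenotype-CSV dialect."""
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotypes_table(cohort.genotypes, outdir / f"{prefix}_genotypes.csv")
    cohort.phenotypes.to_csv(outdir / f"{prefix}_phenotypes.csv", index=False)
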