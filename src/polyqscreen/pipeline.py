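"""End-to-end orchestration: simulate -> (render/quantify) -> call -> report.

Each stage is a function whose inputs and outputs are files under the run
directory, so any stage can be rerun from its predecessor's outputs alone.
A JSON manifest records the config echo, seeds, package versions and the
control-QC log.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import FieldSimConfig, RunConfig
from .image_quant import quantify_well
from .io import (
    read_fasta,
    read_field_images,
    read_wells_csv,
    write_fasta,
    write_field_images,
    write_manifest,
)
from .orthology import assign_orthologs, identity_summary
from .screen_calls import build_report, run_cascade
from .simulate import generate_toy_proteomes, render_field, simulate_screen

log = logging.getLogger("polyqscreen")


def _derive_seed(*parts: int) -> int:
    """Stable sub-seed below 2**31 from the global seed and stage indices."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    """Write simulated proteomes, the screen well table and (optionally)
    per-field images with their plate map."""
    if config.simulate_proteomes:
        pconf = dataclasses.replace(config.proteome, seed=_derive_seed(config.seed, 1))
        source, target, truth = generate_toy_proteomes(pconf)
        write_fasta(source, outdir / "source_proteome.fasta")
        write_fasta(target, outdir / "target_proteome.fasta")
        truth.to_csv(outdir / "orthology_truth.csv", index=False)
        log.info("simulate: %d source / %d target proteins", len(source), len(target))

    if config.simulate_screen:
        sconf = dataclasses.replace(config.screen, seed=_derive_seed(config.seed, 2))
        ds = simulate_screen(sconf)
        ds.wells.to_csv(outdir / "wells_raw.csv", index=False)
        ds.truth.to_csv(outdir / "screen_truth.csv", index=False)
        plate_map = ds.wells[["experiment_id", "round", "well", "gene",
                              "construct_id", "role"]].copy()
        plate_map["n_fields"] = sconf.n_fields_per_well
        plate_map.to_csv(outdir / "plate_map.csv", index=False)
        log.info("simulate: %d wells over %d experiments",
                 len(ds.wells), ds.wells["experiment_id"].nunique())

        if config.render_images:
            img_dir = outdir / "images"
            img_dir.mkdir(exist_ok=True)
            for widx, rec in enumerate(ds.wells.itertuples()):
                frac = min(1.0, rec.raw_pct / 100.0)
                for k in range(sconf.n_fields_per_well):
                    fconf = dataclasses.replace(
                        config.field_sim,
                        aggregate_fraction=frac,
                        seed=_derive_seed(config.seed, 3, widx, k),
                    )
                    write_field_images(render_field(fconf), img_dir,
                                       rec.experiment_id, rec.well, k)
            log.info("simulate: rendered %d fields",
                     len(ds.wells) * sconf.n_fields_per_well)


def stage_orthology(config: RunConfig, outdir: Path) -> None:
    """Assign orthologs from the proteome FASTAs; write the assignment TSV
    and an identity summary."""
    src_path = config.source_fasta or outdir / "source_proteome.fasta"
    tgt_path = config.target_fasta or outdir / "target_proteome.fasta"
    source = read_fasta(src_path, "source")
    target = read_fasta(tgt_path, "target")
    table = assign_orthologs(source, target, config.scoring)
    table.to_csv(outdir / "orthology.tsv", sep="\t", index=False)
    summ = identity_summary(table, config.scoring.identity_threshold)
    write_manifest(outdir / "orthology_summary.json", dataclasses.asdict(summ))
    log.info("orthology: %d accepted, %d%% above %g%% identity",
             summ.n_accepted, summ.percent_above, config.scoring.identity_threshold)


def stage_quantify(config: RunConfig, outdir: Path) -> None:
    """Quantify per-well aggregation from field images via the plate map."""
    img_dir = Path(config.image_dir) if config.image_dir else outdir / "images"
    plate_path = (Path(config.image_dir) / "plate_map.csv"
                  if config.image_dir else outdir / "plate_map.csv")
    if not plate_path.exists():
        plate_path = outdir / "plate_map.csv"
    if not plate_path.exists():
        raise FileNotFoundError(f"plate map not found: {plate_path}")
    plate = pd.read_csv(plate_path, keep_default_na=False, na_values=[])
    rows = []
    for rec in plate.itertuples():
        fields = read_field_images(img_dir, rec.experiment_id, rec.well,
                                   int(rec.n_fields))
        wq = quantify_well(fields, config.quant)
        for wmsg in wq.warnings:
            log.warning("quantify: %s", wmsg)
        rows.append({
            "experiment_id": rec.experiment_id, "round": rec.round,
            "well": rec.well, "gene": rec.gene,
            "construct_id": rec.construct_id, "role": rec.role,
            "raw_pct": wq.well_pct if wq.well_pct is not None else np.nan,
        })
    pd.DataFrame(rows).to_csv(outdir / "wells_quant.csv", index=False)
    log.info("quantify: %d wells quantified", len(rows))


def stage_call(config: RunConfig, outdir: Path) -> list:
    """Run the selection cascade on the best available well table."""
    if config.wells_csv:
        wells_path = Path(config.wells_csv)
    elif (outdir / "wells_quant.csv").exists():
        wells_path = outdir / "wells_quant.csv"
    else:
        wells_path = outdir / "wells_raw.csv"
    wells = read_wells_csv(wells_path)
    records, gene_calls, qc_log = run_cascade(wells, config.calls, config.qc)
    flat = records.copy()
    flat["confirm_norms"] = [
        ";".join(repr(v) for v in r) for r in records["confirm_norms"]
    ]
    flat.to_csv(outdir / "constructs.tsv", sep="\t", index=False)
    gene_calls.to_csv(outdir / "gene_calls.tsv", sep="\t", index=False)
    n_hits = int(gene_calls["final_hit"].sum())
    log.info("call: %d/%d genes advanced, %d final hits",
             int(gene_calls["advanced"].sum()), len(gene_calls), n_hits)
    return qc_log


def stage_report(config: RunConfig, outdir: Path) -> None:
    """Join gene calls with orthology identities into report tables."""
    gene_calls = pd.read_csv(outdir / "gene_calls.tsv", sep="\t")
    records = pd.read_csv(outdir / "constructs.tsv", sep="\t",
                          keep_default_na=False, na_values=["", "nan"])
    records["confirm_norms"] = [
        [float(x) for x in str(s).split(";") if x] if s else []
        for s in records["confirm_norms"]
    ]
    ortho_path = outdir / "orthology.tsv"
    ortho = pd.read_csv(ortho_path, sep="\t") if ortho_path.exists() else None
    con, genes, warnings = build_report(gene_calls, records, ortho)
    for w in warnings:
        log.warning("report: %s", w)
    con.to_csv(outdir / "report_constructs.tsv", sep="\t", index=False)
    genes.to_csv(outdir / "report_genes.tsv", sep="\t", index=False)


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages (default: all applicable) and write the
    manifest; returns the run directory."""
    for sub in ("proteome", "field_sim", "screen"):
        getattr(config, sub).validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_stages = ["simulate", "orthology", "quantify", "call", "report"]
    stages = stages or all_stages
    unknown = set(stages) - set(all_stages)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    qc_log: list = []
    if "simulate" in stages and (config.simulate_proteomes or config.simulate_screen):
        stage_simulate(config, outdir)
    if "orthology" in stages and (
        config.simulate_proteomes or (config.source_fasta and config.target_fasta)
    ):
        stage_orthology(config, outdir)
    if "quantify" in stages and (
        config.render_images or config.image_dir is not None
    ):
        stage_quantify(config, outdir)
    if "call" in stages:
        qc_log = stage_call(config, outdir)
    if "report" in stages and (outdir / "gene_calls.tsv").exists():
        stage_report(config, outdir)

    write_manifest(outdir / "run_manifest.json", {
        "polyqscreen_version": __version__,
        "seed": config.seed,
        "stages": stages,
        "config": config.to_dict(),
        "qc_log": [dataclasses.asdict(r) for r in qc_log],
    })
    return outdir
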