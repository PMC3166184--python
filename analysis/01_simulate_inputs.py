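#!/usr/bin/env python
"""Generate every synthetic input the screen pipeline consumes.

Writes, under results/analysis/: a source/target toy proteome pair with
planted orthology (FASTA + truth table), a simulated 200-gene screen with
20% planted suppressors (well table + plate map + truth), and one example
rendered two-channel field as 16-bit TIFFs.
"""

from pathlib import Path

from polyqscreen.config import FieldSimConfig, ProteomeSimConfig, ScreenSimConfig
from polyqscreen.io import write_fasta, write_field_images
from polyqscreen.simulate import generate_toy_proteomes, render_field, simulate_screen

OUT = Path("results/analysis")
SEED = 20260917

OUT.mkdir(parents=True, exist_ok=True)

source, target, ortho_truth = generate_toy_proteomes(
    ProteomeSimConfig(n_families=50, frac_unmappable=0.1, seed=SEED % 2**31)
)
write_fasta(source, OUT / "source_proteome.fasta")
write_fasta(target, OUT / "target_proteome.fasta")
ortho_truth.to_csv(OUT / "orthology_truth.csv", index=False)
n_mapped = (ortho_truth["true_target_id"] != "").sum()
print(f"proteomes: {len(source)} source / {len(target)} target genes, "
      f"{n_mapped} planted ortholog pairs, "
      f"{len(ortho_truth) - n_mapped} unmappable")

screen = simulate_screen(ScreenSimConfig(
    n_genes=200, frac_true_suppressors=0.2, effect_mean=2.2,
    measurement_cv=0.15, seed=(SEED + 1) % 2**31,
))
screen.wells.to_csv(OUT / "wells_raw.csv", index=False)
screen.truth.to_csv(OUT / "screen_truth.csv", index=False)
n_sup = screen.truth.groupby("gene")["status"].first().eq("suppressor").sum()
print(f"screen: {screen.wells['experiment_id'].nunique()} experiments, "
      f"{len(screen.wells)} wells, {n_sup}/200 genes planted as suppressors")

field = render_field(FieldSimConfig(n_cells=25, aggregate_fraction=0.4,
                                    seed=(SEED + 2) % 2**31))
write_field_images(field, OUT / "example_field", "demo", "w01", 0)
print(f"example field: {field.n_cells} nuclei, {field.n_aggregates} aggregates "
      f"-> {OUT / 'example_field'}")
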