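#!/usr/bin/env python
"""Assemble the final report tables.

Joins the gene-level calls from 04 with the orthology assignments from 02
into a hit table (number of confirmed shRNAs, highest average induction,
source-organism gene and percent identity where mapped) and a wide
construct-level table of all normalized values.
"""

from pathlib import Path

import pandas as pd

from polyqscreen.screen_calls import build_report

OUT = Path("results/analysis")

gene_calls = pd.read_csv(OUT / "gene_calls.tsv", sep="\t")
records = pd.read_csv(OUT / "constructs.tsv", sep="\t",
                      keep_default_na=False, na_values=["", "nan"])
records["confirm_norms"] = [
    [float(x) for x in str(s).split(";") if x] if s else []
    for s in records["confirm_norms"]
]
ortho = pd.read_csv(OUT / "orthology.tsv", sep="\t")

con, genes, warnings = build_report(gene_calls, records, ortho)
con.to_csv(OUT / "report_constructs.tsv", sep="\t", index=False)
genes.to_csv(OUT / "report_genes.tsv", sep="\t", index=False)

hits = genes[genes["final_hit"].astype(bool)]
print(f"report: {len(genes)} genes, {len(hits)} final suppressor hits "
      f"({len(warnings)} genes without an orthology record)")
if len(hits):
    cols = ["gene", "n_confirmed", "max_avg_induction"]
    print(hits[cols].head(10).to_string(index=False))
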