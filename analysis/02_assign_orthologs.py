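#!/usr/bin/env python
"""Assign target-organism orthologs to every source gene and check the
planted truth.

Reads the FASTA pair from 01, runs reciprocal best-match assignment with
the four discard rules and the 0.20 score cutoff, writes the full
assignment table plus the identity summary, and reports recovery against
the generator's truth table.
"""

import json
from pathlib import Path

import pandas as pd

from polyqscreen.io import read_fasta
from polyqscreen.orthology import DISCARD_NONE, assign_orthologs, identity_summary

OUT = Path("results/analysis")

source = read_fasta(OUT / "source_proteome.fasta", "source")
target = read_fasta(OUT / "target_proteome.fasta", "target")
table = assign_orthologs(source, target)
table.to_csv(OUT / "orthology.tsv", sep="\t", index=False)

truth = pd.read_csv(OUT / "orthology_truth.csv", keep_default_na=False)
merged = table.merge(truth, on="source_id")
accepted = merged[merged["discard_reason"] == DISCARD_NONE]
mapped = merged[merged["true_target_id"] != ""]
correct = (accepted["best_target_id"] == accepted["true_target_id"]).sum()
print(f"accepted {len(accepted)}/{len(table)} assignments; "
      f"{correct} correct, {len(accepted) - correct} spurious; "
      f"{len(mapped) - len(accepted)} planted pairs missed")
print("discard reasons:", merged["discard_reason"].value_counts().to_dict())

summ = identity_summary(table, identity_threshold=40.0)
(OUT / "orthology_summary.json").write_text(json.dumps({
    "n_accepted": summ.n_accepted,
    "n_above_threshold": summ.n_above_threshold,
    "percent_above": summ.percent_above,
}, indent=2))
print(f"identity: {summ.n_above_threshold}/{summ.n_accepted} accepted genes "
      f"above 40% identity ({summ.percent_above}%)")
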