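"""Selection cascade for suppressor-gene calling.

Stages, in screen order:

1. control QC — GFP knockdown must reduce and CCT2 knockdown must induce
   aggregation, else the experiment is uninterpretable;
2. SCR normalization — the scrambled-control level defines 100% within
   each experiment, never pooled across experiments;
3. round-1 construct calls — normalized induction >= 150% (inclusive);
4. gene advancement — >= 2 positive constructs sends all of a gene's
   constructs into triplicate confirmation;
5. confirmation — per-construct mean over the three confirmation
   experiments against the same cutoff; a gene is a final suppressor hit
   when >= 2 constructs confirm.

All tables are pandas DataFrames; the well table schema is
``experiment_id, round, well, gene, construct_id, role, raw_pct`` with
roles test/SCR/GFP/CCT2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CallParams, QCThresholds
from .simulate import ROLE_CCT2, ROLE_GFP, ROLE_SCR, ROLE_TEST


@dataclass
class QCResult:
    experiment_id: str
    passed: bool
    reason: str | None = None
    gfp_norm: float | None = None
    cct2_norm: float | None = None


def qc_experiment(exp: pd.DataFrame, qc: QCThresholds | None = None) -> QCResult:
    """Check one experiment's GFP/CCT2 controls on the SCR=100 scale.

    Pass requires normalized GFP <= ``gfp_max`` (knockdown of the reporter
    reduces aggregation) and normalized CCT2 >= ``cct2_min`` (chaperonin
    knockdown induces it). Missing controls fail distinctly.
    """
    qc = qc or QCThresholds()
    exp_id = str(exp["experiment_id"].iloc[0]) if len(exp) else "?"
    for role in (ROLE_SCR, ROLE_GFP, ROLE_CCT2):
        if not (exp["role"] == role).any():
            return QCResult(exp_id, False, "missing_control")
    scr = exp.loc[exp["role"] == ROLE_SCR, "raw_pct"].mean()
    if not np.isfinite(scr) or scr <= 0:
        return QCResult(exp_id, False, "uninterpretable_scr")
    gfp = 100.0 * exp.loc[exp["role"] == ROLE_GFP, "raw_pct"].mean() / scr
    cct2 = 100.0 * exp.loc[exp["role"] == ROLE_CCT2, "raw_pct"].mean() / scr
    if gfp > qc.gfp_max:
        return QCResult(exp_id, False, "GFP", gfp, cct2)
    if cct2 < qc.cct2_min:
        return QCResult(exp_id, False, "CCT2", gfp, cct2)
    return QCResult(exp_id, True, None, gfp, cct2)


def normalize_to_scr(wells: pd.DataFrame, value_col: str = "raw_pct") -> pd.DataFrame:
    """Set each experiment's mean SCR level to 100% and scale its wells.

    Normalization is strictly within-experiment. Raises ``ValueError``
    when an experiment has no usable SCR well (mean zero or all missing).
    Applying the function to already-normalized values is the identity,
    since normalized SCR wells average exactly 100.
    """
    out = wells.copy()
    norm = np.full(len(out), np.nan)
    for exp_id, idx in out.groupby("experiment_id").groups.items():
        sub = out.loc[idx]
        scr_vals = sub.loc[sub["role"] == ROLE_SCR, value_col]
        scr_mean = scr_vals.mean()
        if not np.isfinite(scr_mean) or scr_mean <= 0:
            raise ValueError(
                f"experiment {exp_id}: SCR wells missing, blank or zero; "
                "uninterpretable experiment"
            )
        norm[out.index.get_indexer(idx)] = 100.0 * sub[value_col] / scr_mean
    out["norm_pct"] = norm
    return out


def build_construct_records(wells_norm: pd.DataFrame) -> pd.DataFrame:
    """Collapse normalized test wells into one row per shRNA construct.

    ``round1_norm`` averages the (usually single) round-1 well(s);
    ``confirm_norms`` collects the confirmation-round values in experiment
    order. Round-1 values never enter the confirmation average.
    """
    test = wells_norm[wells_norm["role"] == ROLE_TEST]
    rows = []
    for (gene, cid), grp in test.groupby(["gene", "construct_id"], sort=True):
        r1 = grp.loc[grp["round"] == "round1", "norm_pct"]
        confirm = grp[grp["round"] == "confirm"].sort_values("experiment_id")
        rows.append({
            "gene": gene,
            "construct_id": cid,
            "round1_norm": float(r1.mean()) if len(r1) else np.nan,
            "confirm_norms": [float(v) for v in confirm["norm_pct"] if np.isfinite(v)],
        })
    return pd.DataFrame(rows)


def call_round1(records: pd.DataFrame, induction_cutoff: float = 150.0) -> pd.DataFrame:
    """Flag round-1 positive constructs: normalized induction >= cutoff."""
    out = records.copy()
    out["round1_positive"] = out["round1_norm"] >= induction_cutoff
    return out


def advance_genes(records: pd.DataFrame) -> pd.DataFrame:
    """Gene-level advancement: >= 2 round-1-positive constructs.

    Returns a gene table with ``n_constructs, n_round1_positive, advanced``.
    All constructs of an advanced gene (including round-1 negatives)
    proceed to confirmation.
    """
    grouped = records.groupby("gene", sort=True)
    genes = grouped.agg(
        n_constructs=("construct_id", "size"),
        n_round1_positive=("round1_positive", "sum"),
    ).reset_index()
    genes["n_round1_positive"] = genes["n_round1_positive"].astype(int)
    genes["advanced"] = genes["n_round1_positive"] >= 2
    return genes


def confirm_and_call(
    records: pd.DataFrame,
    genes: pd.DataFrame,
    calls: CallParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average the confirmation repeats and make the final gene calls.

    A construct confirms when the mean of exactly ``n_confirm_repeats``
    confirmation values meets the cutoff; a gene is a final hit when it
    advanced and >= ``min_positive_constructs`` constructs confirm. Genes
    whose constructs lack the full set of valid repeats are flagged
    ``incomplete`` and not callable. ``max_avg_induction`` is the highest
    per-construct confirmation average observed for the gene.
    """
    calls = calls or CallParams()
    rec = records.merge(genes[["gene", "advanced"]], on="gene", how="left")
    rec["n_confirm"] = rec["confirm_norms"].map(len)
    rec["confirm_avg"] = [
        float(np.mean(v)) if len(v) else np.nan for v in rec["confirm_norms"]
    ]
    complete = rec["n_confirm"] >= calls.n_confirm_repeats
    rec["confirmed_positive"] = (
        rec["advanced"] & complete & (rec["confirm_avg"] >= calls.induction_cutoff)
    )

    rows = []
    for gene, grp in rec.groupby("gene", sort=True):
        ginfo = genes.loc[genes["gene"] == gene].iloc[0]
        advanced = bool(ginfo["advanced"])
        incomplete = advanced and bool((grp["n_confirm"] < calls.n_confirm_repeats).any())
        n_confirmed = int(grp["confirmed_positive"].sum())
        rows.append({
            "gene": gene,
            "n_constructs": int(ginfo["n_constructs"]),
            "n_round1_positive": int(ginfo["n_round1_positive"]),
            "advanced": advanced,
            "incomplete": incomplete,
            "n_confirmed": n_confirmed,
            "final_hit": advanced and not incomplete
            and n_confirmed >= calls.min_positive_constructs,
            "max_avg_induction": float(grp["confirm_avg"].max())
            if advanced and grp["confirm_avg"].notna().any() else np.nan,
        })
    gene_calls = pd.DataFrame(rows)
    return rec, gene_calls


def run_cascade(
    wells: pd.DataFrame,
    calls: CallParams | None = None,
    qc: QCThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[QCResult]]:
    """Full cascade on a raw well table; returns (records, gene_calls, qc log).

    Experiments failing control QC are dropped before normalization
    (upstream they would be repeated; dropping them here mirrors that the
    failed measurement never counts).
    """
    calls = calls or CallParams()
    qc_log = [qc_experiment(exp, qc) for _, exp in wells.groupby("experiment_id")]
    passing = {r.experiment_id for r in qc_log if r.passed}
    usable = wells[wells["experiment_id"].isin(passing)]
    if usable.empty:
        raise ValueError("no experiment passed control QC")
    normed = normalize_to_scr(usable)
    records = call_round1(build_construct_records(normed), calls.induction_cutoff)
    genes = advance_genes(records)
    records, gene_calls = confirm_and_call(records, genes, calls)
    return records, gene_calls, qc_log


def build_report(
    gene_calls: pd.DataFrame,
    records: pd.DataFrame,
    orthology_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Wide construct-level and gene-level report tables.

    When an orthology table is supplied (keyed by ``best_target_id``), the
    gene table gains source-gene and percent-identity columns; genes absent
    from it are reported with empty identity and a warning, never dropped.
    """
    warnings: list[str] = []
    con = records.copy()
    max_rep = int(con["confirm_norms"].map(len).max()) if len(con) else 0
    for k in range(max_rep):
        con[f"confirm_{k + 1}"] = [
            v[k] if len(v) > k else np.nan for v in con["confirm_norms"]
        ]
    con = con.drop(columns=["confirm_norms"])

    genes = gene_calls.copy()
    if orthology_table is not None and len(genes):
        ortho = orthology_table.rename(
            columns={"best_target_id": "gene", "source_id": "source_gene"}
        )[["gene", "source_gene", "pct_identity"]]
        genes = genes.merge(ortho, on="gene", how="left")
        missing = genes.loc[genes["source_gene"].isna(), "gene"].tolist()
        for g in missing:
            warnings.append(f"gene {g}: no orthology record; identity left empty")
    return con, genes, warnings
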