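"""Reciprocal best-match orthology with score and identity reporting.

Each source-organism gene is assigned its highest-scoring target-organism
sequence under global alignment (BLOSUM62, affine gaps). The raw alignment
score is normalized by the self-alignment score of the shorter sequence,
giving a homology score in [0, 1] with self-score 1. Assignments are then
filtered by four discard rules, applied in order:

1. ``no_ortholog`` — no candidate scores above zero;
2. ``reverse_mismatch`` — the best target's own best match in the source
   proteome is a different gene (paralogy guard);
3. ``multi_source_ambiguity`` — two or more surviving source genes claim
   the same best target ("doubles");
4. ``low_score`` — homology score below the cutoff (default 0.20).

Percent amino-acid identity is computed over aligned columns excluding
terminal gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .config import ScoringParams

_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

DISCARD_NONE = "none"
DISCARD_NO_ORTHOLOG = "no_ortholog"
DISCARD_REVERSE_MISMATCH = "reverse_mismatch"
DISCARD_MULTI_SOURCE = "multi_source_ambiguity"
DISCARD_LOW_SCORE = "low_score"


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with organism tag and optional class label."""

    id: str
    organism: str  # "source" | "target"
    residues: str
    annotation: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")


@dataclass
class BestMatch:
    record: SequenceRecord
    score: float
    ambiguous: bool = False


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _raw_score(a: str, b: str, scoring: ScoringParams) -> float:
    return float(_aligner(scoring.matrix, scoring.gap_open,
                          scoring.gap_extend).score(a.upper(), b.upper()))


def _normalized(raw: float, a: str, b: str, scoring: ScoringParams) -> float:
    shorter = a if len(a) <= len(b) else b
    self_score = _raw_score(shorter, shorter, scoring)
    return float(np.clip(raw / self_score, 0.0, 1.0))


def align_pair(
    a: SequenceRecord, b: SequenceRecord, scoring: ScoringParams | None = None
) -> tuple[float, float]:
    """Globally align two sequences; return (homology score, % identity).

    The score is the raw global-alignment score divided by the
    self-alignment score of the shorter sequence, clipped to [0, 1]; it is
    symmetric in its arguments. Identity counts identical residue pairs
    over aligned columns between the first and last column where both rows
    carry a residue (terminal gaps excluded).
    """
    scoring = scoring or ScoringParams()
    aligner = _aligner(scoring.matrix, scoring.gap_open, scoring.gap_extend)
    sa, sb = a.residues.upper(), b.residues.upper()
    aln = aligner.align(sa, sb)[0]
    raw = aln.score
    score = _normalized(raw, sa, sb, scoring)

    r0, r1 = str(aln[0]), str(aln[1])
    both = [i for i in range(len(r0)) if r0[i] != "-" and r1[i] != "-"]
    if not both:
        return score, 0.0
    lo, hi = both[0], both[-1]
    n_cols = hi - lo + 1
    n_match = sum(1 for i in range(lo, hi + 1) if r0[i] == r1[i] and r0[i] != "-")
    return score, 100.0 * n_match / n_cols


def best_match(
    query: SequenceRecord,
    candidates: list[SequenceRecord],
    scoring: ScoringParams | None = None,
) -> BestMatch | None:
    """Highest-scoring candidate, or None for an empty candidate set.

    Exact score ties are broken toward the lexicographically smaller id and
    flagged ambiguous.
    """
    scoring = scoring or ScoringParams()
    if not candidates:
        return None
    scored = [
        (_normalized(_raw_score(query.residues, c.residues, scoring),
                     query.residues, c.residues, scoring), c)
        for c in candidates
    ]
    top = max(s for s, _ in scored)
    tied = sorted((c for s, c in scored if s == top), key=lambda c: c.id)
    return BestMatch(record=tied[0], score=top, ambiguous=len(tied) > 1)


def _argmax_lex(scores: np.ndarray, ids: list[str]) -> tuple[int, bool]:
    """Index of the max score; ties resolved to the smallest id."""
    top = scores.max()
    tied = [i for i in np.flatnonzero(scores == top)]
    best = min(tied, key=lambda i: ids[i])
    return best, len(tied) > 1


def apply_discard_rules(table: pd.DataFrame, min_score: float = 0.20) -> pd.Series:
    """Assign each row its discard reason, applying the four rules in order.

    ``table`` needs columns ``source_id, best_target_id, score,
    reverse_best_source_id`` (``best_target_id`` empty/None when no
    candidate scored above zero). Rule precedence follows the listing
    order: a gene already discarded by an earlier rule keeps that reason,
    and only genes surviving rules 1-2 participate in the doubles check.
    """
    reason = pd.Series(DISCARD_NONE, index=table.index)
    no_target = table["best_target_id"].isna() | (table["best_target_id"] == "")
    reason[no_target] = DISCARD_NO_ORTHOLOG

    mismatch = (~no_target) & (table["reverse_best_source_id"] != table["source_id"])
    reason[mismatch] = DISCARD_REVERSE_MISMATCH

    surviving = reason == DISCARD_NONE
    counts = table.loc[surviving, "best_target_id"].value_counts()
    doubles = set(counts[counts >= 2].index)
    reason[surviving & table["best_target_id"].isin(doubles)] = DISCARD_MULTI_SOURCE

    reason[(reason == DISCARD_NONE) & (table["score"] < min_score)] = DISCARD_LOW_SCORE
    return reason


def assign_orthologs(
    source: list[SequenceRecord],
    target: list[SequenceRecord],
    scoring: ScoringParams | None = None,
) -> pd.DataFrame:
    """Best-match assignment with reverse confirmation for every source gene.

    Returns one row per source gene with columns ``source_id,
    best_target_id, score, pct_identity, reverse_best_source_id, ambiguous,
    discard_reason``. Percent identity is reported for every gene with a
    best target, discarded or not, so reports can mirror the full
    orthology table.
    """
    scoring = scoring or ScoringParams()
    if not source or not target:
        raise ValueError("source and target sets must be non-empty")

    src_ids = [r.id for r in source]
    tgt_ids = [r.id for r in target]
    matrix = np.empty((len(source), len(target)))
    for i, s in enumerate(source):
        for j, t in enumerate(target):
            matrix[i, j] = _normalized(
                _raw_score(s.residues, t.residues, scoring),
                s.residues, t.residues, scoring,
            )

    rows = []
    for i, s in enumerate(source):
        if matrix[i].max() <= 0.0:
            rows.append({"source_id": s.id, "best_target_id": "", "score": 0.0,
                         "pct_identity": np.nan, "reverse_best_source_id": "",
                         "ambiguous": False})
            continue
        j, ambiguous = _argmax_lex(matrix[i], tgt_ids)
        rev_i, _ = _argmax_lex(matrix[:, j], src_ids)
        _, identity = align_pair(s, target[j], scoring)
        rows.append({"source_id": s.id, "best_target_id": tgt_ids[j],
                     "score": float(matrix[i, j]), "pct_identity": identity,
                     "reverse_best_source_id": src_ids[rev_i],
                     "ambiguous": ambiguous})

    table = pd.DataFrame(rows)
    table["discard_reason"] = apply_discard_rules(table, min_score=scoring.min_score)
    return table


@dataclass
class IdentitySummary:
    n_accepted: int
    n_above_threshold: int
    percent_above: int  # rounded to the nearest integer
    class_mean_identity: dict[str, float]


def identity_summary(
    table: pd.DataFrame,
    identity_threshold: float = 40.0,
    annotations: pd.DataFrame | None = None,
) -> IdentitySummary:
    """Summarize identity over accepted assignments.

    Counts assignments with identity strictly above ``identity_threshold``
    and reports the share as a rounded percentage; when an annotation table
    (``gene_id, functional_class``) is supplied, also reports per-class
    mean identity.
    """
    if table.empty:
        raise ValueError("assignment table is empty")
    accepted = table[table["discard_reason"] == DISCARD_NONE]
    n_acc = len(accepted)
    n_above = int((accepted["pct_identity"] > identity_threshold).sum())
    percent = int(round(100.0 * n_above / n_acc)) if n_acc else 0

    class_means: dict[str, float] = {}
    if annotations is not None and not annotations.empty:
        merged = accepted.merge(
            annotations.rename(columns={"gene_id": "source_id"}),
            on="source_id", how="left",
        )
        grouped = merged.dropna(subset=["functional_class"]).groupby("functional_class")
        class_means = grouped["pct_identity"].mean().to_dict()
    return IdentitySummary(n_acc, n_above, percent, class_means)
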