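import numpy as np
import pandas as pd
import pytest

from polyqscreen.config import ProteomeSimConfig
from polyqscreen.orthology import SequenceRecord
from polyqscreen.simulate import generate_toy_proteomes


@pytest.fixture(scope="session")
def toy_proteomes():
    """Small planted proteome pair shared by the orthology tests."""
    cfg = ProteomeSimConfig(n_families=10, family_size_range=(1, 3),
                            seq_length_range=(80, 140), frac_unmappable=0.1,
                            seed=11)
    source, target, truth = generate_toy_proteomes(cfg)
    src = [SequenceRecord(i, "source", s) for i, s in source]
    tgt = [SequenceRecord(i, "target", s) for i, s in target]
    return src, tgt, truth


def make_records(rows):
    """Construct-record table from (gene, construct, round1, confirms) tuples."""
    return pd.DataFrame(
        [{"gene": g, "construct_id": c, "round1_norm": r1,
          "confirm_norms": list(cf)} for g, c, r1, cf in rows]
    )


def random_record_table(rng: np.random.Generator) -> pd.DataFrame:
    """Random screen records spanning the decision boundary (150 included)."""
    rows = []
    for g in range(int(rng.integers(3, 12))):
        for c in range(int(rng.integers(1, 4))):
            r1 = float(rng.choice([rng.uniform(50, 250), 150.0, 149.999]))
            n_rep = int(rng.choice([3, 3, 3, 2]))
            confirms = [float(rng.uniform(50, 250)) for _ in range(n_rep)]
            rows.append((f"g{g:02d}", f"sh{c + 1}", r1, confirms))
    return make_records(rows)


def cascade_oracle(records: pd.DataFrame, cutoff: float = 150.0,
                   n_repeats: int = 3, min_positive: int = 2) -> dict:
    """Plain-loop re-evaluation of the full selection cascade.

    Independent of the pandas implementation: dict grouping, explicit
    means, explicit rule checks.
    """
    per_gene: dict[str, list] = {}
    for row in records.itertuples():
        per_gene.setdefault(row.gene, []).append(row)
    out = {}
    for gene, cons in per_gene.items():
        n_pos = sum(1 for r in cons
                    if r.round1_norm == r.round1_norm and r.round1_norm >= cutoff)
        advanced = n_pos >= 2
        incomplete = advanced and any(len(r.confirm_norms) < n_repeats for r in cons)
        n_confirmed = 0
        for r in cons:
            if not advanced or len(r.confirm_norms) < n_repeats:
                continue
            avg = sum(r.confirm_norms) / len(r.confirm_norms)
            if avg >= cutoff:
                n_confirmed += 1
        final = advanced and not incomplete and n_confirmed >= min_positive
        out[gene] = {"advanced": advanced, "n_confirmed": n_confirmed,
                     "incomplete": incomplete, "final_hit": final}
    return out
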