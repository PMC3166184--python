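"""Selection-cascade rules: control QC, SCR normalization, the inclusive
150% cutoff, gene advancement, triplicate confirmation and reporting —
with a plain-loop oracle and monotonicity properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import cascade_oracle, make_records, random_record_table
from polyqscreen.config import CallParams, QCThresholds, ScreenSimConfig
from polyqscreen.screen_calls import (
    advance_genes,
    build_report,
    call_round1,
    confirm_and_call,
    normalize_to_scr,
    qc_experiment,
    run_cascade,
)
from polyqscreen.simulate import simulate_screen


def _wells(rows):
    return pd.DataFrame(
        rows,
        columns=["experiment_id", "round", "well", "gene", "construct_id",
                 "role", "raw_pct"],
    )


def _exp(scr=8.0, gfp=4.0, cct2=16.0, tests=()):
    rows = [("E1", "round1", "w1", "", "", "SCR", scr),
            ("E1", "round1", "w2", "GFP", "", "GFP", gfp),
            ("E1", "round1", "w3", "CCT2", "", "CCT2", cct2)]
    rows += [("E1", "round1", f"w{4+i}", g, c, "test", v)
             for i, (g, c, v) in enumerate(tests)]
    return _wells(rows)


class TestQC:
    def test_controls_on_correct_sides_pass(self):
        res = qc_experiment(_exp(scr=8.0, gfp=4.8, cct2=14.4))  # 60% / 180%
        assert res.passed and res.reason is None

    def test_gfp_without_reduction_fails(self):
        res = qc_experiment(_exp(scr=8.0, gfp=8.0, cct2=14.4))  # GFP at 100%
        assert not res.passed and res.reason == "GFP"

    def test_cct2_without_induction_fails(self):
        res = qc_experiment(_exp(scr=8.0, gfp=4.0, cct2=8.8))  # CCT2 at 110%
        assert not res.passed and res.reason == "CCT2"

    def test_missing_control_fails_distinctly(self):
        exp = _exp()
        res = qc_experiment(exp[exp["role"] != "CCT2"])
        assert not res.passed and res.reason == "missing_control"


class TestNormalization:
    def test_test_well_scaled_against_scr(self):
        normed = normalize_to_scr(_exp(scr=8.0, tests=[("g1", "sh1", 12.0)]))
        val = normed.loc[normed["gene"] == "g1", "norm_pct"].iloc[0]
        assert val == pytest.approx(150.0)

    def test_scr_wells_map_to_100(self):
        wells = _exp()
        extra = _wells([("E1", "round1", "w9", "", "", "SCR", 8.0)])
        normed = normalize_to_scr(pd.concat([wells, extra], ignore_index=True))
        scr = normed.loc[normed["role"] == "SCR", "norm_pct"]
        assert scr.tolist() == pytest.approx([100.0, 100.0])

    def test_reducer_recorded_but_below_baseline(self):
        normed = normalize_to_scr(_exp(tests=[("g1", "sh1", 4.0)]))
        assert normed.loc[normed["gene"] == "g1", "norm_pct"].iloc[0] == 50.0

    def test_never_pools_across_experiments(self):
        e1 = _exp(scr=8.0, tests=[("g1", "sh1", 12.0)])
        e2 = _exp(scr=16.0, tests=[("g1", "sh1", 12.0)])
        e2["experiment_id"] = "E2"
        normed = normalize_to_scr(pd.concat([e1, e2], ignore_index=True))
        vals = normed.loc[normed["gene"] == "g1", "norm_pct"].tolist()
        assert vals == pytest.approx([150.0, 75.0])

    def test_idempotent(self):
        normed = normalize_to_scr(_exp(tests=[("g1", "sh1", 12.0)]))
        again = normalize_to_scr(normed, value_col="norm_pct")
        assert again["norm_pct"].tolist() == pytest.approx(normed["norm_pct"].tolist())

    def test_zero_scr_is_uninterpretable(self):
        with pytest.raises(ValueError, match="uninterpretable"):
            normalize_to_scr(_exp(scr=0.0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scr=st.lists(st.floats(0.5, 50.0), min_size=1, max_size=4),
           vals=st.lists(st.floats(0.0, 60.0), min_size=1, max_size=5))
    def test_mean_normalized_scr_is_always_100(self, scr, vals):
        rows = [("E1", "round1", f"s{i}", "", "", "SCR", v)
                for i, v in enumerate(scr)]
        rows += [("E1", "round1", f"t{i}", f"g{i}", "sh1", "test", v)
                 for i, v in enumerate(vals)]
        normed = normalize_to_scr(_wells(rows))
        assert normed.loc[normed["role"] == "SCR", "norm_pct"].mean() == \
            pytest.approx(100.0)


class TestRoundOneAndAdvancement:
    @pytest.mark.parametrize("value,positive", [
        (150.0, True),    # "at least 150%" read as inclusive
        (149.9, False),
        (100.0, False),
        (151.0, True),
    ])
    def test_cutoff_inclusive(self, value, positive):
        rec = call_round1(make_records([("g", "sh1", value, [])]))
        assert bool(rec["round1_positive"].iloc[0]) is positive

    def test_worked_example_43_genes_advance(self):
        """30 genes with two positive constructs plus 13 with three advance;
        fillers with <=1 positive do not."""
        rows = []
        for g in range(30):
            rows += [(f"two{g:02d}", f"sh{i+1}", v, [])
                     for i, v in enumerate([200.0, 180.0, 120.0])]
        for g in range(13):
            rows += [(f"three{g:02d}", f"sh{i+1}", 200.0, []) for i in range(3)]
        for g in range(100):
            rows += [(f"null{g:03d}", f"sh{i+1}", v, [])
                     for i, v in enumerate([160.0, 90.0, 110.0])]
        genes = advance_genes(call_round1(make_records(rows)))
        assert int(genes["advanced"].sum()) == 43
        assert set(genes.loc[genes["advanced"], "gene"]) == \
            {f"two{g:02d}" for g in range(30)} | {f"three{g:02d}" for g in range(13)}

    def test_single_positive_excluded_after_round_one(self):
        genes = advance_genes(call_round1(make_records([
            ("aars", "sh1", 190.0, []), ("aars", "sh2", 120.0, []),
            ("aars", "sh3", 80.0, []),
        ])))
        assert not genes["advanced"].iloc[0]

    def test_two_construct_gene_with_both_positive_advances(self):
        genes = advance_genes(call_round1(make_records([
            ("small", "sh1", 160.0, []), ("small", "sh2", 155.0, []),
        ])))
        assert genes["advanced"].iloc[0]


class TestConfirmation:
    def test_mean_then_cutoff(self):
        rec = make_records([
            ("g", "sh1", 200.0, [160.0, 140.0, 155.0]),
            ("g", "sh2", 200.0, [200.0, 210.0, 190.0]),
        ])
        rec = call_round1(rec)
        genes = advance_genes(rec)
        rec2, calls = confirm_and_call(rec, genes)
        avg = rec2.loc[rec2["construct_id"] == "sh1", "confirm_avg"].iloc[0]
        assert avg == pytest.approx(151.6667, abs=1e-3)
        assert bool(rec2["confirmed_positive"].iloc[0])
        assert bool(calls["final_hit"].iloc[0])
        assert calls["max_avg_induction"].iloc[0] == pytest.approx(200.0)

    def test_single_confirmed_construct_is_not_a_final_hit(self):
        rec = call_round1(make_records([
            ("g", "sh1", 200.0, [200.0, 200.0, 200.0]),
            ("g", "sh2", 200.0, [100.0, 100.0, 100.0]),
            ("g", "sh3", 100.0, [90.0, 90.0, 90.0]),
        ]))
        _, calls = confirm_and_call(rec, advance_genes(rec))
        assert calls["n_confirmed"].iloc[0] == 1
        assert not calls["final_hit"].iloc[0]

    def test_missing_repeats_flag_gene_incomplete(self):
        rec = call_round1(make_records([
            ("g", "sh1", 200.0, [200.0, 200.0]),   # only two valid repeats
            ("g", "sh2", 200.0, [200.0, 200.0, 200.0]),
        ]))
        _, calls = confirm_and_call(rec, advance_genes(rec))
        assert calls["incomplete"].iloc[0]
        assert not calls["final_hit"].iloc[0]


class TestCascadeProperties:
    def test_matches_plain_loop_oracle_on_random_screens(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            rec = random_record_table(rng)
            rec = call_round1(rec)
            genes = advance_genes(rec)
            _, calls = confirm_and_call(rec, genes)
            oracle = cascade_oracle(rec)
            for row in calls.itertuples():
                exp = oracle[row.gene]
                assert row.advanced == exp["advanced"], row.gene
                assert row.final_hit == exp["final_hit"], row.gene
                assert row.n_confirmed == exp["n_confirmed"], row.gene

    def test_raising_a_construct_never_removes_hits(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            rec = random_record_table(rng)

            def hits(r):
                r = call_round1(r)
                _, calls = confirm_and_call(r, advance_genes(r))
                return (set(calls.loc[calls["advanced"], "gene"]),
                        set(calls.loc[calls["final_hit"], "gene"]))

            adv0, fin0 = hits(rec)
            bumped = rec.copy(deep=True)
            i = int(rng.integers(len(bumped)))
            bumped.loc[i, "round1_norm"] += 100.0
            bumped.at[i, "confirm_norms"] = [
                v + 100.0 for v in bumped.at[i, "confirm_norms"]
            ]
            adv1, fin1 = hits(bumped)
            assert adv0 <= adv1 and fin0 <= fin1

    def test_cascade_set_consistency(self):
        ds = simulate_screen(ScreenSimConfig(n_genes=60, seed=3))
        _, calls, _ = run_cascade(ds.wells)
        final = set(calls.loc[calls["final_hit"], "gene"])
        advanced = set(calls.loc[calls["advanced"], "gene"])
        multi = set(calls.loc[calls["n_constructs"] >= 2, "gene"])
        assert final <= advanced <= multi


class TestReport:
    def test_row_conservation_and_orthology_join(self):
        rec = call_round1(make_records([
            ("hA", "sh1", 200.0, [200, 200, 200]),
            ("hA", "sh2", 200.0, [210, 190, 200]),
            ("hB", "sh1", 90.0, [80, 85, 90]),
        ]))
        _, calls = confirm_and_call(rec, advance_genes(rec))
        ortho = pd.DataFrame({
            "source_id": ["ceA"], "best_target_id": ["hA"],
            "pct_identity": [62.0],
        })
        con, genes, warnings = build_report(calls, rec, ortho)
        assert len(genes) == len(calls) == 2
        assert len(con) == 3
        joined = genes.set_index("gene")
        assert joined.loc["hA", "source_gene"] == "ceA"
        assert np.isnan(joined.loc["hB", "pct_identity"])
        assert any("hB" in w for w in warnings)
        assert {"confirm_1", "confirm_2", "confirm_3"} <= set(con.columns)

    def test_empty_input_gives_empty_tables(self):
        rec = call_round1(make_records([]).reindex(
            columns=["gene", "construct_id", "round1_norm", "confirm_norms"]))
        con, genes, _ = build_report(rec.iloc[0:0].assign(), rec, None)
        assert genes.empty
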