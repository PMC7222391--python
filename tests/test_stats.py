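"""Inferential layer vs from-scratch sums-of-squares and closed-form oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mstnet.stats import (
    CONTRASTS,
    EFFECTS,
    analyze_metric_table,
    compare_to_reference,
    condition_summary,
    fdr_adjust,
    paired_contrasts,
    rm_anova_2x2,
)
from mstnet.trial_io import CONDITIONS


def ss_decomposition_oracle(wide: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Two-factor repeated-measures ANOVA by explicit sums of squares.

    ``wide`` is subjects x the four conditions. Returns
    {effect: (F, partial eta squared)} with the effect-by-subject interaction
    as each effect's error stratum.
    """
    y = wide[list(CONDITIONS)].to_numpy()  # HAHV HALV LAHV LALV
    n = y.shape[0]
    # arrange as (subject, arousal level, valence level): [[HAHV, HALV], [LAHV, LALV]]
    cube = y.reshape(n, 2, 2)
    grand = cube.mean()
    subj_mean = cube.mean(axis=(1, 2))
    a_mean = cube.mean(axis=(0, 2))   # arousal levels
    v_mean = cube.mean(axis=(0, 1))   # valence levels
    av_mean = cube.mean(axis=0)       # 2 x 2 cell means
    sa_mean = cube.mean(axis=2)       # subject x arousal
    sv_mean = cube.mean(axis=1)       # subject x valence

    ss_a = 2 * n * ((a_mean - grand) ** 2).sum()
    ss_v = 2 * n * ((v_mean - grand) ** 2).sum()
    ss_av = n * (
        (av_mean - a_mean[:, None] - v_mean[None, :] + grand) ** 2
    ).sum()
    ss_sa = 2 * (
        (sa_mean - subj_mean[:, None] - a_mean[None, :] + grand) ** 2
    ).sum()
    ss_sv = 2 * (
        (sv_mean - subj_mean[:, None] - v_mean[None, :] + grand) ** 2
    ).sum()
    ss_total = ((cube - grand) ** 2).sum()
    ss_subj = 4 * ((subj_mean - grand) ** 2).sum()
    ss_sav = ss_total - ss_subj - ss_a - ss_v - ss_av - ss_sa - ss_sv

    df_err = n - 1
    out = {}
    for effect, ss_eff, ss_err in (
        ("arousal", ss_a, ss_sa),
        ("valence", ss_v, ss_sv),
        ("interaction", ss_av, ss_sav),
    ):
        f = (ss_eff / 1) / (ss_err / df_err)
        out[effect] = (f, ss_eff / (ss_eff + ss_err))
    return out


class TestRmAnova:
    def test_matches_ss_decomposition_oracle(self, hand_metric_table):
        wide = hand_metric_table.pivot(
            index="subject_id", columns="condition", values="value"
        )
        oracle = ss_decomposition_oracle(wide)
        res = rm_anova_2x2(hand_metric_table, "mpli", "gamma").set_index("effect")
        for effect in EFFECTS:
            f_exp, es_exp = oracle[effect]
            assert res.loc[effect, "F"] == pytest.approx(f_exp, rel=1e-9)
            assert res.loc[effect, "es"] == pytest.approx(es_exp, rel=1e-9)
            assert res.loc[effect, "df_effect"] == 1
            assert res.loc[effect, "df_error"] == 5

    def test_matches_pingouin(self, hand_metric_table):
        pingouin = pytest.importorskip("pingouin")
        df = hand_metric_table.copy()
        df["arousal"] = df.condition.str[:2]
        df["valence"] = df.condition.str[2:]
        ref = pingouin.rm_anova(
            data=df, dv="value", within=["arousal", "valence"],
            subject="subject_id", detailed=True,
        ).set_index("Source")
        res = rm_anova_2x2(hand_metric_table, "mpli", "gamma").set_index("effect")
        mapping = {
            "arousal": "arousal", "valence": "valence",
            "interaction": "arousal * valence",
        }
        for effect, src in mapping.items():
            assert res.loc[effect, "F"] == pytest.approx(ref.loc[src, "F"], rel=1e-6)
            assert res.loc[effect, "p"] == pytest.approx(
                ref.loc[src, "p_unc"], abs=1e-9
            )

    def test_identical_values_give_zero_f(self):
        rows = [
            {"subject_id": f"s{s}", "condition": c, "band": "gamma",
             "metric": "m", "value": 0.5}
            for s in range(4) for c in CONDITIONS
        ]
        res = rm_anova_2x2(pd.DataFrame(rows), "m", "gamma")
        assert (res.F == 0).all()
        assert (res.p == 1).all()

    def test_noiseless_planted_effect_hits_degenerate_guard(self):
        rows = [
            {"subject_id": f"s{s}", "condition": c, "band": "gamma",
             "metric": "m", "value": 0.6 if c.startswith("HA") else 0.4}
            for s in range(4) for c in CONDITIONS
        ]
        res = rm_anova_2x2(pd.DataFrame(rows), "m", "gamma").set_index("effect")
        assert np.isinf(res.loc["arousal", "F"])
        assert res.loc["arousal", "p"] == 0.0
        assert res.loc["arousal", "es"] == 1.0

    def test_incomplete_subject_dropped_and_logged(self, hand_metric_table):
        table = hand_metric_table[
            ~((hand_metric_table.subject_id == "s0")
              & (hand_metric_table.condition == "LALV"))
        ]
        res = rm_anova_2x2(table, "mpli", "gamma")
        assert (res.n_subjects == 5).all()
        assert (res.dropped_subjects == "s0").all()

    def test_fewer_than_three_complete_subjects_rejected(self, hand_metric_table):
        table = hand_metric_table[hand_metric_table.subject_id.isin(["s0", "s1"])]
        with pytest.raises(ValueError):
            rm_anova_2x2(table, "mpli", "gamma")


class TestPairedContrasts:
    def test_matches_closed_form_on_hand_vectors(self, hand_metric_table):
        res = paired_contrasts(hand_metric_table, "mpli", "gamma").set_index("contrast")
        wide = hand_metric_table.pivot(
            index="subject_id", columns="condition", values="value"
        )
        n = len(wide)
        for a, b in CONTRASTS:
            d = wide[a].to_numpy() - wide[b].to_numpy()
            t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            assert res.loc[f"{a}-{b}", "t"] == pytest.approx(t_exp, rel=1e-9)
        # cross-check one p value against scipy's paired test
        from scipy.stats import ttest_rel

        t_sp, p_sp = ttest_rel(wide["HAHV"], wide["LAHV"])
        assert res.loc["HAHV-LAHV", "t"] == pytest.approx(t_sp, rel=1e-9)
        assert res.loc["HAHV-LAHV", "p_raw"] == pytest.approx(p_sp, rel=1e-9)

    def test_identical_vectors_give_t_zero_p_one(self):
        rows = [
            {"subject_id": f"s{s}", "condition": c, "band": "g",
             "metric": "m", "value": float(s)}
            for s in range(5) for c in CONDITIONS
        ]
        res = paired_contrasts(pd.DataFrame(rows), "m", "g")
        assert (res.t == 0).all() and (res.p_raw == 1).all()

    def test_constant_nonzero_difference_reported_missing(self):
        rows = []
        for s in range(5):
            for c in CONDITIONS:
                value = 1.0 if c == "HAHV" else 0.0
                rows.append(
                    {"subject_id": f"s{s}", "condition": c, "band": "g",
                     "metric": "m", "value": value}
                )
        res = paired_contrasts(pd.DataFrame(rows), "m", "g").set_index("contrast")
        assert np.isnan(res.loc["HAHV-LAHV", "t"])
        assert res.loc["LAHV-LALV", "t"] == 0.0


class TestFdr:
    def test_hand_applied_bh_example(self):
        adjusted = fdr_adjust([0.01, 0.02, 0.04, 0.5])
        assert adjusted == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.5])

    def test_all_equal_unchanged(self):
        assert fdr_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.123]) == pytest.approx([0.123])

    def test_empty_list(self):
        assert fdr_adjust([]) == []

    def test_never_decreases_and_order_invariant(self, rng):
        p = rng.uniform(0, 1, size=12).tolist()
        adj = fdr_adjust(p)
        assert all(a >= x for a, x in zip(adj, p))
        assert all(a <= 1 for a in adj)
        perm = rng.permutation(12)
        adj_perm = fdr_adjust([p[k] for k in perm])
        assert sorted(adj_perm) == pytest.approx(sorted(adj))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestAnalyzeTable:
    def test_families_and_columns(self, hand_metric_table):
        res = analyze_metric_table(hand_metric_table, fdr_family="per-metric")
        assert set(res) == {"anova", "contrasts", "summary"}
        assert len(res["anova"]) == 3
        assert len(res["contrasts"]) == 4
        assert res["contrasts"].p_fdr.notna().all()
        summary = res["summary"]
        assert set(summary.condition) == set(CONDITIONS)

    def test_reference_benchmark_comparison_machinery(self, hand_metric_table):
        summary = condition_summary(hand_metric_table)
        out = compare_to_reference(summary)
        assert len(out) == 20  # 5 metrics x 4 conditions in the benchmark
        mpli_rows = out[out.metric == "mpli"]
        assert mpli_rows.observed_mean.notna().all()
        assert mpli_rows.z.notna().all()
        # metrics absent from the hand table stay NaN rather than failing
        assert out[out.metric == "diameter"].observed_mean.isna().all()
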