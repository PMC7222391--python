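"""Group-level inference for the 2 (arousal) x 2 (valence) within-subject design.

Input is a long-format metric table with one value per
subject x condition x band x metric. Each metric x band cell receives:

* a two-factor repeated-measures ANOVA (main effects of arousal and valence
  and their interaction). With two levels per within factor the ANOVA is
  computed exactly through per-subject contrast scores: for each effect the
  contrast c_s collapses the subject's four condition means with +/- weights,
  and F = t^2 of the one-sample t-test on c_s with df = (1, n-1). This is
  algebraically identical to the sums-of-squares decomposition (the
  effect-by-subject interaction is the error stratum) and sphericity is
  trivially satisfied with two levels. The effect size is partial eta
  squared, SS_effect / (SS_effect + SS_error) = t^2 / (t^2 + df_error);
* paired two-sided t-tests on the four fixed condition contrasts
  HAHV-LAHV, HALV-LALV, HAHV-HALV, LAHV-LALV;
* Benjamini-Hochberg FDR adjustment of the contrast p values. The default
  adjustment family is the four contrasts of one metric within one band;
  optionally the family pools all metrics within a band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .trial_io import CONDITIONS

__all__ = [
    "EFFECTS",
    "CONTRASTS",
    "rm_anova_2x2",
    "paired_contrasts",
    "fdr_adjust",
    "condition_summary",
    "analyze_metric_table",
    "GAMMA_REFERENCE_SUMMARY",
    "compare_to_reference",
]

EFFECTS: tuple[str, ...] = ("arousal", "valence", "interaction")

#: The four fixed paired contrasts, as (minuend, subtrahend).
CONTRASTS: tuple[tuple[str, str], ...] = (
    ("HAHV", "LAHV"),
    ("HALV", "LALV"),
    ("HAHV", "HALV"),
    ("LAHV", "LALV"),
)

# +/- 1/2 weights per condition for each effect's per-subject contrast score
_EFFECT_WEIGHTS: dict[str, dict[str, float]] = {
    "arousal": {"HAHV": 0.5, "HALV": 0.5, "LAHV": -0.5, "LALV": -0.5},
    "valence": {"HAHV": 0.5, "LAHV": 0.5, "HALV": -0.5, "LALV": -0.5},
    "interaction": {"HAHV": 0.5, "LALV": 0.5, "HALV": -0.5, "LAHV": -0.5},
}


def _pivot_complete(
    table: pd.DataFrame, metric: str, band: str
) -> tuple[pd.DataFrame, list[str]]:
    """Subjects x conditions value grid; incomplete subjects are dropped."""
    sub = table[(table["metric"] == metric) & (table["band"] == band)]
    if sub.empty:
        raise ValueError(f"no rows for metric={metric!r}, band={band!r}")
    if sub.duplicated(["subject_id", "condition"]).any():
        raise ValueError("metric table has duplicate subject x condition rows")
    wide = sub.pivot(index="subject_id", columns="condition", values="value")
    missing_cols = [c for c in CONDITIONS if c not in wide.columns]
    for c in missing_cols:
        wide[c] = np.nan
    dropped = list(wide.index[wide[list(CONDITIONS)].isna().any(axis=1)])
    wide = wide.dropna(subset=list(CONDITIONS))
    return wide[list(CONDITIONS)], dropped


def _one_sample_f(c: np.ndarray) -> tuple[float, float, float]:
    """F, p, partial eta squared of the one-sample test that mean(c) = 0."""
    n = len(c)
    df_error = n - 1
    sd = c.std(ddof=1)
    mean = c.mean()
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0, 0.0
        return float("inf"), 0.0, 1.0  # noiseless planted effect
    t = mean / (sd / np.sqrt(n))
    f = t**2
    p = float(sp_stats.f.sf(f, 1, df_error))
    es = f / (f + df_error)
    return float(f), p, float(es)


def rm_anova_2x2(table: pd.DataFrame, metric: str, band: str) -> pd.DataFrame:
    """Repeated-measures 2x2 ANOVA for one metric x band.

    Returns one row per effect (arousal, valence, interaction) with columns
    ``metric, band, effect, F, df_effect, df_error, p, es, n_subjects,
    dropped_subjects``. Effect df is 1; error df is n_subjects - 1; ``es`` is
    partial eta squared.
    """
    wide, dropped = _pivot_complete(table, metric, band)
    n = len(wide)
    if n < 3:
        raise ValueError(
            f"only {n} subjects with complete 2x2 data for {metric}/{band}; need >= 3"
        )
    rows = []
    for effect in EFFECTS:
        weights = _EFFECT_WEIGHTS[effect]
        c = sum(weights[cond] * wide[cond].to_numpy() for cond in CONDITIONS)
        f, p, es = _one_sample_f(np.asarray(c))
        rows.append(
            {
                "metric": metric,
                "band": band,
                "effect": effect,
                "F": f,
                "df_effect": 1,
                "df_error": n - 1,
                "p": p,
                "es": es,
                "n_subjects": n,
                "dropped_subjects": ";".join(map(str, dropped)),
            }
        )
    return pd.DataFrame(rows)


def paired_contrasts(table: pd.DataFrame, metric: str, band: str) -> pd.DataFrame:
    """Two-sided paired t-tests on the four fixed condition contrasts.

    t = mean(diff) / (sd(diff) / sqrt(n)) on subject-matched values. A
    zero-variance nonzero difference leaves t undefined (reported as NaN);
    identical vectors give t = 0, p = 1.
    """
    wide, _ = _pivot_complete(table, metric, band)
    n = len(wide)
    if n < 2:
        raise ValueError(f"need >= 2 complete subjects for paired tests, got {n}")
    rows = []
    for a, b in CONTRASTS:
        d = wide[a].to_numpy() - wide[b].to_numpy()
        sd = d.std(ddof=1)
        if sd == 0:
            t, p = (0.0, 1.0) if np.all(d == 0) else (float("nan"), float("nan"))
        else:
            t = d.mean() / (sd / np.sqrt(n))
            p = float(2 * sp_stats.t.sf(abs(t), n - 1))
        rows.append(
            {
                "metric": metric,
                "band": band,
                "contrast": f"{a}-{b}",
                "t": float(t),
                "p_raw": p,
                "n_subjects": n,
            }
        )
    return pd.DataFrame(rows)


def fdr_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = list(p_values)
    if not p:
        return []
    if any(not (0 <= x <= 1) for x in p if not np.isnan(x)):
        raise ValueError("p values must lie in [0, 1]")
    arr = np.asarray(p, dtype=float)
    ok = ~np.isnan(arr)
    out = np.full(arr.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    return out.tolist()


#: Published gamma-band condition means and SDs from the DEAP-cohort study of
#: emotional MST topology. These are an *optional* benchmark: they come from
#: real recordings, so synthetic studies are not expected to match them —
#: they are only meaningful when the pipeline is run on the actual DEAP data.
GAMMA_REFERENCE_SUMMARY: pd.DataFrame = pd.DataFrame(
    [
        ("mpli", "HAHV", 0.119, 0.0017), ("mpli", "LAHV", 0.118, 0.0033),
        ("mpli", "HALV", 0.121, 0.0027), ("mpli", "LALV", 0.118, 0.0032),
        ("degree_max", "HAHV", 0.236, 0.037), ("degree_max", "LAHV", 0.201, 0.024),
        ("degree_max", "HALV", 0.27, 0.052), ("degree_max", "LALV", 0.214, 0.036),
        ("leaf_fraction", "HAHV", 0.562, 0.035), ("leaf_fraction", "LAHV", 0.54, 0.056),
        ("leaf_fraction", "HALV", 0.593, 0.052), ("leaf_fraction", "LALV", 0.546, 0.048),
        ("diameter", "HAHV", 0.052, 0.0045), ("diameter", "LAHV", 0.056, 0.0071),
        ("diameter", "HALV", 0.048, 0.0045), ("diameter", "LALV", 0.055, 0.0062),
        ("eccentricity", "HAHV", 0.039, 0.0034), ("eccentricity", "LAHV", 0.042, 0.0051),
        ("eccentricity", "HALV", 0.037, 0.0033), ("eccentricity", "LALV", 0.042, 0.0048),
    ],
    columns=["metric", "condition", "ref_mean", "ref_sd"],
)


def compare_to_reference(
    summary: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    band: str = "gamma",
    n_sd: float = 2.0,
) -> pd.DataFrame:
    """Compare observed condition means against the published benchmark.

    ``summary`` is the output of :func:`condition_summary`. Returns one row
    per benchmark entry with the observed mean, the z-score
    ``(observed - ref_mean) / ref_sd`` and whether it falls within ``n_sd``
    reference SDs. Benchmark entries without an observed counterpart get NaN.
    """
    if reference is None:
        reference = GAMMA_REFERENCE_SUMMARY
    obs = summary[summary["band"] == band][["metric", "condition", "mean"]]
    out = reference.merge(obs, on=["metric", "condition"], how="left")
    out = out.rename(columns={"mean": "observed_mean"})
    out["z"] = (out["observed_mean"] - out["ref_mean"]) / out["ref_sd"]
    within = pd.array(out["z"].abs() <= n_sd, dtype="boolean")
    within[out["z"].isna().to_numpy()] = pd.NA
    out["within_tolerance"] = within
    return out


def condition_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per metric x band x condition mean and SD across subjects."""
    g = table.groupby(["metric", "band", "condition"])["value"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"count": "n_subjects"})


def analyze_metric_table(
    table: pd.DataFrame, fdr_family: str = "per-metric"
) -> dict[str, pd.DataFrame]:
    """Run the full inferential layer over every metric x band in the table.

    ``fdr_family`` controls the Benjamini-Hochberg adjustment family for the
    contrast p values: ``'per-metric'`` (default) adjusts the four contrasts
    of each metric within each band; ``'per-band'`` pools all metrics of a
    band into one family.

    Returns ``{'anova': ..., 'contrasts': ..., 'summary': ...}``.
    """
    if fdr_family not in ("per-metric", "per-band"):
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    anova_rows, contrast_rows = [], []
    for (band, metric), _ in table.groupby(["band", "metric"], sort=True):
        anova_rows.append(rm_anova_2x2(table, metric, band))
        contrast_rows.append(paired_contrasts(table, metric, band))
    anova = pd.concat(anova_rows, ignore_index=True)
    contrasts = pd.concat(contrast_rows, ignore_index=True)
    group_cols = ["band", "metric"] if fdr_family == "per-metric" else ["band"]
    contrasts["p_fdr"] = np.nan
    for _, idx in contrasts.groupby(group_cols).groups.items():
        contrasts.loc[idx, "p_fdr"] = fdr_adjust(contrasts.loc[idx, "p_raw"].tolist())
    return {
        "anova": anova,
        "contrasts": contrasts,
        "summary": condition_summary(table),
    }
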