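"""Repertoire summary statistics over annotated rearrangement tables.

All statistics run on the AIRR-style rearrangement table (one row per
retained read — duplicate junctions are separate rows, never collapsed) and,
following the bait-capture quantification convention, count only records
whose junction breakpoints are on-target (within the RSS +/- w window of
every assigned segment).  Ambiguous segment sets (sequence-identical
segments, reported as "id1,id2") contribute fractionally, 1/k per member.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "UsageProfile",
    "Cdr3Profile",
    "usage_frequencies",
    "productive_fraction",
    "dj_vdj_ratio",
    "cdr3_profile",
    "compare_profiles",
    "plot_usage",
    "plot_cdr3_lengths",
]

AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY*")


@dataclass
class UsageProfile:
    """Per-segment counts and frequencies, optionally stratified."""

    table: pd.DataFrame  # columns: [*strata], segment, count, frequency
    segment_field: str
    strata: list[str] = field(default_factory=list)
    ambiguous_segments: list[str] = field(default_factory=list)

    def frequencies(self, **stratum) -> pd.Series:
        t = self.table
        for k, v in stratum.items():
            t = t[t[k] == v]
        return t.set_index("segment")["frequency"]


@dataclass
class Cdr3Profile:
    """CDR3 length histogram and per-length positional aa frequencies."""

    length_histogram: pd.Series        # index: length (aa), values: counts
    median_length: float
    position_frequency: dict           # length -> DataFrame (position x aa)
    n_records: int


def _norm_strata(stratify_by) -> list[str]:
    if stratify_by is None:
        return []
    if isinstance(stratify_by, str):
        return [stratify_by]
    return list(stratify_by)


def usage_frequencies(
    records: pd.DataFrame,
    segment_field: str = "v_call",
    stratify_by=None,
    on_target_only: bool = True,
) -> UsageProfile:
    """Segment usage counts and within-stratum frequencies.

    Rows with an empty segment call are skipped; ambiguous sets split one
    count equally among their members and are listed in
    ``UsageProfile.ambiguous_segments`` as a caveat (the apportionment between
    sequence-identical segments is arbitrary).  An empty selection yields an
    empty profile, not NaNs.
    """
    strata = _norm_strata(stratify_by)
    df = records
    if on_target_only and "on_target" in df.columns:
        df = df[df["on_target"].astype(bool)]
    df = df[df[segment_field].astype(str) != ""]
    ambiguous = sorted(set(df.loc[df[segment_field].astype(str).str.contains(","),
                                  segment_field]))

    if df.empty:
        cols = strata + ["segment", "count", "frequency"]
        return UsageProfile(pd.DataFrame(columns=cols), segment_field, strata,
                            ambiguous)

    rows = []
    for tup in df.itertuples(index=False):
        rec = tup._asdict()
        members = str(rec[segment_field]).split(",")
        w = 1.0 / len(members)
        base = {k: rec[k] for k in strata}
        for m in members:
            rows.append({**base, "segment": m, "count": w})
    counts = pd.DataFrame(rows)
    grouped = counts.groupby(strata + ["segment"], as_index=False)["count"].sum()
    if strata:
        totals = grouped.groupby(strata)["count"].transform("sum")
    else:
        totals = grouped["count"].sum()
    grouped["frequency"] = grouped["count"] / totals
    return UsageProfile(grouped, segment_field, strata, ambiguous)


def productive_fraction(records: pd.DataFrame, stratify_by=None,
                        ci_alpha: float = 0.05) -> pd.DataFrame:
    """Fraction of productive VDJ rearrangements with a binomial CI (Wilson)."""
    strata = _norm_strata(stratify_by)
    df = records[records["event_class"] == "VDJ"]
    groups = df.groupby(strata) if strata else [((), df)]
    rows = []
    for key, g in groups:
        n = len(g)
        k = int(g["productive"].astype(bool).sum())
        frac = k / n if n else float("nan")
        lo, hi = proportion_confint(k, n, alpha=ci_alpha, method="wilson") \
            if n else (float("nan"), float("nan"))
        row = dict(zip(strata, key if isinstance(key, tuple) else (key,)))
        row.update({"n": n, "n_productive": k, "productive_fraction": frac,
                    "ci_low": lo, "ci_high": hi})
        rows.append(row)
    return pd.DataFrame(rows)


def dj_vdj_ratio(records: pd.DataFrame, stratify_by=None,
                 on_target_only: bool = True) -> pd.DataFrame:
    """Ratio of DJ-class to VDJ-class on-target junction counts."""
    strata = _norm_strata(stratify_by)
    df = records[records["event_class"].isin(["DJ", "VDJ"])]
    if on_target_only and "on_target" in df.columns:
        df = df[df["on_target"].astype(bool)]
    groups = df.groupby(strata) if strata else [((), df)]
    rows = []
    for key, g in groups:
        n_dj = int((g["event_class"] == "DJ").sum())
        n_vdj = int((g["event_class"] == "VDJ").sum())
        if n_vdj == 0:
            warnings.warn("zero VDJ junctions in stratum; ratio is infinite",
                          stacklevel=2)
            ratio = float("inf")
        else:
            ratio = n_dj / n_vdj
        row = dict(zip(strata, key if isinstance(key, tuple) else (key,)))
        row.update({"n_dj": n_dj, "n_vdj": n_vdj, "dj_vdj_ratio": ratio})
        rows.append(row)
    return pd.DataFrame(rows)


def cdr3_profile(records: pd.DataFrame) -> Cdr3Profile:
    """Length histogram, median and positional aa frequencies of CDR3s.

    Uses productive records with a CDR3 amino-acid sequence; each
    position-frequency matrix column (position) sums to 1.
    """
    df = records[records["productive"].astype(bool)
                 & (records["junction_aa"].astype(str) != "")]
    lengths = df["junction_aa"].str.len()
    hist = lengths.value_counts().sort_index()
    hist.index.name = "cdr3_length_aa"
    median = float(lengths.median()) if len(lengths) else float("nan")

    pfms: dict[int, pd.DataFrame] = {}
    for length, g in df.groupby(lengths):
        mat = np.zeros((int(length), len(AMINO_ACIDS)))
        aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
        for seq in g["junction_aa"]:
            for pos, aa in enumerate(seq):
                mat[pos, aa_index.get(aa, aa_index["*"])] += 1
        mat /= mat.sum(axis=1, keepdims=True)
        pfms[int(length)] = pd.DataFrame(
            mat, columns=AMINO_ACIDS,
            index=pd.RangeIndex(1, int(length) + 1, name="position"),
        )
    return Cdr3Profile(hist, median, pfms, len(df))


def _ttest(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided two-sample t-test; degenerate zero-variance null gives p=1."""
    if np.allclose(x.var(ddof=0) + y.var(ddof=0), 0.0):
        return 1.0 if np.isclose(x.mean(), y.mean()) else 0.0
    return float(stats.ttest_ind(x, y).pvalue)


def compare_profiles(a: UsageProfile, b: UsageProfile,
                     group_names: tuple[str, str] = ("a", "b")) -> dict:
    """Per-segment replicate-level comparison of two usage profiles.

    Requires >= 2 replicates per group (``replicate`` stratum).  Returns a
    dict with a per-segment table (two-sided t-test across replicate
    frequencies, raw and Holm-adjusted p, Tukey-adjusted p from the pairwise
    group comparison) and the two-way segment x group ANOVA table.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    frames = []
    for prof, name in ((a, group_names[0]), (b, group_names[1])):
        if "replicate" not in prof.strata:
            raise ValueError("profiles must be stratified by 'replicate'")
        t = prof.table.copy()
        if t["replicate"].nunique() < 2:
            raise ValueError("need at least 2 replicates per group")
        t["group"] = name
        frames.append(t[["replicate", "segment", "frequency", "group"]])
    df = pd.concat(frames, ignore_index=True)
    # absent segment in a replicate means frequency zero
    full = (df.set_index(["group", "replicate", "segment"])["frequency"]
              .unstack(fill_value=0.0).stack().rename("frequency").reset_index())

    rows = []
    for seg, g in full.groupby("segment"):
        x = g.loc[g["group"] == group_names[0], "frequency"].to_numpy(float)
        y = g.loc[g["group"] == group_names[1], "frequency"].to_numpy(float)
        p = _ttest(x, y)
        if np.allclose(np.concatenate([x, y]).var(), 0.0):
            tk = 1.0
        else:
            tk = float(pairwise_tukeyhsd(g["frequency"], g["group"]).pvalues[0])
        rows.append({"segment": seg,
                     f"mean_{group_names[0]}": x.mean(),
                     f"mean_{group_names[1]}": y.mean(),
                     "p_raw": p, "p_tukey": tk})
    table = pd.DataFrame(rows)
    table["p_holm"] = multipletests(table["p_raw"], method="holm")[1]

    if full["frequency"].var() > 0:
        model = ols("frequency ~ C(segment) * C(group)", data=full).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    else:
        anova = None
    return {"per_segment": table, "anova": anova}


def plot_usage(profile: UsageProfile, ax=None, productive_split: Optional[pd.DataFrame] = None):
    """Bar chart of segment usage frequencies (matplotlib Axes returned)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, len(profile.table) * 0.3), 3))
    t = (profile.table.groupby("segment", as_index=False)["frequency"].mean()
         if profile.strata else profile.table)
    ax.bar(t["segment"], t["frequency"])
    ax.set_ylabel("usage frequency")
    ax.tick_params(axis="x", rotation=90)
    return ax


def plot_cdr3_lengths(profile: Cdr3Profile, ax=None):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.bar(profile.length_histogram.index, profile.length_histogram.values)
    ax.set_xlabel("CDR3 length (aa)")
    ax.set_ylabel("productive records")
    return ax
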