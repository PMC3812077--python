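"""Repertoire-level summaries: repeat-context assignment, per-repeat-length
averages, S/I ratios, InDel length distributions, tolerated-position calls,
region summaries and log-linear repeat-length regressions.

The central quantity is the per-run InDel frequency: because all placements
of an InDel inside a homonucleotide run are indistinguishable and calls are
left-aligned, a run carries its whole InDel burden at its first position,
and the per-run frequency is the sum of corrected insertion + deletion
frequencies there.  Class means average this over *all* runs of a
(length, base) class, runs without any detected InDel contributing zero;
pooled per-length means weight the per-base class means by their occurrence
counts.  The regression fits log10(mean frequency) on run length by
ordinary least squares; the fold change per repeat nucleotide is 10^slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import GeneReference, RepeatRun, run_at

CONTEXT_REPEAT = "repeat"
CONTEXT_ADJACENT = "adjacent-to-repeat"
CONTEXT_NONREPEAT = "non-repeat"

#: run length from which a homonucleotide stretch is tabulated as a repeat
MIN_REPEAT_LENGTH = 3


def _indel_base(kind: str, payload, ref_seq: str, position: int) -> str:
    if kind == "del":
        return ref_seq[position - 1]
    payload = str(payload)
    return payload[0]


def assign_repeat_context(
    freq_table: pd.DataFrame, ref: GeneReference, runs: list[RepeatRun]
) -> pd.DataFrame:
    """Annotate each call with its homonucleotide-run context.

    InDel calls whose base matches the run at their canonical position are
    'repeat' (or 'non-repeat' when that run has length 1); calls whose base
    differs from a flanking run of >= MIN_REPEAT_LENGTH are
    'adjacent-to-repeat' (InDels at repeat ends of a different base).
    """
    out = freq_table.copy()
    run_base, run_len, run_start, context = [], [], [], []
    for row in out.itertuples(index=False):
        run = run_at(runs, row.position)
        if row.type == "sub":
            run_base.append(run.base)
            run_len.append(run.length)
            run_start.append(run.start)
            context.append(CONTEXT_REPEAT if run.length > 1 else CONTEXT_NONREPEAT)
            continue
        base = _indel_base(row.type, row.payload, ref.sequence, row.position)
        if base == run.base:
            run_base.append(run.base)
            run_len.append(run.length)
            run_start.append(run.start)
            context.append(
                CONTEXT_REPEAT if run.length > 1 else CONTEXT_NONREPEAT
            )
        else:
            # a call that borders a repeat of a different base: find the
            # longest flanking run (the one it sits at the end of)
            neighbours = [run]
            if row.position > 1:
                neighbours.append(run_at(runs, row.position - 1))
            best = max(neighbours, key=lambda r: r.length)
            run_base.append(best.base)
            run_len.append(best.length)
            run_start.append(best.start)
            context.append(
                CONTEXT_ADJACENT
                if best.length >= MIN_REPEAT_LENGTH
                else CONTEXT_NONREPEAT
            )
    out["run_base"] = run_base
    out["run_length"] = run_len
    out["run_start"] = run_start
    out["context"] = context
    return out


def per_run_frequencies(
    annotated: pd.DataFrame, runs: list[RepeatRun], min_length: int = MIN_REPEAT_LENGTH
) -> pd.DataFrame:
    """Corrected InDel frequency per run (ins + del summed at the run's
    canonical position) for every run of length >= min_length; runs without
    calls appear with frequency 0."""
    indels = annotated[
        annotated["type"].isin(["ins", "del"])
        & (annotated["context"] == CONTEXT_REPEAT)
        & annotated["corrected"].notna()
    ]
    by_start = indels.groupby("run_start")["corrected"].sum()
    rows = [
        {
            "run_start": r.start,
            "base": r.base,
            "length": r.length,
            "frequency": float(by_start.get(r.start, 0.0)),
        }
        for r in runs
        if r.length >= min_length
    ]
    return pd.DataFrame(rows, columns=["run_start", "base", "length", "frequency"])


def summarize_by_repeat(
    annotated: pd.DataFrame,
    runs: list[RepeatRun],
    background_indel: float,
    min_length: int = MIN_REPEAT_LENGTH,
) -> pd.DataFrame:
    """Per-(length, base) summary: mean per-run frequency over all runs of
    the class, run count, and the number of runs at >= 10x background."""
    per_run = per_run_frequencies(annotated, runs, min_length)
    if per_run.empty:
        return pd.DataFrame(
            columns=["length", "base", "occurrence", "mean_frequency", "n_above_background"]
        )
    thresh = 10.0 * background_indel
    grouped = per_run.groupby(["length", "base"])
    out = grouped.agg(
        occurrence=("frequency", "size"),
        mean_frequency=("frequency", "mean"),
        n_above_background=("frequency", lambda f: int((f >= thresh).sum())),
    ).reset_index()
    return out.sort_values(["length", "base"], ascending=[False, True]).reset_index(drop=True)


def pooled_length_means(summary: pd.DataFrame, weighted: bool = True) -> pd.Series:
    """Mean frequency per run length.  By default the occurrence-weighted
    average of the per-base class means (equivalently, the average over all
    runs of that length); ``weighted=False`` gives the plain mean of the
    per-base class means instead."""
    if weighted:
        w = summary["mean_frequency"] * summary["occurrence"]
        return w.groupby(summary["length"]).sum() / summary.groupby("length")["occurrence"].sum()
    return summary.groupby("length")["mean_frequency"].mean()


@dataclass(frozen=True)
class RegressionFit:
    """Least-squares fit of log10(mean InDel frequency) on repeat length."""

    slope: float
    intercept: float
    r_squared: float
    lengths_used: tuple[int, ...]
    excluded_zero_lengths: tuple[int, ...]

    @property
    def fold_per_nt(self) -> float:
        return 10.0**self.slope

    def predict(self, length: float) -> float:
        """Mean frequency predicted at a given repeat length (same scale as
        the fitted means)."""
        return 10.0 ** (self.intercept + self.slope * length)


def fit_loglinear(length_means, lengths_to_use=None) -> RegressionFit:
    """Fit log10(mean frequency) vs repeat length.

    ``length_means`` maps run length -> mean frequency (Series or dict).
    Zero (or negative) means cannot enter the log fit; they are excluded and
    reported.  Requires >= 3 usable length classes.
    """
    s = pd.Series(dict(length_means)).sort_index()
    if lengths_to_use is not None:
        s = s[s.index.isin(lengths_to_use)]
    zero = tuple(int(i) for i in s.index[s <= 0])
    s = s[s > 0]
    if len(s) < 3:
        raise ValueError(
            f"insufficient points for the log-linear fit: {len(s)} usable length classes"
        )
    res = stats.linregress(s.index.to_numpy(float), np.log10(s.to_numpy(float)))
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        lengths_used=tuple(int(i) for i in s.index),
        excluded_zero_lengths=zero,
    )


def si_ratio(sub_frequency: float, indel_frequency: float) -> float | None:
    """Point-mutation to InDel frequency ratio; None when undefined (I=0
    with S>0)."""
    if indel_frequency == 0:
        return 0.0 if sub_frequency == 0 else None
    return sub_frequency / indel_frequency


_LENGTH_CATEGORIES = ["<-1", "-1", "+1", "+2", "+3", ">+3"]


def _length_category(signed_length: int) -> str:
    if signed_length <= -2:
        return "<-1"
    if signed_length == -1:
        return "-1"
    if signed_length <= 3:
        return f"+{signed_length}"
    return ">+3"


def indel_length_distribution(table: pd.DataFrame) -> dict[str, float]:
    """Percentage of each signed InDel length class among all InDel events
    (weighted by read support); percentages sum to 100."""
    indels = table[table["type"].isin(["ins", "del"]) & (table["flag"] != "edge_artifact")]
    if indels.empty or indels["count"].sum() == 0:
        raise ValueError("no InDel events to distribute")
    counts: dict[str, float] = {}
    for row in indels.itertuples(index=False):
        length = len(str(row.payload)) if row.type == "ins" else -int(row.payload)
        cat = _length_category(length)
        counts[cat] = counts.get(cat, 0) + row.count
    total = sum(counts.values())
    return {
        cat: 100.0 * counts[cat] / total
        for cat in _LENGTH_CATEGORIES
        if cat in counts
    }


def tolerated_positions(
    table: pd.DataFrame, background_indel: float, fold: float = 10.0
) -> set[tuple[int, str]]:
    """Positions whose corrected InDel frequency is at least ``fold`` times
    the repertoire's InDel background (inclusive threshold)."""
    indels = table[table["type"].isin(["ins", "del"]) & table["corrected"].notna()]
    thresh = fold * background_indel
    return {
        (int(r.position), r.type)
        for r in indels.itertuples(index=False)
        if r.corrected >= thresh
    }


def region_summary(
    table: pd.DataFrame,
    ref: GeneReference,
    regions: dict[str, tuple[int, int]],
) -> pd.DataFrame:
    """Per-region S (mean substitution frequency per position), I (mean
    InDel frequency per position), S/I, insertion and deletion rates, and
    the InDel length distribution."""
    rows = []
    ok = table[(table["flag"] != "edge_artifact") & table["corrected"].notna()]
    for label, (lo, hi) in regions.items():
        n_pos = hi - lo + 1
        if n_pos <= 0:
            raise ValueError(f"empty region {label!r}")
        sub = ok[(ok["type"] == "sub") & ok["position"].between(lo, hi)]
        ins = ok[(ok["type"] == "ins") & ok["position"].between(lo, hi)]
        dele = ok[(ok["type"] == "del") & ok["position"].between(lo, hi)]
        S = sub["corrected"].sum() / n_pos
        ins_rate = ins["corrected"].sum() / n_pos
        del_rate = dele["corrected"].sum() / n_pos
        I = ins_rate + del_rate
        region_indels = pd.concat([ins, dele])
        dist = (
            indel_length_distribution(region_indels)
            if not region_indels.empty and region_indels["count"].sum() > 0
            else {}
        )
        rows.append(
            {
                "region": label, "n_positions": n_pos,
                "S": S, "I": I, "S_over_I": si_ratio(S, I),
                "insertions": ins_rate, "deletions": del_rate,
                "length_distribution_pct": dist,
            }
        )
    return pd.DataFrame(rows)


def compare_repertoires(
    g0_table: pd.DataFrame,
    g17_table: pd.DataFrame,
    g0_background: float,
    g17_background: float,
    threshold_folds: tuple[float, ...] = (10.0, 100.0),
) -> pd.DataFrame:
    """Joint per-(position, type) view of both repertoires with detection
    flags at each background-fold threshold (the machine-readable form of a
    per-position frequency track comparison)."""
    def prep(t, name):
        indels = t[t["type"].isin(["ins", "del"]) & t["corrected"].notna()]
        agg = indels.groupby(["position", "type"])["corrected"].sum()
        return agg.rename(name)

    merged = pd.concat(
        [prep(g0_table, "g0_frequency"), prep(g17_table, "g17_frequency")], axis=1
    ).fillna(0.0).reset_index()
    for fold in threshold_folds:
        merged[f"g0_ge_{int(fold)}x"] = merged["g0_frequency"] >= fold * g0_background
        merged[f"g17_ge_{int(fold)}x"] = merged["g17_frequency"] >= fold * g17_background
    return merged
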