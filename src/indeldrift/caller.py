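"""Pooled-read mutation calling with background subtraction.

Pipeline: align each read (``align.ReadAligner``), record one observation
per mismatch or gap passing the base-quality threshold, left-align indels to
their canonical repeat position, tally per-position counts and coverage,
flag read-edge artifact calls, estimate the sequencing-error background from
the unmutagenized control region, and emit a per-position frequency table
with raw and background-corrected frequencies.

Frequencies follow the pooled-amplicon definition: the number of reads
carrying a given mutation at a position divided by the number of reads
covering that position.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignParams, ReadAligner, ReadAlignment, left_align_indel
from .reference import GeneReference

FLAG_OK = ""
FLAG_EDGE = "edge_artifact"
FLAG_LOW_SUPPORT = "low_support"


@dataclass(frozen=True)
class MutationObservation:
    """One read-level mutation observation at a canonical reference position.

    ``payload`` is the substituted base (sub), the inserted bases (ins), or
    the deleted length (del).  ``read_offset`` is the 0-based distance of
    the event from the nearer read end, used by the edge-artifact filter.
    """

    position: int
    kind: str  # 'sub' | 'ins' | 'del'
    payload: object
    read_offset: int
    base_quality: int


@dataclass
class CallerParams:
    quality_threshold: int = 20
    edge_margin: int = 3          # nt from either read end counted as "edge"
    edge_mass_threshold: float = 0.9
    uniformity_alpha: float = 0.01
    min_support: int = 5
    align: AlignParams = field(default_factory=AlignParams)


class PositionCounts:
    """Per-position coverage and per-(position, kind, payload) mutation
    counts, plus read-offset histograms for the edge filter."""

    def __init__(self, ref_length: int, read_length_hint: int = 40):
        self.coverage = np.zeros(ref_length + 1, dtype=np.int64)  # 1-based
        # indel-effective coverage: an indel at the first or last aligned
        # position of a read cannot alter its best alignment (it is absorbed
        # into the fitting-alignment ends), so those positions do not probe
        # indels; using this denominator removes the resulting ~2/L
        # detection bias from indel frequencies
        self.indel_coverage = np.zeros(ref_length + 1, dtype=np.int64)
        self.counts: dict[tuple[int, str, object], int] = defaultdict(int)
        self.offsets: dict[tuple[int, str, object], list[int]] = defaultdict(list)
        self.read_length_hint = read_length_hint
        self.n_reads = 0

    def add_alignment(self, aln: ReadAlignment, observations: list[MutationObservation]) -> None:
        self.coverage[aln.ref_start : aln.ref_end + 1] += 1
        self.indel_coverage[aln.ref_start + 1 : aln.ref_end] += 1
        self.n_reads += 1
        for obs in observations:
            key = (obs.position, obs.kind, obs.payload)
            self.counts[key] += 1
            self.offsets[key].append(obs.read_offset)


def collect_observations(
    aln: ReadAlignment,
    read_seq: str,
    read_quals,
    ref: GeneReference | str,
    quality_threshold: int = 20,
) -> list[MutationObservation]:
    """Walk an alignment and emit observations for every mismatch and gap
    whose involved bases all reach the quality threshold.

    Deletions carry no read bases; they are kept when both flanking read
    bases pass the threshold.  Indel positions are canonical (left-aligned).
    """
    ref_seq = ref.sequence if isinstance(ref, GeneReference) else ref
    m = len(read_seq)

    def offset(read_pos: int) -> int:
        return min(read_pos, m - 1 - read_pos)

    def equiv_offset(read_pos: int, base: str | None) -> int:
        """Distance from the nearer read end of the most edge-compatible
        equivalent placement of an indel.  Inside a homopolymer run the gap
        placement is ambiguous in read coordinates; an event is treated as
        edge-proximal if ANY equivalent placement is, which keeps the edge
        filter sensitive to artifacts absorbed into runs."""
        if base is None:
            return offset(read_pos)
        lo = hi = min(read_pos, m - 1)
        while lo > 0 and read_seq[lo - 1] == base:
            lo -= 1
        while hi + 1 < m and read_seq[hi + 1] == base:
            hi += 1
        return min(offset(lo), offset(hi))

    out: list[MutationObservation] = []
    i, j = 0, aln.ref_start  # read index (0-based), ref position (1-based)
    for op, length in aln.cigar:
        if op == "M":
            for k in range(length):
                if read_seq[i + k] != ref_seq[j + k - 1]:
                    q = int(read_quals[i + k])
                    if q >= quality_threshold:
                        out.append(
                            MutationObservation(j + k, "sub", read_seq[i + k], offset(i + k), q)
                        )
            i += length
            j += length
        elif op == "I":
            ins = read_seq[i : i + length]
            q = int(min(read_quals[i : i + length]))
            if q >= quality_threshold:
                pos, payload = left_align_indel(ref_seq, j, "ins", ins)
                base = ins[0] if len(set(ins)) == 1 else None
                out.append(MutationObservation(pos, "ins", payload, equiv_offset(i, base), q))
            i += length
        elif op == "D":
            flank_q = [int(read_quals[i - 1])] if i > 0 else []
            if i < m:
                flank_q.append(int(read_quals[i]))
            q = min(flank_q) if flank_q else 0
            if q >= quality_threshold:
                pos, payload = left_align_indel(ref_seq, j, "del", length)
                deleted = ref_seq[j - 1 : j - 1 + length]
                base = deleted[0] if len(set(deleted)) == 1 else None
                out.append(
                    MutationObservation(pos, "del", payload, equiv_offset(min(i, m - 1), base), q)
                )
            j += length
    return out


def edge_bias_filter(
    counts: PositionCounts, params: CallerParams | None = None
) -> dict[tuple[int, str, object], str]:
    """Flag indel calls whose supporting observations cluster at read ends.

    A call is 'edge_artifact' when (a) at least ``edge_mass_threshold`` of
    its support lies within ``edge_margin`` nt of a read end, or (b) a
    chi-square test rejects uniformity of its offset histogram at
    ``uniformity_alpha`` AND a one-sided binomial test finds the edge mass
    significantly above its uniform expectation at the same alpha.
    Calls with fewer than ``min_support`` observations are 'low_support'
    (retained).  Substitution calls are never flagged.
    """
    params = params or CallerParams()
    half = max(1, counts.read_length_hint // 2)
    expected_edge_frac = min(1.0, params.edge_margin / half)
    flags: dict[tuple[int, str, object], str] = {}
    for key, offs in counts.offsets.items():
        if key[1] == "sub":
            flags[key] = FLAG_OK
            continue
        n = len(offs)
        if n < params.min_support:
            flags[key] = FLAG_LOW_SUPPORT
            continue
        arr = np.asarray(offs)
        edge_frac = float((arr < params.edge_margin).mean())
        if edge_frac >= params.edge_mass_threshold:
            flags[key] = FLAG_EDGE
            continue
        hist = np.bincount(arr, minlength=half)[:half]
        chi2_p = stats.chisquare(hist).pvalue
        k_edge = int((arr < params.edge_margin).sum())
        edge_p = stats.binomtest(k_edge, n, expected_edge_frac, alternative="greater").pvalue
        if chi2_p < params.uniformity_alpha and edge_p < params.uniformity_alpha:
            flags[key] = FLAG_EDGE
        else:
            flags[key] = FLAG_OK
    return flags


def estimate_background(
    counts: PositionCounts,
    ref: GeneReference,
    flags: dict | None = None,
) -> tuple[float, float]:
    """Pooled sequencing-error rates (sub_rate, indel_rate) over the
    unmutagenized control region: total counts of each type divided by total
    coverage of control positions.  Edge-flagged calls are excluded."""
    if ref.control_interval is None:
        raise ValueError("reference has no control interval")
    s, e = ref.control_interval
    total_cov = int(counts.coverage[s : e + 1].sum())
    total_indel_cov = int(counts.indel_coverage[s : e + 1].sum())
    if total_cov == 0 or total_indel_cov == 0:
        raise ValueError("control region has zero coverage")
    sub = indel = 0
    for (pos, kind, payload), c in counts.counts.items():
        if not s <= pos <= e:
            continue
        if flags is not None and flags.get((pos, kind, payload)) == FLAG_EDGE:
            continue
        if kind == "sub":
            sub += c
        else:
            indel += c
    return sub / total_cov, indel / total_indel_cov


def build_frequency_table(
    counts: PositionCounts,
    background: tuple[float, float],
    flags: dict[tuple[int, str, object], str],
    ref: GeneReference,
    repertoire: str = "G0",
    interval: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-position, per-type frequency table for the analyzed interval.

    raw = count / coverage; corrected = max(0, raw - background of that
    type).  Edge-flagged calls keep their row but report NaN frequencies
    (excluded from all downstream summaries).  Positions with zero coverage
    are reported as missing (NaN frequencies).
    """
    sub_bg, indel_bg = background
    lo, hi = interval if interval is not None else ref.orf_interval
    rows = []
    for (pos, kind, payload), c in sorted(
        counts.counts.items(), key=lambda kv: (kv[0][0], kv[0][1], str(kv[0][2]))
    ):
        if not lo <= pos <= hi:
            continue
        cov = int(counts.coverage[pos] if kind == "sub" else counts.indel_coverage[pos])
        flag = flags.get((pos, kind, payload), FLAG_OK)
        if cov == 0:
            raw = corrected = np.nan
        elif flag == FLAG_EDGE:
            raw = c / cov
            corrected = np.nan
        else:
            raw = c / cov
            bg = sub_bg if kind == "sub" else indel_bg
            corrected = max(0.0, raw - bg)
        rows.append(
            {
                "position": pos,
                "region": ref.region_of(pos),
                "type": kind,
                "payload": payload,
                "count": c,
                "coverage": cov,
                "raw": raw,
                "corrected": corrected,
                "flag": flag,
                "repertoire": repertoire,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "position", "region", "type", "payload", "count",
            "coverage", "raw", "corrected", "flag", "repertoire",
        ],
    )
    df.attrs["background_sub"] = sub_bg
    df.attrs["background_indel"] = indel_bg
    df.attrs["repertoire"] = repertoire
    df.attrs["interval"] = (lo, hi)
    return df


@dataclass
class CallResult:
    frequency_table: pd.DataFrame
    counts: PositionCounts
    flags: dict
    background: tuple[float, float]  # (sub_rate, indel_rate)
    n_aligned: int
    discards: object


def call_reads(
    reads,
    ref: GeneReference,
    params: CallerParams | None = None,
    repertoire: str = "G0",
    interval: tuple[int, int] | None = None,
) -> CallResult:
    """Full calling pipeline over an iterable of (read_id, seq, quals).

    ``quals`` is a sequence of phred scores, one per base.
    """
    params = params or CallerParams()
    aligner = ReadAligner(ref.sequence, params.align)
    counts: PositionCounts | None = None
    n_aligned = 0
    for read_id, seq, quals in reads:
        if counts is None:
            counts = PositionCounts(len(ref), read_length_hint=len(seq))
        aln = aligner.align(seq, read_id)
        if aln is None:
            continue
        obs = collect_observations(aln, seq, quals, ref, params.quality_threshold)
        counts.add_alignment(aln, obs)
        n_aligned += 1
    if counts is None:
        raise ValueError("no reads supplied")
    flags = edge_bias_filter(counts, params)
    background = estimate_background(counts, ref, flags)
    table = build_frequency_table(counts, background, flags, ref, repertoire, interval)
    return CallResult(table, counts, flags, background, n_aligned, aligner.discards)


def write_frequency_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    with open(path, "w") as fh:
        fh.write(
            f"# repertoire={df.attrs.get('repertoire')} "
            f"background_sub={df.attrs.get('background_sub'):.6g} "
            f"background_indel={df.attrs.get('background_indel'):.6g}\n"
        )
        out.to_csv(fh, sep="\t", index=False)


def read_frequency_table(path: str | Path) -> pd.DataFrame:
    header = Path(path).open().readline()
    df = pd.read_csv(path, sep="\t", comment="#")
    if header.startswith("#"):
        for tok in header[1:].split():
            k, _, v = tok.partition("=")
            df.attrs[k] = float(v) if k.startswith("background") else v
    return df
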