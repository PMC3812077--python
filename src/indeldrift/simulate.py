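"""Synthetic laboratory genetic drift with repeat-length-dependent slippage
and frame-shift bypass.

The generator emulates the study conditions of the M.HaeIII drift
experiment: error-prone PCR adds ~2.2±1.6 substitutions per gene per round
plus slippage InDels whose per-run probability grows ~2.5-fold per repeat
nucleotide; purifying selection removes non-functional variants, but
frame-shifting InDels survive with a probability that itself grows with
repeat length (transcriptional/translational bypass, ~1.36-fold per
nucleotide so that occurrence x bypass reproduces the observed ~3.4-fold
post-selection slope); short single-end reads are then sampled with a
background sequencing-error model (substitutions ~1.7e-3/base, InDels
~2.1e-5/base) and optional read-edge InDel artifacts.

Selection is phenotypic and memoryless: a frame-shifting InDel re-rolls its
bypass at every round, so its pool frequency equilibrates at
slip_L * p_L / (1 - p_L).  Substitution lethality, in contrast, is an
intrinsic property assigned once when the substitution arises.

All randomness flows from one ``numpy.random.Generator`` seeded from
``SimulationConfig.seed``; identical configs give identical outputs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple
import warnings

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import GeneReference, RepeatRun, find_homonucleotide_runs
from .synthetic_reference import motif_mask_positions, synthetic_gene_reference

BASES = "ACGT"
_ALT = {b: [x for x in BASES if x != b] for b in BASES}


class EmptyPoolError(RuntimeError):
    """Selection left no survivors; the caller may resample or re-seed."""


class Edit(NamedTuple):
    """One genomic edit relative to the reference.

    position: canonical 1-based reference position (run start for InDels);
    kind: 'sub' | 'ins' | 'del';
    payload: alt base (sub), inserted bases (ins) or deleted length (del);
    run_length: homonucleotide run length at the InDel site (0 for subs);
    lethal: substitutions only — drawn once when the edit arises.
    """

    position: int
    kind: str
    payload: object
    run_length: int = 0
    lethal: bool = False

    @property
    def indel_length(self) -> int:
        if self.kind == "ins":
            return len(self.payload)
        if self.kind == "del":
            return -int(self.payload)
        return 0


@dataclass
class VariantGenome:
    edits: dict[int, Edit] = field(default_factory=dict)
    lineage_id: int = 0

    def copy(self) -> "VariantGenome":
        return VariantGenome(dict(self.edits), self.lineage_id)


@dataclass(frozen=True)
class SlippageModel:
    """Replication-slippage InDel model: per-run event probability
    rate_length1 * fold_per_nt**(L-1), with event lengths drawn from
    ``event_probs`` (signed: -1 deletion, +k insertion of k run bases)."""

    rate_length1: float = 1e-4
    fold_per_nt: float = 2.5
    event_probs: dict[int, float] = field(
        default_factory=lambda: {-1: 0.69, +1: 0.289, +2: 0.018, +3: 0.0015}
    )

    def __post_init__(self):
        if not 0 <= self.rate_length1 < 1:
            raise ValueError("rate_length1 must be in [0, 1)")
        if self.fold_per_nt <= 0:
            raise ValueError("fold_per_nt must be positive")

    @property
    def deletion_fraction(self) -> float:
        total = sum(self.event_probs.values())
        return sum(v for k, v in self.event_probs.items() if k < 0) / total

    def run_probability(self, length: int) -> float:
        return min(1.0, self.rate_length1 * self.fold_per_nt ** (length - 1))


@dataclass(frozen=True)
class BypassModel:
    """Survival model under purifying selection.

    A frame-shifting InDel in a run of length L survives one selection with
    probability min(1, bypass_length1 * fold_per_nt**(L-1)); survival is 0
    at motif-masked positions.  In-frame InDels survive with the flat
    ``inframe_survival`` (a free parameter: they need no bypass but remain
    deleterious)."""

    bypass_length1: float = 0.03
    fold_per_nt: float = 1.36
    motif_mask: frozenset[int] = frozenset()
    inframe_survival: float = 0.1

    def survival(self, edit: Edit) -> float:
        if edit.kind == "sub":
            return 0.0 if edit.lethal else 1.0
        if edit.position in self.motif_mask:
            return 0.0
        if abs(edit.indel_length) % 3 == 0:
            return self.inframe_survival
        return min(1.0, self.bypass_length1 * self.fold_per_nt ** (edit.run_length - 1))


@dataclass
class SimulationConfig:
    mutation_load_mean: float = 2.2   # substitutions per gene per round
    mutation_load_sd: float = 1.6
    rounds: int = 17
    pool_size: int = 10_000
    read_length: int = 40
    mean_depth: float = 500.0         # reads covering each position, on average
    seq_error_sub: float = 1.7e-3     # background substitution rate per base
    seq_error_indel: float = 2.1e-5   # background InDel rate per base
    edge_artifact_rate: float = 0.0   # per-read rate of edge-confined InDel artifacts
    edge_artifact_quality: int = 15   # phred score of artifact bases
    base_quality: int = 30
    lethal_sub_fraction: float = 0.3  # free parameter: lethal share of substitutions
    enrichment_cycles: int = 1        # selection stringency per round
    seed: int = 0

    def __post_init__(self):
        for name in ("seq_error_sub", "seq_error_indel", "edge_artifact_rate",
                     "lethal_sub_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.pool_size < 1 or self.rounds < 0:
            raise ValueError("pool_size must be >= 1 and rounds >= 0")


def sample_mutation_count(config: SimulationConfig, rng: np.random.Generator) -> int:
    """Number of substitutions for one gene in one mutagenesis, drawn from a
    negative binomial parameterized to the configured mean and SD (the
    simplest two-parameter family matching both moments when overdispersed);
    falls back to Poisson when sd^2 < mean."""
    m, v = config.mutation_load_mean, config.mutation_load_sd**2
    if v <= m:
        if v < m:
            warnings.warn("mutation load sd^2 < mean: falling back to Poisson")
        return int(rng.poisson(m))
    r = m * m / (v - m)
    return int(rng.negative_binomial(r, m / v))


def _mutation_count_batch(config: SimulationConfig, rng, size: int) -> np.ndarray:
    m, v = config.mutation_load_mean, config.mutation_load_sd**2
    if v <= m:
        return rng.poisson(m, size)
    r = m * m / (v - m)
    return rng.negative_binomial(r, m / v, size)


def orf_runs(ref: GeneReference) -> list[RepeatRun]:
    """Maximal runs of the reference restricted to the mutagenized ORF."""
    lo, hi = ref.orf_interval
    return [
        r for r in find_homonucleotide_runs(ref.sequence)
        if r.start >= lo and r.end <= hi
    ]


def _slippage_edit(run: RepeatRun, event_length: int) -> Edit:
    if event_length < 0:
        return Edit(run.start, "del", -event_length, run.length)
    return Edit(run.start, "ins", run.base * event_length, run.length)


def mutate_genome(
    genome: VariantGenome,
    ref: GeneReference,
    runs: list[RepeatRun],
    slippage: SlippageModel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> VariantGenome:
    """One error-prone replication of one genome: adds sampled substitutions
    at uniform ORF positions and, independently per run, slippage InDels.
    Positions already carrying an edit are left untouched."""
    g = genome.copy()
    lo, hi = ref.orf_interval
    n_sub = sample_mutation_count(config, rng)
    for pos in rng.integers(lo, hi + 1, n_sub):
        pos = int(pos)
        if pos in g.edits:
            continue
        alt = _ALT[ref.base_at(pos)][int(rng.integers(3))]
        g.edits[pos] = Edit(pos, "sub", alt, 0, bool(rng.random() < config.lethal_sub_fraction))
    lengths = np.array(sorted(slippage.event_probs), dtype=int)
    probs = np.array([slippage.event_probs[k] for k in lengths], dtype=float)
    probs = probs / probs.sum()
    for run in runs:
        if rng.random() < slippage.run_probability(run.length):
            if run.start in g.edits:
                continue
            ev = int(rng.choice(lengths, p=probs))
            g.edits[run.start] = _slippage_edit(run, ev)
    return g


def mutate_pool(
    pool: list[VariantGenome],
    ref: GeneReference,
    runs: list[RepeatRun],
    slippage: SlippageModel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[VariantGenome]:
    """Vectorized error-prone replication of a whole pool (one round);
    equivalent in distribution to mapping ``mutate_genome``."""
    n = len(pool)
    lo, hi = ref.orf_interval
    out = [g.copy() for g in pool]

    n_sub = _mutation_count_batch(config, rng, n)
    total = int(n_sub.sum())
    positions = rng.integers(lo, hi + 1, total)
    alt_idx = rng.integers(3, size=total)
    lethal = rng.random(total) < config.lethal_sub_fraction
    k = 0
    for gi, cnt in enumerate(n_sub):
        g = out[gi]
        for _ in range(cnt):
            pos = int(positions[k])
            if pos not in g.edits:
                alt = _ALT[ref.base_at(pos)][int(alt_idx[k])]
                g.edits[pos] = Edit(pos, "sub", alt, 0, bool(lethal[k]))
            k += 1

    run_p = np.array([slippage.run_probability(r.length) for r in runs])
    hits = np.nonzero(rng.random((n, len(runs))) < run_p[None, :])
    lengths = np.array(sorted(slippage.event_probs), dtype=int)
    probs = np.array([slippage.event_probs[k] for k in lengths], dtype=float)
    probs = probs / probs.sum()
    events = rng.choice(lengths, size=len(hits[0]), p=probs)
    for gi, ri, ev in zip(*hits, events):
        g = out[gi]
        run = runs[ri]
        if run.start not in g.edits:
            g.edits[run.start] = _slippage_edit(run, int(ev))
    return out


def selection_round(
    pool: list[VariantGenome],
    bypass: BypassModel,
    rng: np.random.Generator,
    cycles: int = 1,
) -> list[VariantGenome]:
    """One round of purifying selection: each genome survives only if every
    edit survives; frame-shifting InDels roll their bypass probability
    independently in each of ``cycles`` enrichment cycles."""
    if not pool:
        raise EmptyPoolError("selection applied to an empty pool")
    survivors = []
    for g in pool:
        p = 1.0
        for e in g.edits.values():
            p *= bypass.survival(e) ** (cycles if e.kind != "sub" else 1)
            if p == 0.0:
                break
        if p == 1.0 or rng.random() < p:
            survivors.append(g)
    if not survivors:
        raise EmptyPoolError("no genome survived selection")
    return survivors


def pool_truth_table(pool: list[VariantGenome], repertoire: str) -> pd.DataFrame:
    """True per-(position, type, payload) frequencies in a pool: edit count
    divided by pool size (the oracle for parameter-recovery checks)."""
    counts = Counter(
        (e.position, e.kind, str(e.payload)) for g in pool for e in g.edits.values()
    )
    rows = [
        {
            "position": pos, "type": kind, "payload": payload,
            "true_frequency": c / len(pool), "repertoire": repertoire,
        }
        for (pos, kind, payload), c in sorted(counts.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
    ]
    return pd.DataFrame(rows, columns=["position", "type", "payload", "true_frequency", "repertoire"])


def _apply_edits(ref_seq: str, genome: VariantGenome) -> str:
    """Materialize a genome's sequence from the reference and its edits."""
    pieces: list[str] = []
    cursor = 0  # 0-based index into ref_seq
    for pos in sorted(genome.edits):
        e = genome.edits[pos]
        p0 = pos - 1
        if p0 < cursor:
            continue  # overlapped by a previous deletion
        pieces.append(ref_seq[cursor:p0])
        if e.kind == "sub":
            pieces.append(e.payload)
            cursor = p0 + 1
        elif e.kind == "ins":
            pieces.append(e.payload + ref_seq[p0])
            cursor = p0 + 1
        else:  # del
            cursor = p0 + int(e.payload)
    pieces.append(ref_seq[cursor:])
    return "".join(pieces)


def generate_reads(
    pool: list[VariantGenome],
    ref: GeneReference,
    config: SimulationConfig,
    rng: np.random.Generator,
    repertoire: str = "G0",
    region: tuple[int, int] | None = None,
) -> tuple[list[tuple[str, str, np.ndarray]], pd.DataFrame]:
    """Fragment pool genomes into single-end reads with background errors.

    Returns (reads, truth table); each read is (id, sequence, phred array).
    ``region`` restricts read start positions (1-based ref interval), e.g.
    to oversample the control region; by default reads start anywhere.
    Background substitutions and InDels are injected uniformly (control
    region included); edge artifacts are 1-nt insertions confined to the
    terminal ``edge_margin`` (3) nt of reads, at reduced base quality.
    """
    if not pool:
        raise ValueError("empty pool")
    L = config.read_length
    if L > len(ref):
        raise ValueError("read_length exceeds the reference length")
    truth = pool_truth_table(pool, repertoire)

    if region is None:
        span = len(ref)
        start_lo = 0
    else:
        start_lo = region[0] - 1
        span = min(region[1], len(ref)) - region[0] + 1
    n_reads = int(round(config.mean_depth * span / L))

    genome_idx = rng.integers(0, len(pool), n_reads)
    n_sub_err = rng.binomial(L, config.seq_error_sub, n_reads)
    n_indel_err = rng.binomial(L, config.seq_error_indel, n_reads)
    artifact = rng.random(n_reads) < config.edge_artifact_rate
    seq_cache: dict[int, str] = {}

    reads: list[tuple[str, str, np.ndarray]] = []
    for ri in range(n_reads):
        gi = int(genome_idx[ri])
        if gi not in seq_cache:
            seq_cache[gi] = _apply_edits(ref.sequence, pool[gi])
        template = seq_cache[gi]
        hi = min(start_lo + span, len(template)) - L
        lo = min(start_lo, hi)
        start = int(rng.integers(lo, hi + 1))
        seq = list(template[start : start + L + 4])  # slack for deletions
        qual = [config.base_quality] * len(seq)

        for _ in range(int(n_sub_err[ri])):
            i = int(rng.integers(L))
            seq[i] = _ALT[seq[i]][int(rng.integers(3))]
        for _ in range(int(n_indel_err[ri])):
            i = int(rng.integers(L))
            if rng.random() < 0.5:
                seq.insert(i, seq[i])  # polymerase-stutter duplication
                qual.insert(i, config.base_quality)
            else:
                del seq[i]
                del qual[i]
        seq, qual = seq[:L], qual[:L]
        if artifact[ri]:
            off = int(rng.integers(3))
            base = BASES[int(rng.integers(4))]
            if rng.random() < 0.5:
                seq.insert(off, base)
                qual.insert(off, config.edge_artifact_quality)
                seq, qual = seq[:L], qual[:L]
            else:
                seq.insert(len(seq) - off, base)
                qual.insert(len(qual) - off, config.edge_artifact_quality)
                seq, qual = seq[1:], qual[1:]
        reads.append((f"{repertoire}_{ri:07d}", "".join(seq), np.array(qual)))
    return reads, truth


@dataclass
class DriftResult:
    ref: GeneReference
    g0_reads: list
    g17_reads: list
    g0_truth: pd.DataFrame
    g17_truth: pd.DataFrame
    g0_pool: list[VariantGenome]
    g17_pool: list[VariantGenome]


def default_models(ref: GeneReference) -> tuple[SlippageModel, BypassModel]:
    """Study-condition defaults: slippage calibrated to the published G0
    repeat table, bypass to the post-selection table, conserved-motif
    repeats fully intolerant."""
    return SlippageModel(), BypassModel(motif_mask=motif_mask_positions(ref))


def simulate_drift(
    config: SimulationConfig,
    slippage: SlippageModel | None = None,
    bypass: BypassModel | None = None,
    ref: GeneReference | None = None,
) -> DriftResult:
    """Run the full drift: G0 = pool after the first mutagenesis, before any
    selection; G17 = pool after ``config.rounds`` iterations of
    mutagenesis + selection (re-transformed to pool_size after each round).
    With rounds=0 the selected pool is the naive pool itself."""
    rng = np.random.default_rng(config.seed)
    if ref is None:
        ref = synthetic_gene_reference()
    if slippage is None or bypass is None:
        s_def, b_def = default_models(ref)
        slippage = slippage or s_def
        bypass = bypass or b_def
    runs = orf_runs(ref)

    initial = [VariantGenome(lineage_id=i) for i in range(config.pool_size)]
    g0_pool = mutate_pool(initial, ref, runs, slippage, config, rng)

    if config.rounds == 0:
        g17_pool = g0_pool
    else:
        pool = selection_round(g0_pool, bypass, rng, config.enrichment_cycles)
        pool = _resample(pool, config.pool_size, rng)
        for _ in range(config.rounds - 1):
            pool = mutate_pool(pool, ref, runs, slippage, config, rng)
            pool = selection_round(pool, bypass, rng, config.enrichment_cycles)
            pool = _resample(pool, config.pool_size, rng)
        g17_pool = pool

    g0_reads, g0_truth = generate_reads(g0_pool, ref, config, rng, "G0")
    g17_reads, g17_truth = generate_reads(g17_pool, ref, config, rng, "G17")
    return DriftResult(ref, g0_reads, g17_reads, g0_truth, g17_truth, g0_pool, g17_pool)


def _resample(pool: list[VariantGenome], size: int, rng) -> list[VariantGenome]:
    idx = rng.integers(0, len(pool), size)
    return [pool[int(i)].copy() for i in idx]


# ---------------------------------------------------------------------------
# file-format boundary

def write_fastq(reads, path: str | Path) -> None:
    records = []
    for read_id, seq, qual in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in qual]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path):
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None or len(rec.seq) == 0:
            raise ValueError(f"malformed FASTQ record at index {i} in {path}")
        out.append((rec.id, str(rec.seq), np.asarray(quals)))
    return out


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
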