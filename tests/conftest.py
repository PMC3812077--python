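import functools
import sys

import numpy as np
import pytest

from indeldrift.align import AlignParams
from indeldrift.caller import call_reads
from indeldrift.reference import find_homonucleotide_runs
from indeldrift.simulate import SimulationConfig, simulate_drift
from indeldrift.synthetic_reference import synthetic_gene_reference


@pytest.fixture(scope="session")
def ref():
    """The synthetic M.HaeIII-like reference (98-nt control + 993-nt gene)."""
    return synthetic_gene_reference()


@pytest.fixture(scope="session")
def ref_runs(ref):
    return find_homonucleotide_runs(ref.sequence)


@pytest.fixture(scope="session")
def small_drift():
    """A desk-scale drift (pool 2000, 3 rounds, depth 300) shared by tests
    that only need plausible G0/G17 read pools."""
    cfg = SimulationConfig(pool_size=2000, rounds=3, mean_depth=300, seed=11)
    return simulate_drift(cfg)


@pytest.fixture(scope="session")
def small_g0_calls(small_drift):
    return call_reads(small_drift.g0_reads, small_drift.ref, repertoire="G0")


def brute_force_fitting_score(read: str, ref_seq: str, p: AlignParams) -> int:
    """Independent oracle: exhaustive recursive enumeration of all fitting
    alignments (read consumed fully, local in the reference) under affine
    gap costs; returns the maximal score."""
    sys.setrecursionlimit(200_000)
    NEG = -(10**9)

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> int:
        if i == 0:
            return 0 if state == "M" else NEG  # 'M' doubles as the start state
        if state == "M":
            if j == 0:
                return NEG
            s = p.match if read[i - 1] == ref_seq[j - 1] else p.mismatch
            return max(best(i - 1, j - 1, st) for st in "MDI") + s
        if state == "D":
            if j == 0:
                return NEG
            return max(best(i, j - 1, "M") + p.gap_open, best(i, j - 1, "D") + p.gap_extend)
        return max(best(i - 1, j, "M") + p.gap_open, best(i - 1, j, "I") + p.gap_extend)

    score = max(
        best(len(read), j, st) for j in range(len(ref_seq) + 1) for st in "MI"
    )
    best.cache_clear()
    return score


def random_alignment_case(rng: np.random.Generator, max_edits: int = 2):
    """A random (reference <=30 nt, read <=15 nt) pair where the read is a
    substring of the reference carrying up to ``max_edits`` random edits."""
    n = int(rng.integers(12, 31))
    ref_seq = "".join(rng.choice(list("ACGT"), n))
    m = int(rng.integers(6, min(16, n - 1)))
    s = int(rng.integers(0, n - m + 1))
    read = list(ref_seq[s : s + m])
    for _ in range(int(rng.integers(0, max_edits + 1))):
        op = rng.choice(["sub", "ins", "del"])
        if op == "sub":
            i = int(rng.integers(len(read)))
            read[i] = str(rng.choice([b for b in "ACGT" if b != read[i]]))
        elif op == "ins":
            i = int(rng.integers(len(read) + 1))
            read.insert(i, str(rng.choice(list("ACGT"))))
        elif len(read) > 5:
            read.pop(int(rng.integers(len(read))))
    return ref_seq, "".join(read)
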