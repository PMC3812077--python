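#!/usr/bin/env python
"""Simulate the laboratory drift at desk scale.

Runs one full drift under the study conditions (pool 10^4 variants,
17 rounds of mutagenesis + purifying selection, ~40-nt reads at mean depth
500) on the synthetic M.HaeIII-like reference and writes the read pools and
truth tables.  Reads are large and go under scratch/; the truth tables
(the pool's true per-position mutation frequencies, the oracle for the
later calling steps) are small TSVs under results/.
"""

from pathlib import Path

from indeldrift.simulate import SimulationConfig, simulate_drift, write_fastq, write_truth_table

SCRATCH = Path("scratch/drift")
RESULTS = Path("results")


def main(seed: int = 1) -> None:
    cfg = SimulationConfig(pool_size=10_000, rounds=17, mean_depth=500, seed=seed)
    print(f"simulating: pool {cfg.pool_size}, {cfg.rounds} rounds, depth {cfg.mean_depth}, seed {seed}")
    res = simulate_drift(cfg)

    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    write_fastq(res.g0_reads, SCRATCH / "g0.fastq")
    write_fastq(res.g17_reads, SCRATCH / "g17.fastq")
    with open(SCRATCH / "reference.fasta", "w") as fh:
        fh.write(f">{res.ref.name}\n{res.ref.sequence}\n")
    write_truth_table(res.g0_truth, RESULTS / "g0_truth.tsv")
    write_truth_table(res.g17_truth, RESULTS / "g17_truth.tsv")

    n_indel_g0 = res.g0_truth[res.g0_truth["type"] != "sub"]["true_frequency"].sum()
    n_indel_g17 = res.g17_truth[res.g17_truth["type"] != "sub"]["true_frequency"].sum()
    print(f"G0: {len(res.g0_reads)} reads; summed pool InDel frequency {n_indel_g0:.3f}")
    print(f"G17: {len(res.g17_reads)} reads; summed pool InDel frequency {n_indel_g17:.3f}")
    print("selection purged most InDels; long-repeat ones persist preferentially")


if __name__ == "__main__":
    main()
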