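#!/usr/bin/env python
"""Call per-position mutation frequencies from the simulated read pools.

Aligns the G0 and G17 reads of 01_simulate.py back to the reference,
applies the Q20 base filter and the read-edge artifact filter, estimates
the sequencing-error background from the 98-nt unmutagenized control
region, and writes background-corrected frequency tables.
"""

from pathlib import Path

from indeldrift.caller import call_reads, write_frequency_table
from indeldrift.reference import read_reference_fasta
from indeldrift.simulate import read_fastq
from indeldrift.synthetic_reference import synthetic_gene_reference

SCRATCH = Path("scratch/drift")
RESULTS = Path("results")


def main() -> None:
    ref = synthetic_gene_reference()
    name, seq = read_reference_fasta(SCRATCH / "reference.fasta")
    assert seq == ref.sequence, "reads were simulated on a different reference"

    for label in ("G0", "G17"):
        reads = read_fastq(SCRATCH / f"{label.lower()}.fastq")
        result = call_reads(reads, ref, repertoire=label)
        write_frequency_table(result.frequency_table, RESULTS / f"{label.lower()}_frequencies.tsv")
        sub_bg, indel_bg = result.background
        print(
            f"{label}: aligned {result.n_aligned}/{len(reads)} reads "
            f"(discarded {result.discards.total}); "
            f"background sub {sub_bg:.3g}, InDel {indel_bg:.3g}"
        )
    print(f"frequency tables in {RESULTS}/")


if __name__ == "__main__":
    main()
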