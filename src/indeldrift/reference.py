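"""Reference gene model: regions, homonucleotide runs, and position context.

Coordinates are 1-based inclusive throughout the package, matching the
nucleotide numbering conventions of amplicon deep-sequencing studies
(e.g. "position 306" is the 306th base of the gene).  Converters to/from
0-based half-open coordinates exist only at the file-format boundary
(BED-like region files).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

VALID_BASES = frozenset("ACGT")


class ReferenceError(ValueError):
    """Raised for malformed reference sequences or coordinates."""


@dataclass(frozen=True)
class RepeatRun:
    """A maximal homonucleotide run: `length` copies of `base` starting at
    1-based position `start` (inclusive)."""

    base: str
    start: int
    length: int

    @property
    def end(self) -> int:
        """1-based inclusive position of the last base of the run."""
        return self.start + self.length - 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class RepeatContext:
    """Repeat context of a single reference position."""

    run: RepeatRun
    offset: int  # 0-based offset of the position within its run
    region_label: str | None = None

    @property
    def is_repeat(self) -> bool:
        """A position is 'within a repeat' when both flanking copies exist,
        i.e. the run has length >= 2; a length-1 run is a non-repeat
        position (both flanking bases differ)."""
        return self.run.length > 1


@dataclass
class GeneReference:
    """Reference sequence with annotated regions.

    `orf_interval` is the mutagenized open reading frame, `control_interval`
    the upstream region never subjected to mutagenesis (used for sequencing-
    error background estimation).  `named_subregions` holds extra analysis
    windows such as the disordered C-terminus.  `gene_start` is the full-
    sequence coordinate at which gene-local numbering begins at 1, so that
    positions can be quoted in the gene's own frame of reference.
    """

    sequence: str
    orf_interval: tuple[int, int]
    control_interval: tuple[int, int] | None = None
    named_subregions: dict[str, tuple[int, int]] = field(default_factory=dict)
    gene_start: int = 1
    name: str = "reference"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for i, b in enumerate(self.sequence):
            if b not in VALID_BASES:
                raise ReferenceError(
                    f"non-ACGT character {b!r} at position {i + 1}"
                )
        n = len(self.sequence)
        for label, iv in self._all_intervals():
            s, e = iv
            if not (1 <= s <= e <= n):
                raise ReferenceError(f"interval {label}={iv} outside sequence of length {n}")
        if self.control_interval is not None:
            cs, ce = self.control_interval
            os_, oe = self.orf_interval
            if not (ce < os_ or oe < cs):
                raise ReferenceError("control and ORF intervals overlap")

    def _all_intervals(self):
        yield "orf", self.orf_interval
        if self.control_interval is not None:
            yield "control", self.control_interval
        yield from self.named_subregions.items()

    def __len__(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        return self.sequence[position - 1]

    def to_full(self, gene_position: int) -> int:
        """Gene-local 1-based position -> full-sequence 1-based position."""
        return self.gene_start - 1 + gene_position

    def to_gene(self, full_position: int) -> int:
        return full_position - self.gene_start + 1

    def region_of(self, position: int) -> str | None:
        """Label of the region containing a full-sequence position; named
        subregions take precedence over orf/control."""
        for label, (s, e) in self.named_subregions.items():
            if s <= position <= e:
                return label
        if self.control_interval is not None:
            s, e = self.control_interval
            if s <= position <= e:
                return "control"
        s, e = self.orf_interval
        if s <= position <= e:
            return "orf"
        return None


def find_homonucleotide_runs(sequence: str) -> list[RepeatRun]:
    """Decompose a sequence into its maximal homonucleotide runs.

    The runs partition the sequence exactly: lengths sum to the sequence
    length, no two adjacent runs share a base, and runs touching the
    sequence ends are maximal (no sentinel bases are assumed).
    """
    if not sequence:
        raise ReferenceError("empty sequence")
    sequence = sequence.upper()
    runs: list[RepeatRun] = []
    start = 0
    prev = sequence[0]
    for i, b in enumerate(sequence):
        if b not in VALID_BASES:
            raise ReferenceError(f"non-ACGT character {b!r} at position {i + 1}")
        if b != prev:
            runs.append(RepeatRun(prev, start + 1, i - start))
            start, prev = i, b
    runs.append(RepeatRun(prev, start + 1, len(sequence) - start))
    return runs


def repeat_census(
    runs: list[RepeatRun], min_length: int = 1
) -> dict[tuple[int, str], int]:
    """Count maximal runs per (length, base) class, for length >= min_length.

    A run contributes only to its own exact-length class (an AAAA run is one
    4-run, not also a 3-run), mirroring how repeat occurrence tables are
    tallied.
    """
    counts = Counter(
        (r.length, r.base) for r in runs if r.length >= min_length
    )
    return dict(counts)


def classify_frame_effect(indel_length: int) -> str:
    """'in_frame' for multiples of 3, else 'frameshift'.

    `indel_length` is signed: +k insertion, -k deletion; 0 is rejected.
    """
    if indel_length == 0:
        raise ValueError("an InDel has non-zero length")
    return "in_frame" if abs(indel_length) % 3 == 0 else "frameshift"


def position_context(
    ref: GeneReference,
    runs: list[RepeatRun],
    position: int,
) -> RepeatContext:
    """Repeat context (run, offset within run, region label) of a 1-based
    full-sequence position. Runs must come from ``find_homonucleotide_runs``
    on ``ref.sequence``."""
    if not 1 <= position <= len(ref):
        raise ReferenceError(f"position {position} outside sequence of length {len(ref)}")
    run = run_at(runs, position)
    return RepeatContext(
        run=run,
        offset=position - run.start,
        region_label=ref.region_of(position),
    )


def run_at(runs: list[RepeatRun], position: int) -> RepeatRun:
    """Binary search for the run containing a 1-based position."""
    lo, hi = 0, len(runs) - 1
    while lo <= hi:
        mid = (lo + hi) // 2
        r = runs[mid]
        if position < r.start:
            hi = mid - 1
        elif position > r.end:
            lo = mid + 1
        else:
            return r
    raise ReferenceError(f"position {position} not covered by runs")


# ---------------------------------------------------------------------------
# file-format boundary

def read_reference_fasta(path: str | Path) -> tuple[str, str]:
    """Read a single-record FASTA; returns (record id, sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ReferenceError(f"expected a single FASTA record, got {len(records)}")
    return records[0].id, str(records[0].seq).upper()


def read_regions_tsv(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a BED-like TSV (chrom, start, end, label; 0-based half-open)
    and convert to 1-based inclusive intervals keyed by label."""
    regions: dict[str, tuple[int, int]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ReferenceError(f"{path}:{line_no}: expected 4 columns (chrom, start, end, label)")
        start, end, label = int(parts[1]), int(parts[2]), parts[3]
        regions[label] = (start + 1, end)
    return regions


def write_repeat_track(runs: list[RepeatRun], path: str | Path) -> None:
    """Write runs as a TSV with columns base, start (1-based), length."""
    with open(path, "w") as fh:
        fh.write("base\tstart\tlength\n")
        for r in runs:
            fh.write(f"{r.base}\t{r.start}\t{r.length}\n")
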