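# indeldrift

Analysis of short insertion/deletion (InDel) occurrence and frame-shift
bypass in a laboratory genetic drift of the DNA methyltransferase M.HaeIII.

Short InDels are the most deleterious class of point events: two-thirds
shift the reading frame. Yet both their *creation* (DNA-polymerase slippage)
and their *rescue* (transcriptional/translational slippage restoring the
frame, "bypass") happen preferentially in homonucleotide repeats, and the
longer the repeat the more likely both become. In the drift experiment this
package models, a gene was taken through 17 rounds of error-prone PCR and
purifying selection; pooled ~40-nt deep-sequencing reads of the naive (G0)
and selected (G17) repertoires give a per-position map of every InDel's
frequency before and after selection.

The package provides, as importable library + CLI + numbered analysis
scripts:

* **drift simulator** (`indeldrift.simulate`) — error-prone PCR with
  repeat-length-dependent slippage (per-run InDel probability
  `r1 * f^(L-1)`, defaults r1 = 1e-4, f = 2.5), purifying selection with
  repeat-length-dependent frame-shift bypass
  (`min(1, b1 * g^(L-1))`, defaults b1 = 0.03, g = 1.36; zero inside
  conserved motifs), and short-read generation with realistic background
  error rates (substitutions 1.7e-3/base, InDels 2.1e-5/base) and optional
  read-edge InDel artifacts. Every run records a truth table of pool
  frequencies.
* **mutation caller** (`indeldrift.caller`, `indeldrift.align`) — an
  internal affine-gap fitting aligner (≤6 mismatches, ≥24-nt alignments),
  Q20 base filtering, VCF-style left-alignment of InDels so that every
  placement inside a repeat collapses to one call at the repeat's first
  position, an automatic read-edge artifact filter, and background
  subtraction using an unmutagenized 98-nt control region.
* **repertoire analysis** (`indeldrift.analysis`) — repeat-context
  assignment, per-repeat-length average frequencies, S/I ratios, InDel
  length distributions, tolerated-position calls (≥10× background), and the
  central statistic: an ordinary least-squares fit of log10(mean InDel
  frequency) on repeat length, whose `10^slope` is the fold change per
  repeat nucleotide.

The reference gene ships as a *synthetic* construct
(`indeldrift.synthetic_reference`): the real sequence is not available in
machine-readable form, so a 993-nt gene is built deterministically with
exactly the published homonucleotide-repeat census (one 8A, three 6T, two
6G, … eighteen 3A, sixteen 3T, …) and the individually characterized
repeats at their published positions (e.g. the 8A hotspot ending at
nucleotide 306).

## Worked example

Regressions on the published per-repeat-class average frequencies
(`python analysis/04_published_regressions.py`):

```
G0: 2.29-fold per repeat nucleotide (R^2 0.958); length-1 extrapolation 1.20e-04 per position
G17: 3.57-fold per repeat nucleotide (R^2 0.988); length-1 extrapolation 2.23e-06 per position
```

Each extra repeat nucleotide multiplies the naive InDel frequency by ~2.5
and the post-selection frequency by ~3.4; extrapolated to non-repeat
positions (length 1), occurrence is ~1e-4 and tolerated frequency drops
below the sequencing background (~0.3e-5).

The same numbers re-emerge end to end from simulation. Running

```
python analysis/01_simulate.py   # pool 10^4, 17 rounds, depth 500
python analysis/02_call.py
python analysis/03_analyze.py
```

prints (seed 1):

```
G0: fold/nt 2.24 (R^2 0.965), lengths [3, 4, 5, 6, 8]
G17: called-table regression not fit (...); using the truth table
G17: fold/nt 3.82 (R^2 0.966), lengths [3, 4, 5, 6, 8]
selection steepened the repeat-length dependence: 2.24 -> 3.82 per nt
```

i.e. the caller recovers the injected slippage fold (2.5) from the G0
reads, and selection steepens the slope by the bypass fold — the product
of the two is the post-selection ~3.4-fold law. (At desk-scale depth 500
the G17 *called* table resolves only the longest repeat, so the
post-selection slope is read from the simulator's truth table; see
`docs/methods.md`.)

The same pipeline is available as a CLI:

```
indeldrift simulate --seed 1 --out sim/
indeldrift call sim/g0.fastq --reference sim/reference.fasta --out g0.tsv
indeldrift analyze --g0 g0.tsv --reference sim/reference.fasta --out out/
```

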