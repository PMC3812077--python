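# Methods

## The system being modelled

A single gene (the DNA methyltransferase M.HaeIII, 987-nt ORF) is taken
through repeated rounds of *in-vitro* error-prone PCR and purifying
selection: plasmids encoding an active methyltransferase methylate their
own GGCC sites and survive digestion by the cognate restriction enzyme;
plasmids encoding inactive variants are destroyed. Pooled short-read
sequencing of the naive repertoire (G0, after one mutagenesis, before any
selection) and of the selected repertoire (G17, after 17 rounds) yields
per-position frequencies of every substitution and InDel. A 98-nt plasmid
region upstream of the ORF is never mutagenized and measures the
sequencing-error background.

Two repeat-length laws summarize the data. InDels arise by DNA-polymerase
slippage, so their occurrence frequency grows geometrically with the length
L of the homonucleotide run they fall in: `f_occ(L) ≈ r1 · f^(L-1)`. A
frame-shifting InDel can nevertheless yield functional protein when RNA
polymerase or the ribosome slips over the same repeat and restores the
frame ("bypass"); the per-selection survival probability of a frameshift
grows the same way: `p_byp(L) ≈ b1 · g^(L-1)`. Post-selection frequencies
therefore scale like the product, and the log-linear slope of the selected
repertoire is steeper than the naive one by the bypass fold g.

## Coordinates and canonicalization

All coordinates are 1-based inclusive, numbered in the gene's own frame
(the full reference is control region + gene; `GeneReference.to_full`
converts). Within a homonucleotide run every placement of a 1-nt InDel is
indistinguishable, so all InDel calls are left-aligned (VCF convention):
shifted left while the base preceding the event equals the event's edge
base, with insertion payloads rotated accordingly. A run hence reports its
whole InDel burden at its first position. A multi-nucleotide InDel spanning
a run boundary is assigned the run of its leftmost affected base.

## Synthetic reference

The real M.HaeIII sequence is not available as machine-readable text, so
`synthetic_reference.py` constructs a stand-in deterministically from a
seed: a 993-nt gene whose repeat census for runs ≥3 nt *exactly* matches
the published occurrence table, with the eleven individually characterized
repeats placed so their last base sits at the published nucleotide position
(8A ending at 306, 6G at 204, …), plus a run-free 98-nt control region.
Everything else is pseudo-random filler constrained to create no extra
runs ≥3 nt. The construct encodes no real protein; census-conditioned
results (the repeat census check, run-position anchors) are exact by
construction, which is precisely what they are meant to verify: that run
finding, census and context assignment recover the published structure.

## Drift simulator

Study-condition defaults, changed only by explicit argument:

| parameter | default | meaning |
|---|---|---|
| mutation load | 2.2 ± 1.6 per gene per round | substitutions from one error-prone PCR |
| rounds | 17 | mutagenesis + selection iterations |
| pool size | 10^4 | variants kept per round (desk scale; the experiment kept ≥10^5) |
| slippage `r1`, `f` | 1e-4, 2.5 | per-run InDel probability r1·f^(L-1) per mutagenesis |
| event lengths | −1: 0.69, +1: 0.289, +2: 0.018, +3: 0.0015 | matches the published G0 length distribution |
| bypass `b1`, `g` | 0.03, 1.36 | per-selection frameshift survival min(1, b1·g^(L-1)) |
| lethal substitution fraction | 0.3 | free parameter (not a published value) |
| in-frame InDel survival | 0.1 | free parameter (in-frame InDels need no bypass but remain deleterious) |
| read length / depth | 40 nt / 500× | single-end; desk scale |
| background errors | sub 1.7e-3, InDel 2.1e-5 per base | injected uniformly, control region included |
| base qualities | Q30 (artifacts Q15) | exercises the caller's Q20 filter |

The mutation load is drawn from a negative binomial matched to the stated
mean and SD (the simplest two-moment family; 1.6² > 2.2 so it is
overdispersed), with a Poisson fallback when sd² < mean.

Selection semantics matter for what G17 means. Substitution lethality is an
intrinsic property drawn once when the substitution arises — otherwise no
lineage could survive 17 rounds. Bypass, in contrast, is phenotypic and
memoryless: a frameshift re-rolls `p_byp` at every selection it passes
through. Pool frequencies of a frameshift at run length L then equilibrate
at `f_occ(L) · p/(1-p)` with `p = p_byp(L)`, so the selected-repertoire
slope is the product of the two folds, mildly steepened by the convexity of
p/(1-p) (observed ≈3.5–3.8 per nt against the nominal 2.5 × 1.36 = 3.4).
With defaults, predicted G17 frequencies reproduce the published magnitudes
(8A: ≈0.018 vs printed 0.01804). After each selection the pool is resampled
with replacement to its nominal size (re-transformation), which adds
genuine drift noise to per-run frequencies. The per-round selection
stringency (`enrichment_cycles`) defaults to 1; the calibration of g = 1.36
is to one effective selection per round.

Conserved-motif intolerance is modelled as a position mask (the 6G, 4T and
5T repeats whose InDel variants showed no activity); InDels there never
survive selection regardless of run length.

## Caller

One internal affine-gap *fitting* aligner (read consumed end-to-end, placed
anywhere in the reference; match +2, mismatch −3, gap open −5, extend −2)
replaces external mapping tools, keeping the published thresholds as
defaults: reads with >6 mismatches or <24 aligned nt are discarded, as are
reads whose best score recurs at a disjoint locus (whole-read repeats). The
DP fill is numba-compiled; error-free reads take an exact-substring fast
path. Ties are broken deterministically: lowest reference start, then
deletions before insertions. One consequence is faithful ambiguity: a 1-nt
insertion at the very first read position ties with "start one base
earlier + interior deletion" and the lowest-start rule picks the deletion;
an InDel at the terminal aligned position of a read is invisible
altogether. InDel frequencies therefore use an *indel-effective coverage*
denominator that excludes each alignment's first and last reference
position, removing the resulting ~2/L detection bias (verified by
background-rate recovery to within 2 Poisson SE at 10^7 bases).

Base quality: observations require Q≥20 on all involved read bases
(deletions: both flanking bases). Background: one pooled rate per type
(substitution, InDel) per repertoire from the control region; corrected
frequency = max(0, raw − background), applied per (position, type,
payload) row. Because the pooled per-type background is subtracted from
each payload row separately, summed substitution frequencies are somewhat
over-subtracted at low depth; this mirrors the published procedure rather
than a payload-resolved background, which the control region is too small
to estimate.

Edge-artifact filter (the published analysis removed edge-biased calls
manually; here the policy is explicit and automatic): an InDel call is
flagged when ≥90% of its supporting observations lie within 3 nt of a read
end, or when a chi-square test rejects offset uniformity at p<0.01 *and* a
one-sided binomial test finds the edge mass significantly above its
uniform expectation at the same level. Calls with <5 observations are
passed through with a low-support flag. Offsets are measured to the nearer
read end, and for an InDel absorbed into a run the most edge-compatible
equivalent placement is used, so artifacts hidden inside repeats still
register as edge-proximal. Measured performance: 100% of injected
edge artifacts flagged at ≥20 supporting reads; ≤1% of uniformly supported
calls flagged.

## Analysis

Per-run frequency = sum of corrected insertion + deletion frequencies at
the run's canonical (first) position. Class mean over ALL runs of a
(length, base) class, zero for runs without calls; pooled per-length mean =
occurrence-weighted average of class means (equivalently the plain average
over runs of that length; an unweighted mean of class means is available
behind a flag since the published aggregation is not fully specified). The
regression fits log10(mean) on length by ordinary least squares; zero-mean
classes cannot enter the log fit and are excluded but reported; ≥3 usable
classes are required; fold per nt = 10^slope (base-independent). The
"tolerated" threshold is 10× the *measured* InDel background of the same
repertoire — the rule, not its published instance (0.2e-3).

Insertions whose base differs from the run at their canonical position but
borders a run ≥3 nt are classed "adjacent-to-repeat"; positions in
length-1 runs are "non-repeat".

## Problem sizes and resolution limits

Library-scale runs use pool 10^4, depth 500, 17 rounds (a few seconds per
drift), against the experiment's ≥10^5 variants and much deeper
sequencing. At depth 500 a single read corresponds to frequency 2e-3, so
post-selection frequencies at short repeats (1e-5..1e-4) are not resolvable
from the called table; end-to-end checks therefore read the G0 fold from
called frequencies and the G17 fold from the simulator's truth table (pool
frequencies). The published-table regressions are exact reproductions and
independent of scale.

## What the generator does and does not emulate

Emulated: repeat-length-geometric slippage and bypass, compounded rounds
with re-transformation bottlenecks, motif intolerance, uniform sequencing
background in ORF and control, Q-score structure, edge-confined artifacts.
Not emulated: PCR amplification bias, concatemer library chemistry,
paired-end reads, quality recalibration, epistasis/compensatory mutations
(each edit's effect is independent), any fitness structure for
substitutions beyond a flat lethal fraction, and real codon structure in
the synthetic gene. Passing tests demonstrate internal consistency of the
pipeline under these idealized conditions, not performance on real
sequencing data.

## Known limitations

* The aligner mis-attributes indels at terminal read positions (corrected
  in aggregate by the effective-coverage denominator, but individual edge
  events are lost or become substitution calls).
* The selected repertoire's S/I ratio depends on the free lethality
  parameters and should not be read as a calibrated reproduction.
* The published analysis excluded "low accuracy" contigs by an undefined
  score; only the Q20 base filter and the edge filter are implemented.
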