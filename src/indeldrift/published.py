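"""Reference summary statistics from the published deep-sequencing study of
the M.HaeIII laboratory drift.

These are transcriptions of the printed summary tables of that study: the
per-repeat-class census with average InDel frequencies before (G0) and after
(G17) selection, and the per-region mutation-frequency summaries.  They serve
two purposes: as direct inputs to the regression analysis (the raw reads of
the original experiment were never deposited), and as calibration targets
for the drift simulator's defaults.

Frequencies in ``REPEAT_TABLE`` are on the table's printed x10^-3 scale;
frequencies in ``REGION_TABLE`` are absolute.
"""

from __future__ import annotations

import pandas as pd

#: Per (run length, base): number of runs in the gene, mean InDel frequency
#: (x10^-3) across those runs in G0 and in G17, and the number of runs whose
#: frequency exceeded 10x background ("fraction" numerator) per repertoire.
_REPEAT_ROWS = [
    # length, base, occurrence, g0_mean_e3, g0_above_bg, g17_mean_e3, g17_above_bg
    (8, "A", 1, 50.25, 1, 18.04, 1),
    (6, "T", 3, 4.72, 3, 1.11, 3),
    (6, "G", 2, 4.80, 2, 0.56, 2),
    (5, "A", 3, 2.81, 3, 0.39, 1),
    (5, "T", 2, 2.95, 2, 0.76, 1),
    (5, "C", 1, 3.38, 1, 0.25, 1),
    (5, "G", 1, 2.04, 1, 0.16, 0),
    (4, "A", 12, 1.93, 12, 0.15, 4),
    (4, "T", 5, 2.51, 5, 0.10, 1),
    (4, "G", 1, 2.08, 1, 0.06, 0),
    (3, "A", 18, 0.61, 17, 0.02, 0),
    (3, "T", 16, 0.66, 15, 0.03, 0),
    (3, "C", 2, 0.21, 2, 0.00, 0),
    (3, "G", 3, 0.50, 3, 0.03, 0),
]

REPEAT_TABLE = pd.DataFrame(
    _REPEAT_ROWS,
    columns=[
        "length", "base", "occurrence",
        "g0_mean_e3", "g0_above_bg", "g17_mean_e3", "g17_above_bg",
    ],
)

#: Per-region mutation summaries for the two repertoires.  S = point-mutation
#: frequency, I = InDel frequency (background-subtracted, per position);
#: the distribution rows give the percentage of each InDel length class out
#: of all InDels in that region/repertoire.
REGION_TABLE: dict[str, dict[str, dict]] = {
    "orf": {  # gene nt 4-990, amino acids 2-330
        "G0": {
            "S": 3e-3, "I": 2.2e-4, "S_over_I": 16,
            "insertions": 6.7e-5, "deletions": 1.5e-4,
            "length_distribution_pct": {">+3": 0.00, "+3": 0.15, "+2": 1.8, "+1": 28.9, "-1": 69.1},
        },
        "G17": {
            "S": 2e-2, "I": 1.1e-4, "S_over_I": 190,
            "insertions": 1.7e-5, "deletions": 0.9e-4,
            "length_distribution_pct": {">+3": 0.03, "+3": 0.18, "+2": 0.4, "+1": 9.2, "-1": 90.2},
        },
    },
    "C-terminus": {  # gene nt 969-990, amino acids 324-330 (disordered)
        "G0": {
            "S": 3e-3, "I": 2.0e-4, "S_over_I": 16,
            "insertions": 1.2e-5, "deletions": 1.9e-4,
            "length_distribution_pct": {"+1": 6.3, "-1": 93.7},
        },
        "G17": {
            "S": 3e-2, "I": 0.4e-2, "S_over_I": 9,
            "insertions": 8.5e-5, "deletions": 3.5e-3,
            "length_distribution_pct": {"+1": 1.4, "-1": 98.6},
        },
    },
}

#: Sequencing-error background frequencies measured on the unmutagenized
#: 98-nt control region, per repertoire.
BACKGROUND = {
    "G0": {"indel": 2.1e-5, "sub": 1.7e-3},
    "G17": {"indel": 1.6e-5, "sub": 8.6e-4},
}

#: Headline per-position counts of the published analysis: positions with
#: detected InDels in G0, those still carrying InDels in G17, and those at
#: >= 10x background in G17 ("tolerated").
POSITION_COUNTS = {"g0_detected": 337, "g17_detected": 79, "g17_tolerated": 26}


def pooled_length_means(repertoire: str = "G0") -> pd.Series:
    """Occurrence-weighted mean InDel frequency per run length (x10^-3
    scale), pooling bases within a length class; the quantity regressed on
    run length."""
    col = {"G0": "g0_mean_e3", "G17": "g17_mean_e3"}[repertoire]
    t = REPEAT_TABLE
    weighted = (t[col] * t["occurrence"]).groupby(t["length"]).sum()
    return weighted / t.groupby("length")["occurrence"].sum()
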