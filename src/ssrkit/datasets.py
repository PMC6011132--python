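"""Published reference tables bundled as in-memory datasets.

Two small datasets from the *Octodonta nipae* (nipa palm hispid beetle)
transcriptome SSR survey are bundled for demonstrations and arithmetic
cross-checks:

* the motif-class x repeat-count frequency matrix of the 1274 SSR loci
  mined from 49,919 unigenes (bins 4..11 and >=12 full copies);
* the nine-locus marker panel (On1-On9) evaluated on two Fujian
  populations (Zhangzhou ``ZZ`` and Fuzhou ``FZ``) of 12 beetles each,
  with the printed per-locus NA / He / Ho / PIC columns.

These are printed summary tables, not raw data: the underlying
transcriptome and genotypes were never deposited, which is why the
toolkit ships a synthetic-data generator instead of fixtures.
"""

from __future__ import annotations

import pandas as pd

from .motif_classification import REPEAT_BINS
from .ssr_mining import SSRLocus

# motif-class frequency matrix: class label -> counts in bins 4..11, >=12.
# Row sums within each motif length reproduce the repeat-type margins
# (555 mono / 333 di / 359 tri / 17 tetra / 6 penta / 4 hexa; total 1274).
_SSR_SURVEY_COUNTS: dict[str, list[int]] = {
    # label:          4   5   6    7   8   9  10  11 >=12
    "A/T":          [0,  0,  0,   0,  0,  0,  0,  0, 525],
    "C/G":          [0,  0,  0,   0,  0,  0,  0,  0,  30],
    "AC/GT":        [0,  0,  28, 17, 14,  5,  4,  2,   0],
    "AG/CT":        [0,  0,  28,  9, 10,  4,  4,  6,   0],
    "AT/TA":        [0,  0, 103, 45, 19,  9, 12, 14,   0],
    "AAC/GTT":      [0, 33,  9,   1,  1,  0,  0,  0,   0],
    "AAG/CTT":      [0, 63, 23,   6,  5,  0,  0,  0,   0],
    "AAT/ATT":      [0, 70, 17,   2,  3,  0,  0,  0,   0],
    "ACC/GGT":      [0, 28,  9,   3,  0,  0,  0,  0,   0],
    "ACG/CGT":      [0,  2,  1,   1,  0,  0,  0,  0,   0],
    "ACT/AGT":      [0,  8,  2,   1,  2,  0,  0,  0,   0],
    "AGC/CTG":      [0, 14,  5,   1,  0,  0,  0,  0,   0],
    "AGG/CCT":      [0, 11,  1,   0,  0,  0,  0,  0,   0],
    "ATC/ATG":      [0, 24,  7,   0,  0,  0,  0,  0,   0],
    "CCG/CGG":      [0,  2,  4,   0,  0,  0,  0,  0,   0],
    "AAAC/GTTT":    [0,  1,  0,   0,  0,  0,  0,  0,   0],
    "AAAG/CTTT":    [0,  1,  0,   0,  0,  0,  0,  0,   0],
    "AAAT/ATTT":    [0,  6,  0,   0,  0,  0,  0,  0,   0],
    "AACC/GGTT":    [0,  3,  0,   0,  0,  0,  0,  0,   0],
    "AAGT/ACTT":    [0,  1,  1,   0,  0,  0,  0,  0,   0],
    "AATC/ATTG":    [0,  1,  0,   0,  0,  0,  0,  0,   0],
    "ACTG/AGTC":    [0,  0,  2,   0,  0,  0,  0,  0,   0],
    "AGAT/ATCT":    [0,  1,  0,   0,  0,  0,  0,  0,   0],
    "AAAAT/ATTTT":  [3,  0,  0,   0,  0,  0,  0,  0,   0],
    "AAACT/AGTTT":  [1,  0,  0,   0,  0,  0,  0,  0,   0],
    "AACCT/AGGTT":  [1,  0,  0,   0,  0,  0,  0,  0,   0],
    "AATGT/ACATT":  [1,  0,  0,   0,  0,  0,  0,  0,   0],
    "AAATTC/AATTTG": [2, 0,  0,   0,  0,  0,  0,  0,   0],
    "AATGGG/ATTCCC": [1, 0,  0,   0,  0,  0,  0,  0,   0],
    "AGCGGC/CCGCTG": [1, 0,  0,   0,  0,  0,  0,  0,   0],
}


def ssr_survey_class_counts() -> pd.DataFrame:
    """Motif-class x repeat-bin count matrix of the beetle transcriptome survey."""
    return pd.DataFrame.from_dict(
        _SSR_SURVEY_COUNTS, orient="index", columns=REPEAT_BINS
    ).rename_axis("motif_class")


def ssr_survey_loci() -> list[SSRLocus]:
    """Reconstruct the survey's 1274-locus multiset from its count matrix.

    Each class is represented by the left-hand motif of its label (class
    membership is rotation/revcomp-invariant, so any representative
    tabulates identically); the >=12 bin is materialised at 12 copies.
    """
    from .motif_classification import loci_from_count_table

    triples: list[tuple[str, int, int]] = []
    for label, counts in _SSR_SURVEY_COUNTS.items():
        motif = label.split("/")[0]
        for bin_label, count in zip(REPEAT_BINS, counts):
            if count == 0:
                continue
            repeats = 12 if bin_label == ">=12" else int(bin_label)
            triples.append((motif, repeats, count))
    return loci_from_count_table(triples)


# nine-locus marker panel: printed per-locus statistics for the two
# populations.  NA is the per-locus allele count (shared column).
_MARKER_PANEL_ROWS = [
    # locus, motif,   NA,  He_ZZ, He_FZ, Ho_ZZ, Ho_FZ, PIC_ZZ, PIC_FZ
    ("On1", "(TA)8",   2, 0.083, 0.344, 0.083, 0.250, 0.077, 0.275),
    ("On2", "(GT)9",   3, 0.681, 0.591, 0.667, 0.250, 0.579, 0.501),
    ("On3", "(CA)10",  3, 0.678, 0.359, 0.750, 0.417, 0.584, 0.307),
    ("On4", "(AT)6",   2, 0.159, 0.000, 0.167, 0.000, 0.141, 0.001),
    ("On5", "(GT)8",   3, 0.562, 0.522, 0.583, 0.333, 0.432, 0.375),
    ("On6", "(AT)6",   2, 0.159, 0.000, 0.167, 0.000, 0.141, 0.001),
    ("On7", "(CT)7",   3, 0.663, 0.453, 0.417, 0.417, 0.561, 0.369),
    ("On8", "(AAG)5",  3, 0.344, 0.431, 0.417, 0.583, 0.275, 0.328),
    ("On9", "(CAA)5",  2, 0.663, 0.163, 0.167, 0.167, 0.561, 0.150),
]


def marker_panel() -> pd.DataFrame:
    """Printed per-locus statistics of the nine-marker beetle panel."""
    return pd.DataFrame(
        _MARKER_PANEL_ROWS,
        columns=[
            "locus", "repeat_motif", "NA",
            "He_ZZ", "He_FZ", "Ho_ZZ", "Ho_FZ", "PIC_ZZ", "PIC_FZ",
        ],
    ).set_index("locus")
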