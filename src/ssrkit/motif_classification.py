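"""Canonical motif classes and SSR frequency matrices.

Survey tables of transcriptome SSRs group motifs into classes that are
closed under cyclic rotation and reverse complementation: a ``CTT`` run
on the transcript strand belongs to the same class as ``TTC``, ``TCT``
and the opposite-strand ``AAG``/``AGA``/``GAA``.  The class *key* is the
lexicographically smallest word over the union of both rotation sets;
the display *label* is ``m/r`` where ``m`` and ``r`` are the minimal
rotations of the two strand sets, in lexicographic order.  For a
self-reverse-complement class (both strand sets coincide, e.g. the
``AT`` dinucleotide) the right-hand part falls back to the second
smallest rotation, giving the conventional ``AT/TA``.

Frequency matrices bin loci by number of full repeat units (columns
4, 5, ..., 11, >=12) against either repeat type (motif length) or
canonical motif class, with row totals and percentages of the grand
total, mirroring the layout of published SSR survey tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import pandas as pd

from .ssr_mining import SSRLocus, is_primitive

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: repeat-count bins used by the frequency matrices
REPEAT_BINS: list[str] = [str(k) for k in range(4, 12)] + [">=12"]

REPEAT_TYPE_NAMES = {
    1: "mononucleotide", 2: "dinucleotide", 3: "trinucleotide",
    4: "tetranucleotide", 5: "pentanucleotide", 6: "hexanucleotide",
}


def reverse_complement(word: str) -> str:
    return word.translate(_COMPLEMENT)[::-1]


def _rotations(word: str) -> list[str]:
    return [word[i:] + word[:i] for i in range(len(word))]


@dataclass(frozen=True)
class MotifClass:
    """Canonical equivalence class of a motif under rotation + revcomp."""

    key: str
    label: str

    def __str__(self) -> str:  # pragma: no cover - display sugar
        return self.label


def canonical_motif_class(motif: str) -> MotifClass:
    """Canonical class of a primitive 1-6 bp motif.

    Raises ``ValueError`` for an empty, overlong, non-ACGT or
    non-primitive motif.
    """
    motif = motif.upper()
    if not (1 <= len(motif) <= 6):
        raise ValueError(f"motif length must be 1..6, got {motif!r}")
    if any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    own = _rotations(motif)
    rc = _rotations(reverse_complement(motif))
    m, r = min(own), min(rc)
    if m == r:
        # self-revcomp class: fall back to the second-smallest rotation
        combined = sorted(set(own) | set(rc))
        right = combined[1] if len(combined) > 1 else combined[0]
        label = f"{m}/{right}"
    else:
        lo, hi = sorted((m, r))
        label = f"{lo}/{hi}"
    return MotifClass(key=min(m, r), label=label)


@dataclass
class FrequencyMatrix:
    """Counts of SSR loci per row category x repeat-count bin.

    ``table`` carries the bin columns plus ``total`` and ``percent``
    (share of the grand total, rounded half-up to 2 decimals).
    """

    table: pd.DataFrame
    grand_total: int

    def row_total(self, row: str | int) -> int:
        return int(self.table.loc[row, "total"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label=self.table.index.name)


def _percent(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    raw = Decimal(count) / Decimal(total) * 100
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _bin_label(repeats: int) -> str:
    if repeats < 4:
        raise ValueError(
            f"repeat count {repeats} below the smallest frequency bin (4)"
        )
    return ">=12" if repeats >= 12 else str(repeats)


def tabulate_frequencies(
    loci: Iterable[SSRLocus],
) -> tuple[FrequencyMatrix, FrequencyMatrix]:
    """Build the (by repeat type, by motif class) frequency matrix pair.

    The repeat-type matrix has one row per motif length present in the
    conventional order mono..hexa; the motif-class matrix is sorted by
    motif length then class key.  Empty input yields all-zero matrices.
    """
    loci = list(loci)
    grand = len(loci)

    by_type = pd.DataFrame(
        0, index=[REPEAT_TYPE_NAMES[k] for k in range(1, 7)], columns=REPEAT_BINS
    )
    class_rows: dict[tuple[int, str], dict[str, int]] = {}
    class_labels: dict[tuple[int, str], str] = {}
    for locus in loci:
        b = _bin_label(locus.repeats)
        by_type.loc[REPEAT_TYPE_NAMES[len(locus.motif)], b] += 1
        cls = canonical_motif_class(locus.motif)
        rk = (len(locus.motif), cls.key)
        row = class_rows.setdefault(rk, {c: 0 for c in REPEAT_BINS})
        row[b] += 1
        class_labels[rk] = cls.label

    by_class = pd.DataFrame(
        [class_rows[k] for k in sorted(class_rows)],
        index=[class_labels[k] for k in sorted(class_rows)],
        columns=REPEAT_BINS,
        dtype=int,
    )

    for frame, name in ((by_type, "repeat_type"), (by_class, "motif_class")):
        frame.index.name = name
        frame["total"] = frame[REPEAT_BINS].sum(axis=1)
        frame["percent"] = [_percent(int(t), grand) for t in frame["total"]]
    return (
        FrequencyMatrix(table=by_type, grand_total=grand),
        FrequencyMatrix(table=by_class, grand_total=grand),
    )


def count_high_repeat_loci(
    matrix: FrequencyMatrix, motif_len: int, min_units: int
) -> int:
    """Number of loci of one motif length with >= ``min_units`` full copies.

    Operates on the repeat-type matrix; ``min_units`` below the smallest
    bin is an error because loci under 4 copies were never tabulated.
    """
    if min_units < 4:
        raise ValueError("min_units below the smallest tabulated bin (4)")
    row = matrix.table.loc[REPEAT_TYPE_NAMES[motif_len]]
    cols = [c for c in REPEAT_BINS if c == ">=12" or int(c) >= min_units]
    if min_units > 12:
        cols = []  # bins cannot resolve above the >=12 pool
    return int(row[cols].sum()) if cols else 0


def loci_from_count_table(
    counts: Sequence[tuple[str, int, int]],
) -> list[SSRLocus]:
    """Expand (motif, repeats, count) triples into a synthetic locus multiset.

    Convenience for reconstructing a survey's locus population from its
    printed frequency matrix; coordinates are placed at the sequence
    start since only motif and repeat count matter for tabulation.
    """
    loci: list[SSRLocus] = []
    idx = 0
    for motif, repeats, count in counts:
        for _ in range(count):
            idx += 1
            loci.append(
                SSRLocus(
                    seq_id=f"syn{idx}", motif=motif, repeats=repeats,
                    start=1, end=repeats * len(motif),
                )
            )
    return loci
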