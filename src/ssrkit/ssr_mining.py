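"""Detection of maximal perfect microsatellites (SSRs) in nucleotide sequences.

A perfect microsatellite is an uninterrupted tandem run of a primitive
1-6 bp motif.  The miner reports every maximal run whose number of full
motif copies meets a per-motif-length minimum; the defaults are the
transcriptome-survey thresholds 12, 6, 5, 5, 4 and 4 copies for mono-
through hexanucleotide motifs.

Conventions:

* a run is reported exactly once, under its shortest primitive period
  (a poly-A run is ``A`` x n, never additionally ``AA`` x n/2);
* partial trailing motif copies are neither counted nor included in the
  reported span;
* coordinates are 1-based inclusive on the given strand;
* characters outside ``{A, C, G, T}`` (including N) break runs, and the
  segments on either side are scored independently;
* only the given strand is scanned; reverse-complement grouping happens
  at classification time.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import SequenceRecord, read_fasta

#: default minimum full-copy counts per motif length 1..6
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 12, 2: 6, 3: 5, 4: 5, 5: 4, 6: 4}

_ACGT = frozenset("ACGT")

#: columns of the mining report TSV
SSR_TSV_COLUMNS = [
    "seq_id", "motif", "canonical_class", "repeats", "start", "end", "length_bp",
]


@dataclass(frozen=True)
class MiningThresholds:
    """Minimum number of full motif copies per motif length (1..6)."""

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )

    def __post_init__(self) -> None:
        if set(self.min_repeats) != set(range(1, 7)):
            raise ValueError("min_repeats must cover motif lengths 1..6")
        if any(v < 2 for v in self.min_repeats.values()):
            raise ValueError("all repeat minima must be >= 2")

    @classmethod
    def from_csv(cls, text: str) -> "MiningThresholds":
        """Parse ``"12,6,5,5,4,4"`` (mono..hexa)."""
        parts = [int(x) for x in text.split(",")]
        if len(parts) != 6:
            raise ValueError("expected 6 comma-separated minima (mono..hexa)")
        return cls({i + 1: v for i, v in enumerate(parts)})

    def __getitem__(self, motif_len: int) -> int:
        return self.min_repeats[motif_len]


@dataclass(frozen=True)
class SSRLocus:
    """One detected perfect repeat.

    ``start``/``end`` are 1-based inclusive; the spanned substring equals
    ``motif * repeats`` and the motif is primitive.
    """

    seq_id: str
    motif: str
    repeats: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= len(self.motif) <= 6):
            raise ValueError(f"motif length must be 1..6, got {self.motif!r}")
        if is_primitive(self.motif) is False:
            raise ValueError(f"motif {self.motif!r} is not primitive")
        if self.end - self.start + 1 != self.repeats * len(self.motif):
            raise ValueError(
                f"span [{self.start},{self.end}] inconsistent with "
                f"{self.repeats} copies of {self.motif!r}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def is_primitive(motif: str) -> bool:
    """True if ``motif`` is not a whole-number repetition of a shorter word."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def _acgt_segments(seq: str) -> Iterable[tuple[int, str]]:
    """Yield (offset, substring) for maximal runs of pure A/C/G/T."""
    start = None
    for i, base in enumerate(seq):
        if base in _ACGT:
            if start is None:
                start = i
        elif start is not None:
            yield start, seq[start:i]
            start = None
    if start is not None:
        yield start, seq[start:]


def _scan_segment(seg: str, offset: int, seq_id: str,
                  thresholds: MiningThresholds) -> list[SSRLocus]:
    n = len(seg)
    loci: list[SSRLocus] = []
    for p in range(1, 7):
        min_copies = thresholds[p]
        i = 0
        while i + p * 2 <= n:
            # extend the period-p run anchored at i
            j = i + p
            while j < n and seg[j] == seg[j - p]:
                j += 1
            run_len = j - i  # chars with period p, incl. trailing partial
            copies = run_len // p
            motif = seg[i:i + p]
            if copies >= min_copies and is_primitive(motif):
                # primitivity + copies >= 2 guarantees p is the shortest
                # period of the run (Fine & Wilf), so each run is reported
                # under exactly one motif length
                start0 = offset + i
                loci.append(
                    SSRLocus(
                        seq_id=seq_id,
                        motif=motif,
                        repeats=copies,
                        start=start0 + 1,
                        end=start0 + copies * p,
                    )
                )
            # next candidate run cannot begin inside the current one
            i = j - p + 1 if run_len >= 2 * p else i + 1
    loci.sort(key=lambda l: (l.start, len(l.motif)))
    return loci


def find_perfect_ssrs(
    record: SequenceRecord | str,
    thresholds: MiningThresholds | None = None,
    seq_id: str = "seq",
) -> list[SSRLocus]:
    """Find every maximal perfect SSR in one sequence, left to right.

    Accepts a :class:`SequenceRecord` or a raw (uppercase) string; an
    empty sequence simply yields no loci.
    """
    thresholds = thresholds or MiningThresholds()
    if isinstance(record, SequenceRecord):
        seq, seq_id = record.seq, record.id
    else:
        seq = record
    loci: list[SSRLocus] = []
    for offset, seg in _acgt_segments(seq):
        loci.extend(_scan_segment(seg, offset, seq_id, thresholds))
    loci.sort(key=lambda l: (l.start, len(l.motif)))
    return loci


def loci_to_frame(loci: Iterable[SSRLocus]) -> pd.DataFrame:
    """Mining report as a DataFrame with the standard TSV columns."""
    from .motif_classification import canonical_motif_class

    rows = [
        {
            "seq_id": l.seq_id,
            "motif": l.motif,
            "canonical_class": canonical_motif_class(l.motif).label,
            "repeats": l.repeats,
            "start": l.start,
            "end": l.end,
            "length_bp": l.length_bp,
        }
        for l in loci
    ]
    return pd.DataFrame(rows, columns=SSR_TSV_COLUMNS)


def frame_to_loci(frame: pd.DataFrame) -> list[SSRLocus]:
    """Rebuild :class:`SSRLocus` objects from a mining report frame."""
    return [
        SSRLocus(
            seq_id=str(r.seq_id), motif=str(r.motif), repeats=int(r.repeats),
            start=int(r.start), end=int(r.end),
        )
        for r in frame.itertuples(index=False)
    ]


def mine_fasta(
    path: str | Path,
    thresholds: MiningThresholds | None = None,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Mine every record of a FASTA file.

    Returns the concatenated per-record report plus a tally of detected
    loci per motif length.
    """
    thresholds = thresholds or MiningThresholds()
    all_loci: list[SSRLocus] = []
    for rec in read_fasta(path):
        all_loci.extend(find_perfect_ssrs(rec, thresholds))
    tally = collections.Counter(len(l.motif) for l in all_loci)
    return loci_to_frame(all_loci), {k: tally.get(k, 0) for k in range(1, 7)}
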