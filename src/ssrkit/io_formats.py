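"""Readers and writers for the plain-text formats the pipeline touches.

Three formats flow through the toolkit: FASTA for transcript/unigene
sequences, GENEPOP for diploid codominant genotypes, and TSV for every
tabular report.  FASTA goes through Biopython; GENEPOP is parsed here
because the dialect is small and the toolkit needs strict, line-numbered
diagnostics.

GENEPOP dialect accepted
------------------------
* line 1: free-text title;
* locus names: one per line, or a single comma-separated line;
* each population introduced by a line equal to ``Pop`` (case-insensitive);
* individual lines ``id , g1 g2 ...`` where each genotype field is 4
  characters (two 2-digit allele codes) or 6 characters (two 3-digit
  codes); ``00``/``000`` encodes a missing allele.

Population names follow the GENEPOP convention of taking the identifier
of the *last* individual in each block; callers may override.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: nucleotide codes accepted on ingest (IUPAC, including ambiguity codes)
IUPAC_NUCLEOTIDES = frozenset("ACGTNRYSWKMBDHVU")

#: allele code reserved for a missing allele
MISSING_ALLELE = 0

Call = tuple[int, int] | None


@dataclass(frozen=True)
class SequenceRecord:
    """A single nucleotide sequence (a transcript/unigene).

    Sequences are uppercased on ingest; the identifier is the first
    whitespace-delimited token of the FASTA header.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenotypeMatrix:
    """Diploid codominant genotypes for one population.

    ``calls[i][l]`` is the unordered allele pair of individual ``i`` at
    locus ``l`` (codes are positive integers) or ``None`` for a missing
    call.  The matrix is rectangular by construction.
    """

    population_name: str
    individual_ids: list[str]
    locus_names: list[str]
    calls: list[list[Call]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.individual_ids):
            raise ValueError("one call row required per individual")
        for ind, row in zip(self.individual_ids, self.calls):
            if len(row) != len(self.locus_names):
                raise ValueError(
                    f"individual {ind!r} has {len(row)} genotypes, "
                    f"expected {len(self.locus_names)}"
                )
            for call in row:
                if call is None:
                    continue
                if len(call) != 2 or any(a <= 0 for a in call):
                    raise ValueError(
                        f"bad call {call!r} for individual {ind!r}: "
                        "expected two positive allele codes or None"
                    )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_names.index(locus)
        except ValueError:
            raise KeyError(f"locus {locus!r} not in matrix") from None

    def calls_at(self, locus: str) -> list[Call]:
        """All calls (including missing) at one locus, in individual order."""
        j = self.locus_index(locus)
        return [row[j] for row in self.calls]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and line folding is undone.  Raises
    ``ValueError`` for an empty file, a duplicate identifier, or a
    character outside the IUPAC nucleotide alphabet (reported with its
    1-based position).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for pos, base in enumerate(seq, start=1):
            if base not in IUPAC_NUCLEOTIDES:
                raise ValueError(
                    f"non-IUPAC character {base!r} at position {pos} "
                    f"of sequence {rec.id!r}"
                )
        records.append(SequenceRecord(id=rec.id, seq=seq))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as wrapped multi-FASTA."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)


def _parse_genotype_field(
    token: str, lineno: int
) -> tuple[Call, int]:
    """Decode one fixed-width genotype field; returns (call, digits-per-allele)."""
    if len(token) == 4:
        width = 2
    elif len(token) == 6:
        width = 3
    else:
        raise ValueError(
            f"line {lineno}: genotype field {token!r} has width {len(token)}; "
            "expected 4 (2-digit alleles) or 6 (3-digit alleles)"
        )
    if not token.isdigit():
        raise ValueError(f"line {lineno}: non-numeric genotype field {token!r}")
    a1, a2 = int(token[:width]), int(token[width:])
    if a1 == MISSING_ALLELE or a2 == MISSING_ALLELE:
        return None, width
    return (a1, a2), width


def read_genepop(
    path: str | Path,
    population_names: Sequence[str] | None = None,
) -> list[GenotypeMatrix]:
    """Parse a GENEPOP file into one :class:`GenotypeMatrix` per Pop block.

    Parameters
    ----------
    path:
        GENEPOP text file.
    population_names:
        Optional override of the per-block names; by default the id of the
        last individual of each block names the population.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"empty GENEPOP file {path}")

    # locus names span from line 2 to the first Pop line
    first_pop = next(
        (i for i, ln in enumerate(lines[1:], start=1) if _POP_RE.match(ln.strip())),
        None,
    )
    if first_pop is None:
        raise ValueError(f"{path}: no 'Pop' line found")
    locus_lines = [ln.strip() for ln in lines[1:first_pop] if ln.strip()]
    locus_names: list[str] = []
    for ln in locus_lines:
        locus_names.extend(name.strip() for name in ln.split(",") if name.strip())
    if not locus_names:
        raise ValueError(f"{path}: no locus names before first 'Pop'")

    matrices: list[GenotypeMatrix] = []
    ind_ids: list[str] = []
    rows: list[list[Call]] = []
    allele_width: int | None = None

    def _flush() -> None:
        nonlocal ind_ids, rows
        if not ind_ids:
            raise ValueError(f"{path}: empty 'Pop' block")
        name = ind_ids[-1]
        matrices.append(
            GenotypeMatrix(
                population_name=name,
                individual_ids=ind_ids,
                locus_names=list(locus_names),
                calls=rows,
            )
        )
        ind_ids, rows = [], []

    in_block = False
    for lineno, raw in enumerate(lines[first_pop:], start=first_pop + 1):
        line = raw.strip()
        if not line:
            continue
        if _POP_RE.match(line):
            if in_block:
                _flush()
            in_block = True
            continue
        if "," not in line:
            raise ValueError(
                f"line {lineno}: expected 'id , genotypes...' (missing comma)"
            )
        ind_id, _, rest = line.partition(",")
        ind_id = ind_id.strip()
        tokens = rest.split()
        if len(tokens) != len(locus_names):
            raise ValueError(
                f"line {lineno}: individual {ind_id!r} has {len(tokens)} "
                f"genotype fields, expected {len(locus_names)}"
            )
        row: list[Call] = []
        for tok in tokens:
            call, width = _parse_genotype_field(tok, lineno)
            if allele_width is None:
                allele_width = width
            elif width != allele_width:
                raise ValueError(
                    f"line {lineno}: mixed allele-code widths "
                    f"({width} vs {allele_width} digits)"
                )
            row.append(call)
        ind_ids.append(ind_id)
        rows.append(row)
    if in_block:
        _flush()

    if population_names is not None:
        if len(population_names) != len(matrices):
            raise ValueError(
                f"{len(population_names)} population names supplied for "
                f"{len(matrices)} Pop blocks"
            )
        for mat, name in zip(matrices, population_names):
            mat.population_name = name
    return matrices


def write_genepop(
    matrices: Sequence[GenotypeMatrix],
    path: str | Path,
    title: str = "ssrkit genotypes",
) -> None:
    """Write populations to GENEPOP text with 3-digit allele codes.

    All matrices must share locus names (order included); allele codes
    above 999 cannot be represented and raise ``ValueError``.
    """
    if not matrices:
        raise ValueError("no populations to write")
    locus_names = matrices[0].locus_names
    for mat in matrices[1:]:
        if mat.locus_names != locus_names:
            raise ValueError("all populations must share locus names")
    out: list[str] = [title]
    out.extend(locus_names)
    for mat in matrices:
        out.append("Pop")
        for ind, row in zip(mat.individual_ids, mat.calls):
            fields = []
            for call in row:
                if call is None:
                    fields.append("000000")
                    continue
                a1, a2 = call
                if a1 > 999 or a2 > 999:
                    raise ValueError(
                        f"allele code above 999 at individual {ind!r}; "
                        "GENEPOP 3-digit encoding cannot represent it"
                    )
                fields.append(f"{a1:03d}{a2:03d}")
            out.append(f"{ind} , " + " ".join(fields))
    Path(path).write_text("\n".join(out) + "\n")
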