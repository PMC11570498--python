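"""FASTA/TSV/JSON I/O and the pairwise-identity utility.

Reading is deliberately forgiving by default (proteome releases routinely
contain stop codons, lowercase stretches and rare letters such as U or B);
``strict=True`` turns every sanitization step into an error instead.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

logger = logging.getLogger(__name__)

#: the 20 canonical amino acids plus the unknown-residue placeholder
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")

GAP = "-"


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: a whitespace-free id, free-text description and
    an uppercase sequence over the 20 canonical letters plus X."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"protein id must be a whitespace-free token: {self.id!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"illegal residue letters {sorted(bad)} in {self.id!r}; "
                "sanitize via read_fasta or sanitize_sequence first"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment: two equal-length gapped strings and the
    affine-gap alignment score."""

    gapped_a: str
    gapped_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped sequences differ in length")
        if any(a == GAP and b == GAP for a, b in zip(self.gapped_a, self.gapped_b)):
            raise ValueError("gap-vs-gap column in alignment")

    @property
    def a(self) -> str:
        return self.gapped_a.replace(GAP, "")

    @property
    def b(self) -> str:
        return self.gapped_b.replace(GAP, "")


def sanitize_sequence(raw: str, *, strict: bool = False, id: str = "?") -> str:
    """Uppercase, strip terminal stop codons, and map letters outside the
    20-canonical+X alphabet to X (or raise when ``strict``)."""
    seq = raw.upper().rstrip("*")
    out = []
    replaced = set()
    for c in seq:
        if c in ALPHABET:
            out.append(c)
        elif strict:
            raise ValueError(f"illegal residue letter {c!r} in {id!r}")
        else:
            replaced.add(c)
            out.append("X")
    if replaced:
        logger.warning(
            "record %s: replaced non-standard letters %s with X",
            id, "".join(sorted(replaced)),
        )
    return "".join(out)


def read_fasta(path: str | Path, strict: bool = False) -> list[ProteinRecord]:
    """Parse a protein FASTA into sanitized :class:`ProteinRecord` objects.

    Raises ``ValueError`` on an empty file, a header with no sequence, a
    duplicate id, or (in strict mode) a letter outside the alphabet.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = sanitize_sequence(str(rec.seq), strict=strict, id=rec.id)
        if not seq:
            raise ValueError(f"header {rec.id!r} has no sequence")
        records.append(ProteinRecord(rec.id, rec.description, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as multi-line FASTA with a fixed wrap width."""
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            desc = rec.description
            header = desc if desc.startswith(rec.id) else f"{rec.id} {desc}".rstrip()
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def _format_value(v: object) -> str:
    if isinstance(v, bool) or v is None:
        return "" if v is None else str(v)
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


def _as_mapping(row: object) -> Mapping[str, object]:
    if dataclasses.is_dataclass(row) and not isinstance(row, type):
        return dataclasses.asdict(row)
    if hasattr(row, "to_row"):
        return row.to_row()  # type: ignore[union-attr]
    if isinstance(row, Mapping):
        return row
    raise TypeError(f"cannot convert {type(row).__name__} to a table row")


def write_table(rows: Sequence[object], path: str | Path, format: str = "tsv",
                columns: Sequence[str] | None = None) -> None:
    """Write row mappings (or dataclasses) as TSV or JSON.

    Column order is the key order of the first row unless ``columns`` is
    given; floats are rendered to 6 significant digits, so identical input
    yields byte-identical output.
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown table format {format!r}")
    mapped = [_as_mapping(r) for r in rows]
    if columns is None:
        columns = list(mapped[0].keys()) if mapped else []
    with open(path, "w", newline="\n") as fh:
        if format == "tsv":
            fh.write("\t".join(columns) + "\n")
            for m in mapped:
                fh.write("\t".join(_format_value(m.get(c)) for c in columns) + "\n")
        else:
            payload = [
                {c: (float(f"{v:.6g}") if isinstance(v := m.get(c), float) else v)
                 for c in columns}
                for m in mapped
            ]
            json.dump(payload, fh, indent=1, sort_keys=False)
            fh.write("\n")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    try:
        sub = substitution_matrices.load(matrix)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix!r}") from exc
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = sub
    # a gap of length L costs gap_open + gap_extend * L
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(a: str, b: str, matrix: str = "BLOSUM62",
                 gap_open: float = 10.0, gap_extend: float = 1.0) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (length-L gap costs
    ``gap_open + gap_extend * L``); default BLOSUM62, open 10, extend 1.

    The first optimal traceback of the aligner is returned, which makes the
    result deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def percent_identity(aln: PairwiseAlignment,
                     denominator: str = "columns") -> float:
    """Percent identical columns, to one decimal.

    Terminal gap-only overhangs are trimmed before counting.  The
    denominator is configurable: ``columns`` (alignment columns after
    trimming, including internal gaps), ``shorter`` or ``longer``
    (ungapped sequence lengths).
    """
    if denominator not in ("columns", "shorter", "longer"):
        raise ValueError(f"unknown identity denominator {denominator!r}")
    ga, gb = aln.gapped_a, aln.gapped_b
    n = len(ga)
    if n == 0:
        raise ValueError("zero-length alignment")
    lo = 0
    while lo < n and (ga[lo] == GAP or gb[lo] == GAP):
        lo += 1
    hi = n
    while hi > lo and (ga[hi - 1] == GAP or gb[hi - 1] == GAP):
        hi -= 1
    if hi <= lo:
        raise ValueError("alignment is all terminal overhang")
    matches = sum(1 for i in range(lo, hi) if ga[i] == gb[i] and ga[i] != GAP)
    if denominator == "columns":
        denom = hi - lo
    elif denominator == "shorter":
        denom = min(len(aln.a), len(aln.b))
    else:
        denom = max(len(aln.a), len(aln.b))
    return round(100.0 * matches / denom, 1)
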