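"""Alignment-column conservation mapped to reference-sequence positions.

Conservation is scored as consensus identity: the fraction of non-gap
letters in a column equal to the column's modal letter (ties broken
alphabetically).  Positions are 1-based in the ungapped reference sequence
and are mapped through the reference's gaps to alignment columns, so a
claim like "position 26 is conserved" refers to the residue numbering of
the reference protein, not to a raw column index.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Literal

from Bio import AlignIO

from .errors import InputError, ValidationError

GAP_CHARS = {"-", "."}


@dataclass(frozen=True)
class MSA:
    """An alignment: ordered (identifier, aligned sequence) records."""

    records: tuple[tuple[str, str], ...]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            bad = [name for name, seq in self.records]
            raise ValidationError(f"aligned sequences have unequal lengths: {bad}")
        if self.reference_id not in {name for name, _ in self.records}:
            raise ValidationError(f"reference {self.reference_id!r} not in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def reference_sequence(self) -> str:
        return dict(self.records)[self.reference_id]


def _normalize(seq: str) -> str:
    return "".join("-" if ch in GAP_CHARS else ch.upper() for ch in seq)


def read_alignment(
    path: str | Path,
    format: Literal["clustal", "aligned-fasta"] = "aligned-fasta",
    reference_id: str | None = None,
) -> MSA:
    """Read a Clustal or aligned-FASTA alignment.

    Letters are upper-cased and '.' gaps normalized to '-'.  The reference
    defaults to the first record.
    """
    fmt = {"clustal": "clustal", "aligned-fasta": "fasta"}.get(format)
    if fmt is None:
        raise ValidationError(f"unknown alignment format {format!r}")
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    return parse_alignment(text, format=format, reference_id=reference_id)


def parse_alignment(
    text: str,
    format: Literal["clustal", "aligned-fasta"] = "aligned-fasta",
    reference_id: str | None = None,
) -> MSA:
    fmt = {"clustal": "clustal", "aligned-fasta": "fasta"}[format]
    try:
        alignment = AlignIO.read(StringIO(text), fmt)
    except ValueError as exc:
        # ragged FASTA "alignments" are rejected by AlignIO with the ids lost;
        # recover them for the error message
        if fmt == "fasta":
            names = [line[1:].split()[0] for line in text.splitlines() if line.startswith(">")]
            raise ValidationError(
                f"records do not align (unequal lengths?) among {names}: {exc}"
            ) from exc
        raise InputError(f"cannot parse {format} alignment: {exc}") from exc
    records = tuple((rec.id, _normalize(str(rec.seq))) for rec in alignment)
    ref = reference_id if reference_id is not None else records[0][0]
    return MSA(records=records, reference_id=ref)


@dataclass(frozen=True)
class ConservationEntry:
    position: int  # 1-based ungapped reference position
    column: int  # 1-based alignment column
    consensus: str
    identity: float  # fraction of non-gap letters equal to the consensus


def _reference_columns(msa: MSA) -> list[int]:
    """0-based alignment column of each ungapped reference position."""
    return [i for i, ch in enumerate(msa.reference_sequence) if ch != "-"]


def column_conservation(
    msa: MSA, reference_positions: list[int]
) -> dict[int, ConservationEntry]:
    """Consensus identity of the columns holding the reference positions.

    Gaps count neither towards the consensus nor the denominator.  Raises if
    a position exceeds the reference's ungapped length.
    """
    ref_cols = _reference_columns(msa)
    out: dict[int, ConservationEntry] = {}
    for pos in reference_positions:
        if not 1 <= pos <= len(ref_cols):
            raise ValidationError(
                f"reference position {pos} beyond ungapped reference length "
                f"{len(ref_cols)}"
            )
        col = ref_cols[pos - 1]
        letters = [seq[col] for _, seq in msa.records if seq[col] != "-"]
        if not letters:
            out[pos] = ConservationEntry(pos, col + 1, "-", 0.0)
            continue
        counts = Counter(letters)
        top = max(counts.values())
        consensus = min(letter for letter, c in counts.items() if c == top)
        out[pos] = ConservationEntry(
            position=pos,
            column=col + 1,
            consensus=consensus,
            identity=counts[consensus] / len(letters),
        )
    return out


def conservation_tsv(entries: dict[int, ConservationEntry]) -> str:
    lines = ["position\tcolumn\tconsensus\tidentity"]
    for pos in sorted(entries):
        e = entries[pos]
        lines.append(f"{e.position}\t{e.column}\t{e.consensus}\t{e.identity:.3f}")
    return "\n".join(lines) + "\n"
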