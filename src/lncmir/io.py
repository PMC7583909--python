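"""Reading, validation and canonicalization of RNA sequences and pair tables.

Sequences are canonicalized to the DNA alphabet: uppercased, with uracil (U)
mapped to thymine (T), so every downstream encoder works over {A, C, G, T}.
Ambiguity codes (N, R, Y, ...) are rejected outright rather than dropped,
because all encoders assume a strict 4-letter alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RNARecord",
    "InteractionPair",
    "read_fasta",
    "write_fasta",
    "read_pairs",
    "write_pairs",
    "canonicalize",
]

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGT")

#: miRNAs are typically 20-25 nt; records longer than this are flagged, not
#: rejected (precursor hairpins and odd annotations do occur).
MIRNA_FLAG_LENGTH = 30


class SequenceError(ValueError):
    """Raised for malformed or invalid sequence input."""


class PairTableError(ValueError):
    """Raised for malformed or unresolvable pair-table input."""


def canonicalize(seq: str) -> str:
    """Uppercase a nucleotide string and map U to T. Idempotent."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class RNARecord:
    """A single RNA: identifier plus canonicalized sequence.

    Parameters
    ----------
    id : str
        Identifier, the first whitespace-delimited token of the FASTA header.
    seq : str
        Canonicalized sequence over {A, C, G, T}.
    kind : {"lncRNA", "miRNA"}
        Which class of RNA this record is; drives feature dimensionality.
    flagged : bool
        True for miRNA records longer than 30 nt (kept, but marked).
    """

    id: str
    seq: str
    kind: Literal["lncRNA", "miRNA"]
    flagged: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.seq:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        bad = [
            (i + 1, ch) for i, ch in enumerate(self.seq) if ch not in VALID_ALPHABET
        ]
        if bad:
            pos, ch = bad[0]
            raise SequenceError(
                f"record {self.id!r}: invalid character {ch!r} at position {pos} "
                f"(alphabet is A, C, G, T after U->T mapping)"
            )
        if self.kind not in ("lncRNA", "miRNA"):
            raise SequenceError(f"record {self.id!r}: unknown kind {self.kind!r}")
        if self.kind == "miRNA" and len(self.seq) > MIRNA_FLAG_LENGTH:
            object.__setattr__(self, "flagged", True)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class InteractionPair:
    """A labeled lncRNA-miRNA pair.

    ``source`` distinguishes curated positives from sampled negatives.
    """

    lnc_id: str
    mir_id: str
    label: int
    source: Literal["curated", "sampled"] = "curated"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise PairTableError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.lnc_id, self.mir_id)


def read_fasta(path: str | Path, kind: Literal["lncRNA", "miRNA"]) -> list[RNARecord]:
    """Read a FASTA file into canonicalized :class:`RNARecord` objects.

    The record id is the first whitespace-delimited header token. Sequences
    are uppercased and U is mapped to T. Duplicate ids and ambiguity codes
    raise :class:`SequenceError`; an empty file raises too.
    """
    path = Path(path)
    records: list[RNARecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise SequenceError(f"duplicate FASTA id {rid!r} in {path}")
        seen.add(rid)
        records.append(RNARecord(id=rid, seq=canonicalize(str(entry.seq)), kind=kind))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[RNARecord], path: str | Path) -> None:
    """Write records to FASTA (id as header, canonicalized sequence)."""
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(Path(path)), "fasta")


def _index(records: Sequence[RNARecord], kind: str) -> dict[str, RNARecord]:
    idx: dict[str, RNARecord] = {}
    for r in records:
        if r.kind != kind:
            raise PairTableError(f"record {r.id!r} has kind {r.kind!r}, expected {kind!r}")
        idx[r.id] = r
    return idx


def read_pairs(
    path: str | Path,
    lncs: Sequence[RNARecord],
    mirs: Sequence[RNARecord],
) -> list[InteractionPair]:
    """Read a two-column TSV of positive pairs (lnc_id TAB mir_id).

    Every id must resolve against the loaded records. An optional header line
    is auto-detected: if the first row does not resolve but a later row would,
    the first row is treated as a header. Duplicate pairs are collapsed and
    counted in a log message.
    """
    path = Path(path)
    lnc_idx = _index(lncs, "lncRNA")
    mir_idx = _index(mirs, "miRNA")

    rows: list[tuple[int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise PairTableError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            rows.append((lineno, parts[0].strip(), parts[1].strip()))

    if not rows:
        raise PairTableError(f"no pairs found in {path}")

    # Header auto-detection: drop the first row iff it does not resolve.
    first = rows[0]
    if first[1] not in lnc_idx or first[2] not in mir_idx:
        if len(rows) > 1:
            rows = rows[1:]

    pairs: list[InteractionPair] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for lineno, lnc_id, mir_id in rows:
        if lnc_id not in lnc_idx:
            raise PairTableError(f"{path}:{lineno}: unknown lncRNA id {lnc_id!r}")
        if mir_id not in mir_idx:
            raise PairTableError(f"{path}:{lineno}: unknown miRNA id {mir_id!r}")
        key = (lnc_id, mir_id)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        pairs.append(InteractionPair(lnc_id, mir_id, label=1, source="curated"))
    if n_dup:
        logger.info("collapsed %d duplicate pair(s) in %s", n_dup, path)
    return pairs


def write_pairs(
    pairs: Iterable[InteractionPair],
    path: str | Path,
    folds: dict[tuple[str, str], int] | None = None,
) -> None:
    """Write pairs as TSV with columns lnc_id, mir_id, label, source[, fold]."""
    with open(path, "w") as fh:
        header = ["lnc_id", "mir_id", "label", "source"]
        if folds is not None:
            header.append("fold")
        fh.write("\t".join(header) + "\n")
        for p in pairs:
            row = [p.lnc_id, p.mir_id, str(p.label), p.source]
            if folds is not None:
                row.append(str(folds[p.key]))
            fh.write("\t".join(row) + "\n")
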