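"""Reading, writing and validating gene (CDS) sequences and protein-pair tables.

Sequences are coding-sequence nucleotide strings over {A, C, G, T}.  FASTA
input is normalised (upper-cased, RNA ``U`` mapped to ``T``) and validated
under one of three policies for ambiguity codes (``N``, ``R``, ``Y``, ...):

``strict``
    any non-ACGT character is an error (default; mirrors how curated CDS
    sets are normally used),
``drop``
    records containing non-ACGT characters are discarded with a warning,
``mask``
    the record is kept and downstream feature extraction ignores positions
    and k-mer windows touching the offending character.

Pair tables are tab-separated files with two or three columns
(``id_a``, ``id_b``, optional ``label`` in {0, 1}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_NUCLEOTIDES = frozenset("ACGT")
POLICIES = ("strict", "drop", "mask")


class SequenceValidationError(ValueError):
    """A sequence or FASTA file violates the validation policy."""


class PairTableError(ValueError):
    """A pair table row is malformed."""


@dataclass(frozen=True)
class GeneSequence:
    """One CDS: identifier plus nucleotide string ``s_1 ... s_N``."""

    id: str
    seq: str

    @property
    def N(self) -> int:
        """Sequence length in nucleotides."""
        return len(self.seq)

    def __post_init__(self) -> None:
        if not self.seq:
            raise SequenceValidationError(f"sequence {self.id!r} is empty")


@dataclass(frozen=True)
class ProteinPair:
    """Two protein ids with an optional interaction label (1 = interacting)."""

    id_a: str
    id_b: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise PairTableError(
                f"label for pair ({self.id_a}, {self.id_b}) must be 0 or 1, "
                f"got {self.label!r}"
            )

    def key(self) -> tuple[str, str]:
        """Unordered pair identity: (a, b) and (b, a) share a key."""
        return (self.id_a, self.id_b) if self.id_a <= self.id_b else (self.id_b, self.id_a)


def _normalize(raw: str) -> str:
    return raw.upper().replace("U", "T")


def validate_sequence(id_: str, seq: str, policy: str = "strict") -> Optional[GeneSequence]:
    """Normalise and validate one sequence under ``policy``.

    Returns the validated :class:`GeneSequence`, or ``None`` when the policy
    discards it.  Logs a warning when the length is not a multiple of 3
    (no reading-frame check is enforced beyond that).
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    seq = _normalize(seq)
    bad = [i for i, ch in enumerate(seq) if ch not in VALID_NUCLEOTIDES]
    if bad:
        if policy == "strict":
            pos = bad[0] + 1
            raise SequenceValidationError(
                f"sequence {id_!r}: invalid character {seq[bad[0]]!r} at position {pos}"
            )
        if policy == "drop":
            logger.warning(
                "dropping sequence %r: %d non-ACGT character(s), first at position %d",
                id_, len(bad), bad[0] + 1,
            )
            return None
        # mask: keep the characters; feature extraction skips them
    if len(seq) % 3 != 0:
        logger.warning("sequence %r length %d is not a multiple of 3", id_, len(seq))
    return GeneSequence(id=id_, seq=seq)


def read_fasta(path: str | Path, policy: str = "strict") -> list[GeneSequence]:
    """Read a multi-record FASTA of CDS sequences.

    Records are upper-cased with U mapped to T.  Raises on an empty file and
    on duplicate record ids; ambiguity characters are handled per ``policy``.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceValidationError(f"{path}: no FASTA records found")
    out: list[GeneSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        gs = validate_sequence(rec.id, str(rec.seq), policy=policy)
        if gs is not None:
            out.append(gs)
    return out


def write_fasta(sequences: Iterable[GeneSequence], path: str | Path) -> None:
    """Write sequences as unwrapped FASTA (one sequence line per record)."""
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(records)


_HEADER_TOKENS = {"id_a", "id_b", "label"}


def read_pair_table(path: str | Path) -> list[ProteinPair]:
    """Read a tab-separated pair table (2 or 3 columns, optional header).

    The third column, when present, is the {0, 1} interaction label; rows
    without it yield unlabeled pairs.  Input order is preserved.
    """
    path = Path(path)
    pairs: list[ProteinPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and any(f.strip().lower() in _HEADER_TOKENS for f in fields):
                continue
            if len(fields) not in (2, 3):
                raise PairTableError(
                    f"{path}, line {lineno}: expected 2 or 3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            label: Optional[int] = None
            if len(fields) == 3 and fields[2].strip() != "":
                raw = fields[2].strip()
                if raw not in ("0", "1"):
                    raise PairTableError(
                        f"{path}, line {lineno}: label must be 0 or 1, got {raw!r}"
                    )
                label = int(raw)
            pairs.append(ProteinPair(fields[0].strip(), fields[1].strip(), label))
    return pairs


def write_pair_table(pairs: Iterable[ProteinPair], path: str | Path,
                     header: bool = True) -> None:
    """Write pairs as TSV (id_a, id_b, label); label column blank if absent."""
    with open(path, "w") as fh:
        if header:
            fh.write("id_a\tid_b\tlabel\n")
        for p in pairs:
            lab = "" if p.label is None else str(p.label)
            fh.write(f"{p.id_a}\t{p.id_b}\t{lab}\n")


def sequence_index(sequences: Iterable[GeneSequence]) -> dict[str, GeneSequence]:
    """Map id -> sequence, raising on duplicates."""
    idx: dict[str, GeneSequence] = {}
    for s in sequences:
        if s.id in idx:
            raise SequenceValidationError(f"duplicate sequence id {s.id!r}")
        idx[s.id] = s
    return idx
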