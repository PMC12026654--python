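"""Reading, validating, filtering and writing RNA transcript sequences.

Transcripts arrive as FASTA (DNA or RNA alphabet); everything downstream of
this module works on uppercase RNA over {A, C, G, U}.  Records containing
ambiguity codes (N, X, ...) are skipped, not fatal: public transcript dumps
routinely contain a small fraction of low-quality entries and the pipeline
mirrors the usual batch behaviour of dropping them with a logged report.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
_ALLOWED_INPUT = frozenset("ACGUTacgut")

NucleotideCounts = namedtuple("NucleotideCounts", ["nA", "nC", "nG", "nU"])

SkipRecord = namedtuple("SkipRecord", ["id", "reason"])


class InvalidSequenceError(ValueError):
    """Raised when a raw sequence cannot be normalized to the RNA alphabet."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated transcript: uppercase residues over {A, C, G, U}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise InvalidSequenceError(f"{self.id}: empty sequence")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise InvalidSequenceError(
                f"{self.id}: invalid residues {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def counts(self) -> NucleotideCounts:
        r = self.residues
        return NucleotideCounts(
            nA=r.count("A"), nC=r.count("C"), nG=r.count("G"), nU=r.count("U")
        )


@dataclass
class SequenceSet:
    """An ordered collection of transcripts with unique ids.

    ``label`` optionally tags the whole set with its class
    (1 = lncRNA / positive, 0 = mRNA / negative).
    """

    records: list[RnaSequence] = field(default_factory=list)
    label: Optional[int] = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate sequence id: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RnaSequence]:
        return iter(self.records)

    def __getitem__(self, idx: int) -> RnaSequence:
        return self.records[idx]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def normalize_sequence(raw: str, id: str) -> RnaSequence:
    """Uppercase, convert DNA T to RNA U, and validate a raw sequence.

    Raises
    ------
    InvalidSequenceError
        If ``raw`` is empty or contains symbols outside {A,C,G,U,T} in
        either case (ambiguity codes such as N or X are rejected).
    """
    if not raw:
        raise InvalidSequenceError(f"{id}: empty sequence")
    bad = set(raw) - _ALLOWED_INPUT
    if bad:
        raise InvalidSequenceError(f"{id}: invalid symbols {sorted(bad)!r}")
    return RnaSequence(id=id, residues=raw.upper().replace("T", "U"))


def read_fasta(path: str | Path) -> tuple[SequenceSet, list[SkipRecord]]:
    """Read a FASTA file into a :class:`SequenceSet`.

    Records that fail normalization (ambiguity codes, empty sequences) are
    dropped and reported in the returned skip list rather than aborting the
    whole file.

    Returns
    -------
    (SequenceSet, list of SkipRecord)

    Raises
    ------
    ValueError
        If the file yields zero parseable records.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    records: list[RnaSequence] = []
    skipped: list[SkipRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(normalize_sequence(str(rec.seq), rec.id))
        except InvalidSequenceError as exc:
            skipped.append(SkipRecord(rec.id, str(exc)))
            logger.warning("skipping %s: %s", rec.id, exc)
    if not records and not skipped:
        raise ValueError(f"{path}: no FASTA records found")
    if not records:
        raise ValueError(f"{path}: all {len(skipped)} records failed validation")
    return SequenceSet(records=records), skipped


def write_fasta(seqs: SequenceSet | Iterable[RnaSequence], path: str | Path) -> int:
    """Write sequences as FASTA with 60-column line wrapping.

    Returns the number of records written; raises ``ValueError`` on an
    empty set.  Round-trips losslessly through :func:`read_fasta`
    (ids and residues).
    """
    records = list(seqs)
    if not records:
        raise ValueError("refusing to write an empty sequence set")
    bio = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")
    return len(records)


def filter_by_length(
    seqs: SequenceSet, min_len: int = 200, max_len: int = 6000
) -> SequenceSet:
    """Keep records with ``min_len <= L <= max_len`` (inclusive bounds)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = [r for r in seqs if min_len <= r.length <= max_len]
    return SequenceSet(records=kept, label=getattr(seqs, "label", None))


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped sliding identity between two sequences.

    The shorter sequence is slid along the longer at every offset
    (partial overlaps included); at each offset the number of matching
    positions in the overlap is counted, and identity is the best match
    count divided by the length of the shorter sequence — the convention
    of greedy incremental clustering tools.
    """
    if len(a) < len(b):
        a, b = b, a
    la, lb = len(a), len(b)
    best = 0
    # offset of b's start relative to a's start; negative = b hangs off left
    for off in range(-(lb - 1), la):
        start_b = max(0, -off)
        start_a = max(0, off)
        overlap = min(lb - start_b, la - start_a)
        if overlap <= best:  # cannot beat current best
            continue
        matches = sum(
            1
            for x, y in zip(
                a[start_a : start_a + overlap], b[start_b : start_b + overlap]
            )
            if x == y
        )
        if matches > best:
            best = matches
    return best / lb


def reduce_redundancy(
    seqs: SequenceSet, identity_threshold: float = 0.9
) -> SequenceSet:
    """Greedy longest-first redundancy removal.

    Records are visited longest first; a record is discarded when its
    :func:`pairwise_identity` to any already-retained record reaches the
    threshold.  This is a desk-scale stand-in for external clustering
    tools (e.g. CD-HIT at 0.9); pre-clustered input passes through
    unchanged.  Deterministic given input order (ties in length keep
    input order).
    """
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity_threshold must be in (0, 1]")
    order = sorted(range(len(seqs)), key=lambda i: -seqs[i].length)
    retained_idx: list[int] = []
    for i in order:
        cand = seqs[i]
        if all(
            pairwise_identity(cand.residues, seqs[j].residues)
            < identity_threshold
            for j in retained_idx
        ):
            retained_idx.append(i)
    retained_idx.sort()  # restore input order
    return SequenceSet(
        records=[seqs[i] for i in retained_idx],
        label=getattr(seqs, "label", None),
    )


def write_skip_report(skipped: list[SkipRecord], path: str | Path) -> None:
    """Write a tab-separated (id, reason) log of skipped records."""
    with open(path, "w") as fh:
        for rec in skipped:
            fh.write(f"{rec.id}\t{rec.reason}\n")
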