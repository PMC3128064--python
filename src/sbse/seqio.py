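"""Build a masked, one-to-one 3'UTR repository from FASTA and mapping tables.

Seed-match scanning assumes every expression identifier resolves to exactly
one 3'UTR sequence and that low-complexity repeats have been masked so that
they cannot masquerade as seed sites.  This module provides the plumbing:
FASTA ingest with normalization to the {A,C,G,T,N} alphabet, the
longest-UTR rule for many-to-one transcript mappings, and a windowed
triplet-composition masker in the DUST family.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class UtrRecord:
    """A single 3'UTR sequence, normalized to uppercase {A,C,G,T,N}."""

    utr_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.utr_id:
            raise ValueError("utr_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"zero-length sequence for {self.utr_id!r}")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"sequence for {self.utr_id!r} contains invalid characters {bad!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class UtrRepository:
    """One masked UTR per expression-row identifier (one-to-one mapping).

    ``entries`` maps an expression identifier (e.g. a probe-set id) to
    exactly one :class:`UtrRecord`; ``unmapped_count`` records how many
    expression identifiers in the source mapping had no UTR sequence.
    """

    entries: dict[str, UtrRecord] = field(default_factory=dict)
    unmapped_count: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self.entries

    def get(self, identifier: str) -> UtrRecord | None:
        return self.entries.get(identifier)


def _normalize(seq: str) -> tuple[str, int]:
    """Uppercase and collapse any non-ACGT character (IUPAC ambiguity
    codes included) to N; returns the sequence and the number collapsed."""
    seq = seq.upper()
    ambiguous = sum(1 for c in seq if c not in _VALID)
    if ambiguous:
        seq = "".join(c if c in _VALID else "N" for c in seq)
    return seq, ambiguous


def read_fasta(path: str | Path) -> list[UtrRecord]:
    """Read a (multi-line) FASTA file into a list of :class:`UtrRecord`.

    Headers are parsed up to the first whitespace as the UTR identifier.
    Characters outside {A,C,G,T,N} are converted to N; the total
    conversion count is logged.  Zero-length entries are rejected with a
    warning rather than raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[UtrRecord] = []
    n_ambiguous = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq, amb = _normalize(str(rec.seq))
        n_ambiguous += amb
        if not seq:
            logger.warning("rejecting zero-length sequence %r", rec.id)
            continue
        records.append(UtrRecord(rec.id, seq))
    if n_ambiguous:
        logger.info("converted %d ambiguous bases to N", n_ambiguous)
    return records


def write_fasta(repo: UtrRepository | Iterable[UtrRecord], path: str | Path,
                wrap: int = 60) -> None:
    """Write records (or a repository's records keyed by expression id) to
    FASTA with ``wrap``-column line wrapping."""
    if isinstance(repo, UtrRepository):
        items = [(key, rec.sequence) for key, rec in repo.entries.items()]
    else:
        items = [(rec.utr_id, rec.sequence) for rec in repo]
    seq_records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)


def resolve_longest(records: Iterable[UtrRecord],
                    probe_map: Mapping[str, str] | None = None) -> UtrRepository:
    """Resolve many-to-one UTR mappings by keeping the longest UTR.

    ``probe_map`` maps expression identifiers to UTR identifiers; several
    expression rows may share a UTR and several FASTA entries may carry the
    same identifier (transcript isoforms).  For every expression identifier
    the longest candidate sequence is retained; length ties are broken by
    first occurrence in input order and logged.  Without a mapping, the
    UTR identifiers themselves serve as expression identifiers.
    """
    by_utr_id: dict[str, UtrRecord] = {}
    for rec in records:
        prev = by_utr_id.get(rec.utr_id)
        if prev is None:
            by_utr_id[rec.utr_id] = rec
        elif rec.length > prev.length:
            by_utr_id[rec.utr_id] = rec
        else:
            if rec.length == prev.length:
                logger.info("length tie for %r: keeping first occurrence", rec.utr_id)
    if probe_map is None:
        return UtrRepository(entries=dict(by_utr_id), unmapped_count=0)
    entries: dict[str, UtrRecord] = {}
    unmapped = 0
    for expr_id, utr_id in probe_map.items():
        rec = by_utr_id.get(utr_id)
        if rec is None:
            unmapped += 1
        else:
            entries[expr_id] = rec
    return UtrRepository(entries=entries, unmapped_count=unmapped)


def _triplet_mask_pass(seq: list[str], window: int, threshold: float) -> int:
    """One masking pass: mark every window whose normalized triplet score
    exceeds ``threshold``; returns the number of newly masked positions.

    Window score is sum over triplet counts c of c*(c-1)/2, divided by
    (l - 1) where l is the number of {A,C,G,T}-only triplets in the window
    — the classic repeat-composition statistic behind DUST-style maskers.
    """
    n = len(seq)
    w = min(window, n)
    to_mask: set[int] = set()

    counts: Counter[str] = Counter()
    sum_pairs = 0  # Σ c(c-1)/2 over triplet counts
    valid = 0

    def triplet(pos: int) -> str | None:
        t = seq[pos] + seq[pos + 1] + seq[pos + 2]
        return t if "N" not in t else None

    # initial window [0, w)
    for p in range(w - 2):
        t = triplet(p)
        if t is not None:
            counts[t] += 1
            sum_pairs += counts[t] - 1
            valid += 1

    for start in range(n - w + 1):
        if valid >= 2 and sum_pairs / (valid - 1) > threshold:
            to_mask.update(range(start, start + w))
        if start + w < n:  # roll window forward
            t_out = triplet(start)
            if t_out is not None:
                sum_pairs -= counts[t_out] - 1
                counts[t_out] -= 1
                valid -= 1
            t_in = triplet(start + w - 2)
            if t_in is not None:
                counts[t_in] += 1
                sum_pairs += counts[t_in] - 1
                valid += 1

    newly = [i for i in to_mask if seq[i] != "N"]
    for i in newly:
        seq[i] = "N"
    return len(newly)


def mask_low_complexity(sequence: str, window: int = 64,
                        threshold: float = 2.0) -> str:
    """Mask low-complexity (repeat-rich) regions with N.

    A sliding window of length ``window`` is scored by its triplet
    composition (see :func:`_triplet_mask_pass`); windows scoring above
    ``threshold`` are masked entirely.  Passes repeat until a fixed point,
    which makes the operation idempotent by construction.  Sequences
    shorter than three bases have no triplet and are returned unchanged.
    """
    if window < 3:
        raise ValueError(f"window must be >= 3, got {window}")
    bad = set(sequence) - _VALID
    if bad:
        raise ValueError(f"sequence contains invalid characters {bad!r}")
    if len(sequence) < 3:
        return sequence
    seq = list(sequence)
    while _triplet_mask_pass(seq, window, threshold):
        pass
    return "".join(seq)


def load_probe_map(path: str | Path, header: bool = False) -> dict[str, str]:
    """Load a two-column tab-delimited expression-id → UTR-id mapping.

    Duplicate expression identifiers are an error (the one-to-one mapping
    would be ambiguous); duplicate UTR identifiers are fine — many probes
    may interrogate one transcript.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{lineno}: malformed mapping row {line!r}")
            expr_id, utr_id = fields
            if expr_id in mapping:
                raise ValueError(
                    f"{path}:{lineno}: duplicate expression identifier {expr_id!r}"
                )
            mapping[expr_id] = utr_id
    if not mapping:
        logger.warning("empty probe map %s", path)
    return mapping
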