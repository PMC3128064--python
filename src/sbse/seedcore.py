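"""Seed queries and match vectors.

An RNAi guide strand represses targets through complementarity between
its 5' seed region and the target 3'UTR, so the query motif scanned for
in UTRs is the reverse complement (written as DNA) of a guide-strand
span.  A profile plus a UTR repository plus a query yields the ordered
binary match vector D that the Bayesian engine consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np

from Bio.Seq import Seq

from .profile import RankedProfile
from .seqio import UtrRepository

logger = logging.getLogger(__name__)

_DNA = frozenset("ACGT")
MAX_MOTIF = 10


@dataclass(frozen=True)
class SeedQuery:
    """A DNA motif to match in 3'UTRs, with optional guide provenance.

    Biological seed queries are 4-10 nt (hexamers and heptamers in
    practice); shorter motifs are admitted only so that exhaustive k-mer
    libraries can be enumerated at any k.
    """

    motif: str
    guide: str | None = None
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if set(self.motif) - _DNA:
            raise ValueError(f"motif {self.motif!r} must be uppercase DNA over ACGT")
        if not 1 <= len(self.motif) <= MAX_MOTIF:
            raise ValueError(
                f"motif length must be 1-{MAX_MOTIF}, got {len(self.motif)}"
            )

    def __len__(self) -> int:
        return len(self.motif)


@dataclass
class MatchVector:
    """Binary presence/absence of a motif along the ranked profile.

    ``bits[r-1]`` is 1 iff the motif occurs in the UTR of the gene at rank
    r, over the post-exclusion profile (rows without a UTR are removed
    before ranks are assigned, not zero-filled, so the vector describes
    exactly the analyzed sequence universe).
    """

    bits: np.ndarray
    excluded: int = 0
    profile: RankedProfile | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if not np.all((self.bits == 0) | (self.bits == 1)):
            raise ValueError("bits must be 0/1")

    def __len__(self) -> int:
        return len(self.bits)


def seed_complement(guide: str, start: int, end: int) -> SeedQuery:
    """Reverse complement of guide[start..end] (1-based, inclusive) as DNA.

    The guide is given 5'→3' in RNA or DNA; U pairs as T.  The returned
    motif is the sequence a target 3'UTR must contain for seed pairing.
    """
    guide_dna = guide.upper().replace("U", "T")
    if set(guide_dna) - _DNA:
        raise ValueError(f"guide contains non-nucleotide characters: {guide!r}")
    if not (1 <= start < end <= len(guide_dna)):
        raise ValueError(
            f"span {start}:{end} out of bounds for guide of length {len(guide_dna)}"
        )
    sub = guide_dna[start - 1:end]
    motif = str(Seq(sub).reverse_complement())
    return SeedQuery(motif=motif, guide=guide.upper(), span=(start, end))


def enumerate_kmers(k: int) -> list[SeedQuery]:
    """All 4**k DNA motifs of length k in lexicographic A<C<G<T order."""
    if not 1 <= k <= MAX_MOTIF:
        raise ValueError(f"k must be in 1..{MAX_MOTIF}, got {k}")
    return [SeedQuery(motif="".join(tup)) for tup in product("ACGT", repeat=k)]


def build_match_vector(profile: RankedProfile, repo: UtrRepository,
                       query: SeedQuery | str) -> MatchVector:
    """Presence/absence of the motif in each ranked gene's masked UTR.

    Presence is exact substring occurrence (at least once; multiplicity is
    deliberately ignored — one seed site per UTR is assumed relevant).
    Masked positions are N and never match.  Profile rows with no UTR in
    the repository are excluded and the ranks of the survivors reassigned.
    """
    motif = query.motif if isinstance(query, SeedQuery) else query
    keep_idx = [i for i, ident in enumerate(profile.identifiers) if ident in repo]
    excluded = profile.N - len(keep_idx)
    if not keep_idx:
        raise ValueError("every profile row lacks a UTR; nothing to scan")
    if excluded:
        sub = RankedProfile(
            identifiers=[profile.identifiers[i] for i in keep_idx],
            fold_changes=profile.fold_changes[keep_idx],
            p_values=profile.p_values[keep_idx],
        )
    else:
        sub = profile
    bits = np.fromiter(
        (motif in repo.entries[ident].sequence for ident in sub.identifiers),
        dtype=np.uint8, count=len(sub.identifiers),
    )
    return MatchVector(bits=bits, excluded=excluded, profile=sub)


def encode_kmers_present(sequence: str, k: int) -> np.ndarray:
    """Sorted codes (base-4, A=0,C=1,G=2,T=3) of the distinct k-mers
    present in ``sequence``; windows containing N are skipped.

    Used by the composite scan to score all 4**k motifs in one pass per
    UTR instead of 4**k substring searches.
    """
    codes = np.frombuffer(sequence.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for base, val in zip(b"ACGT", range(4)):
        lut[base] = val
    vals = lut[codes]
    n = len(vals) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(vals, k)
    valid = np.all(windows >= 0, axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    kmer_codes = windows[valid] @ powers
    return np.unique(kmer_codes)


def match_matrix(profile: RankedProfile, repo: UtrRepository,
                 k: int) -> tuple[np.ndarray, RankedProfile, int]:
    """Boolean matrix (post-exclusion genes × 4**k motifs) of k-mer
    presence, plus the post-exclusion profile and the excluded count."""
    keep_idx = [i for i, ident in enumerate(profile.identifiers) if ident in repo]
    excluded = profile.N - len(keep_idx)
    if not keep_idx:
        raise ValueError("every profile row lacks a UTR; nothing to scan")
    sub = RankedProfile(
        identifiers=[profile.identifiers[i] for i in keep_idx],
        fold_changes=profile.fold_changes[keep_idx],
        p_values=profile.p_values[keep_idx],
    ) if excluded else profile
    mat = np.zeros((len(sub.identifiers), 4 ** k), dtype=bool)
    for row, ident in enumerate(sub.identifiers):
        present = encode_kmers_present(repo.entries[ident].sequence, k)
        mat[row, present] = True
    return mat, sub, excluded


def motif_to_code(motif: str) -> int:
    """Base-4 code of a DNA motif (A=0, C=1, G=2, T=3)."""
    code = 0
    for c in motif:
        code = code * 4 + "ACGT".index(c)
    return code
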