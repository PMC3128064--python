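"""Differential-expression profiles: ingest, ranking, processing order.

The scan consumes a profile twice over: once as the ranked axis (most
up-regulated at rank 1, most down-regulated at rank N) against which every
candidate division is defined, and once as the *absolute* processing order
that feeds observations to the Bayesian update from most to least
dysregulated.  Shuffled profiles — identifiers permuted against their
statistics — are the negative control: they destroy any genuine
association between the ranking and seed-motif presence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionRecord:
    identifier: str
    fold_change: float
    p_value: float | None = None

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("identifier must be non-empty")
        if not math.isfinite(self.fold_change):
            raise ValueError(f"non-finite fold change for {self.identifier!r}")


@dataclass
class RankedProfile:
    """Expression records ordered from most up- to most down-regulated.

    Rank r = 1..N is implicit in position; fold changes are non-increasing.
    """

    identifiers: list[str]
    fold_changes: np.ndarray
    p_values: np.ndarray  # NaN where absent

    def __post_init__(self) -> None:
        self.fold_changes = np.asarray(self.fold_changes, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.N < 2:
            raise ValueError("a ranked profile needs at least two records")
        if np.any(np.diff(self.fold_changes) > 0):
            raise ValueError("fold changes must be non-increasing along ranks")

    @property
    def N(self) -> int:
        return len(self.identifiers)

    def records(self) -> list[ExpressionRecord]:
        return [
            ExpressionRecord(i, fc, None if np.isnan(p) else p)
            for i, fc, p in zip(self.identifiers, self.fold_changes, self.p_values)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "identifier": self.identifiers,
                "fold_change": self.fold_changes,
                "p_value": self.p_values,
            }
        )


@dataclass(frozen=True)
class AbsoluteOrder:
    """Permutation of ranks 1..N from most to least dysregulated.

    ``order[j]`` is the rank (1-based position on the ranked axis) of the
    observation consumed at step j+1; |fold change| is non-increasing
    along the order.
    """

    order: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        arr = np.asarray(self.order, dtype=int)
        object.__setattr__(self, "order", arr)
        n = len(arr)
        if sorted(arr.tolist()) != list(range(1, n + 1)):
            raise ValueError("order must be a permutation of 1..N")

    def __len__(self) -> int:
        return len(self.order)

    def __iter__(self):
        return iter(self.order)


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def load_profile(path: str | Path, id_col: int = 0, fc_col: int = 1,
                 p_col: int | None = 2) -> list[ExpressionRecord]:
    """Load a tab-delimited expression table (identifier, fold change,
    optional p-value).  A header line is auto-detected by a non-numeric
    fold-change field; rows whose fold change does not parse to a finite
    number are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#",
                     skip_blank_lines=True)
    if df.shape[1] <= max(id_col, fc_col):
        raise ValueError(f"{path}: fewer columns than required")
    if not _looks_numeric(str(df.iloc[0, fc_col])):
        df = df.iloc[1:]
    records: list[ExpressionRecord] = []
    dropped = 0
    has_p = p_col is not None and p_col < df.shape[1]
    for row in df.itertuples(index=False):
        ident = str(row[id_col])
        fc = pd.to_numeric(row[fc_col], errors="coerce")
        if pd.isna(fc) or not math.isfinite(fc):
            dropped += 1
            continue
        p = None
        if has_p:
            p = pd.to_numeric(row[p_col], errors="coerce")
            p = None if pd.isna(p) else float(p)
        records.append(ExpressionRecord(ident, float(fc), p))
    if dropped:
        logger.warning("dropped %d rows with unparseable fold change", dropped)
    if len(records) < 2:
        raise ValueError(f"{path}: fewer than two parseable rows")
    return records


def rank_by_fold_change(records: Iterable[ExpressionRecord]) -> RankedProfile:
    """Order records from most up- to most down-regulated.

    Ties on fold change are broken by ascending p-value (absent treated
    as 1), then lexicographic identifier — an arbitrary but deterministic
    rule so that repeated runs agree on the optimum division.
    """
    recs = list(records)
    if len(recs) < 2:
        raise ValueError("need at least two records to rank")
    recs.sort(key=lambda r: (-r.fold_change,
                             1.0 if r.p_value is None else r.p_value,
                             r.identifier))
    return RankedProfile(
        identifiers=[r.identifier for r in recs],
        fold_changes=np.array([r.fold_change for r in recs], dtype=float),
        p_values=np.array(
            [np.nan if r.p_value is None else r.p_value for r in recs], dtype=float
        ),
    )


def _absolute_sort_key(fc: np.ndarray) -> np.ndarray:
    """Ranks 1..N sorted by descending |fold change|; ties go to the
    up-regulated member first, then to the smaller rank."""
    n = len(fc)
    ranks = np.arange(1, n + 1)
    keys = sorted(range(n), key=lambda i: (-abs(fc[i]), 0 if fc[i] > 0 else 1, i))
    return ranks[keys]


def absolute_order(profile: RankedProfile) -> AbsoluteOrder:
    """Derive the processing order: most- to least-dysregulated rank."""
    return AbsoluteOrder(order=_absolute_sort_key(profile.fold_changes))


def shuffle_profile(profile: RankedProfile,
                    seed: int | np.random.Generator) -> RankedProfile:
    """Negative control: permute identifiers against the statistics.

    The (fold change, p-value) columns keep their ranked order; only the
    identifier column is permuted, severing the link between the ranking
    and each gene's UTR.  Identical seeds give identical permutations.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    perm = rng.permutation(profile.N)
    return RankedProfile(
        identifiers=[profile.identifiers[i] for i in perm],
        fold_changes=profile.fold_changes.copy(),
        p_values=profile.p_values.copy(),
    )


def count_dysregulated(records: Iterable[ExpressionRecord] | RankedProfile,
                       fc_threshold: float, p_threshold: float,
                       log2_scale: bool = True) -> int:
    """Count records with |linear fold change| > fc_threshold and
    p-value < p_threshold (the volcano-plot filter).

    ``log2_scale`` says the stored fold changes are log2 ratios (the LIMMA
    convention); they are converted via |fc_linear| = 2**|fc_log2| before
    comparison against the linear-scale threshold.
    """
    recs = records.records() if isinstance(records, RankedProfile) else list(records)
    count = 0
    for r in recs:
        if r.p_value is None:
            raise ValueError(f"record {r.identifier!r} has no p-value")
        mag = 2.0 ** abs(r.fold_change) if log2_scale else abs(r.fold_change)
        if mag > fc_threshold and r.p_value < p_threshold:
            count += 1
    return count


def write_profile(profile: RankedProfile, path: str | Path,
                  provenance: Sequence[str] = ()) -> None:
    """Write a ranked profile as tab-delimited text with '#' provenance
    header lines."""
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        for ident, fc, p in zip(profile.identifiers, profile.fold_changes,
                                profile.p_values):
            p_str = "" if np.isnan(p) else f"{p:.6g}"
            fh.write(f"{ident}\t{fc:.6g}\t{p_str}\n")
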