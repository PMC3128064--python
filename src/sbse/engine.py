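"""Sequential Bayesian evaluation of seed enrichment along a ranked profile.

The model: the ranked profile can be split at any of the N-1 divisions i
into a "left" (up-regulated, ranks 1..i) and a "right" (down-regulated,
ranks i+1..N) side.  Hypothesis H_i says the observed binary seed-match
vector D is best explained by a differential distribution of matches
across division i; the null H_0 says match placement is independent of
the ranking.  Observations are consumed from most to least dysregulated
(the absolute order A), and after each observation every division's
posterior is updated by Bayes' rule:

    P{H_i | D_1..j} ∝ P{d_j | H_i} · P{H_i | D_1..j-1}

with likelihoods built from running counts over the observations
processed so far, including the current one:

  * a matching gene falling on a side contributes the ratio of matches on
    that side to all matches processed;
  * a non-matching gene contributes the analogous non-match ratio;
  * under H_0 the gene contributes the ratio of genes on that side to all
    genes processed.

A ratio with zero denominator is uninformative and contributes a factor
of one — in particular the first observation leaves every posterior at
its prior.  All arithmetic is in log space; the enrichment score is
-log P{H_0 | D_1..j}, floored so it never exceeds -log(1e-300).

Binning groups the ranked list into M contiguous bins, reducing the
N(N-1) updates to M(M-1): a bin with x matches and y non-matches
contributes p^x · q^y (match and non-match side-ratios) under H_i and
p^(x+y) (gene side-ratio) under H_0.  With M = N the binned scan is
identical to the unbinned one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profile import AbsoluteOrder, RankedProfile
from .seedcore import MatchVector, SeedQuery, enumerate_kmers, match_matrix, motif_to_code
from .seqio import UtrRepository

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
LOG_P_FLOOR = math.log(P_FLOOR)
UNBINNED_WARN_N = 3000
DEFAULT_MAX_BINS = 1000
MAD_SCALE = 1.4826  # normal-consistency factor for the median absolute deviation
DEFAULT_PROMINENCE_Z = 5.0


@dataclass
class BinnedProfile:
    """M contiguous bins along the ranked axis with per-bin match counts.

    ``x[b]``/``y[b]`` are the match/non-match counts in bin b (bins are
    numbered left to right along the ranking); ``spans`` holds 1-based
    inclusive rank spans; ``order`` is the 0-based bin consumption order
    (most dysregulated bin first).
    """

    x: np.ndarray
    y: np.ndarray
    spans: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if len(self.x) != len(self.y) or len(self.x) < 1:
            raise ValueError("x and y must have equal, positive length")
        if sorted(np.asarray(self.order).tolist()) != list(range(self.M)):
            raise ValueError("order must be a permutation of bin indices")

    @property
    def M(self) -> int:
        return len(self.x)

    @property
    def sizes(self) -> np.ndarray:
        return self.x + self.y

    @property
    def N(self) -> int:
        return int(self.sizes.sum())


@dataclass
class HypothesisTrace:
    """Per-division log posteriors, optionally at every step.

    ``log_posterior_h0[d]`` is log P{H_0 | all data} for division d;
    ``matrix[j, d]`` (when recorded) is the same quantity after step j+1.
    """

    log_posterior_h0: np.ndarray
    matrix: np.ndarray | None = None

    @property
    def log_posterior_h(self) -> np.ndarray:
        return np.log1p(-np.exp(self.log_posterior_h0))


@dataclass
class ScanResult:
    """Outcome of one scan: traces, optimum partition and metadata.

    ``division_ranks[d]`` is the number of genes left of division d, so
    divisions are expressed in rank units regardless of binning.
    ``i_star`` is the rank boundary of the global score optimum,
    ``j_star`` the number of *genes* consumed when it was attained and
    ``side`` which half ("up" or "down") is enriched there.
    """

    final_trace: np.ndarray
    step_trace: np.ndarray
    division_path: np.ndarray
    division_ranks: np.ndarray
    genes_consumed: np.ndarray
    i_star: int
    j_star: int
    j_star_step: int
    max_score: float
    side: str
    trace: HypothesisTrace | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_divisions(self) -> int:
        return len(self.final_trace)

    def score_at(self, division: int, step: int) -> float:
        """Enrichment score for a division (0-based) after a step (1-based);
        requires the full trace matrix (small scans keep it by default)."""
        if self.trace is None or self.trace.matrix is None:
            raise ValueError("full trace matrix was not recorded for this scan")
        base = self.metadata.get("log_base", math.e)
        return float(-self.trace.matrix[step - 1, division] / math.log(base))


def enrichment_score(posterior_h: float, log_base: float = math.e) -> float:
    """Score a posterior: -log of the null posterior, floored at 1e-300.

    Strictly increasing in ``posterior_h``; equals -log(1 - prior) before
    any informative observation.
    """
    p0 = min(max(1.0 - posterior_h, P_FLOOR), 1.0)
    return -math.log(p0) / math.log(log_base)


def _scan_core(
    X: np.ndarray,
    Y: np.ndarray,
    order: np.ndarray,
    prior: float,
    log_base: float,
    keep_matrix: bool,
) -> tuple[np.ndarray, ...]:
    """Shared scan recursion, vectorized over motifs (rows of X/Y) and
    divisions.  Returns per-motif traces and optimum bookkeeping arrays.
    """
    n_mot, M = X.shape
    n_div = M - 1
    base = math.log(log_base)

    log_ph = np.full((n_mot, n_div), math.log(prior))
    log_ph0 = np.full((n_mot, n_div), math.log1p(-prior))
    ones_left = np.zeros((n_mot, n_div), dtype=np.int64)
    zeros_left = np.zeros((n_mot, n_div), dtype=np.int64)
    genes_left = np.zeros(n_div, dtype=np.int64)
    t_ones = np.zeros(n_mot, dtype=np.int64)
    t_zeros = np.zeros(n_mot, dtype=np.int64)
    t_genes = 0

    step_trace = np.empty((n_mot, M))
    division_path = np.empty((n_mot, M), dtype=np.int64)
    genes_consumed = np.empty(M, dtype=np.int64)
    g_max = np.full(n_mot, -np.inf)
    g_div = np.zeros(n_mot, dtype=np.int64)
    g_step = np.zeros(n_mot, dtype=np.int64)
    matrix = np.empty((M, n_div)) if keep_matrix and n_mot == 1 else None

    for step, b in enumerate(order):
        xb = X[:, b]
        yb = Y[:, b]
        t_ones += xb
        t_zeros += yb
        sizes_b = xb + yb  # x+y per bin is motif-independent
        t_genes += int(sizes_b[0])
        if b < n_div:
            ones_left[:, b:] += xb[:, None]
            zeros_left[:, b:] += yb[:, None]
            genes_left[b:] += int(sizes_b[0])
        # side containing bin b: left for divisions d >= b, else right
        left = np.arange(n_div) >= b
        ones_side = np.where(left, ones_left, t_ones[:, None] - ones_left)
        zeros_side = np.where(left, zeros_left, t_zeros[:, None] - zeros_left)
        genes_side = np.where(left, genes_left, t_genes - genes_left)

        with np.errstate(divide="ignore", invalid="ignore"):
            log_lh = np.where(
                xb[:, None] > 0,
                xb[:, None] * (np.log(ones_side) - np.log(t_ones)[:, None]),
                0.0,
            )
            log_lh += np.where(
                yb[:, None] > 0,
                yb[:, None] * (np.log(zeros_side) - np.log(t_zeros)[:, None]),
                0.0,
            )
        log_lh0 = sizes_b[:, None] * (np.log(genes_side) - math.log(t_genes))

        log_ph += log_lh
        log_ph0 += log_lh0
        log_z = np.logaddexp(log_ph, log_ph0)
        log_ph -= log_z
        log_ph0 -= log_z
        np.clip(log_ph0, LOG_P_FLOOR, 0.0, out=log_ph0)
        np.clip(log_ph, LOG_P_FLOOR, 0.0, out=log_ph)

        scores = -log_ph0 / base
        best_div = np.argmax(scores, axis=1)
        best = scores[np.arange(n_mot), best_div]
        step_trace[:, step] = best
        division_path[:, step] = best_div
        genes_consumed[step] = t_genes
        improved = best > g_max
        g_max[improved] = best[improved]
        g_div[improved] = best_div[improved]
        g_step[improved] = step
        if matrix is not None:
            matrix[step] = log_ph0[0]

    final_trace = -log_ph0 / base
    return (final_trace, step_trace, division_path, genes_consumed,
            g_max, g_div, g_step, matrix)


def _result_from_core(core, x_total, y_total, division_ranks, prior, log_base,
                      metadata):
    (final_trace, step_trace, division_path, genes_consumed,
     g_max, g_div, g_step, matrix) = core
    i_div = int(g_div[0])
    i_star = int(division_ranks[i_div])
    # enriched side at the optimum: where is match density higher?
    cum_x = np.cumsum(x_total)
    cum_n = np.cumsum(x_total + y_total)
    xl, nl = cum_x[i_div], cum_n[i_div]
    xr, nr = cum_x[-1] - xl, cum_n[-1] - nl
    frac_l = xl / nl if nl else 0.0
    frac_r = xr / nr if nr else 0.0
    side = "down" if frac_r >= frac_l else "up"
    trace = HypothesisTrace(
        log_posterior_h0=(-final_trace[0] * math.log(log_base)),
        matrix=matrix,
    )
    return ScanResult(
        final_trace=final_trace[0],
        step_trace=step_trace[0],
        division_path=division_path[0],
        division_ranks=np.asarray(division_ranks),
        genes_consumed=genes_consumed,
        i_star=i_star,
        j_star=int(genes_consumed[g_step[0]]),
        j_star_step=int(g_step[0]) + 1,
        max_score=float(g_max[0]),
        side=side,
        trace=trace,
        metadata=dict(metadata, prior=prior, log_base=log_base),
    )


def sbse_scan(
    D: MatchVector | np.ndarray,
    A: AbsoluteOrder | np.ndarray,
    prior: float = 0.5,
    log_base: float = math.e,
    keep_matrix: bool | None = None,
) -> ScanResult:
    """Unbinned scan: one observation per gene, N-1 division hypotheses.

    ``D`` is the ordered binary match vector, ``A`` the absolute
    processing order (ranks, most dysregulated first).  Requires N(N-1)
    likelihood evaluations; above a few thousand genes prefer
    :func:`sbse_scan_binned`.
    """
    bits = np.asarray(D.bits if isinstance(D, MatchVector) else D, dtype=np.int64)
    order_ranks = np.asarray(A.order if isinstance(A, AbsoluteOrder) else A,
                             dtype=np.int64)
    n = len(bits)
    if n < 2:
        raise ValueError("need at least two observations")
    if len(order_ranks) != n:
        raise ValueError("D and A have inconsistent lengths")
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior must lie strictly inside (0, 1), got {prior}")
    if n > UNBINNED_WARN_N:
        logger.warning(
            "unbinned scan over %d genes needs %d updates; consider binning", n,
            n * (n - 1),
        )
    if keep_matrix is None:
        keep_matrix = n <= 2000
    X = bits[None, :]
    Y = (1 - bits)[None, :]
    core = _scan_core(X, Y, order_ranks - 1, prior, log_base, keep_matrix)
    meta = {"M": n, "binned": False, "order": order_ranks}
    if isinstance(D, MatchVector):
        meta["excluded"] = D.excluded
    return _result_from_core(core, X[0], Y[0], np.arange(1, n), prior,
                             log_base, meta)


def _bin_edges(n: int, m: int) -> np.ndarray:
    """Start indices of M near-equal contiguous bins (larger bins first)."""
    sizes = np.full(m, n // m, dtype=np.int64)
    sizes[: n % m] += 1
    return np.concatenate([[0], np.cumsum(sizes)])


def _bin_order(spans: np.ndarray, profile: RankedProfile | None, m: int) -> np.ndarray:
    """Bin consumption order, the binned analogue of the absolute order:
    descending maximum |fold change| among bin members, ties toward the
    up-regulated side, then the smaller bin index.  Without fold changes,
    bins alternate from the two extremes inward, up-regulated end first.
    """
    if profile is not None:
        keys = []
        for b in range(m):
            lo, hi = spans[b]
            members = profile.fold_changes[lo - 1:hi]
            j = int(np.argmax(np.abs(members)))  # first = most up-regulated on ties
            keys.append((-abs(members[j]), 0 if members[j] > 0 else 1, b))
        return np.array([b for *_, b in sorted(keys)], dtype=np.int64)
    order = []
    lo, hi = 0, m - 1
    while lo <= hi:
        order.append(lo)
        if hi != lo:
            order.append(hi)
        lo += 1
        hi -= 1
    return np.array(order, dtype=np.int64)


def bin_matches(D: MatchVector | np.ndarray, M: int,
                profile: RankedProfile | None = None) -> BinnedProfile:
    """Group the ordered match vector into M contiguous, near-equal bins.

    Bin sizes differ by at most one, larger bins first.  The consumption
    order uses the profile's fold changes when available (see
    :func:`_bin_order`); a :class:`~sbse.seedcore.MatchVector` built from
    a profile carries it along automatically.
    """
    if profile is None and isinstance(D, MatchVector):
        profile = D.profile
    bits = np.asarray(D.bits if isinstance(D, MatchVector) else D, dtype=np.int64)
    n = len(bits)
    if not 2 <= M <= n:
        raise ValueError(f"M must be in 2..{n}, got {M}")
    edges = _bin_edges(n, M)
    x = np.add.reduceat(bits, edges[:-1])
    sizes = np.diff(edges)
    y = sizes - x
    spans = np.column_stack([edges[:-1] + 1, edges[1:]])
    order = _bin_order(spans, profile, M)
    return BinnedProfile(x=x, y=y, spans=spans, order=order)


def sbse_scan_binned(
    B: BinnedProfile,
    prior: float = 0.5,
    log_base: float = math.e,
    keep_matrix: bool | None = None,
) -> ScanResult:
    """Binned scan over the M-1 bin boundaries; M(M-1) updates.

    Each bin contributes its x matches and y non-matches in one block
    update (likelihood p^x q^y per side under H_i, p^(x+y) under H_0).
    With M = N this reproduces the unbinned scan exactly.
    """
    if B.M < 2:
        raise ValueError("need at least two bins")
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior must lie strictly inside (0, 1), got {prior}")
    if keep_matrix is None:
        keep_matrix = B.M <= 2000
    X = B.x[None, :]
    Y = B.y[None, :]
    core = _scan_core(X, Y, B.order, prior, log_base, keep_matrix)
    division_ranks = np.cumsum(B.sizes)[:-1]
    meta = {"M": B.M, "binned": True, "spans": B.spans, "order_bins": B.order}
    return _result_from_core(core, B.x, B.y, division_ranks, prior, log_base, meta)


@dataclass
class CompositeResult:
    """Per-motif scan summaries for an exhaustive k-mer library.

    ``table`` has one row per motif (motif, max_score, i_star, j_star,
    side, robust_z, prominent) in lexicographic motif order;
    ``step_traces[m, j]`` is motif m's best score over divisions at step
    j+1, the quantity drawn in composite plots.
    """

    table: pd.DataFrame
    step_traces: np.ndarray
    division_ranks: np.ndarray
    k: int
    M: int
    metadata: dict = field(default_factory=dict)

    def rank_of(self, motif: str) -> int:
        """1-based rank of a motif's max_score among all 4**k motifs
        (rank 1 = highest score; ties share the better rank)."""
        scores = self.table["max_score"].to_numpy()
        target = scores[motif_to_code(motif)]
        return int(1 + np.sum(scores > target))

    def robust_z_of(self, motif: str) -> float:
        return float(self.table["robust_z"].to_numpy()[motif_to_code(motif)])


def composite_scan(
    profile: RankedProfile,
    repo: UtrRepository,
    k: int = 6,
    M: int | None = None,
    prior: float = 0.5,
    log_base: float = math.e,
    prominence_z: float = DEFAULT_PROMINENCE_Z,
) -> CompositeResult:
    """Scan the profile with the complete 4**k motif library.

    Each motif's match vector is derived from one k-mer indexing pass over
    the repository, then all motifs are scanned simultaneously over the
    binned profile.  A motif is "prominent" when its robust z — max_score
    centred on the library median and scaled by 1.4826·MAD — exceeds
    ``prominence_z``; this operationalizes "distinctly larger than the
    majority" without assuming a null shape.
    """
    mat, sub, excluded = match_matrix(profile, repo, k)
    n = sub.N
    if M is None:
        M = min(n, DEFAULT_MAX_BINS)
    if not 2 <= M <= n:
        raise ValueError(f"M must be in 2..{n}, got {M}")
    edges = _bin_edges(n, M)
    X = np.add.reduceat(mat.astype(np.int64), edges[:-1], axis=0).T  # motifs × bins
    sizes = np.diff(edges)
    Y = sizes[None, :] - X
    spans = np.column_stack([edges[:-1] + 1, edges[1:]])
    order = _bin_order(spans, sub, M)

    core = _scan_core(X, Y, order, prior, log_base, keep_matrix=False)
    (final_trace, step_trace, division_path, genes_consumed,
     g_max, g_div, g_step, _) = core
    division_ranks = np.cumsum(sizes)[:-1]

    cum_x = np.cumsum(X, axis=1)
    cum_n = np.cumsum(sizes)
    xl = cum_x[np.arange(len(g_div)), g_div]
    nl = cum_n[g_div]
    frac_l = xl / nl
    frac_r = (cum_x[:, -1] - xl) / (cum_n[-1] - nl)
    side = np.where(frac_r >= frac_l, "down", "up")

    med = float(np.median(g_max))
    mad = float(np.median(np.abs(g_max - med)))
    denom = MAD_SCALE * mad
    if denom == 0.0:
        denom = float(np.std(g_max)) or 1.0
    robust_z = (g_max - med) / denom

    motifs = [q.motif for q in enumerate_kmers(k)]
    table = pd.DataFrame(
        {
            "motif": motifs,
            "max_score": g_max,
            "i_star": division_ranks[g_div],
            "j_star": genes_consumed[g_step],
            "side": side,
            "robust_z": robust_z,
            "prominent": robust_z > prominence_z,
        }
    )
    return CompositeResult(
        table=table,
        step_traces=step_trace,
        division_ranks=division_ranks,
        k=k,
        M=M,
        metadata={
            "prior": prior,
            "log_base": log_base,
            "excluded": excluded,
            "prominence_z": prominence_z,
            "N": n,
        },
    )
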