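"""Synthetic ranked profiles and UTR repositories with planted enrichment.

The generator emulates the statistical structure the scan assumes: an
RNAi agent shifts its direct targets toward the down-regulated tail of a
log2 fold-change profile, and those targets carry the seed-complement
motif in their 3'UTRs.  Everything else is noise — a standard-normal
baseline on the log2 scale, uniform-random UTR sequences, and a
background rate of spurious motif carriers.  Because random UTRs also
contain any hexamer by chance (about L/4096 per UTR), the emitted truth
records *realized* motif presence, recomputed from the final sequences,
rather than insertion intent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .profile import ExpressionRecord, RankedProfile, rank_by_fold_change, write_profile
from .seedcore import SeedQuery
from .seqio import UtrRecord, UtrRepository, write_fasta

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic planted-enrichment experiment.

    Defaults describe a mid-sized knockdown profile: 5000 genes, a tenth
    of them direct targets shifted two log2 units down, every target UTR
    carrying the planted motif and 5% of the rest carrying it spuriously.
    UTR lengths are geometric with mean 800 nt (floor 50 nt).
    """

    n_genes: int = 5000
    utr_length_mean: float = 800.0
    utr_length_min: int = 50
    background_rate: float = 0.05
    planted_motif: str = "GCCTTA"
    target_fraction: float = 0.1
    plant_prob: float = 1.0
    effect_shift: float = 2.0
    noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be at least 10")
        if not 0.0 <= self.target_fraction <= 0.5:
            raise ValueError("target_fraction must lie in [0, 0.5]")
        for name in ("background_rate", "plant_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.planted_motif) > self.utr_length_min:
            raise ValueError("planted motif longer than the minimum UTR length")
        if isinstance(self.planted_motif, SeedQuery):
            object.__setattr__(self, "planted_motif", self.planted_motif.motif)

    @property
    def n_targets(self) -> int:
        return int(round(self.target_fraction * self.n_genes))

    @property
    def boundary_rank(self) -> int:
        """True division: targets occupy ranks boundary+1..N when the
        effect shift dominates the noise."""
        return math.ceil((1.0 - self.target_fraction) * self.n_genes)


@dataclass
class FixtureTruth:
    """Ground truth of a generated fixture."""

    target_ids: list[str]
    boundary_rank: int
    presence: dict[str, bool]  # realized motif presence per identifier
    is_target: dict[str, bool] = field(default_factory=dict)


def _random_utrs(rng: np.random.Generator, spec: FixtureSpec) -> list[np.ndarray]:
    scale = spec.utr_length_mean - spec.utr_length_min + 1
    lengths = spec.utr_length_min - 1 + rng.geometric(1.0 / scale, spec.n_genes)
    total = int(lengths.sum())
    flat = _LETTERS[rng.integers(0, 4, total)]
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    return [flat[offsets[i]:offsets[i + 1]] for i in range(spec.n_genes)]


def _insert_motif(seq: np.ndarray, motif: bytes, rng: np.random.Generator) -> None:
    pos = int(rng.integers(0, len(seq) - len(motif) + 1))
    seq[pos:pos + len(motif)] = np.frombuffer(motif, dtype=np.uint8)


def _normal_two_sided_p(fc: np.ndarray, noise: float) -> np.ndarray:
    scale = noise * math.sqrt(2.0) if noise > 0 else 1.0
    return np.array([math.erfc(abs(v) / scale) for v in fc])


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[RankedProfile, UtrRepository, FixtureTruth]:
    """Generate a ranked profile, UTR repository and ground truth.

    Fully reproducible from ``spec.seed``: baseline log2 fold changes are
    drawn from N(0, noise²); the ``n_targets`` most negative genes are the
    direct targets and are shifted down by ``effect_shift``, so they form
    the bottom tail of the ranking with a known boundary; the planted
    motif is written at a uniform random position into target UTRs with
    probability ``plant_prob`` and into the rest with ``background_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    width = len(str(n))
    idents = [f"g{i + 1:0{width}d}" for i in range(n)]

    fc = rng.normal(0.0, spec.noise, n)
    # targets are the most down-regulated genes: the lowest-baseline q·n
    # genes get the additional knockdown shift, so they occupy exactly the
    # bottom tail and the true boundary is ceil((1-q)·n)
    target_idx = np.argsort(fc, kind="stable")[: spec.n_targets]
    fc[target_idx] -= spec.effect_shift
    is_target = np.zeros(n, dtype=bool)
    is_target[target_idx] = True

    seqs = _random_utrs(rng, spec)
    motif = spec.planted_motif.encode()
    plant_draw = rng.random(n)
    for i in range(n):
        p = spec.plant_prob if is_target[i] else spec.background_rate
        if plant_draw[i] < p:
            _insert_motif(seqs[i], motif, rng)

    pvals = _normal_two_sided_p(fc, spec.noise)
    records = [
        ExpressionRecord(idents[i], float(fc[i]), float(pvals[i])) for i in range(n)
    ]
    profile = rank_by_fold_change(records)

    entries = {
        idents[i]: UtrRecord(idents[i], seqs[i].tobytes().decode()) for i in range(n)
    }
    repo = UtrRepository(entries=entries, unmapped_count=0)

    presence = {
        ident: spec.planted_motif in rec.sequence for ident, rec in entries.items()
    }
    truth = FixtureTruth(
        target_ids=[idents[i] for i in sorted(target_idx)],
        boundary_rank=spec.boundary_rank,
        presence=presence,
        is_target={idents[i]: bool(is_target[i]) for i in range(n)},
    )
    return profile, repo, truth


def generate_at_rich_confounder(
    spec: FixtureSpec,
    tail: str = "up",
    rate: float = 0.3,
    block_length: int = 24,
) -> tuple[RankedProfile, UtrRepository, FixtureTruth]:
    """Fixture variant with AT-rich sequence enriched in one tail.

    Emulates the transfection-response artifact in which many AT-rich
    motifs surge among up-regulated transcripts: with probability ``rate``
    each UTR in the chosen tail (the ``target_fraction`` most extreme
    ranks on that side) has a random A/T block of ``block_length`` written
    into it.  With ``rate`` = 0 the output is identical to
    :func:`generate_fixture`.  Confounder randomness comes from a separate
    stream, so the base fixture is unchanged for any rate.
    """
    if tail not in ("up", "down"):
        raise ValueError(f"tail must be 'up' or 'down', got {tail!r}")
    profile, repo, truth = generate_fixture(spec)
    if rate <= 0.0:
        return profile, repo, truth
    rng = np.random.default_rng([spec.seed, 7919])
    n = profile.N
    n_tail = int(round(spec.target_fraction * n))
    ranks = range(n_tail) if tail == "up" else range(n - n_tail, n)
    at_letters = np.frombuffer(b"AT", dtype=np.uint8)
    new_entries = dict(repo.entries)
    for r in ranks:
        if rng.random() >= rate:
            continue
        ident = profile.identifiers[r]
        seq = np.frombuffer(new_entries[ident].sequence.encode(), np.uint8).copy()
        block = at_letters[rng.integers(0, 2, min(block_length, len(seq)))]
        pos = int(rng.integers(0, len(seq) - len(block) + 1))
        seq[pos:pos + len(block)] = block
        new_entries[ident] = UtrRecord(ident, seq.tobytes().decode())
    repo = UtrRepository(entries=new_entries, unmapped_count=0)
    presence = {
        ident: spec.planted_motif in rec.sequence
        for ident, rec in new_entries.items()
    }
    truth = FixtureTruth(
        target_ids=truth.target_ids,
        boundary_rank=truth.boundary_rank,
        presence=presence,
        is_target=truth.is_target,
    )
    return profile, repo, truth


def write_fixture(profile: RankedProfile, repo: UtrRepository, truth: FixtureTruth,
                  outdir: str | Path, prefix: str = "fixture") -> dict[str, Path]:
    """Emit a fixture as FASTA + tab-delimited profile + truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "profile": outdir / f"{prefix}_profile.tsv",
        "utrs": outdir / f"{prefix}_utrs.fa",
        "truth": outdir / f"{prefix}_truth.tsv",
    }
    write_profile(profile, paths["profile"],
                  provenance=[f"synthetic fixture, boundary={truth.boundary_rank}"])
    write_fasta(repo, paths["utrs"])
    with open(paths["truth"], "w") as fh:
        fh.write(f"# boundary_rank\t{truth.boundary_rank}\n")
        fh.write("identifier\tis_target\thas_motif\n")
        for ident in profile.identifiers:
            fh.write(
                f"{ident}\t{int(truth.is_target.get(ident, False))}"
                f"\t{int(truth.presence.get(ident, False))}\n"
            )
    return paths
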