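import math

import numpy as np
import pytest

from sbse import (
    ExpressionRecord,
    FixtureSpec,
    RankedProfile,
    absolute_order,
    rank_by_fold_change,
)

TOY_FC = [4.0, 2.0, 0.5, -0.2, -1.5, -3.0]
TOY_D = np.array([0, 0, 1, 1, 0, 1])
TOY_A = np.array([1, 6, 2, 5, 3, 4])


@pytest.fixture
def toy_profile() -> RankedProfile:
    records = [ExpressionRecord(f"g{i}", fc) for i, fc in enumerate(TOY_FC, 1)]
    return rank_by_fold_change(records)


@pytest.fixture
def toy_absolute(toy_profile):
    return absolute_order(toy_profile)


def random_profile(rng: np.random.Generator, n: int) -> RankedProfile:
    fc = rng.normal(0, 1, n)
    recs = [ExpressionRecord(f"r{i}", float(v)) for i, v in enumerate(fc)]
    return rank_by_fold_change(recs)


def direct_scan(D, A, prior=0.5):
    """Independent oracle: the same sequential Bayesian update computed in
    direct probability space with literal products of the running-count
    ratios (no logarithms, no vectorization).

    Returns (posteriors, scores): lists over steps of per-division
    posterior P{H_i | D_1..j} and score -ln P{H_0 | D_1..j}.
    """
    D = list(D)
    A = list(A)
    n = len(D)
    n_div = n - 1
    ph = [prior] * n_div
    ones_left = [0] * n_div
    zeros_left = [0] * n_div
    genes_left = [0] * n_div
    t1 = t0 = t = 0
    post_steps, score_steps = [], []
    for r in A:
        d = D[r - 1]
        t1 += d
        t0 += 1 - d
        t += 1
        for i in range(1, n):  # division i separates ranks 1..i | i+1..n
            if r <= i:
                ones_left[i - 1] += d
                zeros_left[i - 1] += 1 - d
                genes_left[i - 1] += 1
        new_ph = []
        for i in range(1, n):
            left = r <= i
            if d:
                side = ones_left[i - 1] if left else t1 - ones_left[i - 1]
                lh = side / t1 if t1 else 1.0
            else:
                side = zeros_left[i - 1] if left else t0 - zeros_left[i - 1]
                lh = side / t0 if t0 else 1.0
            gside = genes_left[i - 1] if left else t - genes_left[i - 1]
            lh0 = gside / t
            num = ph[i - 1] * lh
            num0 = (1 - ph[i - 1]) * lh0
            new_ph.append(num / (num + num0))
        ph = new_ph
        post_steps.append(list(ph))
        score_steps.append([-math.log(max(1 - p, 1e-300)) for p in ph])
    return post_steps, score_steps
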