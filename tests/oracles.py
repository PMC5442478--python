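"""Independent brute-force oracles used to validate the pipeline.

These deliberately re-derive results by the most literal route available —
per-base exhaustive evaluation, term-by-term series summation — and share
no code path with the implementations they check.
"""

import math

import numpy as np


def exhaustive_greedy_calls(
    pos: np.ndarray,
    cnt: np.ndarray,
    length: int,
    sigma: float = 20.0,
    exclusion: int = 147,
    min_count: int = 6,
    support_halfwidth: int = 73,
):
    """Exhaustive per-base greedy nucleosome caller.

    Evaluates the Gaussian-smoothed dyad density at every base of the
    chromosome (summing dyad contributions in ascending dyad order),
    repeatedly picks the highest remaining base (leftmost on ties) and
    suppresses everything within < exclusion bp, then filters on
    supporting-read count.  Returns sorted midpoints and read counts.
    """
    pos = np.asarray(pos, dtype=np.int64)
    cnt = np.asarray(cnt, dtype=np.int64)
    x = np.arange(length, dtype=np.int64)
    diff = x[:, None].astype(float) - pos[None, :].astype(float)
    terms = cnt.astype(float) * np.exp(-(diff * diff) / (2.0 * sigma * sigma))
    # sequential left-to-right accumulation over dyads, matching a literal
    # "sum over dyads in ascending order" reading of the definition
    s = np.add.accumulate(terms, axis=1)[:, -1] if pos.size else np.zeros(length)

    alive = s > 0
    picks = []
    while True:
        masked = np.where(alive, s, -1.0)
        i = int(np.argmax(masked))  # argmax takes the first (leftmost) max
        if masked[i] <= 0:
            break
        picks.append(i)
        alive[max(0, i - exclusion + 1) : i + exclusion] = False

    midpoints, counts = [], []
    for m in sorted(picks):
        support = np.abs(pos - m) <= support_halfwidth
        n = int(cnt[support].sum())
        if n >= min_count:
            midpoints.append(m)
            counts.append(n)
    return np.asarray(midpoints, dtype=np.int64), np.asarray(counts, dtype=np.int64)


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam) by direct term-by-term summation."""
    if k <= 0:
        return 1.0
    if lam <= 0:
        return 0.0
    log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
    term = math.exp(log_term)
    total = 0.0
    i = k
    while term > 0 and (total == 0 or term > total * 1e-20):
        total += term
        i += 1
        term *= lam / i
    return total


def population_sd(coords) -> float:
    """Direct population standard deviation (independent of the package)."""
    coords = list(coords)
    mean = sum(coords) / len(coords)
    return math.sqrt(sum((c - mean) ** 2 for c in coords) / len(coords))
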