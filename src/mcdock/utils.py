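"""Small statistical helpers shared across modules."""

from __future__ import annotations

import numpy as np

from .errors import InputError


def weighted_mean(values, weights):
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return float(np.sum(weights * values) / np.sum(weights))


def weighted_var(values, weights):
    """Weighted population variance about the weighted mean."""
    m = weighted_mean(values, weights)
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return float(np.sum(weights * (values - m) ** 2) / np.sum(weights))


def blocked_standard_error(values, weights=None, n_blocks=20):
    """Standard error of a (weighted) mean from sequentially blocked data.

    Markov-chain samples are autocorrelated, so the naive i.i.d. standard
    error underestimates the true uncertainty.  Splitting the sequence into
    ``n_blocks`` contiguous blocks and taking the spread of the block means
    gives a robust estimate as long as the blocks are longer than the
    correlation time.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise InputError("cannot estimate a standard error from no samples")
    if weights is None:
        weights = np.full(n, 1.0 / n)
    weights = np.asarray(weights, dtype=float)
    n_blocks = int(min(n_blocks, n))
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        w = weights[lo:hi]
        if w.sum() <= 0:
            continue
        means.append(np.sum(w * values[lo:hi]) / w.sum())
    means = np.asarray(means)
    if means.size < 2:
        return float("inf")
    return float(np.std(means, ddof=1) / np.sqrt(means.size))


def count_round_trips(x, low, high):
    """Number of completed low→high→low round trips of a 1D time series.

    A round trip is counted each time the series, having visited the
    region below ``low``, crosses above ``high`` and returns below
    ``low`` again (hysteresis avoids counting boundary chatter).
    """
    x = np.asarray(x, dtype=float)
    if high <= low:
        raise InputError("round-trip thresholds must satisfy low < high")
    state = 0  # 0: unseen, 1: at/below low, 2: has reached high after low
    trips = 0
    for v in x:
        if state == 0:
            if v <= low:
                state = 1
        elif state == 1:
            if v >= high:
                state = 2
        else:
            if v <= low:
                trips += 1
                state = 1
    return trips
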