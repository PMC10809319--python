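"""Canonical reweighting of multicanonical ensembles.

A multicanonical run samples ρ_mc(x) ∝ exp(−[E + b(E)]/kB·T_ref).  The
canonical ensemble at temperature T is recovered by weighting each snapshot
with the ratio of the target Boltzmann density to the sampled density:

    w_i ∝ exp(−E_i/(kB·T) + [E_i + b(E_i)]/(kB·T_ref))

computed in log space and normalised with log-sum-exp, so arbitrarily
large energy spans cannot underflow.  This is the standard single-ensemble
multicanonical reweighting identity; no multi-ensemble (WHAM/MBAR)
machinery is involved because there is only one generalized ensemble.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import KB
from .engine import BiasFunction, energies_array
from .errors import DegenerateEnsembleError, InputError

logger = logging.getLogger(__name__)


@dataclass
class WeightedEnsemble:
    """Snapshots with normalized canonical weights at temperature ``T``."""

    snapshots: list
    weights: np.ndarray
    T: float
    source_bias: BiasFunction | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.snapshots) != self.weights.size:
            raise InputError("one weight per snapshot required")
        if np.any(self.weights < 0):
            raise InputError("weights must be non-negative")
        if self.weights.size and abs(self.weights.sum() - 1.0) > 1e-12:
            raise InputError("weights must be normalized to 1 (within 1e-12)")

    def __len__(self):
        return len(self.snapshots)

    def coords(self) -> np.ndarray:
        return np.stack([s.coords for s in self.snapshots])

    def energies(self) -> np.ndarray:
        return energies_array(self.snapshots)

    def subensemble(self, indices) -> "WeightedEnsemble":
        """Members ``indices`` with weights renormalized within the subset."""
        indices = np.asarray(indices, dtype=int)
        w = self.weights[indices]
        tot = w.sum()
        if tot <= 0:
            raise InputError("subensemble has zero total weight")
        w = w / tot
        w = w / w.sum()  # exact renormalization
        return WeightedEnsemble(
            [self.snapshots[i] for i in indices], w, self.T, self.source_bias
        )

    @classmethod
    def uniform(cls, snapshots, T: float = 300.0) -> "WeightedEnsemble":
        n = len(snapshots)
        if n == 0:
            raise InputError("cannot build an ensemble from no snapshots")
        return cls(snapshots, np.full(n, 1.0 / n), T)


def log_canonical_weights(energies, bias: BiasFunction, T: float) -> np.ndarray:
    """Unnormalized log-weights for reweighting to temperature ``T``."""
    energies = np.asarray(energies, dtype=float)
    b = bias(energies)
    return -energies / (KB * T) + (energies + b) / (KB * bias.T_ref)


def canonical_weights(ensemble, bias: BiasFunction, T: float) -> WeightedEnsemble:
    """Reweight a multicanonical ensemble to the canonical ensemble at ``T``.

    Warns when the Kish effective sample size drops below 1% of the
    ensemble size (reweighting far outside the flattened range); raises
    :class:`DegenerateEnsembleError` when the weights are unusable.
    """
    if T <= 0:
        raise InputError("temperature must be positive")
    if len(ensemble) == 0:
        raise InputError("cannot reweight an empty ensemble")
    energies = energies_array(ensemble)
    logw = log_canonical_weights(energies, bias, T)
    norm = logsumexp(logw)
    if not np.isfinite(norm):
        ess = 0.0
        raise DegenerateEnsembleError(
            f"all reweighting weights underflowed (effective sample size {ess})",
            effective_sample_size=ess,
        )
    w = np.exp(logw - norm)
    w = w / w.sum()
    ess = effective_sample_size(w)
    if ess < 0.01 * w.size:
        warnings.warn(
            f"reweighting to T={T} K is degenerate: effective sample size "
            f"{ess:.1f} of {w.size}",
            RuntimeWarning,
            stacklevel=2,
        )
    return WeightedEnsemble(list(ensemble), w, T, source_bias=bias)


def effective_sample_size(weights) -> float:
    """Kish effective sample size 1/Σw² of normalized weights."""
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        raise InputError("effective sample size of an empty weight vector")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise InputError("weights must be normalized")
    return float(1.0 / np.sum(weights**2))


def energy_distribution(
    ensemble, bias: BiasFunction, T_list, n_bins: int = 60, e_range=None
) -> dict:
    """Weighted energy histograms at each T, plus the raw multicanonical one.

    Returns ``{"edges": bin edges, "multicanonical": h, T: h, ...}`` where
    every histogram is normalized to sum to 1.
    """
    if len(ensemble) == 0:
        raise InputError("cannot histogram an empty ensemble")
    energies = energies_array(ensemble)
    if e_range is None:
        e_range = (float(energies.min()), float(energies.max()))
    edges = np.linspace(e_range[0], e_range[1], n_bins + 1)
    out = {"edges": edges}
    h, _ = np.histogram(energies, bins=edges)
    tot = h.sum()
    out["multicanonical"] = h / tot if tot else h.astype(float)
    for T in T_list:
        we = canonical_weights(ensemble, bias, T)
        hw, _ = np.histogram(energies, bins=edges, weights=we.weights)
        s = hw.sum()
        out[T] = hw / s if s else hw
    return out


def flatness_ratio(
    ensemble,
    bias: BiasFunction,
    T_low: float | None = None,
    T_high: float | None = None,
    n_bins: int = 25,
):
    """Min/max occupied-bin ratio of the multicanonical energy histogram
    over the canonical-mean-energy range [⟨E⟩_{T_low}, ⟨E⟩_{T_high}].

    The range endpoints are themselves obtained by reweighting the supplied
    ensemble, so the diagnostic is self-contained.
    """
    T_low = bias.T_low if T_low is None else T_low
    T_high = bias.T_high if T_high is None else T_high
    energies = energies_array(ensemble)
    e_lo = float(np.sum(canonical_weights(ensemble, bias, T_low).weights * energies))
    e_hi = float(np.sum(canonical_weights(ensemble, bias, T_high).weights * energies))
    if e_hi <= e_lo:
        raise InputError("degenerate flatness range (⟨E⟩ not increasing in T)")
    h, _ = np.histogram(energies, bins=np.linspace(e_lo, e_hi, n_bins + 1))
    occ = h[h > 0]
    if occ.size == 0:
        return 0.0
    if occ.size < h.size:
        return 0.0  # unvisited bins inside the target range: not flat
    return float(occ.min() / occ.max())
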