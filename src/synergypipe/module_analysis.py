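"""Similarity, matching and waveform summaries of motor-module sets.

Similarity between weighting vectors or activation signals is the
normalized scalar product (cosine), which compares shape rather than
amplitude and lies in [0, 1] for nonnegative vectors; 0.8 is the
conventional threshold for calling two modules "similar". Because the
factorization returns modules in arbitrary correspondence across
datasets, sets are matched by maximum-similarity optimal assignment
before any pairwise comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .nmf_core import ModuleSet

#: Conventional similarity threshold above which two modules are "similar".
SIMILARITY_THRESHOLD = 0.8


@dataclass
class ModuleMatch:
    """Bijection between the modules of two sets, with per-pair similarities.

    ``pairing[i] = j`` matches module i of set A with module j of set B.
    """

    pairing: np.ndarray
    weighting_similarity: np.ndarray
    activation_similarity: np.ndarray

    def __post_init__(self) -> None:
        if sorted(self.pairing) != list(range(len(self.pairing))):
            raise ValueError("pairing must be a permutation")

    @property
    def all_similar(self) -> bool:
        return bool(np.all(self.weighting_similarity >= SIMILARITY_THRESHOLD))


@dataclass
class ActivationSummary:
    """Across-cycle average activation waveform of one module."""

    mean_curve: np.ndarray  # (samples_per_cycle,)
    peak_value: float
    peak_time_pct: float  # % of gait cycle in [0, 100)


def similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Normalized scalar product (u.v)/(|u||v|)."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("similarity undefined for zero-norm vectors")
    return float(u @ v / (nu * nv))


def _pairwise_similarity(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cosine similarity between the columns of a and the columns of b."""
    an = a / (np.linalg.norm(a, axis=0, keepdims=True) + 1e-300)
    bn = b / (np.linalg.norm(b, axis=0, keepdims=True) + 1e-300)
    return an.T @ bn


def match_modules(set_a: ModuleSet, set_b: ModuleSet) -> ModuleMatch:
    """Optimal module correspondence by weighting similarity.

    The Hungarian algorithm maximizes total weighting similarity over all
    bijections (weightings define correspondence since they carry the
    shared structure across conditions); activation similarity is then
    reported for the resulting pairs.
    """
    if set_a.k != set_b.k:
        raise ValueError("module sets must have equal k")
    sim_w = _pairwise_similarity(set_a.weightings, set_b.weightings)
    rows, cols = linear_sum_assignment(-sim_w)
    pairing = cols[np.argsort(rows)]
    sim_p = _pairwise_similarity(set_a.activations.T, set_b.activations.T)
    return ModuleMatch(
        pairing=pairing,
        weighting_similarity=sim_w[np.arange(set_a.k), pairing],
        activation_similarity=sim_p[np.arange(set_a.k), pairing],
    )


def mean_activation(
    activations: np.ndarray, n_cycles: int, samples_per_cycle: int = 200
) -> list[ActivationSummary]:
    """Average each module's concatenated activation across cycles.

    The peak and its instant (as % of the gait cycle) are read from the
    across-cycle mean curve; ties take the first index.
    """
    p = np.asarray(activations, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    if p.shape[1] != n_cycles * samples_per_cycle:
        raise ValueError("activation length must equal n_cycles * samples_per_cycle")
    out = []
    for row in p:
        mean = row.reshape(n_cycles, samples_per_cycle).mean(axis=0)
        idx = int(np.argmax(mean))
        out.append(
            ActivationSummary(
                mean_curve=mean,
                peak_value=float(mean[idx]),
                peak_time_pct=100.0 * idx / samples_per_cycle,
            )
        )
    return out


def curve_subtraction(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """Sample-wise absolute difference of two mean activation curves."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must have the same length")
    return np.abs(a - b)


def inter_subject_similarity(
    sets: list[ModuleSet], on: str = "weightings"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All pairwise module similarities across subjects within a condition.

    Sets must already be matched to a common module ordering. For each
    module position, every subject pair contributes one similarity;
    returns (mean, sample SD, raw pairwise values of shape
    (n_pairs, k)).
    """
    if len(sets) < 2:
        raise ValueError("need at least two module sets")
    k = sets[0].k
    if any(s.k != k for s in sets):
        raise ValueError("all sets must share k")
    vals = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if on == "weightings":
                a, b = sets[i].weightings, sets[j].weightings
            elif on == "activations":
                a, b = sets[i].activations.T, sets[j].activations.T
            else:
                raise ValueError("on must be 'weightings' or 'activations'")
            vals.append(
                [similarity(a[:, m], b[:, m]) for m in range(k)]
            )
    arr = np.asarray(vals)
    return arr.mean(axis=0), arr.std(axis=0, ddof=1), arr
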