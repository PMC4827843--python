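"""Non-negative matrix factorization of concatenated EMG envelopes.

The motor-module model approximates the muscles x time envelope matrix X
as X ~= S @ P, where S (muscles x k) holds nonnegative muscle weightings
and P (k x time) the nonnegative activation signals. Factorization uses
Euclidean-cost Lee-Seung multiplicative updates with seeded random
restarts; reconstruction quality is the variance accounted for,
VAF = 1 - SSE/SST with uncentered (pooled) total sum of squares.
Dimensionality is the smallest k that clears a VAF floor and after which
the curve's slope flattens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


@dataclass
class ModuleSet:
    """One factorization: weightings S, activation signals P, and its VAF.

    Columns of S are max-normalized to 1 (scale moved into P) and modules
    are ordered by ascending activation peak time so module labels are
    stable across runs and conditions.
    """

    weightings: np.ndarray  # (n_muscles, k)
    activations: np.ndarray  # (k, T)
    vaf: float
    k: int
    restarts_used: int = 1
    seed: int | None = None
    channel_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.weightings.shape[1] != self.k or self.activations.shape[0] != self.k:
            raise ValueError("factor shapes inconsistent with k")
        if np.any(self.weightings < 0) or np.any(self.activations < 0):
            raise ValueError("factors must be nonnegative")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError("vaf must lie in [0, 1]")

    @property
    def reconstruction(self) -> np.ndarray:
        return self.weightings @ self.activations


@dataclass
class VafCurve:
    """VAF of the best restart for k = 1..k_max."""

    vaf_by_k: np.ndarray  # index 0 -> k=1

    @property
    def k_max(self) -> int:
        return len(self.vaf_by_k)

    def __getitem__(self, k: int) -> float:
        return float(self.vaf_by_k[k - 1])


def vaf(x: np.ndarray, xr: np.ndarray) -> float:
    """Variance accounted for: 1 - SSE/SST with uncentered SST.

    SST pools the squared data over the whole matrix (sum of X**2), so a
    zero reconstruction scores exactly 0.
    """
    x = np.asarray(x, dtype=float)
    xr = np.asarray(xr, dtype=float)
    if x.shape != xr.shape:
        raise ValueError("X and Xr must have the same shape")
    sst = float((x**2).sum())
    if sst == 0.0:
        raise ValueError("X is identically zero; VAF undefined")
    sse = float(((x - xr) ** 2).sum())
    return 1.0 - sse / sst


def _multiplicative_updates(
    x: np.ndarray,
    w: np.ndarray,
    h: np.ndarray,
    max_iter: int,
    tol: float,
    update_w: bool = True,
    update_h: bool = True,
    check_every: int = 10,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Lee-Seung Euclidean updates; either factor may be held fixed.

    Convergence is declared when the relative VAF change between checks
    falls below ``tol``. A small epsilon in the denominators protects
    zero rows/columns.
    """
    last = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        if update_h:
            h *= (w.T @ x) / (w.T @ w @ h + _EPS)
        if update_w:
            w *= (x @ h.T) / (w @ (h @ h.T) + _EPS)
        if it % check_every == 0 or it == max_iter:
            current = vaf(x, w @ h)
            if abs(current - last) < tol * max(abs(last), _EPS):
                break
            last = current
    return w, h, it


def _normalize_and_order(
    w: np.ndarray, h: np.ndarray, samples_per_cycle: int | None
) -> tuple[np.ndarray, np.ndarray]:
    """Fix scale (max-1 weighting columns) and order modules by peak time."""
    scale = w.max(axis=0)
    scale[scale == 0] = 1.0
    w = w / scale
    h = h * scale[:, None]
    t = h.shape[1]
    if samples_per_cycle and t % samples_per_cycle == 0 and t > samples_per_cycle:
        per_cycle = h.reshape(h.shape[0], -1, samples_per_cycle).mean(axis=1)
        peak_times = per_cycle.argmax(axis=1)
    else:
        peak_times = h.argmax(axis=1)
    order = np.argsort(peak_times, kind="stable")
    return w[:, order], h[order]


def nmf(
    x: np.ndarray,
    k: int,
    restarts: int = 25,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int | None = None,
    samples_per_cycle: int | None = 200,
    channel_labels: tuple[str, ...] | None = None,
) -> ModuleSet:
    """Best-of-restarts multiplicative-update NMF.

    Each restart draws uniform-random nonnegative initial factors from a
    seeded stream; the solution with the highest VAF wins. Results are
    bit-reproducible for a given (x, k, restarts, seed).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("X must be nonnegative")
    n_m, t = x.shape
    if not 1 <= k <= min(n_m, t):
        raise ValueError(f"k must lie in [1, {min(n_m, t)}]")
    ss = np.random.SeedSequence(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    scale = np.sqrt(x.mean() / max(k, 1)) if x.mean() > 0 else 1.0
    for child in ss.spawn(restarts):
        rng = np.random.default_rng(child)
        w0 = scale * rng.random((n_m, k)) + _EPS
        h0 = scale * rng.random((k, t)) + _EPS
        w, h, _ = _multiplicative_updates(x, w0, h0, max_iter, tol)
        v = vaf(x, w @ h)
        if best is None or v > best[0]:
            best = (v, w, h)
    assert best is not None
    v, w, h = best
    w, h = _normalize_and_order(w, h, samples_per_cycle)
    return ModuleSet(
        weightings=w,
        activations=np.clip(h, 0.0, None),
        vaf=float(np.clip(v, 0.0, 1.0)),
        k=k,
        restarts_used=restarts,
        seed=seed,
        channel_labels=channel_labels,
    )


def vaf_curve(
    x: np.ndarray,
    k_max: int,
    restarts: int = 25,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int | None = None,
) -> VafCurve:
    """Best-restart VAF for each k from 1 to k_max."""
    x = np.asarray(x, dtype=float)
    if k_max > x.shape[0]:
        raise ValueError("k_max cannot exceed the number of muscles")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(k_max)]
    vals = [
        nmf(x, k, restarts=restarts, max_iter=max_iter, tol=tol, seed=seeds[k - 1]).vaf
        for k in range(1, k_max + 1)
    ]
    return VafCurve(np.asarray(vals))


def select_dimensionality(
    curve: VafCurve, vaf_min: float = 0.90, gain_eps: float = 0.03
) -> tuple[int, bool]:
    """Smallest k clearing the VAF floor after which the curve flattens.

    Returns (k, criterion_met). k must satisfy vaf(k) >= vaf_min and
    either be k_max or gain less than ``gain_eps`` VAF by adding one more
    module. If no k qualifies, k_max is returned with criterion_met False.
    """
    v = curve.vaf_by_k
    for k in range(1, curve.k_max + 1):
        if v[k - 1] >= vaf_min and (k == curve.k_max or v[k] - v[k - 1] < gain_eps):
            return k, True
    return curve.k_max, False
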