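"""Cross-condition fixed-factor reconstruction (REC_W, REC_A, REC_WA).

To test whether two locomotion conditions share modular structure, a
condition's EMG matrix is reconstructed while holding one (or both)
factors fixed to values taken from the other condition:

- REC_W  fixes the muscle weightings S from the other condition and
  re-estimates the activation signals P on the target data;
- REC_A  fixes the activation signals P from the other condition and
  re-estimates S;
- REC_WA fixes both, with no updates at all.

If the conditions share weightings but differ in cycle-to-cycle timing,
REC_W remains close to the regular (fully free) factorization while
REC_A and REC_WA degrade — the signature of shared spatial structure
with condition-specific temporal detail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nmf_core import ModuleSet, _multiplicative_updates, vaf, _EPS
from .module_analysis import match_modules


@dataclass
class MixedRecResult:
    """Outcome of one (possibly fixed-factor) reconstruction."""

    mode: str  # regular | REC_W | REC_A | REC_WA
    vaf: float
    fixed_source: str | None
    free_source: str | None
    iterations_used: int
    vaf_clipped: bool = False  # True if raw VAF was negative (pathological fit)


def _check_nonneg(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"{name} must be nonnegative")
    return x


def reconstruct_fixed_weightings(
    x_target: np.ndarray,
    s_other: np.ndarray,
    p_init: np.ndarray | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int | None = None,
    fixed_source: str = "other",
    free_source: str = "target",
) -> MixedRecResult:
    """REC_W: hold the weightings fixed, re-estimate activations.

    The free activation matrix is warm-started from ``p_init`` (typically
    the target condition's own activations, matched to the fixed
    weightings' module order) or random nonnegative values if omitted.
    """
    x = _check_nonneg(x_target, "X_target")
    s = _check_nonneg(s_other, "S_other")
    if s.shape[0] != x.shape[0]:
        raise ValueError("S_other rows must match the muscle count of X_target")
    k = s.shape[1]
    if p_init is None:
        rng = np.random.default_rng(seed)
        scale = np.sqrt(x.mean() / max(k, 1)) if x.mean() > 0 else 1.0
        p = scale * rng.random((k, x.shape[1])) + _EPS
    else:
        p = _check_nonneg(p_init, "p_init").copy()
        if p.shape != (k, x.shape[1]):
            raise ValueError("p_init shape must be (k, T)")
        p = np.maximum(p, _EPS)
    _, p, iters = _multiplicative_updates(
        x, s.copy(), p, max_iter, tol, update_w=False, update_h=True
    )
    v = vaf(x, s @ p)
    return MixedRecResult(
        mode="REC_W",
        vaf=float(np.clip(v, 0.0, 1.0)),
        fixed_source=fixed_source,
        free_source=free_source,
        iterations_used=iters,
        vaf_clipped=v < 0,
    )


def reconstruct_fixed_activations(
    x_target: np.ndarray,
    p_other: np.ndarray,
    s_init: np.ndarray | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int | None = None,
    fixed_source: str = "other",
    free_source: str = "target",
) -> MixedRecResult:
    """REC_A: hold the activation signals fixed, re-estimate weightings."""
    x = _check_nonneg(x_target, "X_target")
    p = _check_nonneg(p_other, "P_other")
    if p.shape[1] != x.shape[1]:
        raise ValueError("P_other columns must match the time length of X_target")
    if not np.any(p > 0):
        raise ValueError("P_other is identically zero; reconstruction degenerate")
    k = p.shape[0]
    if s_init is None:
        rng = np.random.default_rng(seed)
        scale = np.sqrt(x.mean() / max(k, 1)) if x.mean() > 0 else 1.0
        s = scale * rng.random((x.shape[0], k)) + _EPS
    else:
        s = _check_nonneg(s_init, "s_init").copy()
        if s.shape != (x.shape[0], k):
            raise ValueError("s_init shape must be (n_muscles, k)")
        s = np.maximum(s, _EPS)
    s, _, iters = _multiplicative_updates(
        x, s, p.copy(), max_iter, tol, update_w=True, update_h=False
    )
    v = vaf(x, s @ p)
    return MixedRecResult(
        mode="REC_A",
        vaf=float(np.clip(v, 0.0, 1.0)),
        fixed_source=fixed_source,
        free_source=free_source,
        iterations_used=iters,
        vaf_clipped=v < 0,
    )


def reconstruct_fixed_both(
    x_target: np.ndarray,
    s_other: np.ndarray,
    p_other: np.ndarray,
    fixed_source: str = "other",
) -> MixedRecResult:
    """REC_WA: both factors fixed, VAF of S_other @ P_other against the target.

    No updates and no rescaling are applied; a negative raw VAF (the fixed
    product explains less than the zero matrix) is clipped to 0 and
    flagged.
    """
    x = _check_nonneg(x_target, "X_target")
    s = _check_nonneg(s_other, "S_other")
    p = _check_nonneg(p_other, "P_other")
    if s.shape[0] != x.shape[0] or p.shape[1] != x.shape[1] or s.shape[1] != p.shape[0]:
        raise ValueError("shape mismatch between X_target, S_other and P_other")
    v = vaf(x, s @ p)
    return MixedRecResult(
        mode="REC_WA",
        vaf=float(np.clip(v, 0.0, 1.0)),
        fixed_source=fixed_source,
        free_source=None,
        iterations_used=0,
        vaf_clipped=v < 0,
    )


def mode_comparison(
    x_a: np.ndarray,
    x_b: np.ndarray,
    set_a: ModuleSet,
    set_b: ModuleSet,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int | None = None,
) -> dict[str, dict[str, float]]:
    """All four reconstruction VAFs in both directions.

    For each direction (reconstructing A from B's factors and vice
    versa) the table holds the regular VAF plus REC_W, REC_A and REC_WA.
    Module correspondence between the two sets is established by optimal
    weighting-similarity assignment before any factor is fixed, so fixed
    and warm-start factors refer to the same modules. Free factors are
    warm-started from the target's own factorization.
    """
    if set_a.k != set_b.k:
        raise ValueError("module sets must share k")
    match = match_modules(set_a, set_b)
    # Reorder B's modules to A's ordering so columns correspond.
    s_b = set_b.weightings[:, match.pairing]
    p_b = set_b.activations[match.pairing]
    s_a, p_a = set_a.weightings, set_a.activations

    out: dict[str, dict[str, float]] = {}
    for direction, (x_t, s_own, p_own, s_oth, p_oth) in {
        "A_from_B": (x_a, s_a, p_a, s_b, p_b),
        "B_from_A": (x_b, s_b, p_b, s_a, p_a),
    }.items():
        rec_w = reconstruct_fixed_weightings(
            x_t, s_oth, p_init=p_own, max_iter=max_iter, tol=tol, seed=seed
        )
        rec_a = reconstruct_fixed_activations(
            x_t, p_oth, s_init=s_own, max_iter=max_iter, tol=tol, seed=seed
        )
        rec_wa = reconstruct_fixed_both(x_t, s_oth, p_oth)
        out[direction] = {
            "regular": vaf(x_t, s_own @ p_own),
            "REC_W": rec_w.vaf,
            "REC_A": rec_a.vaf,
            "REC_WA": rec_wa.vaf,
        }
    return out
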