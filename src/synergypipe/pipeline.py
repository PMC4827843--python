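"""End-to-end orchestration: one condition's run, and the two-condition
comparison (similarities, activation peaks, curve subtractions, fixed-
factor cross-reconstruction, statistics).

All randomness flows from a single master seed split per stage, so a
given configuration reproduces byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import __version__
from .core import AccelTrace, CycleTensor, EmgRecording, GaitCycles
from . import accel_segmentation as accel
from . import emg_preprocess as prep
from . import module_analysis as ma
from . import mixed_reconstruction as mrec
from . import nmf_core
from . import stats as st


@dataclass
class RunConfig:
    """Stage parameters for a condition run.

    ``input_kind`` distinguishes raw interference-pattern EMG (band-pass
    filtered before rectification) from envelope-level input (rectified
    and low-pass filtered only), e.g. from the synthetic generator.
    """

    input_kind: str = "raw"  # raw | envelope
    bandpass_lo: float = 10.0
    bandpass_hi: float = 500.0
    envelope_lp: float = 10.0
    accel_cutoff_hz: float = 60.0
    threshold_sd: float = 2.0
    min_spacing_s: float = 0.5
    n_cycles: int = 20
    cycle_start: int = 0
    n_points: int = 200
    k: int | str = "auto"  # int or "auto"
    k_max: int = 11
    restarts: int = 25
    max_iter: int = 2000
    tol: float = 1e-6
    vaf_min: float = 0.90
    gain_eps: float = 0.03
    drop_outliers: bool = False
    seed: int = 0


@dataclass
class ConditionResult:
    """Everything computed for one condition."""

    cycles: GaitCycles
    tensor: CycleTensor  # amplitude-normalized, n_cycles consecutive
    module_set: nmf_core.ModuleSet
    vaf_curve: nmf_core.VafCurve | None
    k_selected: int
    k_criterion_met: bool
    peak_negative_accel_g: np.ndarray
    cv_stance_pct: float
    cv_prelanding_pct: float


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage '{name}': {e}") from e

        return wrapper

    return deco


def run_condition(
    emg: EmgRecording, accel_trace: AccelTrace, config: RunConfig
) -> ConditionResult:
    """Segment, preprocess, select cycles, normalize and factorize.

    Chains foot-strike detection on the acceleration trace, EMG envelope
    extraction, strike-to-strike time normalization (200 points/cycle),
    selection of ``n_cycles`` consecutive cycles, per-muscle amplitude
    normalization, and NMF with either a fixed k or the VAF-curve rule.
    """
    filt = _stage("accel-filter")(accel.lowpass_accel)(
        accel_trace, config.accel_cutoff_hz
    )
    cycles = _stage("strike-detection")(accel.detect_foot_strikes)(
        filt, config.threshold_sd, config.min_spacing_s
    )

    if config.input_kind == "raw":
        emg = _stage("bandpass")(prep.bandpass_emg)(
            emg, config.bandpass_lo, config.bandpass_hi
        )
        env = _stage("envelope")(prep.envelope)(emg, config.envelope_lp)
    elif config.input_kind == "envelope":
        # Input is already an envelope: rectification is the identity and
        # re-low-passing would distort it, so it is used as-is.
        env = emg
    else:
        raise PipelineError("stage 'config': input_kind must be 'raw' or 'envelope'")

    tensor = _stage("segmentation")(prep.segment_and_normalize)(
        env, cycles, config.n_points
    )
    if config.drop_outliers:
        tensor = _stage("outlier-rejection")(prep.drop_outlier_cycles)(tensor)
    tensor = _stage("cycle-selection")(prep.select_consecutive_cycles)(
        tensor, config.n_cycles, config.cycle_start
    )
    tensor = _stage("amplitude-normalization")(prep.amplitude_normalize)(tensor)

    x = tensor.concatenated
    rng = np.random.SeedSequence(config.seed)
    nmf_seed, curve_seed = (int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(2))

    curve = None
    if config.k == "auto":
        curve = _stage("vaf-curve")(nmf_core.vaf_curve)(
            x,
            min(config.k_max, tensor.n_muscles),
            restarts=config.restarts,
            max_iter=config.max_iter,
            tol=config.tol,
            seed=curve_seed,
        )
        k, met = nmf_core.select_dimensionality(curve, config.vaf_min, config.gain_eps)
    else:
        k, met = int(config.k), True
    module_set = _stage("nmf")(nmf_core.nmf)(
        x,
        k,
        restarts=config.restarts,
        max_iter=config.max_iter,
        tol=config.tol,
        seed=nmf_seed,
        samples_per_cycle=config.n_points,
        channel_labels=tensor.channel_labels,
    )

    pna = _stage("peak-neg-accel")(accel.peak_negative_acceleration)(filt, cycles)
    accel_stack = _stage("accel-cycles")(
        lambda: np.stack(
            [
                accel.normalize_cycle(filt.samples[s0:s1], config.n_points)
                for s0, s1 in zip(cycles.strike_samples[:-1], cycles.strike_samples[1:])
            ]
        )
    )()
    cv_stance = accel.cycle_variability(accel_stack, (0.0, 35.0))
    cv_pre = accel.cycle_variability(accel_stack, (91.0, 100.0))

    return ConditionResult(
        cycles=cycles,
        tensor=tensor,
        module_set=module_set,
        vaf_curve=curve,
        k_selected=k,
        k_criterion_met=met,
        peak_negative_accel_g=pna,
        cv_stance_pct=cv_stance,
        cv_prelanding_pct=cv_pre,
    )


def compare_conditions(
    result_a: ConditionResult,
    result_b: ConditionResult,
    config: RunConfig | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> dict:
    """Two-condition comparison report.

    Matches the module sets, reports weighting/activation similarities,
    activation-peak magnitude and timing per matched module, absolute
    curve subtractions, and the four-mode cross-reconstruction table in
    both directions. Raises if the two conditions selected different k
    (force a common k via config in that case).
    """
    config = config or RunConfig()
    ms_a, ms_b = result_a.module_set, result_b.module_set
    if ms_a.k != ms_b.k:
        raise PipelineError(
            f"stage 'compare': conditions selected k={ms_a.k} vs k={ms_b.k}; "
            "re-run with a forced common k"
        )
    if result_a.tensor.channel_labels != result_b.tensor.channel_labels:
        raise PipelineError("stage 'compare': incompatible channel sets")

    match = ma.match_modules(ms_a, ms_b)
    n_pts = result_a.tensor.n_points
    summ_a = ma.mean_activation(ms_a.activations, result_a.tensor.n_cycles, n_pts)
    summ_b = ma.mean_activation(ms_b.activations, result_b.tensor.n_cycles, n_pts)

    modules = []
    for i in range(ms_a.k):
        j = int(match.pairing[i])
        sub = ma.curve_subtraction(summ_a[i].mean_curve, summ_b[j].mean_curve)
        modules.append(
            {
                "module": f"M{i + 1}",
                "pair": (i, j),
                "weighting_similarity": float(match.weighting_similarity[i]),
                "activation_similarity": float(match.activation_similarity[i]),
                "similar": bool(
                    match.weighting_similarity[i] >= ma.SIMILARITY_THRESHOLD
                ),
                "peak": {
                    label_a: {
                        "value": summ_a[i].peak_value,
                        "time_pct": summ_a[i].peak_time_pct,
                    },
                    label_b: {
                        "value": summ_b[j].peak_value,
                        "time_pct": summ_b[j].peak_time_pct,
                    },
                },
                "curve_subtraction": sub.tolist(),
            }
        )

    rec = mrec.mode_comparison(
        result_a.tensor.concatenated,
        result_b.tensor.concatenated,
        ms_a,
        ms_b,
        max_iter=config.max_iter,
        tol=config.tol,
        seed=config.seed,
    )

    report = {
        "software": {"package": "synergypipe", "version": __version__},
        "config": asdict(config),
        "conditions": {
            label_a: _condition_summary(result_a),
            label_b: _condition_summary(result_b),
        },
        "module_comparison": modules,
        "cross_reconstruction": rec,
    }
    return report


def _condition_summary(result: ConditionResult) -> dict:
    return {
        "n_cycles": result.tensor.n_cycles,
        "k_selected": result.k_selected,
        "k_criterion_met": result.k_criterion_met,
        "vaf": result.module_set.vaf,
        "vaf_curve": None
        if result.vaf_curve is None
        else result.vaf_curve.vaf_by_k.tolist(),
        "peak_negative_accel_g_mean": float(result.peak_negative_accel_g.mean()),
        "cv_stance_pct": result.cv_stance_pct,
        "cv_prelanding_pct": result.cv_prelanding_pct,
        "normalization_divisors": result.tensor.normalization.tolist(),
    }


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
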