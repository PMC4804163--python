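"""Single-molecule FRET trace analysis.

Implements the trace-selection and binding-classification procedure for
vesicle-encapsulated DNA pairs:

1. *single-pair selection* — a trace is kept when both the
   donor-excitation total (I_D + I_A) and the direct-excitation acceptor
   channel show exactly one downward photobleaching step (or none, with
   pre-bleach intensities inside the configured single-fluorophore bands);
2. *binding classification* — on the pre-bleach proximity-ratio series
   E = I_A / (I_A + I_D), a trace is *binding* when E exceeds 0.5 for at
   least ``min_jump_frames`` consecutive frames (a FRET jump), or, absent
   jumps, when the median pre-bleach E stays at 0.25 or higher (sustained
   binding);
3. *binding fraction* — bound traces over single-pair traces, averaged
   over triplicate batches with the s.e.m. across replicates as the error;
4. titration-peak and parallel-preference summary statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stepfind import Step, estimate_noise_sd, find_steps
from .synth.traces import FluorescenceTrace

__all__ = [
    "SelectionBands",
    "TraceClassification",
    "BindingFractionResult",
    "TitrationPeak",
    "PreferenceResult",
    "fret_efficiency",
    "select_single_pairs",
    "classify_binding",
    "binding_fraction",
    "titration_peak",
    "parallel_preference",
]


@dataclass(frozen=True)
class SelectionBands:
    """Pre-bleach intensity bands consistent with exactly one fluorophore.

    Defaults bracket the generator's single-fluorophore scales
    (donor-excitation total 1000 ± 100, direct acceptor 500 ± 50) at ±4 s.d.
    """

    total_lo: float = 600.0
    total_hi: float = 1400.0
    direct_lo: float = 300.0
    direct_hi: float = 700.0


@dataclass
class TraceClassification:
    trace_id: str
    is_single_pair: bool
    donor_bleach_frame: int | None
    acceptor_bleach_frame: int | None
    is_binding: bool = False
    binding_mode: str = "none"  # {"jump", "sustained", "none"}
    E_series: np.ndarray | None = None  # pre-bleach only; NaN = invalid frame
    construct: str = ""
    batch: str = ""
    c_spm: float = np.nan
    reject_reason: str = ""


@dataclass
class BindingFractionResult:
    fraction: float
    sem: float
    n_single_pair: int
    per_replicate: dict[str, float]
    construct: str = ""
    c_spm: float = np.nan


@dataclass
class TitrationPeak:
    c_peak_mM: float
    is_peak: bool  # False when the curve is monotone (boundary returned)
    fit_window_mM: tuple[float, ...] = ()


@dataclass
class PreferenceResult:
    percent: float
    percent_err: float
    defined: bool = True


def _prebleach_end(steps_total: list[Step], steps_direct: list[Step],
                   n_frames: int) -> tuple[int | None, int | None, int]:
    donor_bleach = steps_total[0].index if steps_total else None
    acceptor_bleach = steps_direct[0].index if steps_direct else None
    candidates = [b for b in (donor_bleach, acceptor_bleach) if b is not None]
    end = min(candidates) if candidates else n_frames
    return donor_bleach, acceptor_bleach, end


def fret_efficiency(
    trace: FluorescenceTrace,
    background: tuple[float, float] | None = None,
    min_total_frac: float = 0.25,
) -> np.ndarray:
    """Proximity-ratio series E_t = I_A/(I_A + I_D) after background removal.

    Background per channel is the median intensity after the last detected
    bleaching step (when one exists) or the supplied ``(bg_D, bg_A)``
    constants.  Frames whose background-corrected total is non-positive —
    or below ``min_total_frac`` of the trace's median positive total, where
    the ratio of two noise channels is meaningless (e.g. the straggler
    frames around an imperfectly located bleach step) — are flagged invalid
    (NaN) and excluded from classification.  Values are clipped to [0, 1];
    no gamma correction is applied (the classification thresholds are
    ratio-scale).
    """
    if trace.n_frames < 1:
        raise ValueError("trace has no frames")
    I_D = trace.I_D.astype(float)
    I_A = trace.I_A.astype(float)
    if background is None:
        steps_total = find_steps(I_D + I_A)
        last = steps_total[-1].index if steps_total else None
        # a guard band after the detected step absorbs localization error
        # (the detector cannot place a step closer than its minimum
        # segment length to the trace end)
        if last is not None and trace.n_frames - last >= 10:
            bg_d = float(np.median(I_D[last + 5:]))
            bg_a = float(np.median(I_A[last + 5:]))
        else:
            bg_d = bg_a = 0.0
    else:
        bg_d, bg_a = background
    a = I_A - bg_a
    d = I_D - bg_d
    tot = a + d
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.clip(a / tot, 0.0, 1.0)
    floor = 0.0
    if np.any(tot > 0):
        floor = min_total_frac * float(np.median(tot[tot > 0]))
    e[tot <= max(floor, 0.0)] = np.nan
    return e


def select_single_pairs(
    traces: list[FluorescenceTrace],
    *,
    bands: SelectionBands | None = None,
    min_step_sigmas: float = 3.0,
    min_segment: int = 5,
) -> list[TraceClassification]:
    """Label every trace as single donor–acceptor pair or not.

    A channel is consistent with a single fluorophore when it shows exactly
    one downward bleaching step, or no step at all (photobleaching outside
    the observation window) with its pre-bleach mean inside the
    single-fluorophore intensity band.  Traces failing the criteria are
    labelled with a reason, never dropped.
    """
    bands = bands or SelectionBands()
    out: list[TraceClassification] = []
    for tr in traces:
        total = tr.I_D + tr.I_A
        steps_total = find_steps(total, threshold_sigmas=min_step_sigmas,
                                 min_size=min_segment)
        steps_direct = find_steps(tr.I_A_direct,
                                  threshold_sigmas=min_step_sigmas,
                                  min_size=min_segment)
        donor_b, acceptor_b, end = _prebleach_end(
            steps_total, steps_direct, tr.n_frames
        )
        reason = ""
        down_total = [s for s in steps_total if s.is_down]
        down_direct = [s for s in steps_direct if s.is_down]
        if len(steps_total) != len(down_total) or \
                len(steps_direct) != len(down_direct):
            reason = "upward intensity step"
        elif len(down_total) > 1:
            reason = "multiple donor-channel bleach steps"
        elif len(down_direct) > 1:
            reason = "multiple acceptor-channel bleach steps"
        else:
            pre_total = float(np.mean(total[:end])) if end > 0 else 0.0
            pre_direct_end = acceptor_b if acceptor_b is not None else tr.n_frames
            pre_direct = float(np.mean(tr.I_A_direct[:pre_direct_end])) \
                if pre_direct_end > 0 else 0.0
            if not (bands.total_lo <= pre_total <= bands.total_hi):
                reason = "donor-channel intensity outside single-pair band"
            elif not (bands.direct_lo <= pre_direct <= bands.direct_hi):
                reason = "acceptor-channel intensity outside single-pair band"
        is_single = reason == ""
        tc = TraceClassification(
            trace_id=tr.trace_id,
            is_single_pair=is_single,
            donor_bleach_frame=donor_b,
            acceptor_bleach_frame=acceptor_b,
            construct=tr.construct,
            batch=tr.batch,
            c_spm=tr.c_spm,
            reject_reason=reason,
        )
        if is_single:
            e = fret_efficiency(tr)[:end].copy()
            # straggler frames around an imperfectly located bleach step
            # carry near-zero signal in both channels; their ratio is noise
            if end > 0:
                pre_mean = float(np.mean(total[:end]))
                e[total[:end] < 0.5 * pre_mean] = np.nan
            tc.E_series = e
        out.append(tc)
    return out


def classify_binding(
    tc: TraceClassification,
    jump_thresh: float = 0.5,
    sustained_thresh: float = 0.25,
    min_jump_frames: int = 2,
) -> TraceClassification:
    """Apply the jump / sustained binding criteria to a single-pair trace.

    ``jump``: E exceeds ``jump_thresh`` for at least ``min_jump_frames``
    consecutive valid pre-bleach frames.  ``sustained``: no jump, but the
    median pre-bleach E is at least ``sustained_thresh``.
    """
    if not tc.is_single_pair:
        raise ValueError("classify_binding requires a single-pair trace")
    e = tc.E_series
    valid = e[~np.isnan(e)] if e is not None else np.array([])
    if valid.size < min_jump_frames:
        warnings.warn(
            f"trace {tc.trace_id}: fewer than {min_jump_frames} valid "
            "pre-bleach frames; classified as non-binding",
            RuntimeWarning,
        )
        tc.is_binding = False
        tc.binding_mode = "none"
        return tc
    above = ~np.isnan(e) & (e > jump_thresh)
    run = 0
    longest = 0
    for flag in above:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    if longest >= min_jump_frames:
        tc.is_binding = True
        tc.binding_mode = "jump"
    elif float(np.median(valid)) >= sustained_thresh:
        tc.is_binding = True
        tc.binding_mode = "sustained"
    else:
        tc.is_binding = False
        tc.binding_mode = "none"
    return tc


def binding_fraction(
    classifications: list[TraceClassification],
) -> BindingFractionResult:
    """Bound / single-pair fraction, averaged across replicate batches.

    Replicates (``batch`` labels) with zero single-pair traces are excluded
    with a warning.  The reported fraction is the mean of per-replicate
    fractions and the error their s.e.m. (NaN for a single replicate).
    """
    singles = [tc for tc in classifications if tc.is_single_pair]
    if not singles:
        raise ValueError("no single-pair traces")
    batches: dict[str, list[TraceClassification]] = {}
    for tc in singles:
        batches.setdefault(tc.batch, []).append(tc)
    per_rep: dict[str, float] = {}
    for batch in sorted(batches):
        group = batches[batch]
        if not group:
            continue
        per_rep[batch] = sum(tc.is_binding for tc in group) / len(group)
    all_batches = {tc.batch for tc in classifications}
    empty = all_batches - set(per_rep)
    if empty:
        warnings.warn(
            f"replicates without single-pair traces excluded: {sorted(empty)}",
            RuntimeWarning,
        )
    vals = np.array(list(per_rep.values()))
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
    first = singles[0]
    return BindingFractionResult(
        fraction=float(vals.mean()),
        sem=sem,
        n_single_pair=len(singles),
        per_replicate=per_rep,
        construct=first.construct,
        c_spm=first.c_spm,
    )


def titration_peak(
    results: list[tuple[float, BindingFractionResult | float]],
) -> TitrationPeak:
    """Peak spermine concentration of a binding-fraction titration.

    Fits a quadratic in log10(c) to the empirical maximum and its two
    neighbours and returns the vertex concentration.  A monotone curve
    (maximum on the boundary) returns the boundary concentration flagged
    ``is_peak=False``.
    """
    if len(results) < 4:
        raise ValueError("need at least 4 concentrations spanning the peak")
    pairs = sorted(
        (float(c), r.fraction if isinstance(r, BindingFractionResult) else float(r))
        for c, r in results
    )
    c = np.array([p[0] for p in pairs])
    f = np.array([p[1] for p in pairs])
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    i_max = int(np.argmax(f))
    if i_max == 0 or i_max == len(c) - 1:
        return TitrationPeak(c_peak_mM=float(c[i_max]), is_peak=False)
    window = slice(i_max - 1, i_max + 2)
    x = np.log10(c[window])
    y = f[window]
    a, b, _ = np.polyfit(x, y, 2)
    if a >= 0:
        return TitrationPeak(c_peak_mM=float(c[i_max]), is_peak=False,
                             fit_window_mM=tuple(c[window]))
    vertex = -b / (2.0 * a)
    return TitrationPeak(
        c_peak_mM=float(10.0 ** vertex), is_peak=True,
        fit_window_mM=tuple(c[window]),
    )


def parallel_preference(
    frac_parallel: BindingFractionResult,
    frac_anti: BindingFractionResult,
) -> PreferenceResult:
    """Percent excess of the parallel-reporting binding fraction.

    Returns ``100 * (f_par / f_anti - 1)`` with the error propagated from
    the two s.e.m. values.  Undefined (flagged) when the anti-parallel
    fraction is zero.
    """
    fp, fa = frac_parallel.fraction, frac_anti.fraction
    if fa == 0:
        return PreferenceResult(percent=float("nan"), percent_err=float("nan"),
                                defined=False)
    ratio = fp / fa
    rel = 0.0
    if fp > 0 and np.isfinite(frac_parallel.sem) and np.isfinite(frac_anti.sem):
        rel = np.sqrt((frac_parallel.sem / fp) ** 2 + (frac_anti.sem / fa) ** 2)
    return PreferenceResult(
        percent=100.0 * (ratio - 1.0),
        percent_err=100.0 * ratio * rel,
    )
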