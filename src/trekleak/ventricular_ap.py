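"""Ventricular action-potential experiments with a background K₂P leak.

Wraps the packaged human ventricular epicardial model (:mod:`trekleak.tp06`)
and adds a constant-field background K₂P current of configurable relative
sodium permeability α.  The core comparison is α = 0 (ideally K⁺-selective
leak) against α = 0.2 (the sodium-leaky TREK-1 I267T phenotype): sodium
permeability mildly depolarizes the diastolic potential and slows the
upstroke.

Biomarkers follow the standard definitions: RMP is the minimum diastolic
potential, dV/dt_max the maximal upstroke velocity by centered finite
difference, and APD₅₀/APD₉₀ the times from dV/dt_max to 50%/90%
repolarization of the amplitude.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tp06

__all__ = [
    "K2PBackgroundParams",
    "PacingProtocol",
    "APBiomarkers",
    "APTrace",
    "NoUpstrokeError",
    "default_p_k2p",
    "simulate_ap",
    "compute_biomarkers",
    "permeability_sweep",
    "reference_biomarkers",
]


class NoUpstrokeError(ValueError):
    """The trace contains no action-potential upstroke."""


@dataclass(frozen=True)
class K2PBackgroundParams:
    """Background K₂P permeability scale and relative Na⁺ permeability."""

    p_k2p: float
    alpha: float = 0.0

    def __post_init__(self):
        if self.p_k2p < 0:
            raise ValueError("p_k2p must be ≥ 0")
        if self.alpha < 0:
            raise ValueError("alpha must be ≥ 0")


@dataclass(frozen=True)
class PacingProtocol:
    """Regular pacing: cycle length, pre-beats, stimulus shape."""

    cycle_length_ms: float = 1000.0
    n_beats: int = 50
    stim_amplitude: float = -52.0  # pA/pF
    stim_duration_ms: float = 1.0

    def __post_init__(self):
        if self.n_beats < 1:
            raise ValueError("n_beats must be ≥ 1")
        if self.cycle_length_ms <= 0:
            raise ValueError("cycle length must be > 0")


@dataclass(frozen=True)
class APBiomarkers:
    """Resting potential, upstroke velocity and AP durations."""

    rmp_mV: float
    dvdt_max_mV_per_ms: float
    apd50_ms: float
    apd90_ms: float

    def __post_init__(self):
        if not self.apd90_ms >= self.apd50_ms > 0:
            raise ValueError("need apd90 ≥ apd50 > 0")

    def to_dict(self) -> dict:
        return {
            "rmp_mV": self.rmp_mV,
            "dvdt_max_mV_per_ms": self.dvdt_max_mV_per_ms,
            "apd50_ms": self.apd50_ms,
            "apd90_ms": self.apd90_ms,
        }


@dataclass
class APTrace:
    """Membrane potential of the final paced beat."""

    time_ms: np.ndarray
    v_mV: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.time_ms, "v_mV": self.v_mV})

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


def default_p_k2p() -> float:
    """Calibrated 'mild' background permeability scale.

    Chosen so that at baseline intracellular concentrations the α = 0 K₂P
    current at +20 mV equals 5% of the inward-rectifier current at −90 mV —
    an explicit convention for a small leak, closed-form and deterministic.
    """
    y0 = tp06.initial_state()
    ki, nai = y0[2], y0[1]
    ek = tp06.RTONF * math.log(tp06.KO / ki)
    v = -90.0
    ak1 = 0.1 / (1.0 + math.exp(0.06 * (v - ek - 200.0)))
    bk1 = (3.0 * math.exp(0.0002 * (v - ek + 100.0))
           + math.exp(0.1 * (v - ek - 10.0))) / (1.0 + math.exp(-0.5 * (v - ek)))
    ik1 = tp06.GK1 * math.sqrt(tp06.KO / 5.4) * ak1 / (ak1 + bk1) * (v - ek)
    ik2p_per_unit, _ = tp06.k2p_current(20.0, 1.0, 0.0, ki, nai, tp06.KO, tp06.NAO)
    return 0.05 * abs(ik1) / ik2p_per_unit


def simulate_ap(
    k2p: K2PBackgroundParams,
    pacing: PacingProtocol | None = None,
    base_model_id: str = "tp06-epi",
    dt_ms: float = 0.01,
    record_dt_ms: float = 0.01,
) -> APTrace:
    """Pace to quasi-steady state and return the final beat.

    The K₂P current is added to the membrane equation of the base model with
    its K⁺ and Na⁺ limbs feeding the respective ion balances.  The final two
    beats are compared (APD₉₀ and diastolic V) and the trace metadata flags
    alternans when they differ by more than 1%.
    """
    if base_model_id != "tp06-epi":
        raise ValueError(f"unknown base model {base_model_id!r}")
    pacing = pacing or PacingProtocol()
    y = tp06.initial_state()
    cl = pacing.cycle_length_ms

    # pre-pacing (all but the final two beats), recorded coarsely
    n_pre = max(0, pacing.n_beats - 2)
    if n_pre:
        tp06.integrate(
            y, n_pre * cl, dt_ms, pacing.stim_amplitude,
            pacing.stim_duration_ms, cl, k2p.p_k2p, k2p.alpha,
            record_dt_ms=cl / 10,
        )
    n_rec_beats = min(2, pacing.n_beats)
    t, v, y = tp06.integrate(
        y, n_rec_beats * cl, dt_ms, pacing.stim_amplitude,
        pacing.stim_duration_ms, cl, k2p.p_k2p, k2p.alpha,
        record_dt_ms=record_dt_ms,
    )

    per_beat = int(round(cl / record_dt_ms))
    final_t = t[-(per_beat + 1):] - t[-(per_beat + 1)]
    final_v = v[-(per_beat + 1):]
    metadata = {
        "p_k2p": k2p.p_k2p, "alpha": k2p.alpha,
        "cycle_length_ms": cl, "n_beats": pacing.n_beats,
        "dt_ms": dt_ms, "alternans": False,
    }
    if n_rec_beats == 2:
        prev_v = v[: per_beat + 1]
        try:
            b_prev = compute_biomarkers(APTrace(t[: per_beat + 1], prev_v))
            b_last = compute_biomarkers(APTrace(final_t, final_v))
            rel = abs(b_last.apd90_ms - b_prev.apd90_ms) / b_prev.apd90_ms
            metadata["alternans"] = bool(rel > 0.01)
        except NoUpstrokeError:
            pass
    return APTrace(time_ms=final_t, v_mV=final_v, metadata=metadata)


def compute_biomarkers(trace: APTrace, upstroke_threshold_mV_per_ms: float = 1.0) -> APBiomarkers:
    """Extract RMP, dV/dt_max and APD₅₀/APD₉₀ from one full AP.

    dV/dt is a centered finite difference on the recorded grid; APDx runs
    from the time of dV/dt_max to x% repolarization of the amplitude
    (peak − RMP), crossing times linearly interpolated.
    """
    t = np.asarray(trace.time_ms, dtype=float)
    v = np.asarray(trace.v_mV, dtype=float)
    if len(t) < 5:
        raise ValueError("trace too short")
    dvdt = np.empty_like(v)
    dvdt[1:-1] = (v[2:] - v[:-2]) / (t[2:] - t[:-2])
    dvdt[0] = (v[1] - v[0]) / (t[1] - t[0])
    dvdt[-1] = (v[-1] - v[-2]) / (t[-1] - t[-2])
    k_up = int(np.argmax(dvdt))
    dvdt_max = float(dvdt[k_up])
    if dvdt_max < upstroke_threshold_mV_per_ms:
        raise NoUpstrokeError(
            f"no upstroke: max dV/dt {dvdt_max:.3g} mV/ms below threshold"
        )
    rmp = float(np.min(v))
    k_peak = int(np.argmax(v))
    peak = float(v[k_peak])
    amplitude = peak - rmp

    def crossing_time(level):
        below = np.nonzero(v[k_peak:] <= level)[0]
        if len(below) == 0:
            raise ValueError(
                f"trace does not repolarize to {level:.1f} mV"
            )
        k = k_peak + below[0]
        if k == 0 or v[k] == v[k - 1]:
            return t[k]
        # interpolate between the first sample at/below the level and its
        # predecessor
        return t[k - 1] + (t[k] - t[k - 1]) * (v[k - 1] - level) / (v[k - 1] - v[k])

    t_up = t[k_up]
    apd50 = crossing_time(peak - 0.5 * amplitude) - t_up
    apd90 = crossing_time(peak - 0.9 * amplitude) - t_up
    return APBiomarkers(
        rmp_mV=rmp,
        dvdt_max_mV_per_ms=dvdt_max,
        apd50_ms=float(apd50),
        apd90_ms=float(apd90),
    )


def permeability_sweep(
    alphas,
    p_k2p: float | None = None,
    pacing: PacingProtocol | None = None,
    dt_ms: float = 0.01,
) -> pd.DataFrame:
    """Biomarkers as a function of the relative Na⁺ permeability α.

    Over α ∈ [0, 0.5] at fixed p_k2p the RMP is nondecreasing (depolarizing)
    and dV/dt_max nonincreasing.  Solver failures are re-raised annotated
    with the offending α.
    """
    if p_k2p is None:
        p_k2p = default_p_k2p()
    rows = []
    for a in alphas:
        if a < 0:
            raise ValueError("alpha must be ≥ 0")
        try:
            trace = simulate_ap(
                K2PBackgroundParams(p_k2p=p_k2p, alpha=float(a)),
                pacing=pacing, dt_ms=dt_ms,
            )
            bm = compute_biomarkers(trace)
        except RuntimeError as err:
            raise RuntimeError(f"AP simulation failed at alpha={a}: {err}") from err
        rows.append({"alpha": float(a), "p_k2p": p_k2p, **bm.to_dict()})
    return pd.DataFrame(rows)


def reference_biomarkers() -> dict:
    """Packaged regression values of the base model (p_k2p = 0).

    Computed once with the packaged pacing defaults recorded alongside the
    values; see ``data/tp06_epi_reference.json``.
    """
    ref = importlib.resources.files("trekleak").joinpath(
        "data/tp06_epi_reference.json"
    )
    return json.loads(ref.read_text())
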