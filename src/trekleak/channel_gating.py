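"""Stretch activation and desensitization kinetics of TREK-1 macropatches.

TREK-1 is mechanosensitive: negative pipette pressure (suction, mm H₂O)
evokes a peak current that desensitizes along a bi-exponential time course
toward a non-desensitizing persistent level.  Currents are expressed relative
to a reference activation (the peak evoked by intracellular acidification to
pH 5.0), so everything here is dimensionless "normalized current".

The pressure dependence of the peak is modelled as a Boltzmann of pressure;
the I267T selectivity-filter mutant is emulated by a less-negative half-
activation pressure (hypersensitivity) and markedly slowed desensitization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model, Parameters, minimize

from .ionic_driving import DegenerateDesignError, FitConvergenceError

__all__ = [
    "PressureSensitivity",
    "DesensParams",
    "StretchProtocol",
    "GatingTrace",
    "DesensFit",
    "WT_PRESSURE",
    "MUTANT_PRESSURE",
    "WT_DESENS",
    "MUTANT_DESENS",
    "peak_open_fraction",
    "simulate_stretch_current",
    "fit_desensitization",
    "pressure_response_curve",
]


@dataclass(frozen=True)
class PressureSensitivity:
    """Boltzmann pressure dependence of peak stretch activation.

    ``p_half_mmH2O`` is the (negative) pressure of half-maximal activation;
    ``k_p_mmH2O`` the slope factor.  More negative pressure (stronger
    suction) gives a larger open fraction.
    """

    p_half_mmH2O: float
    k_p_mmH2O: float

    def __post_init__(self):
        if self.k_p_mmH2O <= 0:
            raise ValueError(f"k_p must be > 0, got {self.k_p_mmH2O}")


@dataclass(frozen=True)
class DesensParams:
    """Bi-exponential desensitization with a persistent fraction.

    Normalized decay: frac_fast·e^(−t/τ_fast) + frac_slow·e^(−t/τ_slow)
    + frac_persistent, fractions summing to 1.
    """

    tau_fast_s: float
    tau_slow_s: float
    frac_fast: float
    frac_slow: float
    frac_persistent: float

    def __post_init__(self):
        if self.tau_fast_s <= 0:
            raise ValueError("tau_fast must be > 0")
        if self.tau_slow_s <= self.tau_fast_s:
            raise ValueError("tau_slow must exceed tau_fast")
        fr = (self.frac_fast, self.frac_slow, self.frac_persistent)
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-6:
            raise ValueError(f"fractions must sum to 1, got {sum(fr)}")

    def decay(self, t_s):
        t = np.asarray(t_s, dtype=float)
        return (
            self.frac_fast * np.exp(-t / self.tau_fast_s)
            + self.frac_slow * np.exp(-t / self.tau_slow_s)
            + self.frac_persistent
        )


# Wild-type kinetics at −50 mm H2O: τ_fast 68 ms, τ_slow 1.4 s.
WT_DESENS = DesensParams(
    tau_fast_s=0.068, tau_slow_s=1.4, frac_fast=0.55, frac_slow=0.35, frac_persistent=0.10
)

# I267T kinetics: τ_fast slowed >10-fold to 1.0 s, τ_slow to 2.5 s, reduced
# fast component and a larger persistent current.
MUTANT_DESENS = DesensParams(
    tau_fast_s=1.0, tau_slow_s=2.5, frac_fast=0.25, frac_slow=0.45, frac_persistent=0.30
)

# Pressure sensitivities are free defaults (the half-activation pressures are
# not printed); the mutant is hypersensitive (less-negative p_half).
WT_PRESSURE = PressureSensitivity(p_half_mmH2O=-35.0, k_p_mmH2O=8.0)
MUTANT_PRESSURE = PressureSensitivity(p_half_mmH2O=-15.0, k_p_mmH2O=8.0)


@dataclass(frozen=True)
class StretchProtocol:
    """Sequence of suction steps: [(pressure_mmH2O, duration_s), ...]."""

    steps: tuple
    sample_rate_Hz: float = 1000.0

    def __post_init__(self):
        if not self.steps:
            raise ValueError("protocol needs at least one pressure step")
        if any(d <= 0 for _, d in self.steps):
            raise ValueError("step durations must be > 0")
        if self.sample_rate_Hz < 100.0:
            raise ValueError(
                "sample rate must be ≥ 100 Hz to resolve fast desensitization"
            )


@dataclass
class GatingTrace:
    """Normalized stretch-evoked current against time, with step pressures."""

    time_s: np.ndarray
    normalized_current: np.ndarray
    pressure_mmH2O: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.normalized_current = np.asarray(self.normalized_current, dtype=float)
        self.pressure_mmH2O = np.asarray(self.pressure_mmH2O, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.normalized_current)):
            raise ValueError("normalized current must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "pressure_mmH2O": self.pressure_mmH2O,
                "i_norm": self.normalized_current,
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "GatingTrace":
        df = pd.read_csv(path_or_buf)
        return cls(
            time_s=df["time_s"].to_numpy(),
            normalized_current=df["i_norm"].to_numpy(),
            pressure_mmH2O=df["pressure_mmH2O"].to_numpy(),
        )


def peak_open_fraction(pressure_mmH2O: float, sens: PressureSensitivity) -> float:
    """Boltzmann peak activation: 1/(1 + exp((P − P½)/k)).

    Monotone decreasing in pressure, so stronger suction (more negative P)
    opens more channels; equals 0.5 at P = P½ and saturates at 1 as P → −∞.
    """
    p = np.asarray(pressure_mmH2O, dtype=float)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp((p - sens.p_half_mmH2O) / sens.k_p_mmH2O))
    return out if out.ndim else float(out)


def simulate_stretch_current(
    protocol: StretchProtocol,
    sens: PressureSensitivity,
    desens: DesensParams,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> GatingTrace:
    """Synthesize a normalized stretch response over a suction protocol.

    Within each step the current is peak_open_fraction(P) times the
    bi-exponential decay measured from step onset (activation is treated as
    instantaneous).  Additive Gaussian noise of standard deviation
    ``noise_sd`` (same normalized units) is reproducible under ``seed``.
    """
    dt = 1.0 / protocol.sample_rate_Hz
    metadata: dict = {"seed": seed, "noise_sd": noise_sd, "warnings": []}
    if dt * 5 > desens.tau_fast_s:
        msg = (
            f"sample interval {dt * 1e3:.1f} ms gives < 5 samples per "
            f"tau_fast = {desens.tau_fast_s * 1e3:.1f} ms"
        )
        metadata["warnings"].append(msg)
        warnings.warn(msg, stacklevel=2)

    times, currents, pressures = [], [], []
    t0 = 0.0
    for pressure, duration in protocol.steps:
        n = max(2, int(round(duration * protocol.sample_rate_Hz)))
        t_local = np.arange(n) * dt
        peak = peak_open_fraction(pressure, sens)
        i = peak * desens.decay(t_local)
        times.append(t0 + t_local)
        currents.append(i)
        pressures.append(np.full(n, pressure))
        t0 += duration
    time_s = np.concatenate(times)
    i_norm = np.concatenate(currents)
    pressure = np.concatenate(pressures)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i_norm = i_norm + rng.normal(0.0, noise_sd, size=i_norm.shape)
    return GatingTrace(
        time_s=time_s,
        normalized_current=i_norm,
        pressure_mmH2O=pressure,
        metadata=metadata,
    )


@dataclass(frozen=True)
class DesensFit:
    """Desensitization fit result with diagnostics."""

    params: DesensParams
    peak: float
    stderr: dict
    single_exponential_like: bool
    short_trace: bool
    redchi: float

    def to_json(self) -> str:
        rec = [
            {"parameter": "tau_fast_s", "estimate": self.params.tau_fast_s,
             "stderr": self.stderr.get("tau_fast_s")},
            {"parameter": "tau_slow_s", "estimate": self.params.tau_slow_s,
             "stderr": self.stderr.get("tau_slow_s")},
            {"parameter": "frac_fast", "estimate": self.params.frac_fast,
             "stderr": self.stderr.get("frac_fast")},
            {"parameter": "frac_slow", "estimate": self.params.frac_slow,
             "stderr": self.stderr.get("frac_slow")},
            {"parameter": "frac_persistent", "estimate": self.params.frac_persistent,
             "stderr": self.stderr.get("frac_persistent")},
        ]
        return json.dumps(
            {"parameters": rec,
             "single_exponential_like": self.single_exponential_like,
             "short_trace": self.short_trace,
             "redchi": self.redchi},
            indent=2,
        )


def _tau_initial_guesses(t, y):
    """Initial τ guesses from the times to 63% and 90% of the total decay."""
    y0, yinf = y[0], y[-1]
    span = y0 - yinf
    if span <= 0:
        return 0.1 * (t[-1] - t[0]), 0.5 * (t[-1] - t[0])
    frac_decayed = (y0 - y) / span
    def t_at(q):
        idx = np.argmax(frac_decayed >= q)
        return t[idx] - t[0] if frac_decayed[idx] >= q else t[-1] - t[0]
    tau_f = max(t_at(0.63) / 2.0, 1e-3)
    tau_s = max(t_at(0.90), 5 * tau_f)
    return tau_f, tau_s


def fit_desensitization(trace: GatingTrace) -> DesensFit:
    """Fit A_f·e^(−t/τ_f) + A_s·e^(−t/τ_s) + A_p to a stretch response.

    The additive constant A_p (persistent current) is free.  Returned
    fractions are normalized to sum to 1 and time constants ordered so that
    τ_slow ≥ τ_fast.  A fit whose τ ratio falls below 2 is flagged
    ``single_exponential_like`` rather than silently returned.
    """
    t = trace.time_s - trace.time_s[0]
    y = trace.normalized_current
    if len(t) < 50:
        raise ValueError(f"fit needs ≥ 50 samples, got {len(t)}")

    tau_f0, tau_s0 = _tau_initial_guesses(t, y)
    span = max(y[0] - y[-1], 1e-9)

    def model(t, a_fast, a_slow, a_pers, tau_fast, tau_slow):
        return (
            a_fast * np.exp(-t / tau_fast)
            + a_slow * np.exp(-t / tau_slow)
            + a_pers
        )

    m = Model(model)
    params = m.make_params(
        a_fast=dict(value=0.6 * span, min=0.0),
        a_slow=dict(value=0.4 * span, min=0.0),
        a_pers=dict(value=max(y[-1], 0.0), min=0.0),
        tau_fast=dict(value=tau_f0, min=1e-3, max=60.0),
        tau_slow=dict(value=tau_s0, min=1e-3, max=60.0),
    )
    result = m.fit(y, params, t=t)
    if not result.success:
        raise FitConvergenceError(
            "desensitization fit did not converge "
            f"(initial guesses tau_fast={tau_f0:.4g} s, tau_slow={tau_s0:.4g} s): "
            f"{result.message}",
            last_iterate={k: v.value for k, v in result.params.items()},
        )

    vals = {k: float(v.value) for k, v in result.params.items()}
    errs = {k: (float(v.stderr) if v.stderr is not None else None)
            for k, v in result.params.items()}
    # order the exponentials: fast = smaller tau
    if vals["tau_fast"] > vals["tau_slow"]:
        vals["tau_fast"], vals["tau_slow"] = vals["tau_slow"], vals["tau_fast"]
        vals["a_fast"], vals["a_slow"] = vals["a_slow"], vals["a_fast"]
        errs["tau_fast"], errs["tau_slow"] = errs["tau_slow"], errs["tau_fast"]
        errs["a_fast"], errs["a_slow"] = errs["a_slow"], errs["a_fast"]

    total = vals["a_fast"] + vals["a_slow"] + vals["a_pers"]
    if total <= 0:
        raise FitConvergenceError(
            "desensitization fit collapsed to zero amplitude", last_iterate=vals
        )
    fractions = {
        "frac_fast": vals["a_fast"] / total,
        "frac_slow": vals["a_slow"] / total,
        "frac_persistent": vals["a_pers"] / total,
    }
    ratio = vals["tau_slow"] / max(vals["tau_fast"], 1e-12)
    degenerate = ratio < 2.0
    duration = t[-1] - t[0]
    short = duration < 3.0 * vals["tau_slow"]

    if degenerate:
        # keep a valid DesensParams by nudging tau_slow above tau_fast
        tau_slow = max(vals["tau_slow"], vals["tau_fast"] * (1 + 1e-9))
    else:
        tau_slow = vals["tau_slow"]
    params_out = DesensParams(
        tau_fast_s=vals["tau_fast"],
        tau_slow_s=tau_slow,
        frac_fast=fractions["frac_fast"],
        frac_slow=fractions["frac_slow"],
        frac_persistent=fractions["frac_persistent"],
    )
    stderr = {
        "tau_fast_s": errs["tau_fast"],
        "tau_slow_s": errs["tau_slow"],
        "frac_fast": None if errs["a_fast"] is None else errs["a_fast"] / total,
        "frac_slow": None if errs["a_slow"] is None else errs["a_slow"] / total,
        "frac_persistent": None if errs["a_pers"] is None else errs["a_pers"] / total,
    }
    return DesensFit(
        params=params_out,
        peak=total,
        stderr=stderr,
        single_exponential_like=degenerate,
        short_trace=short,
        redchi=float(result.redchi),
    )


def pressure_response_curve(traces: list[GatingTrace]):
    """Steady-state activation against pressure, with a Boltzmann fit.

    Each trace must hold a single suction step; the steady state is the mean
    normalized current over the final 10% of the step.  Returns
    (DataFrame[pressure_mmH2O, steady_state], fitted PressureSensitivity).
    """
    rows = []
    for trace in traces:
        pressures = np.unique(trace.pressure_mmH2O)
        if len(pressures) != 1:
            raise ValueError("each trace must hold exactly one pressure step")
        n_tail = max(1, len(trace.time_s) // 10)
        ss = float(np.mean(trace.normalized_current[-n_tail:]))
        rows.append((float(pressures[0]), ss))
    df = pd.DataFrame(rows, columns=["pressure_mmH2O", "steady_state"])
    if df["pressure_mmH2O"].nunique() < 3:
        raise DegenerateDesignError(
            "pressure-response curve needs ≥ 3 distinct pressures"
        )

    p = df["pressure_mmH2O"].to_numpy()
    y = df["steady_state"].to_numpy()
    amax = float(y.max())

    params = Parameters()
    params.add("amplitude", value=amax, min=0.0)
    params.add("p_half", value=float(np.median(p)), min=p.min() - 200, max=p.max() + 200)
    params.add("k_p", value=8.0, min=0.1, max=200.0)

    def resid(pars):
        a = pars["amplitude"].value
        sens = PressureSensitivity(pars["p_half"].value, pars["k_p"].value)
        return a * peak_open_fraction(p, sens) - y

    result = minimize(resid, params, method="leastsq")
    if not result.success:
        raise FitConvergenceError(
            f"Boltzmann pressure fit did not converge: {result.message}",
            last_iterate={k: v.value for k, v in result.params.items()},
        )
    sens = PressureSensitivity(
        p_half_mmH2O=float(result.params["p_half"].value),
        k_p_mmH2O=float(result.params["k_p"].value),
    )
    return df, sens
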