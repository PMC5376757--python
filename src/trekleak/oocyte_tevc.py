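"""Virtual two-electrode voltage clamp of a Xenopus oocyte membrane.

The membrane carries an arbitrary mix of GHK channel populations (wild-type
and sodium-leaky TREK-1 homo-/heterodimers), a phenomenological inward
rectifier (Kir2.1), and an ohmic endogenous leak.  Ramp and step protocols
produce current traces and current–voltage relations; extractors recover the
reversal potential from an IV and the zero-current membrane potential from
the full model.  The module doubles as the synthetic-data generator: with a
seed it writes reproducible fixture datasets for every downstream fit.

All currents are quasi-static (no capacitive transients); the current unit
is a nominal μA whose absolute scale is free (expression level is not
calibrated).
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ionic_driving import (
    ND96,
    OOCYTE_INTERNAL,
    PermeabilityProfile,
    SolutionComposition,
    ThermalContext,
    ghk_flux,
    nernst_potential,
    potassium_substitution_series,
)

__all__ = [
    "ChannelPopulation",
    "OocyteModel",
    "VoltageProtocol",
    "CurrentTrace",
    "IVRelation",
    "NoReversalError",
    "EmRootError",
    "RAMP_PROTOCOL",
    "STEP_PROTOCOL",
    "run_protocol",
    "measure_erev",
    "solve_em",
    "assemble_heteromers",
    "apply_adrenergic",
    "generate_fixture_suite",
    "DEFAULT_ADRENERGIC_RULES",
]


class NoReversalError(ValueError):
    """The IV relation does not bracket a zero crossing."""


class EmRootError(RuntimeError):
    """Zero or multiple zero-current roots in the scanned voltage range."""


@dataclass(frozen=True)
class ChannelPopulation:
    """One channel population: permeability profile × expression scale.

    ``conductance_scale`` lumps channel count and open probability (the
    injected-cRNA dose).  ``modulation`` holds multiplicative (outward,
    inward) limb scales applied to the population's current on either side
    of its own reversal; ``genotype`` tags the population for genotype-
    specific modulation rules ('wt', 'mutant', 'het', or other).
    """

    label: str
    profile: PermeabilityProfile
    conductance_scale: float = 1.0
    modulation: tuple[float, float] = (1.0, 1.0)
    genotype: str = "wt"

    def __post_init__(self):
        if self.conductance_scale < 0:
            raise ValueError("conductance_scale must be ≥ 0")
        if any(s < 0 for s in self.modulation):
            raise ValueError("limb modulation scales must be ≥ 0")


@dataclass(frozen=True)
class OocyteModel:
    """Whole-oocyte membrane: channel populations + Kir2.1 + ohmic leak."""

    populations: tuple[ChannelPopulation, ...] = ()
    kir_conductance: float = 0.0
    leak_conductance: float = 0.0
    leak_reversal_mV: float = -20.0
    bath: SolutionComposition = ND96
    internal: SolutionComposition = OOCYTE_INTERNAL
    thermal: ThermalContext = field(default_factory=ThermalContext)
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "populations", tuple(self.populations))
        if self.kir_conductance < 0 or self.leak_conductance < 0:
            raise ValueError("conductances must be ≥ 0")
        any_cond = (
            self.kir_conductance > 0
            or self.leak_conductance > 0
            or any(p.conductance_scale > 0 for p in self.populations)
        )
        if not any_cond:
            raise ValueError("model needs at least one nonzero conductance")

    # -- current components ------------------------------------------------

    def _kir_current(self, v_mV):
        """Phenomenological Kir2.1: steeply rectifying K⁺ conductance.

        I = g·(V − E_K)·r(V), r(V) = 1/(1 + exp((V − E_K − 10)/6)); passes
        inward current below E_K and shuts off ~10 mV above it.
        """
        e_k = nernst_potential(self.bath.k_mM, self.internal.k_mM, self.thermal)
        v = np.asarray(v_mV, dtype=float)
        r = 1.0 / (1.0 + np.exp((v - e_k - 10.0) / 6.0))
        return self.kir_conductance * (v - e_k) * r

    def total_current(self, v_mV):
        """Noiseless steady-state membrane current (outward positive)."""
        v = np.asarray(v_mV, dtype=float)
        total = np.zeros_like(v)
        for pop in self.populations:
            i = pop.conductance_scale * ghk_flux(
                v, pop.profile, self.bath, self.internal, self.thermal
            )
            out_scale, in_scale = pop.modulation
            i = np.where(np.asarray(i) > 0, i * out_scale, i * in_scale)
            total = total + i
        total = total + self._kir_current(v)
        total = total + self.leak_conductance * (v - self.leak_reversal_mV)
        return total if total.ndim else float(total)


@dataclass(frozen=True)
class VoltageProtocol:
    """Ramp or step command-voltage protocol."""

    kind: str  # "ramp" | "steps"
    holding_mV: float = -80.0
    ramp_start_mV: float = -120.0
    ramp_end_mV: float = 40.0
    ramp_duration_s: float = 3.5
    step_min_mV: float = -130.0
    step_max_mV: float = 50.0
    step_increment_mV: float = 10.0
    step_duration_s: float = 0.2
    sample_rate_Hz: float = 200.0

    def __post_init__(self):
        if self.kind not in ("ramp", "steps"):
            raise ValueError("protocol kind must be 'ramp' or 'steps'")
        if self.kind == "ramp" and self.ramp_duration_s <= 0:
            raise ValueError("ramp duration must be > 0")
        if self.kind == "steps":
            if self.step_increment_mV <= 0:
                raise ValueError("step increment must be > 0")
            if self.step_duration_s <= 0:
                raise ValueError("step duration must be > 0")


#: Standard ramp: −120 → +40 mV over 3.5 s from a −80 mV holding potential.
RAMP_PROTOCOL = VoltageProtocol(kind="ramp")

#: Standard step family: −130 → +50 mV in 10-mV, 200-ms steps.
STEP_PROTOCOL = VoltageProtocol(kind="steps")


@dataclass
class CurrentTrace:
    """Time-indexed commanded voltage and membrane current."""

    time_s: np.ndarray
    v_mV: np.ndarray
    i_uA: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "v_mV": self.v_mV, "i_uA": self.i_uA})

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


@dataclass
class IVRelation:
    """Current–voltage relation with strictly increasing voltages."""

    v_mV: np.ndarray
    i_uA: np.ndarray

    def __post_init__(self):
        self.v_mV = np.asarray(self.v_mV, dtype=float)
        self.i_uA = np.asarray(self.i_uA, dtype=float)
        if np.any(np.diff(self.v_mV) <= 0):
            raise ValueError("IV voltages must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"v_mV": self.v_mV, "i_uA": self.i_uA})

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "IVRelation":
        df = pd.read_csv(path_or_buf)
        return cls(v_mV=df["v_mV"].to_numpy(), i_uA=df["i_uA"].to_numpy())


def run_protocol(
    model: OocyteModel,
    protocol: VoltageProtocol = RAMP_PROTOCOL,
    gating_tau_s: float | None = None,
    gating_start: float = 0.5,
) -> tuple[CurrentTrace, IVRelation]:
    """Run a voltage protocol; return the trace and the derived IV relation.

    Currents are steady-state GHK/Kir/leak sums plus seeded Gaussian noise.
    ``gating_tau_s`` optionally enables a first-order activation relaxation
    of the TREK populations (the slow-activation "hook" seen on steps to
    very negative potentials); it is off by default and steady-state IVs are
    the primary product.
    """
    dt = 1.0 / protocol.sample_rate_Hz
    if protocol.kind == "ramp":
        n = max(2, int(round(protocol.ramp_duration_s * protocol.sample_rate_Hz)))
        t = np.arange(n) * dt
        v = np.linspace(protocol.ramp_start_mV, protocol.ramp_end_mV, n)
    else:
        volts = np.arange(
            protocol.step_min_mV,
            protocol.step_max_mV + 0.5 * protocol.step_increment_mV,
            protocol.step_increment_mV,
        )
        n_per = max(2, int(round(protocol.step_duration_s * protocol.sample_rate_Hz)))
        t = np.arange(len(volts) * n_per) * dt
        v = np.repeat(volts, n_per)

    i = model.total_current(v)
    if gating_tau_s is not None:
        # relaxation of the TREK gate toward its steady level from the
        # holding condition; applied multiplicatively to the channel term
        gate = 1.0 - (1.0 - gating_start) * np.exp(-t / gating_tau_s)
        background = model.total_current(v) - _trek_current(model, v)
        i = background + gate * _trek_current(model, v)
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        i = i + rng.normal(0.0, model.noise_sd, size=np.shape(i))

    trace = CurrentTrace(
        time_s=t,
        v_mV=v,
        i_uA=np.asarray(i, dtype=float),
        metadata={"protocol": protocol.kind, "seed": model.seed, "noise_sd": model.noise_sd},
    )
    if protocol.kind == "ramp":
        iv = IVRelation(v_mV=v, i_uA=np.asarray(i, dtype=float))
    else:
        # steady-state current at the end of each step
        n_per = len(t) // len(np.unique(v))
        idx = np.arange(1, len(np.unique(v)) + 1) * n_per - 1
        iv = IVRelation(v_mV=np.unique(v), i_uA=np.asarray(i, dtype=float)[idx])
    return trace, iv


def _trek_current(model: OocyteModel, v):
    total = np.zeros_like(np.asarray(v, dtype=float))
    for pop in model.populations:
        i = pop.conductance_scale * ghk_flux(
            v, pop.profile, model.bath, model.internal, model.thermal
        )
        out_scale, in_scale = pop.modulation
        total = total + np.where(np.asarray(i) > 0, i * out_scale, i * in_scale)
    return total


def measure_erev(iv: IVRelation) -> float:
    """Reversal potential by linear interpolation at the IV zero crossing.

    With multiple crossings (noise) the most negative one is returned and a
    multiplicity warning issued; an IV without a sign change raises
    :class:`NoReversalError`.
    """
    i = iv.i_uA
    v = iv.v_mV
    idx = np.nonzero(i[:-1] * i[1:] <= 0)[0]
    idx = [k for k in idx if not (i[k] == 0 and i[k + 1] == 0)]
    if len(idx) == 0:
        exact = np.nonzero(i == 0)[0]
        if len(exact):
            return float(v[exact[0]])
        raise NoReversalError("IV relation has no zero crossing")
    if len(idx) > 1:
        warnings.warn(
            f"IV has {len(idx)} zero crossings; returning the most negative",
            stacklevel=2,
        )
    k = idx[0]
    if i[k] == i[k + 1]:
        return float(0.5 * (v[k] + v[k + 1]))
    return float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]))


def solve_em(
    model: OocyteModel, v_min_mV: float = -150.0, v_max_mV: float = 50.0
) -> float:
    """Zero-total-current membrane potential by bracketed root finding.

    The noiseless total current is sign-scanned at 1-mV resolution over
    [v_min, v_max]; a unique bracket is refined by Brent's method to
    1e-3 mV.  Zero or multiple roots raise :class:`EmRootError` with the
    sign pattern.
    """
    grid = np.arange(v_min_mV, v_max_mV + 0.5, 1.0)
    f = np.asarray(model.total_current(grid))
    brackets = np.nonzero(f[:-1] * f[1:] < 0)[0]
    exact = np.nonzero(f == 0)[0]
    if len(brackets) + len(exact) == 0:
        raise EmRootError(
            "no zero-current root in "
            f"[{v_min_mV}, {v_max_mV}] mV; current sign is uniformly "
            f"{'positive' if f[0] > 0 else 'negative'}"
        )
    if len(brackets) + len(exact) > 1:
        signs = "".join("+" if x > 0 else ("-" if x < 0 else "0") for x in f[::10])
        raise EmRootError(f"multiple zero-current roots; sign pattern (10-mV): {signs}")
    if len(exact):
        return float(grid[exact[0]])
    k = brackets[0]
    return float(
        brentq(lambda v: model.total_current(v), grid[k], grid[k + 1], xtol=1e-3)
    )


def assemble_heteromers(
    fraction_wt_cRNA: float, alpha_het: float = 0.20, p_k: float = 1.0
) -> list[tuple[str, float, PermeabilityProfile]]:
    """Binomial dimer assembly from a WT : mutant cRNA mix.

    Subunits dimerize independently, giving weights f², 2f(1−f), (1−f)² for
    WT/WT, WT/mut, mut/mut.  The mutant subunit is dominant for selectivity:
    any dimer containing it carries α = ``alpha_het`` (default 0.2), WT/WT
    carries α = 0.
    """
    f = fraction_wt_cRNA
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction_wt_cRNA must lie in [0, 1]")
    classes = [
        ("wt/wt", f * f, PermeabilityProfile(p_k=p_k, alpha=0.0)),
        ("wt/mut", 2 * f * (1 - f), PermeabilityProfile(p_k=p_k, alpha=alpha_het)),
        ("mut/mut", (1 - f) * (1 - f), PermeabilityProfile(p_k=p_k, alpha=alpha_het)),
    ]
    return [(label, w, prof) for label, w, prof in classes if w > 0]


#: Default β₁-adrenergic modulation: WT current nearly suppressed on both
#: limbs; mutant-containing channels keep their outward current and show an
#: enhanced inward leak.  Free defaults with no ground-truth status.
DEFAULT_ADRENERGIC_RULES = {
    "wt": (0.1, 0.1),
    "mutant": (1.0, 1.3),
    "het": (1.0, 1.3),
}


def apply_adrenergic(
    model: OocyteModel, genotype_rules: dict | None = None
) -> OocyteModel:
    """Scale each population's current limbs by genotype-specific factors.

    ``genotype_rules`` maps genotype tag → (outward_scale, inward_scale);
    populations whose genotype has no rule are left unchanged.  Scales
    compose multiplicatively with any modulation already present.
    """
    rules = DEFAULT_ADRENERGIC_RULES if genotype_rules is None else genotype_rules
    for g, (so, si) in rules.items():
        if so < 0 or si < 0:
            raise ValueError(f"negative modulation scale for genotype {g!r}")
    new_pops = []
    for pop in model.populations:
        if pop.genotype in rules:
            so, si = rules[pop.genotype]
            new_pops.append(
                replace(
                    pop,
                    modulation=(pop.modulation[0] * so, pop.modulation[1] * si),
                )
            )
        else:
            new_pops.append(pop)
    return replace(model, populations=tuple(new_pops))


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

_K_SERIES_MM = (2.0, 5.0, 10.0, 20.0, 40.0, 98.0)


def generate_fixture_suite(config: dict, seed: int, out_dir) -> dict:
    """Write a reproducible synthetic dataset emulating the key experiments.

    ``config['scenarios']`` selects from: ``fig3b`` (K⁺-substitution E_rev
    series, WT and mutant, 1-mV noise), ``fig5d`` (BL-1249 dose–response
    tables, 5% noise), ``fig6`` (−50 mm H₂O stretch traces at 1% noise plus
    arachidonic-acid dose–response tables), ``fig2e`` (ramp IVs for WT-only,
    mutant-only and heterozygous co-expression models).  Returns the manifest
    (also written as ``manifest.json``) recording every seed and generating
    parameter, so each fixture can be re-fitted and checked offline.
    """
    from . import channel_gating as cg
    from . import pharmacology as ph

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenarios = config.get("scenarios", ["fig3b", "fig5d", "fig6", "fig2e"])
    manifest = {"root_seed": int(seed), "scenarios": {}, "files": []}

    def child_seed(tag: str) -> int:
        key = zlib.crc32(tag.encode("utf-8"))
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
        return int(ss.generate_state(1)[0] % 2**31)

    for scen in scenarios:
        if scen == "fig3b":
            entries = {}
            for name, alpha in (("wt", 0.0), ("mutant", 0.20)):
                s = child_seed(f"fig3b/{name}")
                series = potassium_substitution_series(
                    _K_SERIES_MM,
                    PermeabilityProfile(p_k=1.0, alpha=alpha),
                    noise_sd_mV=1.0,
                    rng=np.random.default_rng(s),
                    n_replicates=10,
                )
                fname = f"fig3b_{name}.tsv"
                series.to_tsv(out / fname)
                manifest["files"].append(fname)
                entries[name] = {
                    "seed": s,
                    "alpha": alpha,
                    "k_out_mM": list(_K_SERIES_MM),
                    "noise_sd_mV": 1.0,
                    "n_replicates": 10,
                    "total_cation_mM": 98.0,
                    "internal": {"k_mM": OOCYTE_INTERNAL.k_mM, "na_mM": OOCYTE_INTERNAL.na_mM},
                    "temperature_K": 294.15,
                }
            manifest["scenarios"]["fig3b"] = entries
        elif scen == "fig5d":
            entries = {}
            grid = [1.0, 3.0, 10.0, 30.0, 100.0]
            for name, params, n_rep in (
                ("wt", ph.BL1249_WT, 3),
                ("mutant", ph.BL1249_MUTANT, 8),
            ):
                s = child_seed(f"fig5d/{name}")
                table = ph.synthesize_dose_response(
                    grid, params, n_replicates=n_rep, noise_cv=0.05, seed=s
                )
                fname = f"fig5d_bl1249_{name}.csv"
                table.to_csv(out / fname)
                manifest["files"].append(fname)
                entries[name] = {
                    "seed": s,
                    "ec50_uM": params.ec50_uM,
                    "hill_h": params.hill_h,
                    "fold_max": params.fold_max,
                    "conc_uM": grid,
                    "n_replicates": n_rep,
                    "noise_cv": 0.05,
                }
            manifest["scenarios"]["fig5d"] = entries
        elif scen == "fig6":
            entries = {}
            for name, sens, desens, dur in (
                ("wt", cg.WT_PRESSURE, cg.WT_DESENS, 6.0),
                ("mutant", cg.MUTANT_PRESSURE, cg.MUTANT_DESENS, 10.0),
            ):
                s = child_seed(f"fig6/{name}")
                protocol = cg.StretchProtocol(steps=((-50.0, dur),), sample_rate_Hz=1000.0)
                peak = cg.peak_open_fraction(-50.0, sens)
                trace = cg.simulate_stretch_current(
                    protocol, sens, desens, seed=s, noise_sd=0.01 * peak
                )
                fname = f"fig6_stretch_{name}.csv"
                trace.to_csv(out / fname)
                manifest["files"].append(fname)
                entries[name] = {
                    "seed": s,
                    "pressure_mmH2O": -50.0,
                    "duration_s": dur,
                    "sample_rate_Hz": 1000.0,
                    "noise_sd": 0.01 * peak,
                    "tau_fast_s": desens.tau_fast_s,
                    "tau_slow_s": desens.tau_slow_s,
                    "frac_fast": desens.frac_fast,
                    "frac_slow": desens.frac_slow,
                    "frac_persistent": desens.frac_persistent,
                    "p_half_mmH2O": sens.p_half_mmH2O,
                    "k_p_mmH2O": sens.k_p_mmH2O,
                }
            aa_grid = list(np.round(np.logspace(np.log10(0.3), np.log10(30.0), 11), 4))
            for name, params, n_rep in (
                ("wt", ph.AA_WT, 7),
                ("mutant", ph.AA_MUTANT, 8),
            ):
                s = child_seed(f"fig6f/{name}")
                table = ph.synthesize_dose_response(
                    aa_grid, params, n_replicates=n_rep, noise_cv=0.05, seed=s
                )
                fname = f"fig6f_aa_{name}.csv"
                table.to_csv(out / fname)
                manifest["files"].append(fname)
                entries[f"aa_{name}"] = {
                    "seed": s,
                    "ec50_uM": params.ec50_uM,
                    "hill_h": params.hill_h,
                    "fold_max": params.fold_max,
                    "conc_uM": aa_grid,
                    "n_replicates": n_rep,
                    "noise_cv": 0.05,
                }
            manifest["scenarios"]["fig6"] = entries
        elif scen == "fig2e":
            entries = {}
            wt_pop = ChannelPopulation(
                "TREK-1 WT", PermeabilityProfile(1.0, 0.0), 1.0, genotype="wt"
            )
            mut_pop = ChannelPopulation(
                "TREK-1 I267T", PermeabilityProfile(1.0, 0.20), 1.0, genotype="mutant"
            )
            het_pops = tuple(
                ChannelPopulation(lbl, prof, w, genotype="het")
                for lbl, w, prof in assemble_heteromers(0.5)
            )
            for name, pops in (
                ("wt", (wt_pop,)),
                ("mutant", (mut_pop,)),
                ("het", het_pops),
            ):
                s = child_seed(f"fig2e/{name}")
                model = OocyteModel(populations=pops, noise_sd=0.1, seed=s)
                _, iv = run_protocol(model, RAMP_PROTOCOL)
                fname = f"fig2e_iv_{name}.csv"
                iv.to_csv(out / fname)
                manifest["files"].append(fname)
                entries[name] = {
                    "seed": s,
                    "noise_sd": 0.1,
                    "populations": [
                        {"label": p.label, "alpha": p.profile.alpha,
                         "conductance_scale": p.conductance_scale}
                        for p in pops
                    ],
                }
            manifest["scenarios"]["fig2e"] = entries
        else:
            raise ValueError(f"unknown fixture scenario {scen!r}")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
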