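"""Nernst/Goldman–Hodgkin–Katz electrodiffusion and selectivity inference.

The module treats a channel as a two-cation (K⁺, Na⁺) GHK pore characterised
by a permeability scale ``p_k`` and a relative sodium permeability
``alpha = P_Na / P_K``.  ``alpha = 0`` is an ideally K⁺-selective channel and
recovers the Nernst equation; ``alpha ≈ 0.2`` is the sodium-leaky phenotype of
the TREK-1 I267T selectivity-filter mutant.  Impermeant substitutes (NMDG⁺)
carry zero permeability by definition.

Sign conventions: membrane potential is intracellular minus extracellular
(mV); outward current is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

GAS_CONSTANT_J_PER_MOL_K = 8.31446261815324
FARADAY_C_PER_MOL = 96485.33212

__all__ = [
    "SolutionComposition",
    "PermeabilityProfile",
    "ThermalContext",
    "ErevSeries",
    "PermeabilityFit",
    "CompositionError",
    "DegenerateDesignError",
    "FitConvergenceError",
    "ND96",
    "OOCYTE_INTERNAL",
    "nernst_potential",
    "ghk_reversal",
    "ghk_flux",
    "decade_slope",
    "fit_permeability_ratio",
    "potassium_substitution_series",
]


class CompositionError(ValueError):
    """An ionic composition violates a physical precondition."""


class DegenerateDesignError(ValueError):
    """A regression design carries no usable variation."""


class FitConvergenceError(RuntimeError):
    """A nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class ThermalContext:
    """Absolute temperature and the derived thermal voltage RT/F."""

    temperature_K: float = 294.15  # room temperature, 21 °C

    def __post_init__(self):
        if not 273.0 < self.temperature_K < 320.0:
            raise ValueError(
                f"temperature {self.temperature_K} K outside the physiological "
                "range (273, 320) K"
            )

    @property
    def vt_mV(self) -> float:
        """Thermal voltage RT/F in millivolts (≈25.35 mV at 294.15 K)."""
        return (
            1000.0
            * GAS_CONSTANT_J_PER_MOL_K
            * self.temperature_K
            / FARADAY_C_PER_MOL
        )


@dataclass(frozen=True)
class SolutionComposition:
    """Monovalent-cation milieu on one side of the membrane (mM).

    ``impermeant_mM`` is an NMDG⁺-like substitute that carries no current.
    """

    k_mM: float
    na_mM: float = 0.0
    impermeant_mM: float = 0.0

    def __post_init__(self):
        for name in ("k_mM", "na_mM", "impermeant_mM"):
            if getattr(self, name) < 0:
                raise CompositionError(f"{name} must be ≥ 0, got {getattr(self, name)}")

    def permeant_drive_mM(self, alpha: float) -> float:
        """Permeability-weighted cation activity k + alpha·na."""
        return self.k_mM + alpha * self.na_mM


#: Standard oocyte bath (ND96): 96 mM Na⁺, 2 mM K⁺.
ND96 = SolutionComposition(k_mM=2.0, na_mM=96.0)

#: Default Xenopus oocyte cytosol: 108 mM K⁺, 10 mM Na⁺.
OOCYTE_INTERNAL = SolutionComposition(k_mM=108.0, na_mM=10.0)


@dataclass(frozen=True)
class PermeabilityProfile:
    """Channel permeability scale and relative Na⁺ permeability P_Na/P_K."""

    p_k: float = 1.0
    alpha: float = 0.0

    def __post_init__(self):
        if self.p_k <= 0:
            raise ValueError(f"p_k must be > 0, got {self.p_k}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be ≥ 0, got {self.alpha}")


#: Ideal K⁺-selective (wild-type-like) profile.
WT_PROFILE = PermeabilityProfile(p_k=1.0, alpha=0.0)

#: Sodium-leaky mutant profile, P_Na/P_K = 0.20.
MUTANT_PROFILE = PermeabilityProfile(p_k=1.0, alpha=0.20)


def nernst_potential(
    c_out_mM: float, c_in_mM: float, thermal: ThermalContext | None = None
) -> float:
    """Nernst equilibrium potential (mV) for a monovalent cation.

    E = (RT/F)·ln(c_out/c_in); antisymmetric under swapping the two sides.
    """
    thermal = thermal or ThermalContext()
    if c_out_mM <= 0:
        raise CompositionError(f"external concentration must be > 0, got {c_out_mM}")
    if c_in_mM <= 0:
        raise CompositionError(f"internal concentration must be > 0, got {c_in_mM}")
    return thermal.vt_mV * np.log(c_out_mM / c_in_mM)


def ghk_reversal(
    profile: PermeabilityProfile,
    out: SolutionComposition,
    in_: SolutionComposition,
    thermal: ThermalContext | None = None,
) -> float:
    """Bi-ionic GHK reversal potential (mV).

    E_rev = (RT/F)·ln((K_out + α·Na_out) / (K_in + α·Na_in)).  Reduces
    exactly to the K⁺ Nernst potential when ``alpha = 0``.
    """
    thermal = thermal or ThermalContext()
    drive_out = out.permeant_drive_mM(profile.alpha)
    drive_in = in_.permeant_drive_mM(profile.alpha)
    if drive_out <= 0:
        raise CompositionError(
            "no permeant cation drive on the external side (k + alpha*na = "
            f"{drive_out})"
        )
    if drive_in <= 0:
        raise CompositionError(
            "no permeant cation drive on the internal side (k + alpha*na = "
            f"{drive_in})"
        )
    return thermal.vt_mV * np.log(drive_out / drive_in)


def _ghk_species_flux(v_mV, p, c_out_mM, c_in_mM, vt_mV):
    """Constant-field flux for one monovalent cation, outward positive.

    Arbitrary units proportional to permeability × mM.  The v → 0 singularity
    is removed analytically: flux → p·(c_in − c_out).
    """
    u = np.asarray(v_mV, dtype=float) / vt_mV
    small = np.abs(u) < 1e-10
    u_safe = np.where(small, 1.0, u)
    with np.errstate(over="ignore"):
        numer = c_in_mM - c_out_mM * np.exp(-u_safe)
        denom = -np.expm1(-u_safe)
    flux = p * u_safe * numer / denom
    limit = p * (c_in_mM - c_out_mM)
    out = np.where(small, limit, flux)
    return out if out.ndim else float(out)


def ghk_flux(
    v_mV,
    profile: PermeabilityProfile,
    out: SolutionComposition,
    in_: SolutionComposition,
    thermal: ThermalContext | None = None,
):
    """Total GHK current density over K⁺ and Na⁺ (arbitrary units, outward +).

    Continuous at v = 0 and exactly zero at ``ghk_reversal`` of the same
    profile and compositions.  Accepts scalar or array voltages.
    """
    thermal = thermal or ThermalContext()
    vt = thermal.vt_mV
    i_k = _ghk_species_flux(v_mV, profile.p_k, out.k_mM, in_.k_mM, vt)
    i_na = _ghk_species_flux(
        v_mV, profile.p_k * profile.alpha, out.na_mM, in_.na_mM, vt
    )
    return i_k + i_na


@dataclass
class ErevSeries:
    """Reversal potentials measured over a series of external solutions."""

    external: list[SolutionComposition]
    erev_mV: np.ndarray
    internal: SolutionComposition = OOCYTE_INTERNAL
    thermal: ThermalContext = field(default_factory=ThermalContext)

    def __post_init__(self):
        self.erev_mV = np.asarray(self.erev_mV, dtype=float)
        if len(self.external) != len(self.erev_mV):
            raise ValueError("external solutions and erev_mV must align")
        if len(self.external) < 2:
            raise DegenerateDesignError("an ErevSeries needs at least 2 points")

    @property
    def k_out_mM(self) -> np.ndarray:
        return np.array([s.k_mM for s in self.external])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k_out_mM": [s.k_mM for s in self.external],
                "na_out_mM": [s.na_mM for s in self.external],
                "impermeant_out_mM": [s.impermeant_mM for s in self.external],
                "erev_mV": self.erev_mV,
            }
        )

    def to_tsv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path_or_buf,
        internal: SolutionComposition = OOCYTE_INTERNAL,
        thermal: ThermalContext | None = None,
    ) -> "ErevSeries":
        df = pd.read_csv(path_or_buf, sep="\t")
        external = [
            SolutionComposition(
                k_mM=row.k_out_mM,
                na_mM=row.na_out_mM,
                impermeant_mM=row.impermeant_out_mM,
            )
            for row in df.itertuples()
        ]
        return cls(
            external=external,
            erev_mV=df["erev_mV"].to_numpy(),
            internal=internal,
            thermal=thermal or ThermalContext(),
        )


def potassium_substitution_series(
    k_out_values_mM,
    profile: PermeabilityProfile,
    total_cation_mM: float = 98.0,
    internal: SolutionComposition = OOCYTE_INTERNAL,
    thermal: ThermalContext | None = None,
    noise_sd_mV: float = 0.0,
    rng: np.random.Generator | None = None,
    substitute: str = "na",
    n_replicates: int = 1,
) -> ErevSeries:
    """Synthesize an E_rev series under K⁺-for-Na⁺ (or K⁺-for-NMDG⁺) exchange.

    External K⁺ takes the listed values while the substitute cation makes the
    total up to ``total_cation_mM`` (98 mM mimics the standard oocyte bath).
    ``substitute='na'`` reproduces the NaCl→KCl exchange; ``'impermeant'``
    reproduces the Na⁺-free NMDG⁺ series.  Each tabulated E_rev is the mean
    of ``n_replicates`` independent cells, each carrying additive Gaussian
    noise of ``noise_sd_mV``.
    """
    thermal = thermal or ThermalContext()
    if substitute not in ("na", "impermeant"):
        raise ValueError("substitute must be 'na' or 'impermeant'")
    external = []
    for k in k_out_values_mM:
        rest = total_cation_mM - k
        if rest < 0:
            raise CompositionError(
                f"k_out {k} mM exceeds the total cation budget {total_cation_mM} mM"
            )
        if substitute == "na":
            external.append(SolutionComposition(k_mM=k, na_mM=rest))
        else:
            external.append(SolutionComposition(k_mM=k, impermeant_mM=rest))
    erev = np.array(
        [ghk_reversal(profile, sol, internal, thermal) for sol in external]
    )
    if noise_sd_mV > 0:
        rng = rng or np.random.default_rng()
        draws = erev[None, :] + rng.normal(
            0.0, noise_sd_mV, size=(n_replicates, len(erev))
        )
        erev = draws.mean(axis=0)
    return ErevSeries(external=external, erev_mV=erev, internal=internal, thermal=thermal)


def decade_slope(series: ErevSeries) -> float:
    """OLS slope of E_rev against log₁₀[K⁺]ₒ, in mV per decade.

    For an ideally selective channel this is the Nernst slope 2.303·RT/F
    (≈58.4 mV/decade at 294.15 K); sub-Nernstian slopes diagnose
    non-K⁺ permeability.  With exactly two points the slope is
    ΔE_rev / Δlog₁₀[K⁺]ₒ and is independent of the internal composition.
    """
    k = series.k_out_mM
    if np.any(k <= 0):
        raise CompositionError("decade_slope requires strictly positive [K+]o")
    if len(np.unique(k)) < 2:
        raise DegenerateDesignError(
            "decade_slope needs ≥ 2 distinct external K+ concentrations"
        )
    slope, _ = np.polyfit(np.log10(k), series.erev_mV, 1)
    return float(slope)


@dataclass(frozen=True)
class PermeabilityFit:
    """Result of a relative-permeability fit."""

    alpha: float
    stderr: float | None
    ci95: tuple[float, float]
    n_points: int
    residual_rms_mV: float

    @property
    def alpha_percent(self) -> float:
        return 100.0 * self.alpha


def fit_permeability_ratio(series: ErevSeries) -> PermeabilityFit:
    """Least-squares estimate of P_Na/P_K from a reversal-potential series.

    Minimizes Σ(E_rev,measured − E_rev,GHK(α))² over α ≥ 0.  On noiseless
    GHK-generated data the fit recovers the generating α to ≤ 1e-6 relative
    error; the 95% CI is α ± 1.96·SE from the Jacobian.
    """
    params = Parameters()
    params.add("alpha", value=0.1, min=0.0, max=10.0)

    def resid(p):
        a = p["alpha"].value
        prof = PermeabilityProfile(p_k=1.0, alpha=a)
        model = np.array(
            [
                ghk_reversal(prof, sol, series.internal, series.thermal)
                for sol in series.external
            ]
        )
        return model - series.erev_mV

    result = minimize(resid, params, method="leastsq")
    if not result.success:
        raise FitConvergenceError(
            f"permeability-ratio fit did not converge: {result.message}",
            last_iterate=result.params["alpha"].value,
        )
    alpha = float(result.params["alpha"].value)
    stderr = result.params["alpha"].stderr
    if stderr is None or not np.isfinite(stderr):
        # noiseless data: curvature-based SE unavailable; CI collapses
        ci = (alpha, alpha)
        stderr = None
    else:
        stderr = float(stderr)
        ci = (max(0.0, alpha - 1.96 * stderr), alpha + 1.96 * stderr)
    rms = float(np.sqrt(np.mean(result.residual**2)))
    return PermeabilityFit(
        alpha=alpha,
        stderr=stderr,
        ci95=ci,
        n_points=len(series.external),
        residual_rms_mV=rms,
    )
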