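"""Hill dose–response models for TREK-1 activators and blockers.

Activators (BL-1249, arachidonic acid, 2-APB, riluzole) scale the drug-free
current by a fold factor 1 + (fold_max − 1)·cʰ/(cʰ + EC₅₀ʰ); blockers
(fluoxetine, verapamil) leave a remaining fraction 1/(1 + (c/IC₅₀)ʰ).
Fitting is weighted nonlinear least squares on (concentration, fold) tables.

The module also carries the phenomenological selectivity-rescue rule for
BL-1249 on the sodium-leaky I267T mutant: drug occupancy of the activator
site proportionally restores K⁺ selectivity (reduces α toward 0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .ionic_driving import FitConvergenceError, PermeabilityProfile

__all__ = [
    "HillActivationParams",
    "HillInhibitionParams",
    "DoseResponseTable",
    "HillFit",
    "BL1249_WT",
    "BL1249_MUTANT",
    "AA_WT",
    "AA_MUTANT",
    "FLUOXETINE_WT",
    "FLUOXETINE_MUTANT",
    "VERAPAMIL_WT",
    "VERAPAMIL_MUTANT",
    "hill_fold_activation",
    "hill_inhibition",
    "fit_hill",
    "rescue_selectivity",
    "synthesize_dose_response",
]


@dataclass(frozen=True)
class HillActivationParams:
    """Hill activation: EC₅₀ (μM), Hill coefficient, maximal fold increase."""

    ec50_uM: float
    hill_h: float = 1.0
    fold_max: float = 2.0

    def __post_init__(self):
        if self.ec50_uM <= 0:
            raise ValueError("ec50 must be > 0")
        if self.hill_h <= 0:
            raise ValueError("hill coefficient must be > 0")
        if self.fold_max < 1:
            raise ValueError("fold_max must be ≥ 1")


@dataclass(frozen=True)
class HillInhibitionParams:
    """Hill inhibition: IC₅₀ (μM) and Hill coefficient."""

    ic50_uM: float
    hill_h: float = 1.0

    def __post_init__(self):
        if self.ic50_uM <= 0:
            raise ValueError("ic50 must be > 0")
        if self.hill_h <= 0:
            raise ValueError("hill coefficient must be > 0")


# BL-1249 activation (Hill coefficient not reported; h = 1 throughout).
BL1249_WT = HillActivationParams(ec50_uM=12.8, hill_h=1.0, fold_max=35.0)
BL1249_MUTANT = HillActivationParams(ec50_uM=15.2, hill_h=1.0, fold_max=42.4)

# Arachidonic acid activation; maximal fold is a free default (unprinted).
AA_WT = HillActivationParams(ec50_uM=6.9, hill_h=1.0, fold_max=10.0)
AA_MUTANT = HillActivationParams(ec50_uM=3.6, hill_h=1.0, fold_max=10.0)

# Blocker IC50 defaults (unprinted): near the tested concentrations, with a
# 3-fold reduced mutant sensitivity.
FLUOXETINE_WT = HillInhibitionParams(ic50_uM=80.0)
FLUOXETINE_MUTANT = HillInhibitionParams(ic50_uM=240.0)
VERAPAMIL_WT = HillInhibitionParams(ic50_uM=62.0)
VERAPAMIL_MUTANT = HillInhibitionParams(ic50_uM=186.0)


def hill_fold_activation(conc_uM, params: HillActivationParams):
    """Fold change of current at a drug concentration (fold(0) = 1)."""
    c = np.asarray(conc_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be ≥ 0")
    occ = c**params.hill_h / (c**params.hill_h + params.ec50_uM**params.hill_h)
    out = 1.0 + (params.fold_max - 1.0) * occ
    return out if out.ndim else float(out)


def hill_inhibition(conc_uM, params: HillInhibitionParams):
    """Remaining current fraction under a blocker (1 at zero drug)."""
    c = np.asarray(conc_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be ≥ 0")
    out = 1.0 / (1.0 + (c / params.ic50_uM) ** params.hill_h)
    return out if out.ndim else float(out)


@dataclass
class DoseResponseTable:
    """Mean fold-change per concentration with replicate counts."""

    conc_uM: np.ndarray
    fold_change: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        self.fold_change = np.asarray(self.fold_change, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if len(np.unique(self.conc_uM)) != len(self.conc_uM):
            raise ValueError("concentrations must be distinct")
        if np.any(self.conc_uM < 0):
            raise ValueError("concentrations must be ≥ 0")
        if np.any(self.fold_change <= 0):
            raise ValueError("fold changes must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"conc_uM": self.conc_uM, "fold_change": self.fold_change, "n": self.n}
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "DoseResponseTable":
        df = pd.read_csv(path_or_buf)
        return cls(
            conc_uM=df["conc_uM"].to_numpy(),
            fold_change=df["fold_change"].to_numpy(),
            n=df["n"].to_numpy(),
        )


def synthesize_dose_response(
    conc_uM,
    params: HillActivationParams | HillInhibitionParams,
    n_replicates: int = 5,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> DoseResponseTable:
    """Generate a synthetic dose–response table.

    Each tabulated value is the mean of ``n_replicates`` draws carrying
    multiplicative Gaussian noise of coefficient of variation ``noise_cv``
    (5% emulates oocyte-to-oocyte scatter), reproducible under ``seed``.
    """
    conc = np.asarray(conc_uM, dtype=float)
    if isinstance(params, HillActivationParams):
        mean = hill_fold_activation(conc, params)
    else:
        mean = hill_inhibition(conc, params)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        draws = mean[None, :] * (
            1.0 + rng.normal(0.0, noise_cv, size=(n_replicates, len(conc)))
        )
        values = draws.mean(axis=0)
        values = np.maximum(values, 1e-6)
    else:
        values = mean
    return DoseResponseTable(
        conc_uM=conc, fold_change=values, n=np.full(len(conc), n_replicates)
    )


@dataclass(frozen=True)
class HillFit:
    """Hill fit result; params is HillActivationParams or HillInhibitionParams."""

    params: HillActivationParams | HillInhibitionParams
    stderr: dict
    covariance: np.ndarray | None
    fold_max_extrapolated: bool
    ec50_outside_range: bool
    redchi: float

    def to_json_dict(self) -> dict:
        if isinstance(self.params, HillActivationParams):
            rec = {
                "ec50": self.params.ec50_uM,
                "ec50_se": self.stderr.get("ec50"),
                "hill_h": self.params.hill_h,
                "fold_max": self.params.fold_max,
                "fold_max_se": self.stderr.get("fold_max"),
            }
        else:
            rec = {
                "ic50": self.params.ic50_uM,
                "ic50_se": self.stderr.get("ic50"),
                "hill_h": self.params.hill_h,
            }
        rec["fold_max_extrapolated"] = self.fold_max_extrapolated
        rec["ec50_outside_range"] = self.ec50_outside_range
        return rec


def fit_hill(
    table: DoseResponseTable,
    mode: str = "activation",
    vary_h: bool = False,
    log_residuals: bool = True,
) -> HillFit:
    """Weighted nonlinear least-squares Hill fit of a dose–response table.

    Rows are weighted by √n (replicate count).  Residuals are taken on the
    log scale by default, which matches multiplicative (constant-CV)
    measurement scatter and keeps the top of the curve from dominating; set
    ``log_residuals=False`` for additive-error data.  The Hill coefficient
    is fixed at 1 unless ``vary_h`` is set — a handful of concentrations
    rarely constrains it.  The fit is flagged when the half-maximal
    concentration lands outside the tested range by more than 10-fold, and
    when the maximal fold is extrapolated beyond the highest tested
    concentration (occupancy there < 90%).  Noiseless tables are recovered
    exactly (≤ 1e-6 relative).
    """
    if mode not in ("activation", "inhibition"):
        raise ValueError("mode must be 'activation' or 'inhibition'")
    conc = table.conc_uM
    y = table.fold_change
    nz = conc[conc > 0]
    if len(nz) < 4:
        raise ValueError("fit needs ≥ 4 distinct nonzero concentrations")
    if np.ptp(y) < 1e-3 * np.mean(y):
        raise FitConvergenceError(
            "dose-response table is constant; Hill parameters unidentifiable"
        )
    weights = np.sqrt(table.n.astype(float))
    c_mid = float(np.sqrt(nz.min() * nz.max()))

    params = Parameters()
    params.add("log_ec50", value=np.log(c_mid), min=np.log(nz.min() / 1e4),
               max=np.log(nz.max() * 1e4))
    params.add("hill_h", value=1.0, min=0.1, max=10.0, vary=vary_h)
    if mode == "activation":
        params.add("fold_max", value=max(float(y.max()), 1.0 + 1e-6), min=1.0)

    def resid(p):
        ec50 = np.exp(p["log_ec50"].value)
        h = p["hill_h"].value
        if mode == "activation":
            model = hill_fold_activation(
                conc, HillActivationParams(ec50, h, p["fold_max"].value)
            )
        else:
            model = hill_inhibition(conc, HillInhibitionParams(ec50, h))
        if log_residuals:
            return weights * (np.log(model) - np.log(y))
        return weights * (model - y)

    result = minimize(resid, params, method="leastsq")
    if not result.success:
        raise FitConvergenceError(
            f"Hill fit did not converge: {result.message}",
            last_iterate={k: v.value for k, v in result.params.items()},
        )
    ec50 = float(np.exp(result.params["log_ec50"].value))
    h = float(result.params["hill_h"].value)
    log_se = result.params["log_ec50"].stderr
    ec50_se = None if log_se is None else float(ec50 * log_se)

    outside = ec50 < nz.min() / 10 or ec50 > nz.max() * 10
    if mode == "activation":
        fold_max = float(result.params["fold_max"].value)
        fm_se = result.params["fold_max"].stderr
        occ_top = nz.max() ** h / (nz.max() ** h + ec50**h)
        extrapolated = occ_top < 0.9
        fitted = HillActivationParams(ec50_uM=ec50, hill_h=h, fold_max=fold_max)
        stderr = {
            "ec50": ec50_se,
            "hill_h": None if result.params["hill_h"].stderr is None
            else float(result.params["hill_h"].stderr),
            "fold_max": None if fm_se is None else float(fm_se),
        }
    else:
        fitted = HillInhibitionParams(ic50_uM=ec50, hill_h=h)
        extrapolated = False
        stderr = {
            "ic50": ec50_se,
            "hill_h": None if result.params["hill_h"].stderr is None
            else float(result.params["hill_h"].stderr),
        }
    covar = getattr(result, "covar", None)
    return HillFit(
        params=fitted,
        stderr=stderr,
        covariance=covar,
        fold_max_extrapolated=extrapolated,
        ec50_outside_range=outside,
        redchi=float(result.redchi),
    )


def rescue_selectivity(
    profile: PermeabilityProfile,
    drug_conc_uM: float,
    activation: HillActivationParams = BL1249_MUTANT,
    rescue_rule=None,
) -> PermeabilityProfile:
    """Occupancy-proportional restoration of K⁺ selectivity by an activator.

    Default rule: α_effective = α·(1 − occupancy), with occupancy the Hill
    fraction cʰ/(cʰ + EC₅₀ʰ).  At saturating drug α → 0 and the channel's
    decade slope returns to Nernstian, the rescue phenotype seen with
    BL-1249.  A custom ``rescue_rule(alpha, occupancy) -> alpha`` may be
    supplied; its output is clipped to [0, α].
    """
    if drug_conc_uM < 0:
        raise ValueError("drug concentration must be ≥ 0")
    occupancy = drug_conc_uM**activation.hill_h / (
        drug_conc_uM**activation.hill_h + activation.ec50_uM**activation.hill_h
    )
    if rescue_rule is None:
        alpha_eff = profile.alpha * (1.0 - occupancy)
    else:
        alpha_eff = rescue_rule(profile.alpha, occupancy)
    alpha_eff = float(np.clip(alpha_eff, 0.0, profile.alpha))
    return replace(profile, alpha=alpha_eff)
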