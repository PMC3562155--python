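"""Steady-state phosphoryl-flux distribution across the two PTS branches.

For the intact strain taking up fructose, the regulatory branch can feed
phosphoryl groups into fructose phosphorylation through the FruB/PtsN
cross-talk: at steady state ``r1 = r2 = r3 = -r5`` and
``r4 - r5 = r_fru``, so the fraction of the uptake flux provided by the
regulatory (Ntr) branch is ``r3 / r_fru`` and the direct C-branch share
is ``r4 / r_fru``; the two sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .relay import (
    WT,
    Condition,
    ConvergenceError,
    DomainError,
    PtsParameters,
    StrainGenotype,
    detailed_balance_fraction,
    reaction_rates,
    steady_state,
)

#: default overall equilibrium constant of the relay, K1*K2*K3 = K4*K5
DEFAULT_KEQ = 0.02
#: default cross-talk equilibrium constant (FruB ~ PtsN)
DEFAULT_K5 = 654.6
#: default PEP/pyruvate ratios per growth condition
DEFAULT_PP = {"CAA": 1.0, "CAA_fructose": 0.49, "CAA_glucose": 0.05}


class UndefinedShareError(ValueError):
    """Branch shares are undefined when no fructose is taken up."""


@dataclass(frozen=True)
class BranchFluxResult:
    """Net steady-state rates plus the branch attribution of the uptake flux."""

    r1: float
    r2: float
    r3: float
    r4: float
    r5: float
    r_fru: float
    ntr_share: float | None
    c_share: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k) for k in
                ("r1", "r2", "r3", "r4", "r5", "r_fru", "ntr_share", "c_share")}


def steady_branch_fluxes(params: PtsParameters, pp: float | None = None,
                         r_fru: float | None = None) -> BranchFluxResult:
    """Solve the intact-strain steady state and attribute the uptake flux.

    Parameters may carry ``pp``/``r_fru`` themselves or have them
    overridden here.  With ``r_fru = 0`` all net rates vanish and the
    shares are flagged as undefined (``None``).
    """
    if pp is not None or r_fru is not None:
        params = replace(params,
                         pp=params.pp if pp is None else pp,
                         r_fru=params.r_fru if r_fru is None else r_fru)
    if not params.is_thermodynamically_closed(1e-9):
        raise DomainError(
            "branch-flux attribution requires a thermodynamically closed "
            f"parameter set (cycle gap {params.cycle_gap:.2e})")
    state = steady_state(params, WT)
    r = reaction_rates(state, params, WT)
    if params.r_fru > 0:
        share_n = r.r3 / params.r_fru
        share_c = r.r4 / params.r_fru
    else:
        share_n = share_c = None
    return BranchFluxResult(r.r1, r.r2, r.r3, r.r4, r.r5, r.r_fru,
                            share_n, share_c)


def ntr_share(result: BranchFluxResult) -> float:
    """Fraction of the fructose phosphorylation flux routed via PtsN (r3/r_fru)."""
    if result.r_fru <= 0 or result.ntr_share is None:
        raise UndefinedShareError("ntr share undefined for r_fru = 0")
    return result.ntr_share


def fruB_quasi_equilibrium_fraction(Keq: float, K5: float, pp: float) -> float:
    """Phosphorylated FruB fraction when reaction r4 is at equilibrium.

    Cycle closure forces ``K4 = Keq / K5``; a large cross-talk constant
    ``K5`` therefore makes ``K4`` small, i.e. gives PEP a high affinity
    for FruB, and the equilibrium fraction ``(pp/K4) / (1 + pp/K4)``
    approaches one.
    """
    if Keq <= 0 or K5 <= 0 or pp <= 0:
        raise DomainError("Keq, K5 and pp must all be positive")
    return detailed_balance_fraction(pp, Keq / K5)


def rescale_fluxes(scaled_fluxes: Mapping[str, float],
                   reference_concentrations: Mapping[str, float]
                   ) -> dict[str, float]:
    """Convert scaled rates to absolute fluxes via reference concentrations.

    Pure unit conversion: each scaled rate is multiplied by its reference
    (a concentration/time factor per reaction).  Every flux must have a
    reference entry.
    """
    missing = sorted(set(scaled_fluxes) - set(reference_concentrations))
    if missing:
        raise KeyError(f"missing reference concentrations for: {missing}")
    return {k: v * reference_concentrations[k] for k, v in scaled_fluxes.items()}


def unscale_fluxes(absolute_fluxes: Mapping[str, float],
                   reference_concentrations: Mapping[str, float]
                   ) -> dict[str, float]:
    """Inverse of :func:`rescale_fluxes`."""
    missing = sorted(set(absolute_fluxes) - set(reference_concentrations))
    if missing:
        raise KeyError(f"missing reference concentrations for: {missing}")
    return {k: v / reference_concentrations[k] for k, v in absolute_fluxes.items()}


# ---------------------------------------------------------------------------
# shipped default calibration
# ---------------------------------------------------------------------------

def _mutant_fructose_fraction(params: PtsParameters) -> float:
    """PtsN fraction of a regulatory-branch knockout under fructose uptake."""
    state = steady_state(params, StrainGenotype("delta_ptsP"))
    return state.ptsN_p


@lru_cache(maxsize=8)
def calibrated_parameters(target_ntr_share: float = 0.78,
                          target_mutant_fraction: float = 0.5,
                          Keq: float = DEFAULT_KEQ, K5: float = DEFAULT_K5,
                          pp: float = DEFAULT_PP["CAA_fructose"]
                          ) -> PtsParameters:
    """Default velocity-constant calibration for the fructose condition.

    The equilibrium constants are fixed at the estimated values; the
    velocity constants of the relay chain and of the cross-talk are set
    to 1 (scaled time unit) and the two remaining degrees of freedom --
    the C-branch velocity constant ``k4`` and the fructose uptake rate
    ``r_fru`` -- are solved so that (i) the regulatory branch provides
    ``target_ntr_share`` of the uptake flux and (ii) a relay-chain
    knockout shows the mid-range PtsN phosphorylation characteristic of
    the cross-talk under fructose growth.  This is a calibration of the
    unidentifiable velocity scale, not an independent estimate.
    """

    def share_at(k4: float, r_fru: float) -> float:
        p = PtsParameters.from_equilibrium(Keq, K5, pp=pp, k4=k4, r_fru=r_fru)
        try:
            return steady_branch_fluxes(p).ntr_share
        except ConvergenceError:
            # a C branch too weak to sustain the uptake: the chain would
            # have to provide more than everything
            return 1.0

    def k4_for_share(r_fru: float) -> float:
        f = lambda log_k4: share_at(10.0 ** log_k4, r_fru) - target_ntr_share
        return 10.0 ** brentq(f, -4.0, 6.0, xtol=1e-13)

    def mutant_gap(log_rfru: float) -> float:
        r_fru = 10.0 ** log_rfru
        k4 = k4_for_share(r_fru)
        p = PtsParameters.from_equilibrium(Keq, K5, pp=pp, k4=k4, r_fru=r_fru)
        return _mutant_fructose_fraction(p) - target_mutant_fraction

    log_rfru = brentq(mutant_gap, -6.0, -0.8, xtol=1e-12)
    r_fru = 10.0 ** log_rfru
    k4 = k4_for_share(r_fru)
    return PtsParameters.from_equilibrium(Keq, K5, pp=pp, k4=k4, r_fru=r_fru)
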