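"""Synthetic datasets with the statistical structure the analysis assumes.

Wet-lab inputs of the pipeline are (a) PtsN phosphorylation fractions
per strain and growth condition, (b) flux summaries at the PEP/pyruvate
node, and (c) a stoichiometric network.  This module generates all
three: phosphorylation tables are forward-model steady states with
multiplicative relative noise (the experimental relative errors lie
between 5% and 30%), flux tables are jittered copies of a reference
summary, and the toy central-carbon network mirrors the catabolic map
around the PEP/pyruvate hub.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import branch
from .fba import MetabolicNetwork, Reaction
from .relay import (
    Condition,
    ConvergenceError,
    DomainError,
    PtsParameters,
    StrainGenotype,
    steady_state,
)

#: the strains of the measurement grid (the PtsN knockout itself is
#: omitted by default: its readout is identically zero)
DEFAULT_STRAINS: tuple[str, ...] = ("WT", "delta_ptsP", "delta_ptsO", "delta_fruB")

NOISE_SD_BAND = (0.05, 0.30)


def default_conditions(params: PtsParameters | None = None) -> dict[str, Condition]:
    """The three growth conditions at the estimated PEP/pyruvate ratios."""
    if params is None:
        params = branch.calibrated_parameters()
    return {
        "CAA": Condition.caa(pp=branch.DEFAULT_PP["CAA"]),
        "CAA_fructose": Condition.caa_fructose(
            pp=branch.DEFAULT_PP["CAA_fructose"], r_fru=params.r_fru),
        "CAA_glucose": Condition.caa_glucose(pp=branch.DEFAULT_PP["CAA_glucose"]),
    }


@dataclass
class SyntheticDesign:
    """Ground truth and noise model for a synthetic measurement table.

    ``noise_model`` selects how the relative error ``noise_sd`` is
    realised on a bounded fraction:

    ``"band"`` (default)
        Log-odds (band-ratio) noise: the phosphorylated to
        unphosphorylated band-intensity ratio of the blot is measured
        with lognormal error, ``sd(log odds) = 2 * noise_sd``, chosen so
        that a mid-range fraction (1/2) has relative standard deviation
        exactly ``noise_sd``.  Near-saturated fractions are
        automatically more precise, as intensity ratios make them; the
        sample median equals the true value at every fraction.
    ``"beta"``
        Moment-matched beta noise: mean preserved exactly, standard
        deviation ``noise_sd * fraction`` (where representable in
        [0, 1]).
    ``"gaussian"``
        Multiplicative Gaussian noise truncated to [0, 1]; simplest, but
        truncation shifts the mean of near-saturated fractions.

    Identical seeds give bit-identical output.
    """

    cells: list[tuple[str, str]] = field(default_factory=lambda: [
        (s, c) for c in ("CAA", "CAA_fructose", "CAA_glucose")
        for s in DEFAULT_STRAINS])
    params: PtsParameters | None = None
    conditions: dict[str, Condition] | None = None
    noise_sd: float | Mapping[tuple[str, str], float] = 0.05
    noise_model: str = "band"
    seed: int = 0

    def __post_init__(self):
        if self.params is None:
            self.params = branch.calibrated_parameters()
        if self.conditions is None:
            self.conditions = default_conditions(self.params)
        if self.noise_model not in ("band", "beta", "gaussian"):
            raise DomainError(f"unknown noise model {self.noise_model!r}")
        for sd in self._sd_values():
            if sd < 0:
                raise DomainError("noise sd must be >= 0")
            if sd and not (NOISE_SD_BAND[0] <= sd <= NOISE_SD_BAND[1]):
                import logging
                logging.getLogger(__name__).info(
                    "noise sd %.3g outside the typical experimental band "
                    "[%.2f, %.2f]", sd, *NOISE_SD_BAND)

    def _sd_values(self):
        if isinstance(self.noise_sd, Mapping):
            return list(self.noise_sd.values())
        return [self.noise_sd]

    def sd_for(self, cell: tuple[str, str]) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd[cell])
        return float(self.noise_sd)


def _noisy_fraction(true: float, sd: float, model: str,
                    rng: np.random.Generator) -> float:
    """One noisy measurement of a fraction, kept inside [0, 1]."""
    if sd == 0 or true == 0 or true == 1:
        return true
    if model == "band":
        logodds = math.log(true / (1.0 - true)) + 2.0 * sd * rng.standard_normal()
        return float(1.0 / (1.0 + math.exp(-logodds)))
    var = (sd * true) ** 2
    cap = true * (1.0 - true)
    if model == "beta" and var < 0.95 * cap:
        # moment-matched beta: mean = true, sd = sd * true
        nu = cap / var - 1.0
        return float(rng.beta(true * nu, (1.0 - true) * nu))
    # "gaussian" (and beta fallback where the beta moments are not
    # representable): multiplicative Gaussian, truncated to [0, 1]
    return float(np.clip(true * (1.0 + sd * rng.standard_normal()), 0.0, 1.0))


def generate_phospho_dataset(design: SyntheticDesign) -> pd.DataFrame:
    """Forward steady-state PtsN fractions plus per-cell relative noise.

    Returns the measurement-table layout consumed by the fitting module:
    columns ``strain``, ``condition``, ``ptsN_fraction``, ``rel_error``.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for strain, cond_label in design.cells:
        cond = design.conditions[cond_label]
        try:
            state = steady_state(design.params, StrainGenotype(strain), cond)
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"forward solve failed for cell ({strain}, {cond_label}): {exc}"
            ) from exc
        sd = design.sd_for((strain, cond_label))
        value = _noisy_fraction(state.ptsN_p, sd, design.noise_model, rng)
        rows.append({"strain": strain, "condition": cond_label,
                     "ptsN_fraction": value, "rel_error": sd if sd > 0 else np.nan})
    return pd.DataFrame(rows)


def reference_flux_table() -> pd.DataFrame:
    """Nominal and FVA min/max fluxes at the PEP/pyruvate node.

    The four lumped reactions around the node for growth on casamino
    acids with and without fructose (flux units mmol gDW^-1 h^-1), used
    to calibrate the power-law node kinetics.
    """
    rows = [
        ("CAA", "oaa_to_pyr", 6.32, 6.18, 6.35),
        ("CAA", "pyr_to_accoa", 1.83, 1.68, 1.85),
        ("CAA", "pyr_to_pep", 4.00, 3.96, 4.01),
        ("CAA", "pep_to_2pg", 3.73, 3.68, 3.78),
        ("CAA_fructose", "oaa_to_pyr", 4.69, 4.59, 4.71),
        ("CAA_fructose", "pyr_to_accoa", 1.47, 1.36, 1.49),
        ("CAA_fructose", "pyr_to_pep", 2.93, 2.90, 2.97),
        ("CAA_fructose", "pep_to_2pg", 2.64, 2.61, 2.68),
    ]
    return pd.DataFrame(rows, columns=["condition", "reaction",
                                       "nominal", "min", "max"])


def generate_flux_table(base: pd.DataFrame | None = None,
                        rel_jitter: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Jittered copy of a flux-summary table with consistent envelopes.

    Nominal fluxes receive multiplicative Gaussian jitter; min/max are
    shifted by the same factor and then re-clamped so the sandwich
    ``min <= nominal <= max`` always holds.
    """
    if base is None:
        base = reference_flux_table()
    if (base["nominal"] == 0).any():
        raise DomainError("nominal fluxes must be nonzero")
    out = base.copy().reset_index(drop=True)
    if rel_jitter == 0:
        return out
    rng = np.random.default_rng(seed)
    factor = 1.0 + rel_jitter * rng.standard_normal(len(out))
    out["nominal"] = base["nominal"] * factor
    out["min"] = np.minimum(base["min"] * factor, out["nominal"])
    out["max"] = np.maximum(base["max"] * factor, out["nominal"])
    return out


def make_toy_network(uptake_limit: float = 10.0, ngam: float = 0.0,
                     atp_per_tca: float = 2.0) -> MetabolicNetwork:
    """Toy central-carbon network around the PEP/pyruvate hub.

    Fructose (PTS-coupled), glucose and casamino acids (entering at
    oxaloacetate) feed a network where PEP and pyruvate distribute all
    incoming flux: pyruvate kinase and PEP synthase interconvert the two
    hubs, pyruvate drains to acetyl-CoA, and biomass consumes the four
    precursor pools plus ATP.  A maintenance reaction burns ATP at a
    fixed rate.
    """
    inf = 1e6
    rxns = [
        Reaction("EX_fru", {"fru": 1.0}, 0.0, uptake_limit),
        Reaction("EX_glc", {"glc": 1.0}, 0.0, uptake_limit),
        Reaction("EX_caa", {"caa": 1.0}, 0.0, uptake_limit),
        Reaction("caa_to_oaa", {"caa": -1.0, "oaa": 1.0}, 0.0, inf),
        # fructose PTS: the phosphoryl group comes from PEP
        Reaction("pts_fru", {"fru": -1.0, "pep": -1.0, "f1p": 1.0, "pyr": 1.0},
                 0.0, inf),
        Reaction("f1p_glycolysis", {"f1p": -1.0, "pep": 2.0, "atp": 1.0}, 0.0, inf),
        Reaction("glc_ed", {"glc": -1.0, "pep": 1.0, "pyr": 1.0}, 0.0, inf),
        Reaction("pyk", {"pep": -1.0, "pyr": 1.0, "atp": 1.0}, 0.0, inf),
        Reaction("pps", {"pyr": -1.0, "atp": -1.0, "pep": 1.0}, 0.0, inf),
        Reaction("ppc", {"pep": -1.0, "oaa": 1.0}, 0.0, inf),
        Reaction("oaa_to_pyr", {"oaa": -1.0, "pyr": 1.0}, 0.0, inf),
        Reaction("pdh", {"pyr": -1.0, "accoa": 1.0}, 0.0, inf),
        Reaction("tca", {"accoa": -1.0, "atp": atp_per_tca}, 0.0, inf),
        Reaction("ngam", {"atp": -1.0}, ngam, inf),
        Reaction("biomass", {"pep": -1.0, "pyr": -1.0, "oaa": -1.0,
                             "accoa": -1.0, "atp": -2.0}, 0.0, inf),
    ]
    return MetabolicNetwork(rxns, biomass_id="biomass", ngam_id="ngam",
                            exchange_ids=("EX_fru", "EX_glc", "EX_caa"))
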