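"""Constraint-based estimation of the phosphorelay's equilibrium constants.

The estimation problem mirrors the structure of the measured data: the
degree of phosphorylation of PtsN across strain knockouts and growth
conditions.  Knockouts break the relay at known points, so each
strain x condition cell constrains a small, known subset of parameters
(the per-cell equilibrium restrictions).  The fit enforces the
thermodynamic cycle constraint ``K1*K2*K3 = K4*K5`` exactly by
parameterising the relay with the overall constant ``Keq`` and the
cross-talk constant ``K5`` (so ``K4 = Keq/K5``); individual chain
constants are pure convention (``K1 = K2 = K3 = Keq**(1/3)``) because
only their product is identifiable from detailed-balance data.

Free parameters: ``Keq``, ``K5``, one PEP/pyruvate ratio ``pp`` per
non-reference condition (the CAA reference is fixed, conventionally at
1.0), and the C-branch velocity constant ``k4`` as a nuisance whenever
flux-carrying fructose cells are in the data.  The fructose uptake rate
enters as a known design quantity (it is measured); it can optionally be
freed as a second nuisance parameter.

The public surface follows the Model / Results pattern:

>>> model = PtsPhosphorylationModel(measurements)      # doctest: +SKIP
>>> res = model.fit(seed=0)                            # doctest: +SKIP
>>> print(res.summary())                               # doctest: +SKIP
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import branch
from .relay import (
    CONDITION_LABELS,
    STRAIN_LABELS,
    WT,
    Condition,
    ConvergenceError,
    DomainError,
    PtsParameters,
    StrainGenotype,
    _wt_fructose_steady,
    detailed_balance_fraction,
    steady_state,
)

_PENALTY = 1e3
_DEFAULT_REL_ERROR = 0.10

#: log10 bounds of the fitted parameters
_BOUNDS = {
    "Keq": (-6.0, 2.0),
    "K5": (-2.0, 6.0),
    "pp": (-3.0, 2.0),
    "k4": (-3.0, 3.0),
    "r_fru": (-3.0, 3.0),
}


class IdentifiabilityError(ValueError):
    """The measurement table does not constrain the requested parameters."""


# ---------------------------------------------------------------------------
# per-cell equilibrium restrictions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquilibriumRelationSet:
    """Reactions at individual equilibrium vs carrying flux for one cell."""

    strain: str
    condition: str
    at_equilibrium: frozenset[str]
    carrying_flux: frozenset[str]
    removed: frozenset[str]
    none_in_equilibrium: bool = False


# the restriction sets used for parameter determination, one per
# strain x condition cell of the estimation design (the wild type under
# fructose uptake has no reaction in individual equilibrium and is
# therefore flagged rather than listed)
_TABLE_RESTRICTIONS: dict[tuple[str, str], frozenset[str]] = {
    ("WT", "CAA"): frozenset({"r1", "r2", "r3"}),
    ("delta_ptsP", "CAA"): frozenset({"r3", "r4", "r5"}),
    ("delta_ptsO", "CAA"): frozenset({"r1", "r4", "r5"}),
    ("delta_fruB", "CAA"): frozenset({"r1", "r2", "r3"}),
    ("WT", "CAA_fructose"): frozenset(),
    ("delta_ptsP", "CAA_fructose"): frozenset({"r3", "r5"}),
    ("delta_ptsO", "CAA_fructose"): frozenset({"r1", "r5"}),
    ("delta_fruB", "CAA_fructose"): frozenset({"r1", "r2", "r3"}),
}

_FLUX_CARRIERS: dict[tuple[str, str], frozenset[str]] = {
    ("WT", "CAA_fructose"): frozenset({"r1", "r2", "r3", "r4", "r5", "r_fru"}),
    ("delta_ptsP", "CAA_fructose"): frozenset({"r4", "r_fru"}),
    ("delta_ptsO", "CAA_fructose"): frozenset({"r4", "r_fru"}),
}


def equilibrium_relations(genotype: StrainGenotype | str,
                          condition: Condition | str) -> EquilibriumRelationSet:
    """Which reactions are at individual equilibrium in a given cell.

    For the eight cells of the estimation design the tabulated
    restriction sets are returned verbatim; any other strain/condition
    combination falls back to the generic rule (every reaction not
    removed and not on a flux-carrying path is at equilibrium).
    """
    strain = genotype.label if isinstance(genotype, StrainGenotype) else genotype
    cond = condition.label if isinstance(condition, Condition) else condition
    if strain not in STRAIN_LABELS:
        raise DomainError(f"unknown strain {strain!r}")
    if cond not in CONDITION_LABELS:
        raise DomainError(f"unknown condition {cond!r}")

    removed = StrainGenotype(strain).removed_reactions
    key = (strain, cond)
    if key in _TABLE_RESTRICTIONS:
        eq = _TABLE_RESTRICTIONS[key]
        flux = _FLUX_CARRIERS.get(key, frozenset())
        return EquilibriumRelationSet(
            strain, cond, eq, flux, removed,
            none_in_equilibrium=(not eq and key == ("WT", "CAA_fructose")))

    # generic fallback: without uptake everything intact equilibrates;
    # with uptake the C branch carries flux and the cross-talk balances it
    all_rxn = frozenset({"r1", "r2", "r3", "r4", "r5"})
    active = all_rxn - removed
    has_uptake = (cond == "CAA_fructose" and "r_fru" not in removed)
    if not has_uptake:
        return EquilibriumRelationSet(strain, cond, active, frozenset(), removed)
    flux = (active | {"r_fru"}) if strain == "WT" else frozenset({"r4", "r_fru"})
    eq = active - flux
    return EquilibriumRelationSet(strain, cond, eq, flux, removed,
                                  none_in_equilibrium=(strain == "WT"))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

def _default_conditions() -> dict[str, Condition]:
    rf = branch.calibrated_parameters().r_fru
    return {
        "CAA": Condition.caa(),
        "CAA_fructose": Condition.caa_fructose(r_fru=rf),
        "CAA_glucose": Condition.caa_glucose(),
    }


class PtsPhosphorylationModel:
    """Weighted least-squares model for PtsN phosphorylation measurements.

    Parameters
    ----------
    data:
        DataFrame with columns ``strain``, ``condition``,
        ``ptsN_fraction`` and optionally ``rel_error`` (relative
        measurement error, defaulting to 0.10 where absent).
    conditions:
        Mapping from condition label to :class:`~ptsflux.relay.Condition`
        carrying the design quantities (``pp`` entries are ignored for
        fitted conditions; ``r_fru`` is the known uptake rate of the
        fructose condition).
    pp_reference:
        The PEP/pyruvate ratio of the CAA reference condition, fixed by
        convention (default 1.0).
    chain_split:
        Exponents ``(a, b, c)`` with ``a+b+c = 1`` allocating the overall
        constant to ``K1, K2, K3 = Keq**a, Keq**b, Keq**c``.  A pure
        convention; it only matters for the (flux-carrying) wild-type
        fructose cell.
    k4_reference:
        The C-branch velocity constant, in the scaled time units of the
        relay.  Phosphorylation data alone identify only the ratio
        ``K5 / k4`` (the flux-carrying cells respond to ``K5 * r_fru /
        k4``), so the velocity scale is taken from the flux analysis:
        by default the package's calibrated value.  Pass ``k4_free=True``
        to :meth:`fit` to treat it as a bounded nuisance instead, at the
        cost of leaving ``K5`` undetermined along the ridge.
    residual_scale:
        ``"logit"`` (default) compares predicted and measured fractions
        on the log-odds scale, where band-ratio measurements are
        homoscedastic with standard deviation ``2 * rel_error``;
        ``"linear"`` uses plain weighted differences of the fractions.
        Cells with a measured or predicted value of exactly 0 or 1 fall
        back to the linear residual.
    """

    def __init__(self, data: pd.DataFrame,
                 conditions: Mapping[str, Condition] | None = None,
                 pp_reference: float = 1.0,
                 chain_split: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
                 k4_reference: float | None = None,
                 residual_scale: str = "logit",
                 allow_partial: bool = False):
        if residual_scale not in ("logit", "linear"):
            raise DomainError(f"unknown residual scale {residual_scale!r}")
        self.residual_scale = residual_scale
        self.allow_partial = bool(allow_partial)
        self.data = self._validate_data(data)
        self.conditions = dict(conditions) if conditions is not None \
            else _default_conditions()
        self.pp_reference = float(pp_reference)
        self.k4_reference = float(k4_reference) if k4_reference is not None \
            else branch.calibrated_parameters().k4
        if abs(sum(chain_split) - 1.0) > 1e-12 or len(chain_split) != 3:
            raise DomainError("chain_split must be three exponents summing to 1")
        self.chain_split = tuple(float(a) for a in chain_split)

        present = set(self.data["condition"])
        missing_design = present - set(self.conditions)
        if missing_design:
            raise DomainError(f"no design Condition given for {sorted(missing_design)}")
        #: conditions whose pp is a free parameter (all but the reference)
        self.fitted_pp_conditions = sorted(present - {"CAA"})
        self._has_flux_cells = self._check_identifiability()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "PtsPhosphorylationModel":
        return cls(data, **kwargs)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "PtsPhosphorylationModel":
        from .io import read_measurements
        return cls(read_measurements(path), **kwargs)

    @staticmethod
    def _validate_data(data: pd.DataFrame) -> pd.DataFrame:
        required = {"strain", "condition", "ptsN_fraction"}
        missing = required - set(data.columns)
        if missing:
            raise DomainError(f"measurement table lacks columns {sorted(missing)}")
        data = data.copy().reset_index(drop=True)
        if "rel_error" not in data.columns:
            data["rel_error"] = np.nan
        bad = ~data["strain"].isin(STRAIN_LABELS)
        if bad.any():
            raise DomainError(
                f"unknown strain labels {sorted(set(data.loc[bad, 'strain']))}; "
                f"allowed: {list(STRAIN_LABELS)}")
        bad = ~data["condition"].isin(CONDITION_LABELS)
        if bad.any():
            raise DomainError(
                f"unknown condition labels {sorted(set(data.loc[bad, 'condition']))}; "
                f"allowed: {list(CONDITION_LABELS)}")
        frac = data["ptsN_fraction"].to_numpy(float)
        if np.any((frac < 0) | (frac > 1)) or np.any(~np.isfinite(frac)):
            raise DomainError("ptsN_fraction values must lie in [0, 1]")
        dn = data["strain"] == "delta_ptsN"
        if np.any(data.loc[dn, "ptsN_fraction"] != 0):
            raise DomainError("delta_ptsN rows must have ptsN_fraction = 0")
        return data

    def _check_identifiability(self) -> bool:
        cells = set(zip(self.data["strain"], self.data["condition"]))
        missing = []
        if not cells & {("WT", "CAA"), ("delta_fruB", "CAA")}:
            missing.append("WT or delta_fruB on CAA (pins Keq)")
        has_fru = any(c == "CAA_fructose" for _, c in cells)
        if has_fru:
            if not cells & {("WT", "CAA_fructose"), ("delta_fruB", "CAA_fructose")}:
                missing.append("WT or delta_fruB on CAA_fructose (pins pp)")
        has_flux = bool(cells & {("WT", "CAA_fructose"),
                                 ("delta_ptsP", "CAA_fructose"),
                                 ("delta_ptsO", "CAA_fructose")})
        if has_fru and not cells & {("delta_ptsP", "CAA_fructose"),
                                    ("delta_ptsO", "CAA_fructose")}:
            if not self.allow_partial:
                missing.append("delta_ptsP or delta_ptsO on CAA_fructose "
                               "(pins the cross-talk constant K5)")
        if missing:
            raise IdentifiabilityError(
                "measurement table under-determines the fit; missing cells: "
                + "; ".join(missing))
        return has_flux

    # -- forward predictions -------------------------------------------------

    def _chain_constants(self, Keq: float) -> tuple[float, float, float]:
        a, b, c = self.chain_split
        return Keq ** a, Keq ** b, Keq ** c

    def predict_cell(self, strain: str, condition: str, Keq: float, K5: float,
                     pp: float, k4: float = 1.0, r_fru: float | None = None
                     ) -> float:
        """Steady-state PtsN fraction of one cell under the fit conventions.

        Relay velocity constants are 1 in scaled time units; ``k4`` and
        the uptake rate apply only to flux-carrying fructose cells.
        Returns NaN when no steady state exists for the arguments.
        """
        if strain == "delta_ptsN":
            return 0.0
        cond = self.conditions[condition]
        rf = cond.r_fru if r_fru is None else r_fru
        if cond.label != "CAA_fructose" or rf == 0 or strain == "delta_fruB":
            # every intact path to PtsN is at detailed balance
            return detailed_balance_fraction(pp, Keq)
        if strain in ("delta_ptsP", "delta_ptsO"):
            # relay chain broken: r5 balances, r4 carries the whole uptake
            pep = pp / (1.0 + pp)
            pyr = 1.0 - pep
            K4 = Keq / K5
            f = (pep - rf / k4) / (pep + K4 * pyr)
            if not 0.0 < f < 1.0:
                return math.nan
            phi = f / ((1.0 - f) * K5)
            return phi / (1.0 + phi)
        # intact strain under uptake: full steady state
        params = PtsParameters(
            K1=self._chain_constants(Keq)[0], K2=self._chain_constants(Keq)[1],
            K3=self._chain_constants(Keq)[2], K4=Keq / K5, K5=K5,
            k4=k4, pp=pp, r_fru=rf)
        try:
            return _wt_fructose_steady(params).ptsN_p
        except (ConvergenceError, DomainError):
            return math.nan

    # -- fitting -------------------------------------------------------------

    def _theta_names(self, k4_free: bool, r_fru_free: bool) -> list[str]:
        names = ["Keq"]
        if self._has_flux_cells:
            names.append("K5")
        names += [f"pp_{c}" for c in self.fitted_pp_conditions]
        if self._has_flux_cells:
            if k4_free:
                names.append("k4")
            if r_fru_free:
                names.append("r_fru")
        return names

    def _unpack(self, x: np.ndarray, names: list[str]) -> dict[str, float]:
        theta = {n: 10.0 ** v for n, v in zip(names, x)}
        theta.setdefault("K5", math.nan)
        theta.setdefault("k4", self.k4_reference)
        return theta

    def _cell_residual(self, pred: float, meas: float, rel_error: float) -> float:
        w = rel_error if np.isfinite(rel_error) and rel_error > 0 \
            else _DEFAULT_REL_ERROR
        if math.isnan(pred):
            return _PENALTY
        if (self.residual_scale == "logit"
                and 0.0 < meas < 1.0 and 0.0 < pred < 1.0):
            return (math.log(pred / (1 - pred)) - math.log(meas / (1 - meas))) \
                / (2.0 * w)
        return (pred - meas) / w

    def _residuals(self, theta: Mapping[str, float]) -> np.ndarray:
        pp_by_cond = {"CAA": self.pp_reference}
        for c in self.fitted_pp_conditions:
            pp_by_cond[c] = theta[f"pp_{c}"]
        rf = theta.get("r_fru")
        out = np.empty(len(self.data))
        for i, row in enumerate(self.data.itertuples(index=False)):
            pred = self.predict_cell(
                row.strain, row.condition, theta["Keq"], theta["K5"],
                pp_by_cond[row.condition], theta["k4"], r_fru=rf)
            out[i] = self._cell_residual(pred, row.ptsN_fraction, row.rel_error)
        return out

    def fit(self, n_starts: int = 8, seed: int = 0, k4_free: bool = False,
            r_fru_free: bool = False) -> "PtsFitResults":
        """Multistart trust-region weighted least squares.

        One heuristic start is derived by inverting the detailed-balance
        cells; ``n_starts`` additional log-uniform starts guard against
        local minima.  The best final cost wins.  ``k4_free`` /
        ``r_fru_free`` add the C-branch velocity constant and the uptake
        rate as bounded nuisance parameters (see the class docstring for
        the identifiability caveat).
        """
        names = self._theta_names(k4_free, r_fru_free)
        rng = np.random.default_rng(seed)
        lo = np.array([_BOUNDS[n.split("_")[0] if n.startswith("pp_") else n][0]
                       for n in names])
        hi = np.array([_BOUNDS[n.split("_")[0] if n.startswith("pp_") else n][1]
                       for n in names])

        starts = [self._heuristic_start(names)]
        for _ in range(n_starts):
            starts.append(lo + (hi - lo) * rng.uniform(size=len(names)))

        eval_log: list[float] = []

        def fun(x: np.ndarray) -> np.ndarray:
            r = self._residuals(self._unpack(x, names))
            eval_log.append(float(np.dot(r, r)))
            return r

        best = None
        start_costs = []
        for x0 in starts:
            sol = least_squares(fun, np.clip(x0, lo, hi), bounds=(lo, hi),
                                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
            start_costs.append(float(sol.cost))
            if best is None or sol.cost < best.cost:
                best = sol
        theta = self._unpack(best.x, names)
        return PtsFitResults(self, names, best, theta, start_costs, eval_log,
                             r_fru_free)

    def _heuristic_start(self, names: list[str]) -> np.ndarray:
        """Initial guess from inverting the detailed-balance cells."""
        d = self.data

        def phi_of(mask) -> float | None:
            vals = d.loc[mask, "ptsN_fraction"].to_numpy(float)
            vals = vals[(vals > 1e-6) & (vals < 1 - 1e-6)]
            if not len(vals):
                return None
            m = float(np.median(vals))
            return m / (1.0 - m)

        phi_caa = phi_of((d["condition"] == "CAA")
                         & d["strain"].isin(["WT", "delta_fruB"]))
        Keq0 = self.pp_reference / phi_caa if phi_caa else 0.05
        start = {"Keq": Keq0, "K5": 100.0, "k4": 10.0, "r_fru": 0.05}
        for c in self.fitted_pp_conditions:
            phi_c = phi_of((d["condition"] == c)
                           & d["strain"].isin(["WT", "delta_fruB"]))
            start[f"pp_{c}"] = Keq0 * phi_c if phi_c else 0.5
        return np.array([math.log10(start[n]) for n in names])


class PtsFitResults:
    """Estimates, diagnostics and prediction for a fitted phosphorelay model.

    Attributes
    ----------
    Keq, K5, k4, pp : fitted values (``K5``/``k4`` are NaN when the data
        contain no flux-carrying cells); ``pp`` maps condition labels to
        PEP/pyruvate ratios, including the fixed reference.
    """

    def __init__(self, model: PtsPhosphorylationModel, names: list[str],
                 solution, theta: dict[str, float], start_costs: list[float],
                 eval_log: list[float], r_fru_free: bool):
        self.model = model
        self.param_names = names
        self._solution = solution
        self.theta = theta
        self.start_costs = start_costs
        self._eval_log = eval_log
        self.r_fru_free = r_fru_free

        self.Keq = theta["Keq"]
        self.K5 = theta["K5"]
        self.k4 = theta["k4"]
        self.pp = {"CAA": model.pp_reference}
        for c in model.fitted_pp_conditions:
            self.pp[c] = theta[f"pp_{c}"]
        self.r_fru = theta.get(
            "r_fru",
            {c.label: c.r_fru for c in model.conditions.values()}.get(
                "CAA_fructose", 0.0))
        self.cost = float(solution.cost)
        self.resid = np.asarray(solution.fun)
        self.fittedvalues = self._predictions()
        self.bse_log10 = self._log10_standard_errors()

    def _predictions(self) -> np.ndarray:
        rf = self.theta.get("r_fru")
        return np.array([
            self.model.predict_cell(row.strain, row.condition, self.Keq,
                                    self.K5, self.pp[row.condition],
                                    self.k4, r_fru=rf)
            for row in self.model.data.itertuples(index=False)])

    # -- derived quantities --------------------------------------------------

    def _weights(self) -> np.ndarray:
        w = self.model.data["rel_error"].to_numpy(float)
        w = np.where(np.isfinite(w) & (w > 0), w, _DEFAULT_REL_ERROR)
        return w

    def equilibrium_constants(self) -> dict[str, float]:
        """K1..K5 under the model's chain-split convention (cycle closed)."""
        K1, K2, K3 = self.model._chain_constants(self.Keq)
        K5 = self.K5
        K4 = self.Keq / K5 if np.isfinite(K5) else math.nan
        return {"K1": K1, "K2": K2, "K3": K3, "K4": K4, "K5": K5}

    @property
    def cycle_gap(self) -> float:
        K = self.equilibrium_constants()
        if not np.isfinite(K["K5"]):
            return 0.0
        return abs(K["K1"] * K["K2"] * K["K3"] - K["K4"] * K["K5"]) \
            / (K["K4"] * K["K5"])

    @property
    def mean_relative_residual(self) -> float:
        """Mean |predicted - measured| / measured over nonzero measurements."""
        meas = self.model.data["ptsN_fraction"].to_numpy(float)
        pred = self.fittedvalues
        mask = meas > 0
        return float(np.mean(np.abs(pred[mask] - meas[mask]) / meas[mask]))

    @property
    def cost_path(self) -> np.ndarray:
        """Best objective value reached up to each evaluation (non-increasing)."""
        return np.minimum.accumulate(np.asarray(self._eval_log))

    def _log10_standard_errors(self) -> dict[str, float]:
        J = np.asarray(self._solution.jac)
        dof = max(len(self.resid) - len(self.param_names), 1)
        s2 = 2.0 * self.cost / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(len(self.param_names), np.nan)
        return dict(zip(self.param_names, se))

    # -- prediction ----------------------------------------------------------

    def parameters_for(self, condition: Condition | str) -> PtsParameters:
        """Full relay parameter set for a condition, under the conventions."""
        cond = self.model.conditions[condition] if isinstance(condition, str) \
            else condition
        K5 = self.K5 if np.isfinite(self.K5) else 1.0
        k4 = self.k4 if np.isfinite(self.k4) else 1.0
        pp = self.pp.get(cond.label, cond.pp)
        rf = cond.r_fru
        if cond.label == "CAA_fructose" and self.r_fru_free:
            rf = self.r_fru
        base = PtsParameters.from_equilibrium(self.Keq, K5, k4=k4)
        K1, K2, K3 = self.model._chain_constants(self.Keq)
        from dataclasses import replace
        base = replace(base, K1=K1, K2=K2, K3=K3)
        return base.with_condition(
            Condition(cond.label, pp=pp, fruB_induced=cond.fruB_induced,
                      r_fru=rf, fruB_uninduced_factor=cond.fruB_uninduced_factor))

    def predict(self, strain: str | StrainGenotype,
                condition: str | Condition) -> float:
        """Forward steady-state prediction of the PtsN fraction."""
        genotype = strain if isinstance(strain, StrainGenotype) \
            else StrainGenotype(strain)
        params = self.parameters_for(condition)
        return steady_state(params, genotype).ptsN_p

    # -- reporting -----------------------------------------------------------

    def residual_table(self) -> pd.DataFrame:
        d = self.model.data.copy()
        d["predicted"] = self.fittedvalues
        d["weighted_residual"] = self.resid
        return d

    def to_dict(self) -> dict:
        return {
            "Keq": self.Keq,
            "K5": None if not np.isfinite(self.K5) else self.K5,
            "k4": None if not np.isfinite(self.k4) else self.k4,
            "pp": self.pp,
            "r_fru": self.r_fru,
            "equilibrium_constants": {
                k: (None if not np.isfinite(v) else v)
                for k, v in self.equilibrium_constants().items()},
            "cost": self.cost,
            "mean_relative_residual": self.mean_relative_residual,
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def summary(self) -> str:
        lines = [
            "PTS phosphorelay equilibrium-constant fit",
            "=" * 45,
            f"observations: {len(self.model.data)}"
            f"    parameters: {len(self.param_names)}",
            f"weighted SSR: {2 * self.cost:.6g}"
            f"    mean relative residual: {self.mean_relative_residual:.3f}",
            f"cycle constraint K1K2K3 = K4K5 enforced"
            f" (gap {self.cycle_gap:.1e})",
            "-" * 45,
            f"{'parameter':<16}{'estimate':>12}{'rel. SE':>12}",
        ]
        for n in self.param_names:
            est = self.theta[n]
            se = self.bse_log10.get(n, math.nan)
            rel = math.log(10) * se if np.isfinite(se) else math.nan
            lines.append(f"{n:<16}{est:>12.4g}{rel:>12.2g}")
        lines.append("-" * 45)
        for c, v in sorted(self.pp.items()):
            fixed = " (fixed)" if c == "CAA" else ""
            lines.append(f"pp[{c}] = {v:.4g}{fixed}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

#: the results object doubles as the parameter estimate
ParameterEstimate = PtsFitResults


def fit_equilibrium_constants(data: pd.DataFrame, pp_caa_fixed: float = 1.0,
                              conditions: Mapping[str, Condition] | None = None,
                              n_starts: int = 8, seed: int = 0,
                              r_fru_free: bool = False) -> PtsFitResults:
    """Fit ``Keq``, ``K5`` and per-condition ``pp`` from a measurement table."""
    model = PtsPhosphorylationModel(data, conditions=conditions,
                                    pp_reference=pp_caa_fixed)
    return model.fit(n_starts=n_starts, seed=seed, r_fru_free=r_fru_free)


def estimate_pp(data: pd.DataFrame, constants: PtsFitResults | Mapping[str, float],
                condition: str | None = None,
                conditions: Mapping[str, Condition] | None = None
                ) -> dict[str, float]:
    """Estimate PEP/pyruvate ratios with the equilibrium constants held fixed.

    ``constants`` is either a fitted results object or a mapping with
    keys ``Keq``, ``K5`` and optionally ``k4``.  The CAA reference stays
    fixed at 1 (or at the reference carried by ``constants``).
    """
    if isinstance(constants, PtsFitResults):
        Keq, K5, k4 = constants.Keq, constants.K5, constants.k4
        pp_ref = constants.model.pp_reference
    else:
        Keq = constants["Keq"]
        K5 = constants.get("K5", math.nan)
        k4 = constants.get("k4", 1.0)
        pp_ref = constants.get("pp_CAA", 1.0)

    model = PtsPhosphorylationModel(data, conditions=conditions,
                                    pp_reference=pp_ref)
    targets = [condition] if condition else model.fitted_pp_conditions
    out = {"CAA": pp_ref}
    for cond in targets:
        sub = model.data[model.data["condition"] == cond]
        if sub.empty:
            raise IdentifiabilityError(f"no measurements for condition {cond!r}")
        informative = sub[sub["strain"] != "delta_ptsN"]
        if informative.empty:
            raise IdentifiabilityError(
                f"no measurement sensitive to pp in condition {cond!r}")

        def res(log_pp: np.ndarray) -> np.ndarray:
            pp = 10.0 ** log_pp[0]
            return np.array([
                model._cell_residual(
                    model.predict_cell(row.strain, cond, Keq, K5, pp, k4),
                    row.ptsN_fraction, row.rel_error)
                for row in informative.itertuples(index=False)])

        sol = least_squares(res, [math.log10(0.5)], bounds=([-4.0], [2.0]),
                            method="trf", xtol=1e-14, ftol=1e-14)
        out[cond] = float(10.0 ** sol.x[0])
    return out


def predict_ptsN(estimate: PtsFitResults, genotype: str | StrainGenotype,
                 condition: str | Condition) -> float:
    """Forward steady-state prediction of the PtsN phosphorylated fraction."""
    return estimate.predict(genotype, condition)
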