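"""Desk-scale flux balance analysis (FBA) and flux variability analysis (FVA).

A small linear-programming engine over stoichiometric networks given in
a plain reaction-list dialect.  It implements the estimation procedures
used around the PEP/pyruvate node: fixing the measured growth rate and
minimising substrate uptake, calibrating the non-growth-associated
maintenance (NGAM) so that the minimised uptake matches the measured
one, feeding casamino acids through a virtual "carbon" compound with
carbon-count stoichiometry, and summarising FVA ranges relative to the
nominal flux.

Networks here are toy central-carbon models (a genome-scale
reconstruction can be supplied in the same dialect but is not bundled).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

_MASS_BALANCE_TOL = 1e-9
_BOUND_TOL = 1e-9
_DEFAULT_INF = 1e6


class NetworkError(ValueError):
    """Inconsistent network definition."""


class LPError(RuntimeError):
    """The LP solver returned an unexpected status."""


@dataclass
class Reaction:
    """A reaction with stoichiometry ``{metabolite: coefficient}`` and bounds."""

    id: str
    stoich: dict[str, float]
    lb: float = 0.0
    ub: float = _DEFAULT_INF

    def __post_init__(self):
        if self.lb > self.ub:
            raise NetworkError(f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}")

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub

    def equation(self) -> str:
        def side(items):
            return " + ".join(
                (f"{abs(c):g} {m}" if abs(c) != 1 else m) for m, c in items)
        subs = [(m, c) for m, c in self.stoich.items() if c < 0]
        prods = [(m, c) for m, c in self.stoich.items() if c > 0]
        arrow = "<->" if self.reversible else "->"
        return f"{side(subs)} {arrow} {side(prods)}".strip()


_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def parse_reaction_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A + B -> C"`` (or ``<->``) into a stoichiometry dict."""
    if "<->" in eq:
        lhs, rhs = eq.split("<->")
        reversible = True
    elif "->" in eq:
        lhs, rhs = eq.split("->")
        reversible = False
    else:
        raise NetworkError(f"no arrow in reaction equation {eq!r}")
    stoich: dict[str, float] = {}

    def add(side: str, sign: float):
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            m = _TERM_RE.match(term)
            if not m:
                raise NetworkError(f"cannot parse term {term!r} in {eq!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add(lhs, -1.0)
    add(rhs, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    return stoich, reversible


@dataclass
class MetabolicNetwork:
    """Stoichiometric network with bounds and designated special reactions."""

    reactions: list[Reaction]
    biomass_id: str | None = None
    ngam_id: str | None = None
    exchange_ids: tuple[str, ...] = ()

    def __post_init__(self):
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkError(f"duplicate reaction ids: {dupes}")
        for rid in filter(None, (self.biomass_id, self.ngam_id, *self.exchange_ids)):
            if rid not in ids:
                raise NetworkError(f"designated reaction {rid!r} not in network")

    @property
    def metabolites(self) -> list[str]:
        mets: dict[str, None] = {}
        for r in self.reactions:
            for m in r.stoich:
                mets.setdefault(m)
        return list(mets)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        mets = self.metabolites
        met_idx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoich.items():
                S[met_idx[m], j] = c
        return S, mets, self.reaction_ids

    def bounds(self) -> list[tuple[float, float]]:
        return [(r.lb, r.ub) for r in self.reactions]

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            [Reaction(r.id, dict(r.stoich), r.lb, r.ub) for r in self.reactions],
            self.biomass_id, self.ngam_id, tuple(self.exchange_ids))

    def with_bounds(self, rid: str, lb: float, ub: float) -> "MetabolicNetwork":
        net = self.copy()
        r = net.reaction(rid)
        r.lb, r.ub = lb, ub
        if lb > ub:
            raise NetworkError(f"reaction {rid!r}: lb {lb} > ub {ub}")
        return net

    def set_ngam(self, value: float) -> "MetabolicNetwork":
        """Set the NGAM maintenance flux: fixed lower bound at ``value``."""
        if self.ngam_id is None:
            raise NetworkError("network has no designated NGAM reaction")
        ub = max(self.reaction(self.ngam_id).ub, value)
        return self.with_bounds(self.ngam_id, value, ub)


@dataclass
class FluxDistribution:
    """LP solution: flux per reaction, objective value and solver status."""

    fluxes: pd.Series
    objective: float
    status: str  # "optimal" | "infeasible" | "unbounded" | "failed"

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rid: str) -> float:
        return float(self.fluxes[rid])


_STATUS = {0: "optimal", 1: "failed", 2: "infeasible", 3: "unbounded", 4: "failed"}


def solve_fba(network: MetabolicNetwork, objective_reaction: str,
              sense: str = "max",
              extra_constraints: Sequence[tuple[Mapping[str, float], float, float]] = ()
              ) -> FluxDistribution:
    """Solve the FBA linear programme S v = 0, lb <= v <= ub.

    ``extra_constraints`` are triples ``(coefficients, lo, hi)`` imposing
    ``lo <= sum coef_r * v_r <= hi``.  Infeasibility and unboundedness
    are reported in the returned status, never as silent zeros.
    """
    S, mets, rids = network.stoichiometric_matrix()
    idx = {r: j for j, r in enumerate(rids)}
    if objective_reaction not in idx:
        raise NetworkError(f"objective reaction {objective_reaction!r} not in network")
    c = np.zeros(len(rids))
    c[idx[objective_reaction]] = -1.0 if sense == "max" else 1.0

    A_eq, b_eq = S, np.zeros(S.shape[0])
    A_ub_rows, b_ub = [], []
    for coef, lo, hi in extra_constraints:
        row = np.zeros(len(rids))
        for rid, v in coef.items():
            row[idx[rid]] = v
        if np.isfinite(hi):
            A_ub_rows.append(row)
            b_ub.append(hi)
        if np.isfinite(lo):
            A_ub_rows.append(-row)
            b_ub.append(-lo)
    A_ub = np.array(A_ub_rows) if A_ub_rows else None
    res = linprog(c, A_ub=A_ub, b_ub=b_ub or None, A_eq=A_eq, b_eq=b_eq,
                  bounds=network.bounds(), method="highs")
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxDistribution(pd.Series(np.nan, index=rids), np.nan, status)
    v = pd.Series(res.x, index=rids)
    obj = float(v[objective_reaction])
    return FluxDistribution(v, obj, "optimal")


def minimize_substrate_uptake(network: MetabolicNetwork, growth_rate_measured: float,
                              substrate_reaction: str) -> FluxDistribution:
    """Fix the growth rate at its measured value and minimise uptake.

    The biomass reaction's bounds are pinned to the measurement and the
    substrate exchange flux is minimised.
    """
    if network.biomass_id is None:
        raise NetworkError("network has no designated biomass reaction")
    net = network.with_bounds(network.biomass_id,
                              growth_rate_measured, growth_rate_measured)
    return solve_fba(net, substrate_reaction, sense="min")


def calibrate_ngam(network: MetabolicNetwork, growth_rate_measured: float,
                   uptake_measured: float, substrate_reaction: str,
                   rel_tol: float = 1e-6, ngam_max: float = 1e4) -> float:
    """Find the NGAM value whose minimised uptake matches the measurement.

    Bisection on the NGAM flux; requires the measured uptake to be at
    least the minimum attainable at NGAM = 0 (otherwise no maintenance
    setting can reproduce it).  The calibrated value is intended to be
    reused across growth conditions.
    """

    def uptake_at(ngam: float) -> float:
        sol = minimize_substrate_uptake(network.set_ngam(ngam),
                                        growth_rate_measured, substrate_reaction)
        if not sol.ok:
            return np.inf
        return sol.objective

    u0 = uptake_at(0.0)
    if not np.isfinite(u0):
        raise LPError("growth rate infeasible even at NGAM = 0")
    scale = max(abs(uptake_measured), 1.0)
    if uptake_measured < u0 - rel_tol * scale:
        raise NetworkError(
            f"calibration infeasible: measured uptake {uptake_measured:g} lies "
            f"below the NGAM=0 minimum {u0:g}")
    if abs(uptake_measured - u0) <= rel_tol * scale:
        return 0.0

    hi = 1.0
    while uptake_at(hi) < uptake_measured and hi < ngam_max:
        hi *= 2.0
    if uptake_at(hi) < uptake_measured:
        raise NetworkError(
            f"calibration infeasible: uptake at NGAM={hi:g} still below target")
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        u = uptake_at(mid)
        if abs(u - uptake_measured) <= rel_tol * scale:
            return mid
        if u < uptake_measured:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


#: carbon atoms per proteinogenic amino acid (for the virtual-carbon feed)
AMINO_ACID_CARBONS: dict[str, int] = {
    "gly": 2, "ala": 3, "ser": 3, "cys": 3, "asp": 4, "asn": 4, "thr": 4,
    "glu": 5, "gln": 5, "pro": 5, "val": 5, "met": 5, "ile": 6, "leu": 6,
    "lys": 6, "his": 6, "arg": 6, "phe": 9, "tyr": 9, "trp": 11,
}


def add_virtual_carbon(network: MetabolicNetwork,
                       amino_acid_carbon_counts: Mapping[str, int],
                       exchange_id: str = "EX_carbon") -> MetabolicNetwork:
    """Feed amino acids through a virtual ``carbon`` compound.

    Adds one exchange producing ``carbon`` and, per amino acid, a
    reaction converting ``n_C`` carbon into one unit of that amino acid.
    Minimising the carbon exchange then minimises total casamino-acid
    uptake on the natural carbon scale.
    """
    mets = set(network.metabolites)
    missing = sorted(set(amino_acid_carbon_counts) - mets)
    if missing:
        raise NetworkError(f"amino acids absent from the network: {missing}")
    for aa, n in amino_acid_carbon_counts.items():
        if not (isinstance(n, (int, np.integer)) and n > 0):
            raise NetworkError(f"carbon count for {aa!r} must be a positive integer")
    net = network.copy()
    net.reactions.append(Reaction(exchange_id, {"carbon": 1.0}, 0.0, _DEFAULT_INF))
    for aa, n in amino_acid_carbon_counts.items():
        net.reactions.append(
            Reaction(f"carbon_to_{aa}", {"carbon": -float(n), aa: 1.0},
                     0.0, _DEFAULT_INF))
    net.exchange_ids = tuple(net.exchange_ids) + (exchange_id,)
    return MetabolicNetwork(net.reactions, net.biomass_id, net.ngam_id,
                            net.exchange_ids)


@dataclass
class FVAResult:
    """Per-reaction flux ranges at the fixed optimal objective."""

    table: pd.DataFrame  # columns: reaction, nominal, min, max

    def __post_init__(self):
        t = self.table
        if not ((t["min"] <= t["nominal"] + 1e-7)
                & (t["nominal"] <= t["max"] + 1e-7)).all():
            raise LPError("FVA sandwich min <= nominal <= max violated")

    def relative_ranges(self) -> pd.DataFrame:
        out = self.table.copy()
        out["rel_range_percent"] = [
            fva_relative_range(n, lo, hi) if n != 0 else np.nan
            for n, lo, hi in zip(out["nominal"], out["min"], out["max"])]
        return out


def fva(network: MetabolicNetwork, objective_reaction: str, sense: str = "max",
        nominal: FluxDistribution | None = None) -> FVAResult:
    """Flux variability analysis with the objective fixed at its optimum.

    Each reaction flux is minimised and maximised subject to the mass
    balances, the bounds, and the objective pinned (equality within
    1e-9) to the optimal value of the nominal solution.
    """
    if nominal is None:
        nominal = solve_fba(network, objective_reaction, sense=sense)
    if not nominal.ok:
        raise LPError(f"nominal FBA not optimal: status {nominal.status}")
    opt = nominal.objective
    net = network.with_bounds(objective_reaction, opt - 1e-9, opt + 1e-9)

    rows = []
    for rid in net.reaction_ids:
        lo = solve_fba(net, rid, sense="min")
        hi = solve_fba(net, rid, sense="max")
        if not (lo.ok and hi.ok):
            raise LPError(f"FVA subproblem failed for reaction {rid!r}")
        rows.append({"reaction": rid, "nominal": nominal[rid],
                     "min": lo.objective, "max": hi.objective})
    return FVAResult(pd.DataFrame(rows))


def fva_relative_range(nominal: float, vmin: float, vmax: float) -> float:
    """FVA range relative to the nominal flux, in percent.

    ``100 * (max - min) / nominal`` rounded half-up to one decimal, the
    rounding used in printed flux-summary tables (so 2.69 -> 2.7 and the
    tie 1.25 -> 1.3).  Undefined for a zero nominal flux.
    """
    if nominal == 0:
        raise ZeroDivisionError("relative FVA range undefined for nominal flux 0")
    val = (Decimal(str(vmax)) - Decimal(str(vmin))) / Decimal(str(nominal)) * 100
    return float(val.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# reaction-list I/O
# ---------------------------------------------------------------------------

def read_network_tsv(path) -> MetabolicNetwork:
    """Read a network from the TSV reaction-list dialect.

    Columns: ``id``, ``equation`` (e.g. ``2 A + B -> C``), ``lb``, ``ub``
    and an optional ``role`` column marking ``biomass``, ``ngam`` or
    ``exchange`` reactions.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "equation", "lb", "ub"}
    missing = required - set(df.columns)
    if missing:
        raise NetworkError(f"network table lacks columns {sorted(missing)}")
    reactions, biomass, ngam, exch = [], None, None, []
    for i, row in df.iterrows():
        try:
            stoich, reversible = parse_reaction_equation(str(row["equation"]))
            lb = float(row["lb"]) if np.isfinite(row["lb"]) else -_DEFAULT_INF
            ub = float(row["ub"]) if np.isfinite(row["ub"]) else _DEFAULT_INF
            reactions.append(Reaction(str(row["id"]), stoich, lb, ub))
        except (NetworkError, ValueError) as exc:
            raise NetworkError(f"line {i + 2}: {exc}") from exc
        role = str(row.get("role", "") or "")
        if role == "biomass":
            biomass = str(row["id"])
        elif role == "ngam":
            ngam = str(row["id"])
        elif role == "exchange":
            exch.append(str(row["id"]))
    return MetabolicNetwork(reactions, biomass, ngam, tuple(exch))


def read_network_sbml(path, biomass_id: str | None = None,
                      ngam_id: str | None = None) -> MetabolicNetwork:
    """Optional SBML (level 3, FBC bounds) import, via cobrapy.

    Exchange reactions are detected from the model's boundary; the
    biomass reaction is taken from the model's objective unless given.
    """
    import cobra  # deliberately lazy: SBML input is optional

    model = cobra.io.read_sbml_model(str(path))
    reactions = []
    for r in model.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        reactions.append(Reaction(r.id, stoich,
                                  max(r.lower_bound, -_DEFAULT_INF),
                                  min(r.upper_bound, _DEFAULT_INF)))
    if biomass_id is None:
        obj = [r.id for r in model.reactions
               if r.objective_coefficient not in (0, 0.0)]
        biomass_id = obj[0] if obj else None
    exchanges = tuple(r.id for r in model.boundary)
    return MetabolicNetwork(reactions, biomass_id, ngam_id, exchanges)


def write_network_tsv(network: MetabolicNetwork, path) -> None:
    rows = []
    for r in network.reactions:
        role = ""
        if r.id == network.biomass_id:
            role = "biomass"
        elif r.id == network.ngam_id:
            role = "ngam"
        elif r.id in network.exchange_ids:
            role = "exchange"
        rows.append({"id": r.id, "equation": r.equation(),
                     "lb": r.lb, "ub": r.ub, "role": role})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
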