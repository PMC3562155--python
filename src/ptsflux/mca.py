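"""Metabolic control analysis and the power-law PEP/pyruvate node model.

Two pieces of machinery meet here.  The generic part is structural-rank
screening (can an elasticity matrix of a given sparsity pattern be
inverted?) and the computation of concentration control coefficients
from partitioned stoichiometry: with unknown rates ``r_u(c)`` and known
rates ``r_kn(u)`` driven by an input flux ``u``, the steady-state
condition ``N_u r_u + N_kn r_kn = 0`` differentiates to

    eps * dc/du = -N_u^{-1} N_kn beta,

where ``eps`` is the elasticity matrix and ``beta = d r_kn / d u``.

The specific application is the reduced PEP/pyruvate node: input flux
``ra`` into pyruvate, lumped drain ``rb = rb_s + k (ra - ra_s)``,
pyruvate -> PEP flux ``rc`` (PEP synthase) and PEP -> 2PG flux ``rd``
(gluconeogenetic direction), with power-law kinetics
``rc = kc * Pyr**nc`` and ``rd = kd * PEP**nd``.  Fixing ``kc = nc = 1``
and fitting the two remaining constants through two measured
(flux, PEP/pyruvate-ratio) points characterises the relative kinetics of
the two enzymes; the ratio is increasing in the input flux exactly when
``nc/nd > 1``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

logger = logging.getLogger(__name__)


class SingularityError(np.linalg.LinAlgError):
    """A matrix required to be invertible is (structurally) singular."""


def structural_rank(pattern_matrix) -> int:
    """Maximum rank over all numeric matrices with the given zero pattern.

    Equals the size of a maximum bipartite matching between rows and
    columns of the nonzero entries.
    """
    A = np.asarray(pattern_matrix)
    if A.ndim != 2:
        raise ValueError("pattern must be a 2-d array")
    pattern = (A != 0).astype(np.int8)
    if pattern.sum() == 0:
        return 0
    match = maximum_bipartite_matching(csr_matrix(pattern), perm_type="column")
    return int(np.sum(match >= 0))


@dataclass
class MCAProblem:
    """Partitioned steady-state sensitivity problem.

    ``epsilon`` is the elasticity matrix of the unknown rates with
    respect to the concentrations, ``N_u`` / ``N_kn`` the stoichiometric
    sub-matrices of unknown and known rates, and ``beta`` the derivative
    of the known rates with respect to the chosen input.
    """

    epsilon: np.ndarray
    N_u: np.ndarray
    N_kn: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        self.epsilon = np.atleast_2d(np.asarray(self.epsilon, float))
        self.N_u = np.atleast_2d(np.asarray(self.N_u, float))
        self.N_kn = np.atleast_2d(np.asarray(self.N_kn, float))
        self.beta = np.asarray(self.beta, float).ravel()
        m, n = self.N_u.shape
        if self.epsilon.shape != (n, m):
            raise ValueError(
                f"elasticity matrix must be {(n, m)} (rates x concentrations), "
                f"got {self.epsilon.shape}")
        if self.N_kn.shape[0] != m or self.N_kn.shape[1] != len(self.beta):
            raise ValueError("N_kn and beta dimensions not conformable")


def concentration_control(problem: MCAProblem) -> np.ndarray:
    """Concentration control coefficients dc/du of the partitioned system.

    Solves ``eps dc/du = -N_u^{-1} N_kn beta``.  Both ``N_u`` and the
    elasticity matrix must be invertible; the structural rank of the
    elasticity pattern is checked first, so a pattern-level singularity
    is reported as such.
    """
    eps, N_u = problem.epsilon, problem.N_u
    n = eps.shape[0]
    srank = structural_rank(eps)
    if srank < n:
        raise SingularityError(
            f"elasticity matrix has structural rank {srank} < {n}; no "
            "numeric matrix of this sparsity pattern is invertible")
    if structural_rank(N_u) < N_u.shape[0]:
        raise SingularityError("N_u is structurally singular")
    try:
        rhs = -np.linalg.solve(N_u, problem.N_kn @ problem.beta)
        return np.linalg.solve(eps, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularityError(f"numeric singularity: {exc}") from exc


# ---------------------------------------------------------------------------
# the reduced PEP/pyruvate node
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerLawFit:
    """Power-law constants of the node's two fitted rates.

    ``rc = kc * Pyr**nc`` (PEP synthase, normalised to ``kc = nc = 1``)
    and ``rd = kd * PEP**nd`` (lumped gluconeogenetic drain);
    ``alpha = kc/kd`` and ``n_prime = 1/nd - 1/nc`` are the derived
    constants of the ratio law.
    """

    kc: float
    nc: float
    kd: float
    nd: float

    def __post_init__(self):
        if self.kd <= 0 or self.nd <= 0 or self.kc <= 0 or self.nc <= 0:
            raise ValueError("power-law constants and exponents must be > 0")

    @property
    def alpha(self) -> float:
        return self.kc / self.kd

    @property
    def n_prime(self) -> float:
        return 1.0 / self.nd - 1.0 / self.nc

    def pep_pyruvate_ratio(self, rc: float | np.ndarray) -> float | np.ndarray:
        """The ratio law: pp = alpha**(1/nd) * (rc/kc)**n_prime."""
        return self.alpha ** (1.0 / self.nd) * (np.asarray(rc) / self.kc) ** self.n_prime


@dataclass(frozen=True)
class ReducedNodeModel:
    """The four lumped fluxes of the node and the drain slope ``k``.

    ``ra`` feeds pyruvate, ``rb = rb_s + k (ra - ra_s)`` drains it,
    ``rc`` converts pyruvate to PEP and ``rd`` drains PEP; at steady
    state ``rc = rd = (1 - k) * ra``.
    """

    ra_s: float
    rb_s: float
    k: float

    def __post_init__(self):
        if not 0.0 <= self.k < 1.0:
            raise ValueError(f"slope k={self.k} must lie in [0, 1)")

    def rb(self, ra: float) -> float:
        return self.rb_s + self.k * (ra - self.ra_s)

    def rc(self, ra: float | np.ndarray):
        return (1.0 - self.k) * np.asarray(ra)


def fit_powerlaw_two_points(point1: tuple[float, float],
                            point2: tuple[float, float],
                            kc: float = 1.0, nc: float = 1.0) -> PowerLawFit:
    """Solve the ratio law exactly through two (rc, pp) calibration points.

    With ``pp_i = alpha**(1/nd) * (rc_i/kc)**n_prime`` and
    ``n_prime = 1/nd - 1/nc``, two distinct points determine ``nd`` and
    ``kd = kc / alpha`` in closed form (log-linear system).
    """
    (rc1, pp1), (rc2, pp2) = point1, point2
    for v in (rc1, rc2, pp1, pp2):
        if not (np.isfinite(v) and v > 0):
            raise ValueError("fluxes and ratios must be positive and finite")
    if rc1 == rc2:
        raise ValueError("degenerate calibration: the two rc values coincide")
    n_prime = (math.log(pp1) - math.log(pp2)) / (math.log(rc1) - math.log(rc2))
    nd = 1.0 / (n_prime + 1.0 / nc)
    if nd <= 0:
        raise ValueError(f"no positive exponent solves the two points "
                         f"(n_prime={n_prime:g})")
    log_alpha = nd * (math.log(pp1) - n_prime * math.log(rc1 / kc))
    alpha = math.exp(log_alpha)
    kd = kc / alpha
    logger.info("two-point power-law fit: nd=%.4f (nd/nc=%.4f), kd=%.4f "
                "(kd/kc=%.4f), alpha=%.4f, n'=%.4f",
                nd, nd / nc, kd, kd / kc, alpha, n_prime)
    return PowerLawFit(kc=kc, nc=nc, kd=kd, nd=nd)


def reduced_steady_state(ra: float, k: float, fit: PowerLawFit
                         ) -> tuple[float, float, float]:
    """Steady-state (PEP, Pyr, pp) of the reduced node at input flux ra.

    From ``rc = rd = (1 - k) ra``: ``Pyr = ((1-k) ra / kc)**(1/nc)`` and
    ``PEP = ((1-k) ra / kd)**(1/nd)``.
    """
    if k >= 1.0:
        raise ValueError("k >= 1 leaves no flux for the node: no steady state")
    flux = (1.0 - k) * ra
    if flux <= 0:
        raise ValueError("(1 - k) * ra must be positive")
    pyr = (flux / fit.kc) ** (1.0 / fit.nc)
    pep = (flux / fit.kd) ** (1.0 / fit.nd)
    return pep, pyr, pep / pyr


def node_elasticities(fit: PowerLawFit, ra: float, k: float
                      ) -> tuple[float, float]:
    """Elasticities (eps_c, eps_d) = (nc rc/Pyr, nd rd/PEP) at steady state."""
    pep, pyr, _ = reduced_steady_state(ra, k, fit)
    flux = (1.0 - k) * ra
    return fit.nc * flux / pyr, fit.nd * flux / pep


def reduced_node_problem(fit: PowerLawFit, ra: float, k: float) -> MCAProblem:
    """The node's partitioned sensitivity problem at its steady state.

    Unknown rates (rc, rd) with concentrations ordered (PEP, Pyr); known
    rates (ra, rb) driven by the input ra with ``beta = (1, k)``.
    """
    eps_c, eps_d = node_elasticities(fit, ra, k)
    epsilon = np.array([[0.0, eps_c],
                        [eps_d, 0.0]])
    N_u = np.array([[1.0, -1.0],
                    [-1.0, 0.0]])
    N_kn = np.array([[0.0, 0.0],
                     [1.0, -1.0]])
    return MCAProblem(epsilon, N_u, N_kn, np.array([1.0, k]))


def monotonicity_condition(nc: float, nd: float) -> bool:
    """True iff the PEP/pyruvate ratio increases with the input flux.

    The ratio law has ``d pp / d ra > 0`` exactly when ``nc / nd > 1``.
    """
    if nc <= 0 or nd <= 0:
        raise ValueError("exponents must be positive")
    return nc / nd > 1.0


def characteristic_curve(fit: PowerLawFit, k_nominal: float,
                         k_range: tuple[float, float],
                         ra_grid: Sequence[float]) -> pd.DataFrame:
    """pp(ra) at the nominal slope plus the envelope over a slope band.

    Returns a table with columns ``ra``, ``pp``, ``pp_lo``, ``pp_hi``;
    the band edges are the curves at the extreme slopes, so they are
    themselves valid characteristic curves.
    """
    ra = np.asarray(ra_grid, float)
    if np.any(ra <= 0):
        raise ValueError("ra grid must be positive")
    k_lo, k_hi = min(k_range), max(k_range)
    curves = {}
    for label, k in (("pp", k_nominal), ("a", k_lo), ("b", k_hi)):
        pep_pyr = np.array([reduced_steady_state(r, k, fit)[2] for r in ra])
        curves[label] = pep_pyr
    lo = np.minimum(curves["a"], curves["b"])
    hi = np.maximum(curves["a"], curves["b"])
    return pd.DataFrame({"ra": ra, "pp": curves["pp"],
                         "pp_lo": np.minimum(lo, curves["pp"]),
                         "pp_hi": np.maximum(hi, curves["pp"])})


def slope_k_from_conditions(flux_table: pd.DataFrame, mode: str = "closure",
                            input_reaction: str = "oaa_to_pyr",
                            pep_reaction: str = "pyr_to_pep",
                            drain_reaction: str = "pyr_to_accoa",
                            value: str = "nominal") -> float:
    """Drain slope k = delta(rb) / delta(ra) between two conditions.

    ``mode="closure"`` (default) closes the pyruvate node exactly by
    defining ``rb = ra - rc`` (the printed fluxes do not balance the
    node because of minor drains); ``mode="acetyl-coa"`` uses the
    printed pyruvate -> acetyl-CoA flux alone as the drain.
    """
    conds = list(dict.fromkeys(flux_table["condition"]))
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {conds}")

    def flux(cond: str, reaction: str) -> float:
        sel = flux_table[(flux_table["condition"] == cond)
                         & (flux_table["reaction"] == reaction)]
        if len(sel) != 1:
            raise ValueError(f"no unique {reaction!r} flux for condition {cond!r}")
        return float(sel[value].iloc[0])

    ra = [flux(c, input_reaction) for c in conds]
    if ra[0] == ra[1]:
        raise ValueError("input fluxes are equal: slope undefined")
    if mode == "closure":
        rb = [ra[i] - flux(conds[i], pep_reaction) for i in range(2)]
    elif mode == "acetyl-coa":
        rb = [flux(c, drain_reaction) for c in conds]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return (rb[0] - rb[1]) / (ra[0] - ra[1])
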