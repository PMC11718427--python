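"""Constrained flux balance analysis over a batch time course.

At each sample time the measured per-cell transport rates pin the linked
exchange fluxes to a ±30% band, and a linear program maximizes the biomass
reaction subject to the steady-state constraint S·v = 0 and all bounds.
Because FBA optima are typically degenerate, every optimal solve is
followed by a deterministic parsimonious tie-break: biomass is fixed at its
optimum and the total absolute flux Σ|v_j| is minimized (split-variable LP),
so downstream multivariate models always see the same flux vector.

One extra quantity is computed per solve: the total ATP generation rate,
the sum of each reaction's ATP production counted only where positive at
the solution (a reversible ATP-producing reaction running backward does not
produce).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .network import MetabolicNetwork
from .simdata import BatchRecord, SpecificRateSeries

logger = logging.getLogger(__name__)

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

#: relative half-width of the transport-rate constraint band
TRANSPORT_TOLERANCE = 0.30

#: absolute padding so a measured rate of 0 yields a thin feasible interval
BOUND_EPSILON = 1e-6

#: biomass is held within this slack of its optimum during the tie-break
TIEBREAK_TOLERANCE = 1e-9

_LINPROG_OPTS = {"presolve": True}


@dataclass
class FluxSolution:
    v: np.ndarray          # pmol/cell/h, network reaction order
    objective: float       # biomass rate
    status: str            # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


@dataclass
class FluxMatrix:
    """Reaction rates (plus total ATP) per feasible sample time of one batch."""

    batch_id: str
    times: np.ndarray                      # h, feasible times only, increasing
    columns: list[str]                     # reaction ids + "total_ATP"
    values: np.ndarray                     # len(times) x len(columns)
    skipped: list[tuple[float, str]] = field(default_factory=list)  # (time, diagnostic)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.columns)
        frame.insert(0, "time_h", self.times)
        frame.insert(0, "batch_id", self.batch_id)
        return frame

    @staticmethod
    def from_frame(frame: pd.DataFrame) -> "dict[str, FluxMatrix]":
        out = {}
        cols = [c for c in frame.columns if c not in ("batch_id", "time_h")]
        for batch_id, grp in frame.groupby("batch_id", sort=False):
            grp = grp.sort_values("time_h")
            out[str(batch_id)] = FluxMatrix(
                batch_id=str(batch_id),
                times=grp["time_h"].to_numpy(),
                columns=cols,
                values=grp[cols].to_numpy(),
            )
        return out


def apply_transport_constraints(
    net: MetabolicNetwork,
    rates: list[SpecificRateSeries],
    time: float,
    tolerance: float = TRANSPORT_TOLERANCE,
) -> MetabolicNetwork:
    """Bound each linked exchange to ±tolerance around the measured rate.

    Returns a modified copy; bounds become [q - tol·|q| - ε, q + tol·|q| + ε]
    so that q = 0 still yields a thin feasible interval instead of an
    equality.
    """
    out = net.copy()
    for series in rates:
        q = series.at(time)  # raises KeyError if the time is not covered
        rxn_template = net.exchange_for(series.metabolite)
        rxn = out.reaction(rxn_template.id)
        half = tolerance * abs(q) + BOUND_EPSILON
        rxn.lower_bound = q - half
        rxn.upper_bound = q + half
    return out


def _bounds_list(net: MetabolicNetwork) -> list[tuple[float | None, float | None]]:
    return [
        (None if math.isinf(r.lower_bound) else r.lower_bound,
         None if math.isinf(r.upper_bound) else r.upper_bound)
        for r in net.reactions
    ]


def solve_fba(net: MetabolicNetwork) -> FluxSolution:
    """Maximize biomass under S·v = 0 and bounds; tie-break parsimoniously.

    The tie-break fixes biomass at its optimum (within ``TIEBREAK_TOLERANCE``)
    and minimizes Σ|v| via the standard split-variable reformulation,
    returning a reproducible flux vector.  Solver failures surface in
    ``status``, never as silent zeros.
    """
    n = len(net.reactions)
    S = net.stoichiometric_matrix()
    bounds = _bounds_list(net)
    b_idx = net.reaction_ids().index(net.biomass_id)

    c = np.zeros(n)
    c[b_idx] = -1.0  # linprog minimizes
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs", options=_LINPROG_OPTS)
    if res.status == 2:
        return FluxSolution(v=np.full(n, np.nan), objective=np.nan, status=INFEASIBLE)
    if res.status == 3:
        return FluxSolution(v=np.full(n, np.nan), objective=np.nan, status=UNBOUNDED)
    if res.status != 0:
        raise RuntimeError(f"LP solver failed: {res.message}")
    z_opt = -res.fun

    # Parsimonious stage: v = v_pos - v_neg, minimize sum(v_pos + v_neg).
    lb = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
    ub = np.array([np.inf if b[1] is None else b[1] for b in bounds])
    split_bounds = []
    for j in range(n):
        split_bounds.append((max(0.0, lb[j]), None if np.isinf(ub[j]) else max(0.0, ub[j])))
    for j in range(n):
        split_bounds.append((max(0.0, -ub[j]), None if np.isinf(lb[j]) else max(0.0, -lb[j])))
    # steady state plus biomass pinned at its optimum
    pin = np.zeros((1, 2 * n))
    pin[0, b_idx], pin[0, n + b_idx] = 1.0, -1.0
    A_eq = np.vstack([np.hstack([S, -S]), pin])
    b_eq = np.append(np.zeros(S.shape[0]), z_opt)
    c2 = np.ones(2 * n)
    res2 = linprog(c2, A_eq=A_eq, b_eq=b_eq, bounds=split_bounds,
                   method="highs", options=_LINPROG_OPTS)
    if res2.status != 0:
        logger.warning("parsimonious tie-break failed (%s); returning first-stage optimum",
                       res2.message)
        v = np.asarray(res.x)
    else:
        v = np.asarray(res2.x[:n] - res2.x[n:])
    return FluxSolution(v=v, objective=float(v[b_idx]), status=OPTIMAL)


def total_atp_rate(net: MetabolicNetwork, sol: FluxSolution) -> float:
    """Total ATP generation: Σ_j max(0, s_ATP,j · v_j) at the solution."""
    if not sol.optimal:
        raise ValueError("total ATP rate requires an optimal solution")
    if net.atp_name not in net.metabolites:
        raise KeyError(f"metabolite {net.atp_name!r} missing from network")
    s_atp = net.stoichiometric_matrix()[net.metabolites.index(net.atp_name)]
    production = s_atp * sol.v
    return float(np.sum(production[production > 0]))


def _diagnose(net: MetabolicNetwork, rates: list[SpecificRateSeries], time: float,
              tolerance: float = TRANSPORT_TOLERANCE) -> str:
    parts = []
    for series in rates:
        try:
            rxn = net.exchange_for(series.metabolite)
        except KeyError:
            continue
        try:
            q = series.at(time)
        except KeyError:
            continue
        half = tolerance * abs(q) + BOUND_EPSILON
        parts.append(f"{rxn.id}[{series.metabolite}] in [{q - half:.4g}, {q + half:.4g}]")
    return "; ".join(parts) or "no measured-rate constraints at this time"


def run_time_course(
    net: MetabolicNetwork,
    record: BatchRecord,
    rates: list[SpecificRateSeries],
    tolerance: float = TRANSPORT_TOLERANCE,
) -> FluxMatrix:
    """One constrained FBA solve per sample time of the batch.

    Infeasible timepoints are skipped (missing rows) with a logged
    diagnostic of the active measured-rate bounds; if every timepoint is
    infeasible a hard error names the tightest constraints.
    """
    times, rows, skipped = [], [], []
    for t in record.sample_times():
        constrained = apply_transport_constraints(net, rates, t, tolerance)
        sol = solve_fba(constrained)
        if not sol.optimal:
            diag = _diagnose(net, rates, t, tolerance)
            logger.warning("%s t=%.1f h: %s (%s)", record.batch_id, t, sol.status, diag)
            skipped.append((float(t), f"{sol.status}: {diag}"))
            continue
        rows.append(np.append(sol.v, total_atp_rate(net, sol)))
        times.append(float(t))
    if not rows:
        details = "\n  ".join(f"t={t:.1f} h: {d}" for t, d in skipped)
        raise RuntimeError(
            f"{record.batch_id}: FBA infeasible at every timepoint;\n  {details}")
    return FluxMatrix(
        batch_id=record.batch_id,
        times=np.asarray(times),
        columns=net.reaction_ids() + ["total_ATP"],
        values=np.vstack(rows),
        skipped=skipped,
    )
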