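"""Per-cell metabolite transport rates from sampled trajectories.

In an unfed batch the medium mass balance reduces to

    q_met(t) = (1 / VCD(t)) * d[Met]/dt

with q_met > 0 for secretion and q_met < 0 for consumption.  Bolus feeds
break the differentiability of the raw concentration series, so a
*pseudo-concentration* is built first: for nutrients the recorded
concentration jump of each feed is subtracted from all later samples; for
byproducts the concentration lost to feed dilution is added back.  The
pseudo series then reflects cellular activity only and the same quotient
applies.

Noise is smoothed by least-squares polynomials; the derivative is taken
analytically from the fitted coefficients, and VCD enters the quotient
through its own smoothed series.  Smoothing is fitted per process phase
(unfed batch vs fed-batch, split at the first feed): the phases differ in
feeding regime — and, in shift experiments, in temperature — so a single
global polynomial would leak information across the boundary and bias the
estimated rates on both sides of it.  The configured degree refers to the
full trajectory; each phase receives flexibility proportional to its time
span, never more than leaves one residual degree of freedom.

Unit bookkeeping: concentrations in mM, VCD in 10^6 cells/mL.  mM/h divided
by 10^6 cells/mL is pmol/cell/h with a conversion factor of exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import BatchRecord, FeedEvent, SpecificRateSeries

logger = logging.getLogger(__name__)

NUTRIENT = "nutrient"
BYPRODUCT = "byproduct"
ROLES = (NUTRIENT, BYPRODUCT)

#: role of each metabolite the bundled generator produces
DEFAULT_ROLES = {"glucose": NUTRIENT, "lactate": BYPRODUCT}

#: hours near the domain boundary where polynomial derivatives are least
#: reliable; rates there are flagged, not dropped
EDGE_MARGIN_H = 12.0

DEFAULT_DEGREE = 4


@dataclass
class PseudoConcentrationSeries:
    """Feed-corrected concentration series for one metabolite."""

    metabolite: str
    role: str
    times: np.ndarray   # h
    values: np.ndarray  # mM

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")


class SmoothPolynomial:
    """Least-squares polynomial over time with an analytic derivative.

    Fitting uses a scaled domain for conditioning; ``coefficients`` exposes
    the equivalent coefficients in the natural (unscaled) power basis,
    lowest order first.
    """

    def __init__(self, poly: np.polynomial.Polynomial, degree: int):
        self._poly = poly
        self.degree = degree
        self.domain = (float(poly.domain[0]), float(poly.domain[1]))

    @property
    def coefficients(self) -> np.ndarray:
        return self._poly.convert().coef

    def _check_domain(self, times: np.ndarray) -> None:
        lo, hi = self.domain
        tol = 1e-9 * max(1.0, abs(hi - lo))
        if np.any(times < lo - tol) or np.any(times > hi + tol):
            raise ValueError(f"evaluation outside fitted domain [{lo}, {hi}] h")

    def value(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        self._check_domain(times)
        return self._poly(times)

    def derivative(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        self._check_domain(times)
        return self._poly.deriv()(times)


def build_pseudo_concentrations(
    times,
    values,
    feeds: list[FeedEvent],
    role: str,
    metabolite: str = "",
) -> PseudoConcentrationSeries:
    """Correct a sampled concentration series for bolus feeds.

    Nutrient: subtract the recorded concentration jump of every feed from
    all samples strictly after the feed (a sample timestamped exactly at a
    feed is pre-feed by convention).  Byproduct: add back, to all later
    samples, the concentration the byproduct lost to each feed's dilution,
    computed from the last measured value before that feed.
    """
    if role not in ROLES:
        raise ValueError(f"role must be one of {ROLES}, got {role!r}")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if not np.all(np.diff(times) > 0):
        raise ValueError("sample times must be strictly increasing")

    corrected = values.copy()
    for feed in sorted(feeds, key=lambda f: f.time):
        if not times[0] <= feed.time <= times[-1]:
            raise ValueError(f"feed at {feed.time} h outside the sampled time domain")
        after = times > feed.time
        if role == NUTRIENT:
            if metabolite and metabolite not in feed.delta_conc:
                raise ValueError(f"feed at {feed.time} h has no delta_conc for {metabolite!r}")
            delta = feed.delta_conc[metabolite] if metabolite else next(iter(feed.delta_conc.values()))
            corrected[after] -= delta
        else:
            before = np.flatnonzero(times <= feed.time)
            if before.size == 0:
                raise ValueError(f"feed at {feed.time} h precedes every sample")
            c_pre = values[before[-1]]
            corrected[after] += c_pre * (1.0 - feed.dilution_factor)
    return PseudoConcentrationSeries(metabolite=metabolite, role=role,
                                     times=times, values=corrected)


def fit_smoothing_polynomial(times, values, degree: int) -> SmoothPolynomial:
    """Least-squares polynomial fit; NaN values are dropped before fitting."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values) & np.isfinite(times)
    times, values = times[keep], values[keep]
    if times.size == 0:
        raise ValueError("all values missing; nothing to fit")
    if np.unique(times).size < degree + 1:
        raise ValueError(
            f"underdetermined fit: degree {degree} needs >= {degree + 1} distinct "
            f"time points, got {np.unique(times).size}")
    poly = np.polynomial.Polynomial.fit(times, values, degree)
    return SmoothPolynomial(poly, degree)


def _phase_masks(times: np.ndarray, record: BatchRecord) -> list[np.ndarray]:
    """Boolean masks for the process phases (unfed | fed), split at the
    first feed; a sample timestamped exactly at the feed is pre-feed."""
    if not record.feeds:
        return [np.ones(times.shape, dtype=bool)]
    t_split = min(f.time for f in record.feeds)
    return [times <= t_split, times > t_split]


def _phase_degree(degree: int, phase_span: float, total_span: float, n_points: int) -> int:
    """Span-proportional degree with at least one residual df left.

    ``degree`` describes the flexibility granted to the full trajectory; a
    phase covering a fraction f of it gets ceil(degree*f), clipped so the
    fit never degenerates to interpolation (unless the phase has only two
    points, where a line is all there is).
    """
    want = min(degree, max(1, int(np.ceil(degree * phase_span / total_span))))
    return int(np.clip(min(want, n_points - 2), 1, max(1, n_points - 1)))


def estimate_specific_rates(
    record: BatchRecord,
    metabolite: str,
    role: str | None = None,
    degree: int = DEFAULT_DEGREE,
) -> SpecificRateSeries:
    """Estimate q(t) for one metabolite of one batch at its sample times.

    Builds the feed-corrected pseudo-concentration when feeds exist, fits
    the smoothing polynomials per process phase, and evaluates
    q(t) = conc'(t) / VCD_smooth(t).  Rates within ``EDGE_MARGIN_H`` of the
    batch's domain boundary are flagged as edge estimates.
    """
    if role is None:
        role = DEFAULT_ROLES.get(metabolite)
        if role is None:
            raise ValueError(f"no default role for metabolite {metabolite!r}; pass role=")
    col = f"{metabolite}_mM"
    if col not in record.samples.columns:
        raise KeyError(f"{record.batch_id}: no sampled concentration column {col!r}")
    times = record.sample_times()
    conc = record.samples[col].to_numpy(dtype=float)
    vcd = record.samples["vcd"].to_numpy(dtype=float)

    if record.feeds:
        pseudo = build_pseudo_concentrations(times, conc, record.feeds, role, metabolite)
        conc_series = pseudo.values
    else:
        conc_series = conc

    total_span = times[-1] - times[0]
    q = np.empty_like(times)
    edge = np.zeros(times.shape, dtype=bool)
    for mask in _phase_masks(times, record):
        t_seg = times[mask]
        n_distinct = np.unique(t_seg).size
        deg = _phase_degree(degree, t_seg[-1] - t_seg[0], total_span, n_distinct)
        conc_poly = fit_smoothing_polynomial(t_seg, conc_series[mask], deg)
        vcd_poly = fit_smoothing_polynomial(t_seg, vcd[mask], deg)
        dense = np.linspace(t_seg[0], t_seg[-1], 256)
        vcd_dense = vcd_poly.value(dense)
        if np.any(vcd_dense <= 0):
            raise ValueError(
                f"{record.batch_id}: smoothed VCD non-positive inside the domain "
                f"(min {vcd_dense.min():.3g}); degenerate fit")
        q[mask] = conc_poly.derivative(t_seg) / vcd_poly.value(t_seg)
        # derivatives are least reliable near the boundaries of each fit
        edge |= mask & ((times - t_seg[0] < EDGE_MARGIN_H)
                        | (t_seg[-1] - times < EDGE_MARGIN_H))

    return SpecificRateSeries(metabolite=metabolite, times=times, q=q, edge_flags=edge)


def rates_to_frame(batch_id: str, series: list[SpecificRateSeries]) -> pd.DataFrame:
    """Long-format rate table: batch_id, time_h, metabolite, q, edge_flag."""
    rows = []
    for s in series:
        for t, q, e in zip(s.times, s.q, s.edge_flags):
            rows.append((batch_id, t, s.metabolite, q, bool(e)))
    return pd.DataFrame(rows, columns=["batch_id", "time_h", "metabolite",
                                       "q_pmol_per_cell_h", "edge_flag"])


def frame_to_rates(frame: pd.DataFrame) -> dict[str, list[SpecificRateSeries]]:
    """Inverse of :func:`rates_to_frame`, grouped by batch."""
    out: dict[str, list[SpecificRateSeries]] = {}
    for (batch_id, met), grp in frame.groupby(["batch_id", "metabolite"], sort=False):
        grp = grp.sort_values("time_h")
        out.setdefault(str(batch_id), []).append(SpecificRateSeries(
            metabolite=str(met),
            times=grp["time_h"].to_numpy(),
            q=grp["q_pmol_per_cell_h"].to_numpy(),
            edge_flags=grp["edge_flag"].to_numpy(dtype=bool),
        ))
    return out
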