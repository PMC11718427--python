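"""Seeded generator of synthetic fed-batch CHO cell culture campaigns.

Emulates a two-phase production process: a 3-day unfed batch phase followed
by a 7-day fed-batch phase with glucose-triggered bolus feeds, daily
sampling of viable cell density (VCD), glucose and lactate, and an extra
sample right after each feed.  Selected batches undergo a temperature shift
(37°C → 33°C) at the time of their first glucose feed; the shift is modelled
as a multiplicative slowdown of growth, per-cell glucose consumption and
lactate yield.

The generative model is a Monod-type ODE system::

    dVCD/dt   = mu * VCD,              mu    = mu_max * s(t) * glc/(K_glc+glc)
    d[glc]/dt = q_glc * VCD,           q_glc = -q_glc_max * s(t) * glc/(K_glc+glc)
    d[lac]/dt = q_lac * VCD,           q_lac = -y_lac * s(t) * q_glc

where ``s(t)`` is 1 before the shift and ``shift_factor`` after it (for
shifted batches).  With VCD in 10^6 cells/mL and q in pmol/cell/h the
product q*VCD is exactly mM/h, so no unit factor appears in the ODEs.

Measurement noise is multiplicative Gaussian on the sampled values only;
the underlying state trajectory is retained noise-free on the integration
grid (``BatchRecord.truth``) and serves as ground truth for rate-recovery
tests downstream.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GLUCOSE_MW = 180.16  # g/mol
LACTATE_MW = 90.08   # g/mol

GLUCOSE = "glucose"
LACTATE = "lactate"
METABOLITES = (GLUCOSE, LACTATE)

NORMAL = "normal"
SHIFTED = "shifted"
CONDITIONS = (NORMAL, SHIFTED)


def g_per_l_to_mm(value_g_per_l: float, molar_mass: float) -> float:
    """Convert g/L to mM given a molar mass in g/mol."""
    return value_g_per_l / molar_mass * 1000.0


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic fed-batch process.

    Concentration triggers/targets are in g/L (as read off the process
    recipe); everything internal runs in mM.
    """

    mu_max: float = 0.012        # maximal specific growth rate at 37°C, 1/h
    k_glc: float = 0.5           # Monod constant for glucose, mM
    q_glc_max: float = 0.25      # maximal specific glucose consumption, pmol/cell/h
    y_lac: float = 1.4           # lactate produced per glucose consumed, mol/mol
    shift_factor: float = 0.6    # post-shift multiplier on mu_max, q_glc_max, y_lac
    noise_cv: float = 0.05       # relative measurement noise
    inoc_vcd: float = 0.3        # inoculation density, 10^6 cells/mL
    glc_trigger: float = 3.0     # feed trigger concentration, g/L
    glc_target: float = 6.0      # post-feed target concentration, g/L
    init_glc: float = 4.0        # initial glucose, g/L
    init_lac: float = 0.0        # initial lactate, mM
    batch_days: int = 3          # unfed batch phase duration
    fedbatch_days: int = 7       # fed-batch phase duration
    dt: float = 0.1              # integration step, h
    seed: int = 0
    init_volume_ml: float = 12.0       # working volume at inoculation
    feed_volume_fraction: float = 0.015  # bolus volume / vessel volume

    def validate(self) -> None:
        positive = {
            "k_glc": self.k_glc, "y_lac": self.y_lac,
            "inoc_vcd": self.inoc_vcd, "glc_trigger": self.glc_trigger,
            "glc_target": self.glc_target, "init_glc": self.init_glc,
            "dt": self.dt, "init_volume_ml": self.init_volume_ml,
        }
        for name, value in positive.items():
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"SimParams.{name} must be strictly positive, got {value}")
        # zero is a legitimate degenerate setting (no growth / no consumption)
        for name, value in (("mu_max", self.mu_max), ("q_glc_max", self.q_glc_max)):
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"SimParams.{name} must be >= 0 and finite, got {value}")
        if not 0.0 < self.shift_factor <= 1.0:
            raise ValueError(f"shift_factor must be in (0, 1], got {self.shift_factor}")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.init_lac < 0:
            raise ValueError(f"init_lac must be >= 0, got {self.init_lac}")
        if self.batch_days < 0 or self.fedbatch_days < 0 or self.batch_days + self.fedbatch_days < 1:
            raise ValueError("phase durations must be non-negative and sum to >= 1 day")
        if not 0.0 < self.feed_volume_fraction <= 0.02:
            raise ValueError("feed_volume_fraction must be in (0, 0.02] (bolus <= 2% of volume)")

    @property
    def glc_trigger_mm(self) -> float:
        return g_per_l_to_mm(self.glc_trigger, GLUCOSE_MW)

    @property
    def glc_target_mm(self) -> float:
        return g_per_l_to_mm(self.glc_target, GLUCOSE_MW)

    @property
    def init_glc_mm(self) -> float:
        return g_per_l_to_mm(self.init_glc, GLUCOSE_MW)

    def replace(self, **kwargs) -> "SimParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class FeedEvent:
    """A bolus feed: concentration jumps imparted to the vessel and the
    accompanying dilution (pre-feed volume / post-feed volume)."""

    time: float                      # h since inoculation
    delta_conc: dict[str, float]     # mM jump per metabolite (0 for byproducts)
    dilution_factor: float           # V_pre / V_post, in (0, 1]

    def __post_init__(self) -> None:
        if not 0.0 < self.dilution_factor <= 1.0:
            raise ValueError(f"dilution_factor must be in (0, 1], got {self.dilution_factor}")
        for met, dc in self.delta_conc.items():
            if not np.isfinite(dc):
                raise ValueError(f"delta_conc[{met}] is not finite")


@dataclass
class BatchRecord:
    """One reactor run: sampled trajectories, feed events, condition label.

    ``samples`` columns: time_h, vcd, glucose_mM, lactate_mM, volume_mL,
    post_feed.  ``truth`` (optional) is the dense noise-free state trace with
    the simulator's instantaneous specific rates, used as a ground-truth
    oracle; it is never serialized.
    """

    batch_id: str
    condition: str
    shift_time: float | None
    samples: pd.DataFrame
    feeds: list[FeedEvent] = field(default_factory=list)
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def sample_times(self) -> np.ndarray:
        return self.samples["time_h"].to_numpy()

    def validate(self) -> None:
        t = self.sample_times()
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"{self.batch_id}: sample times must be strictly increasing")
        if not np.all(self.samples["vcd"] > 0):
            raise ValueError(f"{self.batch_id}: VCD must be strictly positive")
        for met in METABOLITES:
            if not np.all(self.samples[f"{met}_mM"] >= 0):
                raise ValueError(f"{self.batch_id}: {met} concentrations must be >= 0")
        for feed in self.feeds:
            if not t[0] <= feed.time <= t[-1]:
                raise ValueError(f"{self.batch_id}: feed at {feed.time} h outside sampled interval")
            if not np.any(t > feed.time):
                raise ValueError(f"{self.batch_id}: feed at {feed.time} h has no sample after it")


@dataclass
class SpecificRateSeries:
    """Per-cell transport rate of one metabolite over time.

    Sign convention: positive = net secretion into the medium, negative =
    net consumption (the rate enters the medium mass balance as production).
    """

    metabolite: str
    times: np.ndarray            # h
    q: np.ndarray                # pmol/cell/h
    edge_flags: np.ndarray | None = None  # True where the estimate sits at the domain edge

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.times.shape != self.q.shape:
            raise ValueError("times and q must have the same shape")
        if self.edge_flags is None:
            self.edge_flags = np.zeros(self.times.shape, dtype=bool)

    def at(self, time: float, atol: float = 1e-6) -> float:
        idx = np.flatnonzero(np.isclose(self.times, time, atol=atol))
        if idx.size == 0:
            raise KeyError(f"no rate value at t={time} h for {self.metabolite}")
        return float(self.q[idx[0]])


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _rates(params: SimParams, glc: float, scale: float) -> tuple[float, float, float]:
    """Instantaneous (mu, q_glc, q_lac) at a given glucose level."""
    monod = glc / (params.k_glc + glc) if glc > 0 else 0.0
    mu = params.mu_max * scale * monod
    q_glc = -params.q_glc_max * scale * monod
    q_lac = -params.y_lac * scale * q_glc
    return mu, q_glc, q_lac


def simulate_batch(params: SimParams, condition: str, batch_id: str) -> BatchRecord:
    """Simulate one reactor run.

    Heun (explicit trapezoid) integration of the Monod ODEs; a daily feed
    check during the fed-batch phase restores glucose to the target when it
    has dropped below the trigger.  For ``condition="shifted"`` the
    temperature shift takes effect at the first feed time.  Daily samples
    are taken pre-feed; one extra sample is recorded immediately after each
    feed (its glucose value is the restoration target by construction).
    """
    params.validate()
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")

    rng = np.random.default_rng(params.seed)
    total_days = params.batch_days + params.fedbatch_days
    dt = params.dt
    steps_per_day = int(round(24.0 / dt))
    if abs(steps_per_day * dt - 24.0) > 1e-9:
        raise ValueError("dt must divide 24 h evenly")

    vcd, glc, lac = params.inoc_vcd, params.init_glc_mm, params.init_lac
    vol = params.init_volume_ml
    shift_time: float | None = None

    truth_rows: list[tuple] = []
    sample_rows: list[tuple] = []
    feeds: list[FeedEvent] = []

    def scale_at(t: float) -> float:
        if condition == SHIFTED and shift_time is not None and t >= shift_time:
            return params.shift_factor
        return 1.0

    def record_truth(t: float) -> None:
        mu, q_g, q_l = _rates(params, glc, scale_at(t))
        truth_rows.append((t, vcd, glc, lac, vol, mu, q_g, q_l))

    def take_sample(t: float, post_feed: bool) -> None:
        def noisy(x: float) -> float:
            if params.noise_cv == 0:
                return x
            return max(0.0, x * (1.0 + params.noise_cv * rng.standard_normal()))
        glc_meas = glc if post_feed else noisy(glc)
        sample_rows.append((t, noisy(vcd), glc_meas, noisy(lac), vol, post_feed))

    record_truth(0.0)
    take_sample(0.0, post_feed=False)

    step = 0
    t = 0.0
    for day in range(1, total_days + 1):
        for _ in range(steps_per_day):
            s0 = scale_at(t)
            mu0, qg0, ql0 = _rates(params, glc, s0)
            d0 = (mu0 * vcd, qg0 * vcd, ql0 * vcd)
            step += 1
            t1 = 24.0 * (step // steps_per_day) + dt * (step % steps_per_day)
            s1 = scale_at(t1)
            glc_p = glc + dt * d0[1]
            vcd_p = vcd + dt * d0[0]
            mu1, qg1, ql1 = _rates(params, max(glc_p, 0.0), s1)
            d1 = (mu1 * vcd_p, qg1 * vcd_p, ql1 * vcd_p)
            vcd += 0.5 * dt * (d0[0] + d1[0])
            glc += 0.5 * dt * (d0[1] + d1[1])
            lac += 0.5 * dt * (d0[2] + d1[2])
            if not all(np.isfinite(x) for x in (vcd, glc, lac)):
                raise FloatingPointError(
                    f"{batch_id}: non-finite state at t={t1:.1f} h; rejecting parameters")
            if glc < 0:
                logger.warning("%s: glucose clipped to 0 at t=%.1f h", batch_id, t1)
                glc = 0.0
            if lac < 0:
                logger.warning("%s: lactate clipped to 0 at t=%.1f h", batch_id, t1)
                lac = 0.0
            t = t1
            record_truth(t)

        # Daily (pre-feed) sample at the day boundary.
        take_sample(t, post_feed=False)

        # Feed check: fed-batch phase only, no feed after the final sample.
        in_fed_phase = params.batch_days <= day < total_days
        if in_fed_phase and glc < params.glc_trigger_mm:
            glc_pre, lac_pre, vcd_pre = glc, lac, vcd
            vol_new = vol * (1.0 + params.feed_volume_fraction)
            dfac = vol / vol_new
            glc = params.glc_target_mm
            lac = lac_pre * dfac
            vcd = vcd_pre * dfac
            vol = vol_new
            feeds.append(FeedEvent(
                time=t,
                delta_conc={GLUCOSE: glc - glc_pre, LACTATE: 0.0},
                dilution_factor=dfac,
            ))
            if condition == SHIFTED and shift_time is None:
                shift_time = t
            # Post-feed sample, timestamped one step after the feed.
            record_truth(t)  # post-feed state at the same clock time
            take_sample(t + dt, post_feed=True)

    samples = pd.DataFrame(
        sample_rows,
        columns=["time_h", "vcd", "glucose_mM", "lactate_mM", "volume_mL", "post_feed"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["time_h", "vcd", "glucose_mM", "lactate_mM", "volume_mL",
                 "mu", "q_glc", "q_lac"],
    )
    record = BatchRecord(
        batch_id=batch_id,
        condition=condition,
        shift_time=shift_time if condition == SHIFTED else None,
        samples=samples,
        feeds=feeds,
        truth=truth,
    )
    record.validate()
    return record


def simulate_campaign(
    params: SimParams,
    n_normal: int,
    n_shifted: int,
    duration_days: int | None = None,
) -> list[BatchRecord]:
    """Simulate a campaign of independent reactor runs.

    Each batch receives a reproducible sub-seed derived from ``params.seed``
    and its index.  ``duration_days`` overrides the total duration by
    shortening/lengthening the fed-batch phase (the unfed phase is fixed).
    """
    if n_normal + n_shifted < 1:
        raise ValueError("campaign must contain at least one batch")
    if duration_days is not None:
        fed = duration_days - params.batch_days
        if fed < 0:
            raise ValueError("duration_days shorter than the unfed batch phase")
        params = params.replace(fedbatch_days=fed)

    children = np.random.SeedSequence(params.seed).spawn(n_normal + n_shifted)
    records = []
    for i, child in enumerate(children):
        condition = NORMAL if i < n_normal else SHIFTED
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        batch_params = params.replace(seed=sub_seed)
        records.append(simulate_batch(batch_params, condition, batch_id=f"B{i + 1:02d}"))
    return records


def true_specific_rates(params: SimParams, record: BatchRecord) -> dict[str, SpecificRateSeries]:
    """Ground-truth per-cell rates at the record's sample times.

    Reads the simulator's retained noise-free state trace; the returned
    q_glc is negative (consumption) and q_lac positive (secretion), matching
    the medium-accumulation sign convention used throughout.
    """
    if record.truth is None:
        raise ValueError(f"{record.batch_id}: no retained state trace; "
                         "record was not generated by this module")
    truth = record.truth
    out: dict[str, SpecificRateSeries] = {}
    times = record.sample_times()
    for met, col in ((GLUCOSE, "q_glc"), (LACTATE, "q_lac")):
        # Post-feed samples are timestamped dt after the feed; interpolate on
        # the dense grid (duplicate feed-time entries: take the last, i.e.
        # the post-feed state).
        tt = truth["time_h"].to_numpy()
        qq = truth[col].to_numpy()
        # The trace holds pre- and post-feed rows at the same clock time;
        # keep the first (pre-feed) so daily pre-feed samples map correctly.
        # Post-feed samples sit one dt later, on an ordinary grid point.
        keep = np.append(True, np.diff(tt) > 0)
        q_at = np.interp(times, tt[keep], qq[keep])
        out[met] = SpecificRateSeries(metabolite=met, times=times, q=q_at)
    return out


# ---------------------------------------------------------------------------
# CSV interchange (long format)
# ---------------------------------------------------------------------------

_UNIT = {"vcd": "1e6 cells/mL", "glucose_mM": "mM", "lactate_mM": "mM",
         "volume_mL": "mL", "post_feed": "flag"}


def campaign_to_frames(records: list[BatchRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a campaign into (samples, feeds) long-format DataFrames."""
    sample_parts, feed_rows = [], []
    for rec in records:
        long = rec.samples.melt(id_vars=["time_h"], var_name="variable", value_name="value")
        long.insert(0, "batch_id", rec.batch_id)
        long.insert(1, "condition", rec.condition)
        long["unit"] = long["variable"].map(_UNIT)
        sample_parts.append(long)
        for feed in rec.feeds:
            for met in METABOLITES:
                feed_rows.append((rec.batch_id, feed.time, met,
                                  feed.delta_conc.get(met, 0.0), feed.dilution_factor))
    samples = pd.concat(sample_parts, ignore_index=True)
    feeds = pd.DataFrame(
        feed_rows,
        columns=["batch_id", "time_h", "metabolite", "delta_conc_mM", "dilution_factor"],
    )
    return samples, feeds


def write_campaign(records: list[BatchRecord], samples_path, feeds_path) -> None:
    samples, feeds = campaign_to_frames(records)
    samples.to_csv(samples_path, index=False, float_format="%.12g")
    feeds.to_csv(feeds_path, index=False, float_format="%.12g")


def read_campaign(samples_path, feeds_path) -> list[BatchRecord]:
    """Rebuild BatchRecords from the CSV pair (no ground-truth trace)."""
    samples = pd.read_csv(samples_path)
    feeds = pd.read_csv(feeds_path)
    records = []
    for batch_id, grp in samples.groupby("batch_id", sort=False):
        condition = str(grp["condition"].iloc[0])
        wide = grp.pivot_table(index="time_h", columns="variable", values="value").reset_index()
        wide["post_feed"] = wide["post_feed"].astype(bool)
        wide = wide[["time_h", "vcd", "glucose_mM", "lactate_mM", "volume_mL", "post_feed"]]
        batch_feeds = []
        fsub = feeds[feeds["batch_id"] == batch_id]
        for time_h, fgrp in fsub.groupby("time_h", sort=True):
            delta = dict(zip(fgrp["metabolite"], fgrp["delta_conc_mM"]))
            batch_feeds.append(FeedEvent(
                time=float(time_h), delta_conc=delta,
                dilution_factor=float(fgrp["dilution_factor"].iloc[0])))
        shift_time = batch_feeds[0].time if (condition == SHIFTED and batch_feeds) else None
        rec = BatchRecord(batch_id=str(batch_id), condition=condition,
                          shift_time=shift_time, samples=wide, feeds=batch_feeds)
        rec.validate()
        records.append(rec)
    return records
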