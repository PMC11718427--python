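"""Golden-batch monitoring from flux time courses.

Two constructs operate on the per-batch flux matrices:

* **Batch evolution model (BEM)** — observation-wise unfolding (one row per
  batch/time pair), PLS1 against batch maturity (hours since inoculation),
  and per-component control charts built from the training batches' score
  trajectories: mean ± 3 standard deviations at each common time.  The
  charts collectively define the golden batch; a monitored batch whose
  score leaves the envelope raises an excursion.

* **Batch level model (BLM)** — batch-wise unfolding (one row per batch,
  one column per time × variable combination), PCA, and a one-dimensional
  classification rule: the component that best separates the two training
  classes, thresholded at the midpoint of the class means.

Batches are aligned on a daily grid by nearest-sample matching inside a
±2 h window; post-feed extra samples (a fraction of an hour after the daily
sample) lose the nearest-match tie and are excluded from the grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fba import FluxMatrix
from .latent import LatentModel, fit_pca, fit_pls1, model_from_dict, model_to_dict

logger = logging.getLogger(__name__)

#: half-width of the daily-grid matching window, h
ALIGN_WINDOW_H = 2.0

#: control-chart half-width in training-score standard deviations
CHART_SD_MULTIPLE = 3.0

NORMAL = "normal"
SHIFTED = "shifted"


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedCampaign:
    """Per-batch flux rows matched onto a common daily time grid."""

    common_times: np.ndarray              # h
    batch_ids: list[str]
    columns: list[str]
    values: np.ndarray                    # (n_batches, n_times, n_columns)

    @property
    def n_batches(self) -> int:
        return len(self.batch_ids)


def _match_daily(times: np.ndarray, anchor: float) -> int | None:
    """Index of the sample nearest to ``anchor`` within the window, or None.

    Near-ties (e.g. a pre-feed daily sample and the post-feed sample a
    fraction of an hour later) resolve to the earlier sample.
    """
    dist = np.abs(times - anchor)
    ok = np.flatnonzero(dist <= ALIGN_WINDOW_H)
    if ok.size == 0:
        return None
    return int(ok[np.argmin(dist[ok])])  # argmin takes the first = earliest on ties


def align_campaign(
    matrices: list[FluxMatrix],
    max_time_h: float | None = None,
) -> AlignedCampaign:
    """Intersect batches onto a daily grid (anchors at 24 k hours).

    An anchor survives only if every batch has a sample within ±2 h of it;
    values come from the nearest such sample, never from extrapolation.
    The shortest batch therefore defines the end of the grid, and
    ``max_time_h`` can truncate it further (e.g. to make a 10-day training
    campaign comparable with a 9-day one).
    """
    if not matrices:
        raise ValueError("no batches to align")
    columns = matrices[0].columns
    for m in matrices:
        if m.columns != columns:
            raise ValueError(f"{m.batch_id}: column set differs from {matrices[0].batch_id}")

    horizon = min(m.times[-1] for m in matrices)
    if max_time_h is not None:
        horizon = min(horizon, max_time_h)
    anchors = np.arange(0.0, horizon + ALIGN_WINDOW_H + 1e-9, 24.0)

    kept, rows_per_batch = [], {m.batch_id: [] for m in matrices}
    for anchor in anchors:
        picks = [_match_daily(m.times, anchor) for m in matrices]
        if any(p is None for p in picks):
            continue
        kept.append(anchor)
        for m, p in zip(matrices, picks):
            rows_per_batch[m.batch_id].append(m.values[p])
    if not kept:
        raise ValueError("empty time intersection: no daily anchor is covered by all batches")

    values = np.stack([np.vstack(rows_per_batch[m.batch_id]) for m in matrices])
    return AlignedCampaign(common_times=np.asarray(kept),
                           batch_ids=[m.batch_id for m in matrices],
                           columns=list(columns), values=values)


def _subset(aligned: AlignedCampaign, batch_ids: list[str]) -> AlignedCampaign:
    idx = [aligned.batch_ids.index(b) for b in batch_ids]
    return AlignedCampaign(common_times=aligned.common_times, batch_ids=list(batch_ids),
                           columns=aligned.columns, values=aligned.values[idx])


# ---------------------------------------------------------------------------
# Batch evolution model
# ---------------------------------------------------------------------------

@dataclass
class ControlChart:
    """±3 SD envelope of one component's training scores over time."""

    component: int                 # 1-based index
    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    @property
    def lower(self) -> np.ndarray:
        return self.mean - CHART_SD_MULTIPLE * self.sd

    @property
    def upper(self) -> np.ndarray:
        return self.mean + CHART_SD_MULTIPLE * self.sd


@dataclass
class BEMModel:
    latent: LatentModel            # PLS1, y = time
    charts: list[ControlChart]
    columns: list[str]
    monitored_components: list[int]  # 1-based


@dataclass
class MonitoringReport:
    batch_id: str
    times: np.ndarray                       # matched chart times
    scores: np.ndarray                      # (n_times, A)
    in_control: np.ndarray                  # (n_times, n_monitored) booleans
    monitored_components: list[int]
    first_excursion_time: float | None
    sustained_k: int = 1

    def to_frame(self, bem: "BEMModel") -> pd.DataFrame:
        rows = []
        for ci, comp in enumerate(self.monitored_components):
            chart = bem.charts[comp - 1]
            for ti, t in enumerate(self.times):
                gi = int(np.argmin(np.abs(chart.times - t)))
                rows.append((self.batch_id, t, comp, self.scores[ti, comp - 1],
                             chart.lower[gi], chart.upper[gi],
                             bool(self.in_control[ti, ci])))
        return pd.DataFrame(rows, columns=["batch_id", "time_h", "component",
                                           "score", "lower", "upper", "in_control"])


def train_bem(
    train: AlignedCampaign,
    n_components: int,
    monitored: list[int] | None = None,
) -> BEMModel:
    """Fit the time-as-response PLS model and its score control charts.

    Rows are the observation-wise unfolded (batch, time) flux vectors; the
    response is the time coordinate.  Limits use the across-batch score
    mean ± 3 SD (n−1 denominator) at each common time, so at least two
    training batches are required.
    """
    if train.n_batches < 2:
        raise ValueError("control limits need at least 2 training batches")
    n_b, n_t, n_v = train.values.shape
    X = train.values.reshape(n_b * n_t, n_v)
    y = np.tile(train.common_times, n_b)
    latent = fit_pls1(X, y, n_components)
    scores = latent.scores_train.reshape(n_b, n_t, n_components)

    charts = []
    for a in range(n_components):
        mean = scores[:, :, a].mean(axis=0)
        sd = scores[:, :, a].std(axis=0, ddof=1)
        if np.all(sd == 0):
            warnings.warn(f"component {a + 1}: zero score spread across training "
                          "batches; control chart is degenerate", stacklevel=2)
        charts.append(ControlChart(component=a + 1, times=train.common_times,
                                   mean=mean, sd=sd))
    monitored = list(range(1, n_components + 1)) if monitored is None else list(monitored)
    for comp in monitored:
        if not 1 <= comp <= n_components:
            raise ValueError(f"monitored component {comp} outside 1..{n_components}")
    return BEMModel(latent=latent, charts=charts, columns=list(train.columns),
                    monitored_components=monitored)


def monitor_batch(bem: BEMModel, matrix: FluxMatrix, sustained_k: int = 1) -> MonitoringReport:
    """Project one batch through the BEM and flag chart excursions.

    Each flux row is matched to the nearest chart time within the alignment
    window; the first excursion is the earliest matched time at which any
    monitored component stays outside its limits for ``sustained_k``
    consecutive grid points.
    """
    if matrix.columns != bem.columns:
        missing = set(bem.columns) ^ set(matrix.columns)
        raise ValueError(f"{matrix.batch_id}: column mismatch with the trained model "
                         f"(difference: {sorted(missing)})")
    grid = bem.charts[0].times
    matched_rows, matched_times, grid_idx = [], [], []
    for anchor_i, anchor in enumerate(grid):
        pick = _match_daily(matrix.times, anchor)
        if pick is None:
            continue
        matched_rows.append(matrix.values[pick])
        matched_times.append(anchor)
        grid_idx.append(anchor_i)
    if not matched_rows:
        raise ValueError(f"{matrix.batch_id}: no time overlap with the control-chart grid")

    scores = bem.latent.project(np.vstack(matched_rows))
    times = np.asarray(matched_times)
    flags = np.ones((len(times), len(bem.monitored_components)), dtype=bool)
    for ci, comp in enumerate(bem.monitored_components):
        chart = bem.charts[comp - 1]
        lo, hi = chart.lower[grid_idx], chart.upper[grid_idx]
        s = scores[:, comp - 1]
        flags[:, ci] = (s >= lo) & (s <= hi)

    out = ~flags.all(axis=1)
    first = None
    run = 0
    for ti in range(len(times)):
        run = run + 1 if out[ti] else 0
        if run >= sustained_k:
            first = float(times[ti - sustained_k + 1])
            break
    return MonitoringReport(batch_id=matrix.batch_id, times=times, scores=scores,
                            in_control=flags,
                            monitored_components=list(bem.monitored_components),
                            first_excursion_time=first, sustained_k=sustained_k)


# ---------------------------------------------------------------------------
# Batch level model
# ---------------------------------------------------------------------------

def unfold_batchwise(aligned: AlignedCampaign) -> np.ndarray:
    """One row per batch; columns ordered time-major, variable-minor."""
    n_b, n_t, n_v = aligned.values.shape
    return aligned.values.reshape(n_b, n_t * n_v)


def batchwise_column_ids(aligned: AlignedCampaign) -> list[str]:
    return [f"t{t:g}h:{c}" for t in aligned.common_times for c in aligned.columns]


@dataclass
class BLMModel:
    latent: LatentModel              # PCA on batch-wise unfolded rows
    discriminating_component: int    # 1-based
    threshold: float
    normal_side: int                 # +1: normal scores above threshold; -1: below
    common_times: np.ndarray
    columns: list[str]


def train_blm(rows: np.ndarray, labels: list[str], n_components: int = 2) -> BLMModel:
    """PCA + one-component midpoint classifier between normal and shifted.

    The discriminating component maximizes |mean difference| / pooled SD of
    the two classes' training scores; the threshold is the midpoint of the
    class means, and the side containing the normal-class mean is recorded.
    """
    labels = list(labels)
    classes = set(labels)
    if classes != {NORMAL, SHIFTED}:
        raise ValueError(f"labels must contain both {NORMAL!r} and {SHIFTED!r}; got {classes}")
    is_normal = np.array([lab == NORMAL for lab in labels])
    if is_normal.sum() < 2 or (~is_normal).sum() < 2:
        raise ValueError("need at least 2 batches per class")

    latent = fit_pca(rows, n_components)
    T = latent.scores_train
    best, best_sep = None, -np.inf
    for a in range(n_components):
        m_n, m_s = T[is_normal, a].mean(), T[~is_normal, a].mean()
        pooled = np.sqrt(0.5 * (T[is_normal, a].var(ddof=1) + T[~is_normal, a].var(ddof=1)))
        sep = np.inf if pooled == 0 and m_n != m_s else abs(m_n - m_s) / pooled if pooled > 0 else 0.0
        if sep > best_sep:
            best, best_sep = a, sep
    a = best
    m_n, m_s = T[is_normal, a].mean(), T[~is_normal, a].mean()
    if np.isclose(m_n, m_s):
        raise ValueError("class score means coincide on every component; "
                         "zero-width classification threshold")
    return BLMModel(latent=latent, discriminating_component=a + 1,
                    threshold=float(0.5 * (m_n + m_s)),
                    normal_side=+1 if m_n > m_s else -1,
                    common_times=np.array([]), columns=[])


def train_blm_from_campaign(
    aligned: AlignedCampaign,
    labels: list[str],
    n_components: int = 2,
) -> BLMModel:
    """Convenience wrapper recording the unfolding layout on the model."""
    blm = train_blm(unfold_batchwise(aligned), labels, n_components)
    blm.common_times = aligned.common_times.copy()
    blm.columns = list(aligned.columns)
    return blm


def separation_statistic(rows: np.ndarray, labels: list[str], n_components: int = 2) -> float:
    """|class mean difference| / pooled SD on the discriminating component."""
    blm = train_blm(rows, labels, n_components)
    T = blm.latent.scores_train[:, blm.discriminating_component - 1]
    is_normal = np.array([lab == NORMAL for lab in labels])
    pooled = np.sqrt(0.5 * (T[is_normal].var(ddof=1) + T[~is_normal].var(ddof=1)))
    return float(abs(T[is_normal].mean() - T[~is_normal].mean()) / pooled)


def classify_batch(blm: BLMModel, row: np.ndarray) -> tuple[str, float]:
    """Classify one batch-wise unfolded row; ties at the threshold are shifted."""
    score = float(blm.latent.project(np.atleast_2d(row))[0, blm.discriminating_component - 1])
    on_normal_side = blm.normal_side * (score - blm.threshold) > 0
    return (NORMAL if on_normal_side else SHIFTED), score


def classify_flux_matrix(blm: BLMModel, matrix: FluxMatrix) -> tuple[str, float]:
    """Align one batch's flux matrix onto the model's stored grid and classify."""
    if matrix.columns != blm.columns:
        missing = set(blm.columns) ^ set(matrix.columns)
        raise ValueError(f"{matrix.batch_id}: column mismatch (difference: {sorted(missing)})")
    rows = []
    for anchor in blm.common_times:
        pick = _match_daily(matrix.times, anchor)
        if pick is None:
            raise ValueError(f"{matrix.batch_id}: no sample within {ALIGN_WINDOW_H} h "
                             f"of grid time {anchor} h")
        rows.append(matrix.values[pick])
    return classify_batch(blm, np.concatenate(rows))


# ---------------------------------------------------------------------------
# Serialization (golden-batch export/import)
# ---------------------------------------------------------------------------

def bem_to_dict(bem: BEMModel) -> dict:
    return {
        "latent": model_to_dict(bem.latent),
        "columns": bem.columns,
        "monitored_components": bem.monitored_components,
        "charts": [
            {"component": c.component, "times": c.times.tolist(),
             "mean": c.mean.tolist(), "sd": c.sd.tolist()}
            for c in bem.charts
        ],
    }


def bem_from_dict(data: dict) -> BEMModel:
    charts = [ControlChart(component=int(c["component"]), times=np.array(c["times"]),
                           mean=np.array(c["mean"]), sd=np.array(c["sd"]))
              for c in data["charts"]]
    return BEMModel(latent=model_from_dict(data["latent"]), charts=charts,
                    columns=list(data["columns"]),
                    monitored_components=list(data["monitored_components"]))


def blm_to_dict(blm: BLMModel) -> dict:
    return {
        "latent": model_to_dict(blm.latent),
        "discriminating_component": blm.discriminating_component,
        "threshold": blm.threshold,
        "normal_side": blm.normal_side,
        "common_times": blm.common_times.tolist(),
        "columns": blm.columns,
    }


def blm_from_dict(data: dict) -> BLMModel:
    return BLMModel(latent=model_from_dict(data["latent"]),
                    discriminating_component=int(data["discriminating_component"]),
                    threshold=float(data["threshold"]),
                    normal_side=int(data["normal_side"]),
                    common_times=np.array(data["common_times"]),
                    columns=list(data["columns"]))
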