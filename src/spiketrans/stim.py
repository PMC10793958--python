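"""Closed-loop feedback metrics: trigger efficiency and light activation.

The closed-loop efficiency (CLE) of a unit is the fraction of its spikes
that were used to generate light stimuli, estimated from the excess of the
peristimulus time histogram (PSTH) in the −5 ≤ τ < 0 ms region immediately
preceding stimulus onset, over a hollowed-median baseline. It is bounded to
[0, 1]: 0 when no spikes triggered stimuli, 1 when every spike was followed
by exactly one stimulus.

Light activation of a (putative PV) unit is assessed from the same PSTH:
the firing rate in 10 ≤ τ < 30 ms after onset is compared with the mean
rate in a pre-onset baseline window (−30 ≤ τ < −15 ms) with a Poisson test,
and their ratio is the light-induced rate gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Session, SpikeTrain, StimulusEvents
from .correlograms import (
    hollow_bins,
    hollowed_median_baseline,
    poisson_excess_test,
    psth,
)

__all__ = ["StimResponse", "closed_loop_efficiency", "light_response",
           "stim_responses"]

PSTH_BIN_S = 0.001
PSTH_WINDOW = (-0.050, 0.050)
CLE_ROI = (-0.005, 0.0)          # −5 ≤ τ < 0 ms
LIGHT_ROI = (0.010, 0.030)       # 10 ≤ τ < 30 ms
LIGHT_BASELINE = (-0.030, -0.015)  # −30 ≤ τ < −15 ms
P_TRIGGER_THRESHOLD = 0.001
P_LIGHT_THRESHOLD = 0.05


@dataclass
class StimResponse:
    """Per-unit closed-loop feedback summary."""

    unit_id: str
    cle: float
    p_trigger: float
    is_trigger: bool
    light_gain: float
    p_light: float
    is_light_activated: bool


def _half_open_roi(edges: np.ndarray, low: float, high: float) -> slice:
    """Bins fully inside the half-open window [low, high)."""
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.flatnonzero((centers > low) & (centers < high))
    if idx.size == 0:
        raise ValueError("ROI covers no bins")
    return slice(int(idx[0]), int(idx[-1]) + 1)


def closed_loop_efficiency(
    train: SpikeTrain,
    events: StimulusEvents,
    period: tuple[float, float] | None = None,
    bin_width_s: float = PSTH_BIN_S,
    window: tuple[float, float] = PSTH_WINDOW,
    baseline_half_width_s: float = 0.005,
) -> tuple[float, float]:
    """CLE and trigger p-value for one unit.

    ``period`` is the analyzed interval (typically the stimulation epoch);
    its spike count is the denominator — "what fraction of this unit's
    spikes generated stimuli". Defaults to the full span of the train.
    """
    if events.n_events == 0:
        raise ValueError("CLE undefined without events")
    if period is not None:
        train = train.restrict([period])
    if train.n_spikes == 0:
        raise ValueError("CLE undefined without spikes in the analyzed period")
    h = psth(train, events.onsets, bin_width_s, window)
    hw = hollow_bins(baseline_half_width_s, bin_width_s)
    baseline = hollowed_median_baseline(h.counts, hw)
    roi = _half_open_roi(h.edges, *CLE_ROI)
    excess = float((h.counts[roi] - baseline[roi]).sum())
    cle = float(np.clip(excess / train.n_spikes, 0.0, 1.0))
    p_trigger = poisson_excess_test(
        int(h.counts[roi].sum()), float(baseline[roi].sum())
    )
    return cle, p_trigger


def light_response(
    post_train: SpikeTrain,
    events: StimulusEvents,
    bin_width_s: float = PSTH_BIN_S,
    window: tuple[float, float] = PSTH_WINDOW,
) -> tuple[float, float]:
    """Light-induced rate gain and its Poisson p-value.

    Gain is the mean PSTH rate in 10 ≤ τ < 30 ms divided by the mean rate
    in the pre-onset baseline −30 ≤ τ < −15 ms; NaN (flagged) when the
    baseline window holds no counts.
    """
    if events.n_events == 0:
        raise ValueError("light response undefined without events")
    h = psth(post_train, events.onsets, bin_width_s, window)
    roi = _half_open_roi(h.edges, *LIGHT_ROI)
    base = _half_open_roi(h.edges, *LIGHT_BASELINE)
    n_roi_bins = roi.stop - roi.start
    n_base_bins = base.stop - base.start
    obs = int(h.counts[roi].sum())
    base_counts = float(h.counts[base].sum())
    expected = base_counts * n_roi_bins / n_base_bins
    p_light = poisson_excess_test(obs, expected)
    if base_counts == 0:
        return float("nan"), p_light
    gain = (obs / n_roi_bins) / (base_counts / n_base_bins)
    return float(gain), p_light


def stim_responses(session: Session, unit_ids: list[str] | None = None):
    """Closed-loop feedback summary for every unit of a session."""
    import pandas as pd

    if session.events.n_events == 0:
        raise ValueError("session has no stimulus events")
    period = (
        session.epochs["Experience"] if "Experience" in session.epochs else None
    )
    rows = []
    for uid in unit_ids or session.units():
        train = session.trains[uid]
        try:
            cle, p_trig = closed_loop_efficiency(train, session.events, period)
        except ValueError:
            cle, p_trig = float("nan"), float("nan")
        gain, p_light = light_response(train, session.events)
        rows.append(
            StimResponse(
                unit_id=uid, cle=cle, p_trigger=p_trig,
                is_trigger=bool(p_trig < P_TRIGGER_THRESHOLD),
                light_gain=gain, p_light=p_light,
                is_light_activated=bool(p_light < P_LIGHT_THRESHOLD),
            ).__dict__
        )
    return pd.DataFrame(rows)
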