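"""Synthetic closed-loop sessions with known ground truth.

The generator emulates the statistics of CA1 recordings under closed-loop
optogenetic feedback: sparse pyramidal-cell (PYR) trains with absolute
refractoriness, fast-spiking PV interneurons receiving monosynaptic excess
drive from several converging PYRs (a converging assembly), real-time spike
detection driving 30-ms light stimuli after a 3-ms delay with a 20-ms dead
time, a multiplicative light-induced PV rate gain, and a multiplicative
change of transmission probability between the Before and the
Experience/After epochs (the injected "plasticity").

The postsynaptic process is an inhomogeneous Poisson superposition

    λ(t) = base_rate · g(t) + Σ_pairs Σ_{s ∈ presyn} k(t − s),

with g(t) the light gain inside stimulus intervals and k a per-pair causal
kernel of integral p (the transmission probability). It is sampled exactly
by superposing the piecewise-constant baseline process with Poisson(p)
offspring per presynaptic spike drawn from the kernel shape; absolute
refractoriness is then imposed on the merged train.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CellClass, EpochSet, Session, SpikeTrain, StimulusEvents

__all__ = [
    "SimConfig",
    "PairCoupling",
    "GroundTruth",
    "simulate_refractory_poisson",
    "simulate_presyn_trains",
    "run_closed_loop",
    "simulate_postsyn_train",
    "generate_session",
    "simulate_pair",
    "simulate_stim_feature_cohort",
]

DEFAULT_KERNEL_WINDOW = (0.0005, 0.0035)  # causal rectangular kernel, (0.5, 3.5] ms


@dataclass
class SimConfig:
    """Parameters of the synthetic closed-loop session.

    Defaults follow the experimental schedule being emulated: 45/55/45-min
    Before/Experience/After epochs, PYR rates 0.5–5 spk/s, PV rates
    5–30 spk/s, transmission probabilities 0.005–0.2 (log-uniform), a 3-ms
    detection delay, 30-ms stimuli, a 20-ms dead time, and a light-induced PV
    rate gain of 1.56.
    """

    n_assemblies: int = 4
    presyn_per_assembly: int = 3
    presyn_rate_spk_s: tuple[float, float] = (0.5, 5.0)
    postsyn_rate_spk_s: tuple[float, float] = (5.0, 30.0)
    refractory_s: float = 0.002
    transmission_prob: tuple[float, float] = (0.005, 0.2)
    kernel_window_s: tuple[float, float] = DEFAULT_KERNEL_WINDOW
    plasticity_factor: float | Sequence[float] = 1.0
    # When > 0, plasticity factors are drawn as 2**N(0, σ) instead of taken
    # from plasticity_factor: one draw per assembly ("assembly", coherent
    # changes) or per pair ("pair", independent changes).
    plasticity_sigma_log2: float = 0.0
    plasticity_mode: str = "assembly"
    before_s: float = 45 * 60.0
    experience_s: float = 55 * 60.0
    after_s: float = 45 * 60.0
    closed_loop: bool = True
    triggers_per_assembly: int = 1
    detection_prob: float = 0.5
    delay_s: float = 0.003
    stim_duration_s: float = 0.030
    dead_time_s: float = 0.020
    light_gain: float | Sequence[float] = 1.56
    seed: int = 0

    def __post_init__(self) -> None:
        if self.refractory_s < 0:
            raise ValueError("refractory period must be non-negative")
        lo, hi = self.transmission_prob
        if not (0 <= lo <= hi < 1):
            raise ValueError("transmission probabilities must lie in [0, 1)")
        gains = np.atleast_1d(np.asarray(self.light_gain, dtype=float))
        if np.any(gains <= 0):
            raise ValueError("light gain must be positive")
        factors = np.atleast_1d(np.asarray(self.plasticity_factor, dtype=float))
        if np.any(factors <= 0):
            raise ValueError("plasticity factors must be positive")

    @property
    def duration_s(self) -> float:
        return self.before_s + self.experience_s + self.after_s

    def epochs(self) -> EpochSet:
        t1 = self.before_s
        t2 = t1 + self.experience_s
        return EpochSet(
            {
                "Before": (0.0, t1),
                "Experience": (t1, t2),
                "After": (t2, self.duration_s),
            }
        )

    def assembly_factor(self, a: int) -> float:
        f = np.atleast_1d(np.asarray(self.plasticity_factor, dtype=float))
        return float(f[a % f.size])

    def assembly_gain(self, a: int) -> float:
        g = np.atleast_1d(np.asarray(self.light_gain, dtype=float))
        return float(g[a % g.size])

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = dict(d)
        for k in ("presyn_rate_spk_s", "postsyn_rate_spk_s", "transmission_prob",
                  "kernel_window_s"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        for k in ("plasticity_factor", "light_gain"):
            if k in kwargs and isinstance(kwargs[k], list):
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


@dataclass
class PairCoupling:
    """Causal coupling of one presynaptic train onto a postsynaptic cell.

    ``p_before`` applies to presynaptic spikes in the Before epoch and
    ``p_after`` from the Experience epoch onward. ``stim_extra_p`` adds an
    extra, stimulus-gated kernel (support ``stim_extra_window_s``) for
    presynaptic spikes that occur during a light stimulus — used to emulate
    light-induced restructuring of pair spike timing.
    """

    pre_id: str
    p_before: float
    p_after: float
    window_s: tuple[float, float] = DEFAULT_KERNEL_WINDOW
    stim_extra_p: float = 0.0
    stim_extra_window_s: tuple[float, float] | None = None


@dataclass
class GroundTruth:
    """Injected parameters of a synthetic session, for recovery tests."""

    pairs: pd.DataFrame       # pre_id, post_id, assembly, p_before, p_after, true_stg_change
    units: pd.DataFrame       # unit_id, cell_class, rate_spk_s, is_trigger, realized_cle
    assemblies: pd.DataFrame  # assembly, post_id, plasticity_factor, light_gain


def simulate_refractory_poisson(
    rate_spk_s: float,
    duration_s: float,
    rng: np.random.Generator,
    refractory_s: float = 0.002,
    t_start: float = 0.0,
) -> np.ndarray:
    """Stationary renewal train: Poisson with an absolute refractory period.

    Inter-spike intervals are ``refractory + Exp(λ')`` with the hazard
    corrected so the mean rate equals the nominal rate exactly:
    ``λ' = rate / (1 − rate·refractory)``.
    """
    if rate_spk_s <= 0:
        raise ValueError("rate must be positive")
    occupancy = rate_spk_s * refractory_s
    if occupancy >= 1:
        raise ValueError(
            f"rate {rate_spk_s} spk/s with {refractory_s}-s refractoriness is "
            "unrealizable (rate × refractory ≥ 1)"
        )
    lam = rate_spk_s / (1.0 - occupancy)
    out: list[np.ndarray] = []
    t = t_start
    expected = int(duration_s * rate_spk_s * 1.25) + 50
    while t < t_start + duration_s:
        isi = refractory_s + rng.exponential(1.0 / lam, size=expected)
        chunk = t + np.cumsum(isi)
        out.append(chunk)
        t = chunk[-1]
    times = np.concatenate(out)
    return times[times < t_start + duration_s]


def simulate_presyn_trains(
    config: SimConfig, rng: np.random.Generator | int
) -> dict[str, SpikeTrain]:
    """Presynaptic PYR trains for every assembly, keyed by unit id."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    trains: dict[str, SpikeTrain] = {}
    lo, hi = config.presyn_rate_spk_s
    for a in range(config.n_assemblies):
        for i in range(config.presyn_per_assembly):
            uid = f"pyr_a{a}_{i}"
            rate = rng.uniform(lo, hi)
            times = simulate_refractory_poisson(
                rate, config.duration_s, rng, config.refractory_s
            )
            trains[uid] = SpikeTrain(uid, times, CellClass.PYR, shank=a + 1)
    return trains


def run_closed_loop(
    presyn_trains: dict[str, SpikeTrain],
    trigger_ids: Sequence[str],
    config: SimConfig,
    rng: np.random.Generator | int,
    window: tuple[float, float] | None = None,
) -> StimulusEvents:
    """Emulate the closed-loop controller over the trigger units' spikes.

    Each trigger spike is detected independently with ``detection_prob``; a
    detected spike at *t* emits a stimulus onset at ``t + delay`` unless that
    onset falls within ``stim_duration + dead_time`` of the previous onset.
    ``window`` restricts triggering to an interval (default: the Experience
    epoch of the config schedule).
    """
    missing = [u for u in trigger_ids if u not in presyn_trains]
    if missing:
        raise KeyError(f"trigger units not in session: {missing}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if window is None:
        window = config.epochs()["Experience"]
    spikes: list[tuple[float, str]] = []
    for uid in trigger_ids:
        t = presyn_trains[uid].restrict([window]).times
        detected = t[rng.random(t.size) < config.detection_prob]
        spikes.extend((float(s), uid) for s in detected)
    spikes.sort()
    min_gap = config.stim_duration_s + config.dead_time_s
    onsets: list[float] = []
    triggers: list[str] = []
    last = -np.inf
    for t, uid in spikes:
        onset = t + config.delay_s
        if onset >= window[1]:
            continue
        if onset - last >= min_gap:
            onsets.append(onset)
            triggers.append(uid)
            last = onset
    return StimulusEvents(
        np.array(onsets),
        config.stim_duration_s,
        config.dead_time_s,
        tuple(triggers) if onsets else None,
    )


def _sample_piecewise_baseline(
    base_rate: float,
    gain: float,
    duration_s: float,
    stim_intervals: list[tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson samples from base_rate outside stimuli and base_rate·gain inside."""
    n = rng.poisson(base_rate * duration_s)
    times = rng.uniform(0.0, duration_s, size=n)
    if stim_intervals and gain != 1.0:
        starts = np.array([a for a, _ in stim_intervals])
        stops = np.array([b for _, b in stim_intervals])
        idx = np.searchsorted(starts, times, side="right") - 1
        inside = (idx >= 0) & (times < stops[np.clip(idx, 0, None)])
        if gain < 1.0:
            drop = inside & (rng.random(times.size) >= gain)
            times = times[~drop]
        else:
            total_stim = float(np.sum(stops - starts))
            n_extra = rng.poisson(base_rate * (gain - 1.0) * total_stim)
            if n_extra:
                u = rng.uniform(0.0, total_stim, size=n_extra)
                cum = np.concatenate(([0.0], np.cumsum(stops - starts)))
                k = np.searchsorted(cum, u, side="right") - 1
                extra = starts[k] + (u - cum[k])
                times = np.concatenate([times, extra])
    return times


def _offspring(
    presyn_times: np.ndarray,
    p: np.ndarray,
    window: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """At most one evoked spike per presynaptic spike (Bernoulli(p)), with a
    latency drawn uniformly over the kernel window."""
    evoked = rng.random(presyn_times.size) < p
    total = int(evoked.sum())
    if total == 0:
        return np.empty(0)
    lo, hi = window
    return presyn_times[evoked] + rng.uniform(lo, hi, size=total)


def _enforce_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    if times.size == 0 or refractory_s <= 0:
        return times
    keep = np.ones(times.size, dtype=bool)
    last = times[0]
    for i in range(1, times.size):
        if times[i] - last < refractory_s:
            keep[i] = False
        else:
            last = times[i]
    return times[keep]


def simulate_postsyn_train(
    presyn_trains: dict[str, SpikeTrain],
    pair_params: Sequence[PairCoupling],
    events: StimulusEvents,
    config: SimConfig,
    rng: np.random.Generator | int,
    unit_id: str = "pv_0",
    base_rate_spk_s: float = 10.0,
    light_gain: float | None = None,
    shank: int = 1,
    gain_pad_s: float = 0.0,
) -> SpikeTrain:
    """Sample a postsynaptic PV train coupled to its assembly's PYR trains.

    ``gain_pad_s`` widens the rate-gain envelope by a margin on both sides
    of each nominal stimulus interval (the stimulus-gated coupling still
    uses the nominal intervals). Used by rate-only synthetic conditions to
    keep the gain constant across a correlogram analysis window.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    gain = config.assembly_gain(0) if light_gain is None else float(light_gain)
    if gain <= 0 or base_rate_spk_s <= 0:
        raise ValueError("postsynaptic rate and light gain must be positive")
    stim_intervals = events.intervals()
    gain_intervals = [
        (max(0.0, a - gain_pad_s), b + gain_pad_s) for a, b in stim_intervals
    ]
    parts = [
        _sample_piecewise_baseline(
            base_rate_spk_s, gain, config.duration_s, gain_intervals, rng
        )
    ]
    before_end = config.before_s
    stim_starts = np.array([a for a, _ in stim_intervals])
    stim_stops = np.array([b for _, b in stim_intervals])
    for pair in pair_params:
        pre = presyn_trains[pair.pre_id].times
        in_before = pre < before_end
        p = np.where(in_before, pair.p_before, pair.p_after)
        parts.append(_offspring(pre, p, pair.window_s, rng))
        if pair.stim_extra_p > 0 and stim_starts.size:
            idx = np.searchsorted(stim_starts, pre, side="right") - 1
            in_stim = (idx >= 0) & (pre < stim_stops[np.clip(idx, 0, None)])
            extra_window = pair.stim_extra_window_s or pair.window_s
            parts.append(
                _offspring(
                    pre[in_stim],
                    np.full(int(in_stim.sum()), pair.stim_extra_p),
                    extra_window,
                    rng,
                )
            )
    merged = np.sort(np.concatenate(parts))
    merged = merged[(merged >= 0) & (merged < config.duration_s)]
    merged = _enforce_refractory(merged, config.refractory_s)
    # strict monotonicity for the SpikeTrain invariant
    merged = np.unique(merged)
    return SpikeTrain(unit_id, merged, CellClass.PV, shank=shank)


def generate_session(config: SimConfig, seed: int | None = None) -> tuple[Session, GroundTruth]:
    """A full synthetic session plus its ground truth, reproducible from the seed."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    epochs = config.epochs()
    presyn = simulate_presyn_trains(config, rng)

    trigger_ids: list[str] = []
    for a in range(config.n_assemblies):
        for i in range(min(config.triggers_per_assembly, config.presyn_per_assembly)):
            trigger_ids.append(f"pyr_a{a}_{i}")
    if config.closed_loop and trigger_ids:
        events = run_closed_loop(presyn, trigger_ids, config, rng)
    else:
        events = StimulusEvents(
            np.array([]), config.stim_duration_s, config.dead_time_s
        )

    trains: dict[str, SpikeTrain] = dict(presyn)
    pair_rows, unit_rows, assembly_rows = [], [], []
    p_lo, p_hi = config.transmission_prob
    r_lo, r_hi = config.postsyn_rate_spk_s
    sigma = config.plasticity_sigma_log2
    if config.plasticity_mode not in ("assembly", "pair"):
        raise ValueError(f"unknown plasticity mode {config.plasticity_mode!r}")
    for a in range(config.n_assemblies):
        post_id = f"pv_a{a}"
        factor = config.assembly_factor(a)
        if sigma > 0 and config.plasticity_mode == "assembly":
            factor = float(2.0 ** rng.normal(0.0, sigma))
        gain = config.assembly_gain(a)
        base_rate = rng.uniform(r_lo, r_hi)
        couplings = []
        for i in range(config.presyn_per_assembly):
            pre_id = f"pyr_a{a}_{i}"
            if sigma > 0 and config.plasticity_mode == "pair":
                factor = float(2.0 ** rng.normal(0.0, sigma))
            p = float(np.exp(rng.uniform(np.log(p_lo), np.log(p_hi)))) if p_lo > 0 else 0.0
            p_after = min(p * factor, 0.999)
            couplings.append(
                PairCoupling(pre_id, p, p_after, config.kernel_window_s)
            )
            change = np.log2(p_after / p) if p > 0 and p_after > 0 else np.nan
            pair_rows.append(
                dict(
                    pre_id=pre_id, post_id=post_id, assembly=a,
                    p_before=p, p_after=p_after, true_stg_change=change,
                )
            )
        trains[post_id] = simulate_postsyn_train(
            presyn, couplings, events, config, rng,
            unit_id=post_id, base_rate_spk_s=base_rate,
            light_gain=gain, shank=a + 1,
        )
        assembly_rows.append(
            dict(
                assembly=a, post_id=post_id,
                plasticity_factor=(
                    factor if not (sigma > 0 and config.plasticity_mode == "pair")
                    else float("nan")
                ),
                light_gain=gain,
            )
        )

    exp_window = epochs["Experience"]
    trigger_counts: dict[str, int] = {}
    if events.trigger_unit:
        for uid in events.trigger_unit:
            if uid:
                trigger_counts[uid] = trigger_counts.get(uid, 0) + 1
    for uid, train in trains.items():
        n_exp = train.restrict([exp_window]).n_spikes
        cle = trigger_counts.get(uid, 0) / n_exp if n_exp else np.nan
        unit_rows.append(
            dict(
                unit_id=uid, cell_class=train.cell_class.value,
                rate_spk_s=train.n_spikes / config.duration_s,
                is_trigger=uid in trigger_ids and config.closed_loop,
                realized_cle=cle,
            )
        )

    session = Session(trains=trains, epochs=epochs, events=events,
                      duration_s=config.duration_s)
    truth = GroundTruth(
        pairs=pd.DataFrame(pair_rows),
        units=pd.DataFrame(unit_rows),
        assemblies=pd.DataFrame(assembly_rows),
    )
    return session, truth


def simulate_pair(
    p_before: float,
    p_after: float,
    seed: int,
    pre_rate_spk_s: float = 2.0,
    post_rate_spk_s: float = 10.0,
    epoch_s: float = 2700.0,
    experience_s: float = 60.0,
    refractory_s: float = 0.002,
    kernel_window_s: tuple[float, float] = DEFAULT_KERNEL_WINDOW,
) -> tuple[Session, PairCoupling]:
    """A minimal one-pair session (no stimulation) for recovery tests.

    Before and After epochs of ``epoch_s`` seconds separated by a short,
    stimulus-free Experience epoch; the pair's transmission probability is
    ``p_before`` in the Before epoch and ``p_after`` afterwards.
    """
    config = SimConfig(
        n_assemblies=1, presyn_per_assembly=1,
        presyn_rate_spk_s=(pre_rate_spk_s, pre_rate_spk_s),
        postsyn_rate_spk_s=(post_rate_spk_s, post_rate_spk_s),
        before_s=epoch_s, experience_s=experience_s, after_s=epoch_s,
        refractory_s=refractory_s, kernel_window_s=kernel_window_s,
        closed_loop=False, light_gain=1.0, seed=seed,
    )
    rng = np.random.default_rng(seed)
    pre_times = simulate_refractory_poisson(
        pre_rate_spk_s, config.duration_s, rng, refractory_s
    )
    pre = SpikeTrain("pre", pre_times, CellClass.PYR, 1)
    coupling = PairCoupling("pre", p_before, p_after, kernel_window_s)
    events = StimulusEvents(np.array([]))
    post = simulate_postsyn_train(
        {"pre": pre}, [coupling], events, config, rng,
        unit_id="post", base_rate_spk_s=post_rate_spk_s, light_gain=1.0,
    )
    session = Session(
        trains={"pre": pre, "post": post}, epochs=config.epochs(),
        events=events, duration_s=config.duration_s,
    )
    return session, coupling


def simulate_stim_feature_cohort(
    n_assemblies: int,
    mode: str,
    seed: int,
    experience_s: float = 300.0,
    presyn_per_assembly: int = 3,
    pre_rate_spk_s: float = 2.0,
    post_rate_spk_s: float = 10.0,
    p_base: float = 0.05,
) -> list[dict]:
    """Experience-epoch assemblies whose stimulus response encodes a label.

    Each assembly receives closed-loop stimulation from all of its PYRs and
    carries a binary label (+1 "increase" / −1 "decrease", balanced across
    the cohort) that is linked to the stimulus effect according to ``mode``:

    * ``"gain"`` — the light-induced PV rate gain differs by label
      (≈2.1 vs ≈1.3); pair spike timing during stimuli is otherwise
      unchanged. Only co-firing ("rate") information separates the classes.
      Stimuli are long (100 ms) relative to the ±10-ms classifier window so
      that the rate effect is unstructured across the analyzed lags: with
      short stimuli the in-stimulus occupancy of the lagged bin would fall
      off with |τ|, leaking timing-like shape into a nominally rate-only
      condition.
    * ``"latency"`` — the rate gain is 1 for everyone, but presynaptic spikes
      occurring during a stimulus recruit an extra transmission kernel of
      fixed integral whose latency depends on the label (0.5–3.5 ms vs
      5.5–8.5 ms). Class-conditional added rate is equal, so only
      millisecond-timescale timing separates the classes.
    * ``"none"`` — stimulation has no effect (gain 1, no extra kernel);
      labels are independent of the features.

    Returns one dict per assembly with the mini-``Session`` (Experience epoch
    only), the pre/post unit ids and the label.
    """
    if mode not in ("gain", "latency", "none"):
        raise ValueError(f"unknown cohort mode {mode!r}")
    rng = np.random.default_rng(seed)
    out: list[dict] = []
    for a in range(n_assemblies):
        label = 1 if a % 2 == 0 else -1
        stim_duration, detection, gain_pad = 0.030, 1.0, 0.0
        if mode == "gain":
            gain = (2.1 if label > 0 else 1.3) * float(np.exp(rng.normal(0, 0.05)))
            extra_p, extra_window = 0.0, None
            # long stimuli plus a padded gain envelope keep the rate effect
            # constant across the ±10-ms analysis window around every
            # in-stimulus reference spike
            stim_duration, detection, gain_pad = 0.100, 0.5, 0.0105
        elif mode == "latency":
            gain = 1.0
            extra_p = 0.1
            extra_window = (0.0005, 0.0035) if label > 0 else (0.0055, 0.0085)
        else:
            gain, extra_p, extra_window = 1.0, 0.0, None
        cfg = SimConfig(
            n_assemblies=1, presyn_per_assembly=presyn_per_assembly,
            presyn_rate_spk_s=(pre_rate_spk_s, pre_rate_spk_s),
            postsyn_rate_spk_s=(post_rate_spk_s, post_rate_spk_s),
            before_s=0.0, experience_s=experience_s, after_s=0.0,
            detection_prob=detection, light_gain=gain, seed=seed,
            stim_duration_s=stim_duration,
        )
        epochs = EpochSet({"Experience": (0.0, experience_s)})
        pre_ids = [f"a{a}_pyr{i}" for i in range(presyn_per_assembly)]
        presyn = {
            uid: SpikeTrain(
                uid,
                simulate_refractory_poisson(
                    pre_rate_spk_s, experience_s, rng, cfg.refractory_s
                ),
                CellClass.PYR, 1,
            )
            for uid in pre_ids
        }
        events = run_closed_loop(presyn, pre_ids, cfg, rng, window=(0.0, experience_s))
        couplings = [
            PairCoupling(uid, p_base, p_base, stim_extra_p=extra_p,
                         stim_extra_window_s=extra_window)
            for uid in pre_ids
        ]
        post_id = f"a{a}_pv"
        post = simulate_postsyn_train(
            presyn, couplings, events, cfg, rng,
            unit_id=post_id, base_rate_spk_s=post_rate_spk_s, light_gain=gain,
            gain_pad_s=gain_pad,
        )
        session = Session(
            trains={**presyn, post_id: post}, epochs=epochs, events=events,
            duration_s=experience_s,
        )
        out.append(
            dict(assembly=a, session=session, post_id=post_id,
                 pre_ids=pre_ids, label=label)
        )
    return out
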