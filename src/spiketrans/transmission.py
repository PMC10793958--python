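"""Spike transmission gain (STG), its change, and the permutation test.

The STG of a presynaptic→postsynaptic pair is the expected number of excess
postsynaptic spikes per presynaptic spike: the area under the peak of the
deconvolved, baseline-subtracted spike transmission curve in the
monosynaptic region of interest (0 < τ ≤ 5 ms), extended from the peak to
the causal zero-crossing points. The STG change between the Before and
After epochs is ``log2(STG_After / STG_Before)`` — +1 means the gain
doubled, −1 that it halved.

Consistency of a change is assessed by a row-label permutation test on the
binary spike-time lag matrix: each row is one presynaptic spike (from the
Before or After epoch), each column a 0.5-ms lag bin, and entries mark
postsynaptic spike occupancy. Shuffling row labels and recomputing the STG
change through the identical deconvolution path yields the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EpochSet, Session, SpikeTrain
from .correlograms import (
    Correlogram,
    DeconvolutionSolver,
    TransmissionCurve,
    compute_ach,
    compute_cch,
    deconvolve_transmission,
    hollow_bins,
    hollowed_median_baseline,
    lag_edges,
    poisson_excess_test,
)

__all__ = [
    "PairResult",
    "compute_stg",
    "stg_change",
    "detect_monosynaptic",
    "permutation_test_stg_change",
    "PermutationResult",
    "evaluate_pair",
    "screen_pairs",
    "select_eligible_pairs",
]

BIN_WIDTH_S = 0.0005
MAX_LAG_S = 0.030
ROI_S = 0.005  # monosynaptic ROI: 0 < τ ≤ 5 ms
# Half-width of the hollowed-median baseline for transmission curves. Wider
# than the 5 ms used for PSTH/synchrony baselines: the monosynaptic peak spans
# up to 10 of the 0.5-ms bins, so the median window must be wide enough that
# the elevated bins cannot shift its order statistic.
BASELINE_HALF_WIDTH_S = 0.015
MIN_COUNTS = 400  # per-epoch CCH counts required in −30 < τ ≤ 30 ms
P_CONNECT_THRESHOLD = 0.001
P_CHANGE_THRESHOLD = 0.05


@dataclass
class PairResult:
    """Per-pair transmission measurements across the Before/After contrast."""

    pre_id: str
    post_id: str
    stg_before: float
    stg_after: float
    stg_change: float
    p_connect: float
    p_change: float
    direction: str
    counts_before: int
    counts_after: int
    eligible: bool


def _stg_from_rate(rate: np.ndarray, n_bins: int, bin_width_s: float,
                   roi_bins: int) -> float:
    """Area under the causal peak, extended to the zero-crossing points.

    The peak is the maximal bin among the causal ROI bins; the integration
    region grows from it leftward (bounded by lag 0) and rightward until the
    curve first drops to ≤ 0 or the window edge.
    """
    causal = n_bins // 2  # first bin with lag in (0, Δ]
    seg = rate[causal : causal + roi_bins]
    peak = int(np.argmax(seg)) + causal
    if rate[peak] <= 0:
        return 0.0
    left = peak
    while left - 1 >= causal and rate[left - 1] > 0:
        left -= 1
    right = peak
    while right + 1 < n_bins and rate[right + 1] > 0:
        right += 1
    return float(rate[left : right + 1].sum() * bin_width_s)


def stg_from_curve(curve: TransmissionCurve, roi_s: float = ROI_S) -> float:
    roi_bins = int(round(roi_s / curve.bin_width_s))
    return _stg_from_rate(
        curve.rate_spk_s, curve.rate_spk_s.size, curve.bin_width_s, roi_bins
    )


def compute_stg(
    pre_train: SpikeTrain,
    post_train: SpikeTrain,
    bin_width_s: float = BIN_WIDTH_S,
    max_lag_s: float = MAX_LAG_S,
    roi_s: float = ROI_S,
    baseline_half_width_s: float = BASELINE_HALF_WIDTH_S,
) -> tuple[float, TransmissionCurve]:
    """STG of a pair from trains already restricted to one epoch."""
    cch = compute_cch(pre_train, post_train, bin_width_s, max_lag_s)
    ach = compute_ach(pre_train, bin_width_s, max_lag_s)
    curve = deconvolve_transmission(cch, ach, baseline_half_width_s)
    return stg_from_curve(curve, roi_s), curve


def stg_change(stg_before: float, stg_after: float) -> float:
    """Base-2 log of the After/Before STG ratio; NaN if either is ≤ 0."""
    if stg_before <= 0 or stg_after <= 0:
        return float("nan")
    return float(np.log2(stg_after / stg_before))


def detect_monosynaptic(
    pre_train: SpikeTrain,
    post_train: SpikeTrain,
    bin_width_s: float = BIN_WIDTH_S,
    max_lag_s: float = MAX_LAG_S,
    roi_s: float = ROI_S,
    baseline_half_width_s: float = BASELINE_HALF_WIDTH_S,
) -> float:
    """Poisson-test p-value for an excitatory monosynaptic CCH peak.

    Counts in the causal ROI (0 < τ ≤ 5 ms) of the count CCH are compared
    with the hollowed-median baseline expectation. Trains should span the
    combined Before and After epochs.
    """
    if pre_train.n_spikes < 1 or post_train.n_spikes < 1:
        raise ValueError("both trains must contain at least one spike")
    cch = compute_cch(pre_train, post_train, bin_width_s, max_lag_s)
    hw = hollow_bins(baseline_half_width_s, bin_width_s)
    baseline = hollowed_median_baseline(cch.counts, hw)
    causal = cch.n_bins // 2
    roi_bins = int(round(roi_s / bin_width_s))
    sl = slice(causal, causal + roi_bins)
    n_obs = int(cch.counts[sl].sum())
    n_exp = float(baseline[sl].sum())
    return poisson_excess_test(n_obs, n_exp)


def lag_occupancy_matrix(
    pre_times: np.ndarray,
    post_times: np.ndarray,
    edges: np.ndarray,
) -> np.ndarray:
    """Binary matrix: rows = presynaptic spikes, columns = lag bins.

    Entry (i, b) is True when at least one postsynaptic spike falls in
    ``(pre_i + edges[b], pre_i + edges[b+1]]``.
    """
    n_bins = edges.size - 1
    mat = np.zeros((pre_times.size, n_bins), dtype=bool)
    starts = np.searchsorted(post_times, pre_times + edges[0], side="right")
    ends = np.searchsorted(post_times, pre_times + edges[-1], side="right")
    n_per = ends - starts
    total = int(n_per.sum())
    if total == 0:
        return mat
    rows = np.repeat(np.arange(pre_times.size), n_per)
    offsets = np.concatenate(([0], np.cumsum(n_per)[:-1]))
    flat = np.arange(total) - np.repeat(offsets, n_per) + np.repeat(starts, n_per)
    lags = post_times[flat] - pre_times[rows]
    bins = np.searchsorted(edges, lags, side="left") - 1
    ok = (lags > edges[0]) & (lags <= edges[-1])
    mat[rows[ok], bins[ok]] = True
    return mat


@dataclass
class PermutationResult:
    observed_change: float
    p_change: float
    direction: str
    n_shuffles: int
    n_failed: int
    null_changes: np.ndarray


def _batch_stg(
    cch_counts: np.ndarray,
    solver: DeconvolutionSolver,
    hw_bins: int,
    roi_bins: int,
) -> np.ndarray:
    """STG for each column of a (n_bins, m) stack of count CCHs."""
    rates_full = solver.solve(cch_counts)
    rates = rates_full - hollowed_median_baseline(rates_full, hw_bins)
    n_bins = cch_counts.shape[0]
    dt = solver.bin_width_s
    return np.array(
        [_stg_from_rate(rates[:, j], n_bins, dt, roi_bins)
         for j in range(rates.shape[1])]
    )


def permutation_test_stg_change(
    pre_train: SpikeTrain,
    post_train: SpikeTrain,
    epochs: EpochSet,
    n_shuffles: int = 2000,
    seed: int | np.random.Generator = 0,
    bin_width_s: float = BIN_WIDTH_S,
    max_lag_s: float = MAX_LAG_S,
    roi_s: float = ROI_S,
    baseline_half_width_s: float = BASELINE_HALF_WIDTH_S,
    resample_cap: int = 3,
    batch: int = 250,
) -> PermutationResult:
    """Row-label permutation test for the consistency of an STG change.

    The binary lag matrix is built from Before∪After presynaptic spikes;
    the observed change comes from the label-true row partition and the null
    from random row-label permutations, both recomputed through the same
    baseline-subtraction/deconvolution path. The deconvolution kernels are
    label-invariant: the combined-epoch presynaptic ACH, scaled to each
    partition's size, with the zero-displacement term set to the partition's
    row count. Two-sided p-value with the add-one rule:
    ``p = (1 + #{|null| ≥ |observed|}) / (n_shuffles + 1)``.

    Shuffles for which either partition yields a non-positive STG leave the
    change undefined; they are redrawn up to ``resample_cap × n_shuffles``
    total draws, and any remaining failures are counted as extreme
    (conservative).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pre_b = pre_train.restrict([epochs["Before"]]).times
    pre_a = pre_train.restrict([epochs["After"]]).times
    n_b, n_a = pre_b.size, pre_a.size
    if n_b < 2 or n_a < 2:
        raise ValueError("need at least 2 presynaptic spikes in each epoch")
    pre_all = np.concatenate([pre_b, pre_a])
    edges = lag_edges(bin_width_s, max_lag_s)
    mat = lag_occupancy_matrix(pre_all, post_train.times, edges).astype(np.float64)
    n_rows, n_bins = mat.shape
    total = mat.sum(axis=0)

    comb = SpikeTrain(pre_train.unit_id, np.sort(pre_all), pre_train.cell_class,
                      pre_train.shank)
    ach = compute_ach(comb, bin_width_s, max_lag_s)
    n_tot = n_rows
    solver_b = DeconvolutionSolver(ach, n_ref=n_b,
                                   off_zero_scale=(n_b / n_tot) ** 2)
    solver_a = DeconvolutionSolver(ach, n_ref=n_a,
                                   off_zero_scale=(n_a / n_tot) ** 2)
    hw = hollow_bins(baseline_half_width_s, bin_width_s)
    roi_bins = int(round(roi_s / bin_width_s))

    labels_before = np.zeros(n_rows, dtype=bool)
    labels_before[:n_b] = True
    cch_b_obs = mat[labels_before].sum(axis=0)
    stg_b = _batch_stg(cch_b_obs[:, None], solver_b, hw, roi_bins)[0]
    stg_a = _batch_stg((total - cch_b_obs)[:, None], solver_a, hw, roi_bins)[0]
    observed = stg_change(stg_b, stg_a)
    if not np.isfinite(observed):
        raise ValueError(
            "observed STG change undefined (non-positive STG in an epoch)"
        )

    null: list[float] = []
    draws = 0
    max_draws = resample_cap * n_shuffles
    matT = mat.T  # (n_bins, n_rows)
    while len(null) < n_shuffles and draws < max_draws:
        m = min(batch, max_draws - draws)
        draws += m
        sel = np.empty((n_rows, m))
        for j in range(m):
            sel[:, j] = rng.permutation(labels_before)
        cch_b = matT @ sel
        cch_a = total[:, None] - cch_b
        s_b = _batch_stg(cch_b, solver_b, hw, roi_bins)
        s_a = _batch_stg(cch_a, solver_a, hw, roi_bins)
        with np.errstate(divide="ignore", invalid="ignore"):
            ch = np.log2(s_a / s_b)
        valid = np.isfinite(ch)
        null.extend(ch[valid][: n_shuffles - len(null)])
    n_valid = len(null)
    n_failed = n_shuffles - n_valid
    null_arr = np.array(null)
    n_extreme = int(np.sum(np.abs(null_arr) >= abs(observed) - 1e-12)) + n_failed
    p = (1 + n_extreme) / (n_shuffles + 1)
    if p < P_CHANGE_THRESHOLD:
        direction = "increase" if observed > 0 else "decrease"
    else:
        direction = "none"
    return PermutationResult(observed, p, direction, n_shuffles, n_failed, null_arr)


def evaluate_pair(
    session: Session,
    pre_id: str,
    post_id: str,
    n_shuffles: int = 2000,
    seed: int | np.random.Generator = 0,
    run_permutation: bool = True,
) -> PairResult:
    """Screen and measure one presynaptic→postsynaptic pair.

    Eligibility requires (i) a monosynaptic connection over the combined
    Before+After epochs at P < 0.001 (Poisson test), (ii) at least 400 CCH
    counts in −30 < τ ≤ 30 ms in each epoch, and (iii) the global CCH
    maximum of the Before or the After epoch inside 0 < τ ≤ 5 ms. The
    permutation test runs only for eligible pairs with a defined change.
    """
    pre_comb = session.epoch_trains(pre_id, ("Before", "After"))
    post_comb = session.epoch_trains(post_id, ("Before", "After"))
    p_connect = detect_monosynaptic(pre_comb, post_comb)

    results = {}
    for label in ("Before", "After"):
        pre_e = session.epoch_train(pre_id, label)
        post_e = session.epoch_train(post_id, label)
        cch = compute_cch(pre_e, post_e, BIN_WIDTH_S, MAX_LAG_S)
        stg, _ = compute_stg(pre_e, post_e)
        results[label] = (cch, stg)
    cch_b, stg_b = results["Before"]
    cch_a, stg_a = results["After"]
    counts_b = int(cch_b.counts.sum())
    counts_a = int(cch_a.counts.sum())

    causal = cch_b.n_bins // 2
    roi_bins = int(round(ROI_S / BIN_WIDTH_S))
    roi = slice(causal, causal + roi_bins)

    def _max_in_roi(c: Correlogram) -> bool:
        return int(np.argmax(c.counts)) in range(roi.start, roi.stop)

    eligible = (
        p_connect < P_CONNECT_THRESHOLD
        and counts_b >= MIN_COUNTS
        and counts_a >= MIN_COUNTS
        and (_max_in_roi(cch_b) or _max_in_roi(cch_a))
    )

    change = stg_change(stg_b, stg_a)
    p_change, direction = float("nan"), "none"
    if eligible and run_permutation and np.isfinite(change):
        perm = permutation_test_stg_change(
            session.trains[pre_id], session.trains[post_id], session.epochs,
            n_shuffles=n_shuffles, seed=seed,
        )
        p_change, direction = perm.p_change, perm.direction
    return PairResult(
        pre_id=pre_id, post_id=post_id,
        stg_before=stg_b, stg_after=stg_a, stg_change=change,
        p_connect=p_connect, p_change=p_change, direction=direction,
        counts_before=counts_b, counts_after=counts_a, eligible=eligible,
    )


def screen_pairs(
    session: Session,
    pre_ids: list[str] | None = None,
    post_ids: list[str] | None = None,
    n_shuffles: int = 2000,
    seed: int = 0,
    run_permutation: bool = True,
) -> pd.DataFrame:
    """Evaluate all presynaptic×postsynaptic combinations of a session."""
    pre_ids = session.units("PYR") if pre_ids is None else pre_ids
    post_ids = session.units("PV") if post_ids is None else post_ids
    rng = np.random.default_rng(seed)
    rows = []
    for pre in pre_ids:
        for post in post_ids:
            res = evaluate_pair(
                session, pre, post, n_shuffles=n_shuffles, seed=rng,
                run_permutation=run_permutation,
            )
            rows.append(res.__dict__)
    return pd.DataFrame(rows)


def select_eligible_pairs(pair_table: pd.DataFrame) -> pd.DataFrame:
    """Subset of a :func:`screen_pairs` table that passed all three criteria."""
    return pair_table[pair_table["eligible"]].reset_index(drop=True)


def null_calibration(
    n_pairs: int = 200,
    n_shuffles: int = 1000,
    seed: int = 0,
    p: float = 0.1,
    pre_rate_spk_s: float = 2.0,
    post_rate_spk_s: float = 10.0,
    epoch_s: float = 600.0,
) -> pd.DataFrame:
    """Permutation-test calibration on null pairs (no injected change).

    Simulates ``n_pairs`` connected pairs with a constant transmission
    probability across epochs and runs the permutation test on each; under
    the null the flagged-increase rate should match the per-direction
    chance level (half the two-tailed threshold, 2.5%).
    """
    from .simulate import simulate_pair

    root = np.random.SeedSequence(seed)
    rows = []
    for k, child in enumerate(root.spawn(n_pairs)):
        pair_seed = int(child.generate_state(1)[0] % (2**31))
        session, _ = simulate_pair(
            p, p, seed=pair_seed, pre_rate_spk_s=pre_rate_spk_s,
            post_rate_spk_s=post_rate_spk_s, epoch_s=epoch_s,
        )
        res = permutation_test_stg_change(
            session.trains["pre"], session.trains["post"], session.epochs,
            n_shuffles=n_shuffles, seed=np.random.default_rng(pair_seed + 1),
        )
        rows.append(
            dict(pair=k, observed_change=res.observed_change,
                 p_change=res.p_change, direction=res.direction,
                 n_failed=res.n_failed)
        )
    return pd.DataFrame(rows)
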