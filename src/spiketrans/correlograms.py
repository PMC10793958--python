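"""Binned lag histograms and derived quantities.

The workhorse structures of the pipeline: count and conditional-rate
cross-correlation histograms (CCH), autocorrelation histograms (ACH),
peristimulus time histograms (PSTH), slow-timescale baselines via hollowed
median filtering, deconvolution of the presynaptic autocorrelation from the
CCH to obtain the spike transmission curve, and the continuity-corrected
Poisson excess test.

Bins are half-open on the left and closed on the right, ``(low, high]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, toeplitz

from .core import SpikeTrain

__all__ = [
    "Correlogram",
    "TransmissionCurve",
    "lag_edges",
    "compute_cch",
    "compute_ach",
    "psth",
    "hollowed_median_baseline",
    "DeconvolutionSolver",
    "deconvolve_transmission",
    "poisson_excess_test",
]


def lag_edges(bin_width_s: float, max_lag_s: float) -> np.ndarray:
    """Symmetric lag-bin edges from −max_lag to +max_lag.

    ``max_lag_s`` must be an integer multiple of ``bin_width_s``; bin *b*
    covers ``(edges[b], edges[b+1]]``.
    """
    if bin_width_s <= 0:
        raise ValueError("bin width must be positive")
    n_half = max_lag_s / bin_width_s
    if abs(n_half - round(n_half)) > 1e-9:
        raise ValueError("max_lag must be a multiple of bin_width")
    n_half = int(round(n_half))
    return bin_width_s * np.arange(-n_half, n_half + 1)


def window_edges(bin_width_s: float, window: tuple[float, float]) -> np.ndarray:
    """Edges for an arbitrary (possibly asymmetric) window (w0, w1].

    The span must be an integer number of bins; the grid may be offset by
    half a bin (a zero-centered bin is then possible).
    """
    w0, w1 = window
    n = (w1 - w0) / bin_width_s
    if abs(n - round(n)) > 1e-9:
        raise ValueError("window span must be a multiple of bin_width")
    return w0 + bin_width_s * np.arange(round(n) + 1)


@dataclass
class Correlogram:
    """A binned lag histogram (CCH, ACH or PSTH).

    ``counts[b]`` is the number of (reference, target) pairs whose lag
    ``τ = t_target − t_reference`` falls in bin *b*; ``n_ref`` is the number
    of reference spikes (or stimulus events for a PSTH).
    """

    ref_id: str
    tgt_id: str
    bin_width_s: float
    edges: np.ndarray
    counts: np.ndarray
    n_ref: int
    n_tgt: int
    scale: str = "count"

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def conditional_rate(self) -> np.ndarray:
        """Counts scaled to spk/s per reference spike: count / (n_ref · Δ)."""
        if self.n_ref == 0:
            raise ValueError("conditional rate undefined for n_ref = 0")
        return self.counts / (self.n_ref * self.bin_width_s)

    def roi_mask(self, low_s: float, high_s: float) -> np.ndarray:
        """Bins whose centers lie within [low, high] (region of interest)."""
        c = self.centers
        return (c >= low_s - 1e-12) & (c <= high_s + 1e-12)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("lag_center_s\tcount\trate_spk_s\n")
            rates = (
                self.conditional_rate
                if self.n_ref
                else np.full(self.n_bins, np.nan)
            )
            for c, n, r in zip(self.centers, self.counts, rates):
                fh.write(f"{c:.6f}\t{n:.6f}\t{r:.6f}\n")


def _pair_lags(
    ref: np.ndarray, tgt: np.ndarray, low: float, high: float, exclude_self: bool
) -> np.ndarray:
    """All lags t_tgt − t_ref in (low, high], via sorted-array slicing."""
    starts = np.searchsorted(tgt, ref + low, side="right")
    ends = np.searchsorted(tgt, ref + high, side="right")
    n_per_ref = ends - starts
    total = int(n_per_ref.sum())
    if total == 0:
        return np.empty(0)
    rep = np.repeat(np.arange(ref.size), n_per_ref)
    offsets = np.concatenate(([0], np.cumsum(n_per_ref)[:-1]))
    flat = np.arange(total) - np.repeat(offsets, n_per_ref) + np.repeat(
        starts, n_per_ref
    )
    if exclude_self:
        keep = flat != rep
        flat, rep = flat[keep], rep[keep]
    return tgt[flat] - ref[rep]


def _histogram(lags: np.ndarray, edges: np.ndarray) -> np.ndarray:
    n_bins = edges.size - 1
    if lags.size == 0:
        return np.zeros(n_bins, dtype=np.int64)
    idx = np.searchsorted(edges, lags, side="left") - 1
    valid = (lags > edges[0]) & (lags <= edges[-1])
    return np.bincount(idx[valid], minlength=n_bins).astype(np.int64)


def compute_cch(
    ref_train: SpikeTrain,
    tgt_train: SpikeTrain,
    bin_width_s: float = 0.0005,
    max_lag_s: float = 0.030,
    scale: str = "count",
) -> Correlogram:
    """Count CCH of ``tgt`` relative to ``ref`` over ±max_lag.

    For an autocorrelation (``ref is tgt`` or identical ids and times),
    self-pairs ``i == j`` are excluded.
    """
    if ref_train.n_spikes == 0:
        raise ValueError("empty reference train: n_ref = 0 is undefined")
    edges = lag_edges(bin_width_s, max_lag_s)
    is_auto = ref_train.unit_id == tgt_train.unit_id
    lags = _pair_lags(
        ref_train.times, tgt_train.times, edges[0], edges[-1], exclude_self=is_auto
    )
    counts = _histogram(lags, edges)
    return Correlogram(
        ref_id=ref_train.unit_id,
        tgt_id=tgt_train.unit_id,
        bin_width_s=bin_width_s,
        edges=edges,
        counts=counts,
        n_ref=ref_train.n_spikes,
        n_tgt=tgt_train.n_spikes,
        scale=scale,
    )


def compute_ach(
    train: SpikeTrain, bin_width_s: float = 0.0005, max_lag_s: float = 0.030
) -> Correlogram:
    """Autocorrelation histogram (self-pairs excluded, symmetric about 0)."""
    return compute_cch(train, train, bin_width_s, max_lag_s)


def psth(
    train: SpikeTrain,
    event_onsets: np.ndarray,
    bin_width_s: float = 0.001,
    window: tuple[float, float] = (-0.050, 0.050),
) -> Correlogram:
    """Peristimulus time histogram: spike lags relative to stimulus onsets.

    Positive lag means the spike followed the onset. Reference count is the
    number of events, so :attr:`Correlogram.conditional_rate` is the
    event-conditional firing rate in spk/s.
    """
    onsets = np.asarray(event_onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("PSTH undefined without events")
    edges = window_edges(bin_width_s, window)
    lags = _pair_lags(onsets, train.times, edges[0], edges[-1], exclude_self=False)
    counts = _histogram(lags, edges)
    return Correlogram(
        ref_id="events",
        tgt_id=train.unit_id,
        bin_width_s=bin_width_s,
        edges=edges,
        counts=counts,
        n_ref=int(onsets.size),
        n_tgt=train.n_spikes,
        scale="count",
    )


def hollowed_median_baseline(
    counts: np.ndarray, half_width_bins: int
) -> np.ndarray:
    """Running median excluding the center bin ("hollowed"), edge-truncated.

    ``counts`` may be 1-D (n_bins,) or 2-D (n_bins, m) — columns are filtered
    independently (used to process many permutations at once). The window is
    ±``half_width_bins`` around each bin, the bin itself excluded; at the
    edges the window truncates (no padding values enter the median).
    """
    if half_width_bins < 1:
        raise ValueError("hollowed median window must span at least 3 bins")
    x = np.asarray(counts, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    hw = int(half_width_bins)
    n, m = x.shape
    base = np.empty((n, m))
    keep = np.ones(2 * hw + 1, dtype=bool)
    keep[hw] = False
    if n >= 2 * hw + 1:
        win = sliding_window_view(x, 2 * hw + 1, axis=0)  # (n−2hw, m, 2hw+1)
        base[hw : n - hw] = np.median(win[..., keep], axis=-1)
    edge = list(range(min(hw, n))) + list(range(max(hw, n - hw), n))
    for b in edge:
        lo, hi = max(0, b - hw), min(n, b + hw + 1)
        rows = [i for i in range(lo, hi) if i != b]
        base[b] = np.median(x[rows], axis=0)
    return base[:, 0] if squeeze else base


def hollow_bins(half_width_s: float, bin_width_s: float) -> int:
    """Half-width in bins; must be a positive multiple of the bin width."""
    hw = half_width_s / bin_width_s
    if abs(hw - round(hw)) > 1e-9 or round(hw) < 1:
        raise ValueError("half-width must be a positive multiple of bin_width")
    return int(round(hw))


@dataclass
class TransmissionCurve:
    """Excess conditional rate after deconvolution and baseline subtraction."""

    centers: np.ndarray
    rate_spk_s: np.ndarray
    baseline_rate_spk_s: np.ndarray
    bin_width_s: float
    n_ref: int


class DeconvolutionSolver:
    """Deconvolve a presynaptic ACH kernel from baseline-subtracted CCHs.

    The observed CCH is modeled as the discrete convolution of the
    presynaptic autocorrelation with the causal transmission curve:
    ``cch_excess[i] = Σ_j K[i−j] · c[j]``, where ``K[0] = n_ref`` (each
    reference spike trivially co-occurs with itself) and ``K[d≠0]`` is read
    off the ACH at lag ``d·Δ`` (average of the two straddling bins,
    zero outside the measured window). The system is solved by regularized
    least squares (Tikhonov, ``λ = reg · trace(AᵀA)/n``); for a Poisson
    reference (flat ACH) the solution reduces to ``cch_excess / n_ref``.

    The factorization is computed once, so many right-hand sides (e.g.
    permutation replicates) can be solved cheaply.
    """

    def __init__(
        self,
        ach: Correlogram,
        n_ref: int | None = None,
        reg: float = 1e-6,
        off_zero_scale: float = 1.0,
    ):
        n = ach.n_bins
        if n % 2:
            raise ValueError("ACH grid must be symmetric about zero lag")
        self.n_bins = n
        self.bin_width_s = ach.bin_width_s
        self.n_ref = int(ach.n_ref if n_ref is None else n_ref)
        ach_counts = ach.counts.astype(float) * off_zero_scale
        half = n // 2
        # K[d]: displacement kernel; lag d·Δ straddles bins half−1+d and half+d
        kernel = np.zeros(2 * n - 1)
        for d in range(-(n - 1), n):
            vals = []
            for i in (half - 1 + d, half + d):
                if 0 <= i < n:
                    vals.append(ach_counts[i])
            kernel[d + n - 1] = float(np.mean(vals)) if vals else 0.0
        kernel[n - 1] = float(self.n_ref)
        col = kernel[n - 1 :]
        row = kernel[n - 1 :: -1]
        a = toeplitz(col, row)
        self._a = a
        ata = a.T @ a
        lam = reg * np.trace(ata) / n
        self._factor = cho_factor(ata + lam * np.eye(n))

    def solve(self, excess_counts: np.ndarray) -> np.ndarray:
        """Solve for the transmission curve in spk/s.

        ``excess_counts`` may be (n_bins,) or (n_bins, m) for batch solves.
        """
        b = np.asarray(excess_counts, dtype=float)
        # c is in excess target spikes per reference spike per bin (the
        # kernel carries the n_ref scale); dividing by Δ gives spk/s.
        c = cho_solve(self._factor, self._a.T @ b)
        return c / self.bin_width_s


def deconvolve_transmission(
    cch: Correlogram,
    ach_ref: Correlogram,
    baseline_half_width_s: float = 0.005,
    reg: float = 1e-6,
) -> TransmissionCurve:
    """Spike transmission curve: deconvolved CCH minus its slow baseline, spk/s.

    The presynaptic ACH (same bin grid, zero-displacement term set to
    ``n_ref``) is first deconvolved from the raw count CCH — this removes
    both spike-train autocorrelation structure and the transmission excess
    contributed by neighboring reference spikes — and the result scaled to
    conditional rate. The slow-timescale baseline (uncorrelated co-firing)
    is then estimated by hollowed median filtering of the deconvolved curve
    (default 5-ms half-width) and subtracted.
    """
    if cch.n_bins != ach_ref.n_bins or cch.bin_width_s != ach_ref.bin_width_s:
        raise ValueError("CCH and ACH must share the same bin grid")
    hw = hollow_bins(baseline_half_width_s, cch.bin_width_s)
    solver = DeconvolutionSolver(ach_ref, n_ref=cch.n_ref, reg=reg)
    rate_full = solver.solve(cch.counts.astype(float))
    baseline = hollowed_median_baseline(rate_full, hw)
    return TransmissionCurve(
        centers=cch.centers,
        rate_spk_s=rate_full - baseline,
        baseline_rate_spk_s=baseline,
        bin_width_s=cch.bin_width_s,
        n_ref=cch.n_ref,
    )


_P_MIN = np.nextafter(0.0, 1.0)


def poisson_excess_test(n_obs, n_expected):
    """Continuity-corrected Poisson excess probability.

    ``p = 1 − F(n_obs − 1; λ) − 0.5·f(n_obs; λ)`` with ``λ = n_expected``;
    the probability of observing ``n_obs`` or more counts when ``n_expected``
    are predicted, counting half the probability mass of the observed value.
    Clipped to (0, 1). For ``λ = 0`` and positive observed counts the excess
    is infinitely unlikely under the null; the minimal positive float is
    returned.
    """
    n = np.asarray(n_obs)
    lam = np.asarray(n_expected, dtype=float)
    if np.any(n < 0) or np.any(lam < 0):
        raise ValueError("counts and expectations must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - stats.poisson.cdf(n - 1, lam) - 0.5 * stats.poisson.pmf(n, lam)
    p = np.where((lam == 0) & (n > 0), 0.0, p)
    p = np.clip(p, _P_MIN, 1.0 - np.finfo(float).epsneg)
    return float(p) if p.ndim == 0 else p
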