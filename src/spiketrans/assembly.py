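"""Converging assemblies, peer statistics and stimulus CCH differences.

A converging assembly (CA) is a postsynaptic interneuron together with all
eligible presynaptic pairs that target it. Peer pairs share the
postsynaptic cell of a reference pair; non-peer pairs belong to other
simultaneously recorded assemblies.

The "CCH difference" of a pair captures the specific effect of light on its
spike timing during the Experience epoch: the conditional-rate CCH computed
with presynaptic reference spikes restricted to stimulus-on intervals,
minus the CCH with reference spikes restricted to the intervening
(no-light) intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import Session
from .correlograms import window_edges, _pair_lags, _histogram

__all__ = [
    "Assembly",
    "CCHDifference",
    "build_assemblies",
    "peer_nonpeer_means",
    "cch_difference",
    "aggregate_cch_difference",
    "sham_assemblies",
    "spearman_permutation",
]

PairId = tuple[str, str]


@dataclass
class Assembly:
    """A postsynaptic unit with its connected presynaptic pairs."""

    post_id: str
    members: tuple[PairId, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an assembly needs at least one member pair")
        for pre, post in self.members:
            if post != self.post_id:
                raise ValueError(
                    f"pair ({pre}, {post}) does not target {self.post_id}"
                )

    @property
    def size(self) -> int:
        return len(self.members)


def build_assemblies(pairs: Sequence[PairId]) -> list[Assembly]:
    """Partition eligible pairs into one assembly per postsynaptic unit."""
    by_post: dict[str, list[PairId]] = {}
    for pre, post in pairs:
        by_post.setdefault(post, []).append((pre, post))
    return [Assembly(post, tuple(members)) for post, members in by_post.items()]


def peer_nonpeer_means(
    pair: PairId,
    assemblies: Sequence[Assembly],
    values: Mapping[PairId, float],
) -> tuple[float, float]:
    """Mean value over the pair's peers and over all non-peer pairs.

    Peers are same-assembly pairs excluding the pair itself; non-peers are
    all pairs of the other assemblies. Either mean is NaN when its set is
    empty.
    """
    own = next((a for a in assemblies if pair in a.members), None)
    if own is None:
        raise KeyError(f"pair {pair} not found in any assembly")
    peers = [values[m] for m in own.members if m != pair]
    nonpeers = [
        values[m] for a in assemblies if a is not own for m in a.members
    ]
    mean = lambda v: float(np.mean(v)) if v else float("nan")
    return mean(peers), mean(nonpeers)


@dataclass
class CCHDifference:
    """Stimulus vs between-stimulus conditional-rate CCHs of one pair."""

    pre_id: str
    post_id: str
    centers: np.ndarray
    stim_rate: np.ndarray
    between_rate: np.ndarray
    n_ref_stim: int
    n_ref_between: int

    @property
    def difference(self) -> np.ndarray:
        return self.stim_rate - self.between_rate


def _complement_intervals(
    span: tuple[float, float], blocks: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """The parts of ``span`` not covered by the sorted ``blocks``."""
    a, b = span
    out = []
    cur = a
    for lo, hi in blocks:
        lo, hi = max(lo, a), min(hi, b)
        if hi <= cur:
            continue
        if lo > cur:
            out.append((cur, lo))
        cur = max(cur, hi)
    if cur < b:
        out.append((cur, b))
    return out


def _rate_cch(
    ref_times: np.ndarray, tgt_times: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    counts = _histogram(
        _pair_lags(ref_times, tgt_times, edges[0], edges[-1], False), edges
    )
    dt = edges[1] - edges[0]
    return counts / (ref_times.size * dt)


def cch_difference(
    session: Session,
    pre_id: str,
    post_id: str,
    bin_width_s: float = 0.001,
    window: tuple[float, float] = (-0.0505, 0.0505),
) -> CCHDifference:
    """CCH difference of a pair over the Experience epoch.

    Presynaptic reference spikes are restricted to the nominal stimulus-on
    intervals [onset, onset + duration) and, separately, to the intervening
    no-light intervals of the Experience epoch; the postsynaptic target
    train is used in full. Raises when either interval set holds no
    reference spikes (flagged missing upstream).
    """
    if session.events.n_events == 0:
        raise ValueError("session has no stimulus events")
    exp = session.epochs["Experience"]
    stim_iv = session.events.intervals()
    between_iv = _complement_intervals(exp, stim_iv)
    pre = session.trains[pre_id]
    post = session.trains[post_id]
    ref_stim = pre.restrict(stim_iv).times
    ref_between = pre.restrict(between_iv).times
    if ref_stim.size == 0 or ref_between.size == 0:
        raise ValueError(
            f"pair ({pre_id}, {post_id}): no presynaptic reference spikes in "
            "one of the interval sets"
        )
    edges = window_edges(bin_width_s, window)
    stim_rate = _rate_cch(ref_stim, post.times, edges)
    between_rate = _rate_cch(ref_between, post.times, edges)
    return CCHDifference(
        pre_id=pre_id, post_id=post_id,
        centers=0.5 * (edges[:-1] + edges[1:]),
        stim_rate=stim_rate, between_rate=between_rate,
        n_ref_stim=int(ref_stim.size), n_ref_between=int(ref_between.size),
    )


def aggregate_cch_difference(
    assembly: Assembly,
    pair_diffs: Mapping[PairId, CCHDifference],
    mode: str = "whole_assembly",
    pair: PairId | None = None,
) -> np.ndarray:
    """Element-wise sum of member CCH-difference vectors.

    ``mode="whole_assembly"`` sums every member; ``mode="peers_of"`` sums
    all members except ``pair``.
    """
    if mode == "whole_assembly":
        selected = list(assembly.members)
    elif mode == "peers_of":
        if pair is None:
            raise ValueError("peers_of mode requires the reference pair")
        selected = [m for m in assembly.members if m != pair]
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    vectors = [pair_diffs[m].difference for m in selected if m in pair_diffs]
    if not vectors:
        raise ValueError("no CCH differences to aggregate")
    return np.sum(vectors, axis=0)


def sham_assemblies(
    pairs: Sequence[PairId],
    sizes: Sequence[int],
    seed: int | np.random.Generator = 0,
) -> list[Assembly]:
    """Random re-allocation of pairs to assemblies, preserving the size multiset.

    The sham assemblies keep the session's assembly sizes but shuffle which
    pairs belong together; each sham assembly adopts the postsynaptic id of
    its first allocated pair only as a label.
    """
    if sum(sizes) != len(pairs):
        raise ValueError("sizes must sum to the number of pairs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    shuffled = [pairs[i] for i in order]
    out = []
    cursor = 0
    for k, size in enumerate(sizes):
        chunk = shuffled[cursor : cursor + size]
        cursor += size
        out.append(
            Assembly(
                post_id=f"sham_{k}",
                members=tuple((pre, f"sham_{k}") for pre, _ in chunk),
            )
        )
    return out


def spearman_permutation(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Spearman rank correlation with a two-tailed permutation p-value.

    ``p = (1 + #{|cc_perm| ≥ |cc|}) / (n_perm + 1)`` over random pairings.
    NaN correlation (constant input) is flagged by returning (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        cc = stats.spearmanr(x, y).statistic
    if not np.isfinite(cc):
        return float("nan"), float("nan")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    # Spearman cc is Pearson on ranks; precompute normalized ranks so each
    # permutation is a single dot product.
    zx = (rx - rx.mean()) / np.sqrt(np.sum((rx - rx.mean()) ** 2))
    zy = (ry - ry.mean()) / np.sqrt(np.sum((ry - ry.mean()) ** 2))
    n_extreme = 0
    for _ in range(n_perm):
        cc_perm = float(zx @ rng.permutation(zy))
        if abs(cc_perm) >= abs(cc) - 1e-12:
            n_extreme += 1
    p = (1 + n_extreme) / (n_perm + 1)
    return float(cc), float(p)
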