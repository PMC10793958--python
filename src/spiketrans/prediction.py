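"""Cross-validated prediction of transmission changes.

Regression (RBF-kernel SVR) predicts continuous STG changes from assembly
structure and excitability features; linear SVM classification predicts the
increase/decrease direction from spike-timing features (CCH-difference
vectors). Both use repeated five-fold cross-validation with out-of-fold
predictions pooled within each repeat: the SVR reports one reconstruction
R² per repeat, the SVM one ROC AUC per repeat.

Feature manipulations isolate information channels: Z-scoring each
CCH-difference vector removes co-firing ("rate") information and keeps only
millisecond-scale timing; shuffling the order of its bins destroys timing
while keeping the rate content.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score, roc_auc_score
from sklearn.svm import SVC, SVR

from .core import Session, StimulusEvents

__all__ = [
    "zscore_vector",
    "shuffle_bins",
    "crossval_svr",
    "crossval_svm_auc",
    "window_scan",
    "virtual_closed_loop",
    "default_cle_sampler",
    "pair_feature_table",
]


def zscore_vector(v: np.ndarray) -> np.ndarray:
    """Standardize a vector to mean 0, SD 1; raises on constant input."""
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 elements to Z-score")
    sd = v.std()
    if sd == 0:
        raise ValueError("constant vector cannot be Z-scored")
    return (v - v.mean()) / sd


def shuffle_bins(v: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Random permutation of a vector's bins (multiset preserved)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.permutation(np.asarray(v))


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _median_gamma(x: np.ndarray) -> float:
    """RBF width by the median heuristic of pairwise Euclidean distances."""
    n = x.shape[0]
    if n > 400:
        x = x[:: max(1, n // 400)]
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    med = np.median(np.sqrt(d2[np.triu_indices_from(d2, k=1)]))
    if med <= 0:
        return 1.0
    return 1.0 / (2.0 * med**2)


def _random_folds(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [f for f in np.array_split(idx, folds) if f.size]


def _group_folds(
    groups: np.ndarray, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Folds that never split a group: shuffled greedy size balancing."""
    uniq = np.array(sorted(set(groups)))
    order = rng.permutation(uniq.size)
    fold_members: list[list] = [[] for _ in range(folds)]
    fold_sizes = np.zeros(folds, dtype=int)
    for g in uniq[order]:
        k = int(np.argmin(fold_sizes))
        members = np.flatnonzero(groups == g)
        fold_members[k].extend(members)
        fold_sizes[k] += members.size
    return [np.array(sorted(m)) for m in fold_members if m]


def crossval_svr(
    features: np.ndarray,
    target: np.ndarray,
    folds: int = 5,
    repeats: int = 100,
    seed: int | np.random.Generator = 0,
    c: float = 1.0,
) -> np.ndarray:
    """Repeated five-fold cross-validated SVR (RBF kernel); R² per repeat.

    Features are standardized on the training folds only; the kernel width
    follows the median heuristic on the standardized training features. The
    R² of each repeat is computed once from the pooled out-of-fold
    predictions.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[0] == 1 and np.asarray(target).size != 1:
        x = x.T
    y = np.asarray(target, dtype=float)
    if x.shape[0] < folds:
        raise ValueError("need at least as many rows as folds")
    if np.var(y) == 0:
        raise ValueError("degenerate target variance")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = np.empty(repeats)
    for r in range(repeats):
        pred = np.empty_like(y)
        for test_idx in _random_folds(y.size, folds, rng):
            train_idx = np.setdiff1d(np.arange(y.size), test_idx)
            xtr, xte = _standardize(x[train_idx], x[test_idx])
            model = SVR(kernel="rbf", C=c, gamma=_median_gamma(xtr))
            model.fit(xtr, y[train_idx])
            pred[test_idx] = model.predict(xte)
        scores[r] = r2_score(y, pred)
    return scores


def _fit_fold_scores(
    x: np.ndarray,
    y: np.ndarray,
    fold_list: list[np.ndarray],
    c: float,
) -> np.ndarray | None:
    """Pooled out-of-fold decision values; None if a fold is single-class."""
    scores = np.empty(y.size)
    for test_idx in fold_list:
        train_idx = np.setdiff1d(np.arange(y.size), test_idx)
        if len(set(y[train_idx])) < 2:
            return None
        xtr, xte = _standardize(x[train_idx], x[test_idx])
        model = SVC(kernel="linear", C=c)
        model.fit(xtr, y[train_idx])
        scores[test_idx] = model.decision_function(xte)
    return scores


def crossval_svm_auc(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 5,
    repeats: int = 100,
    seed: int | np.random.Generator = 0,
    scheme: str = "random",
    groups: np.ndarray | None = None,
    shuffle_labels: bool = False,
    c: float = 1.0,
    max_retries: int = 20,
) -> np.ndarray:
    """Repeated five-fold cross-validated linear SVM; ROC AUC per repeat.

    ``scheme`` controls the fold structure: ``"random"`` uses row-level
    folds; ``"entire_assembly"`` keeps all rows of one group (assembly) in
    the same fold, so no assembly spans train and test;
    ``"subsample_one_per_assembly"`` repeatedly draws one row per group and
    cross-validates the subsample until each row has ``repeats``
    predictions, then scores one AUC per prediction round. With
    ``shuffle_labels`` the labels are randomly re-assigned independently in
    every repeat (the chance control). Fold partitions yielding a
    single-class training fold are redrawn (bounded retries).
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if x.shape[0] != y.size:
        x = x.T
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    ybin = (y == classes[1]).astype(int)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if scheme == "subsample_one_per_assembly":
        if groups is None:
            raise ValueError("subsampling requires groups")
        return _subsample_auc(x, ybin, np.asarray(groups), folds, repeats, rng, c)

    aucs = np.empty(repeats)
    for r in range(repeats):
        yr = rng.permutation(ybin) if shuffle_labels else ybin
        scores = None
        for _ in range(max_retries):
            if scheme == "random":
                fold_list = _random_folds(yr.size, folds, rng)
            elif scheme == "entire_assembly":
                if groups is None:
                    raise ValueError("entire_assembly scheme requires groups")
                fold_list = _group_folds(np.asarray(groups), folds, rng)
            else:
                raise ValueError(f"unknown scheme {scheme!r}")
            scores = _fit_fold_scores(x, yr, fold_list, c)
            if scores is not None:
                break
        if scores is None:
            raise RuntimeError("could not draw folds with both classes")
        aucs[r] = roc_auc_score(yr, scores)
    return aucs


def _subsample_auc(
    x: np.ndarray,
    ybin: np.ndarray,
    groups: np.ndarray,
    folds: int,
    repeats: int,
    rng: np.random.Generator,
    c: float,
) -> np.ndarray:
    """One row per assembly per round until every row has `repeats` predictions."""
    n = ybin.size
    uniq = sorted(set(groups))
    preds: list[list[float]] = [[] for _ in range(n)]
    guard = 0
    while min(len(p) for p in preds) < repeats:
        guard += 1
        if guard > 50 * repeats:
            raise RuntimeError("subsampling failed to cover all rows")
        chosen = np.array(
            [rng.choice(np.flatnonzero(groups == g)) for g in uniq]
        )
        ys = ybin[chosen]
        if len(set(ys)) < 2:
            continue
        scores = _fit_fold_scores(
            x[chosen], ys, _random_folds(chosen.size, folds, rng), c
        )
        if scores is None:
            continue
        for i, s in zip(chosen, scores):
            preds[i].append(float(s))
    kept = np.array(
        [rng.choice(p, size=repeats, replace=False) for p in preds]
    )  # (n, repeats)
    return np.array(
        [roc_auc_score(ybin, kept[:, r]) for r in range(repeats)]
    )


def window_scan(
    diff_matrix: np.ndarray,
    centers_s: np.ndarray,
    labels: np.ndarray,
    half_widths_s: Sequence[float] | None = None,
    offsets_s: Sequence[float] | None = None,
    offset_window_s: float = 0.021,
    repeats: int = 20,
    seed: int | np.random.Generator = 0,
    **svm_kwargs,
) -> pd.DataFrame:
    """AUC summary of classifiers on lag-window slices of CCH differences.

    Either scan symmetric windows centered at zero lag (``half_widths_s``)
    or slide a fixed-width window across ``offsets_s``. Returns one row per
    setting with the slice size and the mean/SD of per-repeat AUCs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diff_matrix = np.asarray(diff_matrix, dtype=float)
    centers = np.asarray(centers_s, dtype=float)
    rows = []
    if (half_widths_s is None) == (offsets_s is None):
        raise ValueError("give exactly one of half_widths_s or offsets_s")
    settings = (
        [("half_width", w, np.abs(centers) <= w + 1e-12) for w in half_widths_s]
        if half_widths_s is not None
        else [
            (
                "offset",
                o,
                np.abs(centers - o) <= offset_window_s / 2 + 1e-12,
            )
            for o in offsets_s
        ]
    )
    for kind, value, mask in settings:
        if not mask.any():
            raise ValueError(f"window {kind}={value} covers no bins")
        aucs = crossval_svm_auc(
            diff_matrix[:, mask], labels, repeats=repeats, seed=rng, **svm_kwargs
        )
        rows.append(
            {kind: value, "n_bins": int(mask.sum()),
             "auc_mean": float(np.mean(aucs)), "auc_sd": float(np.std(aucs))}
        )
    return pd.DataFrame(rows)


def default_cle_sampler(
    rng: np.random.Generator,
    median: float = 0.054,
    iqr: tuple[float, float] = (0.013, 0.184),
) -> float:
    """Log-normal CLE draw matched to the trigger-unit quantiles, clipped to [0, 1]."""
    mu = np.log(median)
    sigma = (np.log(iqr[1]) - np.log(iqr[0])) / (2 * 0.6744897501960817)
    return float(np.clip(rng.lognormal(mu, sigma), 0.0, 1.0))


def virtual_closed_loop(
    session: Session,
    assembly_units: Sequence[Sequence[str]],
    seed: int | np.random.Generator = 0,
    cle_sampler: Callable[[np.random.Generator], float] | None = None,
    delay_s: float = 0.003,
    stim_duration_s: float = 0.030,
    dead_time_s: float = 0.020,
) -> tuple[StimulusEvents, pd.DataFrame]:
    """Assign sham stimulation periods to an unstimulated session.

    For each assembly one presynaptic trigger unit is chosen at random and a
    target CLE drawn from ``cle_sampler`` (default: log-normal matched to
    the closed-loop trigger quantiles). That fraction of the unit's
    Experience-epoch spikes is selected at random as virtual triggers;
    onsets follow at the detection delay, with dead-time blanking applied to
    the merged schedule. No spikes are altered. Returns the events and a
    table of chosen units and their drawn CLEs.
    """
    if session.events.n_events:
        raise ValueError("virtual closed loop requires a stimulus-free session")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sampler = cle_sampler or default_cle_sampler
    exp = session.epochs["Experience"]
    chosen_rows = []
    tagged: list[tuple[float, str]] = []
    for k, units in enumerate(assembly_units):
        uid = units[int(rng.integers(len(units)))]
        spikes = session.trains[uid].restrict([exp]).times
        if spikes.size == 0:
            raise ValueError(f"unit {uid}: no Experience-epoch spikes")
        cle = sampler(rng)
        n_sel = int(round(cle * spikes.size))
        sel = rng.choice(spikes.size, size=n_sel, replace=False)
        tagged.extend((float(spikes[i]), uid) for i in sel)
        chosen_rows.append(dict(assembly=k, trigger_unit=uid, drawn_cle=cle,
                                n_selected=n_sel, n_spikes=int(spikes.size)))
    tagged.sort()
    min_gap = stim_duration_s + dead_time_s
    onsets, triggers = [], []
    last = -np.inf
    for t, uid in tagged:
        onset = t + delay_s
        if onset >= exp[1]:
            continue
        if onset - last >= min_gap:
            onsets.append(onset)
            triggers.append(uid)
            last = onset
    events = StimulusEvents(
        np.array(onsets), stim_duration_s, dead_time_s,
        tuple(triggers) if onsets else None,
    )
    return events, pd.DataFrame(chosen_rows)


def cohort_difference_features(
    cohort: Sequence[dict],
    half_width_s: float = 0.0105,
    bin_width_s: float = 0.001,
    window: tuple[float, float] = (-0.0505, 0.0505),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assembly CCH-difference feature matrix for a simulated cohort.

    For each cohort assembly, computes the per-pair CCH differences, sums
    them into the assembly difference vector, and slices the lags with
    ``|center| ≤ half_width_s`` (±10 ms keeps the 21 one-ms
    bins centered at zero lag). Returns
    ``(features, labels, lag_centers)``.
    """
    from .assembly import aggregate_cch_difference, build_assemblies, cch_difference

    feats, labels = [], []
    centers = None
    for item in cohort:
        session = item["session"]
        diffs = {}
        for pre in item["pre_ids"]:
            d = cch_difference(session, pre, item["post_id"], bin_width_s, window)
            diffs[(pre, item["post_id"])] = d
            centers = d.centers
        assembly = build_assemblies(list(diffs))[0]
        vec = aggregate_cch_difference(assembly, diffs)
        mask = np.abs(centers) <= half_width_s + 1e-12
        feats.append(vec[mask])
        labels.append(item["label"])
    return np.array(feats), np.array(labels), centers[np.abs(centers) <= half_width_s + 1e-12]


def pair_feature_table(
    pair_table: pd.DataFrame,
    session: Session,
) -> pd.DataFrame:
    """Per-pair features for STG-change prediction.

    Builds, for every eligible pair: the mean STG change of its peers and of
    its non-peers, the postsynaptic rate changes (log2 After/Before and
    log2 After/Experience), the initial STG and presynaptic Before-epoch
    rate, plus the continuous target (stg_change) and its direction.
    """
    from .assembly import build_assemblies, peer_nonpeer_means

    eligible = pair_table[pair_table["eligible"]].reset_index(drop=True)
    pairs = list(zip(eligible["pre_id"], eligible["post_id"]))
    assemblies = build_assemblies(pairs)
    changes = dict(zip(pairs, eligible["stg_change"]))
    epochs = session.epochs
    rows = []
    for i, pair in enumerate(pairs):
        pre_id, post_id = pair
        peer, nonpeer = peer_nonpeer_means(pair, assemblies, changes)
        rates = {
            label: session.epoch_train(post_id, label).n_spikes
            / epochs.duration(label)
            for label in ("Before", "Experience", "After")
        }
        pre_rate_before = (
            session.epoch_train(pre_id, "Before").n_spikes
            / epochs.duration("Before")
        )
        rec = eligible.iloc[i]
        rows.append(
            dict(
                pre_id=pre_id, post_id=post_id,
                peer_mean_change=peer, nonpeer_mean_change=nonpeer,
                post_rate_change_ab=np.log2(rates["After"] / rates["Before"]),
                post_rate_change_ae=np.log2(rates["After"] / rates["Experience"]),
                stg_before=rec["stg_before"],
                pre_rate_before=pre_rate_before,
                stg_change=rec["stg_change"],
                direction_increase=rec["stg_change"] > 0,
            )
        )
    return pd.DataFrame(rows)
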