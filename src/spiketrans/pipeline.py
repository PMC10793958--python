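"""End-to-end orchestration: simulate → screen → measure → predict → report.

Every stage writes a plain-text table under the run directory; the whole
run is reproducible bit-identically from the configuration and the seed
(all randomness flows from one seed sequence, and all tables are written
with fixed float formatting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .assembly import build_assemblies, cch_difference
from .core import Session
from .io import save_config, write_session
from .prediction import crossval_svr, pair_feature_table
from .simulate import GroundTruth, SimConfig, generate_session
from .stim import stim_responses
from .synchrony import sync_change, sync_measure
from .transmission import screen_pairs, select_eligible_pairs

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "compare_conditions",
           "demo_sim_config"]

_FLOAT_FMT = "%.6g"


def demo_sim_config(seed: int = 0) -> SimConfig:
    """A desk-scale synthetic session: 3 assemblies with mixed plasticity."""
    return SimConfig(
        n_assemblies=3,
        presyn_per_assembly=3,
        presyn_rate_spk_s=(1.5, 3.0),
        postsyn_rate_spk_s=(8.0, 15.0),
        transmission_prob=(0.03, 0.15),
        plasticity_factor=(0.5, 1.0, 2.0),
        before_s=600.0, experience_s=720.0, after_s=600.0,
        detection_prob=0.6,
        light_gain=1.56,
        seed=seed,
    )


@dataclass
class PipelineConfig:
    """Run-level knobs on top of the simulation configuration."""

    sim: SimConfig = field(default_factory=demo_sim_config)
    n_shuffles: int = 200
    svr_repeats: int = 20
    seed: int = 0

    def to_dict(self) -> dict:
        return dict(
            sim=self.sim.to_dict(), n_shuffles=self.n_shuffles,
            svr_repeats=self.svr_repeats, seed=self.seed,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)


@dataclass
class RunReport:
    """All per-stage tables of one pipeline run plus the summary."""

    session: Session
    truth: GroundTruth
    pairs: pd.DataFrame
    stim: pd.DataFrame | None
    sync: pd.DataFrame
    assemblies: pd.DataFrame
    cch_diff: pd.DataFrame | None
    features: pd.DataFrame
    predictions: pd.DataFrame
    summary: dict


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Run every stage on a synthetic session and optionally write all tables."""
    config = config or PipelineConfig()
    root = np.random.SeedSequence(config.seed)
    s_screen, s_svr = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2)]

    # --- simulate -----------------------------------------------------------
    session, truth = generate_session(config.sim, seed=config.sim.seed)
    if not session.units("PYR") or not session.units("PV"):
        raise RuntimeError("stage simulate: session contains no PYR/PV units")

    # --- screen + transmission ---------------------------------------------
    pairs = screen_pairs(
        session, n_shuffles=config.n_shuffles, seed=s_screen,
    )
    eligible = select_eligible_pairs(pairs)
    if eligible.empty:
        raise RuntimeError("stage screen: no eligible pairs")

    # --- stimulation metrics ------------------------------------------------
    stim = stim_responses(session) if session.events.n_events else None

    # --- synchrony ----------------------------------------------------------
    sync_rows = []
    stim_iv = session.events.intervals()
    from .assembly import _complement_intervals  # session minus stimuli

    quiet = _complement_intervals((0.0, session.duration_s), stim_iv)
    pyr = session.units("PYR")
    for i, u1 in enumerate(pyr):
        for u2 in pyr[i + 1:]:
            t1 = session.trains[u1].restrict(quiet)
            t2 = session.trains[u2].restrict(quiet)
            if t1.n_spikes == 0 or t2.n_spikes == 0:
                continue
            r = sync_measure(t1, t2)
            sync_rows.append(
                dict(id_1=u1, id_2=u2, kind="PYR-PYR",
                     same_shank=session.trains[u1].shank == session.trains[u2].shank,
                     delta_eta=r.delta_eta, p_sync=r.p_sync,
                     sync_change=np.nan)
            )
    pv = session.units("PV")
    for i, u1 in enumerate(pv):
        for u2 in pv[i + 1:]:
            res = {}
            for label in ("Before", "After"):
                res[label] = sync_measure(
                    session.epoch_train(u1, label), session.epoch_train(u2, label)
                )
            sync_rows.append(
                dict(id_1=u1, id_2=u2, kind="PV-PV", same_shank=False,
                     delta_eta=res["Before"].delta_eta,
                     p_sync=res["Before"].p_sync,
                     sync_change=sync_change(res["Before"], res["After"]))
            )
    sync = pd.DataFrame(sync_rows)

    # --- assemblies and CCH differences ------------------------------------
    pair_ids = list(zip(eligible["pre_id"], eligible["post_id"]))
    assemblies = build_assemblies(pair_ids)
    asm_table = pd.DataFrame(
        [dict(post_id=a.post_id, size=a.size,
              members=";".join(p for p, _ in a.members)) for a in assemblies]
    )
    cch_diff_table = None
    if session.events.n_events:
        diff_rows = []
        for pre_id, post_id in pair_ids:
            try:
                d = cch_difference(session, pre_id, post_id)
            except ValueError:
                continue
            for c, s, b in zip(d.centers, d.stim_rate, d.between_rate):
                diff_rows.append(
                    dict(pre_id=pre_id, post_id=post_id, lag_s=c,
                         stim_rate=s, between_rate=b, difference=s - b)
                )
        cch_diff_table = pd.DataFrame(diff_rows)

    # --- features and prediction -------------------------------------------
    features = pair_feature_table(eligible, session)
    predictions_rows = []
    feat_cols = ["peer_mean_change", "nonpeer_mean_change", "post_rate_change_ab"]
    usable = features.dropna(subset=feat_cols + ["stg_change"])
    if len(usable) >= 5 and np.var(usable["stg_change"]) > 0:
        r2 = crossval_svr(
            usable[feat_cols].to_numpy(), usable["stg_change"].to_numpy(),
            repeats=config.svr_repeats, seed=s_svr,
        )
        predictions_rows = [
            dict(model="svr_full", repeat=i, score=float(v))
            for i, v in enumerate(r2)
        ]
    predictions = pd.DataFrame(predictions_rows)

    # --- summary ------------------------------------------------------------
    finite = eligible["stg_change"].dropna()
    truth_by_pair = truth.pairs.set_index(["pre_id", "post_id"])
    recov = []
    for _, row in eligible.iterrows():
        key = (row["pre_id"], row["post_id"])
        if key in truth_by_pair.index:
            recov.append(
                row["stg_change"] - truth_by_pair.loc[key, "true_stg_change"]
            )
    summary = dict(
        version=__version__,
        seed=config.seed,
        n_units=len(session.trains),
        n_events=session.events.n_events,
        n_pairs_screened=len(pairs),
        n_pairs_eligible=len(eligible),
        n_assemblies=len(assemblies),
        median_stg_change=float(np.median(finite)) if len(finite) else None,
        median_abs_stg_change=float(np.median(np.abs(finite))) if len(finite) else None,
        frac_increase=float(np.mean(eligible["direction"] == "increase")),
        frac_decrease=float(np.mean(eligible["direction"] == "decrease")),
        mean_change_recovery_error=float(np.mean(recov)) if recov else None,
        svr_r2_median=(
            float(np.median(predictions["score"])) if len(predictions) else None
        ),
    )

    report = RunReport(
        session=session, truth=truth, pairs=pairs, stim=stim, sync=sync,
        assemblies=asm_table, cch_diff=cch_diff_table, features=features,
        predictions=predictions, summary=summary,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_session(session, out)
        _write(truth.pairs, out / "ground_truth_pairs.tsv")
        _write(truth.units, out / "ground_truth_units.tsv")
        _write(truth.assemblies, out / "ground_truth_assemblies.tsv")
        _write(pairs, out / "pairs.tsv")
        if stim is not None:
            _write(stim, out / "stim_response.tsv")
        _write(sync, out / "sync.tsv")
        _write(asm_table, out / "assemblies.tsv")
        if cch_diff_table is not None:
            _write(cch_diff_table, out / "cch_diff.tsv")
        _write(features, out / "features.tsv")
        _write(predictions, out / "predictions.tsv")
        save_config(config.to_dict(), out / "config.yaml")
        with open(out / "report.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def assembly_signature(
    mode: str,
    n_sessions: int = 6,
    n_assemblies: int = 5,
    presyn_per_assembly: int = 3,
    sigma_log2: float = 0.8,
    epoch_s: float = 600.0,
    seed: int = 300,
) -> dict:
    """Pair-vs-peer and pair-vs-non-peer association across pooled sessions.

    Simulates ``n_sessions`` stimulus-free sessions whose transmission
    probabilities change between the Before and After epochs either
    coherently per assembly (``mode="assembly"``) or independently per pair
    (``mode="pair"``), estimates every pair's STG change, and correlates it
    (Spearman + permutation test) with the mean change of its peers and of
    its non-peers. Peer/non-peer means are computed within-session; pairs
    are pooled across sessions before correlating.
    """
    from .assembly import build_assemblies, peer_nonpeer_means, spearman_permutation
    from .transmission import compute_stg, stg_change

    x, y_peer, y_nonpeer = [], [], []
    for s in range(n_sessions):
        cfg = SimConfig(
            n_assemblies=n_assemblies, presyn_per_assembly=presyn_per_assembly,
            presyn_rate_spk_s=(2.0, 2.0), postsyn_rate_spk_s=(10.0, 10.0),
            transmission_prob=(0.05, 0.15), plasticity_sigma_log2=sigma_log2,
            plasticity_mode=mode, before_s=epoch_s, experience_s=60.0,
            after_s=epoch_s, closed_loop=False, light_gain=1.0, seed=seed + s,
        )
        session, truth = generate_session(cfg)
        changes = {}
        for _, row in truth.pairs.iterrows():
            pre, post = row["pre_id"], row["post_id"]
            stg_b, _ = compute_stg(
                session.epoch_train(pre, "Before"), session.epoch_train(post, "Before")
            )
            stg_a, _ = compute_stg(
                session.epoch_train(pre, "After"), session.epoch_train(post, "After")
            )
            changes[(pre, post)] = stg_change(stg_b, stg_a)
        pairs = list(changes)
        assemblies = build_assemblies(pairs)
        for pair in pairs:
            peer, nonpeer = peer_nonpeer_means(pair, assemblies, changes)
            if all(np.isfinite(v) for v in (changes[pair], peer, nonpeer)):
                x.append(changes[pair])
                y_peer.append(peer)
                y_nonpeer.append(nonpeer)
    peer_cc, peer_p = spearman_permutation(
        np.array(x), np.array(y_peer), 2000, seed=seed + 1000
    )
    nonpeer_cc, nonpeer_p = spearman_permutation(
        np.array(x), np.array(y_nonpeer), 2000, seed=seed + 2000
    )
    return dict(
        mode=mode, n_pairs=len(x), peer_cc=peer_cc, peer_p=peer_p,
        nonpeer_cc=nonpeer_cc, nonpeer_p=nonpeer_p,
    )


def compare_conditions(
    stim_pairs: pd.DataFrame, control_pairs: pd.DataFrame
) -> dict:
    """Contrast STG changes between stimulated and control pair cohorts.

    Reports medians, IQRs and two-sided rank-sum (Mann–Whitney U) p-values
    for both the signed change and its magnitude.
    """
    a = stim_pairs["stg_change"].dropna().to_numpy()
    b = control_pairs["stg_change"].dropna().to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("both cohorts need finite STG changes")

    def _stats(v):
        return dict(
            median=float(np.median(v)),
            iqr=[float(np.percentile(v, 25)), float(np.percentile(v, 75))],
        )

    return dict(
        stim=_stats(a),
        control=_stats(b),
        stim_abs=_stats(np.abs(a)),
        control_abs=_stats(np.abs(b)),
        p_median=float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue),
        p_magnitude=float(
            stats.mannwhitneyu(
                np.abs(a), np.abs(b), alternative="two-sided"
            ).pvalue
        ),
    )
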