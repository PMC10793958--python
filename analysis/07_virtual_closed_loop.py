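#!/usr/bin/env python
"""Virtual closed loop: sham stimulation assigned to an unstimulated session.

Simulates a stimulus-free control session, picks one trigger PYR per
assembly, draws target closed-loop efficiencies (CLEs) from the log-normal
distribution matched to real trigger-unit quantiles, and tags that
fraction of each trigger's Experience-epoch spikes with virtual stimulus
onsets (3-ms delay, 30-ms duration, 20-ms dead time). The CLE estimator is
then closed over the construction: recomputed CLEs should match the drawn
values, and the virtual "light" has no effect on any spike train.
"""

from pathlib import Path

from spiketrans.pipeline import demo_sim_config
from spiketrans.simulate import generate_session
from spiketrans.stim import closed_loop_efficiency
from spiketrans.prediction import virtual_closed_loop

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 11) -> None:
    cfg = demo_sim_config(seed=seed)
    cfg.closed_loop = False
    session, _ = generate_session(cfg, seed=seed)
    assert session.events.n_events == 0

    assembly_units = [
        [f"pyr_a{a}_{i}" for i in range(cfg.presyn_per_assembly)]
        for a in range(cfg.n_assemblies)
    ]
    events, chosen = virtual_closed_loop(session, assembly_units, seed=seed)
    period = session.epochs["Experience"]
    realized = []
    for _, row in chosen.iterrows():
        cle, _ = closed_loop_efficiency(
            session.trains[row["trigger_unit"]], events, period=period
        )
        realized.append(cle)
    chosen = chosen.assign(realized_cle=realized)
    chosen.to_csv(ROOT / "virtual_closed_loop.tsv", sep="\t", index=False,
                  float_format="%.6g")

    print(f"virtual closed loop: {events.n_events} sham events "
          f"from {len(chosen)} trigger units")
    for _, r in chosen.iterrows():
        print(f"  {r['trigger_unit']}: drawn CLE {r['drawn_cle']:.3f} -> "
              f"recomputed {r['realized_cle']:.3f}")


if __name__ == "__main__":
    main()
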