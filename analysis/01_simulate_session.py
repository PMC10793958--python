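#!/usr/bin/env python
"""Simulate the demo closed-loop session and write it to results/session/.

Three converging assemblies (3 PYRs → 1 PV each) with mixed injected
plasticity (halving / none / doubling), 10/12/10-minute epochs, and
closed-loop stimulation triggered by one PYR per assembly during the
Experience epoch. The written TSV files are the inputs for every later
analysis step.
"""

from pathlib import Path

import numpy as np

from spiketrans.io import save_config, write_session
from spiketrans.pipeline import demo_sim_config
from spiketrans.simulate import generate_session

OUT = Path(__file__).resolve().parent.parent / "results" / "session"


def main(seed: int = 0) -> None:
    cfg = demo_sim_config(seed=seed)
    session, truth = generate_session(cfg, seed=seed)
    OUT.mkdir(parents=True, exist_ok=True)
    write_session(session, OUT)
    for name, table in [
        ("ground_truth_pairs.tsv", truth.pairs),
        ("ground_truth_units.tsv", truth.units),
        ("ground_truth_assemblies.tsv", truth.assemblies),
    ]:
        table.to_csv(OUT / name, sep="\t", index=False, float_format="%.6g")
    save_config(cfg.to_dict(), OUT / "config.yaml")

    n_spikes = sum(t.n_spikes for t in session.trains.values())
    print(f"wrote session to {OUT}")
    print(f"  units: {len(session.trains)} ({len(session.units('PYR'))} PYR, "
          f"{len(session.units('PV'))} PV), spikes: {n_spikes}")
    print(f"  stimulus events: {session.events.n_events}")
    print("  injected per-assembly plasticity factors:",
          np.round(truth.assemblies['plasticity_factor'].to_numpy(), 3))


if __name__ == "__main__":
    main()
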