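#!/usr/bin/env python
"""Simulate pairwise competitions among the Early/Intermediate/Late clones.

Generates flow-cytometry-like competition time courses at several starting
frequencies for each clone pair (and a virus-cured-ancestor control series
with toxin killing disabled) and writes them under results/competitions/.
"""

import argparse
from pathlib import Path

import numpy as np

from nontransim import io as nio
from nontransim.pipeline import DEFAULT_CONFIG, _clones
from nontransim.simcore import SerialTransferProtocol, SimConfig, ToxinModel, simulate_competition


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/competitions"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    early, inter, late, variants = _clones(DEFAULT_CONFIG, 100)
    pairs = [(early, inter), (inter, late), (early, late)]
    n_written = 0
    for kappa, tag in ((0.2, "toxin"), (0.0, "cured")):
        for earlier, later in pairs:
            for f0 in (0.1, 0.5, 0.9):
                cfg = SimConfig(
                    protocol=SerialTransferProtocol(),
                    toxin=ToxinModel(kill_coefficient=kappa),
                    seed=int(rng.integers(2**31)),
                )
                tc = simulate_competition(
                    cfg, later, earlier, f0, 50, 10, sample_size=10_000,
                    variants=variants,
                )
                path = args.out_dir / f"{tag}_{later.id}_vs_{earlier.id}_f{int(f0*100):02d}.csv"
                nio.write_timecourse(tc, path)
                n_written += 1
    print(f"wrote {n_written} competition time courses to {args.out_dir}")


if __name__ == "__main__":
    main()
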