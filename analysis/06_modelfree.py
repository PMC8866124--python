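#!/usr/bin/env python
"""Lipari--Szabo closed loop on synthetic backbone 15N relaxation.

Forward-generates R1/R2/NOE for residues spanning rigid core to
flexible tail (shared 8 ns tumbling), adds 3% noise, refits the
model-free parameters and writes the recovery table.  The dynamic
517-522 region of the SH3 domain motivates the low-order-parameter
band.
"""

import argparse
from pathlib import Path

import pandas as pd

from ringflip.modelfree import MotionParams, fit_modelfree
from ringflip.synthetic import make_relaxation_set

MOTIONS = {
    "core-520s": MotionParams(0.60, 8.0, 300.0),   # dynamic 517-522-like
    "sheet-1": MotionParams(0.88, 8.0, 30.0),
    "sheet-2": MotionParams(0.85, 8.0, 50.0),
    "loop": MotionParams(0.72, 8.0, 150.0),
    "tail": MotionParams(0.45, 8.0, 700.0),
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--noise", type=float, default=0.03)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    data, truth = make_relaxation_set(MOTIONS, noise=args.noise,
                                      seed=args.seed)
    fit = fit_modelfree(data).set_index("residue")
    fit["s2_true"] = {r: m.s2 for r, m in MOTIONS.items()}
    fit["s2_error"] = (fit["s2"] - fit["s2_true"]).round(4)
    fit.to_csv(args.outdir / "modelfree_fit.csv")
    print(fit[["s2_true", "s2", "s2_error", "tau_e_ps", "tau_c_ns", "model"]]
          .to_string())
    print(f"-> {args.outdir / 'modelfree_fit.csv'}")


if __name__ == "__main__":
    main()
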