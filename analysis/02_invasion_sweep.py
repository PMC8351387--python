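"""The mutant-invasion experiment over the mixing x secretion-fold grid.

At full scale this is 11 mixing values x 4 folds x 200 replicates of a
25-transfer run. The default here is a reduced grid (mixing 0, 0.5, 1;
200 replicates) that shows the study's key contrast — invasion of the
over-secreting mutant at zero mixing, extinction at full mixing — in a
few minutes; pass --full for the complete grid.

Writes results/invasion_sweep.csv and prints the per-cell summaries.
"""

import argparse
from pathlib import Path

import numpy as np

from crossfeed.abm import SimConfig
from crossfeed.experiment import fisher_invasion_test, sweep

OUT = Path(__file__).resolve().parent.parent / "results"


def main(full: bool = False, replicates: int = 200, seed: int = 0) -> None:
    mixing = list(np.round(np.arange(0, 1.01, 0.1), 1)) if full \
        else [0.0, 0.5, 1.0]
    OUT.mkdir(exist_ok=True)
    df = sweep(SimConfig(), mixing_values=mixing, folds=(1.0, 1.5, 2.0, 3.0),
               n_replicates=replicates, base_seed=seed)
    df.to_csv(OUT / "invasion_sweep.csv", index=False)
    print(df.to_string(index=False))

    at0 = df[df.mixing == 0.0].set_index("fold")
    n = int(at0.loc[1.0, "n"])
    k1 = round(at0.loc[1.0, "invasion_percent"] * n / 100)
    for fold in (1.5, 2.0, 3.0):
        k = round(at0.loc[fold, "invasion_percent"] * n / 100)
        p = fisher_invasion_test(int(k), n, int(k1), n)
        print(f"mixing 0, fold {fold} vs neutral: {k}/{n} vs {k1}/{n} "
              f"invasions (Fisher two-sided p = {p:.3g})")
    print(f"wrote {OUT / 'invasion_sweep.csv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--full", action="store_true")
    ap.add_argument("--replicates", type=int, default=200)
    ap.add_argument("--seed", type=int, default=0)
    a = ap.parse_args()
    main(a.full, a.replicates, a.seed)
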