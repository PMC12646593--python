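#!/usr/bin/env python
"""Partitioning ratios and in vitro availability of the nominee pool.

Computes ionization-corrected distribution ratios at pH 7.4 for every
nominee in scratch/pool.csv, then the freely dissolved fraction f_free in
the default 10% FBS bioassay medium. Writes:

* results/availability_sweep.csv -- f_free for neutral reference chemicals
  on a half-log D_lip/w grid (the availability curve);
* results/availability_quantiles.csv -- f_free quantiles of the pool split
  by hydrophobicity class.

Expected pattern: chemicals below log D_lip/w ~3 are essentially fully
dissolved; above ~5 they are almost completely bound to medium components.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from toxtriage.invitro import BioassaySetup, d_cell_w, d_medium_w, f_free
from toxtriage.io import read_chemical_table
from toxtriage.partitioning import PartitionConfig, partition_record
from toxtriage.registry import IonizationProfile
from toxtriage.speciation import species_fractions
from toxtriage.partitioning import dbsaw_at_ph, dlipw_at_ph, dspw_at_ph

ROOT = Path(__file__).resolve().parents[1]


def pool_f_free(records, setup, cfg):
    rows = []
    for rec in records:
        pset = partition_record(rec.log_kow, rec.ionization, rec.log_kaw, config=cfg)
        ff = f_free(
            d_medium_w(pset.log_dbsaw, pset.log_dlipw, setup),
            d_cell_w(pset.log_dspw, pset.log_dlipw, setup),
            setup,
        )
        rows.append({"id": rec.identifier, "log_dlipw": pset.log_dlipw, "f_free": ff})
    return pd.DataFrame(rows)


def neutral_sweep(grid, setup, cfg):
    fr = species_fractions(IonizationProfile(), 7.4)
    rows = []
    for target in grid:
        log_kow = (target - cfg.lipw_model.intercept) / cfg.lipw_model.slope
        dl = dlipw_at_ph(cfg.lipw_model(log_kow), fr, cfg.ion_offset)
        ff = f_free(
            d_medium_w(dbsaw_at_ph(log_kow, fr, cfg), dl, setup),
            d_cell_w(dspw_at_ph(log_kow, fr, cfg), dl, setup),
            setup,
        )
        rows.append({"log_dlipw": dl, "f_free": ff})
    return pd.DataFrame(rows)


def main():
    cfg, setup = PartitionConfig(), BioassaySetup()
    records = read_chemical_table(ROOT / "scratch" / "pool.csv")

    sweep = neutral_sweep(np.arange(-1.0, 8.01, 0.5), setup, cfg)
    sweep.to_csv(ROOT / "results" / "availability_sweep.csv", index=False)

    df = pool_f_free(records, setup, cfg)
    df["class"] = pd.cut(
        df.log_dlipw, [-1.01, 3, 5, 9], labels=["<3", "3-5", ">5"]
    )
    q = df.groupby("class", observed=True)["f_free"].describe()[
        ["count", "mean", "min", "max"]
    ]
    q.to_csv(ROOT / "results" / "availability_quantiles.csv")

    print(f"partitioned {len(records)} nominees at pH 7.4")
    print("f_free by hydrophobicity class (log D_lip/w):")
    print(q.to_string())
    print("wrote results/availability_sweep.csv and availability_quantiles.csv")


if __name__ == "__main__":
    main()
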