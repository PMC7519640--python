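"""Calibrate the attribution threshold by theoretical mixing.

Cells are resampled without replacement from the single-phenotype pools so
the true composition is known exactly; sweeping the attribution threshold
and comparing recovered tumor counts with truth selects the working
threshold.  Pool cells are attributed with their out-of-bag votes.  Writes
the per-threshold recovery table under results/.
"""

from pathlib import Path

import numpy as np

import serrscell as sc
from serrscell.config import ForestSection, PoolsConfig, RunConfig

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 23


def main() -> None:
    OUT.mkdir(exist_ok=True)
    # larger pools and forest stabilize the out-of-bag vote fractions that
    # the threshold sweep is computed from
    cfg = RunConfig(
        seed=SEED,
        forest=ForestSection(n_trees=1000),
        pools=PoolsConfig(n_lncap=500, n_u251=500, n_pbmc=5000),
    )
    res = sc.run_pipeline(cfg)
    cal = res.calibration
    cal.table.to_csv(OUT / "threshold_calibration.csv", index=False)

    print("Recovered tumor counts vs truth, summed over 5 theoretical mixes:")
    print(cal.table.to_string(index=False))
    print(f"\nChosen attribution threshold: {cal.tau_attr_pct:.0f}% "
          f"(matched within tolerance: {cal.matched_within_tolerance})")
    print("Counts are monotonically non-increasing in the threshold; the")
    print("chosen value balances PBMC false positives against U251 losses.")


if __name__ == "__main__":
    main()
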