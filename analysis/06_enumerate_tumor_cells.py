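"""Enumerate tumor cells in two spiked mixes with efficiency correction.

Runs the full pipeline (simulate -> render -> detect -> score -> gate ->
attribute -> enumerate) on two independent spiked samples ("Mix 1" and
"Mix 2", both 24 LNCaP/ml and 29 U251/ml nominal) at the 60% attribution
threshold, and compares identified counts with the expected fixed counts
and the efficiency-corrected estimates with the spiked truth.  Writes the
per-cell tables and enumeration reports under results/.
"""

import json
from pathlib import Path

import serrscell as sc
from serrscell.config import CalibrationConfig, ForestSection, RunConfig

OUT = Path(__file__).resolve().parents[1] / "results"
SEEDS = {"mix1": 24, "mix2": 25}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for name, seed in SEEDS.items():
        cfg = RunConfig(
            seed=seed,
            forest=ForestSection(n_trees=500),
            calibration=CalibrationConfig(tau_attr_pct=60.0),
        )
        res = sc.run_pipeline(cfg, outdir=OUT / name)
        r = res.report
        rows.append((name, r))
        with open(OUT / f"enumeration_{name}.json", "w") as fh:
            json.dump(r, fh, indent=2, sort_keys=True)

    print(f"{'':12s}{'mix1':>10s}{'mix2':>10s}")
    fmt = "{:12s}{:>10s}{:>10s}"
    get = lambda key, cls: [f"{r[key][cls]:.1f}" if isinstance(r[key][cls], float)
                            else str(r[key][cls]) for _, r in rows]
    print(fmt.format("Spiked LNCaP", "24", "24"))
    print(fmt.format("Spiked U251", "29", "29"))
    print(fmt.format("Fixed LNCaP", *get("expected_fixed_per_ml", "LNCaP")))
    print(fmt.format("Fixed U251", *get("expected_fixed_per_ml", "U251")))
    print(fmt.format("Ident. LNCaP", *get("identified_per_ml", "LNCaP")))
    print(fmt.format("Ident. U251", *get("identified_per_ml", "U251")))
    print(fmt.format("Corr. LNCaP", *get("corrected_per_ml", "LNCaP")))
    print(fmt.format("Corr. U251", *get("corrected_per_ml", "U251")))
    print("\nIdentified counts use the 60% attribution threshold; corrected")
    print("estimates divide by the 84% capture-and-fixing efficiency.")


if __name__ == "__main__":
    main()
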