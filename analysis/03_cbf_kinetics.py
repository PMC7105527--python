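"""Voxelwise K1/CBF estimation on the phantom by the weighted-integral method.

Fits every brain voxel of the 3-min dynamic data against the corrected
plasma input, converts K1 to CBF with E = 0.65, and tabulates regional
recovery against the generating values.
"""

import argparse

import pandas as pd

from pibflow.pipeline import StudyConfig, StudyRunner


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/study")
    args = ap.parse_args()

    runner = StudyRunner(StudyConfig(out_dir=args.out, seed=args.seed))
    runner.stage_cbf()

    table = pd.read_csv(runner.out / "cbf_regional.csv")
    table = table[table["region"] != "artery"]
    print(table[["region", "hemisphere", "true_cbf", "value", "rel_err_pct"]]
          .rename(columns={"value": "estimated_cbf"})
          .to_string(index=False, float_format=lambda v: f"{v:7.2f}"))
    worst = table["rel_err_pct"].abs().max()
    print(f"\nworst regional CBF error on the noisy phantom: {worst:.2f}%")


if __name__ == "__main__":
    main()
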