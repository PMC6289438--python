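#!/usr/bin/env python
"""MRI SNR comparison and correlation with gait acceleration.

Simulates T2-weighted ROI tables for the seven crus muscles of every dog
at the end of the study, computes pixel-weighted bilateral Ave SNRs,
compares dystrophic vs wild-type dogs per muscle (exact Mann-Whitney U,
5 vs 6), and correlates dystrophic Ave SNRs with each dog's end-of-study
acceleration magnitude per region (Pearson).  The generator plants the
fast-muscle pattern: TC and EDL (and GM, the slow-muscle exception)
negative, GL and FDS positive.
"""

import argparse
from pathlib import Path

from dogait.config import study_defaults
from dogait.pipeline import mri_stage, process_trials, simulate_trials


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    cfg = study_defaults()
    cfg.seed = args.seed
    _, sessions, _ = process_trials(simulate_trials(cfg))
    tables = mri_stage(cfg, sessions)

    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    tables["snr_comparison"].to_csv(out / "mri_snr_comparison.csv", index=False)
    tables["am_snr_correlation"].to_csv(out / "am_snr_correlation.csv",
                                        index=False)

    comp = tables["snr_comparison"]
    print("Ave SNR, dystrophic vs wild-type (exact Mann-Whitney U, 5 vs 6):")
    print(comp.round(4).to_string(index=False))
    print(f"\n{int(comp['significant'].sum())}/{len(comp)} muscles "
          "significantly brighter in dystrophic dogs at the 5% level")

    corr = tables["am_snr_correlation"]
    print("\nPearson r between Ave SNR and AM (dystrophic dogs):")
    print(corr.round(4).to_string(index=False))
    fast = corr[corr["muscle"].isin(["TC", "EDL"])]
    print(f"\nfast-muscle cells with negative r: "
          f"{int((fast['r'] < 0).sum())}/{len(fast)}")
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
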