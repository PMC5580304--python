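#!/usr/bin/env python
"""Parameter-recovery study on simulated 15-expert panels.

Simulates panels in the study's shape (15 experts, 7 criteria, 2
alternatives) from known latent criterion weights and latent mean
ratings, runs both pipelines end to end, and reports (i) one full panel
in detail — per-expert consistency ratios, combined-matrix CR, recovered
weights, MAUT ranking — and (ii) how the median L1 error between
recovered and latent weights moves with the judgment noise sigma_P.
Seeds are paired across noise levels so the comparison is a
common-random-numbers design.

The sweep shows the generator's dithering effect: at sigma_P = 0 every
expert produces the identical snapped matrix, so the snap-to-scale bias
persists in the aggregate, while small noise averages it away.

Writes results/recovery_sweep.csv and results/panel_example.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mcda_hh import PanelSpec
from mcda_hh.synthetic import recovery_experiment

OUT = Path(__file__).resolve().parent.parent / "results"
REPS = 20
SIGMAS = [0.0, 0.1, 0.25, 0.5]


def main() -> None:
    example = recovery_experiment(PanelSpec(seed=42))
    crs = [r["CR"] for r in example["per_expert_consistency"]]
    print("Example panel (seed 42, sigma_P = 0.25):")
    print(f"  per-expert CR: min {min(crs):.3f}, median {np.median(crs):.3f}, "
          f"max {max(crs):.3f}; "
          f"{sum(c >= 0.10 for c in crs)}/15 above the 0.10 threshold")
    print(f"  combined-matrix CR: {example['combined_consistency']['CR']:.3f}")
    print(f"  weight L1 error (recovered vs latent): "
          f"{example['weight_l1_error']:.3f}")
    print(f"  MAUT ranking: {example['maut']['ranking']}"
          f" (latent best: {example['latent_best']})")

    rows = []
    for sigma in SIGMAS:
        errors = [
            recovery_experiment(PanelSpec(seed=11 + rep, sigma_pairwise=sigma))
            ["weight_l1_error"]
            for rep in range(REPS)
        ]
        rows.append({"sigma_pairwise": sigma,
                     "median_l1": float(np.median(errors)),
                     "q25": float(np.quantile(errors, 0.25)),
                     "q75": float(np.quantile(errors, 0.75))})
    sweep = pd.DataFrame(rows)
    print(f"\nRecovery sweep ({REPS} panels per level, paired seeds):")
    print(sweep.round(4).to_string(index=False))
    print("note the non-zero floor at sigma_P = 0: that is pure snap bias")

    OUT.mkdir(exist_ok=True)
    sweep.to_csv(OUT / "recovery_sweep.csv", index=False)
    (OUT / "panel_example.json").write_text(
        json.dumps(example, indent=2) + "\n", encoding="utf-8"
    )
    print(f"\ntables -> {OUT / 'recovery_sweep.csv'}")


if __name__ == "__main__":
    main()
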