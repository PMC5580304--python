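#!/usr/bin/env python
"""AHP analysis of the published combined pairwise-comparison matrix.

Derives criterion priorities from the published 7x7 geometric-mean matrix
by both the principal-eigenvector and row-geometric-mean methods, scores
its consistency, and prints the published study weights alongside.

The recomputation documents a discrepancy: the matrix as printed ranks
"dry and cracked skin" highest and has CR well above the 0.10 threshold,
whereas the study reports "efficiency" (0.35) on top and CR = 0.01. The
printed matrix and the reported summary cannot both be right; this
script shows exactly what the printed matrix implies.

Writes results/combined_matrix_ahp.csv and .json.
"""

import json
from pathlib import Path

import pandas as pd

from mcda_hh import consistency, principal_priorities, row_geometric_mean_priorities
from mcda_hh.reports import (
    TABLE6_DISCREPANCY_NOTE,
    load_combined_pairwise,
    load_participant_crs,
    load_reported_values,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    M = load_combined_pairwise()
    p_eig, lam = principal_priorities(M)
    p_gm = row_geometric_mean_priorities(M)
    rep = consistency(M, lam)
    reported = load_reported_values()["ahp_criterion_weights_reported"]

    table = pd.DataFrame(
        {
            "eigenvector": p_eig,
            "row_geometric_mean": p_gm,
            "reported_weight": [reported.get(c) for c in M.labels],
        },
        index=pd.Index(M.labels, name="criterion"),
    ).sort_values("eigenvector", ascending=False)

    print("Criterion priorities from the published combined matrix:")
    print(table.round(3).to_string())
    print(f"\nlambda_max = {rep.lambda_max:.3f}, CI = {rep.ci:.3f}, "
          f"RI = {rep.ri:.2f}, CR = {rep.cr:.3f} "
          f"({'acceptable' if rep.acceptable else 'NOT acceptable'} at 0.10)")
    print(f"Study-reported combined CR: "
          f"{load_reported_values()['ahp_combined_cr_reported']}")
    print("\n" + TABLE6_DISCREPANCY_NOTE)
    print("\nPublished per-participant CRs (raw matrices unpublished):")
    print(load_participant_crs().to_string())

    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "combined_matrix_ahp.csv")
    (OUT / "combined_matrix_ahp.json").write_text(
        json.dumps({"priorities_eigenvector": dict(zip(M.labels, p_eig.tolist())),
                    "priorities_rowgm": dict(zip(M.labels, p_gm.tolist())),
                    "consistency": rep.to_dict(),
                    "discrepancy_note": TABLE6_DISCREPANCY_NOTE},
                   indent=2) + "\n",
        encoding="utf-8",
    )
    print(f"\ntables -> {OUT / 'combined_matrix_ahp.csv'}")


if __name__ == "__main__":
    main()
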