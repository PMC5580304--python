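# mcda-hh

Multi-criteria decision analysis for expert panels, built around a
concrete question from hospital infection control: which hand-hygiene
method — washing with antimicrobial soap and water, or rubbing with an
alcohol-based antiseptic solution (ABAS) — do infectious-disease and
clinical microbiology specialists consider best, judged against seven
criteria (short application time, glove usage, dry and cracked skin,
staff workload, ease of use, intervention type, efficiency)?

The package implements the two standard MCDA procedures for this kind of
panel study, end to end:

* **Entropy-weighted MAUT** — Likert ratings are averaged into a
  decision matrix `X`; criterion weights come from the Shannon entropy
  of the column-normalized shares, `w_j ∝ 1 − e_j` with
  `e_j = −(1/ln m) Σ_i r_ij ln r_ij`; utilities are min–max rescaled per
  criterion and alternatives ranked by `U_i = Σ_j w_j u_ij`.
* **Group AHP** — positive reciprocal pairwise matrices on the Saaty 1–9
  scale; priorities from the principal eigenvector (power iteration,
  with the row geometric mean as an independent cross-check);
  consistency scored by `CR = CI/RI`, `CI = (λ_max − n)/(n − 1)`,
  acceptable below 0.10; expert panels combined by the entry-wise
  geometric mean; hierarchical (distributive) synthesis of global
  priorities.
* **Cronbach's alpha** for questionnaire reliability, and a **seeded
  panel simulator** that generates Likert ratings and near-consistent
  reciprocal judgment matrices from latent ground truth, so every stage
  is testable without access to the unpublished raw responses.

See `docs/methods.md` for the model details and design choices.

## Worked example

The study's published worked example, replayed from the bundled
fixtures (`python analysis/01_reproduce_worked_example.py`):

```
Total utilities (published weights, binary utilities):
  abas  0.86
  soap  0.14
Best alternative: abas
Dry-and-cracked-skin entropy: computed 0.9928 -> 0.99 (printed 0.99)
Judgments for 7 criteria: 21; RI(7) = 1.32
```

With the published entropy weights (0.22, 0.05, 0.09, 0.22, 0.35, 0.04,
0.03 over the seven criteria) and the 1/0 utility rule — the alternative
with the higher normalized score on a criterion gets that criterion's
full weight — soap wins only glove usage (0.05) and dry skin (0.09),
totalling 0.14, while ABAS collects the other five criteria, totalling
0.86. ABAS is the panel's best alternative, and the two totals sum to 1
as they must for two alternatives without ties.

The same library surface is scriptable from Python:

```python
import pandas as pd
from mcda_hh import DecisionMatrix, maut_report

D = DecisionMatrix(pd.DataFrame(
    [[3.66, 4.27], [4.23, 3.90]],
    index=["soap", "abas"], columns=["short_time", "glove_usage"]))
report = maut_report(D)
print(report["ranking"], report["total_utility"])
```

## Analysis drivers

Numbered scripts under `analysis/` re-run the study's analyses and write
their tables to `results/`:

1. `01_reproduce_worked_example.py` — the MAUT worked example and the
   structural AHP numbers, from fixtures.
2. `02_combined_matrix_ahp.py` — priorities and consistency of the
   published combined 7×7 pairwise matrix, including the documented
   discrepancy between the printed matrix and the study's reported
   weights and CR.
3. `03_panel_simulation.py` — parameter recovery on simulated 15-expert
   panels across judgment-noise levels.

## Command line

```bash
mcda maut --input decision_matrix.csv            # entropy-MAUT ranking
mcda ahp --matrices panel_dir/ --method eigenvector
mcda simulate --seed 42 --outdir panel/          # synthetic 15-expert panel
mcda reproduce                                   # fixture-based study replay
```

JSON reports (full precision) go to stdout or `--output`; human-readable
summaries, rounded to 2 decimals, go to stderr. Exit codes distinguish
validation errors (2) from I/O errors (3).

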