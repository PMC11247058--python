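#!/usr/bin/env python
"""Score generative-coefficient recovery over 200 replicate cohorts.

Each replicate regenerates the full 87-clot cohort with fresh noise and
refits each outcome's generative model (OLS point estimates; HC3 intervals
for the mechanical outcomes, whose generative noise is multiplicative).
Reports per-coefficient bias and 95% CI coverage, and writes
results/recovery_study.csv.
"""

from pathlib import Path

from clotlab import synthetic as syn

SEED = 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rec = syn.recovery_study(n_replicates=200, seed=SEED)
    rec.to_csv(OUT / "recovery_study.csv", index=False, float_format="%.10g")

    print("coefficient recovery over 200 replicate cohorts (n=87):")
    for row in rec.itertuples():
        print(
            f"  {row.outcome:16s} {row.predictor:17s} true={row.beta_true:8.3f} "
            f"mean={row.beta_mean:8.3f} rel.bias={100 * row.rel_bias:6.2f}% "
            f"coverage={row.coverage:.3f}"
        )
    print(
        f"coverage spans {rec.coverage.min():.3f}-{rec.coverage.max():.3f}; "
        f"max |rel bias| {100 * rec[rec.beta_true.abs() > 0.01].rel_bias.abs().max():.2f}% "
        f"(coefficients above Monte-Carlo resolution)"
    )
    print(f"wrote {OUT / 'recovery_study.csv'}")


if __name__ == "__main__":
    main()
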