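#!/usr/bin/env python
"""Synthesise cyclic compression traces per clot and extract the four features.

Each clot's generative mechanical observables (low/high-strain secant
stiffness, hysteresis loss, plastic strain) are turned into a 10-cycle
stress-strain record with closed-form characteristics; the extraction then
recovers them from the sampled record alone (secant-window OLS, trapezoidal
hysteresis areas, baseline-crossing plastic strain). Writes
results/mech_features.csv.
"""

from pathlib import Path

import numpy as np

from clotlab import synthetic as syn
from clotlab.pipeline import RunConfig, mech_stage

SEED = 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    clots = syn.generate_cohort(seed=SEED)
    config = RunConfig(out_dir=str(OUT), seed=SEED, sections_per_clot=2)
    feats = mech_stage(clots, config)
    feats.to_csv(OUT / "mech_features.csv", index=False, float_format="%.10g")

    cohort = syn.cohort_table(clots)
    merged = feats.merge(cohort[["clot_id", "hysteresis_loss", "plastic_strain"]],
                         on="clot_id", suffixes=("_extracted", "_observable"))
    ok = ~feats.features_adjusted
    err = np.abs(
        merged.loc[ok, "hysteresis_loss_extracted"] - merged.loc[ok, "hysteresis_loss_observable"]
    )
    print(f"extracted features for {len(feats)} clots x {config.sections_per_clot} sections")
    print(f"{int((~ok).sum())} clots projected to the feasible curve family "
          f"(negative or contradictory linear-model targets)")
    print(f"unadjusted clots: hysteresis recovered to {err.max():.4f}% (worst absolute)")
    print(f"stiffness range: low {feats.low_stiffness.min():.2f}-{feats.low_stiffness.max():.2f} kPa, "
          f"high {feats.high_stiffness.min():.1f}-{feats.high_stiffness.max():.1f} kPa")
    print(f"wrote {OUT / 'mech_features.csv'}")


if __name__ == "__main__":
    main()
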