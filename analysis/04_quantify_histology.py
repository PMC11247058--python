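#!/usr/bin/env python
"""Generate MSB-like and CD42b-like label masks per clot and quantify them.

Contents are measured as component area over clot cross-sectional area, and
the normalized composition expresses RBC and platelet areas against the
combined MSB clot + CD42b platelet area. Writes results/composition.csv.
"""

from pathlib import Path

import numpy as np

from clotlab import synthetic as syn
from clotlab.pipeline import RunConfig, histo_stage

SEED = 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    clots = syn.generate_cohort(seed=SEED)
    config = RunConfig(out_dir=str(OUT), seed=SEED)
    comp = histo_stage(clots, config, OUT)
    comp.to_csv(OUT / "composition.csv", index=False, float_format="%.10g")

    cohort = syn.cohort_table(clots)
    err = np.abs(comp.rbc_content.to_numpy() - cohort.rbc_content.to_numpy())
    print(f"quantified {len(comp)} clots")
    print(f"mask quantification reproduces generated contents to {err.max():.4f}% "
          f"(pixel quantisation at 0.01%)")
    norm_sum = comp.normalized_rbc + comp.normalized_platelet + comp.normalized_other
    print(f"normalized composition sums to 100 within {np.abs(norm_sum - 100).max():.2e}")
    print(f"wrote {OUT / 'composition.csv'}")


if __name__ == "__main__":
    main()
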