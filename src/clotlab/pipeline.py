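"""End-to-end orchestration: generate -> extract -> quantify -> regress.

``run_all`` mirrors the experimental workflow on a synthetic cohort: blend
recipes, contract, image (phantoms + ROI densitometry), compress (trace
synthesis + feature extraction), stain (label masks + area quantification)
and finally regress the measured quantities, emitting per-outcome
regression tables, scatter-data files and a truth-versus-estimate recovery
table. Every stage is seeded from the single run seed and all outputs are
plain CSV/JSON, so a fixed configuration reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import histo, synthetic
from .ctimg import measure_scan_pair
from .mech import extract_features
from .stats import regression_tables
from .synthetic import (
    DEFAULT_TRUTH,
    CTPhantomParams,
    GenerativeTruth,
    SyntheticClot,
    generate_cohort,
    cohort_table,
)

__all__ = ["RunConfig", "run_all", "mech_stage", "ct_stage", "histo_stage"]

FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of one pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    truth: GenerativeTruth = DEFAULT_TRUTH
    n_donors: int = 6
    sections_per_clot: int = 2
    d_eps_pct: float = 0.1
    n_cycles: int = 10
    mask_style: str = "exact"
    phantom_noise_sigma: Optional[float] = None  # None -> follow truth.hu_sigma
    exclude_flagged: bool = False
    flagged_clot_ids: Tuple[str, ...] = ()
    write_images: bool = False

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def mech_stage(
    clots: Sequence[SyntheticClot], config: RunConfig
) -> pd.DataFrame:
    rows = []
    for clot in clots:
        targets = {k: clot.observed[k] for k in config.truth.mech_models}
        feasible, adjusted = synthetic.project_feasible_features(targets)
        section_feats = []
        for _ in range(config.sections_per_clot):
            trace, geometry, _ = synthetic.generate_mech_trace(
                feasible,
                clot.diameter,
                d_eps_pct=config.d_eps_pct,
                n_cycles=config.n_cycles,
                softening=clot.softening,
            )
            section_feats.append(extract_features(trace, geometry, expected_cycles=config.n_cycles))
        rows.append(
            {
                "clot_id": clot.clot_id,
                "low_stiffness": float(np.mean([f.low_strain_stiffness for f in section_feats])),
                "high_stiffness": float(np.mean([f.high_strain_stiffness for f in section_feats])),
                "hysteresis_loss": float(np.mean([f.hysteresis_loss for f in section_feats])),
                "plastic_strain": float(np.mean([f.plastic_strain for f in section_feats])),
                "peak_stress_cycle1": section_feats[0].peak_stress_per_cycle[0],
                "peak_stress_cycle10": section_feats[0].peak_stress_per_cycle[-1],
                "n_sections": config.sections_per_clot,
                "features_adjusted": adjusted,
            }
        )
    return pd.DataFrame(rows)


def ct_stage(
    clots: Sequence[SyntheticClot], config: RunConfig, out_dir: Path
) -> pd.DataFrame:
    sigma = config.phantom_noise_sigma
    if sigma is None:
        sigma = config.truth.hu_sigma
    params = CTPhantomParams(noise_sigma=sigma)
    seeds = np.random.SeedSequence([config.seed, 2]).generate_state(len(clots)) % (2**31)
    rows = []
    for clot, s in zip(clots, seeds):
        ncct_img, cect_img = synthetic.generate_ct_phantom(clot, params, seed=int(s))
        res = measure_scan_pair(ncct_img, cect_img, sample_diameter=clot.diameter)
        if config.write_images:
            import nibabel as nib

            img_dir = out_dir / "phantoms"
            img_dir.mkdir(exist_ok=True)
            for tag, img in (("ncct", ncct_img), ("cect", cect_img)):
                affine = np.diag([*img.voxel_size[::-1], 1.0])
                nib.save(
                    nib.Nifti1Image(np.transpose(img.hu, (2, 1, 0)).astype(np.float32), affine),
                    str(img_dir / f"{clot.clot_id}_{tag}.nii.gz"),
                )
        rows.append(
            {
                "clot_id": clot.clot_id,
                "ncct_density": res.ncct_density,
                "cect_density": res.cect_density,
                "cect_increase": res.cect_increase,
                "roi_mean_1": res.roi_means[0],
                "roi_mean_2": res.roi_means[1],
                "roi_mean_3": res.roi_means[2],
            }
        )
    return pd.DataFrame(rows)


def histo_stage(
    clots: Sequence[SyntheticClot], config: RunConfig, out_dir: Path
) -> pd.DataFrame:
    seeds = np.random.SeedSequence([config.seed, 3]).generate_state(len(clots)) % (2**31)
    rows = []
    for clot, s in zip(clots, seeds):
        msb, cd42b = synthetic.generate_label_mask(
            clot.rbc_content,
            clot.platelet_content,
            style=config.mask_style,  # type: ignore[arg-type]
            seed=int(s),
        )
        if config.write_images:
            mask_dir = out_dir / "masks"
            mask_dir.mkdir(exist_ok=True)
            histo.save_label_mask(msb, mask_dir / f"{clot.clot_id}_msb.tif")
            histo.save_label_mask(cd42b, mask_dir / f"{clot.clot_id}_cd42b.tif")
        comp = histo.quantify_pair(msb, cd42b)
        rows.append(
            {
                "clot_id": clot.clot_id,
                "rbc_content": comp.rbc_content,
                "platelet_content": comp.platelet_content,
                "normalized_rbc": comp.normalized_rbc,
                "normalized_platelet": comp.normalized_platelet,
                "normalized_other": comp.normalized_other,
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> Dict[str, pd.DataFrame]:
    """Run every stage; write CSV/JSON outputs under ``config.out_dir``.

    Returns the bundle of stage tables. Raises on the first stage error,
    naming the stage (and clot) context.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run_log.jsonl"
    log_entries = []

    def log(stage: str, **info) -> None:
        log_entries.append({"stage": stage, **info})

    t0 = time.time()
    log("config", seed=config.seed, config_hash=_config_hash(config), config=config.to_jsonable())

    stage = "simulate"
    try:
        clots = generate_cohort(config.truth, n_donors=config.n_donors, seed=config.seed)
        cohort = cohort_table(clots)
        _write_csv(cohort, out_dir / "cohort.csv")
        log(stage, n_clots=len(clots))

        stage = "mech"
        mech_df = mech_stage(clots, config)
        _write_csv(mech_df, out_dir / "mech_features.csv")
        log(stage, n_rows=len(mech_df), n_adjusted=int(mech_df["features_adjusted"].sum()))

        stage = "ctimg"
        ct_df = ct_stage(clots, config, out_dir)
        _write_csv(ct_df, out_dir / "ct_density.csv")
        log(stage, n_rows=len(ct_df))

        stage = "histo"
        histo_df = histo_stage(clots, config, out_dir)
        _write_csv(histo_df, out_dir / "composition.csv")
        log(stage, n_rows=len(histo_df))

        stage = "regress"
        analysis = (
            histo_df[["clot_id", "rbc_content", "platelet_content"]]
            .merge(cohort[["clot_id", "diameter"]], on="clot_id")
            .merge(ct_df[["clot_id", "ncct_density", "cect_increase"]], on="clot_id")
            .merge(
                mech_df[
                    ["clot_id", "low_stiffness", "high_stiffness", "hysteresis_loss", "plastic_strain"]
                ],
                on="clot_id",
            )
        )
        if config.exclude_flagged and config.flagged_clot_ids:
            analysis = analysis[~analysis["clot_id"].isin(config.flagged_clot_ids)]
        _write_csv(analysis, out_dir / "analysis_table.csv")
        regression = regression_tables(analysis)
        _write_csv(regression, out_dir / "regression.csv")
        (out_dir / "regression.json").write_text(
            json.dumps(regression.to_dict(orient="records"), indent=1) + "\n"
        )
        for outcome in ("ncct_density", "cect_increase", "low_stiffness",
                        "high_stiffness", "hysteresis_loss", "plastic_strain"):
            _write_csv(
                analysis[["clot_id", "rbc_content", "platelet_content", outcome]],
                out_dir / f"scatter_{outcome}.csv",
            )
        log(stage, n_rows=len(regression))

        stage = "recover"
        recovery = _single_cohort_recovery(config.truth, regression)
        _write_csv(recovery, out_dir / "recovery.csv")
        log(stage, n_rows=len(recovery))
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    log("done", elapsed_s=round(time.time() - t0, 3))
    with open(log_path, "w") as fh:
        for entry in log_entries:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")

    return {
        "cohort": cohort,
        "mech": mech_df,
        "ct": ct_df,
        "histo": histo_df,
        "analysis": analysis,
        "regression": regression,
        "recovery": recovery,
    }


def _single_cohort_recovery(truth: GenerativeTruth, regression: pd.DataFrame) -> pd.DataFrame:
    """Compare this cohort's multiple-regression estimates with the truth."""
    rows = []
    for outcome, (preds, coef_names) in synthetic.RECOVERY_MODELS.items():
        model = synthetic._truth_model(truth, outcome)
        kind = "multiple_size" if outcome == "cect_increase" else "multiple"
        sub = regression[(regression.outcome == outcome) & (regression.model == kind)]
        for pred, coef_name in zip(preds, coef_names):
            row = sub[sub.predictor == pred]
            if row.empty:
                continue
            r = row.iloc[0]
            beta_true = getattr(model, coef_name)
            rows.append(
                {
                    "outcome": outcome,
                    "predictor": pred,
                    "beta_true": beta_true,
                    "beta_est": r.beta,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "covered": bool(r.ci_low <= beta_true <= r.ci_high),
                }
            )
    return pd.DataFrame(rows)
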