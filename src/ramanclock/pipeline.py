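"""End-to-end pipeline: spectra on disk -> R_PF -> calibrated age models.

The runner composes the stages in the order a study would: read donors and
replicate spectra, average replicates, subtract the fluorescence baseline,
crop to the protein spectral zone, deconvolve the Amide I band, compute
R_PF per donor, then correlate, fit the four candidate models, cross-
validate, select, and emit a prediction table.  All outputs are plain CSV
or JSON and byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import calibrate as cal
from .deconvolve import FitOptions, compute_rpf, fit_bands
from .io import (
    DonorRecord,
    Spectrum,
    read_donor_table,
    read_spectrum,
    write_donor_table,
    write_spectrum,
)
from .preprocess import PreprocessConfig, average_spectra, correct_baseline, crop, despike
from .profiles import BandLibrary, default_band_library
from .synthetic import CohortSpec, simulate_cohort

logger = logging.getLogger("ramanclock")

__all__ = ["PipelineConfig", "run_pipeline", "simulate_command", "process_donor_spectra"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (JSON/YAML-loadable)."""

    spectra_dir: str
    donors_path: str
    out_dir: str
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    library: BandLibrary = field(default_factory=default_band_library)
    fit_options: FitOptions = field(default_factory=FitOptions)
    rpf_mode: str = "height"
    models: tuple[int, ...] = (1, 2, 3, 4)
    cv_k: int = 10
    cv_repeats: int = 100
    seed: int = 0
    levels: tuple[float, ...] = (0.50, 0.80, 0.95)
    rpf_grid: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7)

    def __post_init__(self) -> None:
        if not all(0.0 < l < 1.0 for l in self.levels):
            raise ValueError("levels must lie in (0, 1)")
        if not self.models:
            raise ValueError("at least one model id required")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "fit_options" in d and isinstance(d["fit_options"], dict):
            d["fit_options"] = FitOptions(**d["fit_options"])
        for key in ("models", "levels", "rpf_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            text = fh.read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def digest(self) -> str:
        blob = json.dumps(
            {k: v for k, v in asdict(self).items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def process_donor_spectra(
    spectra,
    cfg: PreprocessConfig,
    library: BandLibrary,
    fit_options: FitOptions,
    rpf_mode: str = "height",
):
    """Average -> despike -> baseline-correct -> crop -> fit -> R_PF."""
    avg = average_spectra(spectra)
    if cfg.despike:
        avg = despike(avg, threshold=cfg.despike_threshold)
    corrected = correct_baseline(avg, cfg)
    cropped = crop(corrected, cfg.window)
    fit = fit_bands(cropped, library, fit_options)
    return fit, compute_rpf(fit, mode=rpf_mode)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts to ``out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    logger.info("pipeline start: config %s, seed %d", config.digest(), config.seed)
    donors = read_donor_table(config.donors_path)
    logger.info("read %d donors from %s", len(donors), config.donors_path)

    fits = {}
    for donor in donors:
        pattern = os.path.join(config.spectra_dir, f"{donor.donor_id}_*.csv")
        paths = sorted(glob.glob(pattern))
        if not paths:
            raise FileNotFoundError(
                f"stage read_spectra, donor {donor.donor_id}: no files match {pattern}"
            )
        spectra = [read_spectrum(p, {"donor_id": donor.donor_id}) for p in paths]
        try:
            fit, rpf = process_donor_spectra(
                spectra, config.preprocess, config.library,
                config.fit_options, config.rpf_mode,
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage deconvolve, donor {donor.donor_id}: {exc}"
            ) from exc
        donor.rpf = rpf.value
        fits[donor.donor_id] = {**fit.to_dict(), "rpf": rpf.value}
        logger.info("donor %s: R_PF=%.4f r2=%.5f", donor.donor_id, rpf.value, fit.fit_r2)

    rpf_df = pd.DataFrame(
        {
            "donor_id": [d.donor_id for d in donors],
            "rpf": [d.rpf for d in donors],
            "fit_r2": [fits[d.donor_id]["fit_r2"] for d in donors],
            "converged": [fits[d.donor_id]["converged"] for d in donors],
        }
    )
    rpf_df.to_csv(os.path.join(config.out_dir, "rpf.csv"), index=False)
    with open(os.path.join(config.out_dir, "fits.json"), "w") as fh:
        json.dump(fits, fh, indent=1, sort_keys=True)

    ages = np.array([d.age for d in donors])
    rpfs = np.array([d.rpf for d in donors])
    corr = cal.pearson(ages, rpfs, variables=("age", "rpf"))

    metrics = [
        cal.cross_validate(donors, m, k=config.cv_k, repeats=config.cv_repeats,
                           seed=config.seed)
        for m in config.models
    ]
    if len(metrics) > 1:
        selected = cal.select_model(metrics)
    else:
        selected = metrics[0].model_id
    model = cal.fit_model(donors, selected)
    logger.info("selected model %d (CV seed %d)", selected, config.seed)

    pd.DataFrame(
        [
            {"model_id": m.model_id, "rmse": m.rmse, "r2": m.r2,
             "k": m.k, "repeats": m.repeats, "seed": m.seed}
            for m in metrics
        ]
    ).to_csv(os.path.join(config.out_dir, "cv_metrics.csv"), index=False)

    with open(os.path.join(config.out_dir, "calibration.json"), "w") as fh:
        json.dump(
            {
                "model_id": model.model_id,
                "terms": list(model.terms),
                "coefficients": model.coefficients.tolist(),
                "residual_sd": model.residual_sd,
                "df": model.df,
                "n": model.n,
                "design_moments": model.design_moments.tolist(),
            },
            fh,
            indent=1,
        )

    if model.uses_sex:
        tables = []
        for sex_code, label in ((1, "M"), (0, "F")):
            t = cal.prediction_table(model, config.rpf_grid, config.levels, sex=sex_code)
            t.insert(1, "sex", label)
            tables.append(t)
        table = pd.concat(tables, ignore_index=True)
    else:
        table = cal.prediction_table(model, config.rpf_grid, config.levels)
    table.to_csv(os.path.join(config.out_dir, "prediction_table.csv"), index=False)

    summary = {
        "n_donors": len(donors),
        "age_mean": round(float(ages.mean()), 2),
        "age_sd": round(float(ages.std(ddof=1)), 2),
        "rpf_mean": round(float(rpfs.mean()), 3),
        "rpf_sd": round(float(rpfs.std(ddof=1)), 3),
        "pearson_r": round(corr.r, 4),
        "pearson_p": corr.p_value,
        "cv": [
            {"model_id": m.model_id, "rmse": round(m.rmse, 3), "r2": round(m.r2, 4)}
            for m in metrics
        ],
        "selected_model": selected,
        "config_digest": config.digest(),
        "seed": config.seed,
    }
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    logger.info("pipeline done: n=%d, r=%.3f, selected model %d",
                len(donors), corr.r, selected)
    return summary


def simulate_command(spec: CohortSpec, out_dir) -> list[str]:
    """Write a synthetic cohort to disk: donors.csv + one CSV per replicate."""
    os.makedirs(out_dir, exist_ok=True)
    donors, spectra = simulate_cohort(spec)
    write_donor_table(donors, os.path.join(out_dir, "donors.csv"))
    written = [os.path.join(out_dir, "donors.csv")]
    for donor in donors:
        for r, s in enumerate(spectra[donor.donor_id]):
            path = os.path.join(out_dir, f"{donor.donor_id}_{r:03d}.csv")
            write_spectrum(s, path)
            written.append(path)
    logger.info("simulated cohort: %d donors x %d replicates (seed %d) -> %s",
                spec.n_donors, spec.replicates_per_donor, spec.seed, out_dir)
    return written
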