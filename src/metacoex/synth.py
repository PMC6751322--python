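"""Synthetic cohort generator with planted co-expression structure.

The generator emulates the statistical design the downstream pipeline
assumes: a small treatment cohort measured at baseline and week 12 on a
targeted metabolomics panel run across several plates, with pooled-QC
aliquots on every plate, multiplicative batch effects, left-censoring at
the limit of detection, modules of co-changing metabolites, and a clinical
trait (change in HAM-D17 depression score) coupled to a subset of modules.

Change-score model
------------------
Each module ``m`` has a latent per-subject factor ``f_m ~ N(0, 1)``. A member
metabolite's log2 change is ``loading * f_m + noise_sd * eps``; background
metabolites are pure noise with matched marginal variance. The latent trait
is ``t = sum_m rho_m f_m + sqrt(1 - sum rho^2) eps`` so that
``corr(t, f_m) = rho_m`` exactly in expectation. Integer HAM-D trajectories
are simulated per outcome category and assigned to subjects by rank-matching
their week12-baseline change against ``t``, which preserves the planted
correlations up to a small monotone-coupling attenuation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from metacoex.types import (
    BASELINE,
    WEEK12,
    OUTCOME_CATEGORIES,
    ConfigError,
    DataError,
    PlateDataset,
)

# Table-1 cohort mix: 12 remitters, 3 responders, 4 partial responders,
# 7 treatment failures out of 26.
DEFAULT_OUTCOME_PROPORTIONS = (12 / 26, 3 / 26, 4 / 26, 7 / 26)

# Cohort HAM-D17 at baseline: mean 18.6, sd 3.1, eligibility floor 15.
_HAMD_BASELINE_MEAN = 18.6
_HAMD_BASELINE_SD = 3.1
_HAMD_MIN_BASELINE = 15
_HAMD_MAX = 52

_FEMALE_FRACTION = 0.615  # 16 of 26

# log2 abundance scale for reconstructed baseline levels
_BASELINE_LOG2_MEAN = 5.0
_BASELINE_LOG2_SPREAD = 1.5  # between-metabolite spread of typical abundance
_BASELINE_LOG2_SD = 0.5  # between-subject spread at a fixed metabolite


@dataclass(frozen=True)
class SynthConfig:
    """Free parameters of the synthetic cohort.

    Defaults mirror the study design: 26 subjects, ~180 metabolites on 3
    plates with 2 QC-pool aliquots each, eight planted modules with the
    reported sizes, three of them coupled to the trait at |rho| 0.31-0.36,
    and the Table-1 outcome mix.
    """

    n_subjects: int = 26
    n_metabolites: int = 180
    n_plates: int = 3
    qc_per_plate: int = 2
    module_sizes: tuple = (8, 15, 12, 96, 5, 6, 3, 9)
    module_trait_correlations: tuple = (0.0, 0.0, 0.0, 0.36, 0.0, -0.33, 0.0, -0.31)
    within_module_loading: float = 0.85
    noise_sd: float = 0.3
    measurement_noise_sd: float = 0.0
    batch_multipliers: tuple = (1.0, 1.15, 0.9)
    lod_quantile: float = 0.05
    outcome_proportions: tuple = DEFAULT_OUTCOME_PROPORTIONS
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0 or self.n_metabolites <= 0 or self.n_plates <= 0:
            raise ConfigError("counts must be positive")
        if self.qc_per_plate < 1:
            raise ConfigError("need at least one QC-pool aliquot per plate")
        if sum(self.module_sizes) > self.n_metabolites:
            raise ConfigError(
                f"module sizes sum to {sum(self.module_sizes)} > "
                f"n_metabolites={self.n_metabolites}"
            )
        if any(s < 1 for s in self.module_sizes):
            raise ConfigError("module sizes must be >= 1")
        if len(self.module_trait_correlations) != len(self.module_sizes):
            raise ConfigError("one trait correlation per module required")
        if any(abs(r) > 1 for r in self.module_trait_correlations):
            raise ConfigError("trait correlations must lie in [-1, 1]")
        if sum(r * r for r in self.module_trait_correlations) > 1 + 1e-9:
            raise ConfigError(
                "sum of squared trait correlations exceeds 1; the latent "
                "trait cannot realize them jointly"
            )
        if not 0 < self.within_module_loading <= 1:
            raise ConfigError("within_module_loading must lie in (0, 1]")
        if self.noise_sd < 0 or self.measurement_noise_sd < 0:
            raise ConfigError("noise sds must be nonnegative")
        if len(self.batch_multipliers) != self.n_plates:
            raise ConfigError("one batch multiplier per plate required")
        if any(m <= 0 for m in self.batch_multipliers):
            raise ConfigError("batch multipliers must be positive")
        if not 0 <= self.lod_quantile < 1:
            raise ConfigError("lod_quantile must lie in [0, 1)")
        if len(self.outcome_proportions) != 4:
            raise ConfigError("four outcome proportions required")
        if any(p < 0 for p in self.outcome_proportions):
            raise ConfigError("outcome proportions must be nonnegative")
        if abs(sum(self.outcome_proportions) - 1.0) > 1e-9:
            raise ConfigError("outcome proportions must sum to 1")


@dataclass
class GroundTruth:
    """Planted structure recorded alongside a generated cohort."""

    module_labels: pd.Series  # metabolite_id -> module index (0 = background)
    latent_trait: pd.Series  # subject_id -> latent trait value
    module_trait_correlations: tuple
    within_module_loading: float
    noise_sd: float

    def to_dict(self) -> dict:
        return {
            "module_labels": {k: int(v) for k, v in self.module_labels.items()},
            "latent_trait": {k: float(v) for k, v in self.latent_trait.items()},
            "module_trait_correlations": list(self.module_trait_correlations),
            "within_module_loading": self.within_module_loading,
            "noise_sd": self.noise_sd,
        }


def _apportion(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Largest-remainder apportionment of n into integer category counts."""
    raw = np.asarray(proportions, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _draw_baseline(rng: np.random.Generator) -> int:
    b = int(round(rng.normal(_HAMD_BASELINE_MEAN, _HAMD_BASELINE_SD)))
    return int(np.clip(b, _HAMD_MIN_BASELINE, 40))


def simulate_hamd_trajectories(
    n: int, proportions: Sequence[float], seed=None
) -> pd.DataFrame:
    """Simulate per-subject HAM-D17 (baseline, week10, week12) triples.

    Each triple satisfies its assigned category's defining rule by
    construction: remitters score <=7 at both week 10 and week 12;
    non-remitting responders reduce >=50% from baseline without meeting the
    remitter rule; partial responders reduce 30-49%; treatment failures
    reduce <30% (including worsening). Baselines respect the >=15
    eligibility floor.

    Returns a DataFrame with columns ``hamd_baseline, hamd_wk10, hamd_wk12,
    outcome`` in randomized row order.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ConfigError("proportions must sum to 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = _apportion(n, proportions)
    rows = []
    for category, count in zip(OUTCOME_CATEGORIES, counts):
        for _ in range(count):
            b = _draw_baseline(rng)
            if category == "remitter":
                wk10 = int(rng.integers(0, 8))
                wk12 = int(rng.integers(0, 8))
            elif category == "responder":
                wk12 = int(rng.integers(0, b // 2 + 1))
                wk10 = int(rng.integers(8, b + 1))  # blocks the remitter rule
            elif category == "partial_responder":
                lo, hi = b // 2 + 1, int(math.floor(0.7 * b))
                wk12 = int(rng.integers(lo, hi + 1))
                wk10 = int(rng.integers(wk12, b + 1))
            else:  # failure: <30% reduction, worsening allowed
                lo = int(math.floor(0.7 * b)) + 1
                hi = min(b + 6, _HAMD_MAX)
                wk12 = int(rng.integers(lo, hi + 1))
                wk10 = int(rng.integers(8, max(b, wk12) + 1))
            rows.append((b, wk10, wk12, category))
    df = pd.DataFrame(
        rows, columns=["hamd_baseline", "hamd_wk10", "hamd_wk12", "outcome"]
    )
    if len(df):
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    return df


def _sample_id(subject_id: str, timepoint: str) -> str:
    return f"{subject_id}_{timepoint}"


def apply_measurement_model(
    true_abundances: pd.DataFrame,
    config: SynthConfig,
    sample_plates: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> PlateDataset:
    """Push true abundances through the plate measurement process.

    ``true_abundances`` is a samples x metabolites table of positive values.
    Each plate's measurements are multiplied by its batch multiplier; every
    plate additionally carries ``qc_per_plate`` aliquots of one pooled
    composition (the mean of all subject samples) subject to log2-scale
    measurement noise ``measurement_noise_sd``. Per-metabolite LODs are set
    at the ``lod_quantile`` quantile of the measured subject values, and
    measurements strictly below the LOD are flagged and censored to NaN.
    """
    if (true_abundances.to_numpy() <= 0).any():
        raise DataError("true abundances must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    plates = [f"plate_{i + 1}" for i in range(config.n_plates)]
    mult = dict(zip(plates, config.batch_multipliers))
    if sample_plates is None:
        sample_plates = pd.Series(
            [plates[i % config.n_plates] for i in range(len(true_abundances))],
            index=true_abundances.index,
        )

    measured = true_abundances.mul(
        sample_plates.map(mult).astype(float), axis=0
    )
    pooled = true_abundances.mean(axis=0)

    qc_frames = []
    for plate in plates:
        for k in range(config.qc_per_plate):
            noise = np.exp2(
                rng.normal(0.0, config.measurement_noise_sd, len(pooled))
                if config.measurement_noise_sd > 0
                else np.zeros(len(pooled))
            )
            qc_frames.append(
                pd.Series(
                    pooled.to_numpy() * mult[plate] * noise,
                    index=pooled.index,
                    name=(f"qc_{plate}_{k + 1}", plate),
                )
            )

    # per-metabolite LOD from the pooled measured subject values
    if config.lod_quantile > 0:
        lod = measured.quantile(config.lod_quantile, axis=0)
    else:
        lod = pd.Series(0.0, index=measured.columns)

    n_samples, n_mets = measured.shape
    lod_arr = lod.to_numpy()

    subj_vals = measured.to_numpy().ravel()
    subj_below = subj_vals < np.tile(lod_arr, n_samples)
    qc_ids = [s.name[0] for s in qc_frames]
    qc_plates = [s.name[1] for s in qc_frames]
    qc_vals = np.concatenate([s.to_numpy() for s in qc_frames])
    qc_below = qc_vals < np.tile(lod_arr, len(qc_frames))

    measurements = pd.DataFrame(
        {
            "sample_id": np.concatenate(
                [
                    np.repeat(measured.index.to_numpy(), n_mets),
                    np.repeat(np.asarray(qc_ids, dtype=object), n_mets),
                ]
            ),
            "metabolite_id": np.tile(
                measured.columns.to_numpy(), n_samples + len(qc_frames)
            ),
            "plate_id": np.concatenate(
                [
                    np.repeat(
                        sample_plates.loc[measured.index].to_numpy(), n_mets
                    ),
                    np.repeat(np.asarray(qc_plates, dtype=object), n_mets),
                ]
            ),
            "value": np.where(
                np.concatenate([subj_below, qc_below]),
                np.nan,
                np.concatenate([subj_vals, qc_vals]),
            ),
            "below_lod": np.concatenate([subj_below, qc_below]),
            "is_qc_pool": np.repeat(
                [False, True], [n_samples * n_mets, len(qc_frames) * n_mets]
            ),
        }
    )

    lod_table = pd.DataFrame(
        [
            {"metabolite_id": met, "plate_id": plate, "lod_value": float(lod[met])}
            for met in measured.columns
            for plate in plates
        ]
    )
    sample_map = pd.DataFrame(
        {
            "sample_id": measured.index,
            "subject_id": [sid.rsplit("_", 1)[0] for sid in measured.index],
            "timepoint": [sid.rsplit("_", 1)[1] for sid in measured.index],
        }
    ).reset_index(drop=True)
    ds = PlateDataset(measurements, lod_table, sample_map)
    ds.validate()
    return ds


def generate_cohort(
    config: SynthConfig,
) -> tuple[PlateDataset, pd.DataFrame, GroundTruth]:
    """Generate one synthetic cohort.

    Returns the plate-level dataset, a metadata table (``subject_id, age,
    sex, hamd_baseline, hamd_wk10, hamd_wk12, outcome``), and the planted
    ground truth. Deterministic given ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_traj, rng_factors, rng_covar, rng_levels, rng_meas = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    n = config.n_subjects
    subjects = [f"subj_{i + 1:03d}" for i in range(n)]
    metabolites = [f"met_{j + 1:03d}" for j in range(config.n_metabolites)]

    traj = simulate_hamd_trajectories(n, config.outcome_proportions, rng_traj)

    # planted module labels: 1..M in declaration order, 0 = background
    labels = np.zeros(config.n_metabolites, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[pos : pos + size] = m
        pos += size

    n_modules = len(config.module_sizes)
    factors = rng_factors.standard_normal((n, n_modules))
    loading = config.within_module_loading
    noise = config.noise_sd
    changes = np.empty((n, config.n_metabolites))
    for j, lab in enumerate(labels):
        eps = rng_factors.standard_normal(n)
        if lab > 0:
            changes[:, j] = loading * factors[:, lab - 1] + noise * eps
        else:
            changes[:, j] = math.sqrt(loading**2 + noise**2) * eps

    rho = np.asarray(config.module_trait_correlations, dtype=float)
    resid = math.sqrt(max(0.0, 1.0 - float(rho @ rho)))
    latent = factors @ rho + resid * rng_factors.standard_normal(n)

    # couple integer HAM-D changes to the latent trait by rank matching
    dhamd = (traj["hamd_wk12"] - traj["hamd_baseline"]).to_numpy()
    subj_order = np.argsort(latent, kind="stable")
    traj_order = np.argsort(dhamd, kind="stable")
    assignment = np.empty(n, dtype=int)
    assignment[subj_order] = traj_order
    traj_matched = traj.iloc[assignment].reset_index(drop=True)

    metadata = pd.DataFrame(
        {
            "subject_id": subjects,
            "age": rng_covar.integers(18, 66, n),
            "sex": np.where(rng_covar.random(n) < _FEMALE_FRACTION, "female", "male"),
            "hamd_baseline": traj_matched["hamd_baseline"],
            "hamd_wk10": traj_matched["hamd_wk10"],
            "hamd_wk12": traj_matched["hamd_wk12"],
            "outcome": traj_matched["outcome"],
        }
    )

    # reconstruct two-timepoint log2 levels around metabolite-specific means
    mu = rng_levels.normal(_BASELINE_LOG2_MEAN, _BASELINE_LOG2_SPREAD, config.n_metabolites)
    base_log2 = mu + _BASELINE_LOG2_SD * rng_levels.standard_normal(
        (n, config.n_metabolites)
    )
    wk12_log2 = base_log2 + changes

    index = []
    level_rows = []
    for i, sid in enumerate(subjects):
        index.append(_sample_id(sid, BASELINE))
        level_rows.append(base_log2[i])
        index.append(_sample_id(sid, WEEK12))
        level_rows.append(wk12_log2[i])
    true_abundances = pd.DataFrame(
        np.exp2(np.array(level_rows)), index=index, columns=metabolites
    )

    dataset = apply_measurement_model(true_abundances, config, rng=rng_meas)
    truth = GroundTruth(
        module_labels=pd.Series(labels, index=metabolites, name="module"),
        latent_trait=pd.Series(latent, index=subjects, name="latent_trait"),
        module_trait_correlations=tuple(config.module_trait_correlations),
        within_module_loading=loading,
        noise_sd=noise,
    )
    return dataset, metadata, truth


def write_cohort(
    dataset: PlateDataset,
    metadata: pd.DataFrame,
    truth: GroundTruth,
    outdir: str | Path,
) -> dict:
    """Write the generated cohort to CSV/JSON files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": outdir / "measurements.csv",
        "lod": outdir / "lod.csv",
        "metadata": outdir / "metadata.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    dataset.measurements.to_csv(paths["measurements"], index=False, float_format="%.12g")
    dataset.lod.to_csv(paths["lod"], index=False, float_format="%.12g")
    metadata.to_csv(paths["metadata"], index=False)
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
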