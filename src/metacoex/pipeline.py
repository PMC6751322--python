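"""End-to-end orchestration: configuration, I/O, manifest, artifacts.

``run_pipeline`` executes the full workflow — simulate (or read) plate
measurements, preprocess to a change matrix, detect co-expression modules,
associate modules and metabolites with the HAM-D change trait — and writes
every stage artifact plus a machine-readable run manifest. All stage
parameters default to the analysis conventions (LOD cutoff 0.40, outlier
alpha 0.05, beta 18, deep split 2, minimum module size 3, merge threshold
0.75, |r| > 0.3 at p < 0.1 for module-trait calls).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import metacoex
from metacoex import associate, network, preprocess, synth
from metacoex.types import DataError, PlateDataset

_FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """All stage parameters and paths for one reproducible run."""

    out_dir: str = "metacoex_out"
    measurements_path: str | None = None
    lod_path: str | None = None
    metadata_path: str | None = None
    simulate: bool = True
    seed: int = 0
    n_subjects: int = 26
    lod_max_below_frac: float = preprocess.DEFAULT_LOD_MAX_BELOW_FRAC
    outlier_alpha: float = preprocess.DEFAULT_OUTLIER_ALPHA
    drop_outliers: bool = False
    beta: int | str = network.DEFAULT_BETA  # integer or "auto"
    deep_split: int = network.DEFAULT_DEEP_SPLIT
    min_size: int = network.DEFAULT_MIN_SIZE
    merge_threshold: float = network.DEFAULT_MERGE_THRESHOLD
    r_cut: float = associate.DEFAULT_R_CUT
    p_cut: float = associate.DEFAULT_P_CUT
    trajectory_alpha: float = associate.DEFAULT_TRAJECTORY_ALPHA
    write_heatmap_png: bool = True

    def validate(self) -> None:
        if not 0 <= self.lod_max_below_frac < 1:
            raise DataError("lod_max_below_frac must lie in [0, 1)")
        if not 0 < self.outlier_alpha < 1:
            raise DataError("outlier_alpha must lie in (0, 1)")
        if self.beta != "auto" and (int(self.beta) < 1):
            raise DataError("beta must be a positive integer or 'auto'")
        if self.deep_split not in (0, 1, 2, 3, 4):
            raise DataError("deep_split must be in 0..4")
        if self.min_size < 2:
            raise DataError("min_size must be >= 2")
        if not 0 < self.merge_threshold < 1:
            raise DataError("merge_threshold must lie in (0, 1)")
        for name in ("r_cut", "p_cut", "trajectory_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DataError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_inputs(
    measurements_path: str | Path,
    lod_path: str | Path,
    metadata_path: str | Path,
) -> tuple[PlateDataset, pd.DataFrame]:
    """Read and validate the long-format measurement CSVs and metadata."""
    meas = pd.read_csv(measurements_path)
    lod = pd.read_csv(lod_path)
    metadata = pd.read_csv(metadata_path)
    for col in ("subject_id", "age", "sex", "hamd_baseline", "hamd_wk10", "hamd_wk12"):
        if col not in metadata.columns:
            raise DataError(f"metadata missing column {col!r}")
    if "below_lod" in meas.columns:
        meas["below_lod"] = meas["below_lod"].astype(bool)
    if "is_qc_pool" in meas.columns:
        meas["is_qc_pool"] = meas["is_qc_pool"].astype(bool)
    subj_rows = meas.loc[~meas["is_qc_pool"], "sample_id"].astype(str)
    sample_map = pd.DataFrame(
        {
            "sample_id": subj_rows.unique(),
        }
    )
    parts = sample_map["sample_id"].str.rsplit("_", n=1)
    sample_map["subject_id"] = parts.str[0]
    sample_map["timepoint"] = parts.str[1]
    dataset = PlateDataset(meas, lod, sample_map)
    dataset.validate()
    known_plates = set(lod["plate_id"].unique())
    bad_plates = set(meas["plate_id"].unique()) - known_plates
    if bad_plates:
        raise DataError(f"unknown plate IDs in measurements: {sorted(bad_plates)}")
    if "outcome" not in metadata.columns:
        metadata["outcome"] = [
            associate.classify_outcome(b, w10, w12)
            for b, w10, w12 in zip(
                metadata["hamd_baseline"], metadata["hamd_wk10"], metadata["hamd_wk12"]
            )
        ]
    return dataset, metadata


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the manifest dictionary.

    On a stage failure the manifest (with the failing stage recorded) is
    still written before the exception propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "metacoex",
        "version": metacoex.__version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
        "warnings": [],
        "input_checksums": {},
        "status": "running",
    }

    def _finish(status: str, stage: str | None = None) -> None:
        manifest["status"] = status
        if stage:
            manifest["failed_stage"] = stage
        _write_json(manifest, out / "manifest.json")

    truth = None
    stage = "inputs"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            if config.simulate:
                scfg = synth.SynthConfig(seed=config.seed, n_subjects=config.n_subjects)
                dataset, metadata, truth = synth.generate_cohort(scfg)
                synth.write_cohort(dataset, metadata, truth, out)
            else:
                dataset, metadata = read_inputs(
                    config.measurements_path, config.lod_path, config.metadata_path
                )
            for key in ("measurements_path", "lod_path", "metadata_path"):
                p = getattr(config, key)
                if p and Path(p).exists():
                    manifest["input_checksums"][key] = _sha256(Path(p))
            manifest["stages"]["inputs"] = {
                "n_measurements": int(len(dataset.measurements)),
                "n_subjects": int(metadata.shape[0]),
                "n_metabolites": int(len(dataset.metabolites)),
                "n_plates": int(len(dataset.plates)),
            }

            stage = "preprocess"
            qc = preprocess.QCReport()
            dataset, exclusions = preprocess.filter_by_lod(
                dataset, config.lod_max_below_frac
            )
            qc.metabolites_excluded = exclusions
            dataset, factors = preprocess.batch_correct(dataset)
            qc.correction_factors = factors
            n_censored = int(
                dataset.subject_measurements["below_lod"].sum()
            )
            log_matrix = preprocess.impute_and_log(dataset)
            qc.imputed_count = n_censored
            qc.outliers = preprocess.flag_outliers(log_matrix, config.outlier_alpha)
            qc.n_metabolites_passing = int(log_matrix.shape[1])
            if config.drop_outliers and qc.outliers.flags.any():
                log_matrix = log_matrix[~qc.outliers.flags]
            changes = preprocess.compute_changes(log_matrix, dataset.sample_map)
            _write_json(qc.to_dict(), out / "qc_report.json")
            _write_csv(dataset.measurements, out / "corrected_measurements.csv")
            _write_csv(changes, out / "change_matrix.csv", index=True)
            manifest["stages"]["preprocess"] = {
                "n_excluded": int(len(exclusions)),
                "n_imputed": qc.imputed_count,
                "n_outliers_flagged": int(qc.outliers.flags.sum()),
                "change_matrix_shape": list(changes.shape),
            }

            stage = "network"
            if config.beta == "auto":
                beta, fit_table = network.pick_soft_threshold(changes)
                _write_csv(fit_table, out / "soft_threshold_fit.csv")
            else:
                beta = int(config.beta)
            partition, adj, tom = network.detect_modules(
                changes,
                beta=beta,
                deep_split=config.deep_split,
                min_size=config.min_size,
                merge_threshold=config.merge_threshold,
            )
            kwithin = network.intramodular_connectivity(adj, partition)
            modules_df = pd.DataFrame(
                {
                    "metabolite_id": partition.labels.index,
                    "module": partition.labels.to_numpy(),
                    "kWithin": kwithin.loc[partition.labels.index].to_numpy(),
                }
            )
            modules_df["is_hub"] = [
                partition.hubs.get(mod) == met
                for met, mod in zip(
                    modules_df["metabolite_id"], modules_df["module"]
                )
            ]
            _write_csv(modules_df, out / "modules.csv")
            _write_csv(partition.eigenvectors, out / "eigenvectors.csv", index=True)
            _write_json(
                {
                    "merge_history": partition.merge_history,
                    "explained_variance": partition.explained_variance,
                    "params": partition.params,
                },
                out / "network_details.json",
            )
            manifest["stages"]["network"] = {
                "beta": int(beta),
                "n_modules": int(len(partition.modules)),
                "module_sizes": {
                    str(k): int(v) for k, v in partition.sizes().items()
                },
                "n_grey": int((partition.labels == network.UNASSIGNED).sum()),
            }
            if truth is not None:
                from sklearn.metrics import adjusted_rand_score

                planted = truth.module_labels.loc[partition.labels.index]
                codes = pd.factorize(partition.labels)[0]
                manifest["stages"]["network"]["planted_ari"] = float(
                    adjusted_rand_score(planted.to_numpy(), codes)
                )

            stage = "associate"
            meta_idx = metadata.set_index("subject_id")
            common = changes.index.intersection(meta_idx.index)
            trait = (
                meta_idx.loc[common, "hamd_wk12"] - meta_idx.loc[common, "hamd_baseline"]
            ).astype(float)
            trait.name = "dhamd"
            ch = changes.loc[common]
            if len(partition.modules):
                module_table, heatmap = associate.module_trait_correlation(
                    partition.eigenvectors.loc[common],
                    trait,
                    config.r_cut,
                    config.p_cut,
                )
            else:
                module_table = pd.DataFrame(
                    columns=["unit", "r", "p", "significant"]
                )
                heatmap = pd.DataFrame(columns=["r", "p"])
            met_corr = associate.metabolite_trait_correlation(ch, trait)
            uni = associate.univariate_model(
                ch,
                trait,
                meta_idx.loc[common, "age"].astype(float),
                meta_idx.loc[common, "sex"],
            )
            uni = uni.merge(
                met_corr.rename(columns={"r": "pearson_r", "p": "pearson_p"}),
                on="unit",
            )
            uni["module"] = uni["unit"].map(partition.labels)
            traj = associate.trajectory_summary(
                log_matrix, dataset.sample_map, metadata
            )
            summary = associate.cohort_summary(metadata)
            _write_csv(module_table, out / "module_trait.csv")
            _write_csv(heatmap, out / "module_trait_heatmap.csv", index=True)
            _write_csv(uni, out / "univariate.csv")
            _write_csv(traj, out / "trajectories.csv")
            _write_json(summary, out / "cohort_summary.json")
            if config.write_heatmap_png and len(heatmap):
                _plot_heatmap(heatmap, out / "module_trait_heatmap.png")
            manifest["stages"]["associate"] = {
                "n_modules_tested": int(len(module_table)),
                "n_modules_significant": int(module_table["significant"].sum())
                if len(module_table)
                else 0,
                "n_metabolites_tested": int(len(uni)),
            }

            manifest["warnings"] = [str(w.message) for w in caught]
    except Exception:
        _finish("failed", stage)
        raise
    _finish("ok")
    return manifest


def _plot_heatmap(heatmap: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.2, 0.5 * len(heatmap) + 1.2))
    vals = heatmap[["r"]].to_numpy(dtype=float)
    im = ax.imshow(vals, cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_yticks(range(len(heatmap)), heatmap.index)
    ax.set_xticks([0], ["dHAM-D"])
    for i, (r, p) in enumerate(zip(heatmap["r"], heatmap["p"])):
        ax.text(0, i, f"{r:.2f}\n(p={p:.2g})", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
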