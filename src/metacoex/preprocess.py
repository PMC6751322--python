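"""Plate-level QC: LOD filtering, pooled-QC batch correction, imputation,
log2 transform, multivariate outlier flagging, and change-score assembly.

The QC recipe follows the standard targeted-metabolomics workflow for
Biocrates-style plate designs: metabolites with more than 40% of cohort
measurements below the limit of detection are excluded; between-plate
shifts are removed with per-metabolite correction factors computed from
pooled-QC aliquots (global QC mean / plate QC mean); remaining censored
values are imputed at LOD/2 and the matrix is log2 transformed; multivariate
outlier samples are flagged by squared Mahalanobis distance against a
Bonferroni-corrected chi-square threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from metacoex.types import BASELINE, WEEK12, DataError, PlateDataset

DEFAULT_LOD_MAX_BELOW_FRAC = 0.40
DEFAULT_OUTLIER_ALPHA = 0.05
_PCA_VARIANCE_TARGET = 0.90


@dataclass
class OutlierReport:
    """Squared Mahalanobis distances with the threshold actually used.

    Distances are computed in the PCA subspace capturing at least 90% of
    variance (capped at n-2 components) because the per-metabolite covariance
    is singular whenever metabolites outnumber samples; ``df`` records the
    retained dimension and is the chi-square degrees of freedom.
    """

    distances: pd.Series  # sample_id -> squared Mahalanobis distance
    threshold: float
    df: int
    alpha: float

    @property
    def flags(self) -> pd.Series:
        return self.distances > self.threshold

    def to_dict(self) -> dict:
        return {
            "threshold": float(self.threshold),
            "df": int(self.df),
            "alpha": float(self.alpha),
            "outliers": [
                {"sample_id": sid, "distance": float(d)}
                for sid, d in self.distances[self.flags].items()
            ],
        }


@dataclass
class QCReport:
    """Audit trail of every QC decision taken during preprocessing."""

    metabolites_excluded: pd.DataFrame = None  # metabolite_id, below_lod_fraction
    correction_factors: pd.DataFrame = None  # metabolite_id, plate_id, factor
    imputed_count: int = 0
    outliers: OutlierReport = None
    n_metabolites_passing: int = 0

    def to_dict(self) -> dict:
        return {
            "metabolites_excluded": (
                self.metabolites_excluded.to_dict("records")
                if self.metabolites_excluded is not None
                else []
            ),
            "n_correction_factors": (
                len(self.correction_factors)
                if self.correction_factors is not None
                else 0
            ),
            "imputed_count": int(self.imputed_count),
            "outliers": self.outliers.to_dict() if self.outliers else None,
            "n_metabolites_passing": int(self.n_metabolites_passing),
        }


def filter_by_lod(
    data: PlateDataset, max_below_frac: float = DEFAULT_LOD_MAX_BELOW_FRAC
) -> tuple[PlateDataset, pd.DataFrame]:
    """Drop metabolites with too many below-LOD cohort measurements.

    A metabolite is excluded iff strictly more than ``max_below_frac`` of its
    non-QC measurements are below the LOD; QC-pool aliquots are instrument
    controls and do not count toward the fraction.
    """
    subj = data.subject_measurements
    counts = subj.groupby("metabolite_id")["below_lod"].agg(["mean", "size"])
    missing = set(data.measurements["metabolite_id"].unique()) - set(counts.index)
    if missing:
        raise DataError(
            f"metabolite(s) with zero cohort measurements: {sorted(missing)[:5]}"
        )
    excluded = counts[counts["mean"] > max_below_frac]
    exclusions = (
        excluded["mean"]
        .rename("below_lod_fraction")
        .reset_index()
        .sort_values("metabolite_id", ignore_index=True)
    )
    keep = ~data.measurements["metabolite_id"].isin(excluded.index)
    filtered = PlateDataset(
        data.measurements[keep].reset_index(drop=True),
        data.lod[~data.lod["metabolite_id"].isin(excluded.index)].reset_index(
            drop=True
        ),
        data.sample_map.copy(),
    )
    return filtered, exclusions


def batch_correct(data: PlateDataset) -> tuple[PlateDataset, pd.DataFrame]:
    """Rescale each plate so its QC-pool mean matches the global QC mean.

    The correction factor for (metabolite, plate) is the metabolite's global
    QC average divided by its QC average within the plate; every value on
    that plate (cohort and QC alike) is multiplied by the factor, and the
    plate's LOD is rescaled identically so later LOD/2 imputation stays in
    corrected units. After correction all per-plate QC means equal the global
    QC mean.
    """
    qc = data.measurements[data.measurements["is_qc_pool"]]
    if qc.empty:
        raise DataError("no QC-pool measurements present")
    plate_means = qc.groupby(["metabolite_id", "plate_id"])["value"].mean()
    global_means = qc.groupby("metabolite_id")["value"].mean()

    mets = data.measurements["metabolite_id"].unique()
    plates = data.measurements["plate_id"].unique()
    rows = []
    for met in mets:
        g = global_means.get(met, np.nan)
        for plate in plates:
            pm = plate_means.get((met, plate), np.nan)
            if not np.isfinite(pm) or pm <= 0:
                raise DataError(
                    f"QC mean missing or nonpositive for metabolite {met!r} "
                    f"on plate {plate!r}"
                )
            rows.append((met, plate, float(g) / float(pm)))
    factors = pd.DataFrame(rows, columns=["metabolite_id", "plate_id", "factor"])

    key = pd.MultiIndex.from_frame(
        data.measurements[["metabolite_id", "plate_id"]]
    )
    fmap = factors.set_index(["metabolite_id", "plate_id"])["factor"]
    corrected = data.measurements.copy()
    corrected["value"] = corrected["value"] * fmap.reindex(key).to_numpy()

    lod = data.lod.copy()
    lod_key = pd.MultiIndex.from_frame(lod[["metabolite_id", "plate_id"]])
    lod["lod_value"] = lod["lod_value"] * fmap.reindex(lod_key).to_numpy()

    return PlateDataset(corrected, lod, data.sample_map.copy()), factors


def impute_and_log(data: PlateDataset) -> pd.DataFrame:
    """Replace censored entries with LOD/2 and log2-transform.

    Returns a wide samples x metabolites matrix of log2 abundances for the
    cohort samples (QC aliquots excluded). Uses the plate-specific LOD when
    the LOD table provides one per plate.
    """
    subj = data.subject_measurements.copy()
    lod_map = data.lod.set_index(["metabolite_id", "plate_id"])["lod_value"]
    key = pd.MultiIndex.from_frame(subj[["metabolite_id", "plate_id"]])
    fill = lod_map.reindex(key).to_numpy() / 2.0
    censored = subj["value"].isna()
    if censored.any() and np.isnan(fill[censored.to_numpy()]).any():
        raise DataError("LOD table does not cover all censored entries")
    subj["value"] = np.where(censored, fill, subj["value"])
    if (subj["value"] <= 0).any():
        bad = subj.loc[subj["value"] <= 0, "metabolite_id"].iloc[0]
        raise DataError(f"nonpositive value after correction for {bad!r}")
    wide = subj.pivot(index="sample_id", columns="metabolite_id", values="value")
    if wide.isna().any().any():
        raise DataError("missing (sample, metabolite) entries after imputation")
    return np.log2(wide).sort_index()


def flag_outliers(
    log_matrix: pd.DataFrame, alpha: float = DEFAULT_OUTLIER_ALPHA
) -> OutlierReport:
    """Flag multivariate outlier samples by squared Mahalanobis distance.

    Distances are evaluated in the PCA subspace capturing >=90% of variance
    (at most n-2 components); a sample is flagged when its squared distance
    exceeds the chi-square quantile at probability 1 - alpha/n with df equal
    to the number of retained components. Samples are flagged, never removed.
    """
    X = log_matrix.to_numpy(dtype=float)
    n, m = X.shape
    if n < 3:
        raise DataError("need at least 3 samples for outlier detection")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc.std(axis=0) > 0):
        raise DataError("constant matrix: outlier distances undefined")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    cum = np.cumsum(var) / total
    k = int(np.searchsorted(cum, _PCA_VARIANCE_TARGET) + 1)
    k = max(1, min(k, n - 2, int((s > s[0] * 1e-10).sum())))
    # standardized PC scores: U[:, :k] * sqrt(n-1) has unit column variance
    d2 = (n - 1) * (U[:, :k] ** 2).sum(axis=1)
    threshold = float(stats.chi2.ppf(1 - alpha / n, df=k))
    return OutlierReport(
        distances=pd.Series(d2, index=log_matrix.index, name="sq_mahalanobis"),
        threshold=threshold,
        df=k,
        alpha=alpha,
    )


def compute_changes(
    log_matrix: pd.DataFrame, sample_map: pd.DataFrame
) -> pd.DataFrame:
    """Per-subject log2 change scores: week12 minus baseline.

    Subjects missing either timepoint are dropped with a warning. Duplicate
    samples for one (subject, timepoint) raise an error.
    """
    sm = sample_map.set_index("sample_id")
    present = sm.loc[sm.index.intersection(log_matrix.index)]
    dup = present.duplicated(["subject_id", "timepoint"])
    if dup.any():
        subj = present.loc[dup, "subject_id"].iloc[0]
        raise DataError(f"duplicate samples at one timepoint for subject {subj!r}")

    frames = {}
    for tp in (BASELINE, WEEK12):
        ids = present[present["timepoint"] == tp]
        frames[tp] = log_matrix.loc[ids.index].set_axis(
            ids["subject_id"].to_numpy(), axis=0
        )
    both = frames[BASELINE].index.intersection(frames[WEEK12].index)
    incomplete = sorted(
        set(frames[BASELINE].index).symmetric_difference(frames[WEEK12].index)
    )
    if incomplete:
        warnings.warn(
            f"dropping {len(incomplete)} subject(s) missing a timepoint: "
            f"{incomplete[:5]}",
            stacklevel=2,
        )
    both = sorted(both)
    changes = frames[WEEK12].loc[both] - frames[BASELINE].loc[both]
    changes.index.name = "subject_id"
    changes.columns.name = "metabolite_id"
    return changes.sort_index(axis=1)
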