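"""Cohort containers, diagnostic labeling, preprocessing, and TSV I/O.

Case/control labels for Alzheimer's-type cohorts are assigned from clinical
cognition scales (MMSE, CDR) combined with post-mortem neuropathology (CERAD
plaque score 0-3, Braak tau stage 0-6):

* dementia: MMSE <= 24 (when available) or CDR >= 1 (when available);
* AD case: CERAD in {2,3} and Braak in {3..6} with dementia;
* control: CERAD in {0,1} and Braak in {0..3} without dementia, with the
  extra requirement that Braak 3 is only allowed when CERAD is 0;
* anything else is excluded.

Feature preprocessing follows the order log2(x + pseudocount) -> per-feature
median centering -> ordinary-least-squares residualization on covariates
(age, sex, post-mortem interval, ...), each step per feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortDataset", "DiagnosisRecord", "assign_dementia", "assign_diagnosis",
    "log2_transform", "median_center", "residualize_covariates",
    "SingularDesignError", "read_feature_table", "write_feature_table",
    "read_metadata", "write_metadata",
]


class SingularDesignError(ValueError):
    pass


@dataclass
class DiagnosisRecord:
    cerad: int
    braak: int
    mmse: float | None = None
    cdr: float | None = None

    def __post_init__(self):
        if self.cerad not in (0, 1, 2, 3):
            raise ValueError(f"CERAD must be 0-3, got {self.cerad}")
        if self.braak not in range(7):
            raise ValueError(f"Braak must be 0-6, got {self.braak}")


def assign_dementia(record: DiagnosisRecord) -> bool:
    """Dementia at last evaluation: MMSE <= 24 or CDR >= 1."""
    if record.mmse is None and record.cdr is None:
        raise ValueError("dementia status requires at least one of MMSE or CDR")
    demented = False
    if record.mmse is not None:
        demented = demented or record.mmse <= 24
    if record.cdr is not None:
        demented = demented or record.cdr >= 1
    return demented


def assign_diagnosis(record: DiagnosisRecord, dementia: bool | None = None) -> str:
    """Returns "AD", "control", or "excluded" from the CERAD/Braak/dementia rule."""
    if dementia is None:
        dementia = assign_dementia(record)
    cerad, braak = record.cerad, record.braak
    if cerad in (2, 3) and 3 <= braak <= 6 and dementia:
        return "AD"
    if cerad in (0, 1) and 0 <= braak <= 3 and not dementia:
        if braak == 3 and cerad != 0:
            return "excluded"
        return "control"
    return "excluded"


@dataclass
class CohortDataset:
    """Samples with binary labels, per-modality features, and availability masks.

    ``modality_features[name]`` is (n_samples, d_name); rows where
    ``modality_masks[name]`` is False are absent (their values are ignored,
    conventionally NaN).  Masks partition samples into complete /
    single-modality / absent groups.
    """

    sample_ids: list[str]
    labels: np.ndarray
    modality_features: dict[str, np.ndarray]
    modality_masks: dict[str, np.ndarray]
    feature_ids: dict[str, list[str]]
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        n = len(self.sample_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (n,):
            raise ValueError("labels must be one per sample")
        for name, mat in self.modality_features.items():
            mat = np.asarray(mat, dtype=np.float64)
            self.modality_features[name] = mat
            mask = np.asarray(self.modality_masks[name], dtype=bool)
            self.modality_masks[name] = mask
            if mat.shape != (n, len(self.feature_ids[name])):
                raise ValueError(f"feature matrix shape mismatch for {name!r}")
            if mask.shape != (n,):
                raise ValueError(f"mask shape mismatch for {name!r}")
            if len(set(self.feature_ids[name])) != len(self.feature_ids[name]):
                raise ValueError(f"duplicate feature ids in {name!r}")
            if not np.isfinite(mat[mask]).all():
                raise ValueError(f"non-finite values in present rows of {name!r}")

    @property
    def modalities(self) -> list[str]:
        return list(self.modality_features)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def availability_group(self) -> np.ndarray:
        """String group per sample: "complete", "<modality>_only", or "absent"."""
        names = self.modalities
        out = []
        for i in range(self.n_samples):
            present = [m for m in names if self.modality_masks[m][i]]
            if len(present) == len(names):
                out.append("complete")
            elif len(present) == 1:
                out.append(f"{present[0]}_only")
            elif not present:
                out.append("absent")
            else:
                out.append("partial:" + "+".join(present))
        return np.array(out)

    def single_modality_view(self, name: str) -> "CohortDataset":
        """The samples where ``name`` is present, carrying only that modality."""
        idx = np.flatnonzero(self.modality_masks[name])
        return CohortDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            modality_features={name: self.modality_features[name][idx]},
            modality_masks={name: np.ones(idx.size, dtype=bool)},
            feature_ids={name: list(self.feature_ids[name])},
            metadata=self.metadata.iloc[idx].reset_index(drop=True)
            if self.metadata is not None else None,
        )

    def subset(self, idx) -> "CohortDataset":
        idx = np.asarray(idx)
        return CohortDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            modality_features={m: v[idx] for m, v in self.modality_features.items()},
            modality_masks={m: v[idx] for m, v in self.modality_masks.items()},
            feature_ids={m: list(v) for m, v in self.feature_ids.items()},
            metadata=self.metadata.iloc[idx].reset_index(drop=True)
            if self.metadata is not None else None,
        )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def log2_transform(matrix: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=np.float64)
    if not np.isfinite(matrix).all():
        raise ValueError("non-finite input to log2 transform")
    shifted = matrix + pseudocount
    if (shifted <= 0).any():
        raise ValueError("log2 transform requires value + pseudocount > 0")
    return np.log2(shifted)


def median_center(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=np.float64)
    return matrix - np.median(matrix, axis=0, keepdims=True)


def residualize_covariates(matrix: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of each feature on the covariates plus an intercept.

    Categorical (non-numeric) covariate columns are one-hot encoded with the
    first level dropped; zero-variance columns are dropped.  Samples with a
    missing covariate are excluded from the fit and their residuals computed
    from the fitted coefficients.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    if len(covariates) != n:
        raise ValueError("covariate table not aligned to samples")

    cols, names = [], []
    for col in covariates.columns:
        series = covariates[col]
        if pd.api.types.is_numeric_dtype(series):
            cols.append(series.to_numpy(dtype=np.float64))
            names.append(col)
        else:
            dummies = pd.get_dummies(series.astype("category"), drop_first=True)
            for dcol in dummies.columns:
                cols.append(dummies[dcol].to_numpy(dtype=np.float64))
                names.append(f"{col}[{dcol}]")
    keep_cols, keep_names = [], []
    for arr, nm in zip(cols, names):
        finite = arr[np.isfinite(arr)]
        if finite.size and np.ptp(finite) > 0:
            keep_cols.append(arr)
            keep_names.append(nm)
    X = np.column_stack([np.ones(n)] + keep_cols) if keep_cols else np.ones((n, 1))
    q = X.shape[1]
    if q >= n:
        raise ValueError("more covariates than samples")

    complete = np.isfinite(X).all(axis=1)
    Xc = X[complete]
    rank = np.linalg.matrix_rank(Xc)
    if rank < q:
        # identify the first column that fails to increase the rank
        r = 1
        for j in range(1, q):
            rj = np.linalg.matrix_rank(Xc[:, :j + 1])
            if rj == r:
                raise SingularDesignError(
                    f"covariate {keep_names[j - 1]!r} is collinear with earlier columns")
            r = rj
        raise SingularDesignError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(Xc, matrix[complete], rcond=None)
    fitted = np.where(np.isfinite(X), X, 0.0) @ beta
    return matrix - fitted


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    # tolerate tab and comma via sniffing; writers always emit tab
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_feature_table(path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a samples x features TSV (first column sample id, header symbols)."""
    df = _read_table(path)
    return ([str(s) for s in df.index], [str(c) for c in df.columns],
            df.to_numpy(dtype=np.float64))


def write_feature_table(path, sample_ids, feature_ids, matrix):
    df = pd.DataFrame(np.asarray(matrix), index=list(sample_ids),
                      columns=list(feature_ids))
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    return _read_table(path)


def write_metadata(path, df: pd.DataFrame):
    out = df.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t")
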