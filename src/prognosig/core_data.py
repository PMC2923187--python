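"""Shared data model: expression matrices, clinical tables and prognosis labels.

All tabular I/O is tab-separated UTF-8 text with a header row, ``.`` as the
decimal separator and ``NA`` as the missing token.  Expression values are
non-negative linear-scale intensities (probes in rows, samples in columns);
clinical follow-up time is stored in months.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOW_RISK = "low_risk"
HIGH_RISK = "high_risk"

MISSING_TOKEN = "NA"

#: Mapping from substage to the coarse AJCC stage used in stratified analyses.
COARSE_STAGE = {"IA": "I", "IB": "I", "I": "I", "II": "II", "III": "III"}

_CLINICAL_CATEGORICALS = ("stage", "gender", "race", "smoking", "differentiation")


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """Probes x samples grid of non-negative expression intensities."""

    data: pd.DataFrame  # index = probe ids, columns = sample ids

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicate probe id(s): {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample id(s): {dups}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite value at probe {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        if values.size and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise DataError(
                f"negative intensity at probe {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_probes(self, probes) -> "ExpressionMatrix":
        missing = [p for p in probes if p not in self.data.index]
        if missing:
            raise DataError(f"unknown probe id(s): {missing}")
        return ExpressionMatrix(self.data.loc[list(probes)])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise DataError(f"unknown sample id(s): {missing}")
        return ExpressionMatrix(self.data[list(samples)])

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """Optional log2 view; never applied implicitly anywhere."""
        return np.log2(self.data + pseudocount)

    def write(self, path) -> None:
        out = self.data.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)


def read_expression(path, missing_policy: str = "error") -> ExpressionMatrix:
    """Read a tab-delimited probes x samples matrix.

    First column holds probe ids, header row holds sample ids.  ``NA`` cells
    are either fatal (``missing_policy='error'``) or cause the whole probe row
    to be dropped (``'drop_row'``).  Row and column order is preserved.
    """
    if missing_policy not in ("error", "drop_row"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      na_values=[MISSING_TOKEN], keep_default_na=False)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate probe id(s) in {path}: {dups}")
    if raw.isna().any().any():
        if missing_policy == "error":
            r, c = np.argwhere(raw.isna().to_numpy())[0]
            raise DataError(
                f"missing value at probe {raw.index[r]!r}, sample {raw.columns[c]!r}"
            )
        n_before = len(raw)
        raw = raw.dropna(axis=0)
        logger.info("dropped %d probe row(s) with missing values", n_before - len(raw))
    try:
        data = raw.astype(float)
    except ValueError:
        for r in range(raw.shape[0]):
            for c in range(raw.shape[1]):
                try:
                    float(raw.iat[r, c])
                except ValueError:
                    raise DataError(
                        f"non-numeric cell at probe {raw.index[r]!r}, "
                        f"sample {raw.columns[c]!r}: {raw.iat[r, c]!r}"
                    ) from None
        raise
    data.index = data.index.astype(str)
    data.columns = data.columns.astype(str)
    data.index.name = None
    data.columns.name = None
    return ExpressionMatrix(data)


@dataclass
class ClinicalTable:
    """Per-sample survival time (months), event indicator and covariates."""

    data: pd.DataFrame  # index = sample ids

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample id(s): {dups}")
        for col in ("time_months", "event"):
            if col not in df.columns:
                raise DataError(f"mandatory clinical column {col!r} missing")
        t = df["time_months"].to_numpy(dtype=float)
        if not np.isfinite(t).all() or (t < 0).any():
            raise DataError("time_months must be finite and >= 0")
        ev = df["event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise DataError("event must be 0 or 1")
        for col in _CLINICAL_CATEGORICALS:
            if col not in df.columns:
                df[col] = "Unknown"
            else:
                df[col] = df[col].fillna("Unknown").astype(str)
        if "age_years" not in df.columns:
            df["age_years"] = np.nan
        if "chemo" not in df.columns:
            df["chemo"] = np.nan
        df["stage"] = df["stage"].str.upper().str.strip().replace(
            "UNKNOWN", "Unknown")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time_months(self) -> pd.Series:
        return self.data["time_months"].astype(float)

    @property
    def event(self) -> pd.Series:
        return self.data["event"].astype(int)

    def coarse_stage(self) -> pd.Series:
        """Collapse substages (IA/IB -> I); unknown strings pass through."""
        return self.data["stage"].map(lambda s: COARSE_STAGE.get(s, s))

    def subset(self, samples) -> "ClinicalTable":
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise DataError(f"unknown sample id(s): {missing}")
        return ClinicalTable(self.data.loc[list(samples)].copy())

    def write(self, path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)


def read_clinical(path) -> ClinicalTable:
    """Read a tab-delimited clinical table (first column = sample id).

    Accepts ``time`` as an alias for ``time_months``.  Unknown categorical
    values are preserved; absent covariate columns default to ``Unknown``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0,
                     na_values=[MISSING_TOKEN], keep_default_na=False)
    df.index = df.index.astype(str)
    if "time_months" not in df.columns and "time" in df.columns:
        df = df.rename(columns={"time": "time_months"})
    for col in ("time_months", "event"):
        if col not in df.columns:
            raise DataError(f"mandatory clinical column {col!r} missing in {path}")
    df["time_months"] = pd.to_numeric(df["time_months"])
    df["event"] = pd.to_numeric(df["event"])
    df.index.name = None
    return ClinicalTable(df)


@dataclass
class PrognosisLabels:
    """Binary five-year-outcome labels with the uninformative samples set aside.

    ``labels`` maps sample id -> {low_risk, high_risk}; ``excluded_ids`` are
    censored cases whose follow-up ended before the horizon, which carry no
    usable class information.
    """

    labels: pd.Series  # index = sample ids, values in {LOW_RISK, HIGH_RISK}
    excluded_ids: list[str] = field(default_factory=list)
    horizon_months: float = 60.0

    def __post_init__(self) -> None:
        vals = set(self.labels.unique())
        if not vals <= {LOW_RISK, HIGH_RISK}:
            raise DataError(f"invalid label value(s): {vals - {LOW_RISK, HIGH_RISK}}")
        overlap = set(self.labels.index) & set(self.excluded_ids)
        if overlap:
            raise DataError(f"samples both labeled and excluded: {sorted(overlap)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def ids_for(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def counts(self) -> dict[str, int]:
        return {
            LOW_RISK: int((self.labels == LOW_RISK).sum()),
            HIGH_RISK: int((self.labels == HIGH_RISK).sum()),
        }

    def as_binary(self) -> np.ndarray:
        """1 for high-risk, 0 for low-risk, in label order."""
        return (self.labels == HIGH_RISK).to_numpy(dtype=int)


def dichotomize(clinical: ClinicalTable, horizon_months: float = 60.0) -> PrognosisLabels:
    """Split a cohort into low-/high-risk classes at a survival horizon.

    A death at or before the horizon is high-risk; surviving past the horizon
    (regardless of later status) is low-risk; a censored case whose follow-up
    ended before the horizon is excluded as uninformative.  A case censored at
    exactly the horizon reached it alive and counts as low-risk.
    """
    if horizon_months <= 0:
        raise ValueError("horizon_months must be > 0")
    if len(clinical.data) == 0:
        raise DataError("empty clinical table")
    t = clinical.time_months.to_numpy()
    ev = clinical.event.to_numpy()
    ids = np.asarray(clinical.sample_ids, dtype=object)
    high = (ev == 1) & (t <= horizon_months)
    low = (t > horizon_months) | ((ev == 0) & (t == horizon_months))
    excluded = (ev == 0) & (t < horizon_months)
    labels = pd.Series(
        np.where(high, HIGH_RISK, LOW_RISK)[high | low],
        index=ids[high | low], dtype=object,
    )
    return PrognosisLabels(labels=labels, excluded_ids=list(ids[excluded]),
                           horizon_months=horizon_months)


def align(expr: ExpressionMatrix, clinical: ClinicalTable
          ) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both inputs to their common samples, in expression order."""
    common = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    if not common:
        raise DataError("expression and clinical tables share no sample ids")
    dropped = (set(expr.sample_ids) | set(clinical.sample_ids)) - set(common)
    if dropped:
        logger.warning("align dropped %d sample(s): %s", len(dropped), sorted(dropped))
    return expr.subset_samples(common), clinical.subset(common)
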