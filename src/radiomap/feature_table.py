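"""Radiomics feature tables: taxonomy, containers, and CSV I/O.

Radiomics features computed from a segmented CT lesion fall into six
groups (shape, first-order intensity, and the GLCM/GLDM/GLRLM/GLSZM
texture families) and are extracted from twelve image channels: the
original image, eight wavelet decompositions (low/high-pass filtering
along each axis: LLL ... HHH) and three Laplacian-of-Gaussian channels
(sigma 1, 2, 3). Shape features describe lesion geometry and therefore
exist only on the original channel.

Feature names follow the ``<channel>_<group>_<Metric>`` convention
(e.g. ``wavelet-HLL_glcm_MaximumProbability``). The ``original``
channel prefix may be omitted on input and is always written
explicitly on output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "GROUPS",
    "DEFAULT_METRICS",
    "FeatureDescriptor",
    "FeatureTable",
    "ClinicalRecord",
    "LabelVector",
    "FeatureTableError",
    "parse_feature_name",
    "enumerate_catalog",
    "read_feature_table",
    "write_feature_table",
    "read_labels",
    "write_labels",
    "read_clinical",
    "write_clinical",
    "align",
]

#: Image channels in canonical order: original, eight wavelet
#: decompositions, three Laplacian-of-Gaussian scales.
CHANNELS: tuple[str, ...] = (
    "original",
    "wavelet-LLL",
    "wavelet-LLH",
    "wavelet-LHL",
    "wavelet-LHH",
    "wavelet-HLL",
    "wavelet-HLH",
    "wavelet-HHL",
    "wavelet-HHH",
    "log-sigma-1",
    "log-sigma-2",
    "log-sigma-3",
)

#: Feature groups in canonical order. ``shape`` only pairs with the
#: original channel.
GROUPS: tuple[str, ...] = ("shape", "firstorder", "glcm", "gldm", "glrlm", "glszm")

SUBTYPES: tuple[str, ...] = ("AIS", "MIA", "LPA", "APA", "PPA", "MPA", "SPA", "IMA")

#: Default per-group metric roster (pyradiomics-style base metrics).
#: The total catalog size is config-driven, not fixed: it depends on
#: the extractor version.
DEFAULT_METRICS: dict[str, tuple[str, ...]] = {
    "shape": (
        "Elongation", "Flatness", "LeastAxisLength", "MajorAxisLength",
        "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "Maximum2DDiameterSlice",
        "Maximum3DDiameter", "MeshVolume", "MinorAxisLength", "Sphericity",
        "SurfaceArea", "SurfaceVolumeRatio", "VoxelVolume",
    ),
    "firstorder": (
        "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
        "Kurtosis", "Maximum", "Mean", "MeanAbsoluteDeviation", "Median",
        "Minimum", "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
        "Skewness", "TotalEnergy", "Uniformity", "Variance",
    ),
    "glcm": (
        "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
        "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
        "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
        "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
        "MCC", "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
    ),
    "gldm": (
        "DependenceEntropy", "DependenceNonUniformity",
        "DependenceNonUniformityNormalized", "DependenceVariance",
        "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
        "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
        "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
        "SmallDependenceLowGrayLevelEmphasis",
    ),
    "glrlm": (
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
        "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
        "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
        "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
        "ShortRunLowGrayLevelEmphasis",
    ),
    "glszm": (
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
        "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
        "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
        "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
        "ZoneEntropy", "ZonePercentage", "ZoneVariance",
    ),
}


class FeatureTableError(ValueError):
    """Raised for malformed feature names, tables, or CSV inputs."""


@dataclass(frozen=True)
class FeatureDescriptor:
    """A parsed radiomics feature name: (channel, group, base metric)."""

    name: str
    group: str
    channel: str
    metric: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FeatureTableError(f"unknown feature group {self.group!r}")
        if self.channel not in CHANNELS:
            raise FeatureTableError(f"unknown image channel {self.channel!r}")
        if self.group == "shape" and self.channel != "original":
            raise FeatureTableError(
                f"shape features exist only on the original channel, got {self.name!r}"
            )
        if not self.metric:
            raise FeatureTableError(f"empty base metric in {self.name!r}")

    @classmethod
    def make(cls, channel: str, group: str, metric: str) -> "FeatureDescriptor":
        return cls(name=format_feature_name(channel, group, metric),
                   group=group, channel=channel, metric=metric)


def format_feature_name(channel: str, group: str, metric: str) -> str:
    """Canonical name: channel always explicit, underscore-delimited."""
    return f"{channel}_{group}_{metric}"


def parse_feature_name(name: str) -> FeatureDescriptor:
    """Parse ``<channel>_<group>_<Metric>`` (channel optional ⇒ original).

    The base metric may itself contain underscores; channel and group
    tokens never do, so the parse is unambiguous. Unknown base metrics
    are tolerated; channel and group must be recognisable.
    """
    parts = name.split("_")
    if parts and parts[0] in CHANNELS:
        channel = parts[0]
        rest = parts[1:]
    else:
        channel = "original"
        rest = parts
    if not rest or rest[0] not in GROUPS:
        raise FeatureTableError(
            f"cannot parse feature name {name!r}: expected "
            "'<channel>_<group>_<Metric>' with a known group"
        )
    group = rest[0]
    metric = "_".join(rest[1:])
    if not metric:
        raise FeatureTableError(f"feature name {name!r} has no base metric")
    return FeatureDescriptor(
        name=format_feature_name(channel, group, metric),
        group=group, channel=channel, metric=metric,
    )


def enumerate_catalog(
    metrics: Mapping[str, Sequence[str]] | None = None,
) -> list[FeatureDescriptor]:
    """Enumerate the full feature catalog for a per-group metric roster.

    Shape metrics pair only with the original channel; every other
    group crosses all twelve channels. Order is deterministic:
    channels in canonical order, groups in canonical order, metrics in
    roster order.
    """
    metrics = dict(DEFAULT_METRICS if metrics is None else metrics)
    unknown = set(metrics) - set(GROUPS)
    if unknown:
        raise FeatureTableError(f"unknown groups in catalog config: {sorted(unknown)}")
    for group in GROUPS:
        roster = metrics.get(group, ())
        if not roster:
            raise FeatureTableError(f"catalog config lists no metrics for group {group!r}")
        if len(set(roster)) != len(roster):
            raise FeatureTableError(f"duplicate metric name within group {group!r}")
    out: list[FeatureDescriptor] = []
    for channel in CHANNELS:
        for group in GROUPS:
            if group == "shape" and channel != "original":
                continue
            for metric in metrics[group]:
                out.append(FeatureDescriptor.make(channel, group, metric))
    return out


@dataclass
class FeatureTable:
    """Patients × named radiomics features; the pipeline's currency.

    Invariants enforced at construction: unique patient ids, unique
    feature names, finite values, no missing cells (patients whose
    features cannot be extracted accurately are excluded upstream, not
    imputed).
    """

    patient_ids: list[str]
    features: list[FeatureDescriptor]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = len(self.patient_ids), len(self.features)
        if n == 0:
            raise FeatureTableError("empty table: no patients")
        if p == 0:
            raise FeatureTableError("empty table: no features")
        if self.values.shape != (n, p):
            raise FeatureTableError(
                f"values shape {self.values.shape} != ({n}, {p})"
            )
        if len(set(self.patient_ids)) != n:
            raise FeatureTableError("duplicate patient ids")
        names = self.feature_names
        if len(set(names)) != p:
            raise FeatureTableError("duplicate feature names")
        if not np.isfinite(self.values).all():
            raise FeatureTableError("non-finite or missing feature values")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def subset_patients(self, ids: Sequence[str]) -> "FeatureTable":
        """Row-restrict to ``ids`` in the given order."""
        index = {pid: i for i, pid in enumerate(self.patient_ids)}
        missing = [pid for pid in ids if pid not in index]
        if missing:
            raise FeatureTableError(f"unknown patient ids: {missing[:5]}")
        rows = [index[pid] for pid in ids]
        return FeatureTable(list(ids), list(self.features), self.values[rows])

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        """Column-restrict to ``names`` in the given order."""
        index = {f.name: i for i, f in enumerate(self.features)}
        missing = [nm for nm in names if nm not in index]
        if missing:
            raise FeatureTableError(f"unknown feature names: {missing[:5]}")
        cols = [index[nm] for nm in names]
        return FeatureTable(
            list(self.patient_ids),
            [self.features[c] for c in cols],
            self.values[:, cols],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.patient_ids, name="patient_id"),
                            columns=self.feature_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        features = [parse_feature_name(str(c)) for c in df.columns]
        return cls(
            patient_ids=[str(i) for i in df.index],
            features=features,
            values=df.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinical covariates.

    ``subtype`` is one of the eight histopathological subtypes of lung
    adenocarcinoma, or None for cohorts where it was not recorded.
    """

    patient_id: str
    age: float
    gender: str
    subtype: str | None = None

    def __post_init__(self) -> None:
        if not self.age > 0 or not math.isfinite(self.age):
            raise FeatureTableError(f"age must be a positive real, got {self.age}")
        if self.gender not in ("male", "female"):
            raise FeatureTableError(f"gender must be 'male' or 'female', got {self.gender!r}")
        if self.subtype is not None and self.subtype not in SUBTYPES:
            raise FeatureTableError(f"unknown subtype {self.subtype!r}")


@dataclass
class LabelVector:
    """Binary mutation-status labels: 1 = EGFR(+), 0 = EGFR(−)."""

    patient_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.patient_ids):
            raise FeatureTableError("labels must align one-to-one with patient ids")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise FeatureTableError("duplicate patient ids in labels")
        if not np.isin(self.labels, (0, 1)).all():
            raise FeatureTableError("labels must be binary 0/1")

    def subset(self, ids: Sequence[str]) -> "LabelVector":
        index = {pid: i for i, pid in enumerate(self.patient_ids)}
        missing = [pid for pid in ids if pid not in index]
        if missing:
            raise FeatureTableError(f"unknown patient ids in labels: {missing[:5]}")
        return LabelVector(list(ids), self.labels[[index[pid] for pid in ids]])


# ---------------------------------------------------------------------------
# CSV I/O. All tables share the convention: UTF-8, header row,
# "patient_id" first column. Values round-trip at full double precision
# (written with repr-faithful formatting, 17 significant digits).

_FLOAT_FMT = "%.17g"


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2 or df.shape[0] < 1:
        raise FeatureTableError(f"{path}: empty table (need ≥1 patient and ≥1 feature)")
    id_col = df.columns[0]
    if df[id_col].isna().any():
        raise FeatureTableError(f"{path}: missing patient id")
    df = df.set_index(id_col)
    if df.isna().any().any():
        bad = df.columns[df.isna().any()][0]
        raise FeatureTableError(f"{path}: missing value in feature {bad!r} (imputation is not performed)")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FeatureTableError(f"{path}: non-numeric feature cell ({exc})") from exc
    features = [parse_feature_name(str(c)) for c in df.columns]
    return FeatureTable([str(i) for i in df.index], features, values)


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.to_dataframe()
    df.to_csv(path, float_format=_FLOAT_FMT)


def read_labels(path) -> LabelVector:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns or "egfr" not in df.columns:
        raise FeatureTableError(f"{path}: label CSV needs 'patient_id' and 'egfr' columns")
    return LabelVector(df["patient_id"].tolist(), df["egfr"].to_numpy())


def write_labels(labels: LabelVector, path) -> None:
    pd.DataFrame({"patient_id": labels.patient_ids, "egfr": labels.labels}).to_csv(path, index=False)


def read_clinical(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    needed = {"patient_id", "age", "gender"}
    if not needed.issubset(df.columns):
        raise FeatureTableError(f"{path}: clinical CSV needs columns {sorted(needed)}")
    records = []
    for row in df.itertuples(index=False):
        subtype = getattr(row, "subtype", None)
        if subtype is not None and (pd.isna(subtype) or subtype == ""):
            subtype = None
        records.append(ClinicalRecord(str(row.patient_id), float(row.age),
                                      str(row.gender), subtype))
    return records


def write_clinical(records: Iterable[ClinicalRecord], path) -> None:
    rows = [
        {"patient_id": r.patient_id, "age": r.age, "gender": r.gender,
         "subtype": "" if r.subtype is None else r.subtype}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def align(
    table: FeatureTable,
    labels: LabelVector,
    clinical: Sequence[ClinicalRecord] | None = None,
):
    """Restrict all inputs to the patient-id intersection, in the
    table's row order. Returns ``(table, labels)`` or
    ``(table, labels, clinical)``.
    """
    keep = set(labels.patient_ids)
    if clinical is not None:
        keep &= {r.patient_id for r in clinical}
    ids = [pid for pid in table.patient_ids if pid in keep]
    if not ids:
        raise FeatureTableError("no overlapping patient ids to align")
    table_a = table.subset_patients(ids)
    labels_a = labels.subset(ids)
    if clinical is None:
        return table_a, labels_a
    by_id = {r.patient_id: r for r in clinical}
    return table_a, labels_a, [by_id[pid] for pid in ids]
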