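"""Core data model for multi-omics feature tables.

A study is represented by one or more :class:`OmicsDataSet` objects — a
feature × sample intensity matrix plus MS metadata (m/z, retention time,
ionization mode) for metabolomics tables — and a shared
:class:`SampleDesign` mapping samples to experimental conditions,
biological units (biological replicates), and data-set labels.  Technical
replicates are samples that share a biological unit; they always share the
unit's condition.

The module also provides the standard preprocessing steps: quantile
normalization of intensity columns, per-condition arithmetic mean profiles,
unit-Euclidean-length profile normalization, and concatenation of several
filtered data sets into a single table with per-row provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleDesign",
    "OmicsDataSet",
    "CombinedDataSet",
    "read_design",
    "read_feature_table",
    "write_feature_table",
    "quantile_normalize",
    "condition_means",
    "normalize_profiles",
    "combine_datasets",
]

KINDS = ("metabolomics", "transcriptomics", "other")
ION_MODES = ("positive", "negative")


@dataclass(frozen=True)
class SampleDesign:
    """Sample annotation: condition, biological unit, and data-set label.

    Condition order is first-seen order over ``sample_ids`` and is shared
    by all downstream profile matrices and exports.
    """

    sample_ids: tuple[str, ...]
    condition_of: Mapping[str, str]
    biounit_of: Mapping[str, str]
    dataset_of: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in design")
        for s in self.sample_ids:
            if s not in self.condition_of:
                raise ValueError(f"sample {s!r} has no condition")
            if s not in self.biounit_of:
                raise ValueError(f"sample {s!r} has no biological unit")
        unit_cond: dict[str, str] = {}
        for s in self.sample_ids:
            u, c = self.biounit_of[s], self.condition_of[s]
            if unit_cond.setdefault(u, c) != c:
                raise ValueError(
                    f"biological unit {u!r} assigned to two conditions "
                    f"({unit_cond[u]!r} and {c!r}); technical replicates must "
                    "share one condition"
                )

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.condition_of[s], None)
        return tuple(seen)

    @property
    def units(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.biounit_of[s], None)
        return tuple(seen)

    def condition_of_unit(self, unit: str) -> str:
        for s in self.sample_ids:
            if self.biounit_of[s] == unit:
                return self.condition_of[s]
        raise KeyError(unit)

    def samples_of_condition(self, condition: str) -> tuple[str, ...]:
        return tuple(
            s for s in self.sample_ids if self.condition_of[s] == condition
        )

    def subset(self, sample_ids: Sequence[str]) -> "SampleDesign":
        """Design restricted to ``sample_ids`` (order taken from the argument)."""
        missing = [s for s in sample_ids if s not in self.condition_of]
        if missing:
            raise ValueError(f"unknown sample in design: {missing[0]!r}")
        return SampleDesign(
            sample_ids=tuple(sample_ids),
            condition_of={s: self.condition_of[s] for s in sample_ids},
            biounit_of={s: self.biounit_of[s] for s in sample_ids},
            dataset_of={s: self.dataset_of.get(s, "") for s in sample_ids},
        )

    def with_unit_conditions(self, new_cond: Mapping[str, str]) -> "SampleDesign":
        """Reassign condition labels at the biological-unit level.

        Used by the permutation engine: every technical replicate of a unit
        receives the unit's new label.
        """
        cond = {s: new_cond[self.biounit_of[s]] for s in self.sample_ids}
        return replace(self, condition_of=cond)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_ids),
                "condition": [self.condition_of[s] for s in self.sample_ids],
                "biounit": [self.biounit_of[s] for s in self.sample_ids],
                "dataset": [self.dataset_of.get(s, "") for s in self.sample_ids],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_design(path: str | Path) -> SampleDesign:
    """Read a sidecar design CSV with columns sample_id, condition, biounit, dataset."""
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "condition", "biounit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design file missing columns: {sorted(missing)}")
    if "dataset" not in df.columns:
        df["dataset"] = ""
    df["dataset"] = df["dataset"].fillna("")
    return SampleDesign(
        sample_ids=tuple(df["sample_id"]),
        condition_of=dict(zip(df["sample_id"], df["condition"])),
        biounit_of=dict(zip(df["sample_id"], df["biounit"])),
        dataset_of=dict(zip(df["sample_id"], df["dataset"])),
    )


@dataclass
class OmicsDataSet:
    """One feature table: F features × S samples of non-negative intensities.

    ``mz`` (Da), ``rt`` (minutes) and ``ionization_mode`` are present iff
    ``kind == "metabolomics"``.
    """

    label: str
    kind: str
    feature_ids: tuple[str, ...]
    intensities: np.ndarray
    design: SampleDesign
    mz: np.ndarray | None = None
    rt: np.ndarray | None = None
    ionization_mode: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown data-set kind {self.kind!r}")
        self.intensities = np.asarray(self.intensities, dtype=float)
        F, S = self.intensities.shape
        if F < 1 or S < 2:
            raise ValueError("need at least 1 feature and 2 samples")
        if len(self.feature_ids) != F:
            raise ValueError("feature_ids length does not match intensity rows")
        if len(set(self.feature_ids)) != F:
            dup = pd.Series(self.feature_ids)
            dup = dup[dup.duplicated()].iloc[0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if len(self.design.sample_ids) != S:
            raise ValueError("design sample count does not match intensity columns")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("missing or non-finite intensities are not supported")
        if np.any(self.intensities < 0):
            bad = np.where((self.intensities < 0).any(axis=1))[0][0]
            raise ValueError(
                f"negative intensity for feature {self.feature_ids[bad]!r}"
            )
        if self.kind == "metabolomics":
            if self.mz is None or self.rt is None:
                raise ValueError("metabolomics data sets require mz and rt")
            if self.ionization_mode not in ION_MODES:
                raise ValueError(
                    "metabolomics data sets require ionization_mode "
                    f"in {ION_MODES}"
                )
            self.mz = np.asarray(self.mz, dtype=float)
            self.rt = np.asarray(self.rt, dtype=float)
            if self.mz.shape != (F,) or self.rt.shape != (F,):
                raise ValueError("mz/rt length does not match feature count")
            if np.any(self.mz <= 0) or np.any(self.rt < 0):
                raise ValueError("mz must be positive and rt non-negative")
        else:
            self.mz = None
            self.rt = None
            self.ionization_mode = None

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def subset_features(self, mask: np.ndarray) -> "OmicsDataSet":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.where(idx)[0]
        return OmicsDataSet(
            label=self.label,
            kind=self.kind,
            feature_ids=tuple(self.feature_ids[i] for i in idx),
            intensities=self.intensities[idx],
            design=self.design,
            mz=None if self.mz is None else self.mz[idx],
            rt=None if self.rt is None else self.rt[idx],
            ionization_mode=self.ionization_mode,
        )

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {"feature_id": list(self.feature_ids)}
        if self.kind == "metabolomics":
            data["mz"] = self.mz
            data["rt"] = self.rt
        for j, s in enumerate(self.design.sample_ids):
            data[s] = self.intensities[:, j]
        return pd.DataFrame(data)


def read_feature_table(
    path: str | Path,
    design_path: str | Path | SampleDesign,
    kind: str,
    ionization_mode: str | None = None,
    label: str | None = None,
) -> OmicsDataSet:
    """Read a feature CSV (``feature_id[,mz,rt],<sample>...``) plus its design.

    The design file may cover more samples than the table (a shared design
    for a multi-platform study); it is restricted to the intensity columns
    present.  An intensity column that the design does not know is a hard
    error naming the sample.
    """
    design = design_path if isinstance(design_path, SampleDesign) else read_design(design_path)
    df = pd.read_csv(path)
    if "feature_id" not in df.columns:
        raise ValueError("feature CSV must have a feature_id column")
    meta_cols = ["feature_id"]
    mz = rt = None
    if kind == "metabolomics":
        for col in ("mz", "rt"):
            if col not in df.columns:
                raise ValueError(f"metabolomics feature CSV requires a {col} column")
        mz = df["mz"].to_numpy(float)
        rt = df["rt"].to_numpy(float)
        meta_cols += ["mz", "rt"]
    else:
        for col in ("mz", "rt"):
            if col in df.columns:
                warnings.warn(
                    f"ignoring {col!r} column in {kind} feature table",
                    UserWarning,
                    stacklevel=2,
                )
                meta_cols.append(col)
    sample_cols = [c for c in df.columns if c not in meta_cols]
    for s in sample_cols:
        if s not in design.condition_of:
            raise ValueError(f"unknown sample in design: {s!r}")
    sub = design.subset(sample_cols)
    if label is None:
        labels = {sub.dataset_of.get(s, "") for s in sample_cols} - {""}
        label = labels.pop() if len(labels) == 1 else Path(path).stem
    intens = df[sample_cols].to_numpy(float)
    if np.isnan(intens).any():
        bad = int(np.where(np.isnan(intens).any(axis=1))[0][0])
        raise ValueError(
            f"missing intensity for feature {df['feature_id'].iloc[bad]!r}"
        )
    return OmicsDataSet(
        label=label,
        kind=kind,
        feature_ids=tuple(df["feature_id"].astype(str)),
        intensities=intens,
        design=sub,
        mz=mz,
        rt=rt,
        ionization_mode=ionization_mode,
    )


def write_feature_table(ds: OmicsDataSet, path: str | Path) -> None:
    """Write a feature table in the same CSV dialect the reader accepts."""
    ds.to_frame().to_csv(path, index=False)


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of an F×S matrix.

    After normalization every column holds the same multiset of values: the
    per-rank means of the column-sorted input.  Ties within a column receive
    the mean of the rank-means they span, so the result is deterministic and
    invariant to the order of tied entries.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    F, S = m.shape
    if F == 0:
        raise ValueError("empty matrix")
    order = np.argsort(m, axis=0, kind="stable")
    rank_means = np.take_along_axis(m, order, axis=0).mean(axis=1)
    out = np.empty_like(m)
    for j in range(S):
        vals = np.empty(F)
        vals[order[:, j]] = rank_means
        uniq, inv = np.unique(m[:, j], return_inverse=True)
        if uniq.size < F:  # average rank-means across tied input values
            sums = np.bincount(inv, weights=vals)
            counts = np.bincount(inv)
            vals = (sums / counts)[inv]
        out[:, j] = vals
    return out


def condition_means(ds: OmicsDataSet) -> tuple[np.ndarray, tuple[str, ...]]:
    """Arithmetic mean of replicate intensities per condition and feature.

    Returns the F×C matrix and the ordered condition tuple.
    """
    conds = ds.design.conditions
    cols = []
    for c in conds:
        idx = [
            j
            for j, s in enumerate(ds.design.sample_ids)
            if ds.design.condition_of[s] == c
        ]
        if not idx:
            raise ValueError(f"condition {c!r} has no samples")
        cols.append(ds.intensities[:, idx].mean(axis=1))
    return np.column_stack(cols), conds


def normalize_profiles(means: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Scale each row to unit Euclidean length.

    All-zero rows cannot be normalized; they are excluded and their row
    indices reported.  Returns ``(normalized_rows, excluded_indices)`` where
    the first element contains only the retained rows, in input order.
    """
    m = np.asarray(means, dtype=float)
    norms = np.linalg.norm(m, axis=1)
    excluded = [int(i) for i in np.where(norms == 0)[0]]
    keep = norms > 0
    return m[keep] / norms[keep, None], excluded


@dataclass
class CombinedDataSet:
    """Several filtered data sets concatenated into one feature table.

    ``rows`` records per-feature provenance (source label and kind);
    ``profiles`` holds the per-condition mean intensities row-aligned with
    ``rows``; the raw per-sample columns stay with the ``sources``.
    """

    rows: pd.DataFrame
    profiles: np.ndarray
    conditions: tuple[str, ...]
    sources: dict[str, OmicsDataSet]

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def combine_datasets(datasets: Iterable[OmicsDataSet]) -> CombinedDataSet:
    """Concatenate data tables of several data sets sharing one condition list."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no data sets to combine")
    ref = datasets[0].design.conditions
    for ds in datasets[1:]:
        if ds.design.conditions != ref:
            raise ValueError(
                "condition lists differ: "
                f"{ds.label!r} has {ds.design.conditions} vs {ref}"
            )
    frames = []
    profiles = []
    sources: dict[str, OmicsDataSet] = {}
    for ds in datasets:
        if ds.label in sources:
            raise ValueError(f"duplicate data-set label {ds.label!r}")
        sources[ds.label] = ds
        means, _ = condition_means(ds)
        profiles.append(means)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": list(ds.feature_ids),
                    "source": ds.label,
                    "kind": ds.kind,
                }
            )
        )
    rows = pd.concat(frames, ignore_index=True)
    return CombinedDataSet(
        rows=rows,
        profiles=np.vstack(profiles),
        conditions=ref,
        sources=sources,
    )
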