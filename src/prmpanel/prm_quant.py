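"""Peak-area ingestion, log10 transform, two-step normalization, SIL quantification.

The quantitative backbone of a scheduled PRM experiment: peak areas
exported from chromatogram integration arrive as a long table (peptide ×
sample × light/heavy channel), are log10-transformed, and are corrected in
two steps for instrument drift and batch effects before any statistics.

Normalization model.  All corrections are additive shifts on the log10
scale (equivalently multiplicative rescalings of raw areas, the standard
model for ionization-efficiency and loading drift):

* Step 1 — longitudinal (within batch, per sample): each sample is shifted
  by the difference between its reference-peptide median and the
  reference-peptide median over that batch's QC runs.  References default
  to the spiked heavy (SIL) standards, which see the instrument but not
  the biology.
* Step 2 — transverse (between batches, per feature): each feature is
  centred on its per-batch median and re-anchored at its grand median, so
  after this step every feature's per-batch medians agree across batches.

Both steps are median-based for robustness to outlier runs.  Missing/zero
areas propagate as missing; no imputation is performed by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class PeakAreaMatrix:
    """Features × samples peak areas with sample/feature annotations.

    ``light`` holds the endogenous channel for every quantified feature;
    ``heavy`` holds the spiked-standard channel for reference features
    only.  ``scale`` is "linear" (raw areas) or "log10".
    """

    light: pd.DataFrame
    heavy: pd.DataFrame | None
    sample_meta: pd.DataFrame  # index sample_id; columns group, batch, is_qc
    feature_meta: pd.DataFrame  # index feature_id; columns protein, is_reference
    scale: str = "linear"

    def check(self) -> None:
        if not self.light.columns.equals(self.sample_meta.index):
            raise ValueError("light columns do not match sample metadata index")
        if "batch" not in self.sample_meta.columns:
            raise ValueError("sample metadata lacks a batch column")
        if self.sample_meta["batch"].isna().any():
            raise ValueError("every sample must have a batch id")
        if self.scale == "linear":
            for df in (self.light, self.heavy):
                if df is not None and (df.to_numpy() < 0).any():
                    raise ValueError("negative peak area")
        if self.heavy is not None:
            refs = set(self.feature_meta.index[self.feature_meta["is_reference"]])
            extra = set(self.heavy.index) - refs
            if extra:
                raise ValueError(
                    f"heavy channel present for non-reference features: {sorted(extra)}"
                )

    def reference_ids(self) -> list[str]:
        return list(self.feature_meta.index[self.feature_meta["is_reference"]])

    def study_samples(self) -> list[str]:
        return list(self.sample_meta.index[~self.sample_meta["is_qc"]])

    def copy(self) -> "PeakAreaMatrix":
        return PeakAreaMatrix(
            self.light.copy(),
            None if self.heavy is None else self.heavy.copy(),
            self.sample_meta.copy(),
            self.feature_meta.copy(),
            self.scale,
        )


class PeakTableFormatError(ValueError):
    pass


REQUIRED_COLUMNS = ("feature_id", "protein", "sample_id", "batch", "label", "area")


def write_peak_table(matrix: PeakAreaMatrix, path, meta_path=None) -> None:
    """Serialize to the long CSV layout (and optionally the metadata TSV)."""
    rows = []
    for channel, df in (("light", matrix.light), ("heavy", matrix.heavy)):
        if df is None:
            continue
        for fid in df.index:
            protein = matrix.feature_meta.loc[fid, "protein"]
            for sid in df.columns:
                area = df.loc[fid, sid]
                if pd.isna(area):
                    continue
                rows.append(
                    (fid, protein, sid, matrix.sample_meta.loc[sid, "batch"], channel,
                     repr(float(area)))
                )
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, index=False)
    if meta_path is not None:
        matrix.sample_meta.reset_index().to_csv(meta_path, sep="\t", index=False)


def read_peak_table(path, meta_path) -> PeakAreaMatrix:
    """Read a Skyline-export-style long CSV plus a sample-metadata TSV.

    Duplicate (feature, sample, label) rows and samples absent from the
    metadata are format errors; absent combinations become missing values.
    """
    table = pd.read_csv(path, dtype={"feature_id": str, "sample_id": str, "batch": str})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise PeakTableFormatError(f"peak table lacks columns {missing_cols}")
    dup = table.duplicated(["feature_id", "sample_id", "label"], keep=False)
    if dup.any():
        first = table[dup].iloc[0]
        raise PeakTableFormatError(
            "duplicate (feature, sample, label) rows, e.g. "
            f"feature {first['feature_id']} sample {first['sample_id']} label {first['label']}"
        )

    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "batch": str})
    if "sample_id" not in meta.columns:
        raise PeakTableFormatError("metadata lacks sample_id column")
    meta = meta.set_index("sample_id")
    if "is_qc" in meta.columns:
        meta["is_qc"] = meta["is_qc"].astype(bool)
    unknown = set(table["sample_id"]) - set(meta.index)
    if unknown:
        raise PeakTableFormatError(f"samples missing from metadata: {sorted(unknown)[:5]}")

    light_long = table[table["label"] == "light"]
    heavy_long = table[table["label"] == "heavy"]
    light = light_long.pivot(index="feature_id", columns="sample_id", values="area")
    light = light.reindex(columns=meta.index)
    heavy = None
    if len(heavy_long):
        heavy = heavy_long.pivot(index="feature_id", columns="sample_id", values="area")
        heavy = heavy.reindex(columns=meta.index)

    protein_of = (
        table.drop_duplicates("feature_id").set_index("feature_id")["protein"]
    )
    ref_ids = set(heavy.index) if heavy is not None else set()
    feature_meta = pd.DataFrame(
        {
            "protein": protein_of.reindex(light.index),
            "is_reference": [f in ref_ids for f in light.index],
        },
        index=light.index,
    )
    matrix = PeakAreaMatrix(light, heavy, meta, feature_meta, scale="linear")
    matrix.check()
    return matrix


def log10_transform(matrix: PeakAreaMatrix) -> PeakAreaMatrix:
    """Elementwise log10; zero areas become missing, negatives are errors."""
    if matrix.scale != "linear":
        raise ValueError("matrix is already on log scale")

    def _tf(df: pd.DataFrame | None) -> pd.DataFrame | None:
        if df is None:
            return None
        arr = df.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("negative peak area cannot be log-transformed")
        with np.errstate(divide="ignore"):
            out = np.log10(arr)
        out[arr == 0] = np.nan
        return pd.DataFrame(out, index=df.index, columns=df.columns)

    out = matrix.copy()
    out.light = _tf(matrix.light)
    out.heavy = _tf(matrix.heavy)
    out.scale = "log10"
    return out


def delog(matrix: PeakAreaMatrix) -> PeakAreaMatrix:
    if matrix.scale != "log10":
        raise ValueError("matrix is not on log scale")
    out = matrix.copy()
    out.light = np.power(10.0, matrix.light)
    out.heavy = None if matrix.heavy is None else np.power(10.0, matrix.heavy)
    out.scale = "linear"
    return out


def _reference_levels(matrix: PeakAreaMatrix, reference_ids: Sequence[str]) -> pd.Series:
    """Per-sample median of reference-feature log10 areas (heavy channel
    when available, light otherwise)."""
    if matrix.heavy is not None and set(reference_ids) <= set(matrix.heavy.index):
        ref = matrix.heavy.loc[list(reference_ids)]
    else:
        missing = [r for r in reference_ids if r not in matrix.light.index]
        if missing:
            raise ValueError(f"reference features absent from matrix: {missing}")
        ref = matrix.light.loc[list(reference_ids)]
    levels = ref.median(axis=0, skipna=True)
    dead = levels.index[levels.isna()].tolist()
    if dead:
        raise ValueError(f"no reference feature observed in samples: {dead}")
    return levels


def normalize_longitudinal(
    matrix: PeakAreaMatrix, reference_ids: Sequence[str] | None = None
) -> PeakAreaMatrix:
    """Step 1: per-sample shift anchored on the batch's QC reference level.

    Each sample is shifted by (its reference-feature median − the median
    reference level over the batch's QC runs); batches without QC runs
    fall back to the batch-wide reference median as the anchor.
    """
    if matrix.scale != "log10":
        raise ValueError("normalization expects a log10 matrix")
    if reference_ids is None:
        reference_ids = matrix.reference_ids()
    if len(reference_ids) == 0:
        raise ValueError("no reference features available for normalization")

    out = matrix.copy()
    levels = _reference_levels(out, reference_ids)
    batches = out.sample_meta["batch"]
    is_qc = out.sample_meta["is_qc"].astype(bool)

    shift = pd.Series(0.0, index=out.light.columns)
    for b in batches.unique():
        in_batch = batches == b
        qc_here = in_batch & is_qc
        anchor_pool = levels[qc_here.index[qc_here]] if qc_here.any() else levels[in_batch.index[in_batch]]
        anchor = float(anchor_pool.median())
        shift[in_batch.index[in_batch]] = levels[in_batch.index[in_batch]] - anchor
    out.light = out.light.sub(shift, axis=1)
    if out.heavy is not None:
        out.heavy = out.heavy.sub(shift, axis=1)
    return out


def normalize_transverse(matrix: PeakAreaMatrix) -> PeakAreaMatrix:
    """Step 2: per-feature batch-median centring re-anchored at the grand
    median.  Leaves each feature's grand median unchanged, equalizes its
    per-batch medians, and is idempotent."""
    if matrix.scale != "log10":
        raise ValueError("normalization expects a log10 matrix")
    out = matrix.copy()
    batches = out.sample_meta["batch"]

    def _center(df: pd.DataFrame) -> pd.DataFrame:
        grand = df.median(axis=1, skipna=True)
        centered = df.copy()
        for b in batches.unique():
            cols = batches.index[batches == b]
            med = df[cols].median(axis=1, skipna=True)
            centered[cols] = df[cols].sub(med, axis=0)
        return centered.add(grand, axis=0)

    out.light = _center(out.light)
    if out.heavy is not None:
        out.heavy = _center(out.heavy)
    return out


def normalize_two_step(
    matrix: PeakAreaMatrix, reference_ids: Sequence[str] | None = None
) -> PeakAreaMatrix:
    """Longitudinal (per-sample, QC-anchored) then transverse (per-feature,
    batch-median) correction on the log10 scale."""
    return normalize_transverse(normalize_longitudinal(matrix, reference_ids))


def flag_low_coverage(matrix: PeakAreaMatrix, min_observed_fraction: float = 0.5) -> list[str]:
    """Feature ids observed in fewer than the given fraction of study samples."""
    cols = matrix.study_samples()
    frac = matrix.light[cols].notna().mean(axis=1)
    return list(frac.index[frac < min_observed_fraction])


@dataclass(frozen=True)
class QuantEntry:
    """Stable-isotope-dilution quantification of one endogenous peptide.

    C_endogenous = C_SIS * area_endogenous / area_SIS, in the units of the
    spiked-standard concentration C_SIS.
    """

    area_endogenous: float
    area_sis: float
    c_sis: float
    c_endogenous: float = field(init=False)
    log2_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        if self.area_sis <= 0:
            raise ValueError("SIS (heavy) peak area must be positive")
        if self.c_sis <= 0:
            raise ValueError("spiked-standard concentration must be positive")
        if self.area_endogenous < 0:
            raise ValueError("endogenous peak area must be nonnegative")
        object.__setattr__(
            self, "c_endogenous", self.c_sis * self.area_endogenous / self.area_sis
        )
        ratio = self.area_endogenous / self.area_sis
        object.__setattr__(
            self, "log2_ratio", math.log2(ratio) if ratio > 0 else float("-inf")
        )


def quantify_sil(area_endogenous: float, area_sis: float, c_sis: float) -> QuantEntry:
    """Endogenous concentration from the light/heavy area ratio."""
    return QuantEntry(area_endogenous, area_sis, c_sis)


def quantify_references(
    matrix: PeakAreaMatrix, c_sis: dict[str, float]
) -> pd.DataFrame:
    """L/H quantification of every reference feature in every sample.

    ``matrix`` must be linear-scale with a heavy channel.  Returns a long
    table (feature_id, sample_id, c_endogenous, log2_ratio).
    """
    if matrix.scale != "linear":
        raise ValueError("quantify_references expects linear-scale areas")
    if matrix.heavy is None:
        raise ValueError("matrix has no heavy channel")
    rows = []
    for fid in matrix.heavy.index:
        if fid not in c_sis:
            raise ValueError(f"no spiked concentration supplied for {fid}")
        for sid in matrix.heavy.columns:
            hv = matrix.heavy.loc[fid, sid]
            lt = matrix.light.loc[fid, sid]
            if pd.isna(hv) or pd.isna(lt):
                continue
            q = quantify_sil(float(lt), float(hv), c_sis[fid])
            rows.append((fid, sid, q.c_endogenous, q.log2_ratio))
    return pd.DataFrame(rows, columns=["feature_id", "sample_id", "c_endogenous", "log2_ratio"])


def qc_cv(matrix: PeakAreaMatrix) -> pd.Series:
    """Per-feature coefficient of variation across QC runs, linear scale."""
    lin = matrix if matrix.scale == "linear" else delog(matrix)
    qc_cols = lin.sample_meta.index[lin.sample_meta["is_qc"].astype(bool)]
    qc = lin.light[qc_cols]
    return qc.std(axis=1, ddof=1) / qc.mean(axis=1)
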