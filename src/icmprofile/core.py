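"""Core containers shared across the pipeline.

A :class:`Spectrum` is a pair of equal-length arrays (m/z in Da, intensity in
arbitrary counts) plus acquisition metadata identifying the animal, fertility
group, ejaculate, MALDI target spot and acquisition index.  A
:class:`FeatureMatrix` is the samples x m/z-bins table of normalized peak
intensities that every quality-control and statistical step operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

GROUPS = ("F", "SF", "unknown")

META_COLUMNS = ("sample", "animal", "group", "ejaculate", "spot", "acquisition")


class PipelineError(Exception):
    """Base class for errors raised by the pipeline."""


class SpectrumError(PipelineError):
    """Invalid spectrum content or an operation precondition violation."""


class CalibrationError(PipelineError):
    """Mass calibration could not be established or failed its accuracy bound."""


def _default_meta() -> dict:
    return {
        "animal": "unknown",
        "group": "unknown",
        "ejaculate": 0,
        "spot": 0,
        "acquisition": 0,
        "history": [],
    }


@dataclass
class Spectrum:
    """A single profile mass spectrum.

    Parameters
    ----------
    mz:
        Strictly increasing m/z values in Da.
    intensity:
        Non-negative, finite intensities, same length as ``mz``.
    meta:
        Acquisition metadata; ``history`` records the processing steps applied.
    """

    mz: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=_default_meta)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumError("mz and intensity must be one-dimensional")
        if len(self.mz) != len(self.intensity):
            raise SpectrumError(
                f"length mismatch: {len(self.mz)} mz vs {len(self.intensity)} intensities"
            )
        if len(self.mz) < 2:
            raise SpectrumError("a spectrum needs at least two points")
        if not np.all(np.isfinite(self.mz)):
            raise SpectrumError("non-finite m/z value")
        if np.any(np.diff(self.mz) <= 0):
            raise SpectrumError("m/z values must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise SpectrumError("non-finite intensity value")
        if np.any(self.intensity < 0):
            idx = int(np.argmax(self.intensity < 0))
            raise SpectrumError(f"negative intensity at index {idx}")
        meta = dict(_default_meta())
        meta.update(self.meta or {})
        meta["history"] = list(meta.get("history", []))
        self.meta = meta

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def history(self) -> list[str]:
        return self.meta["history"]

    def sample_id(self) -> str:
        """Identifier of the biological sample (animal + ejaculate)."""
        return f"{self.meta['animal']}.e{self.meta['ejaculate']}"

    def replicate_id(self) -> str:
        """Identifier of the technical replicate (sample + spot + acquisition)."""
        return f"{self.sample_id()}.s{self.meta['spot']}.a{self.meta['acquisition']}"

    def with_arrays(
        self,
        mz: np.ndarray | None = None,
        intensity: np.ndarray | None = None,
        step: str | None = None,
    ) -> "Spectrum":
        """Return a copy with replaced arrays, optionally appending a history flag."""
        meta = dict(self.meta)
        meta["history"] = list(self.meta["history"])
        if step is not None:
            meta["history"].append(step)
        return Spectrum(
            mz=self.mz if mz is None else mz,
            intensity=self.intensity if intensity is None else intensity,
            meta=meta,
        )


@dataclass
class FeatureMatrix:
    """Samples x m/z-bins table of normalized peak intensities.

    ``values`` is indexed by replicate/sample identifier with one column per
    bin; ``bins`` holds the representative m/z (Da, ascending) of each column;
    ``meta`` is row-aligned with ``values`` and carries animal/group/ejaculate/
    spot/acquisition labels (missing levels are filled with defaults after
    replicate merging).
    """

    values: pd.DataFrame
    bins: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.values.shape[1] != len(self.bins):
            raise PipelineError("one bin per value column required")
        if len(self.bins) > 1 and np.any(np.diff(self.bins) <= 0):
            raise PipelineError("bin m/z must be strictly ascending")
        if np.any(self.values.to_numpy() < 0):
            raise PipelineError("feature-matrix values must be non-negative")
        if not self.values.index.equals(self.meta.index):
            raise PipelineError("meta rows must align with value rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def groups(self) -> pd.Series:
        return self.meta["group"]

    def subset_rows(self, mask: Sequence[bool] | pd.Series) -> "FeatureMatrix":
        mask = np.asarray(mask, dtype=bool)
        return FeatureMatrix(
            values=self.values.loc[mask].copy(),
            bins=self.bins.copy(),
            meta=self.meta.loc[mask].copy(),
        )


@dataclass
class QuantTable:
    """Label-free protein-cluster quantification (GeLC-MS/MS branch).

    Rows of ``counts`` / ``intensities`` are member proteins (indexed by
    accession); columns are a two-level (animal, replicate) MultiIndex of
    technical replicates.  ``proteins`` carries per-protein annotation
    (cluster id, gene symbol — possibly empty or LOC-style, description,
    molecular weight in kDa).  ``groups`` maps animal -> fertility group.
    """

    proteins: pd.DataFrame
    counts: pd.DataFrame
    intensities: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        for frame, name in ((self.counts, "counts"), (self.intensities, "intensities")):
            if np.any(frame.to_numpy() < 0):
                raise PipelineError(f"{name} must be non-negative")
        if not self.counts.index.equals(self.proteins.index):
            raise PipelineError("quantification rows must align with protein table")
        if not self.counts.columns.equals(self.intensities.columns):
            raise PipelineError("count and intensity replicate columns must match")
        missing = set(self.counts.columns.get_level_values(0)) - set(self.groups.index)
        if missing:
            raise PipelineError(f"animals without group label: {sorted(missing)}")

    @property
    def animals(self) -> list:
        return list(dict.fromkeys(self.counts.columns.get_level_values(0)))

    def per_animal_means(self, which: str = "counts") -> pd.DataFrame:
        """Mean over technical replicates, one column per animal."""
        frame = self.counts if which == "counts" else self.intensities
        return frame.T.groupby(level=0).mean().T


@dataclass
class QCReport:
    """Replicate-filtering and precision (CV) summary."""

    threshold: float | None = None
    retained: pd.Series | None = None
    correlations: pd.DataFrame | None = None
    cv_per_bin: pd.Series | None = None
    cv_mean: float | None = None
    excluded_bins: list = field(default_factory=list)
    notes: list = field(default_factory=list)
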