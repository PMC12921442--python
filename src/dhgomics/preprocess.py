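"""Missing-value filtering, imputation, log transform and scaling.

The conventional untargeted-metabolomics preparation chain applied before
univariate and multivariate analysis: drop features with more than 20%
missing cells, replace remaining missing cells by half the feature's
observed minimum (left-censoring convention), log2-transform and optionally
scale (Pareto by default for the multivariate models).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import IntensityMatrix


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    max_missing_fraction: float = 0.20
    imputation: str = "half_min"
    transform: str = "log2"
    scaling: str = "pareto"  # pareto | unit_variance | none

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing_fraction < 1:
            raise PreprocessError("max_missing_fraction must lie in [0, 1)")
        if self.imputation != "half_min":
            raise PreprocessError(f"unknown imputation {self.imputation!r}")
        if self.transform != "log2":
            raise PreprocessError(f"unknown transform {self.transform!r}")
        if self.scaling not in ("pareto", "unit_variance", "none"):
            raise PreprocessError(f"unknown scaling {self.scaling!r}")


@dataclass
class PreprocessReport:
    dropped_ids: list[str] = field(default_factory=list)
    n_imputed_cells: int = 0

    def as_dict(self) -> dict:
        return {"dropped_ids": self.dropped_ids,
                "n_imputed_cells": self.n_imputed_cells}


def filter_missing(
    m: IntensityMatrix,
    cfg: PreprocessConfig | None = None,
    report: PreprocessReport | None = None,
) -> IntensityMatrix:
    """Drop features whose missing fraction strictly exceeds the threshold."""
    cfg = cfg or PreprocessConfig()
    if m.n_features == 0:
        raise PreprocessError("empty matrix")
    frac = m.missing_mask.mean(axis=1)
    keep = frac.index[frac <= cfg.max_missing_fraction]
    dropped = frac.index[frac > cfg.max_missing_fraction]
    if len(keep) == 0:
        raise PreprocessError("missing-value filter removed every feature")
    if report is not None:
        report.dropped_ids = list(dropped)
    return m.subset_features(list(keep))


def impute_half_min(
    m: IntensityMatrix, report: PreprocessReport | None = None
) -> IntensityMatrix:
    """Replace each missing cell by half of the feature's observed minimum."""
    values = m.values.copy()
    n_missing = int(values.isna().sum().sum())
    if n_missing:
        obs_min = values.min(axis=1, skipna=True)
        dead = obs_min.index[obs_min.isna()]
        if len(dead):
            raise PreprocessError(
                f"features with no observed values (filter first): {list(dead)[:5]}"
            )
        fill = obs_min / 2.0
        values = values.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    if report is not None:
        report.n_imputed_cells = n_missing
    return IntensityMatrix(values, m.samples.copy())


def transform_scale(
    m: IntensityMatrix, cfg: PreprocessConfig | None = None
) -> IntensityMatrix:
    """log2-transform and scale per feature.

    Pareto: center, divide by sqrt of the feature SD.  Unit variance: center,
    divide by SD; a zero-variance feature scales to a zero vector with a
    warning rather than an error.
    """
    cfg = cfg or PreprocessConfig()
    values = m.values.copy()
    if values.isna().any().any():
        raise PreprocessError("impute before transform_scale")
    if (values <= 0).any().any():
        bad = np.argwhere((values <= 0).to_numpy())[0]
        raise PreprocessError(
            f"non-positive value before log at feature "
            f"{values.index[bad[0]]!r}, sample {values.columns[bad[1]]!r}"
        )
    logv = np.log2(values)
    if cfg.scaling == "none":
        return IntensityMatrix(logv, m.samples.copy())
    centered = logv.sub(logv.mean(axis=1), axis=0)
    sd = logv.std(axis=1, ddof=1)
    zero = sd.index[sd == 0]
    if len(zero):
        warnings.warn(
            f"{len(zero)} constant feature(s) scaled to zeros: {list(zero)[:5]}",
            stacklevel=2,
        )
    denom = sd.where(sd > 0, 1.0)
    if cfg.scaling == "pareto":
        denom = np.sqrt(denom)
    scaled = centered.div(denom, axis=0)
    scaled.loc[zero] = 0.0
    return IntensityMatrix(scaled, m.samples.copy())


def preprocess(
    m: IntensityMatrix, cfg: PreprocessConfig | None = None
) -> tuple[IntensityMatrix, IntensityMatrix, PreprocessReport]:
    """Full chain: filter -> impute -> (imputed linear matrix, scaled matrix).

    Returns the imputed linear-scale matrix (input to univariate statistics
    and fold changes) and the log2-transformed scaled matrix (input to the
    multivariate models), plus a report of dropped ids and imputed cells.
    """
    cfg = cfg or PreprocessConfig()
    report = PreprocessReport()
    filtered = filter_missing(m, cfg, report)
    imputed = impute_half_min(filtered, report)
    scaled = transform_scale(imputed, cfg)
    return imputed, scaled, report
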