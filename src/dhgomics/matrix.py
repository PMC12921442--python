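"""Feature-by-sample intensity matrix with group and cohort metadata.

The container wraps a pandas DataFrame of raw (linear-scale) intensities,
features on the rows, samples on the columns.  Missing measurements are
encoded as NaN; the missing mask is therefore ``values.isna()``.  Sample
metadata (case/control group, discovery/validation cohort) lives in a
companion DataFrame indexed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("case", "control")
COHORTS = ("discovery", "validation")


class MatrixError(ValueError):
    """Raised for inconsistent intensity-matrix construction or I/O."""


@dataclass
class IntensityMatrix:
    """Intensities (features x samples) plus per-sample group/cohort labels.

    Parameters
    ----------
    values
        DataFrame of non-negative intensities, NaN marking missing cells.
    samples
        DataFrame indexed by sample id with columns ``group`` (``case`` /
        ``control``) and ``cohort`` (``discovery`` / ``validation``).
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise MatrixError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise MatrixError(f"duplicate sample ids: {dups[:5]}")
        missing_meta = [s for s in self.values.columns if s not in self.samples.index]
        if missing_meta:
            raise MatrixError(
                f"samples absent from sample sheet: {missing_meta[:5]}"
            )
        self.samples = self.samples.loc[list(self.values.columns)]
        bad = set(self.samples["group"]) - set(GROUPS)
        if bad:
            raise MatrixError(f"unknown group labels: {sorted(bad)}")
        if "cohort" not in self.samples.columns:
            self.samples = self.samples.assign(cohort="discovery")
        bad = set(self.samples["cohort"]) - set(COHORTS)
        if bad:
            raise MatrixError(f"unknown cohort labels: {sorted(bad)}")

    # -- basic views -------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> pd.Series:
        """Group label per sample, aligned with the value columns."""
        return self.samples["group"]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_labels(self) -> np.ndarray:
        """Return +1 for case, -1 for control, aligned with columns."""
        return np.where(self.groups.to_numpy() == "case", 1.0, -1.0)

    def subset_samples(self, sample_ids: list[str]) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values[list(sample_ids)].copy(),
            self.samples.loc[list(sample_ids)].copy(),
        )

    def subset_features(self, feature_ids: list[str]) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.loc[list(feature_ids)].copy(), self.samples.copy()
        )

    def cohort(self, name: str) -> "IntensityMatrix":
        if name not in COHORTS:
            raise MatrixError(f"unknown cohort {name!r}")
        keep = self.samples.index[self.samples["cohort"] == name]
        if len(keep) == 0:
            raise MatrixError(f"cohort {name!r} has no samples")
        return self.subset_samples(list(keep))

    def require_two_groups(self) -> None:
        present = set(self.groups)
        if present != set(GROUPS):
            raise MatrixError(
                f"need both case and control samples, found {sorted(present)}"
            )
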