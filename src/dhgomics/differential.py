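"""Univariate screening: Mann-Whitney tests, FDR, fold changes, selection.

Metabolite features are kept when they pass a triple gate (VIP from the
OPLS-DA model, raw Mann-Whitney p, absolute log2 fold change); proteins use
the conventional proteomics rule of raw p < 0.05 with linear fold change
above 2 or below 0.5.  Benjamini-Hochberg q-values are always computed and
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import IntensityMatrix


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureStats:
    feature_id: str
    p_value: float
    q_value: float
    log2_fc: float  # case mean minus control mean, log2 scale
    vip: float | None = None
    trend: str = "Down"

    def __post_init__(self) -> None:
        if self.q_value + 1e-12 < self.p_value:
            raise StatsError(f"{self.feature_id}: q < p")


@dataclass(frozen=True)
class SelectionRule:
    """Thresholds of the metabolite and protein differential screens."""

    vip_min: float = 0.5
    p_max: float = 0.05
    log2fc_min: float = float(np.log2(1.5))
    protein_fc_up: float = 2.0
    protein_fc_down: float = 0.5

    def __post_init__(self) -> None:
        if min(self.vip_min, self.p_max, self.log2fc_min) < 0:
            raise StatsError("thresholds must be non-negative")
        if not self.protein_fc_down < 1 < self.protein_fc_up:
            raise StatsError("need protein_fc_down < 1 < protein_fc_up")


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p; exact for small tie-free samples."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= 12 and len(y) <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"  # mid-ranks + continuity correction
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def univariate_stats(
    m: IntensityMatrix, vip: dict[str, float] | None = None
) -> list[FeatureStats]:
    """Per-feature Mann-Whitney p, BH q, and log2 fold change (case/control).

    ``m`` is the imputed linear-scale matrix; fold changes are differences of
    group means of log2 intensities.
    """
    m.require_two_groups()
    grp = m.groups.to_numpy()
    case, control = grp == "case", grp == "control"
    if case.sum() < 2 or control.sum() < 2:
        raise StatsError("each group needs at least 2 samples")
    values = m.values.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise StatsError("impute missing values before univariate_stats")
    logv = np.log2(values)
    pvals = np.array([
        _mannwhitney_p(values[i, case], values[i, control])
        for i in range(values.shape[0])
    ])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    log2fc = logv[:, case].mean(axis=1) - logv[:, control].mean(axis=1)
    out = []
    for i, fid in enumerate(m.feature_ids):
        out.append(FeatureStats(
            feature_id=fid,
            p_value=float(pvals[i]),
            q_value=float(qvals[i]),
            log2_fc=float(log2fc[i]),
            vip=None if vip is None else vip.get(fid),
            trend="Up" if log2fc[i] > 0 else "Down",
        ))
    return out


def select_metabolites(
    stats_list: list[FeatureStats],
    vip: dict[str, float],
    rule: SelectionRule | None = None,
) -> list[FeatureStats]:
    """Keep features with VIP > vip_min, p < p_max and |log2FC| > log2fc_min."""
    rule = rule or SelectionRule()
    missing = [s.feature_id for s in stats_list if s.feature_id not in vip]
    if missing:
        raise StatsError(f"features without VIP scores: {missing[:5]}")
    selected = []
    for s in stats_list:
        v = vip[s.feature_id]
        if v > rule.vip_min and s.p_value < rule.p_max and abs(s.log2_fc) > rule.log2fc_min:
            selected.append(FeatureStats(
                s.feature_id, s.p_value, s.q_value, s.log2_fc, v, s.trend
            ))
    return selected


def select_proteins(
    stats_list: list[FeatureStats], rule: SelectionRule | None = None
) -> list[FeatureStats]:
    """Keep proteins with p < p_max and linear FC > 2 or < 0.5."""
    rule = rule or SelectionRule()
    selected = []
    for s in stats_list:
        fc = 2.0 ** s.log2_fc
        if s.p_value < rule.p_max and (fc > rule.protein_fc_up or fc < rule.protein_fc_down):
            selected.append(s)
    return selected
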