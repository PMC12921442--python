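"""Synthetic two-cohort case/control multi-omics data with planted truth.

Emulates the study design this pipeline targets: a discovery and a validation
cohort of serum metabolomics and proteomics intensity matrices, a pathway
membership database, and a pathway-to-symptom link table.  Ground truth —
which features carry a group effect, which pathways they sit in, and the
minimal number of top pathways needed to cover every diagnostic symptom — is
known by construction, so every downstream stage can be tested offline.

Model
-----
Per-feature baseline log2 intensities are drawn uniformly over ~4 orders of
magnitude (log-normal dynamic range typical of LC-MS serum profiling).  Each
cell adds Normal(0, noise_sd) noise on the log2 scale; planted features are
shifted by ``effect_log2fc`` in cases only, with alternating sign so the
panel contains both up- and down-regulated markers.  Missingness is
left-censored: within each feature the lowest-intensity fraction
``missing_rate`` of cells is masked, emulating values below the detection
limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import SymptomTable
from .matrix import IntensityMatrix


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort generator."""

    n_case: int = 30
    n_control: int = 30
    n_met_features: int = 500
    n_prot_features: int = 300
    n_planted_met: int = 10
    n_planted_prot: int = 10
    effect_log2fc: float = 2.0
    noise_sd: float = 0.5
    missing_rate: float = 0.10
    n_pathways: int = 20
    pathway_size: int = 10
    n_planted_pathways: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_met_features", "n_prot_features",
                     "n_pathways", "pathway_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_planted_met > self.n_met_features:
            raise ConfigError("n_planted_met exceeds n_met_features")
        if self.n_planted_prot > self.n_prot_features:
            raise ConfigError("n_planted_prot exceeds n_prot_features")
        if self.effect_log2fc < 0:
            raise ConfigError("effect_log2fc must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.n_planted_pathways > self.n_pathways:
            raise ConfigError("n_planted_pathways exceeds n_pathways")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulated cohort."""

    planted_met_ids: frozenset[str]
    planted_prot_ids: frozenset[str]
    planted_pathway_ids: frozenset[str] = field(default=frozenset())
    minimal_covering_k: int = 0

    @property
    def planted_feature_ids(self) -> frozenset[str]:
        return self.planted_met_ids | self.planted_prot_ids


def _simulate_layer(rng: np.random.Generator, prefix: str, n_features: int,
                    planted_idx: np.ndarray, cfg: SimulationConfig,
                    n_case: int, n_control: int,
                    cohort: str, sample_offset: int) -> IntensityMatrix:
    n = n_case + n_control
    # baseline spans ~4 orders of magnitude: log2 range 13.3 ~ log10 range 4
    baseline = rng.uniform(10.0, 23.3, size=n_features)
    log2v = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_features, n))
    signs = np.where(np.arange(len(planted_idx)) % 2 == 0, 1.0, -1.0)
    log2v[planted_idx, :n_case] += signs[:, None] * cfg.effect_log2fc
    values = 2.0 ** log2v
    if cfg.missing_rate > 0:
        k = int(np.floor(cfg.missing_rate * n))
        if k > 0:
            order = np.argsort(values, axis=1, kind="stable")
            for i in range(n_features):
                values[i, order[i, :k]] = np.nan
    fids = [f"{prefix}{i:04d}" for i in range(n_features)]
    sids = [f"S{sample_offset + j:03d}" for j in range(n)]
    groups = ["case"] * n_case + ["control"] * n_control
    samples = pd.DataFrame(
        {"group": groups, "cohort": cohort}, index=pd.Index(sids, name="sample_id")
    )
    return IntensityMatrix(pd.DataFrame(values, index=fids, columns=sids), samples)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[IntensityMatrix, IntensityMatrix, PlantedTruth]:
    """Simulate discovery-cohort metabolomics and proteomics matrices.

    Returns the two intensity matrices plus the planted truth (which feature
    ids carry the group effect).  Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    met_planted = np.sort(
        rng.choice(config.n_met_features, size=config.n_planted_met, replace=False)
    )
    prot_planted = np.sort(
        rng.choice(config.n_prot_features, size=config.n_planted_prot, replace=False)
    )
    met = _simulate_layer(rng, "MET", config.n_met_features, met_planted,
                          config, config.n_case, config.n_control,
                          "discovery", 0)
    prot = _simulate_layer(rng, "PROT", config.n_prot_features, prot_planted,
                           config, config.n_case, config.n_control,
                           "discovery", 0)
    truth = PlantedTruth(
        planted_met_ids=frozenset(f"MET{i:04d}" for i in met_planted),
        planted_prot_ids=frozenset(f"PROT{i:04d}" for i in prot_planted),
    )
    return met, prot, truth


def generate_validation_cohort(
    config: SimulationConfig, n_case: int, n_control: int
) -> tuple[IntensityMatrix, IntensityMatrix]:
    """Simulate an independent validation cohort with the same planted truth.

    Uses the same planted feature indices as :func:`generate_cohort` for the
    given config (the planted draw is replayed) but fresh sample noise.
    """
    rng = np.random.default_rng(config.seed)
    met_planted = np.sort(
        rng.choice(config.n_met_features, size=config.n_planted_met, replace=False)
    )
    prot_planted = np.sort(
        rng.choice(config.n_prot_features, size=config.n_planted_prot, replace=False)
    )
    rng = np.random.default_rng((config.seed * 2654435761 + 7) % (2**31))
    met = _simulate_layer(rng, "MET", config.n_met_features, met_planted,
                          config, n_case, n_control, "validation", 500)
    prot = _simulate_layer(rng, "PROT", config.n_prot_features, prot_planted,
                           config, n_case, n_control, "validation", 500)
    return met, prot


def generate_pathway_db(
    config: SimulationConfig, truth: PlantedTruth
) -> tuple[dict[str, tuple[str, set[str]]], PlantedTruth]:
    """Build a toy pathway database over the simulated feature ids.

    The first ``n_planted_pathways`` pathways are the planted ones: each
    receives a share of the planted metabolites *and* planted proteins (so
    both omics layers enrich them) and is topped up with unplanted members.
    The remaining pathways draw members from unplanted features only.
    Returns the database and the truth updated with planted pathway ids.
    """
    n_feat = config.n_met_features + config.n_prot_features
    if config.pathway_size > n_feat:
        raise ConfigError("pathway_size exceeds total feature count")
    rng = np.random.default_rng((config.seed * 2654435761 + 13) % (2**31))
    all_met = [f"MET{i:04d}" for i in range(config.n_met_features)]
    all_prot = [f"PROT{i:04d}" for i in range(config.n_prot_features)]
    planted_met = sorted(truth.planted_met_ids)
    planted_prot = sorted(truth.planted_prot_ids)
    unplanted = sorted(
        (set(all_met) | set(all_prot)) - truth.planted_feature_ids
    )
    k = config.n_planted_pathways
    db: dict[str, tuple[str, set[str]]] = {}
    for j in range(config.n_pathways):
        pid = f"PW{j:02d}"
        if j < k:
            members = set(planted_met[j::k]) | set(planted_prot[j::k])
            fill = rng.choice(unplanted, size=max(0, config.pathway_size - len(members)),
                              replace=False)
            members |= set(fill.tolist())
            desc = f"planted pathway {j}"
        else:
            members = set(
                rng.choice(unplanted, size=config.pathway_size, replace=False).tolist()
            )
            desc = f"background pathway {j}"
        db[pid] = (desc, members)
    planted_ids = frozenset(f"PW{j:02d}" for j in range(k))
    for pid in planted_ids:
        if not (db[pid][1] & truth.planted_feature_ids):
            raise ConfigError(f"planted pathway {pid} received no planted feature")
    new_truth = replace(truth, planted_pathway_ids=planted_ids)
    return db, new_truth


def generate_symptom_links(
    config: SimulationConfig, truth: PlantedTruth, symptoms: SymptomTable
) -> tuple[list[tuple[str, str]], PlantedTruth]:
    """Emit pathway->symptom edges with a known minimal covering set size.

    The symptom list is partitioned into ``n_planted_pathways`` disjoint
    blocks, one per planted pathway, so the planted pathways jointly cover
    every symptom and no smaller family of emitted edge sets can (a block of
    symptoms is only reachable through its own pathway or through singleton
    decoys, which never reduce the count).  Each unplanted pathway receives
    at most one decoy edge.
    """
    names = symptoms.symptoms
    if not names:
        raise ConfigError("symptom table is empty")
    planted = sorted(truth.planted_pathway_ids)
    if not planted:
        raise ConfigError("generate_pathway_db must run first (no planted pathways)")
    k = min(len(planted), len(names))
    edges: list[tuple[str, str]] = []
    for i, symptom in enumerate(names):
        edges.append((planted[i % k], symptom))
    rng = np.random.default_rng((config.seed * 2654435761 + 29) % (2**31))
    others = [f"PW{j:02d}" for j in range(config.n_planted_pathways, config.n_pathways)]
    for pid in others[: len(others) // 2]:
        edges.append((pid, names[int(rng.integers(len(names)))]))
    new_truth = replace(truth, minimal_covering_k=k)
    return edges, new_truth
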