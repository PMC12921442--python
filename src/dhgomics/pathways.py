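"""Pathway over-representation, cross-omics intersection, and the
symptom-weighted pathway prioritisation at the heart of the pipeline.

The clinical anchor is a weighted symptom relevance score: each pathway
linked (by curated evidence) to diagnostic symptoms collects 3 points per
primary symptom, 2 per secondary symptom and 1 per tongue-pulse finding.
Pathways are then ranked by the sum of their enrichment rank and their
symptom-score rank, and the smallest prefix of that ranking whose linked
symptoms cover the full diagnostic table defines the crucial pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import SymptomTable

SYMPTOM_WEIGHTS = {"primary": 3, "secondary": 2, "tongue_pulse": 1}


class PathwayError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    description: str
    n_hits: int
    n_members: int
    p_value: float
    q_value: float

    @property
    def enrichment_score(self) -> float:
        """-log10 of the raw hypergeometric p."""
        return float(-np.log10(self.p_value))


@dataclass(frozen=True)
class PathwayRank:
    pathway_id: str
    enrichment_score: float
    symptom_score: int
    combined_rank: int
    covered_symptoms: frozenset[str] = field(default=frozenset())


def ora(
    hits: set[str],
    db: dict[str, tuple[str, set[str]]],
    universe: set[str] | None = None,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation analysis.

    ``universe`` defaults to the union of all pathway members.  Pathway
    membership is restricted to the universe; p is the upper-tail
    probability of drawing at least the observed overlap, and q is BH
    across all tested pathways.  Results are sorted by (p, pathway id).
    """
    if universe is None:
        universe = set().union(*(members for _, members in db.values()))
    outside = hits - universe
    if outside:
        raise PathwayError(f"hits outside the universe: {sorted(outside)[:5]}")
    N, n = len(universe), len(hits)
    rows = []
    for pid in sorted(db):
        desc, members = db[pid]
        members_u = members & universe
        if not members_u:
            continue
        K = len(members_u)
        k = len(hits & members_u)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((pid, desc, k, K, min(p, 1.0)))
    if not rows:
        return []
    qvals = multipletests([r[4] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(pid, desc, k, K, p, float(q))
        for (pid, desc, k, K, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def intersect_pathways(
    met: list[EnrichmentResult],
    prot: list[EnrichmentResult],
    alpha: float = 0.05,
) -> list[str]:
    """Pathways significant (raw p < alpha) in both omics layers.

    Ordered by the combined -log10 p sum, descending; ties by id.
    """
    met_sig = {r.pathway_id: r for r in met if r.p_value < alpha}
    prot_sig = {r.pathway_id: r for r in prot if r.p_value < alpha}
    common = set(met_sig) & set(prot_sig)
    return sorted(
        common,
        key=lambda pid: (
            -(met_sig[pid].enrichment_score + prot_sig[pid].enrichment_score),
            pid,
        ),
    )


def go_display_selection(
    results: list[tuple[EnrichmentResult, str]], per_direction: int = 10
) -> list[tuple[EnrichmentResult, str]]:
    """Pick the plotting subset of GO terms: per direction (up/down), keep
    terms with more than one hit and take the ``per_direction`` smallest
    p-values (ties broken by term id)."""
    out = []
    for direction in ("up", "down"):
        eligible = [
            (r, d) for r, d in results if d == direction and r.n_hits > 1
        ]
        eligible.sort(key=lambda rd: (rd[0].p_value, rd[0].pathway_id))
        out.extend(eligible[:per_direction])
    return out


def ppi_core(
    edges: list[tuple[str, str]], top_n: int = 25, degree_min: int = 5
) -> list[str]:
    """Hub-protein screen on a PPI edge list.

    Deduplicate to a simple undirected graph, take the ``top_n`` proteins by
    degree (ties by id), recompute degree inside the induced subgraph, and
    return proteins whose recomputed degree strictly exceeds ``degree_min``.
    """
    g = nx.Graph()
    for a, b in edges:
        if a != b:
            g.add_edge(a, b)
    if g.number_of_nodes() == 0:
        return []
    top = sorted(g.nodes, key=lambda v: (-g.degree[v], v))[:top_n]
    sub = g.subgraph(top)
    return sorted(v for v in sub.nodes if sub.degree[v] > degree_min)


def symptom_score(
    pathway_id: str,
    links: list[tuple[str, str]],
    symptoms: SymptomTable,
) -> int:
    """Weighted symptom relevance: 3 per primary, 2 per secondary, 1 per
    tongue-pulse symptom linked to the pathway.  Duplicate edges count once."""
    linked = {s for pid, s in links if pid == pathway_id}
    known = set(symptoms.symptoms)
    unknown = linked - known
    if unknown:
        raise PathwayError(
            f"linked symptoms missing from the symptom table: {sorted(unknown)}"
        )
    return sum(SYMPTOM_WEIGHTS[symptoms.category(s)] for s in linked)


def max_symptom_score(symptoms: SymptomTable) -> int:
    """Score of a pathway linked to every symptom in the table."""
    return sum(SYMPTOM_WEIGHTS[c] for _, c in symptoms.entries)


def combined_rank(
    enrichment: list[EnrichmentResult],
    scores: dict[str, int],
    links: list[tuple[str, str]] | None = None,
) -> list[PathwayRank]:
    """Rank pathways by the sum of enrichment rank and symptom-score rank.

    Both criteria are converted to ordinal ranks (1 = best: highest
    enrichment score, highest symptom score; ties by pathway id) and summed;
    the final order is ascending rank sum with ties broken by enrichment
    score (descending) then id.
    """
    missing = [r.pathway_id for r in enrichment if r.pathway_id not in scores]
    if missing:
        raise PathwayError(f"pathways without symptom scores: {missing[:5]}")
    by_enrich = sorted(enrichment, key=lambda r: (-r.enrichment_score, r.pathway_id))
    enrich_rank = {r.pathway_id: i + 1 for i, r in enumerate(by_enrich)}
    by_sym = sorted(enrichment, key=lambda r: (-scores[r.pathway_id], r.pathway_id))
    sym_rank = {r.pathway_id: i + 1 for i, r in enumerate(by_sym)}
    rank_sum = {
        r.pathway_id: enrich_rank[r.pathway_id] + sym_rank[r.pathway_id]
        for r in enrichment
    }
    ordered = sorted(
        enrichment,
        key=lambda r: (rank_sum[r.pathway_id], -r.enrichment_score, r.pathway_id),
    )
    covered = {}
    if links is not None:
        for r in enrichment:
            covered[r.pathway_id] = frozenset(
                s for pid, s in links if pid == r.pathway_id
            )
    return [
        PathwayRank(
            pathway_id=r.pathway_id,
            enrichment_score=r.enrichment_score,
            symptom_score=scores[r.pathway_id],
            combined_rank=i + 1,
            covered_symptoms=covered.get(r.pathway_id, frozenset()),
        )
        for i, r in enumerate(ordered)
    ]


def topk_coverage(
    ranking: list[PathwayRank],
    links: list[tuple[str, str]],
    symptoms: SymptomTable,
    k: int | None = None,
) -> tuple[list[str], frozenset[str], int, bool]:
    """Smallest top-of-ranking prefix whose linked symptoms cover the table.

    Returns (selected pathway ids, covered symptoms, k, full_coverage).  If
    ``k`` is given, that prefix and its coverage are returned instead.  When
    no prefix achieves full coverage the whole ranking is returned with
    ``full_coverage=False``.
    """
    if not ranking:
        raise PathwayError("empty ranking")
    target = set(symptoms.symptoms)
    link_map: dict[str, set[str]] = {}
    for pid, s in links:
        link_map.setdefault(pid, set()).add(s)
    if k is not None:
        chosen = [r.pathway_id for r in ranking[:k]]
        covered = frozenset().union(*(link_map.get(p, set()) for p in chosen)) \
            if chosen else frozenset()
        return chosen, frozenset(covered), k, set(covered) == target
    covered: set[str] = set()
    chosen = []
    for r in ranking:
        chosen.append(r.pathway_id)
        covered |= link_map.get(r.pathway_id, set())
        if covered == target:
            return chosen, frozenset(covered), len(chosen), True
    return chosen, frozenset(covered), len(chosen), False


def extract_pathway_members(
    selected_pathways: list[str],
    db: dict[str, tuple[str, set[str]]],
    met_selected: set[str],
    prot_selected: set[str],
) -> tuple[set[str], set[str]]:
    """Differential features belonging to any selected pathway, split by layer."""
    members: set[str] = set()
    for pid in selected_pathways:
        if pid in db:
            members |= db[pid][1]
    return met_selected & members, prot_selected & members
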