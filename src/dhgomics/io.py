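"""Readers and writers for the pipeline's text formats, plus packaged fixtures.

Formats
-------
* intensity matrices: TSV, first column ``feature_id``, one column per sample;
  a missing cell is an *empty string* (never 0, never a literal ``NA``)
* sample sheets: TSV with columns ``sample_id``, ``group``, ``cohort``
* pathway databases: GMT (``pathway_id<TAB>description<TAB>member...``)
* pathway-symptom links: TSV with columns ``pathway_id``, ``symptom``
  (optional third ``provenance`` column)

Fixtures
--------
Two tables transcribed from the source study ship inside the package: the 56
identified differential serum metabolites (with retention time, measured m/z,
adduct, elemental formula, database ids and regulation trend) and the 11-item
dampness-heat gout diagnostic symptom reference split into primary, secondary
and tongue-pulse categories.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix, MatrixError

ADDUCTS = ("[M+H]+", "[M-H]-")
SYMPTOM_CATEGORIES = ("primary", "secondary", "tongue_pulse")


class FixtureError(RuntimeError):
    """Packaged fixture failed an integrity check."""


@dataclass(frozen=True)
class CompoundRecord:
    """One identified metabolite: ordinal id, chromatography and MS identity."""

    id: str
    retention_time: float
    name: str
    measured_mz: float
    adduct: str
    formula: str
    hmdb_id: str
    kegg_id: str  # empty string when the table prints none
    trend: str  # "Up" or "Down" in cases relative to controls

    def __post_init__(self) -> None:
        if self.adduct not in ADDUCTS:
            raise FixtureError(f"{self.id}: unknown adduct {self.adduct!r}")
        if self.trend not in ("Up", "Down"):
            raise FixtureError(f"{self.id}: unknown trend {self.trend!r}")
        if not self.measured_mz > 0:
            raise FixtureError(f"{self.id}: non-positive m/z")


@dataclass(frozen=True)
class SymptomTable:
    """Diagnostic symptom items tagged primary / secondary / tongue_pulse."""

    entries: tuple[tuple[str, str], ...]  # (symptom, category)

    def __post_init__(self) -> None:
        names = [s for s, _ in self.entries]
        if len(names) != len(set(names)):
            raise FixtureError("duplicate symptom names")
        bad = {c for _, c in self.entries} - set(SYMPTOM_CATEGORIES)
        if bad:
            raise FixtureError(f"unknown symptom categories: {sorted(bad)}")

    @property
    def symptoms(self) -> list[str]:
        return [s for s, _ in self.entries]

    def category(self, symptom: str) -> str:
        for s, c in self.entries:
            if s == symptom:
                return c
        raise KeyError(symptom)

    def by_category(self, category: str) -> list[str]:
        return [s for s, c in self.entries if c == category]


def _data_path(name: str):
    return resources.files("dhgomics.data").joinpath(name)


def load_table2_fixture() -> list[CompoundRecord]:
    """Load the packaged differential-metabolite identification table."""
    text = _data_path("table2_metabolites.tsv").read_text()
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    records = [
        CompoundRecord(
            id=row["id"],
            retention_time=float(row["rt"]),
            name=row["name"],
            measured_mz=float(row["mz"]),
            adduct=row["adduct"],
            formula=row["formula"],
            hmdb_id=row["hmdb_id"],
            kegg_id=row["kegg_id"],
            trend=row["trend"],
        )
        for row in reader
    ]
    if len(records) != len({r.id for r in records}):
        raise FixtureError("duplicate compound ids in metabolite fixture")
    return records


def load_table3_fixture() -> SymptomTable:
    """Load the packaged dampness-heat gout symptom reference table."""
    text = _data_path("table3_symptoms.tsv").read_text()
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    return SymptomTable(tuple((row["symptom"], row["category"]) for row in reader))


# ---------------------------------------------------------------------------
# intensity matrix TSV dialect
# ---------------------------------------------------------------------------

def write_intensity_tsv(m: IntensityMatrix, path, sample_sheet_path) -> None:
    """Write matrix + sample sheet; missing cells become empty strings."""
    df = m.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep="")
    sheet = m.samples.copy()
    sheet.index.name = "sample_id"
    sheet.to_csv(sample_sheet_path, sep="\t")


def read_intensity_tsv(path, sample_sheet_path) -> IntensityMatrix:
    """Read a matrix TSV and its sample sheet into an IntensityMatrix.

    Empty cells are recorded as missing (NaN); any other non-numeric cell is
    a parse error reported with its row and column.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        for idx, cell in raw[col].items():
            if cell == "":
                values.at[idx, col] = np.nan
            else:
                try:
                    values.at[idx, col] = float(cell)
                except ValueError as exc:
                    raise MatrixError(
                        f"non-numeric cell at feature {idx!r}, sample {col!r}: "
                        f"{cell!r}"
                    ) from exc
    sheet = pd.read_csv(sample_sheet_path, sep="\t", index_col=0, dtype=str)
    missing = [c for c in values.columns if c not in sheet.index]
    if missing:
        raise MatrixError(f"sample sheet missing samples: {missing}")
    return IntensityMatrix(values, sheet)


# ---------------------------------------------------------------------------
# GMT pathway databases and link tables
# ---------------------------------------------------------------------------

def write_gmt(pathways: dict[str, tuple[str, set[str]]], path) -> None:
    """Write ``{pathway_id: (description, member set)}`` as GMT lines."""
    with open(path, "w") as fh:
        for pid in sorted(pathways):
            desc, members = pathways[pid]
            fh.write("\t".join([pid, desc, *sorted(members)]) + "\n")


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    pathways: dict[str, tuple[str, set[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise MatrixError(f"{path}:{lineno}: GMT line needs id, desc, members")
        pid, desc, *members = parts
        if pid in pathways:
            raise MatrixError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
        pathways[pid] = (desc, set(members))
    return pathways


def write_links_tsv(edges: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_id\tsymptom\n")
        for pid, symptom in edges:
            fh.write(f"{pid}\t{symptom}\n")


def read_links_tsv(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(df[["pathway_id", "symptom"]].itertuples(index=False, name=None))


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
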