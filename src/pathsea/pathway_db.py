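"""Custom pathway databases and feature -> entry mapping.

A database is a flat CSV (one row per entry-pathway membership) of
compound and gene entries grouped into pathways.  Compound entries carry a
monoisotopic mass, either given directly or computed from the molecular
formula; MS features are matched to compounds by corrected mass within a
tolerance, transcript features to genes by case-insensitive exact id.

Because accurate-mass matching cannot distinguish isobaric compounds, the
entry-based enrichment test does not count compounds individually: entries
whose masses form a single-linkage chain with gaps at most the mass
tolerance are collapsed into one "mass cluster" counting unit.  Gene
entries are never mass-clustered.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .adduct import FeatureCorrection
from .defaults import MASS_TOL

__all__ = [
    "MONOISOTOPIC_MASSES",
    "formula_mass",
    "PathwayDatabase",
    "read_custom_db",
    "write_custom_db",
    "FeatureEntryMap",
    "map_features",
    "EntryMassCluster",
    "mass_cluster_entries",
]

#: Monoisotopic atomic masses (Da) of the elements accepted in formulas.
#: User-extensible: pass an augmented mapping to :func:`formula_mass`.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(
    formula: str, masses: Mapping[str, float] | None = None
) -> float:
    """Monoisotopic mass of a molecular formula such as ``C6H12O6``."""
    masses = masses or MONOISOTOPIC_MASSES
    formula = formula.strip()
    if not formula:
        raise ValueError("empty molecular formula")
    pos = 0
    total = 0.0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = m.end()
        element, count = m.group(1), int(m.group(2) or 1)
        if element not in masses:
            raise ValueError(f"unknown element symbol {element!r} in {formula!r}")
        total += masses[element] * count
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
    return total


@dataclass
class PathwayDatabase:
    """Entries (compounds with masses, genes) and their pathway memberships.

    ``entries`` columns: entry_id, entry_name, entry_type, formula, mass.
    ``pathways`` columns: pathway_id, pathway_name, database_label.
    ``memberships`` columns: pathway_id, entry_id.
    """

    entries: pd.DataFrame
    pathways: pd.DataFrame
    memberships: pd.DataFrame

    def __post_init__(self) -> None:
        if self.entries["entry_id"].duplicated().any():
            dup = self.entries.loc[self.entries["entry_id"].duplicated(), "entry_id"].iloc[0]
            raise ValueError(f"duplicate entry id {dup!r}")
        bad_type = ~self.entries["entry_type"].isin(["compound", "gene"])
        if bad_type.any():
            raise ValueError(
                f"unknown entry type {self.entries.loc[bad_type, 'entry_type'].iloc[0]!r}"
            )
        known = set(self.entries["entry_id"])
        unknown = set(self.memberships["entry_id"]) - known
        if unknown:
            raise ValueError(f"pathway references unknown entry {sorted(unknown)[0]!r}")
        compounds = self.entries["entry_type"] == "compound"
        no_mass = compounds & ~np.isfinite(self.entries["mass"].to_numpy(float))
        if no_mass.any():
            raise ValueError(
                "compound entry "
                f"{self.entries.loc[no_mass, 'entry_id'].iloc[0]!r} has neither "
                "mass nor formula"
            )

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(self.pathways["pathway_id"])

    def members(self, pathway_id: str) -> tuple[str, ...]:
        sel = self.memberships["pathway_id"] == pathway_id
        return tuple(self.memberships.loc[sel, "entry_id"])

    def entry_count(self, pathway_id: str) -> int:
        return int((self.memberships["pathway_id"] == pathway_id).sum())

    def compound_masses(self) -> dict[str, float]:
        sel = self.entries["entry_type"] == "compound"
        return dict(
            zip(self.entries.loc[sel, "entry_id"], self.entries.loc[sel, "mass"])
        )

    def gene_ids(self) -> tuple[str, ...]:
        sel = self.entries["entry_type"] == "gene"
        return tuple(self.entries.loc[sel, "entry_id"])

    def restrict_pathways(self, pathway_ids: Iterable[str]) -> "PathwayDatabase":
        """Database limited to the given pathways and the entries they reference."""
        keep = set(pathway_ids)
        pw = self.pathways[self.pathways["pathway_id"].isin(keep)].reset_index(drop=True)
        mem = self.memberships[self.memberships["pathway_id"].isin(keep)].reset_index(
            drop=True
        )
        ent = self.entries[self.entries["entry_id"].isin(set(mem["entry_id"]))]
        return PathwayDatabase(
            entries=ent.reset_index(drop=True), pathways=pw, memberships=mem
        )


def read_custom_db(
    path: str | Path, masses: Mapping[str, float] | None = None
) -> PathwayDatabase:
    """Read a flat membership CSV into a validated :class:`PathwayDatabase`.

    Columns: entry_id, entry_name, entry_type, formula, mass, pathway_id,
    pathway_name, database_label.  A compound's mass is computed from its
    formula when the mass field is empty.
    """
    df = pd.read_csv(path, dtype={"entry_id": str, "pathway_id": str})
    required = {
        "entry_id",
        "entry_name",
        "entry_type",
        "formula",
        "mass",
        "pathway_id",
        "pathway_name",
        "database_label",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"database CSV missing columns: {sorted(missing)}")

    ent_rows = []
    for eid, grp in df.groupby("entry_id", sort=False):
        types = set(grp["entry_type"])
        if len(types) != 1:
            raise ValueError(f"entry {eid!r} has conflicting types {sorted(types)}")
        etype = types.pop()
        formula = next(
            (f for f in grp["formula"] if isinstance(f, str) and f.strip()), ""
        )
        mass_vals = [m for m in grp["mass"].to_numpy(float) if math.isfinite(m)]
        if mass_vals:
            mass = float(mass_vals[0])
        elif etype == "compound" and formula:
            mass = formula_mass(formula, masses)
        else:
            mass = math.nan
        if etype == "compound" and not math.isfinite(mass):
            raise ValueError(
                f"compound entry {eid!r} has neither mass nor formula"
            )
        ent_rows.append(
            {
                "entry_id": eid,
                "entry_name": str(grp["entry_name"].iloc[0]),
                "entry_type": etype,
                "formula": formula,
                "mass": mass,
            }
        )
    pw = (
        df[["pathway_id", "pathway_name", "database_label"]]
        .drop_duplicates("pathway_id")
        .reset_index(drop=True)
    )
    mem = df[["pathway_id", "entry_id"]].drop_duplicates().reset_index(drop=True)
    return PathwayDatabase(
        entries=pd.DataFrame(ent_rows), pathways=pw, memberships=mem
    )


def write_custom_db(db: PathwayDatabase, path: str | Path) -> None:
    """Write the database back to the flat membership CSV dialect."""
    ent = db.entries.set_index("entry_id")
    pw = db.pathways.set_index("pathway_id")
    rows = []
    for _, r in db.memberships.iterrows():
        e = ent.loc[r["entry_id"]]
        p = pw.loc[r["pathway_id"]]
        rows.append(
            {
                "entry_id": r["entry_id"],
                "entry_name": e["entry_name"],
                "entry_type": e["entry_type"],
                "formula": e["formula"],
                "mass": e["mass"],
                "pathway_id": r["pathway_id"],
                "pathway_name": p["pathway_name"],
                "database_label": p["database_label"],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class FeatureEntryMap:
    """Feature <-> entry assignments with match provenance.

    ``table`` columns: feature_id, entry_id, match_type (mass|id),
    mass_error (Da; 0 for id matches).  A feature may match several entries
    and an entry several features; the ambiguity is preserved.
    """

    table: pd.DataFrame

    def entries_of(self, feature_id: str) -> tuple[str, ...]:
        sel = self.table["feature_id"] == feature_id
        return tuple(self.table.loc[sel, "entry_id"])

    def features_of(self, entry_id: str) -> tuple[str, ...]:
        sel = self.table["entry_id"] == entry_id
        return tuple(self.table.loc[sel, "feature_id"])

    def matched_entries(self) -> set[str]:
        return set(self.table["entry_id"])

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def map_features(
    db: PathwayDatabase,
    corrected: FeatureCorrection | Mapping[str, float] | None = None,
    gene_features: Sequence[str] | Mapping[str, str] | None = None,
    mass_tol: float = MASS_TOL,
) -> FeatureEntryMap:
    """Match MS features to compounds by mass and transcript features to genes by id.

    ``corrected`` supplies corrected monoisotopic masses per MS feature
    (a :class:`FeatureCorrection` or a plain mapping).  ``gene_features``
    is either a sequence of feature ids that double as gene ids, or a
    mapping feature id -> gene id.  All matches within tolerance are
    returned.
    """
    rows = []
    if corrected is not None:
        masses = (
            corrected.corrected_masses()
            if isinstance(corrected, FeatureCorrection)
            else dict(corrected)
        )
        comp = db.entries[db.entries["entry_type"] == "compound"]
        emass = comp["mass"].to_numpy(float)
        eids = comp["entry_id"].to_numpy()
        for fid, m in masses.items():
            err = emass - m
            hit = np.abs(err) <= mass_tol
            for eid, e in zip(eids[hit], err[hit]):
                rows.append(
                    {
                        "feature_id": fid,
                        "entry_id": eid,
                        "match_type": "mass",
                        "mass_error": float(e),
                    }
                )
    if gene_features is not None:
        if isinstance(gene_features, Mapping):
            pairs = list(gene_features.items())
        else:
            pairs = [(f, f) for f in gene_features]
        by_lower = {}
        for gid in db.gene_ids():
            by_lower.setdefault(gid.lower(), []).append(gid)
        for fid, gid in pairs:
            for eid in by_lower.get(gid.lower(), []):
                rows.append(
                    {
                        "feature_id": fid,
                        "entry_id": eid,
                        "match_type": "id",
                        "mass_error": 0.0,
                    }
                )
    table = pd.DataFrame(
        rows, columns=["feature_id", "entry_id", "match_type", "mass_error"]
    )
    return FeatureEntryMap(table=table)


@dataclass(frozen=True)
class EntryMassCluster:
    """Isobaric-compound counting unit: a single-linkage chain of entry masses."""

    cluster_id: int
    entry_ids: tuple[str, ...]
    mass_min: float
    mass_max: float


def mass_cluster_entries(
    db: PathwayDatabase, tol: float = MASS_TOL
) -> list[EntryMassCluster]:
    """Single-linkage clusters of compound entries over sorted masses.

    Consecutive sorted masses with a gap <= ``tol`` chain into one cluster;
    gene entries are never clustered (each gene is its own counting unit in
    enrichment tests and is not returned here).
    """
    masses = db.compound_masses()
    if not masses:
        return []
    items = sorted(masses.items(), key=lambda kv: (kv[1], kv[0]))
    clusters: list[EntryMassCluster] = []
    start = 0
    vals = [m for _, m in items]
    for i in range(1, len(items) + 1):
        if i == len(items) or vals[i] - vals[i - 1] > tol:
            chunk = items[start:i]
            clusters.append(
                EntryMassCluster(
                    cluster_id=len(clusters),
                    entry_ids=tuple(e for e, _ in chunk),
                    mass_min=chunk[0][1],
                    mass_max=chunk[-1][1],
                )
            )
            start = i
    return clusters
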