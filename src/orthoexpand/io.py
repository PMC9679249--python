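"""Readers and writers for every on-disk format the analysis touches.

Formats
-------
gene counts
    Tab-separated in the Orthofinder ``Orthogroups.GeneCount.tsv`` dialect:
    header row mandatory, first column is the orthogroup ID, one column per
    species, optional trailing ``Total`` column (dropped on read and never
    used downstream). Missing cells are not allowed; absence is encoded
    as 0.
species roles
    YAML mapping with keys ``focal`` (string), ``sisters`` (exactly two
    strings) and ``outgroups`` (one or more strings). Names are matched
    exactly and case-sensitively against the counts matrix to avoid silent
    mis-joins.
annotations
    Tab-separated with header ``protein_id  orthogroup_id  namespace
    accession  description``; namespace is one of InterPro, Pfam, GO,
    SignalP. A protein may carry any number of rows.
species tree
    Newick; leaves are species names. Used only for validation and output
    ordering.
classification / domain summary
    Tab-separated outputs with ``#``-prefixed comment headers echoing the
    thresholds, so every result file is self-describing.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import dendropy
import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .core import ExpansionRecord, Thresholds
    from .domains import DomainSummary

__all__ = [
    "NAMESPACES",
    "OrthogroupCounts",
    "SpeciesRoles",
    "AnnotationTable",
    "read_gene_counts",
    "write_gene_counts",
    "read_species_roles",
    "write_species_roles",
    "read_annotations",
    "write_annotations",
    "read_species_tree",
    "write_species_tree",
    "write_classification",
    "read_classification",
    "write_domain_summary",
    "read_domain_summary",
]

#: Allowed annotation namespaces.
NAMESPACES: tuple[str, ...] = ("InterPro", "Pfam", "GO", "SignalP")

_ANNOTATION_COLUMNS = [
    "protein_id",
    "orthogroup_id",
    "namespace",
    "accession",
    "description",
]


@dataclass(frozen=True)
class OrthogroupCounts:
    """Orthogroup x species matrix of non-negative gene copy counts.

    ``table`` is a pandas DataFrame with the orthogroup IDs as index and
    one integer column per species. Invariants (checked on construction):
    counts >= 0, no duplicate orthogroup IDs or species names, every row
    has at least one positive count.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dupes = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate orthogroup IDs: {dupes[:5]}")
        if t.columns.has_duplicates:
            dupes = t.columns[t.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species names: {dupes[:5]}")
        if len(t.columns) == 0:
            raise ValueError("counts matrix has no species columns")
        if len(t) == 0:
            raise ValueError("no orthogroups: counts matrix is empty")
        if not all(pd.api.types.is_integer_dtype(d) for d in t.dtypes):
            raise ValueError("counts must be integers")
        if (t.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (t.to_numpy().sum(axis=1) == 0).any():
            empty = t.index[t.sum(axis=1) == 0].tolist()
            raise ValueError(
                f"orthogroups with zero genes in every species: {empty[:5]}"
            )

    @property
    def orthogroup_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def species_names(self) -> list[str]:
        return self.table.columns.tolist()

    @property
    def counts(self) -> np.ndarray:
        return self.table.to_numpy()

    @property
    def n_orthogroups(self) -> int:
        return len(self.table)

    def row(self, orthogroup_id: str) -> Mapping[str, int]:
        """Species -> count mapping for one orthogroup."""
        if orthogroup_id not in self.table.index:
            raise KeyError(f"unknown orthogroup {orthogroup_id!r}")
        return self.table.loc[orthogroup_id].to_dict()


@dataclass(frozen=True)
class SpeciesRoles:
    """Partition of the species panel into focal / sister pair / outgroups."""

    focal: str
    sisters: tuple[str, str]
    outgroups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sisters) != 2:
            raise ValueError(
                f"exactly two sister species required, got {len(self.sisters)}"
            )
        if len(self.outgroups) < 1:
            raise ValueError("at least one outgroup species required")
        names = [self.focal, *self.sisters, *self.outgroups]
        seen: set[str] = set()
        for name in names:
            if name in seen:
                raise ValueError(
                    f"species {name!r} appears in more than one role"
                )
            seen.add(name)

    @property
    def all_species(self) -> list[str]:
        """Every species in the panel, focal first."""
        return [self.focal, *self.sisters, *self.outgroups]

    @property
    def n_species(self) -> int:
        return 3 + len(self.outgroups)

    def validate_against(self, counts: OrthogroupCounts) -> None:
        """Raise if any role names a species absent from the matrix."""
        missing = [
            sp for sp in self.all_species if sp not in counts.table.columns
        ]
        if missing:
            raise ValueError(
                f"species named in roles but absent from counts matrix: {missing}"
            )


@dataclass(frozen=True)
class AnnotationTable:
    """Per-protein functional labels, grouped by orthogroup on demand.

    ``table`` columns: protein_id, orthogroup_id, namespace, accession,
    description. A protein may carry multiple rows (several domains,
    several namespaces).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table lacks columns: {missing}")
        bad_ns = set(self.table["namespace"]) - set(NAMESPACES)
        if bad_ns:
            raise ValueError(
                f"unknown namespace {sorted(bad_ns)}; allowed: {list(NAMESPACES)}"
            )
        if (self.table["accession"].astype(str).str.len() == 0).any():
            raise ValueError("empty accession in annotation table")

    @property
    def orthogroups(self) -> set[str]:
        return set(self.table["orthogroup_id"])

    def rows_for(
        self, orthogroup_id: str, namespace: str | None = None
    ) -> pd.DataFrame:
        sub = self.table[self.table["orthogroup_id"] == orthogroup_id]
        if namespace is not None:
            sub = sub[sub["namespace"] == namespace]
        return sub


# ---------------------------------------------------------------------------
# gene counts


def read_gene_counts(path: str | Path, drop_total: bool = True) -> OrthogroupCounts:
    """Read an Orthofinder-dialect gene-count TSV.

    A column literally named ``Total`` is dropped (Orthofinder appends it;
    it must never influence downstream numbers). Cells must parse as
    non-negative integers; violations raise with the offending row and
    column named.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: need an ID column plus species columns")
    id_col = raw.columns[0]
    if raw.empty:
        raise ValueError(f"{path}: no orthogroups")
    ids = raw[id_col]
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate orthogroup ID {dupes[0]!r}")
    data = raw.set_index(id_col)
    if drop_total and "Total" in data.columns:
        data = data.drop(columns=["Total"])
    parsed = {}
    for col in data.columns:
        numeric = pd.to_numeric(data[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row_id = data.index[bad][0]
            raise ValueError(
                f"{path}: non-integer count at row {row_id!r}, column {col!r}: "
                f"{data.loc[row_id, col]!r}"
            )
        if ((numeric % 1) != 0).any():
            row_id = data.index[(numeric % 1) != 0][0]
            raise ValueError(
                f"{path}: non-integer count at row {row_id!r}, column {col!r}"
            )
        if (numeric < 0).any():
            row_id = data.index[numeric < 0][0]
            raise ValueError(
                f"{path}: negative count at row {row_id!r}, column {col!r}"
            )
        parsed[col] = numeric.astype(int)
    table = pd.DataFrame(parsed, index=data.index)
    table.index.name = id_col
    return OrthogroupCounts(table)


def write_gene_counts(
    counts: OrthogroupCounts, path: str | Path, total: bool = False
) -> None:
    """Write a counts matrix in the same dialect; ``total`` appends the
    Orthofinder-style row-sum column."""
    table = counts.table.copy()
    if total:
        table["Total"] = table.sum(axis=1)
    if table.index.name is None:
        table.index.name = "Orthogroup"
    table.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# species roles


def read_species_roles(
    path: str | Path, counts: OrthogroupCounts | None = None
) -> SpeciesRoles:
    """Read and validate a roles config; cross-check against ``counts`` if given."""
    path = Path(path)
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: roles config must be a mapping")
    for key in ("focal", "sisters", "outgroups"):
        if key not in raw:
            raise ValueError(f"{path}: roles config lacks key {key!r}")
    sisters = raw["sisters"]
    outgroups = raw["outgroups"]
    if not isinstance(sisters, list) or len(sisters) != 2:
        raise ValueError(
            f"{path}: 'sisters' must list exactly two species, got {sisters!r}"
        )
    if not isinstance(outgroups, list) or len(outgroups) < 1:
        raise ValueError(f"{path}: 'outgroups' must list at least one species")
    roles = SpeciesRoles(
        focal=str(raw["focal"]),
        sisters=(str(sisters[0]), str(sisters[1])),
        outgroups=tuple(str(s) for s in outgroups),
    )
    if counts is not None:
        roles.validate_against(counts)
    return roles


def write_species_roles(roles: SpeciesRoles, path: str | Path) -> None:
    payload = {
        "focal": roles.focal,
        "sisters": list(roles.sisters),
        "outgroups": list(roles.outgroups),
    }
    with open(path, "w") as handle:
        yaml.safe_dump(payload, handle, sort_keys=False)


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a per-protein annotation TSV, validating namespaces and IDs."""
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", dtype=str, header=0, keep_default_na=False
    )
    missing = [c for c in _ANNOTATION_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: annotation table lacks columns {missing}")
    # +2: header line plus 1-based numbering
    for idx, og in enumerate(raw["orthogroup_id"]):
        if not og:
            raise ValueError(
                f"{path}, line {idx + 2}: protein "
                f"{raw['protein_id'].iloc[idx]!r} lacks an orthogroup ID"
            )
    bad_ns = raw.index[~raw["namespace"].isin(NAMESPACES)]
    if len(bad_ns) > 0:
        i = bad_ns[0]
        raise ValueError(
            f"{path}, line {i + 2}: unknown namespace "
            f"{raw['namespace'].iloc[i]!r}; allowed: {list(NAMESPACES)}"
        )
    return AnnotationTable(raw[_ANNOTATION_COLUMNS].copy())


def write_annotations(annotations: AnnotationTable, path: str | Path) -> None:
    annotations.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# species tree


def read_species_tree(
    path: str | Path, roles: SpeciesRoles | None = None
) -> dendropy.Tree:
    """Read a Newick species tree; check leaf uniqueness and role coverage."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("species tree has duplicate leaf labels")
    if roles is not None:
        # dendropy converts underscores to spaces per newick convention
        normalized = {lbl.replace(" ", "_") for lbl in labels} | set(labels)
        missing = [sp for sp in roles.all_species if sp not in normalized]
        if missing:
            raise ValueError(
                f"species named in roles but absent from tree: {missing}"
            )
    return tree


def write_species_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# classification table

_CLASSIFICATION_COLUMNS = [
    "orthogroup_id",
    "category",
    "passed_screen",
    "focal_count",
    "sister_count_1",
    "sister_count_2",
    "outgroup_counts",
    "n_represented",
    "fc_focal_vs_others",
    "fc_focal_vs_sisters",
    "fc_ostreidae_vs_outgroups",
]


def _fmt_float(value: float) -> str:
    if math.isinf(value):
        return "inf"
    return f"{value:.6f}"


def _comment_header(thresholds: "Thresholds | None") -> list[str]:
    if thresholds is None:
        return []
    return [
        f"# screen_fold={thresholds.screen_fold}",
        f"# category_fold={thresholds.category_fold}",
        f"# min_represented={thresholds.min_represented}",
        f"# ancestral_mode={thresholds.ancestral_mode}",
    ]


def write_classification(
    records: Iterable["ExpansionRecord"],
    path: str | Path,
    thresholds: "Thresholds | None" = None,
) -> None:
    """Write the per-orthogroup classification table.

    One row per orthogroup, stable-sorted by orthogroup ID, deterministic
    column order, fold changes to six decimals (``inf`` for clade-absent
    denominators). Zero records produce a header-only file.
    """
    rows = sorted(records, key=lambda r: r.orthogroup_id)
    lines = _comment_header(thresholds)
    lines.append("\t".join(_CLASSIFICATION_COLUMNS))
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r.orthogroup_id,
                    r.category,
                    str(r.passed_screen),
                    str(r.focal_count),
                    str(r.sister_counts[0]),
                    str(r.sister_counts[1]),
                    ";".join(str(c) for c in r.outgroup_counts),
                    str(r.n_represented),
                    _fmt_float(r.fc_focal_vs_others),
                    _fmt_float(r.fc_focal_vs_sisters),
                    _fmt_float(r.fc_ostreidae_vs_outgroups),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_classification(path: str | Path) -> list["ExpansionRecord"]:
    """Read a classification table back into records."""
    from .core import ExpansionRecord

    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=0)
    missing = [c for c in _CLASSIFICATION_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: classification table lacks columns {missing}")
    records = []
    for _, row in raw.iterrows():
        records.append(
            ExpansionRecord(
                orthogroup_id=row["orthogroup_id"],
                focal_count=int(row["focal_count"]),
                sister_counts=(
                    int(row["sister_count_1"]),
                    int(row["sister_count_2"]),
                ),
                outgroup_counts=tuple(
                    int(c) for c in row["outgroup_counts"].split(";")
                ),
                fc_focal_vs_others=float(row["fc_focal_vs_others"]),
                fc_focal_vs_sisters=float(row["fc_focal_vs_sisters"]),
                fc_ostreidae_vs_outgroups=float(
                    row["fc_ostreidae_vs_outgroups"]
                ),
                n_represented=int(row["n_represented"]),
                passed_screen=row["passed_screen"] == "True",
                category=row["category"],
            )
        )
    return records


# ---------------------------------------------------------------------------
# domain summary table


def write_domain_summary(
    summary: "DomainSummary",
    path: str | Path,
    thresholds: "Thresholds | None" = None,
) -> None:
    """Write the accession / description / n_families table with totals as
    comment headers."""
    lines = _comment_header(thresholds)
    lines.append(f"# namespace={summary.namespace}")
    lines.append(f"# n_expanded_families={summary.n_expanded_families}")
    lines.append(f"# n_annotated_families={summary.n_annotated_families}")
    lines.append("\t".join(["accession", "description", "n_families"]))
    for row in summary.table.itertuples(index=False):
        lines.append(f"{row.accession}\t{row.description}\t{row.n_families}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_domain_summary(path: str | Path) -> pd.DataFrame:
    """Read back a domain-summary table (data rows only, comments skipped)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    df["n_families"] = df["n_families"].astype(int)
    return df
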