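"""Reduce per-protein annotations to per-family domains and summarize them.

Each orthogroup is assigned one "top" annotation per namespace: the modal
accession over its member proteins, ties broken by lexicographically
smallest accession (deterministic and order-independent). Counting each
expanded family once toward its single top domain partitions the expanded
families by representative domain; the summary then reports, per accession,
how many expanded families it represents. This is pure counting — no GO
graph propagation and no enrichment statistics.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Sequence
from dataclasses import dataclass

import pandas as pd

from .core import CATEGORIES, ExpansionRecord
from .io import AnnotationTable

__all__ = [
    "OrthogroupAnnotation",
    "DomainSummary",
    "top_annotation",
    "family_domains",
    "summarize_domains",
    "unique_domain_count",
    "signal_peptide_fraction",
]


@dataclass(frozen=True)
class OrthogroupAnnotation:
    """Top annotation of one orthogroup in one namespace.

    ``top_accession`` is None for an orthogroup with member proteins but no
    annotation rows in the requested namespace (the "unannotated" marker).
    ``support`` counts the member proteins carrying the top accession;
    ``n_proteins`` counts distinct member proteins seen in the annotation
    table for this orthogroup.
    """

    orthogroup_id: str
    namespace: str
    top_accession: str | None
    top_description: str
    support: int
    n_proteins: int

    @property
    def annotated(self) -> bool:
        return self.top_accession is not None


@dataclass(frozen=True)
class DomainSummary:
    """Per-accession family counts over the expanded orthogroups.

    ``table`` columns: accession, description, n_families — sorted by
    n_families descending, then accession ascending. Totals:
    ``n_expanded_families`` (families counted, annotated or not) and
    ``n_annotated_families`` (families contributing to the table).
    """

    namespace: str
    table: pd.DataFrame
    n_expanded_families: int
    n_annotated_families: int

    @property
    def n_unique_domains(self) -> int:
        """Number of accessions found in exactly one expanded family."""
        return int((self.table["n_families"] == 1).sum())

    def top(self, n: int) -> pd.DataFrame:
        """The top-``n`` rows for reporting; the full table is retained."""
        return self.table.head(n).copy()


def top_annotation(
    annotations: AnnotationTable, orthogroup_id: str, namespace: str
) -> OrthogroupAnnotation:
    """Modal accession over an orthogroup's member proteins.

    Support counts distinct proteins (a protein carrying the same accession
    twice counts once). Ties go to the lexicographically smallest
    accession, which makes the result independent of row order.

    Raises
    ------
    KeyError
        If the orthogroup has no rows at all in the annotation table.
    ValueError
        For a namespace outside the rankable set (SignalP is summarized
        separately, as a fraction).
    """
    if namespace not in ("InterPro", "Pfam", "GO"):
        raise ValueError(
            f"namespace must be one of InterPro/Pfam/GO, got {namespace!r}"
        )
    all_rows = annotations.rows_for(orthogroup_id)
    if len(all_rows) == 0:
        raise KeyError(f"unknown orthogroup {orthogroup_id!r}")
    n_proteins = all_rows["protein_id"].nunique()
    rows = all_rows[all_rows["namespace"] == namespace]
    if len(rows) == 0:
        return OrthogroupAnnotation(
            orthogroup_id, namespace, None, "", 0, n_proteins
        )
    support = Counter(
        rows[["protein_id", "accession"]]
        .drop_duplicates()["accession"]
        .tolist()
    )
    # modal accession; ties -> lexicographically smallest
    top_acc = min(support, key=lambda acc: (-support[acc], acc))
    desc = rows.loc[rows["accession"] == top_acc, "description"].iloc[0]
    return OrthogroupAnnotation(
        orthogroup_id, namespace, top_acc, desc, support[top_acc], n_proteins
    )


def family_domains(
    annotations: AnnotationTable, orthogroup_id: str, namespace: str
) -> list[tuple[str, str]]:
    """All distinct (accession, description) pairs a family's proteins carry.

    Alternative counting basis to the single-top convention: with it a
    family can contribute to several domains.
    """
    rows = annotations.rows_for(orthogroup_id, namespace)
    pairs = rows[["accession", "description"]].drop_duplicates("accession")
    return list(pairs.itertuples(index=False, name=None))


def summarize_domains(
    records: Sequence[ExpansionRecord],
    annotations: AnnotationTable,
    namespace: str = "InterPro",
    include_none: bool = False,
    multi_domain: bool = False,
) -> DomainSummary:
    """Count, per accession, the expanded families it represents.

    Only records with category i–vi are counted (``include_none`` adds the
    screen-passing-but-uncategorized rows). By default each family
    contributes once, to its top accession; ``multi_domain`` switches to
    counting every distinct accession the family carries.
    """
    wanted = set(CATEGORIES) | ({"none"} if include_none else set())
    expanded = [r for r in records if r.category in wanted]
    known = annotations.orthogroups
    tallies: Counter[str] = Counter()
    descriptions: dict[str, str] = {}
    n_annotated = 0
    for record in expanded:
        og = record.orthogroup_id
        if og not in known:
            continue
        if multi_domain:
            pairs = family_domains(annotations, og, namespace)
            if not pairs:
                continue
            n_annotated += 1
            for acc, desc in pairs:
                tallies[acc] += 1
                descriptions.setdefault(acc, desc)
        else:
            top = top_annotation(annotations, og, namespace)
            if not top.annotated:
                continue
            n_annotated += 1
            tallies[top.top_accession] += 1
            descriptions.setdefault(top.top_accession, top.top_description)
    table = pd.DataFrame(
        {
            "accession": list(tallies),
            "description": [descriptions[a] for a in tallies],
            "n_families": [tallies[a] for a in tallies],
        }
    )
    if len(table) == 0:
        table = pd.DataFrame(
            columns=["accession", "description", "n_families"]
        ).astype({"n_families": int})
    table = table.sort_values(
        ["n_families", "accession"], ascending=[False, True]
    ).reset_index(drop=True)
    return DomainSummary(
        namespace=namespace,
        table=table,
        n_expanded_families=len(expanded),
        n_annotated_families=n_annotated,
    )


def unique_domain_count(summary: DomainSummary) -> int:
    """Number of accessions unique to a single expanded family."""
    return summary.n_unique_domains


def signal_peptide_fraction(
    annotations: AnnotationTable, orthogroup_id: str
) -> float:
    """Fraction of a family's member proteins with a predicted signal peptide.

    SignalP hits are reported as a fraction rather than ranked like domain
    accessions. Returns 0.0 for a family absent from the table.
    """
    rows = annotations.rows_for(orthogroup_id)
    if len(rows) == 0:
        return 0.0
    n_proteins = rows["protein_id"].nunique()
    with_signal = rows.loc[
        rows["namespace"] == "SignalP", "protein_id"
    ].nunique()
    return with_signal / n_proteins
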