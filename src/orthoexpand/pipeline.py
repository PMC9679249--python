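"""End-to-end run: read inputs, classify, summarize domains, write report.

The report's totals are recomputed from the *written* TSVs rather than
carried in memory — a self-audit that runs on every invocation, so a
writer/reader drift can never silently produce an inconsistent report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io
from .core import CATEGORIES, LABELS, Thresholds, classify_all
from .domains import summarize_domains

__all__ = ["RunReport", "run_pipeline"]

logger = logging.getLogger("orthoexpand")


@dataclass
class RunReport:
    """Summary of one pipeline run, audited against the written outputs."""

    counts_path: str
    roles_path: str
    annotations_path: str | None
    thresholds: Thresholds
    tallies: dict[str, int]
    n_orthogroups: int
    n_screened_out: int
    n_expanded: int
    top_domains: list[dict] = field(default_factory=list)
    n_annotated_families: int = 0
    n_unique_domains: int = 0
    classification_file: str = ""
    domain_summary_file: str | None = None

    def validate(self) -> None:
        if self.n_expanded != sum(self.tallies[c] for c in CATEGORIES):
            raise ValueError("report inconsistent: n_expanded != sum of i–vi")
        if sum(self.tallies.values()) != self.n_orthogroups:
            raise ValueError("report inconsistent: tallies do not sum to total")

    def to_dict(self) -> dict:
        return {
            "inputs": {
                "counts": self.counts_path,
                "roles": self.roles_path,
                "annotations": self.annotations_path,
            },
            "thresholds": {
                "screen_fold": self.thresholds.screen_fold,
                "category_fold": self.thresholds.category_fold,
                "min_represented": self.thresholds.min_represented,
                "ancestral_mode": self.thresholds.ancestral_mode,
            },
            "tallies": self.tallies,
            "totals": {
                "n_orthogroups": self.n_orthogroups,
                "n_screened_out": self.n_screened_out,
                "n_expanded": self.n_expanded,
                "n_annotated_families": self.n_annotated_families,
                "n_unique_domains": self.n_unique_domains,
            },
            "top_domains": self.top_domains,
            "outputs": {
                "classification": self.classification_file,
                "domain_summary": self.domain_summary_file,
            },
        }


def run_pipeline(
    counts_path: str | Path,
    roles_path: str | Path,
    annotations_path: str | Path | None = None,
    tree_path: str | Path | None = None,
    thresholds: Thresholds | None = None,
    out_dir: str | Path = ".",
    namespace: str = "InterPro",
    top_n: int = 20,
    include_none: bool = False,
) -> RunReport:
    """Classify a counts matrix and, if annotations are given, summarize
    domains over the expanded families.

    Writes ``classification.tsv``, ``domain_summary.tsv`` (when
    annotations are supplied) and ``report.json`` into ``out_dir``.
    """
    thresholds = thresholds or Thresholds()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    counts = io.read_gene_counts(counts_path)
    roles = io.read_species_roles(roles_path, counts)
    if tree_path is not None:
        io.read_species_tree(tree_path, roles)  # validation only

    records, tally = classify_all(counts, roles, thresholds)
    classification_file = out_dir / "classification.tsv"
    io.write_classification(records, classification_file, thresholds)

    report = RunReport(
        counts_path=str(counts_path),
        roles_path=str(roles_path),
        annotations_path=str(annotations_path) if annotations_path else None,
        thresholds=thresholds,
        tallies=tally,
        n_orthogroups=counts.n_orthogroups,
        n_screened_out=tally["screened_out"],
        n_expanded=sum(tally[c] for c in CATEGORIES),
        classification_file=str(classification_file),
    )

    if annotations_path is not None:
        annotations = io.read_annotations(annotations_path)
        summary = summarize_domains(
            records, annotations, namespace=namespace, include_none=include_none
        )
        summary_file = out_dir / "domain_summary.tsv"
        io.write_domain_summary(summary, summary_file, thresholds)
        report.domain_summary_file = str(summary_file)
        report.n_annotated_families = summary.n_annotated_families
        report.n_unique_domains = summary.n_unique_domains
        report.top_domains = summary.top(top_n).to_dict(orient="records")

    _audit_against_outputs(report)
    report.validate()

    with open(out_dir / "report.json", "w") as handle:
        json.dump(report.to_dict(), handle, indent=2)

    logger.info("classified %d orthogroups", report.n_orthogroups)
    for label in LABELS:
        logger.info("  %-12s %6d", label, report.tallies[label])
    logger.info("expanded families (i–vi): %d", report.n_expanded)
    return report


def _audit_against_outputs(report: RunReport) -> None:
    """Recompute every total from the written files; raise on any drift."""
    written = io.read_classification(report.classification_file)
    tally = {label: 0 for label in LABELS}
    for record in written:
        tally[record.category] += 1
    if tally != report.tallies:
        raise RuntimeError(
            "self-audit failed: tallies recomputed from "
            f"{report.classification_file} disagree with the in-memory run"
        )
    if report.domain_summary_file is not None:
        table = io.read_domain_summary(report.domain_summary_file)
        if int(table["n_families"].sum()) != report.n_annotated_families:
            raise RuntimeError(
                "self-audit failed: domain-summary family counts disagree "
                "with the reported number of annotated families"
            )
        if int((table["n_families"] == 1).sum()) != report.n_unique_domains:
            raise RuntimeError(
                "self-audit failed: singleton-domain count disagrees"
            )
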