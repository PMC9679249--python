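"""Expansion screen and six-category phylogenetic classification.

The unit of analysis is one orthogroup: a vector of gene copy counts over a
fixed species panel partitioned into one *focal* species, a *sister pair*
(which together with the focal species forms the focal family, e.g. the
Ostreidae in an oyster analysis), and a set of *outgroup* species that serve
as the comparative baseline.

Two stages:

1. **Screen** — the focal fold change (focal copy number divided by the
   arithmetic mean copy number over all other species, zeros included) must
   strictly exceed ``screen_fold`` (default 2.5), and the orthogroup must be
   represented (count >= 1) in at least ``min_represented`` species (default
   8) *or* in both sister species ("sister rescue").

2. **Classification** — orthogroups passing the screen are assigned one of
   six categories describing where on the tree the expansion (or loss)
   happened:

   =====  ==========================================================
   label  meaning
   =====  ==========================================================
   i      ancestral family-wide expansion plus further focal expansion
   ii     ancestral family-wide expansion only
   iii    focal-lineage expansion, no ancestral expansion
   iv     family-specific genes (absent from outgroups), focal-expanded
   v      family-specific genes, present in all three members, no
          further focal expansion
   vi     absent from both sisters, expanded in the focal lineage
          (sister-lineage loss + focal expansion)
   =====  ==========================================================

   Rows passing the screen but matching no category are labelled ``none``;
   rows failing the screen are labelled ``screened_out``.

All fold-change comparisons are strict inequalities: a fold change exactly
equal to the threshold does not pass.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from .io import OrthogroupCounts, SpeciesRoles

__all__ = [
    "CATEGORIES",
    "LABELS",
    "Thresholds",
    "ExpansionRecord",
    "fold_change",
    "representation_filter",
    "screen",
    "classify",
    "classify_row",
    "classify_all",
]

#: The six expansion categories, in precedence-independent display order.
CATEGORIES: tuple[str, ...] = ("i", "ii", "iii", "iv", "v", "vi")

#: Every label an orthogroup can receive.
LABELS: tuple[str, ...] = CATEGORIES + ("none", "screened_out")

_ANCESTRAL_MODES = ("per_species", "clade_mean")


@dataclass(frozen=True)
class Thresholds:
    """Numeric knobs of the screen and classification.

    Parameters
    ----------
    screen_fold
        Focal-vs-all-others fold change a row must strictly exceed to pass
        the screen. Dimensionless ratio.
    category_fold
        Fold change used by every within-classification comparison
        (ancestral expansion, further focal expansion, focal vs outgroups).
    min_represented
        Minimum number of species with >= 1 gene for a row to pass the
        representation filter without sister rescue.
    total_species_expected
        Size of the species panel the defaults were chosen for; used only
        for validation.
    ancestral_mode
        How the "expanded in all three family members" predicate of
        categories i/ii is evaluated: ``per_species`` requires each of the
        three counts individually to exceed ``category_fold`` x mean
        outgroup count; ``clade_mean`` compares the mean of the three
        counts instead.
    """

    screen_fold: float = 2.5
    category_fold: float = 3.0
    min_represented: int = 8
    total_species_expected: int = 16
    ancestral_mode: str = "per_species"

    def __post_init__(self) -> None:
        if self.screen_fold <= 0:
            raise ValueError("screen_fold must be positive")
        if self.category_fold <= 0:
            raise ValueError("category_fold must be positive")
        if self.min_represented < 1:
            raise ValueError("min_represented must be a positive integer")
        if self.min_represented > self.total_species_expected:
            raise ValueError(
                "min_represented cannot exceed total_species_expected "
                f"({self.min_represented} > {self.total_species_expected})"
            )
        if self.ancestral_mode not in _ANCESTRAL_MODES:
            raise ValueError(
                f"ancestral_mode must be one of {_ANCESTRAL_MODES}, "
                f"got {self.ancestral_mode!r}"
            )


@dataclass(frozen=True)
class ExpansionRecord:
    """Per-orthogroup screen metrics and assigned category."""

    orthogroup_id: str
    focal_count: int
    sister_counts: tuple[int, int]
    outgroup_counts: tuple[int, ...]
    fc_focal_vs_others: float
    fc_focal_vs_sisters: float
    fc_ostreidae_vs_outgroups: float
    n_represented: int
    passed_screen: bool
    category: str

    def __post_init__(self) -> None:
        if self.category not in LABELS:
            raise ValueError(f"unknown category label {self.category!r}")
        if not self.passed_screen and self.category != "screened_out":
            raise ValueError("rows failing the screen must be screened_out")


def fold_change(
    numerator_count: float, denominator_counts: Sequence[float]
) -> float:
    """Fold change: ``numerator / mean(denominators)``, zeros included.

    Absent species count as 0 in the mean — this is what makes
    clade-specific families register as expanded. A zero mean with a
    positive numerator yields ``+inf`` (which compares greater than any
    finite threshold); 0/0 is defined as 0.

    Raises
    ------
    ValueError
        If ``denominator_counts`` is empty.
    """
    if len(denominator_counts) == 0:
        raise ValueError("fold_change requires a non-empty denominator set")
    mean = sum(denominator_counts) / len(denominator_counts)
    if mean == 0:
        return math.inf if numerator_count > 0 else 0.0
    return numerator_count / mean


def _split_row(
    row: Mapping[str, int], roles: SpeciesRoles
) -> tuple[int, tuple[int, int], tuple[int, ...]]:
    """Split a species->count mapping into (focal, sisters, outgroups).

    Raises ``KeyError`` naming the first species missing from the row.
    """
    try:
        focal = int(row[roles.focal])
        sisters = (int(row[roles.sisters[0]]), int(row[roles.sisters[1]]))
        outgroups = tuple(int(row[sp]) for sp in roles.outgroups)
    except KeyError as exc:
        raise KeyError(
            f"row is inconsistent with species roles: no count for {exc.args[0]!r}"
        ) from None
    return focal, sisters, outgroups


def representation_filter(
    row: Mapping[str, int], roles: SpeciesRoles, thr: Thresholds | None = None
) -> bool:
    """True iff >= ``min_represented`` species have a gene, or both sisters do.

    Representation by copy count (>= 1 gene) proxies presence in the gene
    tree. The sister-rescue clause keeps family-specific orthogroups
    (present only in focal + sisters) in the analysis even though they fall
    below the representation floor.
    """
    thr = thr or Thresholds()
    focal, sisters, outgroups = _split_row(row, roles)
    n_represented = sum(
        1 for c in (focal, *sisters, *outgroups) if c >= 1
    )
    return n_represented >= thr.min_represented or all(s >= 1 for s in sisters)


def screen(
    row: Mapping[str, int], roles: SpeciesRoles, thr: Thresholds | None = None
) -> tuple[bool, float]:
    """Apply the expansion screen to one row.

    Returns ``(passed, fc_focal_vs_others)`` where the fold change compares
    the focal count with the mean over *all* other species (sisters and
    outgroups pooled). Passing requires ``fc > screen_fold`` (strict) and
    the representation filter.
    """
    thr = thr or Thresholds()
    focal, sisters, outgroups = _split_row(row, roles)
    fc = fold_change(focal, [*sisters, *outgroups])
    passed = fc > thr.screen_fold and representation_filter(row, roles, thr)
    return passed, fc


def _categorize(
    focal: int,
    sisters: tuple[int, int],
    outgroups: tuple[int, ...],
    thr: Thresholds,
) -> str:
    """Assign a category to a row that already passed the screen.

    Precedence is fixed first-match: the absence-defined categories
    (iv/v, then vi) are tested before the fold-change categories (i, ii,
    iii), because clade-wide absences produce infinite fold changes that
    would otherwise be swallowed by the latter.
    """
    outgroups_absent = all(o == 0 for o in outgroups)
    sisters_absent = all(s == 0 for s in sisters)
    mean_out = sum(outgroups) / len(outgroups)

    further = fold_change(focal, sisters) > thr.category_fold
    if thr.ancestral_mode == "per_species":
        # "in all Ostreidae species": each member individually expanded
        ancestral = all(
            c > thr.category_fold * mean_out for c in (focal, *sisters)
        )
    else:
        ancestral = (
            fold_change((focal + sum(sisters)) / 3, outgroups)
            > thr.category_fold
        )
    focal_vs_out = fold_change(focal, outgroups) > thr.category_fold

    if outgroups_absent and not sisters_absent:
        if further:
            return "iv"
        # v requires genes retained in all three family members
        return "v" if all(s >= 1 for s in sisters) else "none"
    if sisters_absent and not outgroups_absent and focal_vs_out:
        return "vi"
    if ancestral and further:
        return "i"
    if ancestral:
        return "ii"
    if focal_vs_out:
        return "iii"
    return "none"


def classify(
    row: Mapping[str, int], roles: SpeciesRoles, thr: Thresholds | None = None
) -> str:
    """Category label for one row: screen, then classify.

    Convenience wrapper around :func:`classify_row` returning only the
    label (``screened_out`` if the row fails the screen).
    """
    return classify_row("", row, roles, thr).category


def classify_row(
    orthogroup_id: str,
    row: Mapping[str, int],
    roles: SpeciesRoles,
    thr: Thresholds | None = None,
) -> ExpansionRecord:
    """Full screen + classification of one row, with all metrics."""
    thr = thr or Thresholds()
    focal, sisters, outgroups = _split_row(row, roles)
    fc_others = fold_change(focal, [*sisters, *outgroups])
    fc_sisters = fold_change(focal, sisters)
    fc_clade = fold_change((focal + sum(sisters)) / 3, outgroups)
    n_represented = sum(1 for c in (focal, *sisters, *outgroups) if c >= 1)
    passed = fc_others > thr.screen_fold and (
        n_represented >= thr.min_represented or all(s >= 1 for s in sisters)
    )
    if passed:
        category = _categorize(focal, sisters, outgroups, thr)
    else:
        category = "screened_out"
    return ExpansionRecord(
        orthogroup_id=orthogroup_id,
        focal_count=focal,
        sister_counts=sisters,
        outgroup_counts=outgroups,
        fc_focal_vs_others=fc_others,
        fc_focal_vs_sisters=fc_sisters,
        fc_ostreidae_vs_outgroups=fc_clade,
        n_represented=n_represented,
        passed_screen=passed,
        category=category,
    )


def classify_all(
    counts: OrthogroupCounts,
    roles: SpeciesRoles,
    thr: Thresholds | None = None,
) -> tuple[list[ExpansionRecord], dict[str, int]]:
    """Classify every orthogroup in a counts matrix.

    Returns one :class:`ExpansionRecord` per row (input order preserved)
    and a tally mapping each of the eight labels to its count; the tally
    sums to the number of orthogroups.
    """
    thr = thr or Thresholds()
    roles.validate_against(counts)
    records: list[ExpansionRecord] = []
    tally: dict[str, int] = {label: 0 for label in LABELS}
    for og_id in counts.orthogroup_ids:
        record = classify_row(og_id, counts.row(og_id), roles, thr)
        records.append(record)
        tally[record.category] += 1
    return records, tally
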