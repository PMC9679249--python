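"""Synthetic orthogroup-evolution generator.

Emulates the comparative design the classifier assumes: a 16-species
bivalve-style panel (1 focal + 2 sisters + 13 outgroups), background
families with low copy numbers, planted expansions of each of the six
categories, presence/absence dropout, per-protein domain annotations, and
a species tree. Everything is reproducible bit-for-bit from
(config, seed).

Background copy numbers are shifted Poisson (``1 + Poisson(lambda - 1)``)
with per-species dropout, so the focal fold change is ~1 in expectation.
Planted rows are built from per-category templates and then
rejection-sampled against module-private predicates transcribed directly
from the classification rules (deliberately *not* the classifier code
path), so a generator bug and a classifier bug cannot cancel silently:
every planted row provably satisfies its own category's rule under the
default thresholds, making category recovery exact by construction rather
than statistical.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from typing import NamedTuple

import dendropy
import numpy as np
import pandas as pd

from .core import CATEGORIES, LABELS, ExpansionRecord
from .io import AnnotationTable, OrthogroupCounts, SpeciesRoles

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedData",
    "simulate",
    "truth_confusion",
    "recovery_rate",
]

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator.

    Parameters
    ----------
    n_outgroups
        Outgroup species count; default 13 gives the 16-species panel.
    n_background
        Number of non-expanded background families.
    planted
        Category label -> number of families to plant (e.g. ``{"iv": 20}``).
    baseline_lambda
        Mean background copy number (>= 1); counts are
        ``1 + Poisson(lambda - 1)`` before dropout.
    expansion_multiplier_range
        Fold-size range for planted expansions; its minimum must exceed
        the 3.0 category threshold or the config is unsatisfiable.
    dropout_prob
        Probability a background species count is zeroed (models lineage
        loss / annotation dropout).
    n_domains
        Size of the synthetic accession pool for annotations.
    annotation_prob
        Probability a background family is annotated at all (planted
        families always are, so the domain summary is exercised).
    seed
        Seed for the single numpy Generator behind all sampling.
    """

    n_outgroups: int = 13
    n_background: int = 500
    planted: Mapping[str, int] = field(default_factory=dict)
    baseline_lambda: float = 1.2
    expansion_multiplier_range: tuple[float, float] = (4.0, 10.0)
    dropout_prob: float = 0.1
    n_domains: int = 40
    annotation_prob: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outgroups < 1:
            raise ValueError("need at least one outgroup species")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        if self.baseline_lambda < 1.0:
            raise ValueError("baseline_lambda must be >= 1 (shifted Poisson)")
        lo, hi = self.expansion_multiplier_range
        if not lo <= hi:
            raise ValueError("expansion_multiplier_range must be (lo, hi)")
        if lo <= 3.0:
            raise ValueError(
                "unsatisfiable config: expansion multipliers must exceed the "
                f"3-fold category threshold, got minimum {lo}"
            )
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be a probability")
        if not 0.0 <= self.annotation_prob <= 1.0:
            raise ValueError("annotation_prob must be a probability")
        bad = [c for c in self.planted if c not in CATEGORIES]
        if bad:
            raise ValueError(f"unknown planted categories: {bad}")
        if any(n < 0 for n in self.planted.values()):
            raise ValueError("planted counts must be >= 0")
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted label, realized fold size and assigned domain per orthogroup.

    ``table`` columns: orthogroup_id, label ("background" or i–vi),
    realized_fold (focal count / mean of all other counts), domain
    (assigned primary accession, empty if unannotated).
    """

    table: pd.DataFrame

    def label_of(self, orthogroup_id: str) -> str:
        sub = self.table.loc[
            self.table["orthogroup_id"] == orthogroup_id, "label"
        ]
        if len(sub) == 0:
            raise KeyError(f"unknown orthogroup {orthogroup_id!r}")
        return sub.iloc[0]

    @property
    def planted_ids(self) -> list[str]:
        return self.table.loc[
            self.table["label"] != "background", "orthogroup_id"
        ].tolist()


class SimulatedData(NamedTuple):
    counts: OrthogroupCounts
    annotations: AnnotationTable
    roles: SpeciesRoles
    tree: dendropy.Tree
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# rule predicates for rejection sampling (independent of core.classify)


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values)


def _ratio(num: float, values: Sequence[float]) -> float:
    m = _mean(values)
    if m == 0:
        return math.inf if num > 0 else 0.0
    return num / m


def _screen_ok(focal: int, sisters: Sequence[int], outgroups: Sequence[int]) -> bool:
    if _ratio(focal, [*sisters, *outgroups]) <= 2.5:
        return False
    represented = sum(1 for c in (focal, *sisters, *outgroups) if c >= 1)
    return represented >= 8 or min(sisters) >= 1


def _rule_satisfied(
    category: str, focal: int, sisters: Sequence[int], outgroups: Sequence[int]
) -> bool:
    """Does this vector satisfy its target category's rule text, and no
    earlier rule in the precedence order?"""
    if not _screen_ok(focal, sisters, outgroups):
        return False
    out_absent = all(o == 0 for o in outgroups)
    sis_absent = all(s == 0 for s in sisters)
    mean_out = _mean(outgroups)
    further = _ratio(focal, sisters) > 3.0
    ancestral = all(c > 3.0 * mean_out for c in (focal, *sisters))
    focal_vs_out = _ratio(focal, outgroups) > 3.0
    if category == "iv":
        return out_absent and not sis_absent and further
    if category == "v":
        return out_absent and min(sisters) >= 1 and not further
    if category == "vi":
        return sis_absent and not out_absent and focal_vs_out
    if out_absent or sis_absent:
        return False  # would be captured by iv/v/vi first
    if category == "i":
        return ancestral and further
    if category == "ii":
        return ancestral and not further
    if category == "iii":
        return focal_vs_out and not ancestral
    raise ValueError(f"unknown category {category!r}")


# ---------------------------------------------------------------------------
# sampling


def _background_counts(
    rng: np.random.Generator, n_species: int, cfg: SimulationConfig
) -> np.ndarray:
    """One background row: shifted Poisson with dropout, never all-zero."""
    for _ in range(_MAX_REDRAWS):
        counts = 1 + rng.poisson(cfg.baseline_lambda - 1.0, size=n_species)
        drop = rng.random(n_species) < cfg.dropout_prob
        counts = np.where(drop, 0, counts)
        if counts.sum() > 0:
            return counts.astype(int)
    raise RuntimeError("could not draw a non-empty background row")


def _baseline_one(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    return int(1 + rng.poisson(cfg.baseline_lambda - 1.0))


def _planted_counts(
    rng: np.random.Generator, category: str, cfg: SimulationConfig
) -> tuple[int, list[int], list[int]]:
    """Draw (focal, sisters, outgroups) for one planted family.

    Templates produce vectors near the target rule; rejection against
    :func:`_rule_satisfied` makes satisfaction exact.
    """
    lo, hi = cfg.expansion_multiplier_range
    for _ in range(_MAX_REDRAWS):
        m = rng.uniform(lo, hi)
        if category in ("iv", "v"):
            outgroups = [0] * cfg.n_outgroups
            if category == "iv":
                sisters = [int(rng.integers(1, 3)) for _ in range(2)]
                focal = max(1, round(m * _mean(sisters)))
            else:
                sisters = [_baseline_one(rng, cfg) for _ in range(2)]
                focal = max(1, round(rng.uniform(0.8, 2.0) * _mean(sisters)))
        elif category == "vi":
            sisters = [0, 0]
            outgroups = _outgroups_with_presence(rng, cfg, min_present=7)
            focal = max(1, round(m * _mean(outgroups)))
        elif category in ("i", "ii"):
            outgroups = _outgroups_with_presence(rng, cfg, min_present=1)
            mean_out = max(_mean(outgroups), 1e-9)
            m_anc = rng.uniform(lo, hi)
            sisters = [max(1, round(m_anc * mean_out)) for _ in range(2)]
            if category == "i":
                focal = max(1, round(m * _mean(sisters)))
            else:
                focal = max(1, round(rng.uniform(1.0, 2.5) * _mean(sisters)))
        elif category == "iii":
            outgroups = _outgroups_with_presence(rng, cfg, min_present=1)
            sisters = [
                0 if rng.random() < cfg.dropout_prob else _baseline_one(rng, cfg)
                for _ in range(2)
            ]
            focal = max(
                1, round(m * _mean([*sisters, *outgroups]))
            )
        else:
            raise ValueError(f"unknown category {category!r}")
        if _rule_satisfied(category, focal, sisters, outgroups):
            return focal, sisters, outgroups
    raise RuntimeError(
        f"rejection sampling failed for category {category!r} after "
        f"{_MAX_REDRAWS} draws"
    )


def _outgroups_with_presence(
    rng: np.random.Generator, cfg: SimulationConfig, min_present: int
) -> list[int]:
    for _ in range(_MAX_REDRAWS):
        counts = [
            0 if rng.random() < cfg.dropout_prob else _baseline_one(rng, cfg)
            for _ in range(cfg.n_outgroups)
        ]
        if sum(1 for c in counts if c >= 1) >= min_present:
            return counts
    raise RuntimeError("could not draw outgroup presence pattern")


# ---------------------------------------------------------------------------
# annotations


def _annotate_family(
    rng: np.random.Generator,
    orthogroup_id: str,
    n_proteins: int,
    primary: tuple[str, str],
    pool: list[tuple[str, str]],
    pfam_pool: list[tuple[str, str]],
    go_pool: list[tuple[str, str]],
    rows: list[tuple[str, str, str, str, str]],
) -> None:
    """Emit annotation rows for one family.

    Every member protein carries the family's primary InterPro accession,
    so the modal accession equals the assigned one by construction;
    secondary domains, Pfam/GO rows and SignalP flags are sprinkled on
    subsets to exercise grouping and the signal-peptide fraction.
    """
    acc, desc = primary
    for k in range(n_proteins):
        pid = f"{orthogroup_id}.p{k + 1:04d}"
        rows.append((pid, orthogroup_id, "InterPro", acc, desc))
        if n_proteins > 1 and rng.random() < 0.25:
            s_acc, s_desc = pool[rng.integers(len(pool))]
            if s_acc != acc:
                rows.append((pid, orthogroup_id, "InterPro", s_acc, s_desc))
        if rng.random() < 0.5:
            p_acc, p_desc = pfam_pool[rng.integers(len(pfam_pool))]
            rows.append((pid, orthogroup_id, "Pfam", p_acc, p_desc))
        if rng.random() < 0.3:
            g_acc, g_desc = go_pool[rng.integers(len(go_pool))]
            rows.append((pid, orthogroup_id, "GO", g_acc, g_desc))
        if rng.random() < 0.15:
            rows.append(
                (pid, orthogroup_id, "SignalP", "SignalP-euk", "signal peptide")
            )


# ---------------------------------------------------------------------------
# top level


def _species_panel(cfg: SimulationConfig) -> SpeciesRoles:
    return SpeciesRoles(
        focal="Ostrea_edulis",
        sisters=("Crassostrea_gigas", "Crassostrea_virginica"),
        outgroups=tuple(
            f"Bivalve_outgroup_{i + 1:02d}" for i in range(cfg.n_outgroups)
        ),
    )


def _ladder_tree(roles: SpeciesRoles) -> dendropy.Tree:
    core = f"({roles.focal},({roles.sisters[0]},{roles.sisters[1]}))"
    for outgroup in roles.outgroups:
        core = f"({core},{outgroup})"
    return dendropy.Tree.get(
        data=core + ";", schema="newick", preserve_underscores=True
    )


def simulate(config: SimulationConfig) -> SimulatedData:
    """Generate one synthetic dataset.

    Returns counts, annotations, roles, species tree and ground truth.
    Two calls with the same config produce identical objects.
    """
    rng = np.random.default_rng(config.seed)
    roles = _species_panel(config)
    species = roles.all_species
    n_species = len(species)

    # synthetic accession pools (clearly fake numeric ranges)
    ipr_pool = [
        (f"IPR9{i:05d}", f"synthetic domain {i + 1}")
        for i in range(config.n_domains)
    ]
    pfam_pool = [
        (f"PF9{i:04d}", f"synthetic Pfam family {i + 1}")
        for i in range(config.n_domains)
    ]
    go_pool = [
        (f"GO:99{i:05d}", f"synthetic GO term {i + 1}")
        for i in range(config.n_domains)
    ]

    count_rows: list[np.ndarray] = []
    truth_rows: list[tuple[str, str, float, str]] = []
    ann_rows: list[tuple[str, str, str, str, str]] = []
    og_index = 0

    def next_id() -> str:
        nonlocal og_index
        og_index += 1
        return f"SOG{og_index:07d}"

    # planted families, in fixed category order for determinism
    for category in CATEGORIES:
        for _ in range(config.planted.get(category, 0)):
            focal, sisters, outgroups = _planted_counts(rng, category, config)
            og = next_id()
            vec = np.array([focal, *sisters, *outgroups], dtype=int)
            count_rows.append(vec)
            realized = _ratio(focal, [*sisters, *outgroups])
            primary = ipr_pool[rng.integers(len(ipr_pool))]
            n_proteins = int(vec.sum())
            _annotate_family(
                rng, og, n_proteins, primary, ipr_pool, pfam_pool, go_pool,
                ann_rows,
            )
            truth_rows.append((og, category, realized, primary[0]))

    # background families
    for _ in range(config.n_background):
        vec = _background_counts(rng, n_species, config)
        og = next_id()
        count_rows.append(vec)
        realized = _ratio(int(vec[0]), [int(c) for c in vec[1:]])
        domain = ""
        if rng.random() < config.annotation_prob:
            primary = ipr_pool[rng.integers(len(ipr_pool))]
            domain = primary[0]
            _annotate_family(
                rng, og, int(vec.sum()), primary, ipr_pool, pfam_pool,
                go_pool, ann_rows,
            )
        truth_rows.append((og, "background", realized, domain))

    og_ids = [row[0] for row in truth_rows]
    table = pd.DataFrame(count_rows, index=og_ids, columns=species)
    table.index.name = "Orthogroup"
    counts = OrthogroupCounts(table)
    annotations = AnnotationTable(
        pd.DataFrame(
            ann_rows,
            columns=[
                "protein_id",
                "orthogroup_id",
                "namespace",
                "accession",
                "description",
            ],
        )
    )
    truth = SyntheticTruth(
        pd.DataFrame(
            truth_rows,
            columns=["orthogroup_id", "label", "realized_fold", "domain"],
        )
    )
    return SimulatedData(counts, annotations, roles, _ladder_tree(roles), truth)


# ---------------------------------------------------------------------------
# evaluation


def truth_confusion(
    records: Sequence[ExpansionRecord], truth: SyntheticTruth
) -> pd.DataFrame:
    """Confusion matrix of planted label (rows) vs assigned label (columns).

    Raises on any orthogroup-ID mismatch between records and truth.
    """
    assigned = {r.orthogroup_id: r.category for r in records}
    truth_ids = set(truth.table["orthogroup_id"])
    if set(assigned) != truth_ids:
        missing = sorted(truth_ids ^ set(assigned))
        raise ValueError(
            f"orthogroup universes differ between records and truth: {missing[:5]}"
        )
    truth_labels = ["background", *CATEGORIES]
    matrix = pd.DataFrame(
        0, index=truth_labels, columns=list(LABELS), dtype=int
    )
    for og, label, *_ in truth.table.itertuples(index=False):
        matrix.loc[label, assigned[og]] += 1
    return matrix


def recovery_rate(
    records: Sequence[ExpansionRecord], truth: SyntheticTruth
) -> float:
    """Fraction of planted families assigned exactly their planted category.

    Returns 1.0 when nothing was planted (nothing to recover).
    """
    matrix = truth_confusion(records, truth)
    planted = matrix.loc[list(CATEGORIES)]
    total = int(planted.to_numpy().sum())
    if total == 0:
        return 1.0
    diagonal = sum(int(planted.loc[c, c]) for c in CATEGORIES)
    return diagonal / total
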