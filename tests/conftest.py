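import pandas as pd
import pytest
from hypothesis import settings

from orthoexpand import OrthogroupCounts, SpeciesRoles, Thresholds

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

OUTGROUPS = tuple(f"Bivalve_outgroup_{i + 1:02d}" for i in range(13))


@pytest.fixture
def roles() -> SpeciesRoles:
    """The 16-species panel: focal oyster, two sister oysters, 13 outgroups."""
    return SpeciesRoles(
        focal="Ostrea_edulis",
        sisters=("Crassostrea_gigas", "Crassostrea_virginica"),
        outgroups=OUTGROUPS,
    )


@pytest.fixture
def thresholds() -> Thresholds:
    return Thresholds()


def make_row(roles: SpeciesRoles, focal: int, sisters, outgroups) -> dict:
    """Species -> count mapping from a (focal, sisters, outgroups) triple."""
    row = {roles.focal: focal}
    row[roles.sisters[0]] = sisters[0]
    row[roles.sisters[1]] = sisters[1]
    for name, count in zip(roles.outgroups, outgroups):
        row[name] = count
    return row


def make_counts(roles: SpeciesRoles, vectors: dict) -> OrthogroupCounts:
    """Counts matrix from {orthogroup_id: (focal, (s1, s2), [outgroups])}."""
    rows = {}
    for og_id, (focal, sisters, outgroups) in vectors.items():
        rows[og_id] = [focal, *sisters, *outgroups]
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(roles.all_species)
    ).astype(int)
    table.index.name = "Orthogroup"
    return OrthogroupCounts(table)
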