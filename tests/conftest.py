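import pytest

from phosphokin.io_formats import SiteRecord, SiteTable
from phosphokin.synthetic_data import SimConfig, simulate


def make_window(residue: str, flank_left: str = "AAAAAA", flank_right: str = "AAAAAA") -> str:
    assert len(flank_left) == 6 and len(flank_right) == 6
    return flank_left + residue + flank_right


def make_table(rows) -> SiteTable:
    """Build a SiteTable from (protein, position, residue, ratio[, extras]) tuples."""
    records = []
    for row in rows:
        protein, position, residue, ratio = row[:4]
        extras = row[4] if len(row) > 4 else {}
        records.append(
            SiteRecord(
                protein_id=protein,
                position=position,
                residue=residue,
                window=extras.get("window", make_window(residue)),
                localization_prob=extras.get("localization_prob", 0.99),
                score=extras.get("score", 100.0),
                ratio=ratio,
            )
        )
    return SiteTable.from_records(records)


@pytest.fixture(scope="session")
def sim_result():
    """One simulated experiment shared across read-only tests."""
    return simulate(SimConfig(seed=5))
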