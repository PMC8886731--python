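"""Differential phosphosite calling by fold-change thresholds.

A site is called *up* when its disease/control ratio is strictly above the
upper threshold (default 1.3) and *down* when strictly below the lower
threshold (default 0.77); boundary values are *unchanged*. Summary
statistics cover the per-residue breakdown of regulated sites and the
"constitution" of regulated proteins (how many carry 1, 2, or >=3 regulated
sites), compared between directions with Pearson's chi-square test.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from phosphokin.io_formats import SiteTable

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"

DEFAULT_UP_THRESHOLD = 1.3
DEFAULT_DOWN_THRESHOLD = 0.77

CONSTITUTION_BINS = ("1", "2", "3+")


def call_regulation(
    table: SiteTable,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
) -> pd.DataFrame:
    """Assign each site a regulation status by strict ratio thresholds.

    Returns a copy of the site frame with a ``status`` column in
    {"up", "down", "unchanged"}. Thresholds are strict inequalities, so a
    ratio exactly at either threshold is "unchanged".
    """
    if not down_threshold < up_threshold:
        raise ValueError(
            f"down_threshold ({down_threshold}) must be below up_threshold ({up_threshold})"
        )
    calls = table.frame.copy()
    ratio = calls["ratio"].to_numpy(dtype=float)
    status = np.full(len(calls), UNCHANGED, dtype=object)
    status[ratio > up_threshold] = UP
    status[ratio < down_threshold] = DOWN
    calls["status"] = status
    return calls


def residue_breakdown(calls: pd.DataFrame, status: str) -> dict:
    """Counts and integer percentages of S/T/Y among sites with ``status``.

    Percentages are round-to-nearest-integer of 100*count/total, matching
    the convention of published pie-chart summaries; exact fractions are
    returned alongside.
    """
    subset = calls.loc[calls["status"] == status]
    total = len(subset)
    if total == 0:
        logger.warning("no sites with status %r; empty breakdown", status)
        return {"counts": {r: 0 for r in "STY"}, "percentages": {}, "fractions": {}, "total": 0}
    counts = {r: int((subset["residue"] == r).sum()) for r in "STY"}
    fractions = {r: counts[r] / total for r in "STY"}
    percentages = {r: int(round(100.0 * counts[r] / total)) for r in "STY"}
    return {"counts": counts, "percentages": percentages, "fractions": fractions, "total": total}


def sites_per_protein(calls: pd.DataFrame, status: str) -> dict:
    """Constitution row: proteins carrying exactly 1, exactly 2, or >=3
    sites of the given status.

    Only proteins with at least one such site contribute; fractions sum to 1.
    """
    subset = calls.loc[calls["status"] == status]
    multiplicity = subset.groupby("protein_id").size()
    n_proteins = len(multiplicity)
    counts = {
        "1": int((multiplicity == 1).sum()),
        "2": int((multiplicity == 2).sum()),
        "3+": int((multiplicity >= 3).sum()),
    }
    fractions = (
        {k: v / n_proteins for k, v in counts.items()} if n_proteins else {k: 0.0 for k in counts}
    )
    return {"counts": counts, "fractions": fractions, "n_proteins": n_proteins}


def chi2_constitution(
    up_row: Mapping[str, int] | Sequence[int],
    down_row: Mapping[str, int] | Sequence[int],
) -> tuple[float, int, float]:
    """Pearson chi-square on the 2x3 up/down constitution table.

    No continuity correction; degrees of freedom are (2-1)*(3-1) = 2.
    Returns (statistic, df, p). A zero expected cell raises with advice to
    merge bins, since the chi-square approximation is undefined there.
    """
    def as_vector(row) -> np.ndarray:
        if isinstance(row, Mapping):
            return np.array([row[b] for b in CONSTITUTION_BINS], dtype=float)
        vec = np.asarray(row, dtype=float)
        if vec.shape != (3,):
            raise ValueError("constitution row must have exactly 3 bins (1, 2, 3+)")
        return vec

    table = np.vstack([as_vector(up_row), as_vector(down_row)])
    if table.sum() <= 0:
        raise ValueError("constitution table is empty")
    if np.any(table.sum(axis=1) == 0):
        raise ValueError(
            "chi-square undefined: a direction has no proteins; merge bins or skip the test"
        )
    # an all-zero multiplicity bin has expected 0 and observed 0 in both
    # rows: it contributes nothing to the Pearson sum and is dropped, with
    # the degrees of freedom kept at the 2x3 design value
    nonzero_cols = table.sum(axis=0) > 0
    reduced = table[:, nonzero_cols]
    if reduced.shape[1] < 2:
        raise ValueError(
            "chi-square undefined: fewer than two populated bins; merge bins before testing"
        )
    stat = float(stats.chi2_contingency(reduced, correction=False)[0])
    df = 2
    return stat, df, float(stats.chi2.sf(stat, df))


def regulation_summary(calls: pd.DataFrame) -> dict:
    """Full differential summary: status counts, per-residue breakdowns and
    constitution rows for both directions, with the chi-square comparison
    when both rows are non-degenerate."""
    summary: dict = {
        "n_sites": len(calls),
        "n_up": int((calls["status"] == UP).sum()),
        "n_down": int((calls["status"] == DOWN).sum()),
        "n_unchanged": int((calls["status"] == UNCHANGED).sum()),
        "residue_breakdown": {s: residue_breakdown(calls, s) for s in (UP, DOWN)},
        "constitution": {s: sites_per_protein(calls, s) for s in (UP, DOWN)},
    }
    up_counts = summary["constitution"][UP]["counts"]
    down_counts = summary["constitution"][DOWN]["counts"]
    try:
        stat, df, p = chi2_constitution(up_counts, down_counts)
        summary["chi2"] = {"statistic": stat, "df": df, "p": p}
    except ValueError as exc:
        summary["chi2"] = {"error": str(exc)}
    return summary
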