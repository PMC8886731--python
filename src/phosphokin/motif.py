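"""Positional residue enrichment around phosphosites.

For a set of foreground 13-mer windows (e.g. up-regulated serine sites)
against a background (all identified sites with the same central residue),
each flanking position -6..+6 (excluding the center) is tested per amino
acid: log2 enrichment of foreground vs background frequency, a one-sided
binomial test for over-representation, and Benjamini-Hochberg q-values
across all tested cells. Terminal `_` padding is excluded from both
numerators and denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from phosphokin.io_formats import AMINO_ACIDS, WINDOW_CENTER, WINDOW_LENGTH, WINDOW_PAD

logger = logging.getLogger(__name__)

#: flanking offsets, center excluded
POSITIONS = tuple(p for p in range(-6, 7) if p != 0)

#: pseudocount for the log2 enrichment ratio (not the binomial test)
PSEUDOCOUNT = 0.5

#: below this many foreground windows the profile is statistically fragile
SMALL_N_WARNING = 10

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class MotifProfile:
    """Position-by-residue enrichment matrices for one central residue.

    Matrices are indexed [position, amino_acid] with positions in
    :data:`POSITIONS` order and the 20 amino acids in alphabetical order.
    ``p_values`` are NaN where the background count is zero (enrichment is
    undefined there and the cell is excluded from the BH correction).
    """

    central_residue: str
    n_foreground: int
    n_background: int
    foreground_counts: np.ndarray
    background_counts: np.ndarray
    log2_enrichment: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    positions: tuple = POSITIONS
    amino_acids: str = AMINO_ACIDS

    def to_frame(self, matrix: str = "log2_enrichment") -> pd.DataFrame:
        data = getattr(self, matrix)
        return pd.DataFrame(data, index=list(self.positions), columns=list(self.amino_acids))

    def frequency_matrix(self, which: str = "foreground") -> pd.DataFrame:
        """Per-position residue frequencies (sequence-logo-ready)."""
        counts = self.foreground_counts if which == "foreground" else self.background_counts
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(totals > 0, counts / totals, 0.0)
        return pd.DataFrame(freq, index=list(self.positions), columns=list(self.amino_acids))


def _count_matrix(windows: list[str]) -> np.ndarray:
    """Counts[position, amino acid] over windows; `_` pads are skipped."""
    counts = np.zeros((len(POSITIONS), len(AMINO_ACIDS)), dtype=np.int64)
    for w in windows:
        for row, offset in enumerate(POSITIONS):
            aa = w[WINDOW_CENTER + offset]
            if aa == WINDOW_PAD:
                continue
            counts[row, _AA_INDEX[aa]] += 1
    return counts


def _validate_windows(windows, central_residue: str, label: str) -> list[str]:
    out = []
    for w in windows:
        if len(w) != WINDOW_LENGTH:
            raise ValueError(f"{label} window not {WINDOW_LENGTH}-mer: {w!r}")
        if w[WINDOW_CENTER] != central_residue:
            raise ValueError(
                f"{label} window centered on {w[WINDOW_CENTER]!r}, expected {central_residue!r}: {w!r}"
            )
        out.append(w)
    return out


def build_profile(
    foreground_windows,
    background_windows,
    central_residue: str,
) -> MotifProfile:
    """Positional enrichment of foreground vs background windows.

    Per cell (position, residue) with foreground count f of column total F
    and background count b of column total B:

    * log2 enrichment = log2(((f+0.5)/(F+0.5)) / ((b+0.5)/(B+0.5)))
    * p = one-sided binomial tail P(X >= f | n=F, p0=b/B), defined where b>0
    * q = Benjamini-Hochberg over all defined cells
    """
    fg = _validate_windows(foreground_windows, central_residue, "foreground")
    bg = _validate_windows(background_windows, central_residue, "background")
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    if len(fg) < SMALL_N_WARNING:
        logger.warning(
            "only %d foreground windows for %s profile; estimates will be unstable",
            len(fg),
            central_residue,
        )

    f_counts = _count_matrix(fg)
    b_counts = _count_matrix(bg)
    f_totals = f_counts.sum(axis=1, keepdims=True)  # per-position, padding excluded
    b_totals = b_counts.sum(axis=1, keepdims=True)

    with np.errstate(invalid="ignore", divide="ignore"):
        f_rate = (f_counts + PSEUDOCOUNT) / (f_totals + PSEUDOCOUNT)
        b_rate = (b_counts + PSEUDOCOUNT) / (b_totals + PSEUDOCOUNT)
        log2_enr = np.log2(f_rate / b_rate)

    p_values = np.full(f_counts.shape, np.nan)
    for i in range(f_counts.shape[0]):
        F = int(f_totals[i, 0])
        B = int(b_totals[i, 0])
        if F == 0 or B == 0:
            continue
        for j in range(f_counts.shape[1]):
            b = int(b_counts[i, j])
            if b == 0:
                continue  # enrichment undefined without background support
            f = int(f_counts[i, j])
            p0 = b / B
            # survival function of Binomial(F, p0) at f-1 == P(X >= f)
            p_values[i, j] = float(stats.binom.sf(f - 1, F, p0))

    q_values = np.full(p_values.shape, np.nan)
    tested = ~np.isnan(p_values)
    if tested.any():
        _, q_flat, _, _ = multipletests(p_values[tested], method="fdr_bh")
        q_values[tested] = q_flat

    return MotifProfile(
        central_residue=central_residue,
        n_foreground=len(fg),
        n_background=len(bg),
        foreground_counts=f_counts,
        background_counts=b_counts,
        log2_enrichment=log2_enr,
        p_values=p_values,
        q_values=q_values,
    )


def summarize_motifs(
    profile: MotifProfile,
    q_cutoff: float = 0.05,
    min_log2: float = 1.0,
) -> list[tuple[int, str, float, float]]:
    """Significant enriched cells as (position, residue, log2 enrichment, q),
    sorted by q then by decreasing enrichment. May be empty."""
    hits = []
    for i, pos in enumerate(profile.positions):
        for j, aa in enumerate(profile.amino_acids):
            q = profile.q_values[i, j]
            enr = profile.log2_enrichment[i, j]
            if np.isnan(q):
                continue
            if q <= q_cutoff and enr >= min_log2:
                hits.append((pos, aa, float(enr), float(q)))
    hits.sort(key=lambda t: (t[3], -t[2]))
    return hits


def write_profile(profile: MotifProfile, prefix) -> None:
    """Write the enrichment, p/q and logo frequency matrices as TSV."""
    for name in ("log2_enrichment", "p_values", "q_values"):
        profile.to_frame(name).to_csv(f"{prefix}.{name}.tsv", sep="\t")
    profile.frequency_matrix("foreground").to_csv(f"{prefix}.foreground_freq.tsv", sep="\t")
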