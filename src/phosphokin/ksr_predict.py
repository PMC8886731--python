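"""GPS-style prediction of site-specific kinase-substrate relations.

A candidate p-site's 13-mer window is scored against a kinase's known
substrate windows as the mean pairwise BLOSUM62 similarity (aligned
position by position; any pair involving terminal `_` padding contributes
zero). Each kinase's score cutoff is calibrated on background windows to a
target false-positive rate — the GPS "medium" stringency maps to 6% —
and candidate edges are optionally filtered by protein-level PPI evidence,
mirroring the "Exp./String" interaction filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from phosphokin.io_formats import AMINO_ACIDS, PPINetwork, SiteTable, WINDOW_LENGTH, WINDOW_PAD

logger = logging.getLogger(__name__)

#: GPS stringency levels expressed as target false-positive rates
FPR_HIGH = 0.02
FPR_MEDIUM = 0.06
FPR_LOW = 0.10

_MIN_BACKGROUND = 200

# 21-letter alphabet: the 20 amino acids plus the padding symbol at index 20
_ALPHABET = AMINO_ACIDS + WINDOW_PAD
_CHAR_CODE = {c: i for i, c in enumerate(_ALPHABET)}


def _blosum62_table() -> np.ndarray:
    """21x21 similarity lookup; any pairing with `_` scores 0."""
    blosum = substitution_matrices.load("BLOSUM62")
    table = np.zeros((21, 21), dtype=np.float64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            table[i, j] = blosum[a][b]
    return table


_BLOSUM = _blosum62_table()


def encode_windows(windows) -> np.ndarray:
    """Encode 13-mer windows into an (n, 13) integer code array."""
    arr = np.empty((len(windows), WINDOW_LENGTH), dtype=np.int8)
    for i, w in enumerate(windows):
        if len(w) != WINDOW_LENGTH:
            raise ValueError(f"window must have length {WINDOW_LENGTH}: {w!r}")
        for j, c in enumerate(w):
            code = _CHAR_CODE.get(c)
            if code is None:
                raise ValueError(f"invalid residue {c!r} in window {w!r}")
            arr[i, j] = code
    return arr


@dataclass
class KinaseProfile:
    """A kinase's known substrate windows and calibrated score cutoff.

    ``accepted_residues`` declares the central residues the kinase can
    phosphorylate ({"S", "T"} for Ser/Thr kinases, {"Y"} for Tyr kinases);
    ``protein_id`` is the kinase's own protein accession, used for the
    self-phosphorylation exemption of the PPI filter.
    """

    kinase_name: str
    substrate_windows: tuple[str, ...]
    threshold: float | None = None
    accepted_residues: frozenset = frozenset({"S", "T"})
    protein_id: str | None = None
    interactors: set | None = None
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.substrate_windows = tuple(self.substrate_windows)
        if not self.substrate_windows:
            raise ValueError(f"kinase {self.kinase_name}: needs at least one substrate window")
        self._codes = encode_windows(self.substrate_windows)


def _score_batch(window_codes: np.ndarray, profile: KinaseProfile) -> np.ndarray:
    """Mean pairwise similarity of each query window to the profile set."""
    # (n_query, n_sub, 13) gather then sum positions, mean substrates
    pair = _BLOSUM[window_codes[:, None, :], profile._codes[None, :, :]]
    return pair.sum(axis=2).mean(axis=1)


def score_site(window: str, profile: KinaseProfile) -> float:
    """Similarity score of one 13-mer against a kinase profile.

    Mean over the profile's substrate windows of the summed BLOSUM62
    values at the 13 aligned positions; `_` pairs contribute 0.
    """
    codes = encode_windows([window])
    return float(_score_batch(codes, profile)[0])


def calibrate_threshold(
    profile: KinaseProfile,
    background_windows,
    fpr: float = FPR_MEDIUM,
) -> float:
    """Set the profile's cutoff so ~``fpr`` of background windows reach it.

    The threshold is the k-th largest background score with k = ceil(fpr*n);
    at fpr=0 it is the maximum background score and at fpr=1 the minimum.
    Emission downstream is >= threshold, so up to ties exactly k background
    windows score at or above it. The threshold is stored on the profile
    and returned.
    """
    if not 0 <= fpr <= 1:
        raise ValueError(f"fpr must be in [0,1]: {fpr}")
    background_windows = list(background_windows)
    n = len(background_windows)
    if n == 0:
        raise ValueError("cannot calibrate on an empty background")
    if n < _MIN_BACKGROUND:
        logger.warning(
            "calibrating %s on only %d background windows (recommend >= %d)",
            profile.kinase_name,
            n,
            _MIN_BACKGROUND,
        )
    scores = np.sort(_score_batch(encode_windows(background_windows), profile))[::-1]
    k = math.ceil(fpr * n)
    threshold = float(scores[0]) if k == 0 else float(scores[k - 1])
    profile.threshold = threshold
    return threshold


@dataclass(frozen=True)
class KSREdge:
    """A predicted kinase -> p-site relation above the kinase's cutoff."""

    kinase_name: str
    protein_id: str
    position: int
    residue: str
    score: float
    passed_ppi: bool

    @property
    def site_key(self) -> str:
        return f"{self.protein_id}_{self.position}"


def predict_ksrs(
    table: SiteTable,
    profiles,
    ppi: PPINetwork | None = None,
    require_ppi: bool = True,
) -> list[KSREdge]:
    """Predict kinase-substrate edges over a site table.

    An edge is emitted iff the site's window scores at or above the
    kinase's calibrated threshold, the site's central residue is one the
    kinase accepts, and — when ``require_ppi`` — the kinase's protein and
    the substrate protein interact (or are the same protein). Sites with a
    central residue the kinase does not accept are skipped silently.
    """
    if require_ppi and ppi is None:
        raise ValueError("require_ppi=True needs a PPI network")
    frame = table.frame
    codes = encode_windows(frame["window"].tolist())
    residues = frame["residue"].to_numpy()
    proteins = frame["protein_id"].to_numpy()
    positions = frame["position"].to_numpy()

    edges: list[KSREdge] = []
    for profile in profiles:
        if profile.threshold is None:
            raise ValueError(f"kinase {profile.kinase_name}: threshold not calibrated")
        compatible = np.isin(residues, list(profile.accepted_residues))
        n_skipped = int((~compatible).sum())
        if n_skipped:
            logger.debug(
                "%s: skipping %d residue-incompatible sites", profile.kinase_name, n_skipped
            )
        scores = _score_batch(codes, profile)
        hits = compatible & (scores >= profile.threshold)
        kinase_protein = profile.protein_id or profile.kinase_name
        for idx in np.flatnonzero(hits):
            target = str(proteins[idx])
            ppi_ok = (
                ppi is not None and (ppi.contains(kinase_protein, target) or kinase_protein == target)
            )
            if require_ppi and not ppi_ok:
                continue
            edges.append(
                KSREdge(
                    kinase_name=profile.kinase_name,
                    protein_id=target,
                    position=int(positions[idx]),
                    residue=str(residues[idx]),
                    score=float(scores[idx]),
                    passed_ppi=bool(ppi_ok),
                )
            )
    return edges


def edges_to_frame(edges) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kinase": e.kinase_name,
                "protein_id": e.protein_id,
                "position": e.position,
                "residue": e.residue,
                "score": e.score,
                "passed_ppi": e.passed_ppi,
            }
            for e in edges
        ],
        columns=["kinase", "protein_id", "position", "residue", "score", "passed_ppi"],
    )


def substrate_sets(edges) -> dict[str, list[str]]:
    """Group predicted edges into kinase -> site-key sets (GMT-ready)."""
    out: dict[str, list[str]] = {}
    for e in edges:
        out.setdefault(e.kinase_name, [])
        if e.site_key not in out[e.kinase_name]:
            out[e.kinase_name].append(e.site_key)
    return out
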