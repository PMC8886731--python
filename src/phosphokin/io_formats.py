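"""Readers and writers for the pipeline's standard inputs.

Site tables follow the minimal MaxQuant ``Phospho (STY)Sites.txt`` column
set (protein, gene, position, residue, 13-mer sequence window, localization
probability, search score, disease/control ratio). Search-quality filters —
modified-peptide score strictly above 40 and class-I localization
probability ≥ 0.75 — are applied at read time and recorded in the table's
provenance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: residues that can carry a phosphate group
PHOSPHO_RESIDUES = frozenset("STY")

#: the 20 standard amino acids; `_` pads windows at protein termini
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
WINDOW_PAD = "_"
WINDOW_LENGTH = 13
WINDOW_CENTER = 6


class FormatError(ValueError):
    """A file does not conform to the expected tabular/FASTA/GMT layout."""


@dataclass(frozen=True)
class SiteRecord:
    """One quantified phosphosite.

    ``window`` is the 13-mer spanning positions -6..+6 around the site,
    padded with ``_`` at protein termini; ``ratio`` is oriented
    disease/control and never inverted downstream.
    """

    protein_id: str
    position: int
    residue: str
    window: str
    localization_prob: float
    score: float
    ratio: float
    gene_symbol: str = ""

    @property
    def log2_ratio(self) -> float:
        return math.log2(self.ratio)

    @property
    def site_key(self) -> str:
        return f"{self.protein_id}_{self.position}"

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW_LENGTH:
            raise ValueError(f"window must have length {WINDOW_LENGTH}: {self.window!r}")
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"residue must be one of S/T/Y: {self.residue!r}")
        if self.window[WINDOW_CENTER] != self.residue:
            raise ValueError(
                f"window center {self.window[WINDOW_CENTER]!r} does not match residue {self.residue!r}"
            )
        if not self.ratio > 0:
            raise ValueError(f"ratio must be positive: {self.ratio}")
        if not 0 <= self.localization_prob <= 1:
            raise ValueError(f"localization_prob outside [0,1]: {self.localization_prob}")


_SITE_COLUMNS = [
    "protein_id",
    "gene_symbol",
    "position",
    "residue",
    "window",
    "localization_prob",
    "score",
    "ratio",
    "log2_ratio",
]


@dataclass
class SiteTable:
    """An ordered collection of phosphosites with provenance metadata.

    Wraps a :class:`pandas.DataFrame` with one row per unique
    (protein, position) pair; ``frame`` carries the columns listed in
    ``_SITE_COLUMNS``.
    """

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _SITE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"site table missing columns: {missing}")
        dup = self.frame.duplicated(subset=["protein_id", "position"])
        if dup.any():
            raise ValueError(
                f"duplicate (protein, position) pairs: {self.frame.loc[dup, ['protein_id', 'position']].values.tolist()}"
            )

    def __len__(self) -> int:
        return len(self.frame)

    def records(self) -> Iterator[SiteRecord]:
        for row in self.frame.itertuples(index=False):
            yield SiteRecord(
                protein_id=row.protein_id,
                gene_symbol=row.gene_symbol,
                position=int(row.position),
                residue=row.residue,
                window=row.window,
                localization_prob=float(row.localization_prob),
                score=float(row.score),
                ratio=float(row.ratio),
            )

    @classmethod
    def from_records(cls, records: Iterable[SiteRecord], provenance: dict | None = None) -> "SiteTable":
        rows = [
            {
                "protein_id": r.protein_id,
                "gene_symbol": r.gene_symbol,
                "position": r.position,
                "residue": r.residue,
                "window": r.window,
                "localization_prob": r.localization_prob,
                "score": r.score,
                "ratio": r.ratio,
                "log2_ratio": r.log2_ratio,
            }
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=_SITE_COLUMNS)
        return cls(frame=frame, provenance=provenance or {})


# MaxQuant-style header aliases, matched case-insensitively
_COLUMN_ALIASES: Mapping[str, tuple[str, ...]] = {
    "protein_id": ("protein", "protein_id", "proteins", "leading proteins"),
    "gene_symbol": ("gene", "gene_symbol", "gene names"),
    "position": ("position", "positions within proteins"),
    "residue": ("amino acid", "residue", "amino_acid"),
    "window": ("sequence window", "window", "sequence_window"),
    "localization_prob": ("localization prob", "localization_prob", "localization probability"),
    "score": ("score",),
    "ratio": ("ratio", "ratio t/n", "ratio h/l"),
}

_REQUIRED = ("protein_id", "position", "residue", "window", "localization_prob", "score", "ratio")


def _map_columns(columns: Iterable[str]) -> dict[str, str]:
    lower = {c.lower().strip(): c for c in columns}
    mapping: dict[str, str] = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                mapping[canon] = lower[alias]
                break
    return mapping


def read_site_table(
    path: str | Path,
    min_score: float = 40.0,
    min_loc_prob: float = 0.75,
) -> SiteTable:
    """Read a tab-separated phosphosite table and apply quality filters.

    Records are kept only when the search score is strictly greater than
    ``min_score`` and the localization probability is at least
    ``min_loc_prob`` (0.75 keeps class-I sites). Malformed rows are dropped
    with a row-level warning; duplicate (protein, position) rows collapse to
    the one with the highest localization probability. An empty result after
    filtering is a warning, not an error.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    mapping = _map_columns(raw.columns)
    missing = [c for c in _REQUIRED if c not in mapping]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")

    records: list[SiteRecord] = []
    n_malformed = 0
    for idx, row in raw.iterrows():
        try:
            rec = SiteRecord(
                protein_id=str(row[mapping["protein_id"]]),
                gene_symbol=str(row[mapping["gene_symbol"]]) if "gene_symbol" in mapping else "",
                position=int(row[mapping["position"]]),
                residue=str(row[mapping["residue"]]).strip(),
                window=str(row[mapping["window"]]).strip(),
                localization_prob=float(row[mapping["localization_prob"]]),
                score=float(row[mapping["score"]]),
                ratio=float(row[mapping["ratio"]]),
            )
        except (ValueError, TypeError) as exc:
            n_malformed += 1
            logger.warning("%s row %d rejected: %s", path.name, idx, exc)
            continue
        records.append(rec)

    n_parsed = len(records)
    # strict > on score (the search-engine convention "set >40"); >= on
    # localization probability (class-I definition is inclusive)
    kept = [r for r in records if r.score > min_score and r.localization_prob >= min_loc_prob]

    # collapse duplicates keeping the best-localized row
    best: dict[tuple[str, int], SiteRecord] = {}
    for r in kept:
        key = (r.protein_id, r.position)
        if key not in best or r.localization_prob > best[key].localization_prob:
            best[key] = r

    if not best:
        logger.warning("%s: no records remain after filtering", path)

    provenance = {
        "source": str(path),
        "min_score": min_score,
        "min_loc_prob": min_loc_prob,
        "n_rows_parsed": n_parsed,
        "n_rows_malformed": n_malformed,
        "n_rows_kept": len(best),
    }
    return SiteTable.from_records(best.values(), provenance=provenance)


def write_site_table(table: SiteTable, path: str | Path) -> None:
    """Write a site table with MaxQuant-style headers."""
    out = table.frame.rename(
        columns={
            "protein_id": "Protein",
            "gene_symbol": "Gene",
            "position": "Position",
            "residue": "Amino acid",
            "window": "Sequence window",
            "localization_prob": "Localization prob",
            "score": "Score",
            "ratio": "Ratio",
        }
    ).drop(columns=["log2_ratio"])
    out.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered mapping id -> sequence.

    Duplicate record identifiers raise :class:`FormatError`.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq)
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a Broad-convention GMT file: name <tab> description <tab> members.

    Duplicate members within a line are dropped (order preserved);
    duplicate set names raise :class:`FormatError`.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path} line {lineno}: expected name, description, members")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}: duplicate gene-set name {name!r}")
            members = list(dict.fromkeys(m for m in parts[2:] if m))
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction edge set.

    Membership queries are symmetric; self-loops are stored but flagged in
    ``self_loops``.
    """

    edges: set[frozenset] = field(default_factory=set)
    self_loops: set[str] = field(default_factory=set)

    def add(self, a: str, b: str) -> None:
        if a == b:
            self.self_loops.add(a)
        self.edges.add(frozenset((a, b)))

    def contains(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    def __len__(self) -> int:
        return len(self.edges)


def read_ppi(path: str | Path) -> PPINetwork:
    """Read a two-column TSV edge list into a symmetric PPI set.

    A header row is detected (and skipped) when its first field is a common
    header token; edges listed in both orders deduplicate to one.
    """
    net = PPINetwork()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path} line {lineno}: expected two tab-separated ids")
            a, b = parts[0].strip(), parts[1].strip()
            if lineno == 1 and a.lower() in {"protein_a", "protein1", "node_a", "source"}:
                continue
            net.add(a, b)
    if net.self_loops:
        logger.warning("PPI file %s contains %d self-loop(s)", path, len(net.self_loops))
    return net


def write_ppi(net: PPINetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\n")
        for edge in sorted(net.edges, key=lambda e: sorted(e)):
            pair = sorted(edge)
            if len(pair) == 1:
                pair = [pair[0], pair[0]]
            fh.write(f"{pair[0]}\t{pair[1]}\n")


def extract_window(sequence: str, position: int, flank: int = 6) -> str:
    """13-mer around a 1-based ``position``, `_`-padded at the termini."""
    idx = position - 1
    if idx < 0 or idx >= len(sequence):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    left = sequence[max(0, idx - flank) : idx]
    right = sequence[idx + 1 : idx + 1 + flank]
    return WINDOW_PAD * (flank - len(left)) + left + sequence[idx] + right + WINDOW_PAD * (flank - len(right))
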