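"""Synthetic phosphoproteomics data with planted ground truth.

Emulates a pooled two-group TMT design: each phosphosite carries a single
disease/control ratio. Synthetic kinases are planted as short linear
motifs (a consensus of required residues at fixed offsets in the -6..+6
window) rewritten into randomly generated protein sequences; substrates of
"active" kinases receive a positive log2-ratio shift, substrates of
"inactive" kinases a negative one, and everything rides on lognormal
biological baseline plus measurement noise. The planted kinase->site map,
true shifts, and true activity directions are returned as ground truth so
every downstream stage (differential calling, motif enrichment,
kinase-substrate prediction, activity inference, network assembly) can be
validated end to end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from phosphokin.io_formats import (
    AMINO_ACIDS,
    PPINetwork,
    SiteRecord,
    SiteTable,
    extract_window,
    write_fasta,
    write_ppi,
    write_site_table,
)
from phosphokin.ksr_predict import KinaseProfile

logger = logging.getLogger(__name__)

# average vertebrate proteome composition (fractions over the 20 residues)
BACKGROUND_AA_FREQS = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

MIN_PROTEIN_LENGTH = 200
MAX_PROTEIN_LENGTH = 600

# synthetic kinase specificities, cycled over kinases in order: central
# residue, primary consensus position, two secondary positions. The primary
# anchor is written into every substrate; secondary positions into every
# other substrate only, mirroring real kinase motifs where one anchor
# position is decisive and flanking preferences are partial.
MOTIF_CATALOG = (
    ("S", (1, "P"), ((-2, "L"), (3, "E"))),    # proline-directed, CDK/MAPK-like
    ("S", (-3, "R"), ((-5, "K"), (2, "L"))),   # basophilic, PKA/PKC-like
    ("S", (3, "E"), ((1, "D"), (-2, "E"))),    # acidophilic, CK2-like
    ("Y", (-1, "E"), ((1, "D"), (3, "I"))),    # tyrosine-kinase-like
)

_STREAM_PROTEOME = 1
_STREAM_PLANT = 2
_STREAM_QUANT = 3
_STREAM_PPI = 4


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class GenerationError(RuntimeError):
    """Constraint made placement of a planted site impossible."""


@dataclass
class SimConfig:
    """Study-design parameters of the simulated experiment.

    ``effect_size_delta`` is the true log2-ratio shift of planted
    substrates of active (+) / inactive (-) kinases;
    ``baseline_sd_sigma0`` the biological spread of unshifted log2 ratios;
    ``noise_sd`` the measurement noise on every site. The default residue
    mix (S:T:Y = 0.84:0.14:0.02) and ~2.5 sites per protein match the
    composition typically reported for deep human phosphoproteomes.
    """

    n_proteins: int = 200
    mean_sites_per_protein: float = 2.5
    residue_mix: dict = field(default_factory=lambda: {"S": 0.84, "T": 0.14, "Y": 0.02})
    n_kinases: int = 3
    substrates_per_kinase: int = 20
    active_kinases: frozenset = frozenset({"KIN1"})
    inactive_kinases: frozenset = frozenset({"KIN2"})
    effect_size_delta: float = 1.0
    baseline_sd_sigma0: float = 0.25
    noise_sd: float = 0.5
    ppi_decoy_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.residue_mix) != set("STY"):
            raise ConfigurationError("residue_mix must have exactly the keys S, T, Y")
        if abs(sum(self.residue_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("residue_mix must sum to 1")
        if any(v < 0 for v in self.residue_mix.values()):
            raise ConfigurationError("residue_mix probabilities must be nonnegative")
        for name in ("n_proteins", "n_kinases", "substrates_per_kinase"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.mean_sites_per_protein <= 0:
            raise ConfigurationError("mean_sites_per_protein must be positive")
        if self.baseline_sd_sigma0 <= 0 or self.noise_sd <= 0:
            raise ConfigurationError("standard deviations must be positive")
        self.active_kinases = frozenset(self.active_kinases)
        self.inactive_kinases = frozenset(self.inactive_kinases)
        if self.active_kinases & self.inactive_kinases:
            raise ConfigurationError("active and inactive kinase sets must be disjoint")
        names = set(self.kinase_names())
        stray = (self.active_kinases | self.inactive_kinases) - names
        if stray:
            raise ConfigurationError(f"unknown kinase name(s): {sorted(stray)}")
        if self.n_kinases > self.n_proteins:
            raise ConfigurationError("need at least one protein per kinase")

    def kinase_names(self) -> list[str]:
        return [f"KIN{i + 1}" for i in range(self.n_kinases)]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class GroundTruth:
    """Planted truth: who phosphorylates what, and how activity shifted."""

    site_kinase: dict = field(default_factory=dict)  # (protein, position) -> kinase
    site_shift: dict = field(default_factory=dict)   # (protein, position) -> log2 shift
    kinase_direction: dict = field(default_factory=dict)  # kinase -> positive/negative/null
    kinase_protein: dict = field(default_factory=dict)    # kinase -> its own protein id

    def shift_for(self, protein: str, position: int) -> float:
        return self.site_shift.get((protein, position), 0.0)


def generate_proteome(config: SimConfig) -> dict[str, str]:
    """Random protein sequences with fixed background composition.

    Lengths are uniform on [200, 600]; residues i.i.d. from
    :data:`BACKGROUND_AA_FREQS`. Deterministic given the config seed.
    """
    rng = config._rng(_STREAM_PROTEOME)
    letters = np.array(list(BACKGROUND_AA_FREQS))
    probs = np.array(list(BACKGROUND_AA_FREQS.values()))
    probs = probs / probs.sum()
    width = len(str(config.n_proteins))
    proteome: dict[str, str] = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(MIN_PROTEIN_LENGTH, MAX_PROTEIN_LENGTH + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        proteome[f"PROT{i + 1:0{width}d}"] = seq
    return proteome


def plant_kinases(
    proteome: dict[str, str],
    config: SimConfig,
) -> tuple[list[KinaseProfile], GroundTruth]:
    """Rewrite kinase consensus motifs into the proteome.

    Each synthetic kinase (named KIN1..KINn, hosted on the n first
    proteins) receives a specificity from :data:`MOTIF_CATALOG` and exactly
    ``substrates_per_kinase`` substrate sites: the central residue plus the
    consensus residues are written into randomly chosen, non-overlapping
    window positions. ``proteome`` is modified in place; the returned
    profiles hold the final planted windows as the kinase's known
    substrates.
    """
    if not proteome:
        raise GenerationError("proteome is empty")
    rng = config._rng(_STREAM_PLANT)
    protein_ids = list(proteome)
    mutable = {pid: list(seq) for pid, seq in proteome.items()}
    truth = GroundTruth()
    planted_centers: dict[str, list[int]] = {pid: [] for pid in protein_ids}
    placements: dict[str, list[tuple[str, int]]] = {}

    for i, kinase in enumerate(config.kinase_names()):
        central, primary, secondaries = MOTIF_CATALOG[i % len(MOTIF_CATALOG)]
        truth.kinase_protein[kinase] = protein_ids[i]
        if kinase in config.active_kinases:
            truth.kinase_direction[kinase] = "positive"
            shift = +config.effect_size_delta
        elif kinase in config.inactive_kinases:
            truth.kinase_direction[kinase] = "negative"
            shift = -config.effect_size_delta
        else:
            truth.kinase_direction[kinase] = "null"
            shift = 0.0

        placements[kinase] = []
        for j in range(config.substrates_per_kinase):
            placed = False
            for _attempt in range(2000):
                pid = protein_ids[int(rng.integers(0, len(protein_ids)))]
                seq = mutable[pid]
                if len(seq) < 13:
                    continue
                pos = int(rng.integers(7, len(seq) - 5))  # 1-based, window inside
                if any(abs(pos - c) < 13 for c in planted_centers[pid]):
                    continue
                seq[pos - 1] = central
                constraints = (primary, *secondaries) if j % 2 == 0 else (primary,)
                for offset, residue in constraints:
                    seq[pos - 1 + offset] = residue
                planted_centers[pid].append(pos)
                placements[kinase].append((pid, pos))
                truth.site_kinase[(pid, pos)] = kinase
                truth.site_shift[(pid, pos)] = shift
                placed = True
                break
            if not placed:
                raise GenerationError(
                    f"could not place a substrate for {kinase}; proteome too small/crowded"
                )

    for pid in protein_ids:
        proteome[pid] = "".join(mutable[pid])

    profiles = []
    for i, kinase in enumerate(config.kinase_names()):
        central, primary, secondaries = MOTIF_CATALOG[i % len(MOTIF_CATALOG)]
        windows = tuple(
            extract_window(proteome[pid], pos) for pid, pos in placements[kinase]
        )
        accepted = frozenset({"Y"}) if central == "Y" else frozenset({"S", "T"})
        profiles.append(
            KinaseProfile(
                kinase_name=kinase,
                substrate_windows=windows,
                accepted_residues=accepted,
                protein_id=truth.kinase_protein[kinase],
            )
        )
    return profiles, truth


def simulate_quant(
    proteome: dict[str, str],
    truth: GroundTruth,
    config: SimConfig,
) -> SiteTable:
    """Quantified site table over planted and background sites.

    Every site's log2 ratio is its true shift (0 for background) plus
    biological baseline N(0, sigma0) plus measurement noise N(0, noise_sd);
    the reported ratio is 2**log2ratio. Background sites are sampled from
    naturally occurring S/T/Y positions so that central residues follow
    ``residue_mix``. Localization probabilities concentrate near 1
    (Beta(20, 1)); search scores follow Gamma(4, 30), so a small tail falls
    below the score filter as in real search output.
    """
    for (pid, pos) in truth.site_kinase:
        if pid not in proteome or not 1 <= pos <= len(proteome[pid]):
            raise ConfigurationError(f"ground truth site {pid}:{pos} not in proteome")
    rng = config._rng(_STREAM_QUANT)

    planted = list(truth.site_kinase)
    excluded: dict[str, set[int]] = {}
    for pid, pos in planted:
        excluded.setdefault(pid, set()).update(range(pos - 6, pos + 7))

    pools: dict[str, list[tuple[str, int]]] = {"S": [], "T": [], "Y": []}
    for pid, seq in proteome.items():
        banned = excluded.get(pid, set())
        for idx, aa in enumerate(seq):
            pos = idx + 1
            if aa in pools and pos not in banned:
                pools[aa].append((pid, pos))

    n_total = int(round(config.n_proteins * config.mean_sites_per_protein))
    n_background = max(0, n_total - len(planted))
    residues = list("STY")
    mix = np.array([config.residue_mix[r] for r in residues])
    draws = rng.multinomial(n_background, mix)

    background: list[tuple[str, int]] = []
    for residue, want in zip(residues, draws):
        pool = pools[residue]
        if want > len(pool):
            logger.warning(
                "only %d %s positions available for %d requested background sites",
                len(pool), residue, want,
            )
            want = len(pool)
        chosen = rng.choice(len(pool), size=want, replace=False)
        background.extend(pool[i] for i in chosen)

    sites = sorted(set(planted) | set(background))
    n = len(sites)
    shifts = np.array([truth.shift_for(pid, pos) for pid, pos in sites])
    log2_ratios = (
        shifts
        + rng.normal(0.0, config.baseline_sd_sigma0, size=n)
        + rng.normal(0.0, config.noise_sd, size=n)
    )
    loc_probs = rng.beta(20.0, 1.0, size=n)
    scores = rng.gamma(4.0, 30.0, size=n)

    records = []
    for (pid, pos), lr, loc, score in zip(sites, log2_ratios, loc_probs, scores):
        residue = proteome[pid][pos - 1]
        records.append(
            SiteRecord(
                protein_id=pid,
                gene_symbol=pid.replace("PROT", "GENE"),
                position=pos,
                residue=residue,
                window=extract_window(proteome[pid], pos),
                localization_prob=float(loc),
                score=float(score),
                ratio=float(2.0 ** lr),
            )
        )
    provenance = {
        "generator": "phosphokin.synthetic_data",
        "seed": config.seed,
        "n_planted": len(planted),
        "n_background": len(background),
        "background_aa_freqs": dict(BACKGROUND_AA_FREQS),
    }
    return SiteTable.from_records(records, provenance=provenance)


def make_ppi(truth: GroundTruth, proteome: dict[str, str], config: SimConfig) -> PPINetwork:
    """PPI evidence: every true kinase-substrate protein pair, plus a
    fraction of random decoy interactors per kinase."""
    rng = config._rng(_STREAM_PPI)
    net = PPINetwork()
    protein_ids = list(proteome)
    for (pid, _pos), kinase in truth.site_kinase.items():
        net.add(truth.kinase_protein[kinase], pid)
    n_decoys = int(round(config.ppi_decoy_fraction * len(protein_ids)))
    for kinase in config.kinase_names():
        host = truth.kinase_protein[kinase]
        decoys = rng.choice(len(protein_ids), size=min(n_decoys, len(protein_ids)), replace=False)
        for i in decoys:
            if protein_ids[i] != host:
                net.add(host, protein_ids[i])
    return net


@dataclass
class SimResult:
    """Everything one simulated experiment produced."""

    config: SimConfig
    proteome: dict
    profiles: list
    truth: GroundTruth
    sites: SiteTable
    ppi: PPINetwork


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: proteome, planted kinases, quant table, PPI."""
    proteome = generate_proteome(config)
    profiles, truth = plant_kinases(proteome, config)
    sites = simulate_quant(proteome, truth, config)
    ppi = make_ppi(truth, proteome, config)
    return SimResult(
        config=config, proteome=proteome, profiles=profiles, truth=truth, sites=sites, ppi=ppi
    )


def write_outputs(result: SimResult, outdir: str | Path) -> dict[str, str]:
    """Write FASTA, site table, kinase annotations, PPI and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": outdir / "proteome.fasta",
        "sites": outdir / "sites.tsv",
        "kinase_substrates": outdir / "kinase_substrates.tsv",
        "ppi": outdir / "ppi.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_kinases": outdir / "truth_kinases.tsv",
        "metadata": outdir / "metadata.json",
    }
    write_fasta(result.proteome, paths["proteome"])
    write_site_table(result.sites, paths["sites"])
    with open(paths["kinase_substrates"], "w", encoding="utf-8") as fh:
        fh.write("kinase\tprotein_id\twindow\n")
        for profile in result.profiles:
            for window in profile.substrate_windows:
                fh.write(f"{profile.kinase_name}\t{profile.protein_id}\t{window}\n")
    write_ppi(result.ppi, paths["ppi"])
    truth = result.truth
    pd.DataFrame(
        [
            {
                "protein_id": pid,
                "position": pos,
                "kinase": kin,
                "true_log2_shift": truth.site_shift[(pid, pos)],
            }
            for (pid, pos), kin in sorted(truth.site_kinase.items())
        ]
    ).to_csv(paths["truth_sites"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"kinase": k, "direction": d, "protein_id": truth.kinase_protein[k]}
            for k, d in sorted(truth.kinase_direction.items())
        ]
    ).to_csv(paths["truth_kinases"], sep="\t", index=False)
    meta = {
        "seed": result.config.seed,
        "n_proteins": result.config.n_proteins,
        "residue_mix": result.config.residue_mix,
        "effect_size_delta": result.config.effect_size_delta,
        "baseline_sd_sigma0": result.config.baseline_sd_sigma0,
        "noise_sd": result.config.noise_sd,
        "background_aa_freqs": BACKGROUND_AA_FREQS,
    }
    with open(paths["metadata"], "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}


def read_kinase_substrates(path: str | Path) -> dict[str, KinaseProfile]:
    """Read a kinase substrate annotation TSV into uncalibrated profiles."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    profiles: dict[str, KinaseProfile] = {}
    for kinase, group in frame.groupby("kinase", sort=True):
        windows = tuple(group["window"])
        centers = {w[6] for w in windows}
        accepted = frozenset({"Y"}) if centers == {"Y"} else frozenset({"S", "T"})
        protein_id = group["protein_id"].iloc[0] if "protein_id" in group else None
        profiles[kinase] = KinaseProfile(
            kinase_name=str(kinase),
            substrate_windows=windows,
            accepted_residues=accepted,
            protein_id=protein_id,
        )
    return profiles
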