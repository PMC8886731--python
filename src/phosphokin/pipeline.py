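"""End-to-end orchestration of the analysis chain.

Stages run in dependency order: filter -> differential calling -> motif
profiling -> kinase-substrate prediction -> activity inference -> network
assembly -> optional pathway enrichment over a user GMT. Every stage
writes TSV/JSON artifacts into the output directory and the run records a
manifest of output SHA-256 hashes, so identical (config, seed) pairs
reproduce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from phosphokin import differential, gsea_engine, io_formats, kinase_network, ksr_predict, motif
from phosphokin.synthetic_data import SimConfig, read_kinase_substrates, simulate, write_outputs

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All paths and thresholds for one pipeline run."""

    sites_path: str
    proteome_path: str
    kinase_substrates_path: str
    ppi_path: str
    outdir: str
    gmt_path: str | None = None
    min_score: float = 40.0
    min_loc_prob: float = 0.75
    up_threshold: float = differential.DEFAULT_UP_THRESHOLD
    down_threshold: float = differential.DEFAULT_DOWN_THRESHOLD
    fpr: float = ksr_predict.FPR_MEDIUM
    require_ppi: bool = True
    n_perm: int = 1000
    weight_p: float = 1.0
    p_cutoff: float = 0.05
    min_set_size: int = gsea_engine.MIN_SET_SIZE
    max_set_size: int = gsea_engine.MAX_SET_SIZE
    n_background_windows: int = 1000
    seed: int = 7

    def validate(self) -> None:
        if not self.down_threshold < self.up_threshold:
            raise ValueError(
                f"up_threshold ({self.up_threshold}) must exceed "
                f"down_threshold ({self.down_threshold})"
            )
        if not 0 <= self.fpr <= 1:
            raise ValueError(f"fpr outside [0,1]: {self.fpr}")
        if not 0 <= self.min_loc_prob <= 1:
            raise ValueError(f"min_loc_prob outside [0,1]: {self.min_loc_prob}")
        for path_attr in ("sites_path", "proteome_path", "kinase_substrates_path", "ppi_path"):
            if not Path(getattr(self, path_attr)).exists():
                raise FileNotFoundError(f"{path_attr}: {getattr(self, path_attr)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sample_background_windows(
    proteome: dict[str, str],
    central_residues,
    n: int,
    rng: np.random.Generator,
) -> list[str]:
    """Random windows centered on the requested residues, for calibration."""
    positions = [
        (pid, idx + 1)
        for pid, seq in proteome.items()
        for idx, aa in enumerate(seq)
        if aa in central_residues
    ]
    if not positions:
        raise ValueError(f"proteome has no {sorted(central_residues)} residues")
    take = min(n, len(positions))
    chosen = rng.choice(len(positions), size=take, replace=False)
    return [io_formats.extract_window(proteome[positions[i][0]], positions[i][1]) for i in chosen]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the output manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # stage 1: read + quality filters
    table = io_formats.read_site_table(
        config.sites_path, min_score=config.min_score, min_loc_prob=config.min_loc_prob
    )
    logger.info(
        "filter: %s rows in, %d sites kept",
        table.provenance.get("n_rows_parsed"),
        len(table),
    )
    outputs["filtered_sites"] = outdir / "filtered_sites.tsv"
    io_formats.write_site_table(table, outputs["filtered_sites"])

    # stage 2: differential calling + summaries
    calls = differential.call_regulation(
        table, up_threshold=config.up_threshold, down_threshold=config.down_threshold
    )
    summary = differential.regulation_summary(calls)
    logger.info("diffcall: %d up / %d down / %d unchanged", summary["n_up"], summary["n_down"], summary["n_unchanged"])
    outputs["calls"] = outdir / "regulation_calls.tsv"
    calls.to_csv(outputs["calls"], sep="\t", index=False)
    outputs["summary"] = outdir / "differential_summary.json"
    with open(outputs["summary"], "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=str)

    # stage 3: motif profiles per central residue
    for residue in "STY":
        fg = calls.loc[(calls["status"] == differential.UP) & (calls["residue"] == residue), "window"]
        bg = calls.loc[calls["residue"] == residue, "window"]
        if len(fg) < 1 or len(bg) < 2:
            logger.warning("motif: skipping %s (fg=%d bg=%d)", residue, len(fg), len(bg))
            continue
        profile = motif.build_profile(list(fg), list(bg), residue)
        prefix = outdir / f"motif_{residue}"
        motif.write_profile(profile, prefix)
        for suffix in ("log2_enrichment", "p_values", "q_values"):
            outputs[f"motif_{residue}_{suffix}"] = Path(f"{prefix}.{suffix}.tsv")
        outputs[f"motif_{residue}_foreground_freq"] = Path(f"{prefix}.foreground_freq.tsv")

    # stage 4: kinase-substrate prediction
    proteome = io_formats.read_fasta(config.proteome_path)
    profiles = read_kinase_substrates(config.kinase_substrates_path)
    ppi = io_formats.read_ppi(config.ppi_path)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 99]))
    for profile in profiles.values():
        background = _sample_background_windows(
            proteome, profile.accepted_residues, config.n_background_windows, rng
        )
        ksr_predict.calibrate_threshold(profile, background, fpr=config.fpr)
    edges = ksr_predict.predict_ksrs(
        table, profiles.values(), ppi=ppi, require_ppi=config.require_ppi
    )
    logger.info("ksr: %d edges across %d kinases", len(edges), len(profiles))
    outputs["ksr_edges"] = outdir / "ksr_edges.tsv"
    ksr_predict.edges_to_frame(edges).to_csv(outputs["ksr_edges"], sep="\t", index=False)

    # stage 5: kinase activity inference
    ranked = gsea_engine.rank_sites(table, level="site")
    kin_sets = ksr_predict.substrate_sets(edges)
    results = gsea_engine.permutation_test(
        ranked,
        kin_sets,
        n_perm=config.n_perm,
        weight_p=config.weight_p,
        seed=config.seed,
        min_set_size=config.min_set_size,
        max_set_size=config.max_set_size,
    )
    activities = gsea_engine.classify_kinases(results, p_cutoff=config.p_cutoff)
    logger.info(
        "activity: %s",
        {a.kinase_name: a.direction for a in activities},
    )
    outputs["kinase_activity"] = outdir / "kinase_activity.tsv"
    gsea_engine.activities_to_frame(activities).to_csv(
        outputs["kinase_activity"], sep="\t", index=False
    )

    # stage 6: regulatory network
    network = kinase_network.build_network(activities, edges, calls)
    logger.info("network: %d nodes, %d edges", network.number_of_nodes(), network.number_of_edges())
    outputs["network_edges"] = outdir / "network_edges.tsv"
    kinase_network.network_to_frame(network).to_csv(outputs["network_edges"], sep="\t", index=False)
    outputs["network_graphml"] = outdir / "network.graphml"
    kinase_network.write_graphml(network, outputs["network_graphml"])

    # stage 7: optional pathway enrichment over a user-supplied GMT
    if config.gmt_path:
        gene_sets = io_formats.read_gmt(config.gmt_path)
        protein_ranked = gsea_engine.rank_sites(table, level="protein")
        gsea_results = gsea_engine.permutation_test(
            protein_ranked,
            gene_sets,
            n_perm=config.n_perm,
            weight_p=config.weight_p,
            seed=config.seed,
            min_set_size=config.min_set_size,
            max_set_size=config.max_set_size,
        )
        outputs["pathway_gsea"] = outdir / "pathway_gsea.tsv"
        gsea_engine.results_to_frame(gsea_results).to_csv(
            outputs["pathway_gsea"], sep="\t", index=False
        )
        up_proteins = sorted(set(calls.loc[calls["status"] == differential.UP, "protein_id"]))
        universe = sorted(set(calls["protein_id"]))
        ora_frame = gsea_engine.ora(up_proteins, universe, gene_sets)
        outputs["pathway_ora"] = outdir / "pathway_ora.tsv"
        ora_frame.to_csv(outputs["pathway_ora"], sep="\t", index=False)

    manifest = {
        "config": dataclasses.asdict(config),
        "outputs": {
            name: {"path": str(path), "sha256": _sha256(path)} for name, path in outputs.items()
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def demo(seed: int = 7, outdir: str | Path = "phosphokin_demo") -> dict:
    """One-command synthetic demo: simulate and run the full pipeline.

    Simulates 200 proteins with three planted kinases (one active, one
    inactive, one null) and runs every stage on the written files.
    """
    outdir = Path(outdir)
    sim_dir = outdir / "simulated"
    sim_config = SimConfig(seed=seed)
    result = simulate(sim_config)
    paths = write_outputs(result, sim_dir)
    config = PipelineConfig(
        sites_path=paths["sites"],
        proteome_path=paths["proteome"],
        kinase_substrates_path=paths["kinase_substrates"],
        ppi_path=paths["ppi"],
        outdir=str(outdir / "results"),
        seed=seed,
    )
    manifest = run_pipeline(config)
    manifest["simulated_inputs"] = paths
    return manifest


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
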