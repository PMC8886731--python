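import numpy as np
import pytest
from scipy import stats

from phosphokin.ksr_predict import calibrate_threshold, score_site
from phosphokin.synthetic_data import (
    BACKGROUND_AA_FREQS,
    ConfigurationError,
    SimConfig,
    generate_proteome,
    plant_kinases,
    simulate,
    simulate_quant,
)


class TestSimConfig:
    def test_defaults_are_valid(self):
        config = SimConfig()
        assert abs(sum(config.residue_mix.values()) - 1) < 1e-9

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"residue_mix": {"S": 0.5, "T": 0.4, "Y": 0.2}},   # sums to 1.1
            {"residue_mix": {"S": 1.0, "T": 0.0}},             # missing key
            {"active_kinases": {"KIN1"}, "inactive_kinases": {"KIN1"}},
            {"n_proteins": 0},
            {"substrates_per_kinase": 0},
            {"noise_sd": 0.0},
            {"active_kinases": {"NOPE"}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimConfig(**kwargs)


class TestGenerateProteome:
    def test_same_seed_is_byte_identical(self):
        config = SimConfig(n_proteins=20, seed=42)
        assert generate_proteome(config) == generate_proteome(config)

    def test_record_count(self):
        assert len(generate_proteome(SimConfig(n_proteins=50, seed=1))) == 50

    def test_lengths_in_range(self):
        for seq in generate_proteome(SimConfig(n_proteins=30, seed=2)).values():
            assert 200 <= len(seq) <= 600

    def test_composition_matches_background_table(self):
        proteome = generate_proteome(SimConfig(n_proteins=500, seed=3))
        joined = "".join(proteome.values())
        total = len(joined)
        for aa, expected in BACKGROUND_AA_FREQS.items():
            observed = joined.count(aa) / total
            assert abs(observed - expected) < 0.02


class TestPlantKinases:
    def test_proline_directed_kinase_has_proline_at_plus_one(self):
        config = SimConfig(seed=7)
        proteome = generate_proteome(config)
        profiles, _ = plant_kinases(proteome, config)
        kin1 = next(p for p in profiles if p.kinase_name == "KIN1")
        assert all(w[7] == "P" for w in kin1.substrate_windows)
        assert all(w[6] == "S" for w in kin1.substrate_windows)

    def test_ground_truth_maps_every_planted_site_once(self):
        config = SimConfig(n_kinases=3, substrates_per_kinase=20, seed=1)
        proteome = generate_proteome(config)
        _, truth = plant_kinases(proteome, config)
        assert len(truth.site_kinase) == 60

    def test_windows_match_rewritten_proteome(self):
        config = SimConfig(seed=9)
        proteome = generate_proteome(config)
        profiles, truth = plant_kinases(proteome, config)
        by_kinase = {}
        for (pid, pos), kin in truth.site_kinase.items():
            by_kinase.setdefault(kin, []).append(proteome[pid][pos - 1])
        for profile in profiles:
            centers = {w[6] for w in profile.substrate_windows}
            assert set(by_kinase[profile.kinase_name]) == centers

    def test_planted_windows_score_above_calibrated_threshold(self):
        config = SimConfig(seed=4)
        proteome = generate_proteome(config)
        profiles, _ = plant_kinases(proteome, config)
        rng = np.random.default_rng(0)
        for profile in profiles:
            central = next(iter(profile.accepted_residues))
            positions = [
                (pid, i + 1)
                for pid, seq in proteome.items()
                for i, aa in enumerate(seq)
                if aa == central
            ]
            chosen = rng.choice(len(positions), size=500, replace=False)
            background = []
            for i in chosen:
                pid, pos = positions[i]
                seq = proteome[pid]
                if 7 <= pos <= len(seq) - 6:
                    background.append(seq[pos - 7 : pos + 6])
            calibrate_threshold(profile, background, fpr=0.06)
            hits = [score_site(w, profile) >= profile.threshold for w in profile.substrate_windows]
            assert np.mean(hits) >= 0.9


class TestSimulateQuant:
    def test_null_config_with_tiny_noise_gives_unit_ratios(self):
        config = SimConfig(
            effect_size_delta=0.0, baseline_sd_sigma0=1e-12, noise_sd=1e-12, seed=5
        )
        result = simulate(config)
        assert np.allclose(result.sites.frame["ratio"], 1.0, atol=1e-9)

    def test_active_substrate_mean_near_delta(self):
        config = SimConfig(seed=6)
        result = simulate(config)
        truth, frame = result.truth, result.sites.frame
        active_sites = {
            (p, pos) for (p, pos), k in truth.site_kinase.items() if k in config.active_kinases
        }
        mask = [(p, pos) in active_sites for p, pos in zip(frame["protein_id"], frame["position"])]
        observed = frame.loc[mask, "log2_ratio"]
        total_sd = np.hypot(config.noise_sd, config.baseline_sd_sigma0)
        assert abs(observed.mean() - config.effect_size_delta) < 3 * total_sd / np.sqrt(len(observed))

    def test_background_residue_mix_within_binomial_ci(self):
        # ~5,000 sites; planted sites excluded so only the sampled mix is tested
        config = SimConfig(n_proteins=2000, mean_sites_per_protein=2.5, seed=8)
        result = simulate(config)
        frame = result.sites.frame
        planted = set(result.truth.site_kinase)
        mask = [
            (p, pos) not in planted for p, pos in zip(frame["protein_id"], frame["position"])
        ]
        background = frame.loc[mask]
        n = len(background)
        for residue, expected in config.residue_mix.items():
            count = int((background["residue"] == residue).sum())
            low, high = stats.binom.interval(0.99, n, expected)
            assert low <= count <= high

    def test_windows_consistent_with_proteome(self):
        result = simulate(SimConfig(seed=10))
        for rec in list(result.sites.records())[:50]:
            seq = result.proteome[rec.protein_id]
            assert seq[rec.position - 1] == rec.residue
            assert rec.window[6] == rec.residue

    def test_full_simulation_deterministic(self):
        a = simulate(SimConfig(seed=12))
        b = simulate(SimConfig(seed=12))
        assert a.proteome == b.proteome
        assert a.sites.frame.equals(b.sites.frame)
        assert a.ppi.edges == b.ppi.edges

    def test_quant_alone_deterministic_given_inputs(self):
        config = SimConfig(seed=13)
        proteome = generate_proteome(config)
        _, truth = plant_kinases(proteome, config)
        t1 = simulate_quant(proteome, truth, config)
        t2 = simulate_quant(proteome, truth, config)
        assert t1.frame.equals(t2.frame)
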