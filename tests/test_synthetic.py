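"""The synthetic-data generator: determinism, planted truths, null behaviour."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ranksig.errors import ConfigError
from ranksig.ranks import (
    build_grp,
    compendium_background_ranks,
    compute_scaled_ranks,
    rank_panel,
)
from ranksig.synth import (
    SimConfig,
    TruthRecord,
    check_truth,
    default_config,
    generate_background_compendium,
    generate_coexpression_compendium,
    generate_experiment,
    generate_panel,
    generate_signature_bank,
)
from ranksig.differential import SignedGeneSignature


class TestConfigValidation:
    def test_planted_gene_outside_universe(self):
        with pytest.raises(ConfigError):
            SimConfig(n_genes=10, planted_de=[("G99999", 2.0)])

    def test_concordance_fraction_bounds(self):
        with pytest.raises(ConfigError):
            SimConfig(planted_drugs=[("d", 1.5)])

    def test_probe_budget_below_mapped_total(self):
        with pytest.raises(ConfigError):
            generate_experiment(SimConfig(n_genes=100, n_probes=50, seed=1))

    def test_probe_distribution_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimConfig(probes_per_gene={1: 0.5, 2: 0.1})


class TestExperiment:
    def test_shape_and_groups(self, small_config, small_experiment):
        experiment, pmap, _ = small_experiment
        assert experiment.n_samples == 2 * 2 * small_config.replicates_per_arm
        assert len(experiment.samples_in_group("core:vehicle")) == 4
        assert set(pmap.genes()) <= set(small_config.gene_names())

    def test_determinism_byte_identical(self, small_config):
        a, _, _ = generate_experiment(small_config)
        b, _, _ = generate_experiment(dataclasses.replace(small_config))
        assert a.values.to_csv() == b.values.to_csv()

    def test_seed_changes_output(self, small_config):
        a, _, _ = generate_experiment(small_config)
        b, _, _ = generate_experiment(dataclasses.replace(small_config, seed=12))
        assert not a.values.equals(b.values)

    def test_no_planted_signal_centres_on_zero(self):
        cfg = SimConfig(n_genes=500, seed=3)
        experiment, _, _ = generate_experiment(cfg)
        treated = experiment.values[experiment.samples_in_group("core:treated")]
        control = experiment.values[experiment.samples_in_group("core:vehicle")]
        diff = treated.mean(axis=1) - control.mean(axis=1)
        assert abs(diff.mean()) < 0.02
        assert diff.abs().max() < 1.5  # pure noise at sd 0.25, 4v4

    def test_planted_effect_recovered_in_mean(self):
        """Monte-Carlo check of the generator's own stated model: the
        empirical mean log2FC of a +2 gene is within ±0.2 of 2 over 100 runs."""
        lfcs = []
        for seed in range(100):
            cfg = SimConfig(n_genes=30, planted_de=[("G00005", 2.0)], seed=seed)
            experiment, pmap, _ = generate_experiment(cfg)
            probes = pmap.probes_for("G00005")
            treated = experiment.values[experiment.samples_in_group("core:treated")]
            control = experiment.values[experiment.samples_in_group("core:vehicle")]
            diff = treated.mean(axis=1) - control.mean(axis=1)
            lfcs.append(diff.loc[probes].mean())
        assert np.mean(lfcs) == pytest.approx(2.0, abs=0.2)


class TestBackground:
    def test_series_share_probe_universe(self, small_config):
        series = generate_background_compendium(small_config)
        assert len(series) == small_config.n_background_series
        first = series[0].values.index
        assert all(m.values.index.equals(first) for m in series)

    def test_constitutive_probes_at_rank_extremes(self, small_config):
        from ranksig.synth import _universe
        uni = _universe(small_config)
        series = generate_background_compendium(small_config)
        r0 = compendium_background_ranks(series).ranks
        assert r0.loc[uni.const_high].max() < 0.05   # 0 = highest expression
        assert r0.loc[uni.const_low].min() > 0.95

    def test_too_few_series_rejected(self, small_config):
        with pytest.raises(ConfigError):
            generate_background_compendium(
                dataclasses.replace(small_config, n_background_series=1)
            )


class TestPanel:
    @pytest.fixture(scope="class")
    def grps(self, small_config, small_experiment):
        experiment, pmap, _ = small_experiment
        r0 = compendium_background_ranks(generate_background_compendium(small_config))
        out = {}
        for line in ("core", "margin"):
            r = compute_scaled_ranks(
                experiment, experiment.samples_in_group(f"{line}:vehicle")
            )
            out[line] = build_grp(r, r0, pmap, name=line)
        return out

    def test_twin_recorded_and_ranks_first(self, small_config, grps):
        truth = TruthRecord()
        panel = generate_panel(small_config, grps["core"], grps["margin"], truth)
        assert truth.panel_twin is not None
        rows = rank_panel(grps["core"], panel)
        assert rows[0][0] == truth.panel_twin
        assert rows[0][1].rho > 0.9

    def test_zero_noise_twin_is_perfect(self, small_config, grps):
        cfg = dataclasses.replace(small_config, panel_noise=0.0)
        truth = TruthRecord()
        panel = generate_panel(cfg, grps["core"], grps["margin"], truth)
        twin = dict(panel)[truth.panel_twin]
        rows = rank_panel(grps["core"], [(truth.panel_twin, twin)])
        assert rows[0][1].rho == pytest.approx(1.0)

    def test_independent_entities_uncorrelated(self, small_config, grps):
        truth = TruthRecord()
        panel = generate_panel(small_config, grps["core"], grps["margin"], truth)
        rhos = [res.rho for name, res in rank_panel(grps["core"], panel)
                if name != truth.panel_twin]
        # null Spearman SD is 1/sqrt(n−1) ≈ 0.06 at ~290 genes
        assert max(abs(r) for r in rhos) < 0.25


class TestSignatureBank:
    @pytest.fixture(scope="class")
    def reference(self):
        genes = [f"G{i:05d}" for i in range(1, 301)]
        return SignedGeneSignature(frozenset(genes[10:30]), frozenset(genes[50:70]))

    def test_full_concordance_replicates_reference(self, small_config, reference):
        cfg = dataclasses.replace(small_config, planted_drugs=[("exact", 1.0)])
        bank = generate_signature_bank(cfg, reference)
        sig = bank.signatures["exact"]
        assert sig.up == reference.up and sig.down == reference.down

    def test_zero_concordance_is_full_swap(self, small_config, reference):
        cfg = dataclasses.replace(small_config, planted_drugs=[("swap", 0.0)])
        bank = generate_signature_bank(cfg, reference)
        sig = bank.signatures["swap"]
        assert sig.up == reference.down and sig.down == reference.up

    def test_decoys_size_matched(self, small_config, reference):
        bank = generate_signature_bank(small_config, reference)
        decoys = [s for n, s in bank.items() if n.startswith("DECOY")]
        assert len(bank) == small_config.bank_size
        assert all(len(d.up) == len(reference.up) for d in decoys)

    def test_decoy_overlap_near_independence(self, small_config, reference):
        """Mean decoy overlap with the reference ≈ hypergeometric expectation."""
        bank = generate_signature_bank(small_config, reference)
        n_ref, universe = len(reference.up), small_config.n_genes
        expected = len(reference.up) * n_ref / universe  # E|q.up ∩ t.up|
        overlaps = [len(reference.up & sig.up)
                    for name, sig in bank.items() if name.startswith("DECOY")]
        assert np.mean(overlaps) == pytest.approx(expected, abs=1.0)


class TestCoexpressionCompendium:
    def test_module_gene_tracks_tf(self, small_config):
        compendium = generate_coexpression_compendium(small_config)
        tf, module = small_config.planted_tf_modules[0][:2]
        stacked = pd.concat([m.values for m in compendium], axis=1)
        rho = np.corrcoef(stacked.loc[tf], stacked.loc[module[0]])[0, 1]
        assert rho > 0.7

    def test_antimodule_gene_anticorrelated(self, small_config):
        compendium = generate_coexpression_compendium(small_config)
        tf, _, antimodule = small_config.planted_tf_modules[0]
        stacked = pd.concat([m.values for m in compendium], axis=1)
        rho = np.corrcoef(stacked.loc[tf], stacked.loc[antimodule[0]])[0, 1]
        assert rho < -0.7

    def test_nonmodule_pair_uncorrelated(self, small_config):
        compendium = generate_coexpression_compendium(small_config)
        stacked = pd.concat([m.values for m in compendium], axis=1)
        rho = np.corrcoef(stacked.loc["G00250"], stacked.loc["G00260"])[0, 1]
        assert abs(rho) < 0.25

    def test_requires_planted_modules(self, small_config):
        with pytest.raises(ConfigError):
            generate_coexpression_compendium(
                dataclasses.replace(small_config, planted_tf_modules=[])
            )


class TestTruthRecord:
    def test_round_trip_lossless(self, small_experiment):
        _, _, truth = small_experiment
        again = TruthRecord.from_dict(truth.to_dict())
        assert again == truth

    def test_check_truth_passes_for_generated(self, small_config, small_experiment):
        _, _, truth = small_experiment
        check_truth(truth, small_config)

    def test_check_truth_catches_aliens(self, small_config):
        truth = TruthRecord(de=[("NOT_A_GENE", 2.0)])
        with pytest.raises(ConfigError):
            check_truth(truth, small_config)


def test_default_config_is_valid_and_deterministic():
    a, b = default_config(3), default_config(3)
    assert a == b
    ea, _, _ = generate_experiment(a)
    eb, _, _ = generate_experiment(b)
    assert ea.values.to_csv() == eb.values.to_csv()
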