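"""Synthetic-study generator: determinism, planted constructions, calibration."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from regloop import (
    GroundTruth,
    SimConfig,
    simulate_cellline_expression,
    simulate_drug_response,
    simulate_expression,
    simulate_regulome,
    spearman,
    write_fixture,
)


def file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(frac_de=1.5)
        with pytest.raises(ValueError):
            SimConfig(planted_rho=1.0)
        with pytest.raises(ValueError):
            SimConfig(noise_sd=0.0)
        with pytest.raises(ValueError):
            SimConfig(n_genes=-1)


class TestRegulome:
    def test_null_case_empty(self):
        cfg = SimConfig(edge_prob=0.0, n_planted_ffls=0,
                        n_planted_drug_pairs=0, seed=1)
        catalog, truth = simulate_regulome(cfg)
        assert catalog == [] and truth.planted_ffls == []

    def test_planted_ffls_fully_constructed(self):
        cfg = SimConfig(n_planted_ffls=5, seed=2)
        catalog, truth = simulate_regulome(cfg)
        assert len(truth.planted_ffls) == 5
        assert len(truth.planted_edges) >= 15
        pairs = {(e.source, e.target) for e in catalog}
        arms = {
            "TF-FFL": lambda tf, mi, g: [(tf, mi), (tf, g), (mi, g)],
            "miRNA-FFL": lambda tf, mi, g: [(mi, tf), (tf, g), (mi, g)],
            "composite-FFL": lambda tf, mi, g: [(tf, mi), (mi, tf), (tf, g), (mi, g)],
        }
        de = truth.de_features
        triples = set()
        for tf, mi, g, cls in truth.planted_ffls:
            assert len({tf, mi, g}) == 3
            assert {tf, mi, g} <= de  # planted only among differential features
            for edge in arms[cls](tf, mi, g):
                assert edge in pairs
            triples.add((tf, mi, g))
        assert len(triples) == 5

    def test_no_duplicate_or_self_edges(self):
        catalog, _ = simulate_regulome(SimConfig(edge_prob=0.1, seed=3))
        pairs = [(e.source, e.target) for e in catalog]
        assert len(pairs) == len(set(pairs))
        assert all(s != t for s, t in pairs)

    def test_evidence_labels_valid(self):
        catalog, _ = simulate_regulome(SimConfig(seed=4))
        assert {e.evidence for e in catalog} <= {"experimental", "predicted"}

    def test_infeasible_planting_rejected(self):
        with pytest.raises(ValueError, match="cannot plant"):
            simulate_regulome(SimConfig(n_tfs=2, n_mirnas=2, n_genes=4,
                                        frac_de=0.5, n_planted_ffls=50,
                                        n_planted_drug_pairs=0))

    def test_deterministic(self):
        a = simulate_regulome(SimConfig(seed=42))
        b = simulate_regulome(SimConfig(seed=42))
        assert a[0] == b[0]
        assert a[1].planted_ffls == b[1].planted_ffls

    def test_drug_pairs_reference_existing_ids(self):
        cfg = SimConfig(seed=5)
        _, truth = simulate_regulome(cfg)
        assert len(truth.planted_drug_pairs) == cfg.n_planted_drug_pairs
        for d, g, s in truth.planted_drug_pairs:
            assert d in cfg.drug_ids
            assert g in cfg.gene_ids
            assert s in (-1, 1)


class TestExpression:
    def test_planted_shift_within_sampling_error(self):
        """Observed group-mean difference ~ planted_log2fc +- Gaussian error."""
        cfg = SimConfig(seed=6, n_samples_per_group=15)
        _, truth = simulate_regulome(cfg)
        genes, _ = simulate_expression(cfg, truth)
        tol = 4 * cfg.noise_sd * np.sqrt(2 / cfg.n_samples_per_group)
        for comp, mat in genes.items():
            case = mat.values[mat.samples_in_group("case")].mean(axis=1)
            ctrl = mat.values[mat.samples_in_group("control")].mean(axis=1)
            diff = case - ctrl
            for f in truth.de_genes_up:
                assert abs(diff[f] - cfg.planted_log2fc) < tol
            for f in truth.de_genes_down:
                assert abs(diff[f] + cfg.planted_log2fc) < tol

    def test_noise_free_limit_exact(self):
        cfg = SimConfig(seed=7, noise_sd=1e-9, planted_log2fc=2.0)
        _, truth = simulate_regulome(cfg)
        genes, _ = simulate_expression(cfg, truth)
        mat = genes["A"]
        diff = (mat.values[mat.samples_in_group("case")].mean(axis=1)
                - mat.values[mat.samples_in_group("control")].mean(axis=1))
        some_up = sorted(truth.de_genes_up)[0]
        assert diff[some_up] == pytest.approx(2.0, abs=1e-6)

    def test_null_model_no_shift(self):
        cfg = SimConfig(seed=8, frac_de=0.0, n_planted_ffls=0,
                        n_planted_drug_pairs=0, n_samples_per_group=30)
        _, truth = simulate_regulome(cfg)
        genes, _ = simulate_expression(cfg, truth)
        mat = genes["A"]
        diff = (mat.values[mat.samples_in_group("case")].mean(axis=1)
                - mat.values[mat.samples_in_group("control")].mean(axis=1))
        # each diff ~ N(0, noise_sd*sqrt(2/30)); mean |diff| stays small
        assert abs(diff.mean()) < 0.05
        assert diff.abs().mean() < 0.25

    def test_mirna_counts_are_nonnegative_integers(self):
        cfg = SimConfig(seed=9)
        _, truth = simulate_regulome(cfg)
        _, mirnas = simulate_expression(cfg, truth)
        arr = mirnas["A"].values.to_numpy()
        assert (arr >= 0).all()
        assert np.array_equal(arr, arr.astype(int))

    def test_mirna_fold_shift_direction(self):
        cfg = SimConfig(seed=10)
        _, truth = simulate_regulome(cfg)
        _, mirnas = simulate_expression(cfg, truth)
        mat = mirnas["A"]
        case = mat.values[mat.samples_in_group("case")].mean(axis=1)
        ctrl = mat.values[mat.samples_in_group("control")].mean(axis=1)
        for f in truth.de_mirnas_up:
            assert case[f] > ctrl[f]
        for f in truth.de_mirnas_down:
            assert case[f] < ctrl[f]

    def test_mismatched_truth_rejected(self):
        cfg = SimConfig(seed=11)
        _, truth = simulate_regulome(cfg)
        truth.de_genes_up.add("NOT_A_FEATURE")
        with pytest.raises(ValueError, match="unknown features"):
            simulate_expression(cfg, truth)


class TestDrugResponse:
    def test_monotone_limit_perfect_correlation(self):
        cfg = SimConfig(seed=12, planted_rho=0.999)
        _, truth = simulate_regulome(cfg)
        expr = simulate_cellline_expression(cfg)
        ic50 = simulate_drug_response(cfg, expr, truth)
        for d, g, s in truth.planted_drug_pairs:
            rho, _ = spearman(ic50.loc[d].to_numpy(), expr.loc[g].to_numpy())
            assert rho == pytest.approx(s * 1.0, abs=0.02)

    def test_null_screen_calibrated(self):
        """Without plants, ~5% of pairs reach p<0.05 (99% binomial band)."""
        cfg = SimConfig(seed=13, n_drugs=20, n_genes=50, n_tfs=0, n_mirnas=5,
                        n_planted_drug_pairs=0, n_planted_ffls=0,
                        n_cell_lines=60)
        _, truth = simulate_regulome(cfg)
        expr = simulate_cellline_expression(cfg)
        ic50 = simulate_drug_response(cfg, expr, truth)
        hits = 0
        n_pairs = 0
        for d in cfg.drug_ids:
            dv = ic50.loc[d].to_numpy()
            for g in cfg.gene_ids:
                _, p = spearman(dv, expr.loc[g].to_numpy())
                hits += p < 0.05
                n_pairs += 1
        assert n_pairs == 1000
        lo, hi = stats.binom.ppf([0.005, 0.995], n_pairs, 0.05)
        assert lo <= hits <= hi

    def test_deterministic(self):
        cfg = SimConfig(seed=14)
        _, truth = simulate_regulome(cfg)
        expr = simulate_cellline_expression(cfg)
        a = simulate_drug_response(cfg, expr, truth)
        b = simulate_drug_response(cfg, expr, truth)
        assert a.equals(b)

    def test_absent_gene_rejected(self):
        cfg = SimConfig(seed=15)
        _, truth = simulate_regulome(cfg)
        expr = simulate_cellline_expression(cfg)
        truth.planted_drug_pairs.append(("DRUG001", "NOPE", 1))
        with pytest.raises(ValueError, match="absent genes"):
            simulate_drug_response(cfg, expr, truth)

    def test_wrong_cell_line_count_rejected(self):
        cfg = SimConfig(seed=16)
        _, truth = simulate_regulome(cfg)
        expr = simulate_cellline_expression(cfg).iloc[:, :10]
        with pytest.raises(ValueError, match="cell lines"):
            simulate_drug_response(cfg, expr, truth)


class TestWriteFixture:
    def test_manifest_and_roundtrip(self, fixture_dir, default_config):
        from regloop.io import read_expression_tsv

        d, manifest = fixture_dir
        assert len(manifest) >= 6
        assert all(p.exists() for p in manifest.values())
        # round trip preserves simulated values to 12 significant digits
        expr = read_expression_tsv(manifest["gene_expression"])
        _, truth = simulate_regulome(default_config)
        genes, _ = simulate_expression(default_config, truth)
        import pandas as pd

        combined = pd.concat([genes["A"].values, genes["B"].values], axis=1)
        assert np.allclose(expr.to_numpy(), combined.to_numpy(), rtol=1e-11)

    def test_identical_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=20, n_genes=40, n_tfs=10, n_mirnas=10,
                        n_planted_ffls=2, n_cell_lines=20)
        m1 = write_fixture(tmp_path / "a", cfg)
        m2 = write_fixture(tmp_path / "b", cfg)
        for key in m1:
            assert file_hash(m1[key]) == file_hash(m2[key]), key

    def test_different_seeds_differ(self, tmp_path):
        base = dict(n_genes=40, n_tfs=10, n_mirnas=10, n_planted_ffls=2,
                    n_cell_lines=20)
        m1 = write_fixture(tmp_path / "a", SimConfig(seed=1, **base))
        m2 = write_fixture(tmp_path / "b", SimConfig(seed=2, **base))
        assert file_hash(m1["gene_expression"]) != file_hash(m2["gene_expression"])

    def test_ground_truth_json_roundtrip(self, fixture_dir, fixture_truth):
        _, manifest = fixture_dir
        again = GroundTruth.from_json(manifest["ground_truth"].read_text())
        assert again.planted_ffls == fixture_truth.planted_ffls
        assert again.de_genes_up == fixture_truth.de_genes_up
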