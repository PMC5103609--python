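"""Covariates, initialization, bias fitting and copy-number normalization."""

import numpy as np
import pytest

from xenolink import synthetic
from xenolink.quantify import (
    BiasModel,
    GeneData,
    TrainingFilter,
    build_gene_data,
    compute_covariates,
    estimate_copy_numbers,
    fit_bias_model,
    initialize_v,
    select_training_genes,
)


def _gene(species, gene, length, coverage=None, read_start=None, m=None,
          g=None, n_variants=1):
    n = length
    return GeneData(
        species=species,
        gene_id=gene,
        length=n,
        n_variants=n_variants,
        coverage=np.zeros(n, dtype=np.int64) if coverage is None else coverage,
        read_start=np.zeros(n, dtype=np.int64) if read_start is None else read_start,
        m=np.full(n, 50, dtype=np.int32) if m is None else m,
        g=np.full(n, 0.5) if g is None else g,
        d=np.arange(1, n + 1, dtype=np.float64),
    )


class TestCovariates:
    def test_all_g_transcript_has_gc_one(self):
        g, d = compute_covariates("G" * 120)
        assert np.allclose(g, 1.0)

    def test_all_a_transcript_has_gc_zero(self):
        g, _ = compute_covariates("A" * 120)
        assert np.allclose(g, 0.0)

    def test_distance_convention_one_based_from_three_prime(self):
        _, d = compute_covariates("ACGT" * 30)
        assert d[0] == 1 and d[-1] == 120

    def test_gc_window_is_local_and_poly_a_oriented(self):
        # 100 A's then 100 G's (5'→3'): the 3' end (index 0) is G-rich
        g, _ = compute_covariates("A" * 100 + "G" * 100)
        assert g[0] == 1.0
        assert g[-1] == 0.0
        assert 0.0 < g[100] < 1.0  # junction mixes both


class TestInitializeV:
    def test_uniform_coverage_full_mappability(self):
        gd = _gene("human", "G", 1000,
                   coverage=np.full(1000, 5, dtype=np.int64),
                   m=np.ones(1000, dtype=np.int32))
        # each term is 5; summed over N' = 1000 positions
        assert initialize_v(gd) == pytest.approx(5000.0)

    def test_zero_counts_give_zero(self):
        assert initialize_v(_gene("human", "G", 500)) == 0.0

    def test_only_first_3000_positions_used(self):
        cov = np.zeros(10000, dtype=np.int64)
        cov[5000:] = 1000  # far from the poly-A tail; must be ignored
        cov[:3000] = 2
        gd = _gene("human", "G", 10000, coverage=cov,
                   m=np.ones(10000, dtype=np.int32))
        assert initialize_v(gd) == pytest.approx(2 * 3000)

    def test_all_unmappable_prefix_gives_zero(self):
        gd = _gene("human", "G", 1000,
                   coverage=np.full(1000, 5, dtype=np.int64),
                   m=np.zeros(1000, dtype=np.int32))
        assert initialize_v(gd) == 0.0


class TestTrainingSelection:
    def test_filters_applied(self):
        data = {
            ("human", "OK"): _gene("human", "OK", 9000,
                                   coverage=np.ones(9000, dtype=np.int64)),
            ("human", "SPLICED"): _gene("human", "SPLICED", 9000,
                                        coverage=np.ones(9000, dtype=np.int64),
                                        n_variants=2),
            ("human", "SHORT"): _gene("human", "SHORT", 3000,
                                      coverage=np.ones(3000, dtype=np.int64)),
            ("human", "SPARSE"): _gene("human", "SPARSE", 9000),
        }
        data[("human", "SPARSE")].coverage[:900] = 1  # 10 % covered
        assert select_training_genes(data) == [("human", "OK")]

    def test_relaxed_fallback_when_selection_empty(self, small_gene_data):
        # synthetic transcripts are 2-4 kb: nothing passes the 8 kb default,
        # so the fit must fall back to relaxed thresholds and still converge
        model = fit_bias_model(small_gene_data, max_iterations=20)
        assert model.converged


class TestEstimateCopyNumbers:
    def _flat_profile(self, totals, length=1000):
        data = {}
        for i, tot in enumerate(totals):
            rs = np.zeros(length, dtype=np.int64)
            rs[: length // 2] = tot // (length // 2)
            data[("human", f"G{i}")] = _gene("human", f"G{i}", length,
                                             read_start=rs)
        return data

    def test_sum_at_or_below_95th_percentile_is_300k(self):
        data = self._flat_profile([100 * (i + 1) for i in range(40)])
        profiles = estimate_copy_numbers(data, BiasModel(alpha=0.0, beta=0.0))
        p = profiles["human"]
        vals = np.array([p.raw[g] for g in p.raw if p.raw[g] > 0])
        below = vals[vals <= p.percentile_cutoff]
        assert below.sum() / p.z == pytest.approx(300_000.0, rel=1e-9)

    def test_ratios_preserved_and_scale_invariant(self):
        data = self._flat_profile([1000, 3000, 2000, 4000, 8000, 500])
        p1 = estimate_copy_numbers(data, BiasModel(0.0, 0.0))["human"].normalized
        assert p1["G1"] / p1["G0"] == pytest.approx(3.0)
        doubled = self._flat_profile([2000, 6000, 4000, 8000, 16000, 1000])
        p2 = estimate_copy_numbers(doubled, BiasModel(0.0, 0.0))["human"].normalized
        for g in p1:
            assert p2[g] == pytest.approx(p1[g])

    def test_tpm_like_limit_inverse_length_scaling(self):
        # equal read-start totals, different lengths: the no-bias estimate
        # is a per-mappable-nucleotide rate, i.e. count/length
        data = {}
        for name, length in (("SHORT", 1000), ("LONG", 4000)):
            rs = np.zeros(length, dtype=np.int64)
            rs[:500] = 8
            data[("human", name)] = _gene("human", name, length, read_start=rs)
        prof = estimate_copy_numbers(data, BiasModel(0.0, 0.0))["human"]
        assert prof.raw["SHORT"] / prof.raw["LONG"] == pytest.approx(4.0)

    def test_masked_homologous_block_leaves_estimate_unchanged(self):
        # uniform read starts; masking a block (m=0, no reads there) must
        # not change the per-gene estimate: mappable-length normalisation
        full = _gene("human", "G", 2000,
                     read_start=np.full(2000, 3, dtype=np.int64))
        rs = np.full(2000, 3, dtype=np.int64)
        m = np.full(2000, 50, dtype=np.int32)
        rs[800:1300] = 0
        m[800:1300] = 0
        masked = _gene("human", "G2", 2000, read_start=rs, m=m)
        prof = estimate_copy_numbers(
            {("human", "G"): full, ("human", "G2"): masked}, BiasModel(0.0, 0.0)
        )["human"]
        assert prof.raw["G2"] == pytest.approx(prof.raw["G"])

    def test_all_zero_expression_is_error(self):
        data = {("human", "G"): _gene("human", "G", 500)}
        with pytest.raises(ValueError):
            estimate_copy_numbers(data, BiasModel(0.0, 0.0))


class TestBiasModelFit:
    def test_null_bias_recovered_as_zero(self):
        cfg = synthetic.SimulationConfig(
            seed=21, n_genes=12, n_pairs=30000, alpha_true=0.0, beta_true=0.0,
            homolog_fraction=0.0,
        )
        tx = synthetic.simulate_transcriptomes(cfg)
        counts = synthetic.simulate_counts(cfg, tx)
        gd = build_gene_data(counts, {}, tx.transcripts)
        model = fit_bias_model(
            gd, filters=TrainingFilter(min_length=2000, min_covered_fraction=0.5)
        )
        assert abs(model.alpha) < 0.1
        assert abs(model.beta) < 5e-5

    def test_known_bias_recovered_within_ten_percent(self):
        cfg = synthetic.SimulationConfig(
            seed=22, n_genes=30, n_pairs=60000, homolog_fraction=0.0,
        )
        tx = synthetic.simulate_transcriptomes(cfg)
        counts = synthetic.simulate_counts(cfg, tx)
        gd = build_gene_data(counts, {}, tx.transcripts)
        model = fit_bias_model(
            gd, filters=TrainingFilter(min_length=2000, min_covered_fraction=0.5)
        )
        assert model.converged
        assert abs(model.alpha - cfg.alpha_true) / abs(cfg.alpha_true) < 0.1
        assert abs(model.beta - cfg.beta_true) / abs(cfg.beta_true) < 0.1

    def test_shared_bias_consistent_across_species(self):
        """Human-only and mouse-only training recover the same coefficients."""
        cfg = synthetic.SimulationConfig(
            seed=23, n_genes=30, n_pairs=80000, homolog_fraction=0.0,
        )
        tx = synthetic.simulate_transcriptomes(cfg)
        counts = synthetic.simulate_counts(cfg, tx)
        gd = build_gene_data(counts, {}, tx.transcripts)
        models = {
            sp: fit_bias_model(
                gd, training_keys=[k for k in gd if k[0] == sp]
            )
            for sp in ("human", "mouse")
        }
        assert models["human"].alpha == pytest.approx(models["mouse"].alpha,
                                                      abs=0.15)
        assert models["human"].beta == pytest.approx(models["mouse"].beta,
                                                     abs=1e-4)

    def test_too_few_training_genes_is_error(self, small_gene_data):
        keys = list(small_gene_data)[:1]
        with pytest.raises(ValueError):
            fit_bias_model(small_gene_data, training_keys=keys)


def test_model_json_and_expression_tsv_outputs(tmp_path, small_gene_data):
    import json

    from xenolink.quantify import ExpressionProfile

    model = BiasModel(alpha=-1.5, beta=-1e-3, v={("human", "G"): 12.345678})
    model.to_json(tmp_path / "model.json")
    payload = json.loads((tmp_path / "model.json").read_text())
    assert payload["alpha"] == -1.5
    assert payload["v"]["human:G"] == 12.3457  # 6 significant digits

    profiles = estimate_copy_numbers(small_gene_data, BiasModel(0.0, 0.0))
    path = tmp_path / "expr.tsv"
    profiles["human"].to_tsv(path)
    back = ExpressionProfile.from_tsv(path, "human")
    assert set(back.normalized) == set(profiles["human"].normalized)
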