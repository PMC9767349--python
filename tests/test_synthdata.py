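"""Synthetic-data generators: truth consistency, round-trips, calibration."""

import numpy as np
import pytest

from hifburden import (
    BURDEN,
    BurdenModel,
    CohortSimConfig,
    ConfigurationError,
    ExpressionSimConfig,
    GeneSpec,
    SampleSource,
    carrier_matrix,
    filter_qualifying,
    parse_cohort,
    simulate_cohort,
    simulate_expression,
    summarize_candidates,
    write_cohort,
)


class TestCohortSimulation:
    def test_same_seed_bit_identical(self):
        first = simulate_cohort(CohortSimConfig(seed=5))
        second = simulate_cohort(CohortSimConfig(seed=5))
        assert first[0] == second[0]
        assert first[1].equals(second[1])
        assert first[2].carriers.equals(second[2].carriers)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortSimConfig(fraction_mosaic=1.5)
        with pytest.raises(ConfigurationError):
            GeneSpec("X", control_carrier_prob=0.5, case_enrichment=3.0)
        with pytest.raises(ConfigurationError):
            CohortSimConfig(consequence_mixture={})

    def test_carrier_truth_matches_qualifying_filter(self):
        obs, meta, truth = simulate_cohort(CohortSimConfig(seed=11))
        qualifying = filter_qualifying(obs, BURDEN)
        mat = carrier_matrix(
            qualifying, list(meta.index), list(truth.carriers.columns)
        )
        assert mat.equals(truth.carriers)

    def test_null_enrichment_equal_rates(self):
        # enrichment 1 for every gene: pooled case and control carrier
        # rates agree within binomial error over many simulated genes
        genes = tuple(GeneSpec(f"G{i}", 0.02, 1.0) for i in range(40))
        config = CohortSimConfig(
            genes=genes, n_cases=500, n_controls=500, seed=2,
            background_rate=0.0,
        )
        _, _, truth = simulate_cohort(config)
        case_rate = truth.carriers.iloc[:500].to_numpy().mean()
        control_rate = truth.carriers.iloc[500:].to_numpy().mean()
        se = np.sqrt(2 * 0.02 * 0.98 / (500 * 40))
        assert abs(case_rate - control_rate) < 4 * se

    def test_mosaic_read_support_binomial(self):
        # all-mosaic configuration at VAF 0.37, depth 54: the mean
        # alternate-read count approaches 54 * 0.37 = 19.98
        genes = (GeneSpec("HIF1A", 0.8, 1.0),)
        alt_means = []
        for seed in range(30):
            config = CohortSimConfig(
                genes=genes, n_cases=200, n_controls=0, fraction_mosaic=1.0,
                fraction_tumor_only=0.0, mosaic_vaf=0.37, mosaic_depth=54,
                background_rate=0.0, seed=seed,
            )
            obs, _, truth = simulate_cohort(config)
            mosaic = [o for o in obs if o.sample_source is SampleSource.SALIVA]
            assert all(o.total_reads == 54 for o in mosaic)
            alt_means.extend(o.alt_reads for o in mosaic)
        assert np.mean(alt_means) == pytest.approx(19.98, abs=0.15)

    def test_or_recovery_monte_carlo(self):
        # a VHL-like gene (control rate 8/2054, case expectation 6/94):
        # the mean Haldane-corrected log-OR over many simulations
        # approaches the cross-product ratio of the expected counts
        spec = (GeneSpec("VHL", 8 / 2054, (6 / 94) / (8 / 2054)),)
        log_ors = []
        for seed in range(500):
            obs, meta, _ = simulate_cohort(
                CohortSimConfig(genes=spec, seed=seed, background_rate=0.0,
                                fraction_mosaic=0.0, fraction_tumor_only=0.0)
            )
            labels = meta["status"].to_dict()
            result = BurdenModel.from_observations(
                obs, labels, genes=["VHL"]
            ).fit()["VHL"]
            t = result.table
            log_ors.append(
                np.log((t.a + 0.5) * (t.d + 0.5) / ((t.b + 0.5) * (t.c + 0.5)))
            )
        expected = np.log((6 * 2046) / (8 * 88))
        assert np.mean(log_ors) == pytest.approx(expected, abs=0.25)

    def test_summary_matches_truth_table(self):
        obs, meta, truth = simulate_cohort(CohortSimConfig(seed=13))
        qualifying = filter_qualifying(obs, BURDEN)
        summary = summarize_candidates(qualifying, meta["disease"].to_dict())
        tumor_only = set(
            truth.variants.loc[
                truth.variants.classification == "tumor_only", "individual_id"
            ]
        )
        expected_obs = (truth.variants.classification != "tumor_only").sum()
        assert summary.n_observations == expected_obs
        carriers_nontumor = truth.variants.loc[
            truth.variants.classification != "tumor_only", "individual_id"
        ].nunique()
        assert summary.n_probands == carriers_nontumor


class TestCohortRoundTrip:
    def test_write_parse_identity(self, tmp_path):
        obs, meta, _ = simulate_cohort(CohortSimConfig(seed=3))
        sub_meta = meta.head(60)
        keep = set(sub_meta.index)
        subset = [o for o in obs if o.individual_id in keep]
        write_cohort(subset, sub_meta, tmp_path)
        back = parse_cohort(tmp_path)
        key = lambda o: (o.individual_id, o.variant_id)
        assert sorted(back, key=key) == sorted(subset, key=key)

    def test_mosaic_vaf_survives_round_trip(self, tmp_path, observation_factory):
        obs = observation_factory(
            individual_id="P06", alt_reads=20, total_reads=54,
            sample_source=SampleSource.SALIVA,
        )
        import pandas as pd

        meta = pd.DataFrame({"status": ["case"]}, index=pd.Index(["P06"],
                            name="individual_id"))
        write_cohort([obs], meta, tmp_path)
        (back,) = parse_cohort(tmp_path)
        assert back.alt_reads == 20 and back.total_reads == 54
        assert back.vaf == pytest.approx(0.37, abs=0.005)

    def test_empty_cohort_valid_vcf(self, tmp_path):
        import pandas as pd

        meta = pd.DataFrame({"status": ["case"]}, index=pd.Index(["P01"],
                            name="individual_id"))
        write_cohort([], meta, tmp_path)
        assert (tmp_path / "P01.vcf").exists()
        assert parse_cohort(tmp_path) == []


class TestExpressionSimulation:
    def test_same_seed_bit_identical(self):
        a, _, _ = simulate_expression(ExpressionSimConfig(seed=4, n_genes=500, n_regulon_genes=50))
        b, _, _ = simulate_expression(ExpressionSimConfig(seed=4, n_genes=500, n_regulon_genes=50))
        assert a.counts.equals(b.counts)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            ExpressionSimConfig(dispersion=0.0)
        with pytest.raises(ConfigurationError):
            ExpressionSimConfig(proband_attenuation=1.5)
        with pytest.raises(ConfigurationError):
            ExpressionSimConfig(n_genes=100, n_regulon_genes=200)

    @pytest.mark.parametrize("attenuation", [0.0, 0.5, 1.0])
    def test_truth_attenuation_exact_by_construction(self, attenuation):
        _, regulon, truth = simulate_expression(
            ExpressionSimConfig(seed=9, n_genes=1000, n_regulon_genes=100,
                                proband_attenuation=attenuation)
        )
        reg = truth[truth.is_regulon]
        assert np.allclose(reg.lfc_proband, reg.lfc_control * attenuation)
        nonreg = truth[~truth.is_regulon]
        assert np.allclose(nonreg.lfc_proband, nonreg.lfc_control)
        assert set(reg.index) == regulon.members

    def test_sample_layout(self):
        exp, _, _ = simulate_expression(ExpressionSimConfig(seed=1, n_genes=200, n_regulon_genes=20))
        assert len(exp.sample_ids("control", "hypoxia")) == 3
        assert len(exp.sample_ids("proband", "hypoxia")) == 12
        assert (exp.counts.to_numpy() >= 0).all()

    def test_technical_replicates_share_individual(self):
        exp, _, _ = simulate_expression(ExpressionSimConfig(seed=1, n_genes=200, n_regulon_genes=20))
        collapsed = exp.collapse_technical()
        assert collapsed.counts.shape[1] == (3 + 4) * 2
        assert (collapsed.samples["replicate"] == "biological").all()
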