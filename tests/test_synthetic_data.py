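"""The campaign generator and its ground-truth ledger."""

import numpy as np
import pytest
from pydantic import ValidationError

from ugiqc.detection import DetectionConfig, call_detection
from ugiqc.synthetic_data import (
    SimulationConfig,
    calibrate_purity_weight,
    gen_building_blocks,
    simulate_campaign,
    simulate_peaklists,
    simulate_precipitation,
    simulate_purity,
    simulate_survival,
)


class TestBuildingBlocks:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(seed=1, n_aldehydes=5, n_isocyanides=5)
        assert gen_building_blocks(cfg) == gen_building_blocks(cfg)

    def test_empty(self):
        cfg = SimulationConfig(seed=1, n_aldehydes=0, n_isocyanides=0)
        aldehydes, isocyanides = gen_building_blocks(cfg)
        assert aldehydes == [] and isocyanides == []

    def test_vocabulary_exhausted(self):
        cfg = SimulationConfig(seed=1, n_aldehydes=10_000)
        with pytest.raises(ValueError, match="vocabulary"):
            gen_building_blocks(cfg)

    def test_role_invariants_hold(self):
        cfg = SimulationConfig(seed=3, n_aldehydes=20, n_isocyanides=20)
        aldehydes, isocyanides = gen_building_blocks(cfg)
        for block in aldehydes + isocyanides:
            block.validate()  # raises on violation
            assert block.stock_molarity in (2.5, 5.0)


class TestPrecipitation:
    def test_zero_coefficients_give_coin_flip(self, library_1000):
        products, _ = library_1000
        cfg = SimulationConfig(
            seed=2, precip_beta={}, precip_intercept=0.0
        )
        flags, prob, _ = simulate_precipitation(products, cfg)
        assert np.allclose(prob, 0.5)
        sigma3 = 3 * np.sqrt(0.25 / len(products))
        assert abs(flags.mean() - 0.5) < sigma3

    def test_saturating_intercept(self, library_1000):
        products, _ = library_1000
        cfg = SimulationConfig(seed=2, precip_intercept=10.0)
        flags, _, _ = simulate_precipitation(products, cfg)
        assert flags.mean() > 0.99

    def test_intercept_calibrated_to_target_rate(self, library_1000):
        products, _ = library_1000
        target = 1612 / 2551
        cfg = SimulationConfig(seed=2, target_precip_rate=target)
        flags, prob, intercept = simulate_precipitation(products, cfg)
        assert prob.mean() == pytest.approx(target, abs=1e-8)
        sigma3 = 3 * np.sqrt(target * (1 - target) / len(products))
        assert abs(flags.mean() - target) < sigma3


class TestPurity:
    def test_all_high_component(self):
        cfg = SimulationConfig(seed=4, purity_weight=1.0)
        purity = simulate_purity(500, cfg)
        assert (purity > 80).mean() > 0.9

    def test_all_low_component(self):
        cfg = SimulationConfig(seed=4, purity_weight=0.0)
        purity = simulate_purity(500, cfg)
        assert (purity > 80).mean() < 0.35

    def test_calibrated_green_fraction(self):
        """Weight solved so that, of 1612 precipitates, ~1235 pass >80%."""
        cfg = SimulationConfig(seed=4)
        target = 1235 / 1612
        w = calibrate_purity_weight(cfg)
        assert 0 < w < 1
        purity = simulate_purity(1612, cfg)
        sigma3 = 3 * np.sqrt(target * (1 - target) / 1612)
        assert abs((purity > 80).mean() - target) < sigma3


class TestSurvival:
    @pytest.mark.parametrize("p, expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_degenerate(self, p, expected):
        cfg = SimulationConfig(seed=5, survival_p=p)
        assert simulate_survival(200, cfg).mean() == expected


class TestPeaklists:
    def test_noiseless_recall_is_complete(self, library_1000):
        """Zero mass error, zero background: every responding adduct is found."""
        products, _ = library_1000
        subset = products[:50]
        cfg = SimulationConfig(
            seed=6, ppm_sigma=0.0, noise_rate={"positive": 0.0, "negative": 0.0}
        )
        rng = np.random.default_rng(0)
        for mode, adducts in (("positive", ("[M+H]+", "[M+Na]+")),
                              ("negative", ("[M-H]-",))):
            responses = {
                (p.id, name): True for p in subset for name in adducts
            }
            triples = [(p.id, p.monoisotopic_mass, f"W{i}")
                       for i, p in enumerate(subset)]
            peaklists = simulate_peaklists(
                triples, responses, "AEMS", mode, cfg, rng
            )
            config = DetectionConfig(snr_min=1.0)
            for p, pl in zip(subset, peaklists):
                records = call_detection(p.id, p.monoisotopic_mass, pl, config)
                assert all(r.detected for r in records if r.adduct in adducts)

    def test_no_response_only_noise(self, library_1000):
        products, _ = library_1000
        cfg = SimulationConfig(seed=6)
        rng = np.random.default_rng(1)
        triples = [(products[0].id, products[0].monoisotopic_mass, "W0")]
        (pl,) = simulate_peaklists(triples, {}, "AEMS", "positive", cfg, rng)
        # all peaks are background draws, none tied to the compound
        assert len(pl) == 0 or pl.intensity.max() < 1e4

    def test_positive_noise_must_dominate(self):
        with pytest.raises(ValidationError, match="noise rate"):
            SimulationConfig(noise_rate={"positive": 1.0, "negative": 5.0})


class TestCampaignLedger:
    def test_ledger_flags_recovered_in_clean_limit(self):
        """Detection at snr_min=1 on a noise-free campaign reproduces the
        ledger's per-platform/per-adduct response flags exactly."""
        cfg = SimulationConfig(
            seed=11, n_aldehydes=6, n_isocyanides=6, n_uplc_subset=10,
            ppm_sigma=0.0, noise_rate={"positive": 0.0, "negative": 0.0},
        )
        campaign = simulate_campaign(cfg)
        config = DetectionConfig(snr_min=1.0)
        mass_of = dict(
            zip(campaign.reactions.product_id, campaign.reactions.monoisotopic_mass)
        )
        for (platform, mode), peaklists in campaign.peaklists.items():
            by_well = {pl.well: pl for pl in peaklists}
            measured = (
                campaign.retained_ids if platform == "AEMS" else campaign.subset_ids
            )
            for cid in measured:
                pl = by_well[campaign.well_of(cid)]
                records = call_detection(cid, float(mass_of[cid]), pl, config)
                truth = campaign.ledger["products"][cid]["responses"][platform]
                for record in records:
                    assert record.detected == truth[record.adduct]

    def test_same_seed_same_campaign(self, small_campaign):
        again = simulate_campaign(small_campaign.config)
        assert again.ledger == small_campaign.ledger
        assert again.reactions.equals(small_campaign.reactions)

    def test_purity_only_for_precipitated(self, small_campaign):
        df = small_campaign.reactions
        assert df.loc[~df.precipitated, "purity_pct"].isna().all()
        assert df.loc[df.precipitated, "purity_pct"].notna().all()

    def test_labels_consistent_with_ledger(self, small_campaign):
        df = small_campaign.reactions
        greens = df.label == "green"
        assert (df.loc[greens, "purity_pct"] > 80).all()
        assert set(df.loc[greens, "product_id"]) == set(small_campaign.retained_ids)


def test_unknown_config_key_rejected():
    with pytest.raises(ValidationError):
        SimulationConfig(not_a_field=3)
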