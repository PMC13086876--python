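"""Simulator correctness: determinism, truth consistency, and the analytic
Pearson oracle against brute-force pixel simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucoloc import (
    PlacementError,
    SimulationConfig,
    expected_pearson_two_level,
    generate_control_field,
    generate_field,
    generate_pcna_pattern,
    pearson_within_mask,
    zone_mask,
)


class TestGenerateField:
    def test_same_seed_bit_identical(self, small_config):
        f1, _ = generate_field(small_config)
        f2, _ = generate_field(small_config)
        for role in f1.channels:
            np.testing.assert_array_equal(f1.channels[role], f2.channels[role])

    def test_empty_field(self):
        cfg = SimulationConfig(field_shape=(128, 128), n_nuclei=0)
        field, truth = generate_field(cfg)
        assert truth.n_nuclei == 0
        assert truth.nucleus_labels.max() == 0
        # background-only channels: constant up to noise around the background level
        assert abs(field.channels["dapi"].astype(float).mean() - cfg.background) < 3

    def test_truth_counts_and_containment(self, small_field, small_config):
        _, truth = small_field
        n = small_config.n_nuclei
        assert truth.n_nuclei == n
        assert set(np.unique(truth.nucleus_labels)) == set(range(n + 1))
        for lab in range(1, n + 1):
            ncl = truth.nucleolus_mask(lab)
            nuc = truth.nucleus_mask(lab)
            assert ncl.any()
            assert not (ncl & ~nuc).any(), "nucleolus must lie inside its nucleus"
            frac = ncl.sum() / nuc.sum()
            target = small_config.nucleolar_area_fraction
            assert abs(frac - target) <= 0.2 * target

    def test_noise_free_levels(self, noise_free_field):
        field, truth = noise_free_field
        cfg = truth.config
        m0, m1 = cfg.marker_levels
        nuc = truth.nucleus_mask(1)
        ncl = truth.nucleolus_mask(1)
        plasm = nuc & ~ncl
        assert field.channels["marker"][ncl].mean() == pytest.approx(m1, abs=1)
        assert field.channels["marker"][plasm].mean() == pytest.approx(m0, abs=1)
        # DAPI dips inside nucleoli but is not zero there
        dapi_in = field.channels["dapi"][ncl].mean()
        dapi_out = field.channels["dapi"][plasm].mean()
        assert 0 < dapi_in < dapi_out
        assert field.channels["query"][ncl].mean() == pytest.approx(
            cfg.query_diffuse + cfg.enrichment * cfg.query_boost, abs=1
        )

    def test_placement_error_when_field_too_crowded(self):
        cfg = SimulationConfig(
            field_shape=(96, 96), n_nuclei=30, nucleus_axes_range=(14.0, 18.0),
            max_place_tries=50,
        )
        with pytest.raises(PlacementError):
            generate_field(cfg)

    def test_bit_range_respected(self, small_field):
        field, _ = small_field
        for chan in field.channels.values():
            assert chan.dtype == np.uint8
            assert chan.max() <= 255

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"nucleolar_area_fraction": 0.0},
            {"bleedthrough": 1.0},
            {"marker_levels": (100.0, 50.0)},
            {"enrichment": 1.5},
        ],
    )
    def test_config_validation(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_bleedthrough_induces_false_colocalization(self):
        """With zero enrichment, channel crosstalk alone yields positive mean r —
        the confounder sequential illumination is meant to remove."""
        rs = []
        for seed in range(3):
            cfg = SimulationConfig(
                field_shape=(256, 256), n_nuclei=6, nucleus_axes_range=(12.0, 18.0),
                enrichment=0.0, bleedthrough=0.3, seed=seed,
            )
            field, truth = generate_field(cfg)
            for lab in range(1, truth.n_nuclei + 1):
                r, _ = pearson_within_mask(
                    field.channels["query"], field.channels["marker"],
                    truth.nucleus_mask(lab),
                )
                rs.append(r)
        assert np.mean(rs) > 0.2


class TestPcnaPattern:
    def _masks(self):
        cfg = SimulationConfig(
            field_shape=(128, 128), n_nuclei=1, nucleus_axes_range=(16.0, 20.0), seed=5
        )
        _, truth = generate_field(cfg)
        return truth.nucleus_mask(1), truth.nucleolus_mask(1)

    def test_non_s_is_homogeneous(self):
        nuc, ncl = self._masks()
        pat = generate_pcna_pattern("non_S", nuc, ncl, seed=0)
        vals = pat.image[nuc]
        assert vals.std() / vals.mean() < 0.05
        assert len(pat.centers) == 0

    def test_mid_s_puncta_in_zone(self):
        nuc, ncl = self._masks()
        pat = generate_pcna_pattern("mid_S", nuc, ncl, seed=0, n_foci=8)
        assert len(pat.centers) >= 8
        zone = zone_mask(nuc, ncl)
        for cy, cx in pat.centers:
            assert zone[int(cy), int(cx)]

    def test_empty_nucleus_errors(self):
        empty = np.zeros((64, 64), dtype=bool)
        with pytest.raises(ValueError):
            generate_pcna_pattern("non_S", empty, empty, seed=0)

    def test_too_small_nucleus_errors(self):
        nuc = np.zeros((64, 64), dtype=bool)
        nuc[30:34, 30:34] = True
        with pytest.raises(PlacementError):
            generate_pcna_pattern("mid_S", nuc, np.zeros_like(nuc), seed=0, n_foci=10)


class TestExpectedPearsonOracle:
    def test_noiseless_is_one(self):
        assert expected_pearson_two_level(0.2, 50.0, 100.0, 0.0, 0.0) == pytest.approx(1.0)

    def test_no_enrichment_is_zero(self):
        assert expected_pearson_two_level(0.2, 0.0, 100.0, 5.0, 5.0) == 0.0

    def test_anticorrelated_sign(self):
        assert expected_pearson_two_level(0.2, -50.0, 100.0, 0.0, 0.0) == pytest.approx(-1.0)

    def test_undefined_when_variance_vanishes(self):
        with pytest.raises(ZeroDivisionError):
            expected_pearson_two_level(0.2, 0.0, 100.0, 0.0, 5.0)

    def test_matches_brute_force_pixel_simulation(self, rng):
        """Closed form vs direct simulation of 10^6 two-level noisy pixels."""
        p, dq, dm, sq, sm = 0.1, 50.0, 100.0, 10.0, 10.0
        n = 10**6
        in_ncl = rng.random(n) < p
        q = np.where(in_ncl, dq, 0.0) + rng.normal(0, sq, n)
        m = np.where(in_ncl, dm, 0.0) + rng.normal(0, sm, n)
        emp = float(np.corrcoef(q, m)[0, 1])
        pred = expected_pearson_two_level(p, dq, dm, sq, sm)
        mc_se = (1 - emp**2) / math.sqrt(n)
        assert abs(emp - pred) < 3 * mc_se

    @given(
        f1=st.floats(0.01, 0.99), f2=st.floats(0.01, 0.99),
        p=st.floats(0.05, 0.5), sigma=st.floats(0.5, 30.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_strictly_increasing_in_enrichment(self, f1, f2, p, sigma):
        if abs(f1 - f2) < 1e-6:
            return
        lo, hi = sorted((f1, f2))
        r_lo = expected_pearson_two_level(p, lo * 80.0, 120.0, sigma, sigma)
        r_hi = expected_pearson_two_level(p, hi * 80.0, 120.0, sigma, sigma)
        assert r_hi > r_lo

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_invariant_to_channel_gain(self, scale):
        base = expected_pearson_two_level(0.15, 40.0, 120.0, 8.0, 6.0)
        scaled = expected_pearson_two_level(0.15, 40.0 * scale, 120.0, 8.0 * scale, 6.0)
        assert scaled == pytest.approx(base, rel=1e-12)


class TestEmpiricalVsOracle:
    def test_mean_cell_coefficient_matches_closed_form(self):
        """Per-cell coefficients over >=200 simulated cells agree with the
        analytic value within 3 standard errors."""
        f, sigma = 0.5, 8.0
        rs, preds = [], []
        seed = 0
        while len(rs) < 200:
            cfg = SimulationConfig(
                field_shape=(256, 256), n_nuclei=8, nucleus_axes_range=(12.0, 18.0),
                enrichment=f, noise_sigma=sigma, seed=seed,
            )
            field, truth = generate_field(cfg)
            for lab in range(1, truth.n_nuclei + 1):
                nuc = truth.nucleus_mask(lab)
                r, reason = pearson_within_mask(
                    field.channels["query"], field.channels["marker"], nuc
                )
                assert reason == "none"
                rs.append(r)
                p_real = truth.nucleolus_mask(lab).sum() / nuc.sum()
                preds.append(
                    expected_pearson_two_level(
                        p_real, f * cfg.query_boost,
                        cfg.marker_levels[1] - cfg.marker_levels[0], sigma, sigma,
                    )
                )
            seed += 1
        rs = np.asarray(rs)
        se = rs.std(ddof=1) / math.sqrt(len(rs))
        assert abs(rs.mean() - np.mean(preds)) < 3 * se


class TestControlFields:
    def test_positive_control_duplicates_marker_structure(self):
        cfg = SimulationConfig(
            field_shape=(256, 256), n_nuclei=6, nucleus_axes_range=(12.0, 18.0),
            noise_sigma=5.0, seed=3,
        )
        field, truth = generate_control_field(cfg, "positive")
        rs = [
            pearson_within_mask(
                field.channels["query"], field.channels["marker"],
                truth.nucleus_mask(lab),
            )[0]
            for lab in range(1, truth.n_nuclei + 1)
        ]
        assert np.mean(rs) > 0.9

    def test_unknown_kind_errors(self, small_config):
        with pytest.raises(ValueError):
            generate_control_field(small_config, "bogus")
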