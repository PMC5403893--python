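"""Ground-truth properties of the synthetic cohort generator."""

import numpy as np
import pytest

from plinet import (
    CohortConfig,
    CoupledEdge,
    bandpass,
    desk_scale_config,
    full_scale_config,
    generate_cohort,
    get_band,
    instantaneous_phase,
    pli_matrix_from_phases,
)
from plinet.bands import BandConfigurationError, FrequencyBand

ALPHA = get_band("lower_alpha")


def cohort_mean_pli(cfg, pair):
    """Epoch-averaged PLI of one ROI pair, averaged over subjects."""
    cohort = generate_cohort(cfg)
    vals = []
    for s in cohort.subjects:
        per_epoch = []
        for k in range(s.epochs.shape[0]):
            filtered = bandpass(s.epochs[k], ALPHA, cfg.sampling_rate)
            ph = instantaneous_phase(filtered, edge_trim=31)
            per_epoch.append(pli_matrix_from_phases(ph.phases)[pair])
        vals.append(np.mean(per_epoch))
    return float(np.mean(vals))


def tiny_config(**overrides):
    base = dict(
        n_rois=2,
        n_subjects_per_group=1,
        n_epochs=3,
        epoch_samples=512,
        sampling_rate=250.0,
        band_targets=(ALPHA,),
    )
    base.update(overrides)
    return CohortConfig(**base)


class TestConfigValidation:
    def test_full_scale_preset_matches_protocol(self):
        cfg = full_scale_config()
        assert (cfg.n_rois, cfg.n_subjects_per_group) == (78, 29)
        assert (cfg.n_epochs, cfg.epoch_samples) == (20, 4096)
        assert cfg.sampling_rate == 1000.0

    def test_band_above_nyquist_names_band(self):
        cfg = tiny_config(
            band_targets=(FrequencyBand("gamma", 30.0, 48.0),),
            sampling_rate=90.0,
        )
        with pytest.raises(BandConfigurationError, match="gamma"):
            generate_cohort(cfg)

    @pytest.mark.parametrize("offset", [0.0, np.pi, 2 * np.pi, -np.pi])
    def test_zero_lag_coupling_offsets_rejected(self, offset):
        edge = CoupledEdge(0, 1, 0.5, offset, "lower_alpha")
        cfg = tiny_config(coupling_spec={"A": (edge,), "B": (edge,)})
        with pytest.raises(ValueError, match="zero-lag"):
            generate_cohort(cfg)

    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError, match="n_epochs"):
            generate_cohort(tiny_config(n_epochs=0))


class TestGeneration:
    def test_determinism_bit_identical(self):
        cfg = tiny_config(n_rois=4, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.subject_id == sb.subject_id
            assert np.array_equal(sa.epochs, sb.epochs)

    def test_cohort_structure_and_finiteness(self):
        cfg = desk_scale_config(
            n_subjects_per_group=2, n_epochs=2, seed=1
        )
        cohort = generate_cohort(cfg)
        assert len(cohort.subjects) == 4
        assert sorted({s.group_label for s in cohort.subjects}) == ["A", "B"]
        for s in cohort.subjects:
            assert s.epochs.shape == (2, 30, 1024)
            assert np.all(np.isfinite(s.epochs))

    def test_full_coupling_without_noise_gives_unit_pli(self):
        edge = CoupledEdge(0, 1, 1.0, np.pi / 2, "lower_alpha")
        cfg = tiny_config(
            coupling_spec={"A": (edge,), "B": (edge,)},
            noise_sd=1e-8,
            seed=5,
        )
        # the limit is exact; residual filter/transform edge effects leave
        # a handful of samples off the consistent lag
        assert cohort_mean_pli(cfg, (0, 1)) == pytest.approx(1.0, abs=5e-3)

    def test_uncoupled_pli_matches_independent_noise_null(self):
        # no coupling, no mixing: PLI should sit at the finite-sample null
        null_cfg = tiny_config(seed=11)
        coupled_free = cohort_mean_pli(null_cfg, (0, 1))
        draws = [
            cohort_mean_pli(tiny_config(seed=100 + s), (0, 1))
            for s in range(12)
        ]
        lo, hi = np.quantile(draws, [0.0, 1.0])
        assert lo - 0.1 <= coupled_free <= hi + 0.1

    def test_mean_pli_monotone_in_coupling_strength(self):
        strengths = [0.0, 0.2, 0.4, 0.6, 0.8]
        curves = []
        for seed in range(20):
            plis = []
            for c in strengths:
                edge = CoupledEdge(0, 1, c, np.pi / 2, "lower_alpha")
                cfg = tiny_config(
                    coupling_spec={"A": (edge,), "B": (edge,)},
                    n_epochs=5,
                    epoch_samples=1024,
                    seed=seed,
                )
                plis.append(cohort_mean_pli(cfg, (0, 1)))
            curves.append(plis)
        curves = np.asarray(curves)
        # the seed-ensemble mean is strictly ordered by coupling strength
        ensemble = curves.mean(axis=0)
        assert np.all(np.diff(ensemble) > 0)
        # per-seed curves allow rank violations in at most 5% of pairs
        violations = np.sum(np.diff(curves, axis=1) < 0)
        assert violations / (curves.shape[0] * 4) <= 0.05

    def test_spectral_content_dominates_leakage(self):
        # at the full-scale sampling rate, each requested band carries
        # >= 10x the in-band power of the broadband noise floor
        cfg = CohortConfig(
            n_rois=3,
            n_subjects_per_group=1,
            n_epochs=2,
            epoch_samples=2048,
            sampling_rate=1000.0,
            seed=2,
        )
        cohort = generate_cohort(cfg)
        rng = np.random.default_rng(3)
        noise = cfg.noise_sd * rng.standard_normal((3, 2048))
        trim = slice(256, -256)  # discard filter edge transients
        for band in cfg.band_targets:
            sig_power = bandpass(
                cohort.subjects[0].epochs[0], band, 1000.0
            )[:, trim].var()
            noise_power = bandpass(noise, band, 1000.0)[:, trim].var()
            assert sig_power >= 10 * noise_power

    def test_zero_lag_mixing_raises_plv_not_pli(self):
        # 50 seeded realizations per condition; the naive phase-locking
        # value responds to instantaneous mixing, the PLI does not
        def realization(mix, seed):
            cfg = tiny_config(
                n_rois=6, n_epochs=5, zero_lag_mix=mix, seed=seed
            )
            cohort = generate_cohort(cfg)
            s = cohort.subjects[0]
            plis, plvs = [], []
            iu = np.triu_indices(6, 1)
            for k in range(cfg.n_epochs):
                f = bandpass(s.epochs[k], ALPHA, cfg.sampling_rate)
                ph = instantaneous_phase(f, edge_trim=31).phases
                plis.append(pli_matrix_from_phases(ph)[iu].mean())
                plv = [
                    np.abs(np.mean(np.exp(1j * (ph[i] - ph[j]))))
                    for i, j in zip(*iu)
                ]
                plvs.append(np.mean(plv))
            return np.mean(plis), np.mean(plvs)

        base = np.array([realization(0.0, s) for s in range(50)])
        mixed = np.array([realization(0.5, 1000 + s) for s in range(50)])
        from scipy import stats as scipy_stats

        # mixing shifts the PLV ensemble decisively ...
        plv_test = scipy_stats.ttest_ind(base[:, 1], mixed[:, 1])
        assert mixed[:, 1].mean() > base[:, 1].mean()
        assert plv_test.pvalue < 0.01
        # ... while the PLI difference stays within sampling noise
        pli_shift = abs(mixed[:, 0].mean() - base[:, 0].mean())
        pooled_se = np.sqrt((base[:, 0].var() + mixed[:, 0].var()) / 50)
        assert pli_shift < 3 * pooled_se
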