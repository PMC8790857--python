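import filecmp

import numpy as np
import pytest

from orgnet import (
    SyntheticSpec,
    build_directed,
    confirm_ordinal,
    emit_reports,
    generate_dataset,
    generate_latent,
    multiplexity_matrix,
)
from orgnet.build import binarize
from orgnet.core import NUTRITION_LAYERS
from orgnet.errors import ValidationError


def small_spec(**kw):
    defaults = dict(
        n_per_type={"UN": 5, "NGO": 5, "network": 5, "foundation": 5},
        layers=("policy",),
        p_in=0.3,
        p_out=0.05,
        n_brokers=0,
        nonresponse=0.0,
        discordance=0.0,
        seed=0,
    )
    defaults.update(kw)
    return SyntheticSpec(**defaults)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"discordance": 1.5},
            {"nonresponse": -0.1},
            {"p_broker": 2.0},
            {"frequency_dist": (0.5, 0.5, 0.5, 0.5)},
            {"n_per_type": {"charity": 5}},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValidationError):
            small_spec(**kw)


class TestLatent:
    def test_zero_probabilities_empty_layers(self):
        gt = generate_latent(small_spec(p_in=0.0, p_out=0.0))
        assert not gt.latent["policy"].any()

    def test_certain_ties_at_forced_level(self):
        spec = small_spec(p_in=1.0, p_out=1.0, frequency_dist=(0.0, 1.0, 0.0, 0.0))
        gt = generate_latent(spec)
        values = gt.latent["policy"]
        off_diag = ~np.eye(len(values), dtype=bool)
        assert (values[off_diag] == 2).all()

    def test_latent_matrices_symmetric_zero_diagonal(self):
        gt = generate_latent(small_spec(seed=3))
        m = gt.latent["policy"]
        assert np.array_equal(m, m.T)
        assert not np.diag(m).any()

    def test_block_rates_match_probabilities(self):
        """Monte-Carlo: empirical within/between-type tie rates sit
        within 3 standard errors of p_in/p_out."""
        within = between = n_within = n_between = 0
        for seed in range(300):
            gt = generate_latent(small_spec(seed=seed))
            types = gt.types
            ids = gt.roster.ids
            m = gt.latent["policy"] > 0
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    if types[ids[i]] == types[ids[j]]:
                        n_within += 1
                        within += m[i, j]
                    else:
                        n_between += 1
                        between += m[i, j]
        rate_in, rate_out = within / n_within, between / n_between
        se_in = np.sqrt(0.3 * 0.7 / n_within)
        se_out = np.sqrt(0.05 * 0.95 / n_between)
        assert abs(rate_in - 0.3) < 3 * se_in
        assert abs(rate_out - 0.05) < 3 * se_out


class TestReports:
    def test_noise_free_pipeline_reproduces_latent(self):
        spec = small_spec(layers=("overall", "intensity") + NUTRITION_LAYERS, seed=5)
        gt = generate_latent(spec)
        reports = emit_reports(gt, spec)
        for layer in spec.layers:
            directed = build_directed(reports, layer, gt.roster)
            confirmed = confirm_ordinal(directed)
            assert np.array_equal(confirmed.values, gt.latent[layer]), layer

    def test_full_nonresponse_emits_nothing(self):
        spec = small_spec(nonresponse=1.0)
        gt, reports = generate_dataset(spec)
        assert reports == []
        assert len(gt.roster.respondents) == 0

    def test_determinism_byte_identical_files(self, tmp_path):
        spec = small_spec(
            layers=("overall",) + NUTRITION_LAYERS,
            discordance=0.1,
            nonresponse=0.14,
            seed=11,
        )
        generate_dataset(spec, tmp_path / "a")
        generate_dataset(spec, tmp_path / "b")
        for name in ("roster.csv", "reports.csv"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_asymmetric_dyad_fraction_matches_closed_form(self):
        """With discordance d the two directions of a latent tie differ
        with probability 1 - ((1-d)^2 + d^2/2) for levels >= 2 and
        2d(1-d) for level 1; the observed asymmetric fraction across
        seeds must sit within Monte-Carlo error of the expectation."""
        d = 0.2
        expected_sum = variance_sum = observed = 0.0
        for seed in range(200):
            spec = small_spec(discordance=d, seed=seed)
            gt = generate_latent(spec)
            reports = emit_reports(gt, spec)
            directed = build_directed(reports, "policy", gt.roster).values
            latent = gt.latent["policy"]
            ii, jj = np.nonzero(np.triu(latent))
            for i, j in zip(ii.tolist(), jj.tolist()):
                v = latent[i, j]
                p = 2 * d * (1 - d) if v == 1 else 1 - ((1 - d) ** 2 + d**2 / 2)
                expected_sum += p
                variance_sum += p * (1 - p)
                observed += directed[i, j] != directed[j, i]
        assert abs(observed - expected_sum) < 4 * np.sqrt(variance_sum)

    def test_confirmation_gap_grows_with_discordance(self):
        """Confirmed density never exceeds directed-report density and
        the gap widens as reporting noise rises."""
        gaps = []
        for d in (0.0, 0.15, 0.3):
            gap = 0.0
            for seed in range(30):
                spec = small_spec(discordance=d, seed=seed)
                gt = generate_latent(spec)
                reports = emit_reports(gt, spec)
                directed = build_directed(reports, "policy", gt.roster)
                confirmed = binarize(confirm_ordinal(directed), 1)
                n = confirmed.n
                conf_density = confirmed.values.sum() / (n * (n - 1))
                dir_density = (directed.values > 0).sum() / (n * (n - 1))
                assert conf_density <= dir_density + 1e-12
                gap += dir_density - conf_density
            gaps.append(gap / 30)
        assert gaps[0] == pytest.approx(0.0)
        assert gaps[0] < gaps[1] < gaps[2]


class TestDefaults:
    def test_default_roster_mirrors_survey_shape(self):
        gt, _ = generate_dataset(SyntheticSpec(seed=1))
        assert len(gt.roster) == 50
        assert len(gt.roster.respondents) == 43
        assert len(gt.brokers) == 2

    def test_multiplexity_exercised_across_full_range(self):
        spec = SyntheticSpec(seed=2, discordance=0.0, nonresponse=0.0)
        gt = generate_latent(spec)
        layers = {
            name: binarize(
                confirm_ordinal(
                    build_directed(emit_reports(gt, spec), name, gt.roster)
                ),
                1,
            )
            for name in NUTRITION_LAYERS
        }
        mx = multiplexity_matrix(layers)
        assert mx.scores.max() <= 4
        assert {1, 2}.issubset(set(np.unique(mx.scores)))
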