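import numpy as np
import pytest
from scipy.signal import periodogram

from cardioset import interpret
from cardioset.features import SampleRecord
from cardioset.interpret import (
    band_power_change,
    band_powers,
    cluster_atoms,
    cluster_reconstruction,
    cycle_power,
    embed_latents,
    extract_latents,
    group_clusters,
    smooth_and_filter,
)
from cardioset.model import DeepSetsClassifier, ModelConfig, pack_batch

from conftest import make_decomposition

FS = 4000.0


def toy_samples(rng, n=6, rows=8, dim=10):
    return [
        SampleRecord(
            features=rng.standard_normal((rows, dim)),
            label=i % 2,
            subject_id=f"S{i % 2}",
            segment_ref={"kind": "diastolic_window", "start_sample": i * 512},
        )
        for i in range(n)
    ]


class TestExtractLatents:
    def test_bijection_with_atoms(self, rng):
        model = DeepSetsClassifier(ModelConfig(input_dim=10, latent_dim=6, hidden_dim=8, seed=0))
        samples = toy_samples(rng)
        latents, prov = extract_latents(model, samples)
        assert latents.shape == (6 * 8, 6)
        assert len(prov) == 48
        assert list(prov.columns) == [
            "sample_index", "atom_index", "subject_id", "condition", "segment_kind", "segment_start",
        ]

    def test_identical_rows_identical_latents(self, rng):
        model = DeepSetsClassifier(ModelConfig(input_dim=10, latent_dim=6, hidden_dim=8, seed=0))
        samples = toy_samples(rng, n=2)
        samples[1].features = samples[0].features.copy()
        latents, _ = extract_latents(model, samples)
        np.testing.assert_allclose(latents[:8], latents[8:16], atol=1e-12)

    def test_latent_independent_of_set_context(self, rng):
        model = DeepSetsClassifier(ModelConfig(input_dim=10, latent_dim=6, hidden_dim=8, seed=0))
        full = toy_samples(rng, n=1, rows=10)
        reduced = [SampleRecord(full[0].features[:4], 0, "S0", full[0].segment_ref)]
        lat_full, _ = extract_latents(model, full)
        lat_red, _ = extract_latents(model, reduced)
        np.testing.assert_allclose(lat_full[:4], lat_red, atol=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        model = DeepSetsClassifier(ModelConfig(input_dim=9, latent_dim=6, hidden_dim=8, seed=0))
        with pytest.raises(ValueError, match="input_dim"):
            extract_latents(model, toy_samples(rng))


class TestEmbed:
    def test_shape_and_determinism(self, rng):
        latents = rng.standard_normal((60, 6))
        a = embed_latents(latents, seed=3)
        b = embed_latents(latents, seed=3)
        assert a.shape == (60, 2)
        np.testing.assert_array_equal(a, b)

    def test_separated_blobs_stay_separated(self, rng):
        blob_a = rng.normal(0.0, 1.0, (50, 6))
        blob_b = rng.normal(0.0, 1.0, (50, 6)) + 10.0
        emb = embed_latents(np.vstack([blob_a, blob_b]), seed=0)
        intra = np.linalg.norm(emb[:50] - emb[:50].mean(0), axis=1)
        inter = np.linalg.norm(emb[:50].mean(0) - emb[50:].mean(0))
        assert inter > np.percentile(intra, 95)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            embed_latents(rng.standard_normal((5, 4)))

    def test_per_subject_scope(self, rng):
        latents = rng.standard_normal((40, 4))
        subjects = np.array(["A"] * 20 + ["B"] * 20)
        emb = embed_latents(latents, seed=1, scope="per_subject", subject_ids=subjects)
        assert emb.shape == (40, 2)


class TestClusterAtoms:
    def test_two_blobs(self, rng):
        pts = np.vstack([rng.normal(0, 0.05, (50, 2)), rng.normal(10, 0.05, (50, 2))])
        ids = cluster_atoms(pts)
        assert set(ids) == {0, 1}
        assert (ids[:50] == ids[0]).all() and (ids[50:] == ids[50]).all()

    def test_isolated_points_are_noise(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        assert (cluster_atoms(pts) == -1).all()

    def test_min_cluster_size(self, rng):
        pts = np.vstack([rng.normal(0, 0.05, (50, 2)), rng.normal(8, 0.05, (7, 2))])
        ids = cluster_atoms(pts)
        sizes = [np.sum(ids == c) for c in set(ids) if c >= 0]
        assert all(s >= 5 for s in sizes)

    def test_renumbered_by_size(self, rng):
        pts = np.vstack([rng.normal(0, 0.05, (10, 2)), rng.normal(8, 0.05, (40, 2))])
        ids = cluster_atoms(pts)
        assert np.sum(ids == 0) >= np.sum(ids == 1)


class TestClusterReconstruction:
    def _decs(self):
        decs = []
        for cond, start in (("pre", 0), ("pre", 512), ("post", 0)):
            dec = make_decomposition(
                [(6, 125.0, 256, 0.0, 2.0), (4, 250.0, 100, 0.5, 1.0)],
                segment_ref={"subject_id": "S1", "condition": cond,
                             "kind": "diastolic_window", "start_sample": start},
            )
            decs.append(dec)
        return decs

    def test_partition_property(self):
        decs = self._decs()
        ids = np.array([0, 1, 0, 1, 0, 1])
        recons = cluster_reconstruction(decs, ids, 2048, apply_filter=False)
        all_one = cluster_reconstruction(decs, np.zeros(6, dtype=int), 2048, apply_filter=False)
        total = recons[0]["pre_raw"] + recons[1]["pre_raw"]
        np.testing.assert_allclose(total, all_one[0]["pre_raw"], atol=1e-9)

    def test_misaligned_ids_rejected(self):
        with pytest.raises(ValueError):
            cluster_reconstruction(self._decs(), np.zeros(5, dtype=int), 2048)

    def test_overlap_regions_halved(self):
        # two overlapping full-cycle windows of constant reconstruction weight
        dec_a = make_decomposition(
            [(9, 0.0, 256, 0.0, 1.0)], segment_length=512,
            segment_ref={"subject_id": "S1", "condition": "pre",
                         "kind": "full_cycle_window", "start_sample": 0},
        )
        dec_b = make_decomposition(
            [(9, 0.0, 256, 0.0, 1.0)], segment_length=512,
            segment_ref={"subject_id": "S1", "condition": "pre",
                         "kind": "full_cycle_window", "start_sample": 256},
        )
        recons = cluster_reconstruction([dec_a, dec_b], np.array([0, 0]), 768, apply_filter=False)
        single = cluster_reconstruction([dec_a], np.array([0]), 768, apply_filter=False)
        overlap = slice(256, 512)
        expected = 0.5 * (single[0]["pre_raw"][overlap] + single[0]["pre_raw"][overlap] * 0)
        # both windows contribute the same atom shape shifted; just assert
        # the doubly covered region is downweighted (no energy doubling)
        assert np.max(np.abs(recons[0]["pre_raw"][overlap])) <= 1.01 * np.max(
            np.abs(single[0]["pre_raw"])
        )
        assert expected.shape == (256,)


class TestFilter:
    def test_band_edges(self):
        t = np.arange(8000) / FS
        low_tone = np.sin(2 * np.pi * 30 * t)
        mid_tone = np.sin(2 * np.pi * 150 * t)
        out_low = smooth_and_filter(low_tone, FS, sigma=0.0)
        out_mid = smooth_and_filter(mid_tone, FS, sigma=0.0)
        att_low = 20 * np.log10(np.std(out_low[1000:-1000]) / np.std(low_tone))
        att_mid = 20 * np.log10(np.std(out_mid[1000:-1000]) / np.std(mid_tone))
        assert att_low < -20.0
        assert att_mid > -3.0


class TestCyclePower:
    def test_constant_signal(self):
        sig = np.full(4000, 2.0)
        mean, se = cycle_power(sig, np.array([0, 1000, 2000, 3000]))
        assert mean == pytest.approx(4.0)
        assert se == pytest.approx(0.0)

    def test_zero_signal(self):
        mean, se = cycle_power(np.zeros(4000), np.array([0, 2000]))
        assert (mean, se) == (0.0, 0.0)

    def test_se_shrinks_with_cycles(self, rng):
        ratios = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            sig = r.standard_normal(40000)
            few = cycle_power(sig, np.arange(0, 40001, 8000))[1]    # 5 cycles
            many = cycle_power(sig, np.arange(0, 40001, 2000))[1]   # 20 cycles
            ratios.append(few / many)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.5)  # sqrt(20/5)

    def test_too_few_starts_rejected(self):
        with pytest.raises(ValueError):
            cycle_power(np.zeros(100), np.array([0]))


class TestBandPower:
    def test_pure_tone_lands_in_band(self):
        t = np.arange(16000) / FS
        tone = np.sin(2 * np.pi * 75 * t)
        powers = band_powers(tone, FS)
        assert powers[1] / powers.sum() >= 0.90  # 50-100 Hz band

    def test_identical_signals_zero_delta(self, rng):
        x = rng.standard_normal(8000)
        np.testing.assert_array_equal(band_power_change(x, x), np.zeros(8))

    def test_parseval_consistency(self, rng):
        x = rng.standard_normal(16000)
        total_bands = band_powers(x, FS).sum()
        f, psd = periodogram(x, FS, detrend=False)
        direct = psd[(f >= 0) & (f <= 400)].sum() * (f[1] - f[0])
        assert abs(total_bands - direct) / direct < 0.05


class TestGrouping:
    @pytest.mark.parametrize(
        "deltas,expected",
        [
            ((1.0, 2.0, 0.5), "increase"),
            ((-1.0, 1.0, 0.0), "mixed"),
            ((-1e-9, 1e-9, 3.0), "increase"),   # sub-tolerance signs ignored
            ((-1.0, -2.0, -0.5), "decrease"),
            ((1e-9, -1e-9, -3.0), "decrease"),
            ((1e-9, -1e-9, 1e-8), "mixed"),     # all within tolerance
        ],
    )
    def test_examples(self, deltas, expected):
        assert group_clusters(np.array(deltas + (0.0,) * 5)) == expected

    def test_invariant_to_cluster_relabeling(self, rng):
        deltas = {0: np.array([1.0, 1.0, 1.0] + [0.0] * 5), 7: np.array([-1.0, -1.0, -1.0] + [0.0] * 5)}
        labels = {cid: group_clusters(d) for cid, d in deltas.items()}
        relabeled = {cid + 100: group_clusters(d) for cid, d in deltas.items()}
        assert list(labels.values()) == list(relabeled.values())


class TestClusterReport:
    def test_report_columns(self):
        recons = {
            0: {"pre": np.ones(4000) * 0.1, "post": np.ones(4000) * 0.05,
                "pre_raw": np.ones(4000), "post_raw": np.ones(4000)},
        }
        starts = {"pre": np.array([0, 2000, 3999]), "post": np.array([0, 2000, 3999])}
        report = interpret.cluster_report(recons, starts)
        assert report.loc[0, "group"] in ("increase", "decrease", "mixed")
        assert report.loc[0, "cycle_power_pre"] > report.loc[0, "cycle_power_post"]
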