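"""GFP, similarity measures, TAAHC, back-fitting, smoothing and GEV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mslab.core import (GfpSeries, LabelSequence, MicrostateSegmentation,
                        abs_correlation_matrix, backfit, extract_peak_maps,
                        find_gfp_peaks, gev, gfp, gmd, order_maps,
                        pool_peaks, smooth_labels, spatial_correlation,
                        taahc)
from mslab.core import GfpPeakSet
from mslab.stats import run_length_encode
from mslab.synthetic import make_templates

from conftest import make_recording


class TestGfp:
    def test_zero_data(self):
        rec = make_recording(np.zeros((19, 10)), reference="average")
        assert np.allclose(gfp(rec).values, 0.0)

    def test_two_channel_closed_form(self):
        a = 3.7
        rec = make_recording([[a, 2 * a], [-a, -2 * a]],
                             reference="average")
        assert np.allclose(gfp(rec).values, [a, 2 * a])

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((19, 50))
        data -= data.mean(axis=0)
        rec = make_recording(data, reference="average")
        scaled = make_recording(3 * data, reference="average")
        assert np.allclose(gfp(scaled).values, 3 * gfp(rec).values)

    def test_requires_average_reference(self):
        rec = make_recording(np.ones((19, 10)))
        with pytest.raises(ValueError):
            gfp(rec)


class TestFindGfpPeaks:
    def test_monotone_series_has_no_peaks(self):
        g = GfpSeries(values=np.linspace(0, 1, 500), fs=1000.0)
        assert len(find_gfp_peaks(g)) == 0

    def test_sinusoidal_gfp_peak_count_and_spacing(self):
        t = np.arange(1000) / 1000.0
        g = GfpSeries(values=1.5 + np.sin(2 * np.pi * 10 * t), fs=1000.0)
        idx = find_gfp_peaks(g, min_dist_ms=10)
        assert 9 <= len(idx) <= 10
        assert np.allclose(np.diff(idx), 100, atol=2)

    def test_outlier_peak_excluded_by_sd_rule(self):
        t = np.arange(2000) / 1000.0
        values = 1.5 + np.sin(2 * np.pi * 10 * t)
        values[505] = 10 * values.max()       # artifactual spike
        g = GfpSeries(values=values, fs=1000.0)
        idx = find_gfp_peaks(g, sd_mult=2)
        assert 505 not in idx
        # cross-check against the directly computed exclusion bound
        all_idx = find_gfp_peaks(g, sd_mult=None)
        pv = values[all_idx]
        bound = pv.mean() + 2 * pv.std()
        assert values[505] > bound

    def test_max_peaks_keeps_largest(self):
        t = np.arange(2000) / 1000.0
        values = 1.5 + np.sin(2 * np.pi * 10 * t) * np.linspace(0.5, 1, 2000)
        g = GfpSeries(values=values, fs=1000.0)
        idx = find_gfp_peaks(g, sd_mult=None, max_peaks=5)
        assert len(idx) == 5
        full = find_gfp_peaks(g, sd_mult=None)
        top5 = full[np.argsort(values[full])[::-1][:5]]
        assert set(idx) == set(top5)

    def test_min_dist_validation(self):
        g = GfpSeries(values=np.ones(10), fs=1000.0)
        with pytest.raises(ValueError):
            find_gfp_peaks(g, min_dist_ms=0)


class TestSimilarity:
    def test_self_correlation_is_one(self, templates):
        u = templates.maps[0]
        assert spatial_correlation(u, u) == pytest.approx(1.0)

    def test_polarity_invariance(self, templates):
        u = templates.maps[0]
        assert spatial_correlation(u, -u) == pytest.approx(1.0)
        assert gmd(u, -u) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_maps(self):
        u = np.array([1.0, -1.0, 0.0, 0.0])
        v = np.array([0.0, 0.0, 1.0, -1.0])
        assert spatial_correlation(u, v) == pytest.approx(0.0, abs=1e-12)
        assert gmd(u, v) == pytest.approx(np.sqrt(2.0))

    def test_gmd_identity_with_correlation(self):
        """GMD^2 = 2 (1 - r) cross-validates the two similarity measures."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            u = rng.standard_normal(19)
            v = rng.standard_normal(19)
            r = spatial_correlation(u, v)
            assert gmd(u, v) ** 2 == pytest.approx(2 * (1 - r), abs=1e-9)

    def test_flat_map_rejected(self):
        with pytest.raises(ValueError):
            spatial_correlation(np.ones(19), np.arange(19.0))
        with pytest.raises(ValueError):
            gmd(np.ones(19), np.arange(19.0))


def planted_peaks(templates, n_per_class=50, noise=0.1, seed=0):
    """Peak maps drawn as +-(template + small noise)."""
    rng = np.random.default_rng(seed)
    k, c = templates.maps.shape
    rows, truth = [], []
    for j in range(k):
        for _ in range(n_per_class):
            sign = rng.choice([-1.0, 1.0])
            amp = rng.uniform(5, 15)
            rows.append(sign * amp * (templates.maps[j]
                                      + noise * rng.standard_normal(c)))
            truth.append(j)
    order = rng.permutation(len(rows))
    return np.array(rows)[order], np.array(truth)[order]


class TestTaahc:
    def test_recovers_planted_templates(self, templates):
        x, truth = planted_peaks(templates)
        est = MicrostateSegmentation(n_states=4).fit(x)
        maps, perm = order_maps(est.maps_, templates.maps)
        corr = [spatial_correlation(maps[j], templates.maps[j])
                for j in range(4)]
        assert min(corr) > 0.95
        # assignment purity: estimated cluster -> archetype via perm
        inv = np.argsort(perm)
        purity = np.mean(inv[est.labels_] == truth)
        assert purity > 0.95

    def test_single_atomization_step(self, templates):
        x, _ = planted_peaks(templates, n_per_class=3)
        p = x.shape[0]
        est = MicrostateSegmentation(n_states=p - 1).fit(x)
        assert len(np.unique(est.labels_)) == p - 1

    def test_duplicate_maps_give_same_prototypes(self, templates):
        x, _ = planted_peaks(templates, n_per_class=20)
        single = MicrostateSegmentation(4).fit(x)
        double = MicrostateSegmentation(4).fit(np.vstack([x, x]))
        m1, _ = order_maps(single.maps_, templates.maps)
        m2, _ = order_maps(double.maps_, templates.maps)
        for a, b in zip(m1, m2):
            assert spatial_correlation(a, b) > 0.999

    def test_too_few_peaks_rejected(self, templates):
        with pytest.raises(ValueError):
            MicrostateSegmentation(4).fit(templates.maps)

    def test_alternative_criterion_also_recovers(self, templates):
        x, _ = planted_peaks(templates)
        maps, _ = taahc(x, 4, worst_criterion="abs_corr_sum")
        ordered, _ = order_maps(maps, templates.maps)
        assert min(spatial_correlation(ordered[j], templates.maps[j])
                   for j in range(4)) > 0.95

    def test_sklearn_get_set_params_roundtrip(self):
        est = MicrostateSegmentation(n_states=5)
        params = est.get_params()
        assert params["n_states"] == 5
        est.set_params(n_states=6)
        assert est.n_states == 6


class TestPoolPeaks:
    def _peak_set(self, n, seed, sid):
        rng = np.random.default_rng(seed)
        return GfpPeakSet(indices=np.arange(n),
                          maps=rng.standard_normal((n, 19)),
                          gfp_values=rng.uniform(1, 2, n), subject_id=sid)

    def test_cap_arithmetic(self):
        sets = [self._peak_set(n, i, f"s{i}")
                for i, n in enumerate([600, 508, 900])]
        pooled, owner = pool_peaks(sets, per_subject_cap=508)
        assert pooled.shape == (600 - 92 + 508 + 508, 19)
        assert pooled.shape[0] == 1524
        counts = np.bincount(owner)
        assert counts.max() <= 508

    def test_subject_under_cap_contributes_all(self):
        sets = [self._peak_set(100, 0, "s0")]
        pooled, _ = pool_peaks(sets, per_subject_cap=508)
        assert pooled.shape[0] == 100

    def test_auto_cap_is_smallest_subject(self):
        sets = [self._peak_set(n, i, f"s{i}")
                for i, n in enumerate([40, 70, 55])]
        pooled, owner = pool_peaks(sets, per_subject_cap=None)
        assert np.bincount(owner).tolist() == [40, 40, 40]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_peaks([])


class TestOrderMaps:
    def test_shuffled_canonical_recovers_identity(self, templates):
        perm_in = np.array([2, 0, 3, 1])
        shuffled = templates.maps[perm_in]
        ordered, perm = order_maps(shuffled, templates.maps)
        assert np.allclose(ordered, templates.maps)

    def test_polarity_flips_ignored(self, templates):
        flipped = templates.maps * np.array([[-1], [1], [-1], [1]])
        ordered, perm = order_maps(flipped, templates.maps)
        assert np.array_equal(perm, np.arange(4))

    def test_noisy_copies_assigned_correctly(self, templates):
        rng = np.random.default_rng(3)
        noisy = templates.maps + 0.1 * rng.standard_normal((4, 19))
        shuffled = noisy[[3, 1, 0, 2]]
        _, perm = order_maps(shuffled, templates.maps)
        assert np.array_equal(perm, [2, 1, 3, 0])

    def test_shape_mismatch_rejected(self, templates):
        with pytest.raises(ValueError):
            order_maps(templates.maps[:3], templates.maps)


class TestBackfit:
    def test_exact_map_gets_fit_one(self, templates):
        rec = make_recording(templates.maps[2][:, None] * 5.0,
                             reference="average")
        ls = backfit(templates.maps, rec)
        assert ls.labels[0] == 2
        assert ls.fit[0] == pytest.approx(1.0)

    def test_noiseless_sequence_recovered(self, templates):
        rng = np.random.default_rng(0)
        seq = rng.integers(0, 4, size=40)
        amps = rng.uniform(3, 8, size=40)
        data = (templates.maps[seq] * amps[:, None]).T
        rec = make_recording(data, reference="average")
        ls = backfit(templates.maps, rec)
        assert np.array_equal(ls.labels, seq)

    def test_channel_mismatch_rejected(self, templates):
        rec = make_recording(np.random.default_rng(0)
                             .standard_normal((10, 5)), reference="average")
        with pytest.raises(ValueError):
            backfit(templates.maps, rec)


def _ls(labels, fs=1000.0, k=4):
    labels = np.asarray(labels)
    return LabelSequence(labels=labels, fit=np.ones(len(labels)),
                         fs=fs, n_states=k)


class TestSmoothLabels:
    def test_zero_min_ms_is_identity(self):
        labels = np.array([0] * 5 + [1] * 2 + [0] * 5)
        corr = np.random.default_rng(0).uniform(size=(12, 4))
        out = smooth_labels(_ls(labels), corr, min_ms=0)
        assert np.array_equal(out.labels, labels)

    def test_short_run_merges_into_neighbour(self):
        """A(50 ms) B(10 ms) A(50 ms) with runner-up A becomes one A run."""
        labels = np.array([0] * 50 + [1] * 10 + [0] * 50)
        corr = np.zeros((110, 4))
        corr[:, 0] = 0.8
        corr[50:60, 1] = 0.9        # B wins raw, A is next-best
        corr[:, 2:] = 0.1
        out = smooth_labels(_ls(labels), corr, min_ms=30)
        assert np.all(out.labels == 0)

    def test_no_short_runs_remain_on_random_configs(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            n = int(rng.integers(400, 1200))
            corr = rng.uniform(0.1, 1.0, size=(n, 4))
            labels = np.argmax(corr, axis=1)
            out = smooth_labels(_ls(labels), corr, min_ms=30)
            runs = run_length_encode(out.labels)
            assert min(length for _, _, length in runs) >= 30

    def test_long_runs_untouched(self):
        labels = np.array([2] * 100 + [3] * 100)
        corr = np.tile([0.1, 0.1, 0.5, 0.5], (200, 1))
        out = smooth_labels(_ls(labels), corr, min_ms=30)
        assert np.array_equal(out.labels, labels)


class TestGev:
    def test_perfect_fit_gives_one(self, templates):
        rng = np.random.default_rng(1)
        seq = rng.integers(0, 4, size=100)
        amps = rng.uniform(1, 5, size=100)
        rec = make_recording((templates.maps[seq] * amps[:, None]).T,
                             reference="average")
        ls = backfit(templates.maps, rec)
        total, per_class = gev(rec, templates.maps, ls)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_assignment_gives_zero(self):
        u = np.zeros(19)
        u[:2] = [1, -1]
        v = np.zeros(19)
        v[2:4] = [1, -1]
        rec = make_recording(np.tile(u[:, None], (1, 10)),
                             reference="average")
        ls = _ls(np.zeros(10, dtype=int), k=1)
        total, _ = gev(rec, v[None, :], ls)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_per_class_partition_sums_to_total(self, templates):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((19, 300))
        data -= data.mean(axis=0)
        rec = make_recording(data, reference="average")
        ls = backfit(templates.maps, rec)
        total, per_class = gev(rec, templates.maps, ls)
        assert per_class.sum() == pytest.approx(total, abs=1e-12)
        assert 0.0 <= total <= 1.0

    def test_scale_invariance(self, templates):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((19, 100))
        data -= data.mean(axis=0)
        rec = make_recording(data, reference="average")
        rec3 = make_recording(3 * data, reference="average")
        ls = backfit(templates.maps, rec)
        assert gev(rec, templates.maps, ls)[0] == pytest.approx(
            gev(rec3, templates.maps, ls)[0])

    def test_all_zero_data_rejected(self, templates):
        rec = make_recording(np.zeros((19, 5)), reference="average")
        ls = _ls(np.zeros(5, dtype=int))
        with pytest.raises(ValueError):
            gev(rec, templates.maps, ls)


@settings(max_examples=30, deadline=None)
@given(st.lists(st.integers(0, 3), min_size=40, max_size=300))
def test_smoothing_postcondition_property(seq):
    """After smoothing, every run is at least the threshold long."""
    labels = np.asarray(seq)
    rng = np.random.default_rng(len(seq))
    corr = rng.uniform(0.1, 1.0, size=(len(labels), 4))
    out = smooth_labels(_ls(labels, fs=1000.0), corr, min_ms=20)
    runs = run_length_encode(out.labels)
    if len(out.labels) >= 20:
        assert min(length for _, _, length in runs) >= 20 or len(runs) == 1
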