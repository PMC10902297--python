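"""Generator contracts: reproducibility, coupling ground truth, planting."""

import numpy as np
import pytest

from neuroplex import (
    CohortSpec,
    OscillatorSpec,
    analytic_band,
    gen_cohort,
    gen_oscillators,
    gen_structural,
    binarize_to_density,
    participation,
    build_multiplex,
    plv,
    plv_ground_truth,
    transfer_entropy,
)
from neuroplex.simulate import _partition_sizes


def _pair_coupling(c):
    return np.array([[0.0, c], [c, 0.0]])


class TestGenOscillators:
    def test_identical_seed_identical_output(self):
        spec = OscillatorSpec(n_rois=4, seed=42, duration_s=20)
        a = gen_oscillators(spec)
        b = gen_oscillators(OscillatorSpec(n_rois=4, seed=42, duration_s=20))
        assert np.array_equal(a.data, b.data)
        c = gen_oscillators(OscillatorSpec(n_rois=4, seed=43, duration_s=20))
        assert not np.array_equal(a.data, c.data)

    def test_full_coupling_locks_phases_exactly(self):
        spec = OscillatorSpec(
            n_rois=2, coupling=_pair_coupling(1.0), noise_sd=0.0, seed=1
        )
        sig = analytic_band(gen_oscillators(spec), (8.0, 12.0))
        assert plv(sig.signals[0], sig.signals[1]) == pytest.approx(1.0, abs=1e-6)

    def test_uncoupled_oscillators_decorrelate(self):
        """Independent phase diffusion: all pairwise PLV below 0.1 on a long record."""
        spec = OscillatorSpec(n_rois=3, duration_s=120, noise_sd=0.3, seed=2)
        sig = analytic_band(gen_oscillators(spec), (8.0, 12.0))
        for i in range(3):
            for j in range(i + 1, 3):
                assert plv(sig.signals[i], sig.signals[j]) < 0.1

    def test_plv_tracks_closed_form_ground_truth(self):
        """Empirical pair PLV across seeds matches the diffusion closed form."""
        for c in (0.9, 0.998):
            vals = [
                plv(
                    *analytic_band(
                        gen_oscillators(
                            OscillatorSpec(
                                n_rois=2, coupling=_pair_coupling(c),
                                noise_sd=0.0, duration_s=60, seed=s,
                            )
                        ),
                        (8.0, 12.0),
                    ).signals[:2]
                )
                for s in range(8)
            ]
            expected = plv_ground_truth(c, 3.0, 60.0)
            assert np.sqrt(np.mean(np.square(vals))) == pytest.approx(
                expected, rel=0.35
            )

    def test_directed_influence_breaks_te_symmetry(self):
        influence = np.zeros((2, 2))
        influence[0, 1] = 0.9
        spec = OscillatorSpec(
            n_rois=2, directed_influence=influence, noise_sd=0.2, seed=3
        )
        sig = analytic_band(gen_oscillators(spec), (8.0, 12.0))
        x = sig.signals.real
        assert transfer_entropy(x[0], x[1]) > 3 * transfer_entropy(x[1], x[0])

    def test_asymmetric_coupling_rejected(self):
        c = np.zeros((3, 3))
        c[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            OscillatorSpec(n_rois=3, coupling=c)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            OscillatorSpec(n_rois=2, duration_s=0.0)

    def test_phase_lag_realised_between_coupled_pair(self):
        lag = np.zeros((2, 2))
        lag[0, 1] = np.pi / 3
        spec = OscillatorSpec(
            n_rois=2, coupling=_pair_coupling(1.0), phase_lag=lag,
            noise_sd=0.0, seed=4,
        )
        sig = analytic_band(gen_oscillators(spec), (8.0, 12.0))
        diff = np.angle(sig.signals[1] * np.conj(sig.signals[0]))
        assert np.median(diff) == pytest.approx(np.pi / 3, abs=0.05)


class TestGenStructural:
    def _functional_reference(self, rng, n=20):
        from neuroplex import ConnectivityMatrix

        w = rng.random((n, n))
        w = np.triu(w, 1)
        return ConnectivityMatrix(values=w + w.T, modality="PLV", band="8-12Hz")

    def test_full_overlap_reproduces_the_functional_layer(self, rng):
        fref = self._functional_reference(rng)
        spec = OscillatorSpec(n_rois=20, seed=5)
        cohort = CohortSpec(structural_overlap=1.0)
        fa = gen_structural(spec, cohort, fref)
        a_s = binarize_to_density(fa, 0.22)
        a_f = binarize_to_density(fref, 0.22)
        assert np.array_equal(a_s, a_f)
        mx = build_multiplex(fa, fref, density=0.22)
        res = participation(mx)
        assert np.allclose(res.p[res.o > 0], 1.0)

    def test_zero_overlap_separates_the_layers(self, rng):
        fref = self._functional_reference(rng)
        spec = OscillatorSpec(n_rois=20, seed=6)
        fa = gen_structural(spec, CohortSpec(structural_overlap=0.0), fref)
        a_s = binarize_to_density(fa, 0.22)
        a_f = binarize_to_density(fref, 0.22)
        assert (a_s & a_f).sum() == 0
        res = participation(build_multiplex(fa, fref, density=0.22))
        # disjoint edge sets leave most nodes partially engaged per layer
        assert np.mean(res.p[res.o > 0] < 0.999) > 0.5

    def test_intermediate_overlap_is_binomial(self, rng):
        fref = self._functional_reference(rng, n=40)
        spec = OscillatorSpec(n_rois=40, seed=7)
        fa = gen_structural(spec, CohortSpec(structural_overlap=0.6), fref)
        a_s = binarize_to_density(fa, 0.22)
        a_f = binarize_to_density(fref, 0.22)
        e = a_f.sum() // 2
        shared = (a_s & a_f).sum() // 2
        assert shared / e == pytest.approx(0.6, abs=0.15)

    def test_negative_weight_ranges_rejected(self, rng):
        from neuroplex.simulate import _fa_weights

        with pytest.raises(ValueError, match="nonnegative"):
            _fa_weights(
                rng, 10, np.array([[0, 1]]), strong_range=(0.4, 0.7),
                weak_range=(-0.2, 0.1),
            )

    def test_fa_matrix_is_valid(self, rng):
        fref = self._functional_reference(rng)
        fa = gen_structural(OscillatorSpec(n_rois=20, seed=8), CohortSpec(), fref)
        fa.validate()
        assert np.all(np.diag(fa.values) == 0)


class TestPartitions:
    @pytest.mark.parametrize("n,density", [(20, 0.22), (12, 0.22), (68, 0.22)])
    def test_module_pairs_hit_the_edge_budget(self, n, density):
        e = int(np.floor(density * n * (n - 1) / 2))
        sizes = _partition_sizes(n, e)
        pairs = sum(s * (s - 1) // 2 for s in sizes)
        assert sum(sizes) == n
        assert abs(pairs - e) <= 2


class TestGenCohort:
    def _small(self, seed=0, **kw):
        ospec = OscillatorSpec(n_rois=12, fs_hz=250, duration_s=20, seed=seed)
        defaults = dict(
            n_young=4, n_old=4, target_nodes=(1,), seed=seed, density=0.22
        )
        defaults.update(kw)
        return gen_cohort(ospec, CohortSpec(**defaults))

    def test_seeded_rerun_is_identical(self):
        a = self._small(seed=11)
        b = self._small(seed=11)
        assert a.table.equals(b.table)
        for ta, tb in zip(a.timeseries, b.timeseries):
            assert np.array_equal(ta.data, tb.data)
        for sa, sb in zip(a.structural, b.structural):
            assert np.array_equal(sa.values, sb.values)
        assert np.array_equal(
            a.truth["participation"], b.truth["participation"]
        )

    def test_different_seed_differs(self):
        assert not self._small(seed=1).table.equals(self._small(seed=2).table)

    def test_target_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            self._small(target_nodes=(40,))

    def test_truth_matches_regenerated_degrees(self):
        cohort = self._small(seed=13)
        kf = cohort.truth["k_functional"]
        ks = cohort.truth["k_structural"]
        e = int(np.floor(0.22 * 12 * 11 / 2))
        assert np.all(kf.sum(axis=1) == 2 * e)
        assert np.all(ks.sum(axis=1) == 2 * e)
        p = cohort.truth["participation"]
        o = kf + ks
        expected = np.where(o > 0, 2 * (1 - (kf**2 + ks**2) / np.maximum(o, 1) ** 2), 0)
        assert np.allclose(p, expected)

    def test_planted_group_effect_has_requested_size(self):
        """The true participation shift at targets tracks effect_size_d."""
        ospec = OscillatorSpec(n_rois=20, fs_hz=250, duration_s=20, seed=0)
        shifts = []
        for seed in range(4):
            cohort = gen_cohort(
                ospec,
                CohortSpec(
                    n_young=40, n_old=40, target_nodes=(2,), effect_size_d=-1.2,
                    seed=seed,
                ),
            )
            p = cohort.truth["participation"][:, 2]
            old = (cohort.table["group"] == "old").to_numpy()
            shifts.append(
                (p[old].mean() - p[~old].mean())
                / cohort.truth["participation_baseline_sd"]
            )
        assert np.mean(shifts) == pytest.approx(-1.2, abs=0.4)

    def test_cognition_score_tracks_participation(self):
        cohort = self._small(
            seed=17, n_young=30, n_old=30, cognition_slope=0.8, score_noise_sd=0.01
        )
        old = (cohort.table["group"] == "old").to_numpy()
        p_target = cohort.truth["participation"][old, 1]
        score = cohort.table.loc[old, "VSTM"].to_numpy()
        slope = np.polyfit(p_target, score, 1)[0]
        assert slope == pytest.approx(0.8, abs=0.15)

    def test_cohort_table_schema(self):
        table = self._small(seed=19).table
        for col in (
            "subject_id", "group", "age", "sex", "education",
            "grey_matter_volume", "total_intracranial_volume",
            "MMSE", "VSTM", "Cattell", "Hotel_Num_rows", "Hotel_Time",
        ):
            assert col in table.columns
        assert set(table["group"]) == {"young", "old"}
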