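"""Fragment matching, entropy similarity, auxiliary metrics, peak consumption."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon
from scipy.stats import rankdata

from psmfeat.library import Fragment, PredictedEntry
from psmfeat.peptides import ModifiedPeptide
from psmfeat.similarity import (
    MatchedVectors,
    auxiliary_similarities,
    consume_matched_peaks,
    match_fragments,
    unweighted_spectral_entropy,
)
from psmfeat.spectra import ExperimentalSpectrum
from tests.conftest import entry_for, spectrum_from_entry


def entropy_oracle(p, q):
    """Independent route: 1 - squared Jensen-Shannon distance in bits."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    if q.sum() == 0:
        return 0.0
    return 1.0 - jensenshannon(p / p.sum(), q / q.sum(), base=2) ** 2


def vectors(p, q):
    p, q = np.asarray(p, float), np.asarray(q, float)
    return MatchedVectors(p, q, q > 0, np.where(q > 0, 0, -1), 20.0)


def single_fragment_entry(mz_values, intensities=None):
    pep = ModifiedPeptide("PEPTIDEK", (), 2)
    frags = [
        Fragment(mz, 1.0 if intensities is None else intensities[i], "b", 2, 1)
        for i, mz in enumerate(mz_values)
    ]
    return PredictedEntry(pep, frags, 50.0)


class TestMatching:
    def test_highest_intensity_peak_wins(self):
        entry = single_fragment_entry([500.000])
        spec = ExperimentalSpectrum(1, [499.995, 500.005], [200.0, 100.0], 5.0)
        v = match_fragments(spec, entry, tol_ppm=20.0)
        assert v.experimental[0] == 200.0

    def test_out_of_tolerance_gives_zero_vector(self):
        entry = single_fragment_entry([500.0, 600.0])
        spec = ExperimentalSpectrum(1, [505.0, 610.0], [10.0, 10.0], 5.0)
        v = match_fragments(spec, entry, tol_ppm=20.0)
        assert not v.matched_mask.any()
        assert (v.experimental == 0).all()

    def test_identity_spectrum_matches_everything(self, toy_entry):
        spec = spectrum_from_entry(toy_entry)
        v = match_fragments(spec, toy_entry, tol_ppm=20.0)
        assert v.matched_mask.all()
        np.testing.assert_allclose(
            np.sort(v.experimental), np.sort(toy_entry.intensity_array())
        )

    def test_tie_broken_by_closer_mz(self):
        entry = single_fragment_entry([500.000])
        spec = ExperimentalSpectrum(1, [499.996, 500.002], [100.0, 100.0], 5.0)
        v = match_fragments(spec, entry, tol_ppm=20.0)
        assert v.matched_peak_indices[0] == 1  # 500.002 is closer

    def test_one_peak_may_serve_two_fragments(self):
        entry = single_fragment_entry([500.000, 500.001])
        spec = ExperimentalSpectrum(1, [500.0005], [50.0], 5.0)
        v = match_fragments(spec, entry, tol_ppm=20.0)
        assert v.matched_mask.all()
        assert (v.experimental == 50.0).all()

    def test_empty_fragment_list_rejected(self):
        pep = ModifiedPeptide("PEPTIDEK", (), 2)
        entry = PredictedEntry(pep, [], 50.0)
        spec = ExperimentalSpectrum(1, [500.0], [1.0], 5.0)
        with pytest.raises(ValueError):
            match_fragments(spec, entry, 20.0)

    def test_absolute_da_tolerance_mode(self):
        entry = single_fragment_entry([500.0])
        spec = ExperimentalSpectrum(1, [500.4], [10.0], 5.0)
        assert not match_fragments(spec, entry, tol_ppm=20.0).matched_mask.any()
        assert match_fragments(spec, entry, tol_ppm=20.0, tol_da=0.5).matched_mask.all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_invariant_to_experimental_peak_order(self, rnd):
        rng = np.random.default_rng(rnd.randint(0, 10**6))
        entry = single_fragment_entry(sorted(rng.uniform(200, 1200, size=6)))
        mz = rng.uniform(200, 1200, size=30)
        inten = rng.uniform(0, 100, size=30)
        perm = rng.permutation(30)
        v1 = match_fragments(ExperimentalSpectrum(1, mz, inten, 1.0), entry, 2000.0)
        v2 = match_fragments(
            ExperimentalSpectrum(1, mz[perm], inten[perm], 1.0), entry, 2000.0
        )
        np.testing.assert_array_equal(v1.experimental, v2.experimental)


class TestEntropy:
    def test_identical_spectra_score_exactly_one(self):
        assert unweighted_spectral_entropy(vectors([0.2, 0.5, 0.3], [0.2, 0.5, 0.3])) == 1.0
        assert unweighted_spectral_entropy(vectors([2, 5, 3], [4, 10, 6])) == 1.0

    def test_disjoint_spectra_score_exactly_zero(self):
        assert unweighted_spectral_entropy(vectors([1, 0], [0, 1])) == 0.0

    def test_worked_example(self):
        # 1 - (2 S([0.75, 0.25]) - ln 2 - 0) / ln 4
        s_m = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        expected = 1.0 - (2 * s_m - np.log(2)) / np.log(4)
        got = unweighted_spectral_entropy(vectors([0.5, 0.5], [1.0, 0.0]))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_all_zero_experimental_scores_zero(self):
        assert unweighted_spectral_entropy(vectors([1, 2, 3], [0, 0, 0])) == 0.0

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            unweighted_spectral_entropy(vectors([1, 2], [-1, 2]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 100), min_size=2, max_size=12),
        st.lists(st.floats(0, 100), min_size=2, max_size=12),
    )
    def test_matches_jensen_shannon_oracle_and_stays_in_unit_interval(self, p, q):
        n = min(len(p), len(q))
        p, q = np.array(p[:n]), np.array(q[:n])
        if p.sum() == 0:
            p[0] = 1.0
        got = unweighted_spectral_entropy(vectors(p, q))
        assert 0.0 <= got <= 1.0
        assert got == pytest.approx(entropy_oracle(p, q), abs=1e-9)
        if q.sum() > 0:  # symmetry
            assert unweighted_spectral_entropy(vectors(q, p)) == pytest.approx(got, abs=1e-12)


class TestAuxiliary:
    def test_identical_vectors(self):
        aux = auxiliary_similarities(vectors([1, 2, 3], [1, 2, 3]))
        assert aux["cosine_similarity"] == pytest.approx(1.0)
        assert aux["matched_fraction"] == 1.0
        assert aux["bray_curtis"] == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        aux = auxiliary_similarities(vectors([1, 0], [0, 1]))
        assert aux["cosine_similarity"] == pytest.approx(0.0)

    def test_constant_vector_correlation_is_zero(self):
        aux = auxiliary_similarities(vectors([1, 1, 1], [1, 2, 3]))
        assert aux["pearson_corr"] == 0.0
        assert aux["spearman_corr"] == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_each_metric_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, size=12)
        q = rng.uniform(0, 1, size=12)
        aux = auxiliary_similarities(vectors(p, q))
        assert aux["cosine_similarity"] == pytest.approx(
            float(np.sum(p * q)) / np.sqrt(np.sum(p * p) * np.sum(q * q)), abs=1e-12
        )
        assert aux["dot_product"] == pytest.approx(
            float(np.sum((p / p.sum()) * (q / q.sum()))), abs=1e-12
        )
        pc = np.sum((p - p.mean()) * (q - q.mean())) / (
            np.sqrt(np.sum((p - p.mean()) ** 2)) * np.sqrt(np.sum((q - q.mean()) ** 2))
        )
        assert aux["pearson_corr"] == pytest.approx(float(pc), abs=1e-9)
        rp, rq = rankdata(p), rankdata(q)
        sc = np.corrcoef(rp, rq)[0, 1]
        assert aux["spearman_corr"] == pytest.approx(float(sc), abs=1e-9)
        assert aux["bray_curtis"] == pytest.approx(
            1.0 - np.abs(p - q).sum() / (p + q).sum(), abs=1e-12
        )


class TestConsumption:
    def test_matched_peaks_removed_once(self):
        entry = single_fragment_entry([300.0, 400.0, 500.0, 600.0])
        extra = [150.0, 250.0, 350.0, 450.0, 550.0, 650.0]
        mz = sorted([300.0, 400.0, 500.0, 600.0] + extra)
        spec = ExperimentalSpectrum(1, mz, [1.0] * 10, 5.0)
        consume_matched_peaks(spec, entry, 20.0)
        assert len(spec) == 6
        assert all(m in extra for m in spec.mz)

    def test_shared_peak_deleted_exactly_once(self):
        entry = single_fragment_entry([500.000, 500.001])
        spec = ExperimentalSpectrum(1, [100.0, 500.0005], [1.0, 5.0], 5.0)
        consume_matched_peaks(spec, entry, 20.0)
        assert len(spec) == 1

    def test_nothing_matches_is_noop(self):
        entry = single_fragment_entry([500.0])
        spec = ExperimentalSpectrum(1, [100.0], [1.0], 5.0)
        consume_matched_peaks(spec, entry, 20.0)
        assert len(spec) == 1

    def test_rank2_sharing_all_fragments_scores_zero_after_consumption(self, toy_entry):
        spec = spectrum_from_entry(toy_entry)
        before = match_fragments(spec, toy_entry, 20.0)
        assert unweighted_spectral_entropy(before) == 1.0
        consume_matched_peaks(spec, toy_entry, 20.0)
        after = match_fragments(spec, toy_entry, 20.0)
        assert unweighted_spectral_entropy(after) == 0.0


def test_targets_beat_decoys_on_entropy(sim_dir):
    """Median entropy of true matches exceeds that of mismatched pairings."""
    from psmfeat.library import read_prediction_library
    from psmfeat.pin import read_pin
    from psmfeat.spectra import read_spectra
    from psmfeat.pipeline import resolve_entry
    from psmfeat.config import RunConfig

    _, paths = sim_dir
    table = read_pin(paths["pin"])
    spectra = read_spectra(paths["spectra"])
    library = read_prediction_library(paths["library_tsv"])
    cfg = RunConfig()
    scores = {True: [], False: []}
    for rec in table.records:
        entry = resolve_entry(rec, library, cfg)
        assert entry is not None
        v = match_fragments(spectra[rec.scan_nr], entry, cfg.tol_ppm)
        scores[rec.is_target].append(unweighted_spectral_entropy(v))
    assert np.median(scores[True]) > np.median(scores[False])
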