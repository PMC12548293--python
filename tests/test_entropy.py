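"""Shannon-entropy statistic, stratified summaries, trends and MSI scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msikit.catalog import catalog_by_id
from msikit.entropy import (
    MsiBaseline,
    build_baseline,
    compute_entropies,
    fit_motif_trend,
    score_msi,
    shannon_entropy,
    summarize_strata,
    total_variation,
)
from msikit.simulate import simulate_locus_spectra, synthetic_catalog
from msikit.spectra import AlleleSpectrum


def _sp(counts, locus_id="l", sample_id="s"):
    return AlleleSpectrum(locus_id=locus_id, sample_id=sample_id, counts=counts)


class TestShannonEntropy:
    def test_single_length_spectrum_is_exactly_zero(self):
        """All reads sharing one repeat length means complete stability: SE = 0."""
        assert shannon_entropy(_sp({10: 37})) == 0.0

    def test_uniform_two_lengths_is_one_bit(self):
        assert shannon_entropy(_sp({12: 50, 13: 50})) == pytest.approx(1.0)

    def test_quarter_half_quarter_is_one_and_a_half_bits(self):
        assert shannon_entropy(_sp({9: 25, 10: 50, 11: 25})) == pytest.approx(1.5)

    def test_empty_spectrum_is_undefined(self):
        with pytest.raises(ValueError):
            shannon_entropy({})

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.dictionaries(st.integers(1, 40), st.integers(1, 500), min_size=1, max_size=8))
    def test_bounds_and_label_invariance(self, counts):
        se = shannon_entropy(counts)
        assert 0.0 <= se <= math.log2(len(counts)) + 1e-12
        # permuting the length labels leaves SE unchanged
        relabeled = {k + 100: v for k, v in counts.items()}
        assert shannon_entropy(relabeled) == pytest.approx(se)
        # merging a spectrum with itself (same distribution) leaves SE unchanged
        doubled = {k: 2 * v for k, v in counts.items()}
        assert shannon_entropy(doubled) == pytest.approx(se)


class TestStrata:
    def test_complementary_motifs_combine(self, msi_catalog_by_id):
        cat = synthetic_catalog({"A": [8], "T": [8]}, loci_per_unit_count=6)
        byid = catalog_by_id(cat)
        ents = []
        for loc in cat:
            counts = {8: 10} if loc.motif == "A" else {8: 10}
            ents.append(
                compute_entropies([_sp(counts, locus_id=loc.locus_id)])[0]
            )
        # assign SE 0.2 to A-loci and 0.4 to T-loci via crafted spectra
        from msikit.entropy import LocusEntropy

        ents = [
            LocusEntropy(l.locus_id, "s", 0.2 if l.motif == "A" else 0.4, 10) for l in cat
        ]
        (stratum,) = summarize_strata(ents, byid, assay_kind="WGS")
        assert stratum.canonical_motif == "A"
        assert stratum.n_loci == 12
        assert stratum.mean_se == pytest.approx(0.3)

    def test_wes_excludes_small_strata(self):
        cat = synthetic_catalog({"A": [8]}, loci_per_unit_count=9)
        byid = catalog_by_id(cat)
        from msikit.entropy import LocusEntropy

        ents = [LocusEntropy(l.locus_id, "s", 0.1, 10) for l in cat]
        assert summarize_strata(ents, byid, assay_kind="WES") == []
        assert len(summarize_strata(ents, byid, assay_kind="WGS")) == 1

    def test_unknown_locus_is_hard_error(self, msi_catalog_by_id):
        from msikit.entropy import LocusEntropy

        with pytest.raises(KeyError):
            summarize_strata([LocusEntropy("nope:0:A", "s", 0.0, 10)], msi_catalog_by_id)

    def test_all_zero_entropies_give_zero_strata(self, msi_catalog, msi_catalog_by_id):
        from msikit.entropy import LocusEntropy

        ents = [LocusEntropy(l.locus_id, "s", 0.0, 10) for l in msi_catalog]
        for stratum in summarize_strata(ents, msi_catalog_by_id):
            assert stratum.mean_se == 0.0 and stratum.sd_se == 0.0


class TestMotifTrend:
    def test_exact_linear_points_recovered(self):
        cat = synthetic_catalog({"A": range(5, 11)}, loci_per_unit_count=2)
        byid = catalog_by_id(cat)
        from msikit.entropy import LocusEntropy

        ents = [LocusEntropy(l.locus_id, "s", 0.1 * l.unit_count, 10) for l in cat]
        trend = fit_motif_trend(ents, byid, "A")
        assert trend.slope == pytest.approx(0.1)
        assert trend.intercept == pytest.approx(0.0, abs=1e-10)
        assert trend.slope_ci_low <= trend.slope <= trend.slope_ci_high

    def test_constant_entropy_gives_zero_slope(self):
        cat = synthetic_catalog({"CA": range(4, 9)})
        byid = catalog_by_id(cat)
        from msikit.entropy import LocusEntropy

        ents = [LocusEntropy(l.locus_id, "s", 0.7, 10) for l in cat]
        assert fit_motif_trend(ents, byid, "CA").slope == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_three_distinct_lengths_is_an_error(self):
        cat = synthetic_catalog({"A": [5, 6]}, loci_per_unit_count=5)
        byid = catalog_by_id(cat)
        from msikit.entropy import LocusEntropy

        ents = [LocusEntropy(l.locus_id, "s", 0.2, 10) for l in cat]
        with pytest.raises(ValueError):
            fit_motif_trend(ents, byid, "A")


class TestBaselineAndScore:
    def test_single_normal_pool_equals_its_proportions(self, msi_catalog):
        spectra, _ = simulate_locus_spectra(
            msi_catalog, __import__("msikit.simulate", fromlist=["STABLE_MODEL"]).STABLE_MODEL,
            seed=3, depth=30, sample_id="n1",
        )
        base = build_baseline({"n1": spectra})
        for lid, sp in spectra.items():
            assert base.proportions[lid] == pytest.approx(sp.proportions())
            assert base.tau[lid] == 0.1  # single-normal fallback

    def test_identical_normals_floor_tau(self, msi_catalog):
        sp = {
            l.locus_id: _sp({l.unit_count: 20}, locus_id=l.locus_id, sample_id="x")
            for l in msi_catalog
        }
        base = build_baseline({"n1": sp, "n2": sp, "n3": sp})
        assert all(t == 0.0 for t in base.tau.values())  # LOO distances all zero
        result = score_msi(sp, base)
        assert result.msi_score == 0.0  # floor makes ties/zeros stable

    def test_sample_identical_to_baseline_scores_zero(self, msi_catalog, stable_model):
        spectra, _ = simulate_locus_spectra(msi_catalog, stable_model, seed=4, depth=40,
                                            sample_id="n")
        base = build_baseline({"n": spectra})
        assert score_msi(spectra, base).msi_score == 0.0

    def test_shifted_point_masses_score_one(self, msi_catalog):
        normal = {
            l.locus_id: _sp({l.unit_count: 30}, locus_id=l.locus_id, sample_id="n")
            for l in msi_catalog
        }
        shifted = {
            l.locus_id: _sp({l.unit_count - 1: 30}, locus_id=l.locus_id, sample_id="t")
            for l in msi_catalog
        }
        base = build_baseline({"n": normal})
        result = score_msi(shifted, base)
        assert result.msi_score == 1.0
        assert all(d == pytest.approx(1.0) for d in result.per_locus_distance.values())

    def test_no_shared_loci_is_hard_error(self, msi_catalog):
        normal = {"a:0:A": _sp({5: 10}, locus_id="a:0:A")}
        base = build_baseline({"n": normal})
        with pytest.raises(ValueError):
            score_msi({"b:0:A": _sp({5: 10}, locus_id="b:0:A")}, base)

    def test_zero_normals_is_hard_error(self):
        with pytest.raises(ValueError):
            build_baseline({})

    def test_baseline_json_round_trip(self, tmp_path, msi_catalog, stable_model):
        cohort = {}
        for i in range(3):
            sid = f"n{i}"
            cohort[sid], _ = simulate_locus_spectra(
                msi_catalog, stable_model, seed=10 + i, depth=30, sample_id=sid
            )
        base = build_baseline(cohort)
        path = tmp_path / "base.json"
        base.save(path)
        back = MsiBaseline.load(path)
        assert back.tau == pytest.approx(base.tau)
        assert back.proportions == base.proportions
        assert back.normal_sample_ids == base.normal_sample_ids

    def test_pooled_proportions_match_generating_distribution(self, msi_catalog,
                                                              deficient_model):
        """Pooling many normals recovers the model's allele distribution."""
        cohort = {}
        for i in range(10):
            sid = f"n{i}"
            cohort[sid], _ = simulate_locus_spectra(
                msi_catalog, deficient_model, seed=100 + i, depth=60, sample_id=sid
            )
        base = build_baseline(cohort)
        # at the longest loci the slip rate is p = min(.5, .002*5*11^1.5) ~ 0.365;
        # pooled mass at the reference length should be ~1 - p (+ back-mutation noise)
        longest = [l for l in msi_catalog if l.unit_count == 15]
        for loc in longest:
            p_ref = base.proportions[loc.locus_id].get(15, 0.0)
            expected = 1 - deficient_model.slip_probability(15, 5)
            assert abs(p_ref - expected) < 5 * math.sqrt(expected * (1 - expected) / 600)


def test_total_variation_basics():
    assert total_variation({1: 1.0}, {1: 1.0}) == 0.0
    assert total_variation({1: 1.0}, {2: 1.0}) == pytest.approx(1.0)
    assert total_variation({1: 0.5, 2: 0.5}, {1: 1.0}) == pytest.approx(0.5)


def test_msi_score_monotone_in_distances(msi_catalog):
    """Stretching a sample further from the baseline never lowers the score."""
    normal = {
        l.locus_id: _sp({l.unit_count: 40}, locus_id=l.locus_id, sample_id="n")
        for l in msi_catalog
    }
    base = build_baseline({"n": normal})
    scores = []
    for shifted_reads in (0, 4, 10, 20, 40):
        counts_by_locus = {
            l.locus_id: {
                k: v
                for k, v in {
                    l.unit_count: 40 - shifted_reads,
                    l.unit_count - 1: shifted_reads,
                }.items()
                if v > 0
            }
            for l in msi_catalog
        }
        sample = {
            lid: _sp(c, locus_id=lid, sample_id="t") for lid, c in counts_by_locus.items()
        }
        scores.append(score_msi(sample, base).msi_score)
    assert scores == sorted(scores)


import math  # noqa: E402  (used by the binomial-error bound above)
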