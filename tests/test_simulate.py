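"""Synthetic-data generator: determinism, configured-distribution recovery,
unsatisfiable-target detection, database jitter behaviour and validation
panel construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from indelkit.dbmatch import MatchTier, match_variant
from indelkit.model import Consequence, FrequencyClass, NormalizedIndel, Provenance
from indelkit.normalize import DictReference, left_align
from indelkit.simulate import (
    SimulationConfig,
    UnsatisfiableTargetError,
    _draw_length,
    _stage_rng,
    generate_cohort,
    generate_gene_models,
    generate_reference,
    generate_validation_panel,
    simulate_dataset,
)


def small_config(**kwargs):
    defaults = dict(
        rng_seed=1, n_samples=30, n_familial=6, n_genes=8, variants_per_gene=6,
        validation_panel_sizes={},
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestReference:
    def test_deterministic_under_fixed_seed(self):
        cfg = small_config()
        ref_a, tracts_a = generate_reference(cfg)
        ref_b, tracts_b = generate_reference(cfg)
        assert ref_a == ref_b
        assert tracts_a == tracts_b

    def test_zero_density_means_no_tracts(self):
        _, tracts = generate_reference(small_config(repeat_density=0.0))
        assert tracts == []

    def test_tract_count_within_three_sigma_of_binomial(self):
        cfg = small_config(repeat_density=0.002, contig_length=200_000)
        _, tracts = generate_reference(cfg)
        n, p = 200_000, 0.002
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(len(tracts) - n * p) <= 3 * sigma


class TestGeneModels:
    def test_cds_is_clean_orf(self):
        cfg = small_config()
        ref, _ = generate_reference(cfg)
        ref, transcripts, _ = generate_gene_models(ref, cfg)
        acc = DictReference(ref)
        stops = {"TAA", "TAG", "TGA"}
        from indelkit.consequence import revcomp

        for tx in transcripts:
            seq = "".join(acc.fetch(tx.chrom, s, e) for s, e in tx.cds_intervals())
            if tx.strand == "-":
                seq = revcomp(seq)
            assert len(seq) % 3 == 0
            codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            assert codons[0] == "ATG"
            assert codons[-1] in stops
            assert not any(c in stops for c in codons[1:-1])

    def test_minus_strand_five_prime_utr_at_high_coordinates(self):
        cfg = small_config()
        ref, _ = generate_reference(cfg)
        _, transcripts, fmaps = generate_gene_models(ref, cfg)
        minus = [t for t in transcripts if t.strand == "-"]
        assert minus, "expected at least one minus-strand gene"
        tx = minus[0]
        fmap = fmaps[tx.transcript_id]
        utr5 = [p for p, c in fmap.items() if c is Consequence.FIVE_PRIME_UTR]
        utr3 = [p for p, c in fmap.items() if c is Consequence.THREE_PRIME_UTR]
        assert min(utr5) > max(utr3)

    def test_geometry_that_cannot_fit_raises(self):
        cfg = small_config(contig_length=500)
        ref, _ = generate_reference(cfg)
        with pytest.raises(UnsatisfiableTargetError, match="not fit|too short"):
            generate_gene_models(ref, cfg)


class TestLengthDistribution:
    def test_spectrum_matches_configuration(self):
        """Chi-squared goodness of fit of 10,000 drawn lengths against the
        truncated geometric the generator is configured with (alpha=0.01)."""
        cfg = small_config()
        rng = np.random.default_rng(123)
        draws = np.array([_draw_length(rng, cfg) for _ in range(10_000)])
        assert draws.min() >= 1 and draws.max() <= 15
        support = np.arange(1, 16)
        p = cfg.indel_len_p
        pmf = (1 - p) ** (support - 1) * p
        pmf /= pmf.sum()
        observed = np.bincount(draws, minlength=16)[1:16]
        # merge tail bins with tiny expectation for test validity
        expected = pmf * len(draws)
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        stat, pval = stats.chisquare(obs, exp)
        assert pval > 0.01

    def test_most_lengths_below_six(self):
        cfg = small_config()
        rng = np.random.default_rng(5)
        draws = [_draw_length(rng, cfg) for _ in range(2000)]
        assert np.mean(np.array(draws) < 6) > 0.8


class TestCohortGeneration:
    def test_determinism_of_truth_table(self):
        cfg = small_config()
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.reference == b.reference

    def test_all_variants_left_aligned_and_bounded(self, small_dataset):
        ds = small_dataset
        ref = DictReference(ds.reference)
        for _, row in ds.truth.iterrows():
            v = NormalizedIndel(row["chrom"], row["pos"], row["ref_seq"], row["alt_seq"])
            assert abs(v.length) <= ds.config.max_indel_len
            assert left_align(v, ref) == v

    def test_zero_jitter_gives_exact_allele_matches(self):
        cfg = small_config(db_jitter_min=0, db_jitter_max=0)
        ds = simulate_dataset(cfg)
        known = ds.truth[ds.truth["provenance"] == "KNOWN_DB"]
        assert len(known) > 0
        for _, row in known.iterrows():
            v = NormalizedIndel(row["chrom"], row["pos"], row["ref_seq"], row["alt_seq"])
            assert match_variant(v, ds.known_db).tier is MatchTier.EXACT_ALLELE

    def test_jitter_within_window_always_recovered(self, small_dataset):
        ds = small_dataset
        described = ds.truth[ds.truth["provenance"] != "NOVEL"]
        assert (described["db_offset"] <= 10).all()
        for _, row in described.iterrows():
            v = NormalizedIndel(row["chrom"], row["pos"], row["ref_seq"], row["alt_seq"])
            db = ds.known_db if row["provenance"] == "KNOWN_DB" else ds.newly_released_db
            tier = match_variant(v, db, window_bp=10).tier
            assert tier <= MatchTier.SAME_LENGTH_IN_WINDOW

    def test_private_proportion_within_three_sigma(self):
        mix = {
            Provenance.KNOWN_DB: {FrequencyClass.COMMON: 0.5, FrequencyClass.PRIVATE: 0.5},
            Provenance.NEWLY_RELEASED_ONLY: {FrequencyClass.COMMON: 0.5, FrequencyClass.PRIVATE: 0.5},
            Provenance.NOVEL: {FrequencyClass.COMMON: 0.5, FrequencyClass.PRIVATE: 0.5},
        }
        cfg = small_config(n_genes=25, variants_per_gene=8, freq_class_mix=mix)
        ds = simulate_dataset(cfg)
        n = len(ds.truth)
        frac = (ds.truth["freq_class"] == "PRIVATE").mean()
        sigma = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) <= 3 * sigma

    def test_rare_class_unsatisfiable_in_tiny_cohort(self):
        with pytest.raises(UnsatisfiableTargetError, match="RARE"):
            small_config(n_samples=20, n_familial=4)

    def test_truth_consequences_are_reachable_targets(self, small_dataset):
        weights = small_dataset.config.consequence_weights
        assert set(small_dataset.truth["consequence"]) <= {
            c.name for c, w in weights.items() if w > 0
        }


class TestValidationPanel:
    def _truth(self, n=300):
        cfg = small_config(n_genes=25, variants_per_gene=12)
        return simulate_dataset(cfg).truth, cfg

    def test_rate_one_validates_everything(self):
        truth, cfg = self._truth()
        cfg.validation_tp_rates = {fc: 1.0 for fc in FrequencyClass}
        cfg.validation_panel_sizes = {FrequencyClass.COMMON: 30}
        panel = generate_validation_panel(truth, cfg)
        assert (panel["carrier_confirmed"] == "yes").all()
        assert (panel["reference_confirmed"] == "yes").all()

    def test_panel_larger_than_pool_raises(self):
        truth, cfg = self._truth()
        cfg.validation_panel_sizes = {FrequencyClass.PRIVATE: 10**6}
        with pytest.raises(UnsatisfiableTargetError, match="panel"):
            generate_validation_panel(truth, cfg)

    def test_expected_validated_counts_near_table_rates(self):
        """At the default confirmation rates a large panel rejects
        homogeneity between common and private variants in most replicates;
        check the expected counts and one chi-squared rejection."""
        from indelkit.pipeline import validate_stats

        cfg = small_config(
            n_samples=40, n_familial=8, n_genes=50, variants_per_gene=12,
        )
        cfg.validation_panel_sizes = {
            FrequencyClass.COMMON: 82, FrequencyClass.PRIVATE: 78,
        }
        truth = simulate_dataset(cfg).truth
        validated = []
        rejections = 0
        for rep in range(5):
            cfg.rng_seed = 100 + rep
            panel = generate_validation_panel(truth, cfg)
            common = panel[panel["freq_class"] == "COMMON"]
            validated.append((common["carrier_confirmed"] == "yes").sum())
            vs = validate_stats(panel)
            if vs.chisq_common_vs_private and vs.chisq_common_vs_private[2] < 0.05:
                rejections += 1
        # E[validated common] = 82 * 66/82 = 66
        assert abs(np.mean(validated) - 66) < 3 * np.sqrt(82 * 0.8 * 0.2)
        assert rejections >= 3
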