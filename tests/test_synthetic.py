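"""The synthetic cohort generator: determinism, conservation laws,
calibration of footprints and affinities, and the statistical structure the
downstream stages rely on."""

import numpy as np
import pytest

from tsaquant.errors import ConfigurationError, CoordinateError, ValidationError
from tsaquant.orfs import OrfRecord
from tsaquant.synthetic import (
    CohortConfig,
    generate_cohort,
    simulate_expression,
    simulate_footprints,
    simulate_te_overlap,
    surrogate_affinity,
    surrogate_affinity_batch,
)


def _tiny(**kw):
    defaults = dict(n_patients=6, n_coding=8, n_lncrna=15, n_novel=5, seed=1)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestConfig:
    def test_invalid_probability_names_field(self):
        with pytest.raises(ConfigurationError, match="inframe_read_fraction"):
            CohortConfig(inframe_read_fraction=1.2)

    def test_invalid_count_names_field(self):
        with pytest.raises(ConfigurationError, match="n_patients"):
            CohortConfig(n_patients=0)

    def test_per_class_rate_validation(self):
        with pytest.raises(ConfigurationError, match="lncRNA"):
            CohortConfig(tumor_specific_rate={"lncRNA": 2.0})


class TestDeterminismAndConservation:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = _tiny(seed=11)
        generate_cohort(cfg, outdir=tmp_path / "a")
        generate_cohort(cfg, outdir=tmp_path / "b")
        files_a = sorted((tmp_path / "a").rglob("*"))
        files_b = sorted((tmp_path / "b").rglob("*"))
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            if fa.is_file():
                assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_sample_and_orf_conservation(self, small_bundle):
        b = small_bundle
        assert len(b.matrix.values.columns) == 2 * b.config.n_patients
        tids = {t.transcript_id for t in b.transcripts}
        assert all(o.transcript_id in tids for o in b.orf_catalog)
        # every ground-truth ORF belongs to an emitted transcript
        catalog_ids = {o.orf_id for o in b.orf_catalog}
        assert set(b.ground_truth.translated_orfs) <= catalog_ids

    def test_fasta_matches_spliced_lengths(self, small_bundle):
        for t in small_bundle.transcripts:
            assert len(t.sequence) == t.spliced_length

    def test_zero_rate_yields_no_events(self):
        bundle = generate_cohort(_tiny(tumor_specific_rate=0.0))
        assert bundle.ground_truth.tumor_specific == {}


def test_tumor_specific_event_count_is_binomial():
    """E[#lncRNA activation events] = n_lncrna * rate, checked across seeds."""
    n_lncrna, rate, n_seeds = 50, 0.2, 200
    counts = []
    for seed in range(n_seeds):
        cfg = CohortConfig(
            n_patients=12, n_coding=1, n_lncrna=n_lncrna, n_novel=1,
            tumor_specific_rate=rate, mean_depth=0.0, mutation_rate=0.0,
            seed=seed,
        )
        bundle = generate_cohort(cfg)
        counts.append(sum(
            1 for tid in bundle.ground_truth.tumor_specific
            if bundle.ground_truth.transcripts[tid]["biotype"] == "lncRNA"
        ))
    mean = np.mean(counts)
    se = np.sqrt(n_lncrna * rate * (1 - rate) / n_seeds)
    assert abs(mean - n_lncrna * rate) < 4 * se


class TestExpression:
    def test_class_median_ordering(self):
        cfg = CohortConfig(
            n_patients=4, n_coding=334, n_lncrna=333, n_novel=333,
            tumor_specific_rate=0.0, mean_depth=0.0, mutation_rate=0.0, seed=3,
        )
        bundle = generate_cohort(cfg)
        values = bundle.matrix.values
        tumor = values[[c for c in values.columns if c.endswith("_T")]]
        medians = {}
        for cls, prefix in (("coding", "COD"), ("lncRNA", "LNC"),
                            ("novel", "NOV")):
            rows = [t for t in values.index if t.startswith(prefix)]
            medians[cls] = float(tumor.loc[rows].median(axis=None))
        assert medians["coding"] > medians["lncRNA"] > medians["novel"]

    def test_events_respect_cutoffs_by_construction(self, small_bundle):
        b = small_bundle
        for tid, ev in b.ground_truth.tumor_specific.items():
            for p in ev["carriers"]:
                t_fpkm = b.matrix.values.loc[tid, f"{p}_T"]
                n_fpkm = b.matrix.values.loc[tid, f"{p}_N"]
                assert t_fpkm > 1.0 and n_fpkm < 0.1

    def test_testis_escape_recorded_in_panel(self, small_bundle):
        b = small_bundle
        for tid, ev in b.ground_truth.tumor_specific.items():
            if ev["testis_escape"]:
                assert b.panel_medians.loc[tid, "testis"] > 0.5

    def test_regenerated_expression_is_reproducible(self):
        cfg = _tiny(seed=9)
        b1 = generate_cohort(cfg)
        b2 = generate_cohort(cfg)
        assert b1.matrix.values.equals(b2.matrix.values)


class TestFootprints:
    def _orf(self, length=300):
        return OrfRecord("o1", "t1", 0, length, "ATG", "M" * (length // 3 - 1))

    def test_translated_inframe_fraction(self):
        cfg = CohortConfig(mean_depth=300)
        rng = np.random.default_rng(2)
        fracs = []
        for _ in range(40):
            p = simulate_footprints(self._orf(), True, cfg, rng)
            w = p.counts
            fracs.append(w[0::3].sum() / w.sum())
        assert abs(np.mean(fracs) - 0.58) < 0.05

    def test_null_inframe_fraction_is_one_third(self):
        cfg = CohortConfig(mean_depth=300, noise_fraction=1.0)
        rng = np.random.default_rng(2)
        fracs = []
        for _ in range(40):
            p = simulate_footprints(self._orf(), False, cfg, rng)
            w = p.counts
            fracs.append(w[0::3].sum() / w.sum())
        assert abs(np.mean(fracs) - 1 / 3) < 0.05

    def test_zero_depth_gives_empty_profile(self):
        cfg = CohortConfig(mean_depth=0.0)
        p = simulate_footprints(self._orf(), True, cfg,
                                np.random.default_rng(0))
        assert p.counts.sum() == 0

    def test_law_of_large_numbers_at_high_depth(self):
        cfg = CohortConfig(mean_depth=1e4)
        p = simulate_footprints(self._orf(3000), True, cfg,
                                np.random.default_rng(0))
        w = p.counts
        assert w[0::3].sum() / w.sum() == pytest.approx(0.58, abs=0.02)

    def test_out_of_bounds_orf(self):
        with pytest.raises(CoordinateError):
            simulate_footprints(self._orf(300), True, CohortConfig(),
                                np.random.default_rng(0), transcript_length=100)


class TestSurrogateAffinity:
    def test_deterministic(self):
        a = surrogate_affinity("ACDEFGHIK", "HLA-A*02:01")
        b = surrogate_affinity("ACDEFGHIK", "HLA-A*02:01")
        assert a == b

    def test_allele_dependence(self):
        assert (surrogate_affinity("ACDEFGHIK", "HLA-A*02:01")
                != surrogate_affinity("ACDEFGHIK", "HLA-B*07:02"))

    def test_calibration_of_strong_binder_rate(self, rng):
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        peps = ["".join(aa[rng.integers(0, 20, 9)]) for _ in range(10000)]
        ic50 = surrogate_affinity_batch(peps, "HLA-A*02:01", 0.09)
        assert abs(float((ic50 < 50).mean()) - 0.09) < 0.02

    def test_range(self, rng):
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        peps = ["".join(aa[rng.integers(0, 20, 9)]) for _ in range(500)]
        ic50 = surrogate_affinity_batch(peps, "HLA-C*07:01")
        assert (ic50 > 0).all() and (ic50 <= 50000).all()

    @pytest.mark.parametrize("peptide", ["ACDEFGHI", "ACDEFGHIKL", "ACDEFGHIZ"])
    def test_invalid_peptides_rejected(self, peptide):
        with pytest.raises(ValidationError):
            surrogate_affinity(peptide, "HLA-A*02:01")


def test_te_overlap_odds_boost():
    rng = np.random.default_rng(0)
    ts = np.zeros(4000, dtype=bool)
    ts[:2000] = True
    flags = simulate_te_overlap(ts, odds=4.0, background_prob=0.15, rng=rng)
    p_ts, p_bg = flags[:2000].mean(), flags[2000:].mean()
    expected_ts = 4 * 0.15 / (0.85 + 4 * 0.15)
    assert abs(p_bg - 0.15) < 0.03
    assert abs(p_ts - expected_ts) < 0.03


def test_mutations_are_private_by_default(small_bundle):
    seen = {}
    for patient, muts in small_bundle.ground_truth.mutations.items():
        for m in muts:
            key = (m["gene_id"], m["protein_pos"], m["alt_aa"])
            assert key not in seen, "recurrent mutation under recurrence 0"
            seen[key] = patient


def test_hla_draws_have_requested_size(small_bundle):
    for patient, alleles in small_bundle.hla.items():
        assert len(alleles) == small_bundle.config.n_alleles_per_patient
        assert len(set(alleles)) == len(alleles)
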