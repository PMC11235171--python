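"""9-mer enumeration, mutation windows, binder calling, self filter,
antigen-load arithmetic and shared/private accounting."""

import numpy as np
import pytest

from tsaquant.antigens import (
    AA_ALPHABET,
    VariantRecord,
    antigen_load,
    class_contributions,
    enumerate_9mers,
    filter_variants,
    mutation_windows,
    predict_binders,
    self_filter,
    shared_private_summary,
    strong_binder_sets,
)
from tsaquant.errors import ValidationError


def _random_protein(rng, length):
    return "".join(np.array(list(AA_ALPHABET))[rng.integers(0, 20, length)])


class TestEnumerate9mers:
    @pytest.mark.parametrize("length,n", [(9, 1), (8, 0), (20, 12)])
    def test_window_counts(self, length, n, rng):
        pep = _random_protein(rng, length)
        windows = enumerate_9mers(pep)
        assert len(windows) == n
        assert windows == [pep[i:i + 9] for i in range(max(len(pep) - 8, 0))]

    def test_x_windows_dropped(self):
        pep = "A" * 9 + "X" + "C" * 9
        windows = enumerate_9mers(pep)
        assert windows == ["A" * 9, "C" * 9]


class TestMutationWindows:
    def _variant(self, gene, pos, ref, alt, patient="p1"):
        return VariantRecord(patient, gene, pos, ref, alt, 100, 10)

    def test_internal_position_yields_nine_windows(self, rng):
        protein = _random_protein(rng, 100)
        pos = 50
        v = self._variant("g", pos, protein[pos - 1], "W"
                          if protein[pos - 1] != "W" else "Y")
        windows = mutation_windows(protein, v)
        assert len(windows) == 9
        assert all(v.alt_aa in w for w in windows)

    def test_terminal_position_yields_one_window(self, rng):
        protein = _random_protein(rng, 30)
        v = self._variant("g", 1, protein[0],
                          "W" if protein[0] != "W" else "Y")
        assert len(mutation_windows(protein, v)) == 1

    def test_matches_set_difference_oracle(self, rng):
        for _ in range(40):
            protein = _random_protein(rng, int(rng.integers(9, 60)))
            pos = int(rng.integers(1, len(protein) + 1))
            ref = protein[pos - 1]
            alt = [a for a in AA_ALPHABET if a != ref][int(rng.integers(0, 19))]
            v = self._variant("g", pos, ref, alt)
            got = set(mutation_windows(protein, v))
            mutant = protein[:pos - 1] + alt + protein[pos:]
            oracle = set(enumerate_9mers(mutant)) - set(enumerate_9mers(protein))
            assert got == oracle

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mutation_windows("A" * 20, self._variant("g", 5, "C", "W"))


class TestVariantFilter:
    @pytest.mark.parametrize(
        "depth,alt,cons,passes",
        [
            (10, 3, "missense", False),  # strict ">10"
            (11, 3, "missense", True),
            (11, 2, "missense", False),
            (100, 50, "synonymous", False),
        ],
    )
    def test_thresholds(self, depth, alt, cons, passes):
        r = VariantRecord("p", "g", 1, "A", "C", depth, alt, cons)
        assert (r in filter_variants([r])) is passes


class TestBinderCalling:
    @staticmethod
    def _predictor(table):
        return lambda pep, allele: table[(pep, allele)]

    def test_strict_strong_threshold(self):
        table = {("A" * 9, "hla1"): 49.9, ("C" * 9, "hla1"): 50.0}
        calls = predict_binders(
            [("A" * 9, "coding", "s1"), ("C" * 9, "coding", "s2")],
            {"p1": ["hla1"]}, self._predictor(table),
        )
        by_pep = {c.peptide: c.strong for c in calls}
        assert by_pep["A" * 9] is True
        assert by_pep["C" * 9] is False

    def test_empty_peptides(self):
        assert predict_binders([], {"p1": ["hla1"]}, lambda p, a: 1.0) == []

    def test_missing_affinity_reported(self):
        with pytest.raises(LookupError, match="AAAAAAAAA"):
            predict_binders([("A" * 9, "coding", "s")], {"p1": ["hla1"]},
                            self._predictor({}))

    def test_allele_order_and_duplicates_invariant(self):
        table = {("A" * 9, "h1"): 10.0, ("A" * 9, "h2"): 500.0}
        for alleles in (["h1", "h2"], ["h2", "h1"], ["h1", "h1", "h2"]):
            calls = predict_binders([("A" * 9, "lncRNA", "s")],
                                    {"p1": alleles}, self._predictor(table))
            sets = strong_binder_sets(calls)
            assert sets["p1"]["lncRNA"] == {"A" * 9}


class TestSelfFilter:
    def test_self_match_removed_unique_kept(self):
        strong = {"coding": {"AAAAAAAAA", "CCCCCCCCC"}, "lncRNA": {"DDDDDDDDD"}}
        filtered, removed = self_filter(strong, {"AAAAAAAAA"})
        assert filtered["coding"] == {"CCCCCCCCC"}
        assert filtered["lncRNA"] == {"DDDDDDDDD"}
        assert removed["coding"] == pytest.approx(0.5)
        assert removed["lncRNA"] == 0.0

    def test_class_dependent_overlap_ordering(self, rng):
        """With self-overlap simulated at 25% for coding and 2% for ncORF
        peptides, the removed fractions recover that ordering."""
        self_set = set()
        strong = {"coding": set(), "lncRNA": set()}
        for cls, overlap_rate, n in (("coding", 0.25, 400), ("lncRNA", 0.02, 400)):
            for _ in range(n):
                pep = _random_protein(rng, 9)
                strong[cls].add(pep)
                if rng.random() < overlap_rate:
                    self_set.add(pep)
        _, removed = self_filter(strong, self_set)
        assert removed["coding"] > 5 * removed["lncRNA"]


class TestAntigenLoad:
    def test_index_correction_arithmetic(self, rng):
        peptides = {_random_protein(rng, 9) for _ in range(150)}
        while len(peptides) < 100:
            peptides.add(_random_protein(rng, 9))
        lnc = set(list(peptides)[:100])
        load = antigen_load("p1", {"lncRNA": lnc}, {"lncRNA": lnc},
                            {"lncRNA": 0.116, "novel": 0.0053})
        assert load.n_corrected["lncRNA"] == pytest.approx(11.6)

    def test_zero_index(self):
        load = antigen_load("p1", {"lncRNA": {"A" * 9}}, {"lncRNA": {"A" * 9}},
                            {"lncRNA": 0.0, "novel": 0.0})
        assert load.n_corrected["lncRNA"] == 0.0

    def test_coding_and_mutation_unaffected_by_index(self):
        sets = {"coding": {"A" * 9, "C" * 9}, "mutation": {"D" * 9}}
        for idx in (0.0, 0.116, 1.0):
            load = antigen_load("p1", sets, sets,
                                {"lncRNA": idx, "novel": idx})
            assert load.n_corrected["coding"] == 2
            assert load.n_corrected["mutation"] == 1

    def test_selffiltered_never_exceeds_raw(self, rng):
        raw = {"coding": {_random_protein(rng, 9) for _ in range(50)}}
        filtered, _ = self_filter(raw, {next(iter(raw["coding"]))})
        load = antigen_load("p1", raw, filtered, {})
        for cls in load.n_strong_raw:
            assert load.n_strong_selffiltered[cls] <= load.n_strong_raw[cls]

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValidationError):
            antigen_load("p1", {}, {}, {"lncRNA": 1.5})


class TestSharedPrivate:
    def test_disjoint_peptides_all_private(self):
        cohort = {
            "p1": {"lncRNA": {"AAAAAAAAA"}},
            "p2": {"lncRNA": {"CCCCCCCCC"}},
        }
        s = shared_private_summary(cohort)
        assert s["lncRNA"]["shared"] == 0.0
        assert s["lncRNA"]["private"] == 1.0

    def test_universal_peptide_fully_shared(self):
        cohort = {f"p{i}": {"coding": {"AAAAAAAAA"}} for i in range(5)}
        assert shared_private_summary(cohort)["coding"]["shared"] == 1.0

    def test_conservation_and_oracle_on_random_sets(self, rng):
        pool = [_random_protein(rng, 9) for _ in range(60)]
        cohort = {}
        for p in range(8):
            cohort[f"p{p}"] = {
                "lncRNA": {pool[i] for i in rng.integers(0, 60, 15)},
                "mutation": {_random_protein(rng, 9) for _ in range(5)},
            }
        s = shared_private_summary(cohort)
        for cls in ("lncRNA", "mutation"):
            if s[cls]["n_unique"]:
                assert s[cls]["shared"] + s[cls]["private"] == pytest.approx(1.0)
        # brute-force intersection oracle for the shared fraction
        from collections import Counter

        counts = Counter()
        for sets in cohort.values():
            counts.update(sets["lncRNA"])
        oracle = sum(1 for v in counts.values() if v >= 2) / len(counts)
        assert s["lncRNA"]["shared"] == pytest.approx(oracle)


def test_class_contribution_recovery(rng):
    """Loads simulated in a known 49:39:7:5 ratio are recovered within 5
    points by the contribution accounting."""
    target = {"coding": 0.49, "lncRNA": 0.39, "novel": 0.07, "mutation": 0.05}
    loads = []
    for p in range(20):
        sets = {}
        scale = rng.uniform(0.8, 1.2)
        for cls, frac in target.items():
            n = max(int(rng.poisson(200 * frac * scale)), 0)
            sets[cls] = {_random_protein(rng, 9) for _ in range(n)}
        loads.append(antigen_load(f"p{p}", sets, sets,
                                  {"lncRNA": 1.0, "novel": 1.0}))
    contrib = class_contributions(loads)
    for cls, frac in target.items():
        assert abs(contrib[cls] - frac) < 0.05
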