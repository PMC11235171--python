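"""TE overlap arithmetic, Fisher enrichment, candidate shortlisting and
co-expression structure."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from tsaquant.cohort import (
    TEAnnotation,
    candidate_correlations,
    herv_enrichment,
    select_candidates,
    te_overlap,
)
from tsaquant.errors import ValidationError
from tsaquant.transcriptome import CohortCutoffs, ExpressionMatrix, TranscriptRecord


def _matrix(values: pd.DataFrame) -> ExpressionMatrix:
    meta = pd.DataFrame(
        {"patient_id": [c[:-2] for c in values.columns],
         "tissue": ["tumor" if c.endswith("_T") else "normal"
                    for c in values.columns],
         "cohort_id": "x"},
        index=values.columns,
    )
    return ExpressionMatrix(values, meta)


class TestTEOverlap:
    def _lnc(self, exons, strand="+"):
        return TranscriptRecord("l1", "lncRNA", "chr1", strand, exons)

    def test_overlapping_copies_counted_once(self):
        t = self._lnc([(0, 500)])
        te = TEAnnotation([
            ("chr1", 100, 200, "+", "LTR/HERV"),
            ("chr1", 100, 200, "+", "LTR/HERV"),
            ("chr1", 150, 250, "+", "LTR/HERV"),
        ])
        ov = te_overlap(t, te)["LTR/HERV"]
        assert ov["bp"] == 150
        assert ov["fraction"] == pytest.approx(150 / 500)

    def test_opposite_strand_ignored(self):
        t = self._lnc([(0, 500)])
        te = TEAnnotation([("chr1", 100, 200, "-", "LTR/HERV")])
        assert te_overlap(t, te)["LTR/HERV"]["bp"] == 0

    def test_unstranded_transcript_rejected(self):
        t = TranscriptRecord("l1", "lncRNA", "chr1", "unknown", [(0, 500)])
        with pytest.raises(ValidationError):
            te_overlap(t, TEAnnotation([]))

    def test_unknown_strand_te_rejected(self):
        with pytest.raises(ValidationError):
            TEAnnotation([("chr1", 0, 10, ".", "LINE")])

    def test_matches_per_base_oracle(self, rng):
        for _ in range(25):
            n_ex = int(rng.integers(1, 4))
            exons, pos = [], int(rng.integers(0, 100))
            for _ in range(n_ex):
                end = pos + int(rng.integers(50, 300))
                exons.append((pos, end))
                pos = end + int(rng.integers(10, 100))
            t = self._lnc(exons)
            intervals = []
            for _ in range(int(rng.integers(0, 8))):
                s = int(rng.integers(0, 1200))
                intervals.append(
                    ("chr1", s, s + int(rng.integers(20, 200)),
                     "+" if rng.random() < 0.7 else "-",
                     ["LTR/HERV", "LINE"][int(rng.integers(0, 2))])
                )
            te = TEAnnotation(intervals)
            got = te_overlap(t, te)
            for cls in ("LTR/HERV", "LINE"):
                covered = set()
                for chrom, s, e, strand, c in intervals:
                    if c == cls and strand == "+":
                        covered.update(range(s, e))
                exonic = set()
                for s, e in exons:
                    exonic.update(range(s, e))
                assert got[cls]["bp"] == len(covered & exonic)

    def test_fraction_monotone_in_te_additions(self):
        t = self._lnc([(0, 400)])
        intervals = []
        last = -1.0
        for s in (0, 100, 200, 300):
            intervals.append(("chr1", s, s + 80, "+", "LTR/HERV"))
            frac = te_overlap(t, TEAnnotation(intervals))["LTR/HERV"]["fraction"]
            assert frac >= last
            last = frac
        assert 0 <= last <= 1


def fisher_two_sided_oracle(a, b, c, d) -> float:
    """Exact two-sided Fisher p by hypergeometric enumeration in rational
    arithmetic (tables as or less probable than the observed one)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(k):
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k),
                        math.comb(n, c1))

    p_obs = pmf(a)
    # the conventional relative tie tolerance for float comparability
    cutoff = p_obs * Fraction(1 + 10**-7).limit_denominator(10**12)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        if pmf(k) <= cutoff:
            total += pmf(k)
    return float(total)


class TestHervEnrichment:
    def test_null_table_near_one(self):
        expressed = {f"t{i}" for i in range(40)}
        specific = {f"t{i}" for i in range(10)}
        overlaps = {f"t{i}": i % 2 == 0 for i in range(40)}
        out = herv_enrichment(expressed, specific, overlaps)
        assert out["p_value"] > 0.5

    def test_agrees_with_exact_enumeration(self):
        expressed = {f"t{i}" for i in range(62)}
        specific = {f"t{i}" for i in range(12)}
        overlaps = {f"t{i}": (i < 8 or 12 <= i < 22) for i in range(62)}
        out = herv_enrichment(expressed, specific, overlaps)
        assert out["table"] == [[8, 4], [10, 40]]
        assert out["p_value"] == pytest.approx(
            fisher_two_sided_oracle(8, 4, 10, 40), abs=1e-10
        )

    def test_agreement_on_random_tables(self, rng):
        from scipy.stats import fisher_exact

        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 13, 4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d),
                                      abs=1e-10)

    def test_degenerate_margin_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = herv_enrichment({"a"}, set(), {"a": True})
        assert out["p_value"] == 1.0

    def test_subset_precondition(self):
        with pytest.raises(ValidationError):
            herv_enrichment({"a"}, {"b"}, {})


class TestSelectCandidates:
    def _inputs(self, n_patients, rows):
        sharing = pd.DataFrame(
            {"n_patients_specific": {tid: n for tid, (n, _, _) in rows.items()}}
        ).rename_axis("transcript_id")
        sharing["fraction_patients"] = sharing["n_patients_specific"] / n_patients
        cols = {}
        for s in range(n_patients):
            cols[f"p{s}_T"] = {
                tid: (mx if s == 0 else 0.0) for tid, (_, mx, _) in rows.items()
            }
            cols[f"p{s}_N"] = {
                tid: (2.0 if s < prev else 0.0)
                for tid, (_, _, prev) in rows.items()
            }
        matrix = _matrix(pd.DataFrame(cols))
        return sharing, matrix

    def test_patient_threshold_ceiling(self):
        # 10% of 117 patients -> 12; of 12 patients -> 2 (ceil of 1.2)
        assert math.ceil(0.10 * 117) == 12
        rows = {"keep": (2, 10.0, 0), "drop": (1, 10.0, 0)}
        sharing, matrix = self._inputs(12, rows)
        got = select_candidates(sharing, matrix, CohortCutoffs(),
                                {"keep": "lncRNA", "drop": "lncRNA"})
        assert [c.transcript_id for c in got] == ["keep"]

    def test_three_way_filter_matches_brute_force(self, rng):
        n_patients = 10
        rows = {}
        for i in range(20):
            rows[f"t{i}"] = (
                int(rng.integers(0, 6)),            # patients specific
                float(rng.uniform(0, 12)),          # max tumor fpkm
                int(rng.integers(0, 3)),            # normals expressing it
            )
        sharing, matrix = self._inputs(n_patients, rows)
        got = {c.transcript_id
               for c in select_candidates(sharing, matrix, CohortCutoffs(),
                                          {t: "lncRNA" for t in rows})}
        oracle = {
            tid for tid, (n, mx, prev) in rows.items()
            if n >= math.ceil(0.10 * n_patients)
            and mx > 5.0
            and prev / n_patients < 0.01
        }
        assert got == oracle

    def test_row_order_invariance(self, rng):
        rows = {f"t{i}": (int(rng.integers(0, 6)), float(rng.uniform(0, 12)), 0)
                for i in range(15)}
        sharing, matrix = self._inputs(10, rows)
        biotypes = {t: "lncRNA" for t in rows}
        a = select_candidates(sharing, matrix, CohortCutoffs(), biotypes)
        b = select_candidates(sharing.iloc[::-1], matrix, CohortCutoffs(),
                              biotypes)
        assert [c.transcript_id for c in a] == [c.transcript_id for c in b]


class TestCorrelations:
    def _candidates(self, ids, biotype="lncRNA"):
        from tsaquant.cohort import CandidateTranscript

        return [CandidateTranscript(t, biotype, 3, 0.3, 10.0, 0.0)
                for t in ids]

    def test_self_correlation_is_one(self):
        values = pd.DataFrame(
            {"p1_T": [1, 2], "p2_T": [3, 1], "p3_T": [5, 9],
             "p1_N": [0, 0], "p2_N": [0, 0], "p3_N": [0, 0]},
            index=["a", "b"], dtype=float,
        )
        corr, _ = candidate_correlations(self._candidates(["a", "b"]),
                                         _matrix(values))
        assert corr.loc["a", "a"] == pytest.approx(1.0)

    def test_coactivated_module_beats_independent_candidates(self, rng):
        n = 12
        cols = [f"p{i}_T" for i in range(n)] + [f"p{i}_N" for i in range(n)]
        active = rng.random(n) < 0.5
        data = {}
        for i in range(4):  # co-activated coding module
            data[f"cod{i}"] = np.where(active, rng.uniform(5, 10, n), 0.0)
        for i in range(4):  # independently activated lncRNAs
            mask = rng.random(n) < 0.5
            data[f"lnc{i}"] = np.where(mask, rng.uniform(5, 10, n), 0.0)
        values = pd.DataFrame(data, index=cols[:n]).T
        values = pd.concat(
            [values, pd.DataFrame(0.0, index=values.index, columns=cols[n:])],
            axis=1,
        )
        cands = (self._candidates([f"cod{i}" for i in range(4)], "coding")
                 + self._candidates([f"lnc{i}" for i in range(4)], "lncRNA"))
        _, means = candidate_correlations(cands, _matrix(values))
        assert means["coding"] > means["lncRNA"]

    def test_zero_variance_reported_missing(self):
        values = pd.DataFrame(
            {"p1_T": [1.0, 2.0], "p2_T": [1.0, 4.0],
             "p1_N": [0.0, 0.0], "p2_N": [0.0, 0.0]},
            index=["flat", "ok"],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            corr, _ = candidate_correlations(
                self._candidates(["flat", "ok"]), _matrix(values)
            )
        assert np.isnan(corr.loc["flat", "ok"])
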