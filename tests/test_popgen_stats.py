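"""Heterozygosity, private alleles, Weir-Cockerham F_ST and Wright bins."""

import numpy as np
import pytest

from popsplit import studydata
from popsplit.popgen_stats import (
    pairwise_fst,
    private_alleles,
    summarize_differentiation,
    variant_heterozygosity,
    wc_components_per_site,
)

from conftest import make_matrix, make_popmap


def wc_theta_reference(counts_a, counts_b):
    """Independent textbook evaluation of Weir & Cockerham's theta for one
    biallelic locus and two populations, from per-population diploid dosage
    lists. Written directly from the published component formulas."""
    pops = [np.asarray(counts_a), np.asarray(counts_b)]
    r = 2
    n = [len(p) for p in pops]
    p_hat = [np.sum(p) / (2 * len(p)) for p in pops]
    h_hat = [np.mean(p == 1) for p in pops]
    nbar = sum(n) / r
    nc = (sum(n) - sum(ni**2 for ni in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p_hat)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p_hat)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h_hat)) / (r * nbar)
    a = (
        nbar
        / nc
        * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    )
    b = (
        nbar
        / (nbar - 1)
        * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    )
    c = hbar / 2
    return a / (a + b + c)


class TestHeterozygosity:
    def test_all_heterozygous_group(self):
        m = make_matrix([[1], [1], [1], [1], [0]])
        pm = make_popmap({f"ind{i}": ("A" if i < 4 else "B") for i in range(5)})
        stats = {s.population: s for s in variant_heterozygosity(m, pm)}
        assert stats["A"].het_variant == 1.0

    def test_homozygous_alternatives_score_zero(self):
        m = make_matrix([[0], [2], [1]])
        pm = make_popmap({"ind0": "A", "ind1": "A", "ind2": "B"})
        stats = {s.population: s for s in variant_heterozygosity(m, pm)}
        assert stats["A"].het_variant == 0.0
        assert stats["B"].het_variant == 1.0

    def test_single_individual_group_flagged(self):
        m = make_matrix([[1], [0]])
        pm = make_popmap({"ind0": "A", "ind1": "ZJ"})
        stats = {s.population: s for s in variant_heterozygosity(m, pm)}
        assert stats["ZJ"].flagged_small

    def test_allele_label_swap_invariance(self, random_matrix):
        pm = make_popmap(
            {f"ind{i}": ("A" if i < 5 else "B") for i in range(10)}
        )
        swapped = make_matrix(
            np.where(random_matrix.calls >= 0, 2 - random_matrix.calls, -1)
        )
        a = [s.het_variant for s in variant_heterozygosity(random_matrix, pm)]
        b = [s.het_variant for s in variant_heterozygosity(swapped, pm)]
        np.testing.assert_allclose(a, b)

    def test_survey_mean_heterozygosity(self):
        vals = list(studydata.LOCALITY_HETEROZYGOSITY.values())
        assert len(vals) == 17
        assert round(float(np.mean(vals)), 4) == 0.2321


class TestPrivateAlleles:
    def test_private_and_shared(self):
        # site 0: alt only in B; site 1: alt in both groups
        m = make_matrix([[0, 1], [0, 1], [1, 0], [1, 1]])
        pm = make_popmap({"ind0": "A", "ind1": "A", "ind2": "B", "ind3": "B"})
        counts = private_alleles(m, pm)
        # site0 alt private to B; site1 alt shared; all refs shared
        assert counts == {"A": 0, "B": 1}

    def test_single_group_rejected(self):
        m = make_matrix([[1], [1]])
        pm = make_popmap({"ind0": "A", "ind1": "A"})
        with pytest.raises(ValueError):
            private_alleles(m, pm)

    def test_brute_force_oracle(self, rng):
        calls = rng.integers(0, 3, size=(12, 20)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.15] = -1
        m = make_matrix(calls)
        groups = {f"ind{i}": ["A", "B", "C"][i % 3] for i in range(12)}
        pm = make_popmap(groups)
        counts = private_alleles(m, pm)
        expected = {"A": 0, "B": 0, "C": 0}
        for j in range(20):
            for allele in ("ref", "alt"):
                present = set()
                for i in range(12):
                    c = calls[i, j]
                    if c == -1:
                        continue
                    if (allele == "ref" and c < 2) or (allele == "alt" and c > 0):
                        present.add(groups[f"ind{i}"])
                if len(present) == 1:
                    expected[present.pop()] += 1
        assert counts == expected


class TestPairwiseFst:
    def test_hand_computed_theta(self):
        # two groups of 5 diploids; alt counts 2 vs 8 at one locus
        a_dosage = [1, 1, 0, 0, 0]
        b_dosage = [2, 2, 2, 1, 1]
        a, b, c = wc_components_per_site(
            [np.array([a_dosage]).T.T.reshape(5, 1), np.array(b_dosage).reshape(5, 1)]
        )
        theta = a[0] / (a[0] + b[0] + c[0])
        ref = wc_theta_reference(a_dosage, b_dosage)
        assert theta == pytest.approx(ref, abs=1e-12)

    def test_identical_frequencies_near_zero(self, rng):
        # both groups drawn from identical allele frequencies at 200 loci
        p = rng.uniform(0.2, 0.8, size=200)
        calls = rng.binomial(2, p, size=(40, 200)).astype(np.int8)
        m = make_matrix(calls)
        pm = make_popmap({f"ind{i}": ("A" if i < 20 else "B") for i in range(40)})
        fst = pairwise_fst(m, pm, n_bootstrap=100, seed=1)
        assert abs(fst.values[0, 1]) < 0.02
        assert fst.p_values[0, 1] >= 0.05  # gated: no differentiation

    def test_fixed_differences_give_one(self):
        calls = np.vstack([np.zeros((5, 30)), np.full((5, 30), 2)]).astype(np.int8)
        m = make_matrix(calls)
        pm = make_popmap({f"ind{i}": ("A" if i < 5 else "B") for i in range(10)})
        fst = pairwise_fst(m, pm, n_bootstrap=50, seed=0)
        assert fst.values[0, 1] == pytest.approx(1.0)
        assert fst.p_values[0, 1] < 0.05

    def test_symmetry_and_small_groups_excluded(self, rng):
        calls = rng.integers(0, 3, size=(11, 50)).astype(np.int8)
        m = make_matrix(calls)
        assign = {f"ind{i}": ("A" if i < 5 else "B") for i in range(10)}
        assign["ind10"] = "ZJ"  # single fish: excluded
        pm = make_popmap(assign)
        fst = pairwise_fst(m, pm, n_bootstrap=50, seed=3)
        assert fst.excluded == ["ZJ"]
        assert fst.values[0, 1] == fst.values[1, 0]
        assert np.all(np.diag(fst.values) == 0)

    def test_split_population_is_undifferentiated(self, rng):
        p = rng.uniform(0.1, 0.9, size=300)
        calls = rng.binomial(2, p, size=(30, 300)).astype(np.int8)
        m = make_matrix(calls)
        half = {f"ind{i}": ("A" if i % 2 else "B") for i in range(30)}
        fst = pairwise_fst(m, make_popmap(half), n_bootstrap=100, seed=5)
        assert abs(fst.values[0, 1]) < 0.02

    def test_bad_bootstrap_config(self, random_matrix):
        pm = make_popmap({f"ind{i}": ("A" if i < 5 else "B") for i in range(10)})
        with pytest.raises(ValueError):
            pairwise_fst(random_matrix, pm, n_bootstrap=0)


class TestWrightBins:
    def test_all_minor(self):
        import pandas as pd

        frame = pd.DataFrame(
            0.10 * (1 - np.eye(3)), index=list("abc"), columns=list("abc")
        )
        out = summarize_differentiation(frame)
        assert out["fractions_pairs"]["minor"] == 1.0

    def test_one_pair_per_bin(self):
        import pandas as pd

        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 0.01
        vals[0, 2] = vals[2, 0] = 0.10
        vals[1, 2] = vals[2, 1] = 0.20
        out = summarize_differentiation(
            pd.DataFrame(vals, index=list("abc"), columns=list("abc"))
        )
        f = out["fractions_pairs"]
        assert f["negligible"] == f["minor"] == f["moderate"] == pytest.approx(1 / 3)

    def test_survey_table_extreme_pairs_and_bin_bookkeeping(self):
        import pandas as pd

        codes = sorted({c for pair in studydata.PAIRWISE_FST for c in pair})
        assert len(codes) == 17
        vals = np.zeros((17, 17))
        for (i, a) in enumerate(codes):
            for j, b in enumerate(codes):
                if i != j:
                    vals[i, j] = studydata.PAIRWISE_FST[frozenset((a, b))]
        out = summarize_differentiation(pd.DataFrame(vals, index=codes, columns=codes))
        assert out["max_pair"] in [("DD", "XS"), ("XS", "DD")]
        assert out["max_value"] == pytest.approx(0.1893)
        assert out["min_pair"] in [("BH", "GX"), ("GX", "BH")]
        assert out["min_value"] == pytest.approx(0.0176)
        assert out["n_pairs"] == 136
        assert sum(out["counts"].values()) == 136
        assert sum(out["fractions_pairs"].values()) == pytest.approx(1.0)
        assert sum(out["fractions_with_diagonal"].values()) == pytest.approx(1.0)
        # nothing exceeds Wright's "pronounced" threshold in this survey
        assert out["counts"]["pronounced"] == 0
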