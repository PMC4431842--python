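import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import diagsnp as dg

from conftest import make_matrix, make_markers


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def test_allele_frequency_counting():
    # {AA, AB} with alt=B → p = 1/4; {MISSING, BB} → p = 1 from 2 genes
    G = make_matrix([[0, dg.MISSING, dg.MISSING], [1, 2, dg.MISSING]])
    fa = dg.allele_frequencies(G, ["acc0", "acc1"])
    assert fa.p[0] == 0.25
    assert fa.p[1] == 1.0 and fa.n_genes[1] == 2
    assert fa.undefined[2] and np.isnan(fa.p[2])


def test_empty_group_rejected():
    G = make_matrix([[0]])
    with pytest.raises(dg.ConfigurationError):
        dg.allele_frequencies(G, [])


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------


def test_heterozygosity_values():
    # {AA, AB, AB, BB}: Ho = 0.5, p = 0.5, n_genes = 8
    G = make_matrix([[0], [1], [1], [2]])
    accs = list(G.accession_ids)
    fa = dg.allele_frequencies(G, accs)
    stats = dg.heterozygosity(G, accs, fa)
    row = stats.per_marker.iloc[0]
    assert row["ho"] == 0.5
    assert row["he_nei"] == 0.5
    np.testing.assert_allclose(row["he_unbiased"], 8 / 7 * 0.5)
    np.testing.assert_allclose(row["fw"], 1 - 0.5 / (8 / 7 * 0.5))


def test_unbiased_correction_two_diploids():
    """Two diploids at p = 0.5 → He_unbiased = (4/3)·0.5."""
    G = make_matrix([[1], [1]])
    fa = dg.allele_frequencies(G, G.accession_ids)
    stats = dg.heterozygosity(G, G.accession_ids, fa)
    np.testing.assert_allclose(stats.per_marker["he_unbiased"].iloc[0], 4 / 3 * 0.5)


def test_fw_weir_cockerham_alternative():
    """The single-population variance-components f matches a hand
    evaluation of 1 − c/(b + c) for {AA, AB, AB, BB}."""
    G = make_matrix([[0], [1], [1], [2]])
    fa = dg.allele_frequencies(G, G.accession_ids)
    stats = dg.heterozygosity(G, G.accession_ids, fa, fw_estimator="wc")
    b = (4 / 3) * (0.25 - (7 / 16) * 0.5)
    c = 0.25
    np.testing.assert_allclose(stats.per_marker["fw"].iloc[0], 1 - c / (b + c))
    with pytest.raises(dg.ConfigurationError):
        dg.heterozygosity(G, G.accession_ids, fa, fw_estimator="bogus")


def test_he_maximised_at_half():
    """He_nei peaks at 0.5 for p = 0.5 and decreases with |p − 0.5|."""
    p = np.linspace(0, 1, 21)
    he = dg.he_biallelic(p)
    assert he.max() == 0.5 and p[he.argmax()] == 0.5
    left = he[: 10 + 1]
    assert np.all(np.diff(left) > 0)  # monotone towards the peak
    np.testing.assert_allclose(he, he[::-1])  # symmetric


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST
# ---------------------------------------------------------------------------


def _wc_brute(groups):
    """Independent spreadsheet-style evaluation of the variance components
    for one biallelic marker; groups = list of dosage lists (no missing)."""
    r = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    p = np.array([sum(g) / (2 * len(g)) for g in groups])
    h = np.array([sum(1 for d in g if d == 1) / len(g) for g in groups])
    nbar = n.mean()
    nsum = n.sum()
    nc = (nsum - (n**2).sum() / nsum) / (r - 1)
    pbar = (n * p).sum() / nsum
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / nsum
    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def test_wc_fst_complete_differentiation():
    G = make_matrix([[2], [2], [0], [0]])
    per, multi = dg.wc_fst(G, {"A": ["acc0", "acc1"], "B": ["acc2", "acc3"]})
    np.testing.assert_allclose(per["theta"].iloc[0], 1.0)
    np.testing.assert_allclose(multi, 1.0)


def test_wc_fst_identical_groups_not_positive():
    G = make_matrix([[0], [1], [2], [0], [1], [2]])
    per, _ = dg.wc_fst(G, {"A": ["acc0", "acc1", "acc2"], "B": ["acc3", "acc4", "acc5"]})
    assert per["theta"].iloc[0] <= 0


def test_wc_fst_single_group_rejected():
    G = make_matrix([[0], [1]])
    with pytest.raises(dg.ConfigurationError):
        dg.wc_fst(G, {"A": ["acc0", "acc1"]})


def test_wc_fst_matches_brute_force_exhaustively():
    """Every 2-group instance with 2 diploids per group (all 3⁴ dosage
    combinations) and a sample of 3/4-diploid instances agree with the
    independent variance-components oracle."""
    combos = list(itertools.product([0, 1, 2], repeat=4))
    for g1a, g1b, g2a, g2b in combos:
        groups = [[g1a, g1b], [g2a, g2b]]
        G = make_matrix([[g1a], [g1b], [g2a], [g2b]])
        per, _ = dg.wc_fst(G, {"A": ["acc0", "acc1"], "B": ["acc2", "acc3"]})
        a, b, c = _wc_brute(groups)
        if abs(a + b + c) > 1e-12:
            np.testing.assert_allclose(
                per["theta"].iloc[0], a / (a + b + c), atol=1e-12
            )
        else:
            assert np.isnan(per["theta"].iloc[0])
    # a 3-group toy table of 6 diploids
    rows = [[0], [1], [2], [2], [1], [0]]
    G = make_matrix(rows)
    groups3 = {"A": ["acc0", "acc1"], "B": ["acc2", "acc3"], "C": ["acc4", "acc5"]}
    per, _ = dg.wc_fst(G, groups3)
    a, b, c = _wc_brute([[0, 1], [2, 2], [1, 0]])
    np.testing.assert_allclose(per["theta"].iloc[0], a / (a + b + c), atol=1e-12)


# ---------------------------------------------------------------------------
# SNP density
# ---------------------------------------------------------------------------


def _density_tables(n_snps_per_frag, lengths, chroms):
    frows, mrows, mid = [], [], 0
    for i, (n, L, c) in enumerate(zip(n_snps_per_frag, lengths, chroms)):
        fid = f"f{i}"
        start = i * 100_000
        frows.append({"fragment_id": fid, "chrom": c, "start": start, "end": start + L})
        for k in range(n):
            mrows.append(
                {"marker_id": f"s{mid}", "chrom": c, "pos": start + k + 1,
                 "ref": "A", "alt": "C", "fragment_id": fid}
            )
            mid += 1
    return dg.MarkerTable(pd.DataFrame(mrows)), dg.FragmentTable(pd.DataFrame(frows))


def test_snp_density_per_fragment_and_pooled_chromosome():
    markers, frags = _density_tables([10, 0], [500, 500], ["chr1", "chr1"])
    per_frag, per_chrom, total = dg.snp_density(markers, frags)
    assert per_frag.set_index("fragment_id")["snp_per_kb"]["f0"] == 20.0
    # pooled before division: (10 SNPs)/(1000 bp) → 10/kb, not mean(20, 0)
    assert per_chrom["snp_per_kb"].iloc[0] == 10.0
    assert total == 10.0


def test_snp_density_published_total():
    """1,053 SNPs over 28,507 bp → 36.94 SNP/kb."""
    markers, frags = _density_tables([1053], [28507], ["chr1"])
    _, _, total = dg.snp_density(markers, frags)
    assert round(total, 2) == 36.94


# ---------------------------------------------------------------------------
# simple-matching dissimilarity
# ---------------------------------------------------------------------------


def test_simple_matching_examples():
    # identical → 0; AA vs BB → 1; {(AA,AB),(BB,BB)} → 0.25
    G = make_matrix([[0, 2], [1, 2], [0, 2]])
    D = dg.simple_matching_dissimilarity(G)
    assert D.d[0, 2] == 0.0
    np.testing.assert_allclose(D.d[0, 1], 1 - (0.5 + 1) / 2)
    G2 = make_matrix([[0], [2]])
    assert dg.simple_matching_dissimilarity(G2).d[0, 1] == 1.0


def test_dissimilarity_excludes_missing_and_flags_empty():
    G = make_matrix([[0, dg.MISSING], [dg.MISSING, 2]])
    D = dg.simple_matching_dissimilarity(G)
    assert np.isnan(D.d[0, 1]) and D.n_loci[0, 1] == 0


@given(
    st.integers(min_value=0, max_value=2**31 - 1),
    st.integers(min_value=2, max_value=6),
    st.integers(min_value=1, max_value=8),
)
def test_dissimilarity_symmetric_zero_diagonal(seed, n_acc, n_mark):
    rng = np.random.default_rng(seed)
    d = rng.integers(-1, 3, size=(n_acc, n_mark))
    D = dg.simple_matching_dissimilarity(make_matrix(d))
    assert np.allclose(np.diag(D.d), 0)
    m = D.d.copy()
    np.testing.assert_allclose(m, m.T, equal_nan=True)
    finite = np.isfinite(m)
    assert ((m[finite] >= -1e-12) & (m[finite] <= 1 + 1e-12)).all()


# ---------------------------------------------------------------------------
# group report
# ---------------------------------------------------------------------------


def test_group_report_fields():
    G = make_matrix(
        [
            [0, 1, dg.MISSING],
            [0, 1, 2],
            [0, 1, 2],
        ]
    )
    rep = dg.group_report(G, {"g": list(G.accession_ids)}).iloc[0]
    np.testing.assert_allclose(rep["MD"], 100 / 9)
    # MD + non-missing fraction = 100%
    non_missing = 100.0 * (1 - (G.dosage == dg.MISSING).mean())
    np.testing.assert_allclose(rep["MD"] + non_missing, 100.0)
    assert rep["PL"] == 1  # only m1 shows both alleles within the group
    assert rep["NSG"] == 1  # missing treated as wildcard collapses all three


def test_group_report_monomorphic_and_distinct():
    G = make_matrix([[0, 0], [0, 0], [2, 0]])
    rep = dg.group_report(G, {"g": list(G.accession_ids)}).iloc[0]
    assert rep["MD"] == 0.0
    assert rep["NSG"] == 2
    rep2 = dg.group_report(G.subset(["acc0", "acc1"]), {"g": ["acc0", "acc1"]}).iloc[0]
    assert rep2["PL"] == 0 and rep2["NSG"] == 1


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def test_concordance_rates():
    d = np.zeros((2, 5), dtype=int)
    G1 = make_matrix(d)
    d2 = d.copy()
    d2[0, 0] = 1  # 1 differing call of 10 compared
    G2 = make_matrix(d2)
    _, overall = dg.concordance(G1, G2)
    assert overall == 0.1
    _, same = dg.concordance(G1, G1)
    assert same == 0.0


def test_concordance_all_missing_is_undefined():
    G1 = make_matrix([[0, 1]])
    G2 = make_matrix([[dg.MISSING, dg.MISSING]])
    per, overall = dg.concordance(G1, G2)
    assert np.isnan(overall)
    assert per["discrepancy_rate"].isna().all()


def test_concordance_no_overlap_rejected():
    G1 = make_matrix([[0]], ["a"], ["m1"])
    G2 = make_matrix([[0]], ["b"], ["m1"])
    with pytest.raises(dg.ConfigurationError):
        dg.concordance(G1, G2)
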