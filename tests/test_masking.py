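import numpy as np
import pandas as pd
import pytest

import diagsnp as dg

from conftest import make_matrix


def one_fragment(n_markers=5, chrom="chr1"):
    rows = [
        {"marker_id": f"m{j}", "chrom": chrom, "pos": 10 + j, "ref": "A", "alt": "C",
         "fragment_id": "frag1"}
        for j in range(n_markers)
    ]
    markers = dg.MarkerTable(pd.DataFrame(rows))
    frags = dg.FragmentTable(
        pd.DataFrame([{"fragment_id": "frag1", "chrom": chrom, "start": 0, "end": 100}])
    )
    return markers, frags


# ---------------------------------------------------------------------------
# fragment heterozygosity
# ---------------------------------------------------------------------------


def test_fragment_heterozygosity_values():
    markers, frags = one_fragment(4)
    G = make_matrix([[1, 1, 0, 2], [0, 0, 2, 2], [1, dg.MISSING, dg.MISSING, 0]])
    ho = dg.fragment_heterozygosity(G, markers, frags)
    assert ho.loc["acc0", "frag1"] == 0.5  # het at 2 of 4
    assert ho.loc["acc1", "frag1"] == 0.0  # fully homozygous
    assert ho.loc["acc2", "frag1"] == 0.5  # missing excluded from denominator


def test_fragment_with_no_calls_is_undefined():
    markers, frags = one_fragment(2)
    G = make_matrix([[dg.MISSING, dg.MISSING]])
    ho = dg.fragment_heterozygosity(G, markers, frags)
    assert np.isnan(ho.loc["acc0", "frag1"])


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


def test_pcoa_collinear_points_exact():
    """d(1,2) = d(2,3) = 1, d(1,3) = 2 embeds exactly on one axis at
    (−1, 0, 1) up to sign."""
    D = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
    res = dg.pcoa(D, n_axes=3)
    assert res.coordinates.shape[1] == 1  # single positive eigenvalue
    coords = res.coordinates["axis1"].to_numpy()
    np.testing.assert_allclose(np.sort(coords), [-1, 0, 1], atol=1e-9)
    assert coords[0] > 0  # deterministic sign: first nonzero loading positive


def test_pcoa_identical_points_all_zero():
    D = np.zeros((4, 4))
    res = dg.pcoa(D)
    assert res.coordinates.shape[1] == 0 or np.allclose(res.coordinates, 0)


def test_pcoa_reconstructs_euclidean_distances():
    rng = np.random.default_rng(1)
    X = rng.random((6, 3))
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    res = dg.pcoa(D, n_axes=6)
    C = res.coordinates.to_numpy()
    D2 = np.sqrt(((C[:, None] - C[None]) ** 2).sum(-1))
    np.testing.assert_allclose(D, D2, atol=1e-9)


def test_pcoa_agrees_with_skbio():
    """Eigenvalues and coordinate magnitudes match the scikit-bio
    implementation of classical scaling."""
    skbio_ord = pytest.importorskip("skbio.stats.ordination")
    from skbio import DistanceMatrix

    rng = np.random.default_rng(7)
    X = rng.random((8, 4))
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    ours = dg.pcoa(D, n_axes=4)
    ref = skbio_ord.pcoa(DistanceMatrix(D))
    np.testing.assert_allclose(
        ours.eigenvalues[:4], ref.eigvals.to_numpy()[:4], atol=1e-8
    )
    np.testing.assert_allclose(
        np.abs(ours.coordinates.to_numpy()),
        np.abs(ref.samples.to_numpy()[:, :4]),
        atol=1e-8,
    )


def test_pcoa_rejects_asymmetric_input():
    with pytest.raises(dg.ConfigurationError):
        dg.pcoa(np.array([[0.0, 1], [2, 0]]))


# ---------------------------------------------------------------------------
# flagging rule
# ---------------------------------------------------------------------------


def _two_taxon_setup(acc_dosages, n_markers=6):
    """Two taxa, 3 references each plus one extra accession per row given."""
    markers, frags = one_fragment(n_markers)
    # taxon A fixed ref (0), taxon B fixed alt (2) at every marker
    base = [[0] * n_markers] * 3 + [[2] * n_markers] * 3
    names = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
    rows = base + acc_dosages
    names += [f"x{i}" for i in range(len(acc_dosages))]
    G = dg.GenotypeMatrix(names, markers.marker_ids, np.array(rows, dtype=np.int8))
    tm_rows = [{"accession_id": n, "taxon": "A", "role": "REFERENCE"} for n in names[:3]]
    tm_rows += [{"accession_id": n, "taxon": "B", "role": "REFERENCE"} for n in names[3:6]]
    for n in names[6:]:
        tm_rows.append({"accession_id": n, "taxon": "A", "role": "REFERENCE"})
    tm = dg.TaxonMap(pd.DataFrame(tm_rows), taxa=("A", "B"))
    return G, tm, markers, frags


def test_flag_interspecific_heterozygote():
    """An A-labelled accession heterozygous at every A/B-differential
    marker is flagged with donor B."""
    G, tm, markers, frags = _two_taxon_setup([[1] * 6])
    fq = dg.taxon_frequencies(G, tm.reference_groups())
    flags = dg.flag_introgressed(G, tm, fq, markers, frags)
    assert len(flags) == 1
    row = flags.iloc[0]
    assert row["accession"] == "x0" and row["donor_taxon"] == "B"
    assert row["fragment_ho"] == 1.0 and row["n_differential_hets"] == 6


def test_pure_accession_not_flagged():
    G, tm, markers, frags = _two_taxon_setup([[0, 0, 0, 0, 0, 1]])  # Ho ≈ 0.17
    fq = dg.taxon_frequencies(G, tm.reference_groups())
    flags = dg.flag_introgressed(G, tm, fq, markers, frags)
    assert flags.empty


def test_high_het_without_differential_sites_not_flagged():
    """Fragment Ho above threshold from within-taxon polymorphism alone
    (no near-fixed frequency contrast) must not trigger a flag."""
    markers, frags = one_fragment(6)
    # both taxa held at p = 0.5 everywhere: no marker passes differential_delta
    base = np.ones((6, 6), dtype=int)
    names = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)] + ["x0"]
    rows = np.vstack([base, np.ones((1, 6), dtype=int)])  # x0 het everywhere
    G = dg.GenotypeMatrix(names, markers.marker_ids, rows.astype(np.int8))
    tm = dg.TaxonMap(
        pd.DataFrame(
            [{"accession_id": n, "taxon": "A", "role": "REFERENCE"} for n in names[:3]]
            + [{"accession_id": n, "taxon": "B", "role": "REFERENCE"} for n in names[3:6]]
            + [{"accession_id": "x0", "taxon": "A", "role": "REFERENCE"}]
        ),
        taxa=("A", "B"),
    )
    fq = dg.taxon_frequencies(G, tm.reference_groups())
    flags = dg.flag_introgressed(G, tm, fq, markers, frags)
    assert flags.empty


def test_test_accessions_never_flagged():
    G, tm, markers, frags = _two_taxon_setup([[1] * 6])
    tm.df.loc[tm.df["accession_id"] == "x0", ["taxon", "role"]] = [None, "TEST"]
    tm2 = dg.TaxonMap(tm.df, taxa=("A", "B"))
    fq = dg.taxon_frequencies(G, tm2.reference_groups())
    flags = dg.flag_introgressed(G, tm2, fq, markers, frags)
    assert flags.empty


# ---------------------------------------------------------------------------
# masked re-mining
# ---------------------------------------------------------------------------


def test_masking_is_noop_without_introgression(default_scenario):
    ds = default_scenario
    res = dg.remine_with_mask(
        ds.genotypes, ds.taxon_map, ds.markers, ds.fragments, with_ordination=False
    )
    assert res.flags.empty
    pd.testing.assert_frame_equal(res.panel_pre.table, res.panel_post.table)
    np.testing.assert_array_equal(res.masked.dosage, ds.genotypes.dosage)


def test_masking_only_removes_data(introgression_scenario):
    """Every call used post-mask was also present pre-mask."""
    ds = introgression_scenario
    res = dg.remine_with_mask(
        ds.genotypes, ds.taxon_map, ds.markers, ds.fragments, with_ordination=False
    )
    pre, post = ds.genotypes.dosage, res.masked.dosage
    changed = pre != post
    assert (post[changed] == dg.MISSING).all()
    assert len(res.flags) > 0


def test_masking_never_decreases_gst_of_planted_diagnostics(introgression_scenario):
    ds = introgression_scenario
    res = dg.remine_with_mask(
        ds.genotypes, ds.taxon_map, ds.markers, ds.fragments, with_ordination=False
    )
    truth = ds.truth.markers
    planted = truth.loc[truth["true_class"] == "fixed_difference", ["marker_id", "true_taxon"]]
    pre = res.gst_pre.set_index(["marker_id", "taxon"])["gst"]
    post = res.gst_post.set_index(["marker_id", "taxon"])["gst"]
    for mid, taxon in planted.itertuples(index=False):
        key = (mid, taxon)
        if key in post.index and key in pre.index:
            assert post[key] >= pre[key] - 1e-12


def test_remine_emits_ordination(default_scenario):
    ds = default_scenario
    res = dg.remine_with_mask(
        ds.genotypes, ds.taxon_map, ds.markers, ds.fragments, with_ordination=True
    )
    assert res.ordination is not None
    assert len(res.ordination.coordinates) == sum(
        len(v) for v in ds.taxon_map.reference_groups().values()
    )
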