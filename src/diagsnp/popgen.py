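"""Diversity and differentiation statistics.

Per-group allele frequencies, observed and (unbiased) expected
heterozygosity, the fixation index Fw, the Weir–Cockerham F_ST estimator,
SNP density per fragment/chromosome, the simple-matching dissimilarity
index, per-group summary reports, and genotype-call concordance between two
platforms.

Conventions
-----------
He (Nei gene diversity) for a biallelic marker is ``1 − p² − (1−p)² =
2p(1−p)``.  The *unbiased* estimate applies the small-sample factor
``2n/(2n−1)`` where ``2n`` is the number of non-missing gene copies.
Fw is defined as ``1 − Ho/He_unbiased`` (0 under Hardy–Weinberg, 1 for a
fully inbred group); the Weir–Cockerham within-population f is available
as an alternative estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError
from .io import MISSING, FragmentTable, GenotypeMatrix, MarkerTable


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class AlleleFrequencies:
    """Alternate-allele frequency per marker for one group of accessions.

    ``p`` is NaN where every call is missing (``n_genes == 0``).
    """

    marker_ids: list[str]
    p: np.ndarray
    n_genes: np.ndarray
    group_size: int

    @property
    def undefined(self) -> np.ndarray:
        return self.n_genes == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_ids, "p": self.p, "n_genes": self.n_genes}
        )


def allele_frequencies(G: GenotypeMatrix, group: Sequence[str]) -> AlleleFrequencies:
    """Alternate-allele frequencies over a non-empty accession subset."""
    group = list(group)
    if not group:
        raise ConfigurationError("allele_frequencies: empty group")
    d = G.dosage[G.accession_indices(group)]
    called = d != MISSING
    n_genes = 2 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_genes > 0, alt / np.maximum(n_genes, 1), np.nan)
    return AlleleFrequencies(list(G.marker_ids), p, n_genes, len(group))


def taxon_frequencies(
    G: GenotypeMatrix, groups: Mapping[str, Sequence[str]]
) -> dict[str, AlleleFrequencies]:
    """Frequencies per named group (e.g. per reference taxon)."""
    return {name: allele_frequencies(G, accs) for name, accs in groups.items()}


# ---------------------------------------------------------------------------
# heterozygosity / diversity
# ---------------------------------------------------------------------------


@dataclass
class DiversityStats:
    """Per-marker and multilocus diversity for one group."""

    per_marker: pd.DataFrame  # marker_id, ho, he_nei, he_unbiased, fw
    summary: pd.DataFrame  # statistic, mean, se, n_markers


def _mean_se(x: np.ndarray) -> tuple[float, float, int]:
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return np.nan, np.nan, 0
    se = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
    return float(np.mean(x)), se, len(x)


def heterozygosity(
    G: GenotypeMatrix,
    group: Sequence[str],
    freqs: AlleleFrequencies,
    fw_estimator: str = "ratio",
) -> DiversityStats:
    """Ho, He (Nei and unbiased) and Fw per marker, plus multilocus means.

    ``freqs`` must have been computed on the same group.
    ``fw_estimator`` selects the fixation index: ``"ratio"`` (default) is
    ``1 − Ho/He_unbiased``; ``"wc"`` is the single-population
    Weir–Cockerham f from variance components, ``1 − c/(b + c)``.
    """
    group = list(group)
    if freqs.group_size != len(group):
        raise ConfigurationError("heterozygosity: freqs computed on a different group")
    if fw_estimator not in ("ratio", "wc"):
        raise ConfigurationError(f"unknown fw_estimator {fw_estimator!r}")
    d = G.dosage[G.accession_indices(group)]
    called = (d != MISSING).sum(axis=0)
    het = (d == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(called > 0, het / np.maximum(called, 1), np.nan)
        he_nei = 2.0 * freqs.p * (1.0 - freqs.p)
        n2 = freqs.n_genes.astype(float)
        he_unb = np.where(n2 > 1, n2 / np.maximum(n2 - 1.0, 1e-300) * he_nei, np.nan)
        if fw_estimator == "ratio":
            fw = np.where(
                he_unb > 0, 1.0 - ho / np.where(he_unb > 0, he_unb, np.nan), np.nan
            )
        else:
            n = called.astype(float)  # diploid individuals with a call
            pq = freqs.p * (1.0 - freqs.p)
            b = np.where(
                n > 1,
                n / np.maximum(n - 1.0, 1e-300)
                * (pq - (2.0 * n - 1.0) / (4.0 * n) * ho),
                np.nan,
            )
            c = ho / 2.0
            fw = np.where(np.abs(b + c) > 0, 1.0 - c / np.where(
                np.abs(b + c) > 0, b + c, np.nan), np.nan)
    per_marker = pd.DataFrame(
        {
            "marker_id": G.marker_ids,
            "ho": ho,
            "he_nei": he_nei,
            "he_unbiased": he_unb,
            "fw": fw,
        }
    )
    rows = []
    for stat in ("ho", "he_nei", "he_unbiased", "fw"):
        m, se, n = _mean_se(per_marker[stat].to_numpy(dtype=float))
        rows.append({"statistic": stat, "mean": m, "se": se, "n_markers": n})
    return DiversityStats(per_marker, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------


def wc_fst(
    G: GenotypeMatrix, groups: Mapping[str, Sequence[str]]
) -> tuple[pd.DataFrame, float]:
    """Weir–Cockerham θ per marker and multilocus.

    Uses the standard variance-components estimator (a = among
    populations, b = among individuals within populations, c = within
    individuals).  Multilocus θ = Σa / Σ(a+b+c) over markers where the
    denominator is defined.  Markers with fewer than two populations
    having ≥2 called diploids are reported as NaN.
    """
    if len(groups) < 2:
        raise ConfigurationError("wc_fst requires at least two groups")
    mats = [G.dosage[G.accession_indices(list(a))] for a in groups.values()]
    n_markers = G.n_markers

    a_arr = np.full(n_markers, np.nan)
    b_arr = np.full(n_markers, np.nan)
    c_arr = np.full(n_markers, np.nan)

    # per-population called counts, freqs and het fractions (vectorised)
    n_i = np.stack([(m != MISSING).sum(axis=0) for m in mats])  # (r, M)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack(
            [
                np.where(
                    (m != MISSING).sum(axis=0) > 0,
                    np.where(m != MISSING, m, 0).sum(axis=0)
                    / np.maximum(2.0 * (m != MISSING).sum(axis=0), 1),
                    np.nan,
                )
                for m in mats
            ]
        )
        h_i = np.stack(
            [
                np.where(
                    (m != MISSING).sum(axis=0) > 0,
                    (m == 1).sum(axis=0) / np.maximum((m != MISSING).sum(axis=0), 1),
                    np.nan,
                )
                for m in mats
            ]
        )

    for j in range(n_markers):
        use = n_i[:, j] >= 2
        r = int(use.sum())
        if r < 2:
            continue
        n = n_i[use, j].astype(float)
        p = p_i[use, j]
        h = h_i[use, j]
        nbar = n.mean()
        nsum = n.sum()
        nc = (nsum - (n**2).sum() / nsum) / (r - 1)
        pbar = (n * p).sum() / nsum
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / nsum
        if nbar <= 1 or nc <= 0:
            continue
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        a_arr[j], b_arr[j], c_arr[j] = a, b, c

    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a_arr + b_arr + c_arr
        theta = np.where(np.abs(denom) > 0, a_arr / denom, np.nan)
    per_marker = pd.DataFrame(
        {"marker_id": G.marker_ids, "a": a_arr, "b": b_arr, "c": c_arr, "theta": theta}
    )
    ok = np.isfinite(denom) & (np.abs(denom) > 0)
    multilocus = float(a_arr[ok].sum() / denom[ok].sum()) if ok.any() else np.nan
    return per_marker, multilocus


# ---------------------------------------------------------------------------
# SNP density
# ---------------------------------------------------------------------------


def snp_density(
    markers: MarkerTable, fragments: FragmentTable
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """SNP/kb per fragment, per chromosome, and overall.

    Chromosome (and total) densities pool counts and lengths *before*
    dividing, so two fragments of 10/500 and 0/500 on one chromosome give
    10 SNP/kb, not the mean of 20 and 0.
    """
    fdf = fragments.df
    known = set(fdf["fragment_id"])
    assigned = markers.df["fragment_id"].dropna()
    unknown = assigned[~assigned.isin(known)]
    if len(unknown):
        raise ConsistencyError(f"marker assigned to unknown fragment {unknown.iloc[0]!r}")
    counts = assigned.value_counts()
    per_fragment = fdf[["fragment_id", "chrom", "length_bp"]].copy()
    per_fragment["n_snps"] = per_fragment["fragment_id"].map(counts).fillna(0).astype(int)
    per_fragment["snp_per_kb"] = (
        1000.0 * per_fragment["n_snps"] / per_fragment["length_bp"]
    )
    per_chrom = (
        per_fragment.groupby("chrom", as_index=False)
        .agg(length_bp=("length_bp", "sum"), n_snps=("n_snps", "sum"),
             n_fragments=("fragment_id", "count"))
    )
    per_chrom["snp_per_kb"] = 1000.0 * per_chrom["n_snps"] / per_chrom["length_bp"]
    total = 1000.0 * per_fragment["n_snps"].sum() / per_fragment["length_bp"].sum()
    return per_fragment, per_chrom, float(total)


# ---------------------------------------------------------------------------
# simple-matching dissimilarity
# ---------------------------------------------------------------------------


@dataclass
class DissimilarityMatrix:
    """Accession × accession simple-matching dissimilarities."""

    accession_ids: list[str]
    d: np.ndarray
    n_loci: np.ndarray  # per-pair count of comparable loci

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.accession_ids, columns=self.accession_ids)


def simple_matching_dissimilarity(G: GenotypeMatrix) -> DissimilarityMatrix:
    """Pairwise simple-matching dissimilarity.

    Per locus the similarity between two diploid calls is the number of
    shared allele copies (counting multiplicity) divided by 2, i.e.
    ``1 − |dosage₁ − dosage₂|/2``; the dissimilarity is one minus the mean
    similarity over loci called in both accessions.  Pairs with no
    comparable locus get NaN.
    """
    d = G.dosage.astype(float)
    d[G.dosage == MISSING] = np.nan
    n = G.n_accessions
    out = np.zeros((n, n))
    cnt = np.zeros((n, n), dtype=int)
    for i in range(n):
        diff = np.abs(d[i][None, :] - d)  # (n, M)
        ok = np.isfinite(diff)
        sim = 1.0 - diff / 2.0
        c = ok.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean_sim = np.where(c > 0, np.nansum(np.where(ok, sim, 0.0), axis=1)
                                / np.maximum(c, 1), np.nan)
        out[i] = 1.0 - mean_sim
        cnt[i] = c
    np.fill_diagonal(out, 0.0)
    return DissimilarityMatrix(list(G.accession_ids), out, cnt)


# ---------------------------------------------------------------------------
# group report
# ---------------------------------------------------------------------------


def _distinct_multilocus_genotypes(d: np.ndarray, missing_as_wildcard: bool) -> int:
    """Count distinct genotype vectors.

    With ``missing_as_wildcard`` two vectors are identical when they never
    disagree at a locus called in both; assignment is greedy in input
    order and merges group consensus as calls accumulate.
    """
    if not missing_as_wildcard:
        return len({tuple(row) for row in d})
    reps: list[np.ndarray] = []
    for row in d:
        placed = False
        for rep in reps:
            both = (row != MISSING) & (rep != MISSING)
            if not np.any(both & (row != rep)):
                fill = (rep == MISSING) & (row != MISSING)
                rep[fill] = row[fill]
                placed = True
                break
        if not placed:
            reps.append(row.copy())
    return len(reps)


def group_report(
    G: GenotypeMatrix,
    groups: Mapping[str, Sequence[str]],
    missing_as_wildcard: bool = True,
) -> pd.DataFrame:
    """Per-group Na, missing-data %, polymorphic loci, Ho and NSG.

    Column order follows the reporting convention: group, Na, MD, PL, Ho,
    He, Fw, NSG.
    """
    rows = []
    for name, accs in groups.items():
        accs = list(accs)
        if not accs:
            raise ConfigurationError(f"group {name!r} is empty")
        d = G.dosage[G.accession_indices(accs)]
        total = d.size
        miss = int((d == MISSING).sum())
        md = 100.0 * miss / total if total else np.nan
        freqs = allele_frequencies(G, accs)
        poly = int(np.sum((freqs.p > 0) & (freqs.p < 1)))
        div = heterozygosity(G, accs, freqs)
        ho = div.summary.set_index("statistic").loc["ho", "mean"]
        he = div.summary.set_index("statistic").loc["he_unbiased", "mean"]
        fw = div.summary.set_index("statistic").loc["fw", "mean"]
        nsg = _distinct_multilocus_genotypes(d, missing_as_wildcard)
        rows.append(
            {
                "group": name,
                "Na": len(accs),
                "MD": md,
                "PL": poly,
                "Ho": ho,
                "He": he,
                "Fw": fw,
                "NSG": nsg,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# concordance between genotyping platforms
# ---------------------------------------------------------------------------


def concordance(
    G1: GenotypeMatrix, G2: GenotypeMatrix
) -> tuple[pd.DataFrame, float]:
    """Genotype-call discrepancy between two matrices.

    Compares calls for the shared accessions × shared markers; pairs with
    a missing call in either matrix are excluded.  Returns per-marker
    rates (for ranking problem assays) and the overall rate; the overall
    rate is NaN when no call pair is comparable.
    """
    acc = [a for a in G1.accession_ids if a in set(G2.accession_ids)]
    mk = [m for m in G1.marker_ids if m in set(G2.marker_ids)]
    if not acc or not mk:
        raise ConfigurationError("concordance: no overlapping accessions/markers")
    d1 = G1.subset(acc, mk).dosage
    d2 = G2.subset(acc, mk).dosage
    both = (d1 != MISSING) & (d2 != MISSING)
    differ = both & (d1 != d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_marker_rate = np.where(
            both.sum(axis=0) > 0,
            differ.sum(axis=0) / np.maximum(both.sum(axis=0), 1),
            np.nan,
        )
    per_marker = pd.DataFrame(
        {
            "marker_id": mk,
            "n_compared": both.sum(axis=0),
            "n_discrepant": differ.sum(axis=0),
            "discrepancy_rate": per_marker_rate,
        }
    ).sort_values("discrepancy_rate", ascending=False, kind="stable")
    n_comp = int(both.sum())
    overall = float(differ.sum() / n_comp) if n_comp else np.nan
    return per_marker.reset_index(drop=True), overall
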