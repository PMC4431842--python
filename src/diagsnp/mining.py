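"""Species-diagnostic SNP mining.

For each marker and each ancestral taxon *i*, a two-subpopulation G_ST
contrasts the focal taxon Ti against a pooled population T−i of the
remaining taxa, built by averaging the per-taxon allele frequencies with
equal taxon weights:

    p_rest = mean(p_u, u ≠ i)
    p_tot  = (p_i + p_rest) / 2
    G_ST(i) = (He_tot − (He_i + He_rest)/2) / He_tot,   He(p) = 2p(1−p)

G_ST = 1 marks a fixed difference (the taxon is totally differentiated);
a single heterozygous accession in an otherwise monomorphic system gives
G_ST = 1/3.  He is concave, so G_ST ∈ [0, 1] for every frequency input
(Jensen's inequality).

Markers are then classified:

* DIAGNOSTIC — max G_ST above the diagnostic threshold (default > 0.9);
* TAXON_SPECIFIC_POLYMORPHISM — max G_ST at or below the specific bound
  (default ≤ 0.5) with a variant allele segregating in exactly one taxon
  while the other taxa are fixed for the shared allele;
* ND — max G_ST at or below the bound without such taxon specificity;
* PARTIAL — everything in between.

A proximity filter rejects assay candidates with further variants in
their flanking sequence, and ``build_panel`` assembles the per-taxon
marker panel with a cross-taxon allele-frequency QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import MarkerTable
from .popgen import AlleleFrequencies

logger = logging.getLogger(__name__)

DIAGNOSTIC = "DIAGNOSTIC"
TAXON_SPECIFIC = "TAXON_SPECIFIC_POLYMORPHISM"
PARTIAL = "PARTIAL"
ND = "ND"


# ---------------------------------------------------------------------------
# G_ST
# ---------------------------------------------------------------------------


def he_biallelic(p: np.ndarray) -> np.ndarray:
    """Nei gene diversity 1 − p² − (1−p)² for a biallelic marker."""
    p = np.asarray(p, dtype=float)
    return 2.0 * p * (1.0 - p)


def gst_from_frequencies(
    p_focal: np.ndarray, p_others: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised taxon-vs-rest G_ST from allele frequencies.

    ``p_focal`` has shape (M,); ``p_others`` has shape (K−1, M).  The rest
    pool averages the non-focal taxa with equal weights, and the total
    pool averages focal and rest with equal weights.  Returns
    ``(gst, he_ti, he_rest, he_tot)``; monomorphic markers
    (He_tot = 0) get gst = 0.
    """
    p_focal = np.asarray(p_focal, dtype=float)
    p_others = np.atleast_2d(np.asarray(p_others, dtype=float))
    with np.errstate(invalid="ignore"):
        p_rest = np.nanmean(p_others, axis=0)
    p_tot = 0.5 * (p_focal + p_rest)
    he_ti = he_biallelic(p_focal)
    he_rest = he_biallelic(p_rest)
    he_tot = he_biallelic(p_tot)
    with np.errstate(invalid="ignore", divide="ignore"):
        gst = np.where(
            he_tot > 0, (he_tot - 0.5 * (he_ti + he_rest)) / np.where(he_tot > 0, he_tot, 1.0), 0.0
        )
    gst = np.where(np.isnan(p_focal) | np.isnan(p_rest), np.nan, gst)
    # numerical guard: the statistic is in [0, 1] analytically
    gst = np.clip(gst, 0.0, 1.0)
    return gst, he_ti, he_rest, he_tot


def gst_taxon_vs_rest(
    freqs: Mapping[str, AlleleFrequencies], focal: str
) -> pd.DataFrame:
    """Per-marker G_ST records for one focal taxon.

    Markers with an undefined focal frequency are skipped (logged);
    the returned frame has columns marker_id, taxon, gst, he_ti,
    he_tminus, he_tot, diagnostic_allele, monomorphic.
    """
    if focal not in freqs:
        raise ConfigurationError(f"unknown focal taxon {focal!r}")
    others = [t for t in freqs if t != focal]
    if not others:
        raise ConfigurationError("gst_taxon_vs_rest needs at least two taxa")
    fa = freqs[focal]
    p_focal = fa.p
    p_others = np.stack([freqs[t].p for t in others])
    gst, he_ti, he_rest, he_tot = gst_from_frequencies(p_focal, p_others)
    with np.errstate(invalid="ignore"):
        p_rest = np.nanmean(p_others, axis=0)
    # allele enriched in the focal taxon
    diag_allele = np.where(p_focal >= p_rest, "alt", "ref")
    skipped = np.isnan(gst)
    if skipped.any():
        for mid in np.asarray(fa.marker_ids)[skipped][:10]:
            logger.info("G_ST skipped for marker %s (undefined frequency)", mid)
    out = pd.DataFrame(
        {
            "marker_id": fa.marker_ids,
            "taxon": focal,
            "gst": gst,
            "he_ti": he_ti,
            "he_tminus": he_rest,
            "he_tot": he_tot,
            "diagnostic_allele": np.where(gst > 0, diag_allele, None),
            "monomorphic": he_tot == 0,
        }
    )
    return out[~skipped].reset_index(drop=True)


def gst_all_taxa(freqs: Mapping[str, AlleleFrequencies]) -> pd.DataFrame:
    """G_ST records for every taxon, concatenated."""
    return pd.concat(
        [gst_taxon_vs_rest(freqs, t) for t in freqs], ignore_index=True
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_markers(
    gst_records: pd.DataFrame,
    freqs: Mapping[str, AlleleFrequencies],
    diagnostic_threshold: float = 0.9,
    specific_max_gst: float = 0.5,
    fixed_tol: float = 0.0,
) -> pd.DataFrame:
    """Assign each marker exactly one class.

    ``fixed_tol`` relaxes the "fixed" requirement of the taxon-specific
    rule (a taxon counts as fixed when its frequency is within
    ``fixed_tol`` of 0 or 1); the default is strict.
    Returns columns marker_id, class, taxon, max_gst, diagnostic_allele.
    """
    taxa = list(freqs)
    p_by_taxon = {t: pd.Series(freqs[t].p, index=freqs[t].marker_ids) for t in taxa}
    rows = []
    by_marker = gst_records.groupby("marker_id", sort=False)
    for mid, grp in by_marker:
        best = grp.loc[grp["gst"].idxmax()]
        max_gst = float(best["gst"])
        if max_gst > diagnostic_threshold:
            rows.append(
                {
                    "marker_id": mid,
                    "class": DIAGNOSTIC,
                    "taxon": best["taxon"],
                    "max_gst": max_gst,
                    "diagnostic_allele": best["diagnostic_allele"],
                }
            )
            continue
        if max_gst <= specific_max_gst:
            # taxon-specific polymorphism: variant segregates in exactly one
            # taxon, the others fixed for the shared allele
            p = np.array([p_by_taxon[t].get(mid, np.nan) for t in taxa])
            defined = ~np.isnan(p)
            poly = defined & (p > fixed_tol) & (p < 1 - fixed_tol)
            fixed0 = defined & (p <= fixed_tol)
            fixed1 = defined & (p >= 1 - fixed_tol)
            if poly.sum() == 1 and (fixed0.sum() + fixed1.sum()) == defined.sum() - 1 and (
                fixed0.sum() == defined.sum() - 1 or fixed1.sum() == defined.sum() - 1
            ):
                t_idx = int(np.flatnonzero(poly)[0])
                variant = "alt" if fixed0.sum() == defined.sum() - 1 else "ref"
                rows.append(
                    {
                        "marker_id": mid,
                        "class": TAXON_SPECIFIC,
                        "taxon": taxa[t_idx],
                        "max_gst": max_gst,
                        "diagnostic_allele": variant,
                    }
                )
            else:
                rows.append(
                    {
                        "marker_id": mid,
                        "class": ND,
                        "taxon": None,
                        "max_gst": max_gst,
                        "diagnostic_allele": None,
                    }
                )
            continue
        rows.append(
            {
                "marker_id": mid,
                "class": PARTIAL,
                "taxon": best["taxon"],
                "max_gst": max_gst,
                "diagnostic_allele": None,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# proximity filter
# ---------------------------------------------------------------------------


def proximity_filter(
    candidates: Sequence[str],
    markers: MarkerTable,
    window_bp: int = 50,
    indels: pd.DataFrame | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Reject assay candidates with another variant within ``window_bp``.

    ``indels`` is an optional frame with columns ``chrom`` and ``pos``
    (1-based).  The rule is symmetric: two candidate SNPs inside one
    window reject each other.  Returns (retained ids, rejection records
    naming the offending variant).
    """
    mdf = markers.df.set_index("marker_id")
    var_chrom = list(markers.df["chrom"].astype(str))
    var_pos = list(markers.df["pos"].astype(int))
    var_name = list(markers.df["marker_id"])
    if indels is not None:
        var_chrom += list(indels["chrom"].astype(str))
        var_pos += list(indels["pos"].astype(int))
        var_name += [f"indel:{c}:{p}" for c, p in zip(indels["chrom"], indels["pos"])]
    var = pd.DataFrame({"chrom": var_chrom, "pos": var_pos, "name": var_name})

    retained, rejected = [], []
    for cid in candidates:
        row = mdf.loc[cid]
        near = var[
            (var["chrom"] == str(row["chrom"]))
            & (var["name"] != cid)
            & ((var["pos"] - int(row["pos"])).abs() <= window_bp)
        ]
        if near.empty:
            retained.append(cid)
        else:
            off = near.iloc[(near["pos"] - int(row["pos"])).abs().argmin()]
            rejected.append(
                {
                    "marker_id": cid,
                    "offending_variant": off["name"],
                    "distance_bp": int(abs(off["pos"] - int(row["pos"]))),
                }
            )
    return retained, pd.DataFrame(rejected, columns=["marker_id", "offending_variant", "distance_bp"])


# ---------------------------------------------------------------------------
# panel construction
# ---------------------------------------------------------------------------


@dataclass
class DiagnosticPanel:
    """Per-taxon diagnostic markers with their diagnostic alleles."""

    table: pd.DataFrame  # taxon, marker_id, class, diagnostic_allele, max_gst
    removed: pd.DataFrame = field(default_factory=pd.DataFrame)

    def markers_for(self, taxon: str) -> pd.DataFrame:
        return self.table[self.table["taxon"] == taxon]

    @property
    def taxa(self) -> list[str]:
        return sorted(self.table["taxon"].unique())

    def counts(self) -> pd.Series:
        return self.table.groupby("taxon").size()


def build_panel(
    classifications: pd.DataFrame,
    freqs: Mapping[str, AlleleFrequencies],
    qc_threshold: float = 0.1,
) -> DiagnosticPanel:
    """Assemble the per-taxon panel from DIAGNOSTIC and TAXON_SPECIFIC markers.

    QC removes a marker whose diagnostic allele is also observed at
    frequency ≥ ``qc_threshold`` in a second taxon (the shared-polymorphism
    precedent); removals are returned alongside the panel.
    """
    keep = classifications[
        classifications["class"].isin([DIAGNOSTIC, TAXON_SPECIFIC])
    ].copy()
    p_by_taxon = {
        t: pd.Series(freqs[t].p, index=freqs[t].marker_ids) for t in freqs
    }
    removed_rows = []
    ok_rows = []
    for _, row in keep.iterrows():
        mid, taxon, allele = row["marker_id"], row["taxon"], row["diagnostic_allele"]
        shared_in = []
        for t in freqs:
            if t == taxon:
                continue
            p = p_by_taxon[t].get(mid, np.nan)
            if np.isnan(p):
                continue
            f_allele = p if allele == "alt" else 1.0 - p
            if f_allele >= qc_threshold:
                shared_in.append((t, float(f_allele)))
        if shared_in:
            t2, f2 = shared_in[0]
            removed_rows.append(
                {
                    "marker_id": mid,
                    "taxon": taxon,
                    "shared_with": t2,
                    "freq_in_second_taxon": f2,
                }
            )
            logger.info(
                "panel QC removed %s (diagnostic allele for %s also in %s at %.3f)",
                mid, taxon, t2, f2,
            )
        else:
            ok_rows.append(row)
    table = (
        pd.DataFrame(ok_rows)[["taxon", "marker_id", "class", "diagnostic_allele", "max_gst"]]
        if ok_rows
        else pd.DataFrame(columns=["taxon", "marker_id", "class", "diagnostic_allele", "max_gst"])
    )
    for t in freqs:
        if table.empty or not (table["taxon"] == t).any():
            logger.warning("panel is empty for taxon %r", t)
    removed = pd.DataFrame(
        removed_rows,
        columns=["marker_id", "taxon", "shared_with", "freq_in_second_taxon"],
    )
    return DiagnosticPanel(table.reset_index(drop=True), removed)
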