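"""Admixture profiling from diagnostic-allele zygosity.

For each accession and each ancestral taxon *t*, the fractions of the
taxon-*t* panel markers (with a non-missing call) at which the accession
carries two, one, or zero copies of the diagnostic allele:

    FHom_t + FHet_t + FAbs_t = 1.

The direct contribution estimate normalises the diagnostic-allele dosage
share per taxon by the per-taxon panel size first (panels are unequal),

    s_t = (2·FHom_t + FHet_t) / 2,      c_t = s_t / Σ_u s_u,

so an F1 between two taxa gives c = 0.5 for each parent and a pure
reference gives c = 1 for its own taxon.  A dosage PCA of the accessions
provides the ordination view in which hybrids fall between the parental
clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import MISSING, GenotypeMatrix
from .mining import DiagnosticPanel


def admixture_profile(
    G: GenotypeMatrix,
    panel: DiagnosticPanel,
    accessions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-taxon diagnostic-allele zygosity fractions.

    One row per accession × taxon with columns n_markers_called, f_hom,
    f_het, f_abs.  Markers missing for an accession leave the denominator;
    a taxon with every panel marker missing gets NaN fractions.
    """
    if panel.table.empty:
        raise ConfigurationError("admixture_profile: empty panel")
    accs = list(accessions) if accessions is not None else list(G.accession_ids)
    rows = []
    marker_set = set(G.marker_ids)
    for taxon in panel.taxa:
        sub = panel.markers_for(taxon)
        mids = [m for m in sub["marker_id"] if m in marker_set]
        if not mids:
            for acc in accs:
                rows.append(
                    {"accession": acc, "taxon": taxon, "n_markers_called": 0,
                     "f_hom": np.nan, "f_het": np.nan, "f_abs": np.nan}
                )
            continue
        alleles = sub.set_index("marker_id").loc[mids, "diagnostic_allele"]
        cols = G.marker_indices(mids)
        d = G.dosage[np.ix_(G.accession_indices(accs), cols)].astype(float)
        d[d == MISSING] = np.nan
        # dosage of the diagnostic allele (alt as stored, else 2 − dosage)
        is_alt = (alleles == "alt").to_numpy()
        ddos = np.where(is_alt[None, :], d, 2.0 - d)
        called = np.isfinite(ddos)
        n = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_hom = np.nansum(ddos == 2, axis=1) / np.maximum(n, 1)
            f_het = np.nansum(ddos == 1, axis=1) / np.maximum(n, 1)
            f_abs = np.nansum(ddos == 0, axis=1) / np.maximum(n, 1)
        for i, acc in enumerate(accs):
            rows.append(
                {
                    "accession": acc,
                    "taxon": taxon,
                    "n_markers_called": int(n[i]),
                    "f_hom": f_hom[i] if n[i] else np.nan,
                    "f_het": f_het[i] if n[i] else np.nan,
                    "f_abs": f_abs[i] if n[i] else np.nan,
                }
            )
    return pd.DataFrame(rows)


def contribution_estimate(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon ancestry contribution from diagnostic-allele dosage shares.

    Adds columns ``share`` and ``contribution`` to the profile.  An
    accession with no observed diagnostic allele at all (or with an
    undefined profile) gets NaN contributions.
    """
    out = profile.copy()
    with np.errstate(invalid="ignore"):
        out["share"] = (2.0 * out["f_hom"] + out["f_het"]) / 2.0
    contrib = np.full(len(out), np.nan)
    for acc, idx in out.groupby("accession").groups.items():
        s = out.loc[idx, "share"].to_numpy(dtype=float)
        tot = np.nansum(s)
        if tot > 0 and np.isfinite(tot):
            contrib[np.asarray(idx)] = np.where(np.isfinite(s), s, 0.0) / tot
    out["contribution"] = contrib
    return out


@dataclass
class PcaResult:
    coordinates: pd.DataFrame
    proportions: np.ndarray


def dosage_pca(
    G: GenotypeMatrix, markers: Sequence[str] | None = None, n_axes: int = 3
) -> PcaResult:
    """PCA of the centered alternate-allele dosage matrix.

    Missing calls are imputed to the marker mean dosage before centering;
    the decomposition is by singular values, axis signs fixed so the
    first nonzero loading on each axis is positive.  Zero-variance input
    yields all-zero coordinates.
    """
    if G.n_accessions < 2 or G.n_markers < 1:
        raise ConfigurationError("dosage_pca needs ≥2 accessions and ≥1 marker")
    sub = G if markers is None else G.subset(markers=list(markers))
    X = sub.dosage.astype(float)
    X[sub.dosage == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = S > 1e-10
    k = min(n_axes, int(keep.sum()))
    coords = U[:, :k] * S[:k]
    for a in range(k):
        col = coords[:, a]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            coords[:, a] = -col
    var = S**2
    total = var.sum()
    props = var[:k] / total if total > 0 else np.zeros(k)
    if k == 0:
        coords = np.zeros((sub.n_accessions, 1))
        props = np.zeros(1)
        k = 1
    frame = pd.DataFrame(
        coords, index=sub.accession_ids, columns=[f"axis{i + 1}" for i in range(k)]
    )
    return PcaResult(frame, props)
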