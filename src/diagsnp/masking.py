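"""Interspecific-introgression detection and masked re-mining.

A reference accession that carries one resident and one donor haplotype
over a gene fragment shows two signatures: a fragment-level observed
heterozygosity far above the within-taxon scale, and heterozygous calls at
markers whose allele frequencies are strongly differentiated between its
own taxon and the donor.  The screen combines both (the ordination view
that accompanies the manual workflow is emitted alongside for audit):

flag (accession × fragment) when

  (a) fragment Ho ≥ ``het_threshold``, and
  (b) the accession is heterozygous at ≥ ``min_differential_hets`` markers
      of the fragment whose frequency difference between its own taxon
      (computed leave-one-out, so the accession cannot contaminate its own
      reference) and some other taxon is ≥ ``differential_delta``; the
      donor is the taxon maximising that count.

Flags apply at accession × fragment granularity.  Masking removes the
flagged calls, taxon allele frequencies are re-estimated, and the
diagnostic panel is mined again; masking only ever removes data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import MISSING, FragmentTable, GenotypeMatrix, MarkerTable, TaxonMap
from .mining import DIAGNOSTIC, DiagnosticPanel, build_panel, classify_markers, gst_all_taxa
from .popgen import AlleleFrequencies, simple_matching_dissimilarity, taxon_frequencies

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fragment heterozygosity
# ---------------------------------------------------------------------------


def fragment_heterozygosity(
    G: GenotypeMatrix, markers: MarkerTable, fragments: FragmentTable
) -> pd.DataFrame:
    """Observed heterozygosity per accession per fragment.

    Rows: accessions; columns: fragment ids; NaN where the accession has
    no non-missing call among the fragment's markers.  A companion frame
    of per-cell counts is attached as ``.attrs['n_markers']``.
    """
    frag_ids = fragments.fragment_ids
    ho = pd.DataFrame(index=G.accession_ids, columns=frag_ids, dtype=float)
    counts = pd.DataFrame(0, index=G.accession_ids, columns=frag_ids, dtype=int)
    mdf = markers.df
    for fid in frag_ids:
        mids = mdf.loc[mdf["fragment_id"] == fid, "marker_id"].tolist()
        if not mids:
            ho[fid] = np.nan
            continue
        cols = G.marker_indices(mids)
        d = G.dosage[:, cols]
        called = (d != MISSING).sum(axis=1)
        het = (d == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho[fid] = np.where(called > 0, het / np.maximum(called, 1), np.nan)
        counts[fid] = called
    ho.attrs["n_markers"] = counts
    return ho


# ---------------------------------------------------------------------------
# PCoA (classical metric scaling) — advisory ordination
# ---------------------------------------------------------------------------


@dataclass
class PcoaResult:
    """Principal-coordinates embedding of a dissimilarity matrix."""

    coordinates: pd.DataFrame  # accessions × retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportions: np.ndarray  # variance fraction per retained axis


def pcoa(D: np.ndarray | pd.DataFrame, n_axes: int = 3,
         labels: list[str] | None = None) -> PcoaResult:
    """Classical principal coordinates via double-centering.

    Negative eigenvalues (non-Euclidean input) are excluded from the
    retained axes; each axis sign is fixed so its first nonzero loading
    is positive.
    """
    if isinstance(D, pd.DataFrame):
        labels = list(D.index)
        D = D.to_numpy(dtype=float)
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10, equal_nan=True):
        raise ConfigurationError("pcoa requires a symmetric square matrix")
    n = D.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * max(evals.max(), 1.0))
    k = min(n_axes, int(pos.sum()))
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for a in range(k):  # deterministic axis orientation
        col = coords[:, a]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            coords[:, a] = -col
    total = evals[pos].sum()
    props = evals[:k] / total if total > 0 else np.zeros(k)
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"axis{i + 1}" for i in range(k)]
    )
    return PcoaResult(frame, evals, props)


# ---------------------------------------------------------------------------
# flagging
# ---------------------------------------------------------------------------


@dataclass
class FlagParams:
    """Decision rule for interspecific heterozygosity at a fragment.

    ``het_threshold`` sits well above the intraspecific fragment-Ho scale
    (a few percent) but at the minimum interspecific signal that the
    differential-het condition can certify (two divergent sites on a
    typical ~18-marker fragment); ``differential_delta`` requires
    near-fixed frequency contrast between the accession's own taxon
    (leave-one-out) and the donor; ``min_differential_hets`` demands the
    signal at more than one site, guarding against single genotyping
    errors.
    """

    het_threshold: float = 0.1
    min_differential_hets: int = 2
    differential_delta: float = 0.9


def flag_introgressed(
    G: GenotypeMatrix,
    taxon_map: TaxonMap,
    provisional_freqs: dict[str, AlleleFrequencies],
    markers: MarkerTable,
    fragments: FragmentTable,
    params: FlagParams | None = None,
) -> pd.DataFrame:
    """Flag reference accession × fragment pairs with interspecific heterozygosity.

    TEST accessions are never flagged.  Returns one row per flagged pair:
    accession, fragment, donor_taxon, fragment_ho, n_differential_hets.
    """
    params = params or FlagParams()
    taxa = list(provisional_freqs)
    ho = fragment_heterozygosity(G, markers, fragments)
    mdf = markers.df
    frag_marker_idx = {
        fid: G.marker_indices(mdf.loc[mdf["fragment_id"] == fid, "marker_id"])
        for fid in fragments.fragment_ids
    }
    p_mat = np.stack([provisional_freqs[t].p for t in taxa])  # (K, M)
    alt_mat = np.stack(
        [provisional_freqs[t].p * provisional_freqs[t].n_genes for t in taxa]
    )
    genes_mat = np.stack([provisional_freqs[t].n_genes for t in taxa]).astype(float)

    rows = []
    for _, rec in taxon_map.df.iterrows():
        if rec["role"] != "REFERENCE":
            continue
        acc, own = rec["accession_id"], rec["taxon"]
        ti = taxa.index(own)
        dos = G.row(acc).astype(float)
        called = dos >= 0
        # leave-one-out own-taxon frequency
        alt_loo = alt_mat[ti] - np.where(called, dos, 0.0)
        genes_loo = genes_mat[ti] - np.where(called, 2.0, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_loo = np.where(genes_loo > 0, alt_loo / np.maximum(genes_loo, 1), np.nan)
        het = dos == 1
        for fid, cols in frag_marker_idx.items():
            if len(cols) == 0:
                continue
            frag_ho = ho.loc[acc, fid]
            if not np.isfinite(frag_ho) or frag_ho < params.het_threshold:
                continue
            best_donor, best_count = None, 0
            for ui, u in enumerate(taxa):
                if u == own:
                    continue
                with np.errstate(invalid="ignore"):
                    differential = (
                        np.abs(p_loo[cols] - p_mat[ui, cols]) >= params.differential_delta
                    )
                count = int(np.sum(het[cols] & np.nan_to_num(differential, nan=False)))
                if count > best_count:
                    best_donor, best_count = u, count
            if best_count >= params.min_differential_hets:
                rows.append(
                    {
                        "accession": acc,
                        "fragment": fid,
                        "donor_taxon": best_donor,
                        "fragment_ho": float(frag_ho),
                        "n_differential_hets": best_count,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["accession", "fragment", "donor_taxon", "fragment_ho", "n_differential_hets"],
    )


def apply_mask(
    G: GenotypeMatrix, flags: pd.DataFrame, markers: MarkerTable
) -> GenotypeMatrix:
    """Remove flagged accession × fragment calls (set to MISSING)."""
    d = G.dosage.copy()
    mdf = markers.df
    for _, row in flags.iterrows():
        i = G.accession_indices([row["accession"]])[0]
        cols = G.marker_indices(
            mdf.loc[mdf["fragment_id"] == row["fragment"], "marker_id"]
        )
        d[i, cols] = MISSING
    return GenotypeMatrix(list(G.accession_ids), list(G.marker_ids), d)


# ---------------------------------------------------------------------------
# masked re-mining
# ---------------------------------------------------------------------------


@dataclass
class MaskingResult:
    flags: pd.DataFrame
    gst_pre: pd.DataFrame
    gst_post: pd.DataFrame
    classification_pre: pd.DataFrame
    classification_post: pd.DataFrame
    panel_pre: DiagnosticPanel
    panel_post: DiagnosticPanel
    delta_report: pd.DataFrame
    dropped_markers: list[str]
    masked: GenotypeMatrix
    ordination: PcoaResult | None = None


def remine_with_mask(
    G: GenotypeMatrix,
    taxon_map: TaxonMap,
    markers: MarkerTable,
    fragments: FragmentTable,
    flag_params: FlagParams | None = None,
    diagnostic_threshold: float = 0.9,
    specific_max_gst: float = 0.5,
    qc_threshold: float = 0.1,
    passes: int = 1,
    with_ordination: bool = True,
) -> MaskingResult:
    """Provisional mining → flagging → masking → re-mining.

    Repeats the flag/mask cycle ``passes`` times (new flags accumulate;
    one pass reproduces the single re-estimation workflow).  Markers for
    which masking leaves a taxon without callable genes are dropped from
    the post panel and logged.
    """
    groups = taxon_map.reference_groups()
    if len(groups) < 2:
        raise ConfigurationError("remine_with_mask needs at least two reference taxa")
    flag_params = flag_params or FlagParams()

    freqs_pre = taxon_frequencies(G, groups)
    gst_pre = gst_all_taxa(freqs_pre)
    cls_pre = classify_markers(
        gst_pre, freqs_pre, diagnostic_threshold, specific_max_gst
    )
    panel_pre = build_panel(cls_pre, freqs_pre, qc_threshold)

    current = G
    all_flags: list[pd.DataFrame] = []
    for _ in range(max(1, passes)):
        freqs_now = taxon_frequencies(current, groups)
        flags = flag_introgressed(
            current, taxon_map, freqs_now, markers, fragments, flag_params
        )
        if flags.empty:
            break
        all_flags.append(flags)
        current = apply_mask(current, flags, markers)
    flags_all = (
        pd.concat(all_flags, ignore_index=True).drop_duplicates(
            subset=["accession", "fragment"]
        )
        if all_flags
        else pd.DataFrame(
            columns=["accession", "fragment", "donor_taxon", "fragment_ho",
                     "n_differential_hets"]
        )
    )

    freqs_post = taxon_frequencies(current, groups)
    undefined_pre = {
        m
        for fa in freqs_pre.values()
        for m in np.asarray(fa.marker_ids)[fa.undefined]
    }
    # only markers that *masking* left without callable genes are dropped;
    # markers already undefined pre-mask are handled identically on both sides
    dropped = sorted(
        {
            m
            for fa in freqs_post.values()
            for m in np.asarray(fa.marker_ids)[fa.undefined]
        }
        - undefined_pre
    )
    for m in dropped[:20]:
        logger.info("marker %s dropped post-mask (a taxon has zero callable genes)", m)
    gst_post_full = gst_all_taxa(freqs_post)
    gst_post = gst_post_full[~gst_post_full["marker_id"].isin(dropped)].reset_index(
        drop=True
    )
    cls_post = classify_markers(
        gst_post, freqs_post, diagnostic_threshold, specific_max_gst
    )
    panel_post = build_panel(cls_post, freqs_post, qc_threshold)

    rows = []
    for t in groups:
        rows.append(
            {
                "taxon": t,
                "n_diagnostic_pre": int(
                    ((cls_pre["class"] == DIAGNOSTIC) & (cls_pre["taxon"] == t)).sum()
                ),
                "n_diagnostic_post": int(
                    ((cls_post["class"] == DIAGNOSTIC) & (cls_post["taxon"] == t)).sum()
                ),
                "n_panel_pre": int((panel_pre.table["taxon"] == t).sum()),
                "n_panel_post": int((panel_post.table["taxon"] == t).sum()),
                "n_flags": int(
                    (
                        flags_all["accession"].isin(groups[t])
                        if not flags_all.empty
                        else pd.Series(dtype=bool)
                    ).sum()
                ),
            }
        )
    delta = pd.DataFrame(rows)

    ordination = None
    if with_ordination:
        ref_accs = [a for accs in groups.values() for a in accs]
        D = simple_matching_dissimilarity(G.subset(ref_accs))
        ordination = pcoa(D.to_frame().fillna(0.0), n_axes=3)

    return MaskingResult(
        flags=flags_all,
        gst_pre=gst_pre,
        gst_post=gst_post,
        classification_pre=cls_pre,
        classification_post=cls_post,
        panel_pre=panel_pre,
        panel_post=panel_post,
        delta_report=delta,
        dropped_markers=dropped,
        masked=current,
        ordination=ordination,
    )
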