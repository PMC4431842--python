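"""Data model and file I/O.

Core containers for a diploid, biallelic SNP analysis:

* :class:`GenotypeMatrix` — accessions × markers calls, stored internally as
  alternate-allele dosage (0/1/2, ``-1`` for missing).  Calls are unphased:
  ref/alt and alt/ref are the same genotype.
* :class:`MarkerTable` — per-marker chromosome, 1-based position, ref/alt
  alleles and an optional gene-fragment assignment.
* :class:`FragmentTable` — amplicon fragments as 0-based half-open intervals
  (BED convention); conversion between the two coordinate conventions
  happens once, at load time.
* :class:`TaxonMap` — accession → ancestral-taxon label with a
  REFERENCE/TEST role.

Supported formats: VCF v4.x (GT subfield only, read via cyvcf2), wide
genotype TSV (rows = accessions, columns = markers, calls as two-letter
strings, IUPAC single letters or homozygous single letters), BED3+name for
fragments, and plain TSV for every tabular output.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    BiallelicViolationError,
    ConfigurationError,
    ConsistencyError,
    ParseError,
)

logger = logging.getLogger(__name__)

MISSING = -1

REFERENCE = "REFERENCE"
TEST = "TEST"

#: IUPAC ambiguity letters for heterozygous diploid calls.
IUPAC_HET = {
    "M": ("A", "C"),
    "R": ("A", "G"),
    "W": ("A", "T"),
    "S": ("C", "G"),
    "Y": ("C", "T"),
    "K": ("G", "T"),
}

#: Accepted encodings of a missing call in genotype TSV tables.
MISSING_CODES = {"./.", ".", "NN", "NA", "-", "", "N"}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class MarkerTable:
    """Per-marker metadata.

    ``df`` columns: ``marker_id``, ``chrom``, ``pos`` (1-based), ``ref``,
    ``alt``, ``fragment_id`` (object; ``None`` when unassigned).
    """

    df: pd.DataFrame

    REQUIRED = ("marker_id", "chrom", "pos", "ref", "alt")

    def __post_init__(self) -> None:
        df = self.df
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ConsistencyError(f"marker table lacks column {col!r}")
        if "fragment_id" not in df.columns:
            df = df.assign(fragment_id=None)
        df = df.reset_index(drop=True)
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ConsistencyError(f"duplicate marker_id {dup!r}")
        if (df["pos"].astype(int) <= 0).any():
            raise ConsistencyError("marker positions must be strictly positive")
        if df.duplicated(subset=["chrom", "pos"]).any():
            row = df[df.duplicated(subset=["chrom", "pos"])].iloc[0]
            raise ConsistencyError(
                f"duplicate (chromosome, position) = ({row['chrom']}, {row['pos']})"
            )
        same = df["ref"].astype(str) == df["alt"].astype(str)
        if same.any():
            raise BiallelicViolationError(
                f"marker {df.loc[same, 'marker_id'].iloc[0]!r} has identical ref and alt"
            )
        self.df = df

    @property
    def marker_ids(self) -> list[str]:
        return self.df["marker_id"].tolist()

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class FragmentTable:
    """Gene-fragment intervals, 0-based half-open (BED convention)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        for col in ("fragment_id", "chrom", "start", "end"):
            if col not in df.columns:
                raise ConsistencyError(f"fragment table lacks column {col!r}")
        if df["fragment_id"].duplicated().any():
            dup = df.loc[df["fragment_id"].duplicated(), "fragment_id"].iloc[0]
            raise ConsistencyError(f"duplicate fragment_id {dup!r}")
        if (df["start"].astype(int) >= df["end"].astype(int)).any():
            bad = df[df["start"].astype(int) >= df["end"].astype(int)].iloc[0]
            raise ConsistencyError(f"fragment {bad['fragment_id']!r} has start >= end")
        df["length_bp"] = df["end"].astype(int) - df["start"].astype(int)
        self.df = df

    @property
    def fragment_ids(self) -> list[str]:
        return self.df["fragment_id"].tolist()

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class GenotypeMatrix:
    """Unphased diploid biallelic calls for accessions × markers.

    ``dosage[i, j]`` counts copies of the alternate allele of marker *j* in
    accession *i* (0, 1 or 2), with :data:`MISSING` (−1) for no-calls.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.accession_ids = list(self.accession_ids)
        self.marker_ids = list(self.marker_ids)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ConsistencyError("accession ids are not unique")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ConsistencyError("marker ids are not unique")
        if self.dosage.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise ConsistencyError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.accession_ids)} accessions × {len(self.marker_ids)} markers"
            )
        ok = (self.dosage >= MISSING) & (self.dosage <= 2)
        if not ok.all():
            raise ConsistencyError("dosage values must be in {-1, 0, 1, 2}")
        self._acc_index = {a: i for i, a in enumerate(self.accession_ids)}
        self._marker_index = {m: j for j, m in enumerate(self.marker_ids)}

    # -- shape & lookup ----------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def accession_indices(self, accessions: Iterable[str]) -> np.ndarray:
        return np.array([self._acc_index[a] for a in accessions], dtype=int)

    def marker_indices(self, markers: Iterable[str]) -> np.ndarray:
        return np.array([self._marker_index[m] for m in markers], dtype=int)

    def row(self, accession: str) -> np.ndarray:
        return self.dosage[self._acc_index[accession]]

    def subset(
        self,
        accessions: Sequence[str] | None = None,
        markers: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        acc = list(accessions) if accessions is not None else self.accession_ids
        mk = list(markers) if markers is not None else self.marker_ids
        d = self.dosage[np.ix_(self.accession_indices(acc), self.marker_indices(mk))]
        return GenotypeMatrix(acc, mk, d.copy())

    # -- views -------------------------------------------------------------

    @property
    def is_missing(self) -> np.ndarray:
        return self.dosage == MISSING

    @property
    def is_het(self) -> np.ndarray:
        return self.dosage == 1

    def pair_view(self, markers: MarkerTable) -> pd.DataFrame:
        """Genotypes as two-letter allele strings (``'AC'``), ``'NA'`` missing."""
        mdf = markers.df.set_index("marker_id").loc[self.marker_ids]
        ref = mdf["ref"].to_numpy(dtype=object)
        alt = mdf["alt"].to_numpy(dtype=object)
        out = np.empty(self.dosage.shape, dtype=object)
        for j in range(self.n_markers):
            col = self.dosage[:, j]
            lut = {
                0: ref[j] + ref[j],
                1: "".join(sorted((ref[j], alt[j]))),
                2: alt[j] + alt[j],
                MISSING: "NA",
            }
            out[:, j] = [lut[int(v)] for v in col]
        return pd.DataFrame(out, index=self.accession_ids, columns=self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=self.accession_ids, columns=self.marker_ids
        )


@dataclass
class TaxonMap:
    """Accession → taxon assignment with REFERENCE/TEST roles."""

    df: pd.DataFrame
    taxa: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        for col in ("accession_id", "taxon", "role"):
            if col not in df.columns:
                raise ConsistencyError(f"taxon map lacks column {col!r}")
        if df["accession_id"].duplicated().any():
            raise ConsistencyError("duplicate accession in taxon map")
        bad = df["role"].isin([REFERENCE, TEST])
        if not bad.all():
            raise ConfigurationError(
                f"unknown role {df.loc[~bad, 'role'].iloc[0]!r}"
            )
        ref_no_taxon = (df["role"] == REFERENCE) & df["taxon"].isna()
        if ref_no_taxon.any():
            raise ConfigurationError(
                f"reference accession {df.loc[ref_no_taxon, 'accession_id'].iloc[0]!r}"
                " has no taxon"
            )
        if not self.taxa:
            self.taxa = tuple(
                sorted(df.loc[df["role"] == REFERENCE, "taxon"].dropna().unique())
            )
        for t in self.taxa:
            if not ((df["taxon"] == t) & (df["role"] == REFERENCE)).any():
                raise ConfigurationError(f"taxon {t!r} has no reference accession")
        unknown = df["taxon"].dropna()[~df["taxon"].dropna().isin(self.taxa)]
        if len(unknown):
            raise ConfigurationError(f"unknown taxon label {unknown.iloc[0]!r}")
        self.df = df

    def references(self, taxon: str) -> list[str]:
        m = (self.df["taxon"] == taxon) & (self.df["role"] == REFERENCE)
        return self.df.loc[m, "accession_id"].tolist()

    def reference_groups(self) -> dict[str, list[str]]:
        return {t: self.references(t) for t in self.taxa}

    @property
    def test_accessions(self) -> list[str]:
        return self.df.loc[self.df["role"] == TEST, "accession_id"].tolist()

    def taxon_of(self, accession: str) -> str | None:
        row = self.df.loc[self.df["accession_id"] == accession]
        if row.empty:
            return None
        t = row["taxon"].iloc[0]
        return None if pd.isna(t) else t


# ---------------------------------------------------------------------------
# genotype-string normalisation
# ---------------------------------------------------------------------------


def parse_genotype_string(cell: str) -> tuple[str, str] | None:
    """Normalise one genotype cell to an unordered allele pair.

    Accepts two-letter strings (``'AC'``), slash-separated (``'A/C'``),
    IUPAC heterozygous single letters (``'M'`` → A/C), homozygous single
    letters (``'A'``), and the missing codes in :data:`MISSING_CODES`.
    Returns ``None`` for missing.
    """
    s = str(cell).strip().upper()
    if s in MISSING_CODES:
        return None
    if "/" in s or "|" in s:
        parts = [p for p in s.replace("|", "/").split("/") if p]
        if len(parts) != 2:
            raise ParseError(f"cannot parse genotype {cell!r}")
        a, b = parts
    elif len(s) == 1:
        if s in IUPAC_HET:
            a, b = IUPAC_HET[s]
        else:
            a = b = s
    elif len(s) == 2:
        a, b = s[0], s[1]
    else:
        raise ParseError(f"cannot parse genotype {cell!r}")
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def pair_to_dosage(pair: tuple[str, str] | None, ref: str, alt: str, marker: str) -> int:
    """Dosage of ``alt`` in an allele pair; MISSING for ``None``."""
    if pair is None:
        return MISSING
    d = 0
    for a in pair:
        if a == alt:
            d += 1
        elif a != ref:
            raise BiallelicViolationError(
                f"marker {marker!r}: observed allele {a!r} not in ({ref!r}, {alt!r})"
            )
    return d


def dosage_to_pair(d: int, ref: str, alt: str) -> tuple[str, str] | None:
    if d == MISSING:
        return None
    return tuple(sorted([ref] * (2 - d) + [alt] * d))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _assign_fragments(markers: MarkerTable, fragments: FragmentTable) -> MarkerTable:
    """Attach fragment ids by interval lookup (1-based pos vs half-open BED)."""
    mdf = markers.df.copy()
    fdf = fragments.df
    assigned: list[object] = []
    for _, row in mdf.iterrows():
        pos0 = int(row["pos"]) - 1  # convert once: 1-based → 0-based
        hit = fdf[
            (fdf["chrom"] == row["chrom"])
            & (fdf["start"].astype(int) <= pos0)
            & (pos0 < fdf["end"].astype(int))
        ]
        if row.get("fragment_id") is not None and not pd.isna(row.get("fragment_id")):
            frag = fdf[fdf["fragment_id"] == row["fragment_id"]]
            if frag.empty:
                raise ConsistencyError(
                    f"marker {row['marker_id']!r} assigned to unknown fragment"
                    f" {row['fragment_id']!r}"
                )
            if frag["chrom"].iloc[0] != row["chrom"]:
                raise ConsistencyError(
                    f"marker {row['marker_id']!r} on {row['chrom']} but fragment"
                    f" {row['fragment_id']!r} on {frag['chrom'].iloc[0]}"
                )
            if not (
                int(frag["start"].iloc[0]) <= pos0 < int(frag["end"].iloc[0])
            ):
                raise ConsistencyError(
                    f"marker {row['marker_id']!r} at pos {row['pos']} outside"
                    f" fragment {row['fragment_id']!r}"
                )
            assigned.append(row["fragment_id"])
        elif not hit.empty:
            assigned.append(hit["fragment_id"].iloc[0])
        else:
            assigned.append(None)
    mdf["fragment_id"] = assigned
    return MarkerTable(mdf)


def load_fragments_bed(path: str | os.PathLike) -> FragmentTable:
    """Read BED3+name fragment intervals."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln}: BED needs chrom/start/end/name")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer interval") from exc
            rows.append(
                {"fragment_id": parts[3], "chrom": parts[0], "start": start, "end": end}
            )
    return FragmentTable(pd.DataFrame(rows))


def _load_genotypes_tsv(
    path: str | os.PathLike, markers: MarkerTable | None
) -> tuple[GenotypeMatrix, MarkerTable]:
    try:
        wide = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse genotype TSV {path}: {exc}") from exc
    marker_ids = [str(c) for c in wide.columns]
    accession_ids = [str(i) for i in wide.index]

    pairs: dict[str, list[tuple[str, str] | None]] = {}
    for m in marker_ids:
        col = []
        for acc in accession_ids:
            try:
                col.append(parse_genotype_string(wide.loc[acc, m]))
            except ParseError as exc:
                raise ParseError(f"{path}: accession {acc!r}, marker {m!r}: {exc}")
            # noqa: E722 — re-raise with location
        pairs[m] = col

    if markers is None:
        # infer ref/alt from observed alleles; >2 observed alleles is an error
        rows = []
        for j, m in enumerate(marker_ids):
            seen: set[str] = set()
            for p in pairs[m]:
                if p is not None:
                    seen.update(p)
            alleles = sorted(seen)  # deterministic: ref = alphabetically first
            if len(alleles) > 2:
                raise BiallelicViolationError(
                    f"marker {m!r} shows {len(alleles)} alleles: {sorted(alleles)}"
                )
            while len(alleles) < 2:  # monomorphic / empty column still biallelic model
                for cand in "ACGT":
                    if cand not in alleles:
                        alleles.append(cand)
                        break
            rows.append(
                {
                    "marker_id": m,
                    "chrom": "un",
                    "pos": j + 1,
                    "ref": alleles[0],
                    "alt": alleles[1],
                    "fragment_id": None,
                }
            )
        markers = MarkerTable(pd.DataFrame(rows))
    else:
        missing_meta = [m for m in marker_ids if m not in set(markers.marker_ids)]
        if missing_meta:
            raise ConsistencyError(
                f"genotype TSV marker {missing_meta[0]!r} absent from marker table"
            )
        markers = MarkerTable(
            markers.df.set_index("marker_id").loc[marker_ids].reset_index()
        )

    mdf = markers.df.set_index("marker_id")
    dosage = np.empty((len(accession_ids), len(marker_ids)), dtype=np.int8)
    for j, m in enumerate(marker_ids):
        ref, alt = str(mdf.loc[m, "ref"]), str(mdf.loc[m, "alt"])
        dosage[:, j] = [pair_to_dosage(p, ref, alt, m) for p in pairs[m]]
    return GenotypeMatrix(accession_ids, marker_ids, dosage), markers


def _load_genotypes_vcf(path: str | os.PathLike) -> tuple[GenotypeMatrix, MarkerTable]:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ParseError("cyvcf2 is required to read VCF input") from exc
    vcf = VCF(str(path))
    accession_ids = list(vcf.samples)
    marker_rows = []
    dosage_cols = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise BiallelicViolationError(
                f"marker at {variant.CHROM}:{variant.POS} has alleles"
                f" {[variant.REF] + list(variant.ALT)}; biallelic model"
            )
        mid = variant.ID if variant.ID not in (None, ".", "") else (
            f"{variant.CHROM}_{variant.POS}"
        )
        marker_rows.append(
            {
                "marker_id": mid,
                "chrom": variant.CHROM,
                "pos": int(variant.POS),
                "ref": variant.REF,
                "alt": variant.ALT[0],
                "fragment_id": None,
            }
        )
        col = np.empty(len(accession_ids), dtype=np.int8)
        for i, g in enumerate(variant.genotypes):
            a, b = int(g[0]), int(g[1])
            col[i] = MISSING if (a < 0 or b < 0) else a + b
        dosage_cols.append(col)
    markers = MarkerTable(pd.DataFrame(marker_rows))
    dosage = (
        np.stack(dosage_cols, axis=1)
        if dosage_cols
        else np.empty((len(accession_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(accession_ids, markers.marker_ids, dosage), markers


def load_dataset(
    genotype_path: str | os.PathLike,
    format: str = "tsv",
    fragments_path: str | os.PathLike | None = None,
    markers_path: str | os.PathLike | None = None,
) -> tuple[GenotypeMatrix, MarkerTable, FragmentTable | None]:
    """Load genotypes plus marker metadata, optionally assigning fragments.

    ``format`` is ``'vcf'`` or ``'tsv'``.  For TSV input, per-marker
    metadata may be supplied via ``markers_path`` (TSV with columns
    marker_id, chrom, pos, ref, alt); otherwise alleles are inferred from
    the observed calls.  Markers falling outside every fragment keep
    ``fragment_id = None``.
    """
    if format == "vcf":
        G, markers = _load_genotypes_vcf(genotype_path)
    elif format == "tsv":
        side = None
        if markers_path is not None:
            mdf = pd.read_csv(markers_path, sep="\t", dtype={"chrom": str})
            side = MarkerTable(mdf)
        G, markers = _load_genotypes_tsv(genotype_path, side)
    else:
        raise ConfigurationError(f"unknown genotype format {format!r}")

    fragments: FragmentTable | None = None
    if fragments_path is not None:
        fragments = load_fragments_bed(fragments_path)
        markers = _assign_fragments(markers, fragments)
    return G, markers, fragments


def load_taxon_map(
    path: str | os.PathLike,
    taxa: Sequence[str],
    genotype_accessions: Sequence[str] | None = None,
) -> TaxonMap:
    """Read a two/three-column accession/taxon[/role] TSV.

    Role defaults to REFERENCE when a taxon is given and TEST otherwise.
    Accessions absent from the genotype matrix are logged as warnings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ParseError(f"{path}: taxon map needs ≥2 columns")
    out = pd.DataFrame(
        {
            "accession_id": df[cols[0]].astype(str),
            "taxon": df[cols[1]].replace("", None),
        }
    )
    if len(cols) >= 3:
        role = df[cols[2]].str.upper().replace("", None)
        out["role"] = role
    else:
        out["role"] = None
    out["role"] = out["role"].where(
        out["role"].notna(), out["taxon"].map(lambda t: TEST if t is None else REFERENCE)
    )
    tm = TaxonMap(out, taxa=tuple(taxa))
    if genotype_accessions is not None:
        missing = set(out["accession_id"]) - set(genotype_accessions)
        for acc in sorted(missing):
            logger.warning("taxon map accession %r absent from genotype matrix", acc)
    return tm


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_tables(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a result table as tab-separated UTF-8 with header.

    Missing values are encoded as ``NA``; floats keep 12 significant
    digits so a round-trip reproduces them.  Writes via a temporary file
    and rename so readers never observe a partial table.
    """
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    records.to_csv(
        tmp, sep="\t", index=False, na_rep="NA", float_format="%.17g", encoding="utf-8"
    )
    os.replace(tmp, path)


def write_genotypes_tsv(
    G: GenotypeMatrix, markers: MarkerTable, path: str | os.PathLike
) -> None:
    wide = G.pair_view(markers)
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    wide.to_csv(tmp, sep="\t", index_label="accession_id", encoding="utf-8")
    os.replace(tmp, path)


def write_markers_tsv(markers: MarkerTable, path: str | os.PathLike) -> None:
    write_tables(markers.df, path)


def write_fragments_bed(fragments: FragmentTable, path: str | os.PathLike) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        for _, r in fragments.df.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t{r['fragment_id']}\n")
    os.replace(tmp, path)


def write_taxon_map_tsv(tm: TaxonMap, path: str | os.PathLike) -> None:
    write_tables(tm.df[["accession_id", "taxon", "role"]], path)


def write_vcf(
    G: GenotypeMatrix, markers: MarkerTable, path: str | os.PathLike
) -> None:
    """Write a minimal VCF v4.2 with GT-only FORMAT."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    mdf = markers.df.set_index("marker_id").loc[G.marker_ids]
    # records sorted by (chrom, pos) as VCF expects
    sorted_ids = [G.marker_ids[i] for i in np.lexsort(
        (mdf["pos"].to_numpy(), mdf["chrom"].astype(str).to_numpy())
    )]
    with open(tmp, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(mdf["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.accession_ids)
            + "\n"
        )
        gt_lut = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for mid in sorted_ids:
            j = G.marker_indices([mid])[0]
            r = mdf.loc[mid]
            calls = "\t".join(gt_lut[int(v)] for v in G.dosage[:, j])
            fh.write(
                f"{r['chrom']}\t{int(r['pos'])}\t{mid}\t{r['ref']}\t{r['alt']}"
                f"\t.\t.\t.\tGT\t{calls}\n"
            )
    os.replace(tmp, path)
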