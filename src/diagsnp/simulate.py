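"""Synthetic diploid genotype scenarios with planted truth.

The generator emulates the statistical structure the mining pipeline
assumes: a handful of strongly differentiated ancestral taxa genotyped at
SNPs grouped into short gene fragments along a small set of chromosomes.
Each marker is assigned a generating class:

* ``fixed_difference`` — diagnostic allele at frequency 1 in one focal
  taxon, 0 elsewhere (the planted diagnostics);
* ``private_polymorphism`` — a minor allele segregating in exactly one
  taxon (folded Beta frequency ≤ 0.5), absent elsewhere;
* ``split_difference`` — fixed for alternative alleles across a balanced
  bipartition of the taxa (two-vs-two for four taxa): strongly
  pair-differential but diagnostic for no single taxon;
* ``shared_polymorphism`` — a minor allele segregating in two or more taxa;
* ``monomorphic``.

Reference accessions are drawn under Hardy–Weinberg within taxon as two
independent haplotypes per individual, so crosses can transmit whole
fragments (free recombination between fragments, none within — at the
~500 bp amplicon scale intra-fragment recombination is negligible).
Interspecific introgression is injected by replacing one haplotype of a
target reference accession with a freshly drawn donor haplotype over a
random subset of fragments, producing the donor-heterozygous signature.

Every planted feature is recorded in a truth table; identical configs
(including the seed) regenerate byte-identical outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (
    MISSING,
    REFERENCE,
    TEST,
    FragmentTable,
    GenotypeMatrix,
    MarkerTable,
    TaxonMap,
    write_fragments_bed,
    write_genotypes_tsv,
    write_markers_tsv,
    write_tables,
    write_taxon_map_tsv,
)

FIXED_DIFFERENCE = "fixed_difference"
PRIVATE_POLYMORPHISM = "private_polymorphism"
SPLIT_DIFFERENCE = "split_difference"
SHARED_POLYMORPHISM = "shared_polymorphism"
MONOMORPHIC = "monomorphic"


@dataclass(frozen=True)
class HybridSpec:
    """A pedigree entry; parents are accession ids or earlier hybrid names."""

    name: str
    parent_a: str
    parent_b: str


@dataclass(frozen=True)
class IntrogressionSpec:
    """Donor-heterozygous fragments injected into one reference accession."""

    accession: str
    donor_taxon: str
    fraction_of_fragments: float = 0.2


@dataclass
class ScenarioConfig:
    """Study design for one synthetic dataset.

    Defaults mirror the reference design the pipeline targets: four
    ancestral taxa sampled 11/9/5/1, 57 ~500 bp gene fragments over nine
    chromosomes with ~18 SNPs each, and a marker-class mix giving ≈30%
    planted fixed differences, strong pairwise haplotype divergence
    (≈0.45, hence interspecific fragment heterozygosity near one half)
    and low within-taxon heterozygosity (a few percent).
    """

    taxa: tuple[str, ...] = ("mandarin", "pummelo", "citron", "papeda")
    accessions_per_taxon: Mapping[str, int] | int = field(
        default_factory=lambda: {"mandarin": 11, "pummelo": 9, "citron": 5, "papeda": 1}
    )
    n_chromosomes: int = 9
    fragments_per_chromosome: tuple[int, ...] | int = (7, 7, 7, 6, 6, 6, 6, 6, 6)
    markers_per_fragment: int = 18
    fragment_length_bp: int = 500
    fixed_diff_fraction: float = 0.075  # per taxon
    private_polymorphism_fraction: float = 0.06  # per taxon
    split_difference_fraction: float = 0.40
    shared_polymorphism_fraction: float = 0.03
    maf_beta: tuple[float, float] = (0.5, 3.0)
    missing_rate: float = 0.02
    hybrids: tuple[HybridSpec, ...] = ()
    introgressions: tuple[IntrogressionSpec, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.taxa)
        if k < 2:
            raise ConfigurationError("need at least two taxa")
        if isinstance(self.accessions_per_taxon, int):
            self.accessions_per_taxon = {t: self.accessions_per_taxon for t in self.taxa}
        if set(self.accessions_per_taxon) != set(self.taxa):
            raise ConfigurationError("accessions_per_taxon must cover every taxon")
        if isinstance(self.fragments_per_chromosome, int):
            self.fragments_per_chromosome = tuple(
                [self.fragments_per_chromosome] * self.n_chromosomes
            )
        if len(self.fragments_per_chromosome) != self.n_chromosomes:
            raise ConfigurationError(
                "fragments_per_chromosome length must equal n_chromosomes"
            )
        for f in (
            self.fixed_diff_fraction,
            self.private_polymorphism_fraction,
            self.split_difference_fraction,
            self.shared_polymorphism_fraction,
            self.missing_rate,
        ):
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError("fractions must lie in [0, 1]")
        total = k * (self.fixed_diff_fraction + self.private_polymorphism_fraction) + (
            self.split_difference_fraction + self.shared_polymorphism_fraction
        )
        if total > 1.0 + 1e-12:
            raise ConfigurationError(
                f"marker-class fractions sum to {total:.3f} > 1"
            )

    @property
    def n_fragments(self) -> int:
        return int(sum(self.fragments_per_chromosome))

    @property
    def n_markers(self) -> int:
        return self.n_fragments * self.markers_per_fragment

    def reference_names(self) -> dict[str, list[str]]:
        return {
            t: [f"{t}_{i + 1:02d}" for i in range(self.accessions_per_taxon[t])]
            for t in self.taxa
        }


# ---------------------------------------------------------------------------
# stage 1: coordinates and frequencies
# ---------------------------------------------------------------------------


def _layout(config: ScenarioConfig, rng: np.random.Generator):
    """Fragments and marker coordinates."""
    frag_rows, marker_rows = [], []
    for ci, nfrag in enumerate(config.fragments_per_chromosome, start=1):
        chrom = f"chr{ci}"
        for fj in range(1, nfrag + 1):
            fid = f"C{ci}P{fj}"
            start = (fj - 1) * 10_000  # 0-based half-open
            end = start + config.fragment_length_bp
            frag_rows.append(
                {"fragment_id": fid, "chrom": chrom, "start": start, "end": end}
            )
            pos0 = rng.choice(
                config.fragment_length_bp,
                size=config.markers_per_fragment,
                replace=False,
            )
            for p in np.sort(pos0):
                pos = start + int(p) + 1  # 1-based
                marker_rows.append(
                    {
                        "marker_id": f"{ci}p{pos}",
                        "chrom": chrom,
                        "pos": pos,
                        "ref": "A",
                        "alt": "C",
                        "fragment_id": fid,
                    }
                )
    return FragmentTable(pd.DataFrame(frag_rows)), MarkerTable(pd.DataFrame(marker_rows))


def _folded_maf(rng: np.random.Generator, shape, beta: tuple[float, float]) -> np.ndarray:
    f = rng.beta(*beta, size=shape)
    return np.minimum(f, 1.0 - f)


def sample_taxon_frequencies(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-taxon alternate-allele frequencies and the marker truth table.

    Returns ``(freqs, truth)`` where ``freqs`` has one column per taxon
    indexed by marker ordinal and ``truth`` records each marker's
    generating class and focal taxon (where applicable).
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(1)[0])
    k = len(config.taxa)
    m = config.n_markers
    classes = (
        [(FIXED_DIFFERENCE, t) for t in config.taxa]
        + [(PRIVATE_POLYMORPHISM, t) for t in config.taxa]
        + [(SPLIT_DIFFERENCE, None), (SHARED_POLYMORPHISM, None), (MONOMORPHIC, None)]
    )
    probs = (
        [config.fixed_diff_fraction] * k
        + [config.private_polymorphism_fraction] * k
        + [
            config.split_difference_fraction,
            config.shared_polymorphism_fraction,
            max(
                0.0,
                1.0
                - k
                * (config.fixed_diff_fraction + config.private_polymorphism_fraction)
                - config.split_difference_fraction
                - config.shared_polymorphism_fraction,
            ),
        ]
    )
    probs = np.asarray(probs) / np.sum(probs)
    draw = rng.choice(len(classes), size=m, p=probs)

    p = np.zeros((k, m))
    truth_class, truth_taxon = [], []
    for j, ci in enumerate(draw):
        cls, taxon = classes[int(ci)]
        truth_class.append(cls)
        truth_taxon.append(taxon)
        if cls == FIXED_DIFFERENCE:
            p[config.taxa.index(taxon), j] = 1.0
        elif cls == PRIVATE_POLYMORPHISM:
            p[config.taxa.index(taxon), j] = _folded_maf(rng, None, config.maf_beta)
        elif cls == SPLIT_DIFFERENCE:
            if k >= 4:
                side = rng.permutation(k)[: k // 2]
            else:  # degenerate for K<4: one taxon vs rest is already "fixed diff"
                side = rng.permutation(k)[:1]
            p[side, j] = 1.0
        elif cls == SHARED_POLYMORPHISM:
            n_in = int(rng.integers(2, k + 1))
            side = rng.permutation(k)[:n_in]
            p[side, j] = _folded_maf(rng, len(side), config.maf_beta)
        # monomorphic: all zeros
    freqs = pd.DataFrame(p.T, columns=list(config.taxa))
    truth = pd.DataFrame({"true_class": truth_class, "true_taxon": truth_taxon})
    return freqs, truth


# ---------------------------------------------------------------------------
# stage 2: accessions, crosses, introgression
# ---------------------------------------------------------------------------


@dataclass
class SimAccession:
    """One simulated individual: two haplotypes plus per-fragment origins."""

    name: str
    haplotypes: np.ndarray  # (2, M) 0/1
    origins: np.ndarray  # (2, F) taxon labels (object)

    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0).astype(np.int8)

    def genome_fractions(self, taxa: Sequence[str]) -> dict[str, float]:
        flat = self.origins.ravel()
        return {t: float(np.mean(flat == t)) for t in taxa}


def sample_reference_accessions(
    freqs: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> dict[str, SimAccession]:
    """Hardy–Weinberg reference individuals per taxon (two iid haplotypes)."""
    out: dict[str, SimAccession] = {}
    n_frag = config.n_fragments
    for t, names in config.reference_names().items():
        p = freqs[t].to_numpy()
        for name in names:
            haps = (rng.random((2, len(p))) < p[None, :]).astype(np.int8)
            origins = np.full((2, n_frag), t, dtype=object)
            out[name] = SimAccession(name, haps, origins)
    return out


def _gamete(
    parent: SimAccession, frag_slices: list[np.ndarray], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: whole-fragment transmission, free between-fragment recombination."""
    m = parent.haplotypes.shape[1]
    hap = np.empty(m, dtype=np.int8)
    origin = np.empty(len(frag_slices), dtype=object)
    picks = rng.integers(0, 2, size=len(frag_slices))
    for fi, cols in enumerate(frag_slices):
        hap[cols] = parent.haplotypes[picks[fi], cols]
        origin[fi] = parent.origins[picks[fi], fi]
    return hap, origin


def make_cross(
    parent_a: SimAccession,
    parent_b: SimAccession,
    frag_slices: list[np.ndarray],
    rng: np.random.Generator,
    name: str = "cross",
) -> SimAccession:
    """Offspring of two simulated individuals (one gamete from each)."""
    ha, oa = _gamete(parent_a, frag_slices, rng)
    hb, ob = _gamete(parent_b, frag_slices, rng)
    return SimAccession(name, np.stack([ha, hb]), np.stack([oa, ob]))


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------


@dataclass
class TruthTable:
    markers: pd.DataFrame  # marker_id, fragment_id, true_class, true_taxon
    accessions: pd.DataFrame  # accession_id, pedigree, frac_<taxon>…
    introgressions: pd.DataFrame  # accession, fragment, donor_taxon


@dataclass
class SimulatedDataset:
    """A generated scenario plus its planted truth and raw haplotypes."""

    config: ScenarioConfig
    genotypes: GenotypeMatrix
    markers: MarkerTable
    fragments: FragmentTable
    taxon_map: TaxonMap
    truth: TruthTable
    taxon_freqs: pd.DataFrame
    individuals: dict[str, SimAccession]
    frag_slices: list[np.ndarray]

    def cross(
        self,
        parent_a: str | SimAccession,
        parent_b: str | SimAccession,
        rng: np.random.Generator,
        name: str = "cross",
    ) -> SimAccession:
        """Simulate an offspring without mutating the dataset."""
        pa = self.individuals[parent_a] if isinstance(parent_a, str) else parent_a
        pb = self.individuals[parent_b] if isinstance(parent_b, str) else parent_b
        return make_cross(pa, pb, self.frag_slices, rng, name)

    def with_accessions(self, extra: Sequence[SimAccession]) -> GenotypeMatrix:
        """Genotype matrix extended with additional simulated individuals."""
        names = list(self.genotypes.accession_ids) + [a.name for a in extra]
        rows = np.vstack(
            [self.genotypes.dosage] + [a.dosage()[None, :] for a in extra]
        )
        return GenotypeMatrix(names, list(self.genotypes.marker_ids), rows)

    def write(self, outdir: str | os.PathLike) -> dict[str, Path]:
        """Write genotypes/markers/fragments/taxon map/truth as text files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genotypes": outdir / "genotypes.tsv",
            "markers": outdir / "markers.tsv",
            "fragments": outdir / "fragments.bed",
            "taxon_map": outdir / "taxon_map.tsv",
            "truth_markers": outdir / "truth_markers.tsv",
            "truth_accessions": outdir / "truth_accessions.tsv",
            "truth_introgressions": outdir / "truth_introgressions.tsv",
        }
        write_genotypes_tsv(self.genotypes, self.markers, paths["genotypes"])
        write_markers_tsv(self.markers, paths["markers"])
        write_fragments_bed(self.fragments, paths["fragments"])
        write_taxon_map_tsv(self.taxon_map, paths["taxon_map"])
        write_tables(self.truth.markers, paths["truth_markers"])
        write_tables(self.truth.accessions, paths["truth_accessions"])
        write_tables(self.truth.introgressions, paths["truth_introgressions"])
        return paths


def build_scenario(config: ScenarioConfig) -> SimulatedDataset:
    """Compose frequencies, reference sampling, pedigree crosses and
    introgression injection into one dataset with truth tables."""
    ss = np.random.SeedSequence(config.rng_seed).spawn(5)
    rng_layout, rng_freq, rng_ref, rng_ped, rng_missing = (
        np.random.default_rng(s) for s in ss
    )

    fragments, markers = _layout(config, rng_layout)
    freqs, marker_truth = sample_taxon_frequencies(config, rng_freq)
    marker_truth = marker_truth.assign(
        marker_id=markers.marker_ids,
        fragment_id=markers.df["fragment_id"].to_numpy(),
    )[["marker_id", "fragment_id", "true_class", "true_taxon"]]

    frag_ids = fragments.fragment_ids
    mdf = markers.df
    frag_slices = [
        np.flatnonzero((mdf["fragment_id"] == fid).to_numpy()) for fid in frag_ids
    ]

    individuals = sample_reference_accessions(freqs, config, rng_ref)

    # pedigree crosses, in declaration order
    for spec in config.hybrids:
        for parent in (spec.parent_a, spec.parent_b):
            if parent not in individuals:
                raise ConfigurationError(
                    f"hybrid {spec.name!r} references unknown accession {parent!r}"
                )
        individuals[spec.name] = make_cross(
            individuals[spec.parent_a],
            individuals[spec.parent_b],
            frag_slices,
            rng_ped,
            spec.name,
        )

    # introgression injection: one donor haplotype over a random fragment set
    intro_rows = []
    for spec in config.introgressions:
        if spec.accession not in individuals:
            raise ConfigurationError(
                f"introgression targets unknown accession {spec.accession!r}"
            )
        if spec.donor_taxon not in config.taxa:
            raise ConfigurationError(f"unknown donor taxon {spec.donor_taxon!r}")
        acc = individuals[spec.accession]
        n_aff = int(round(spec.fraction_of_fragments * len(frag_ids)))
        affected = rng_ped.choice(len(frag_ids), size=n_aff, replace=False)
        p_donor = freqs[spec.donor_taxon].to_numpy()
        for fi in np.sort(affected):
            cols = frag_slices[fi]
            donor_hap = (rng_ped.random(len(cols)) < p_donor[cols]).astype(np.int8)
            acc.haplotypes[1, cols] = donor_hap
            acc.origins[1, fi] = spec.donor_taxon
            intro_rows.append(
                {
                    "accession": spec.accession,
                    "fragment": frag_ids[int(fi)],
                    "donor_taxon": spec.donor_taxon,
                }
            )
    introgressions = pd.DataFrame(
        intro_rows, columns=["accession", "fragment", "donor_taxon"]
    )

    # genotype matrix with missingness
    names = list(individuals)
    dosage = np.stack([individuals[n].dosage() for n in names])
    if config.missing_rate > 0:
        mask = rng_missing.random(dosage.shape) < config.missing_rate
        dosage = np.where(mask, np.int8(MISSING), dosage)
    G = GenotypeMatrix(names, markers.marker_ids, dosage)

    # taxon map: references keep their taxon; pedigree offspring are TEST
    ref_names = config.reference_names()
    tm_rows = []
    for t in config.taxa:
        for n in ref_names[t]:
            tm_rows.append({"accession_id": n, "taxon": t, "role": REFERENCE})
    for spec in config.hybrids:
        tm_rows.append({"accession_id": spec.name, "taxon": None, "role": TEST})
    taxon_map = TaxonMap(pd.DataFrame(tm_rows), taxa=config.taxa)

    acc_rows = []
    pedigree = {s.name: f"{s.parent_a} × {s.parent_b}" for s in config.hybrids}
    for n in names:
        fr = individuals[n].genome_fractions(config.taxa)
        acc_rows.append(
            {"accession_id": n, "pedigree": pedigree.get(n, "reference"),
             **{f"frac_{t}": fr[t] for t in config.taxa}}
        )
    truth = TruthTable(marker_truth, pd.DataFrame(acc_rows), introgressions)

    return SimulatedDataset(
        config=config,
        genotypes=G,
        markers=markers,
        fragments=fragments,
        taxon_map=taxon_map,
        truth=truth,
        taxon_freqs=freqs,
        individuals=individuals,
        frag_slices=frag_slices,
    )
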