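"""End-to-end orchestration: simulate/load → stats → mine → mask → profile.

Every stage persists its artifacts as TSV in the output directory (written
via temp-file-and-rename, so files are never partial), and a serialized
copy of the resolved configuration is stored alongside.  Rerunning with
the same resolved configuration into a fresh directory reproduces the
artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .errors import ConfigurationError, DiagsnpError
from .io import (
    FragmentTable,
    GenotypeMatrix,
    MarkerTable,
    TaxonMap,
    load_dataset,
    load_taxon_map,
    write_tables,
)
from .masking import FlagParams, remine_with_mask
from .mining import build_panel, classify_markers, gst_all_taxa, proximity_filter
from .popgen import (
    group_report,
    simple_matching_dissimilarity,
    snp_density,
    taxon_frequencies,
    wc_fst,
)
from .profiling import admixture_profile, contribution_estimate, dosage_pca
from .simulate import ScenarioConfig, SimulatedDataset, build_scenario

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "stats", "mine", "mask", "profile")


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    outdir: str = "diagsnp_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # either a scenario...
    scenario: ScenarioConfig | None = None
    # ...or input files
    genotypes_path: str | None = None
    genotype_format: str = "tsv"
    markers_path: str | None = None
    fragments_path: str | None = None
    taxon_map_path: str | None = None
    taxa: tuple[str, ...] = ()
    # stage parameters (module defaults)
    gst_threshold: float = 0.9
    specific_max_gst: float = 0.5
    proximity_window: int = 50
    qc_threshold: float = 0.1
    het_threshold: float = 0.1
    min_differential_hets: int = 2
    differential_delta: float = 0.9
    passes: int = 1
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s) {sorted(unknown)}")
        if self.scenario is None and "simulate" in self.stages and (
            self.genotypes_path is None
        ):
            # default scenario keyed by the run seed
            self.scenario = ScenarioConfig(rng_seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        if isinstance(d.get("scenario"), dict):
            sd = dict(d["scenario"])
            from .simulate import HybridSpec, IntrogressionSpec

            if "hybrids" in sd:
                sd["hybrids"] = tuple(HybridSpec(**h) for h in sd["hybrids"])
            if "introgressions" in sd:
                sd["introgressions"] = tuple(
                    IntrogressionSpec(**i) for i in sd["introgressions"]
                )
            if "taxa" in sd:
                sd["taxa"] = tuple(sd["taxa"])
            d["scenario"] = ScenarioConfig(**sd)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "taxa" in d:
            d["taxa"] = tuple(d["taxa"])
        return cls(**d)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str, sort_keys=True)


@dataclass
class PipelineResult:
    outdir: Path
    genotypes: GenotypeMatrix
    markers: MarkerTable
    fragments: FragmentTable | None
    taxon_map: TaxonMap
    artifacts: dict[str, Path] = field(default_factory=dict)
    simulated: SimulatedDataset | None = None


def _resolve_inputs(config: RunConfig, outdir: Path):
    if "simulate" in config.stages and config.scenario is not None:
        ds = build_scenario(config.scenario)
        paths = ds.write(outdir / "data")
        logger.info(
            "stage=simulate accessions=%d markers=%d fragments=%d",
            ds.genotypes.n_accessions, ds.genotypes.n_markers, len(ds.fragments),
        )
        return ds.genotypes, ds.markers, ds.fragments, ds.taxon_map, ds, paths
    if config.genotypes_path is None or config.taxon_map_path is None:
        raise ConfigurationError(
            "either a scenario or genotypes_path + taxon_map_path is required"
        )
    G, markers, fragments = load_dataset(
        config.genotypes_path,
        format=config.genotype_format,
        fragments_path=config.fragments_path,
        markers_path=config.markers_path,
    )
    tm = load_taxon_map(
        config.taxon_map_path,
        taxa=config.taxa or (),
        genotype_accessions=G.accession_ids,
    )
    logger.info(
        "stage=load accessions=%d markers=%d", G.n_accessions, G.n_markers
    )
    return G, markers, fragments, tm, None, {}


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the configured stages in order, persisting every artifact."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.json").write_text(config.to_json())

    G, markers, fragments, taxon_map, simulated, artifacts = _resolve_inputs(
        config, outdir
    )
    result = PipelineResult(outdir, G, markers, fragments, taxon_map,
                            dict(artifacts), simulated)
    groups = taxon_map.reference_groups()

    def save(name: str, df: pd.DataFrame) -> None:
        p = outdir / f"{name}.tsv"
        write_tables(df, p)
        result.artifacts[name] = p

    if "stats" in config.stages:
        rep = group_report(G, groups)
        save("group_report", rep)
        fst_per_marker, fst_multi = wc_fst(G, groups)
        save("fst", fst_per_marker)
        D = simple_matching_dissimilarity(G)
        save("dissimilarity", D.to_frame().reset_index(names="accession_id"))
        if fragments is not None:
            per_frag, per_chrom, total = snp_density(markers, fragments)
            save("snp_density_fragment", per_frag)
            save("snp_density_chromosome", per_chrom)
        logger.info("stage=stats groups=%d multilocus_fst=%.4f", len(groups), fst_multi)

    panel = None
    if "mine" in config.stages:
        freqs = taxon_frequencies(G, groups)
        gst = gst_all_taxa(freqs)
        save("gst", gst)
        cls = classify_markers(
            gst, freqs, config.gst_threshold, config.specific_max_gst
        )
        save("classification", cls)
        panel = build_panel(cls, freqs, config.qc_threshold)
        save("panel", panel.table)
        save("panel_removed", panel.removed)
        retained, rejected = proximity_filter(
            list(panel.table["marker_id"]), markers, config.proximity_window
        )
        save("assay_candidates_rejected", rejected)
        save(
            "assay_candidates",
            pd.DataFrame({"marker_id": retained}),
        )
        logger.info(
            "stage=mine markers=%d panel=%d assayable=%d",
            G.n_markers, len(panel.table), len(retained),
        )

    if "mask" in config.stages:
        if fragments is None:
            raise ConfigurationError("mask stage requires fragment intervals")
        mres = remine_with_mask(
            G,
            taxon_map,
            markers,
            fragments,
            FlagParams(
                het_threshold=config.het_threshold,
                min_differential_hets=config.min_differential_hets,
                differential_delta=config.differential_delta,
            ),
            diagnostic_threshold=config.gst_threshold,
            specific_max_gst=config.specific_max_gst,
            qc_threshold=config.qc_threshold,
            passes=config.passes,
        )
        save("flags", mres.flags)
        save("gst_pre", mres.gst_pre)
        save("gst_post", mres.gst_post)
        save("delta_report", mres.delta_report)
        save("panel_post", mres.panel_post.table)
        if mres.ordination is not None:
            save(
                "pcoa_coords",
                mres.ordination.coordinates.reset_index(names="accession_id"),
            )
        panel = mres.panel_post
        logger.info(
            "stage=mask flags=%d dropped_markers=%d", len(mres.flags),
            len(mres.dropped_markers),
        )

    if "profile" in config.stages:
        if panel is None:
            freqs = taxon_frequencies(G, groups)
            gst = gst_all_taxa(freqs)
            cls = classify_markers(
                gst, freqs, config.gst_threshold, config.specific_max_gst
            )
            panel = build_panel(cls, freqs, config.qc_threshold)
        prof = contribution_estimate(admixture_profile(G, panel))
        save("profile", prof)
        panel_markers = [
            m for m in panel.table["marker_id"] if m in set(G.marker_ids)
        ]
        pca = dosage_pca(G, panel_markers or None)
        save("pca_coords", pca.coordinates.reset_index(names="accession_id"))
        logger.info(
            "stage=profile accessions=%d panel_markers=%d",
            G.n_accessions, len(panel_markers),
        )

    return result
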