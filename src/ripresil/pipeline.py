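"""End-to-end per-area workflow: rarefy -> aggregate -> diversity -> RS/RL
-> group tests -> co-occurrence network, driven by one config.

Every stage is a pure function of (inputs, config, seeds); a manifest
records seeds, thresholds, input checksums and output checksums so any
run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community_stats import pairwise_anosim
from .conetwork import build_network, export_network, filter_network_taxa, spearman_matrix, topology_summary
from .diversity import alpha_diversity, bray_curtis_matrix, rarefy
from .resilience import results_frame, rs_rl_profile, taxon_rs_rl
from .synthetic_data import SyntheticConfig, generate_dataset
from .tables_io import (
    CountTable,
    aggregate_to_rank,
    read_abundance_series,
    read_count_table,
    read_sample_metadata,
    relative_abundance,
)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

_ALPHA_METRICS = ("shannon", "chao1", "evenness")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending entity."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Exactly one of (``count_table_path`` + ``metadata_path``) or
    ``simulate`` must be set.  ``rarefaction_depth`` is an explicit integer
    or ``"min-sample"`` (rarefy to the shallowest sample).
    """

    count_table_path: str | None = None
    metadata_path: str | None = None
    abundance_path: str | None = None
    simulate: SyntheticConfig | None = None
    rarefaction_depth: int | str = "min-sample"
    network_rank: str = "genus"
    rho_min: float = 0.6
    p_max: float = 0.01
    min_prevalence: float = 1.0 / 3.0
    n_permutations: int = 999
    top_k_taxa: int = 4
    seed: int = 0
    out_dir: str = "ripresil_out"

    def validate(self) -> None:
        has_paths = self.count_table_path is not None
        if has_paths == (self.simulate is not None):
            raise ValueError(
                "config must provide exactly one of input paths or a simulate block"
            )
        if has_paths and self.metadata_path is None:
            raise ValueError("metadata_path is required with count_table_path")
        if isinstance(self.rarefaction_depth, str) and self.rarefaction_depth != "min-sample":
            raise ValueError('rarefaction_depth must be an integer or "min-sample"')

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("simulate") is not None:
            doc["simulate"] = SyntheticConfig.from_dict(doc["simulate"])
        return cls(**doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        dataset = generate_dataset(config.simulate)
        return dataset.table, dataset.metadata, dataset.abundance
    table = read_count_table(config.count_table_path)
    metadata = read_sample_metadata(config.metadata_path)
    abundance = (
        read_abundance_series(config.abundance_path)
        if config.abundance_path is not None
        else None
    )
    return table, metadata, abundance


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Per area the bundle holds: alpha-diversity TSV, RS/RL TSV (total
    abundance, Shannon, Chao1, evenness, top-k taxa), pairwise ANOSIM TSV,
    network GEXF + edge TSV + topology TSV, and a run manifest.  Returns
    the manifest dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "ripresil_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "rho_min": config.rho_min,
            "p_max": config.p_max,
            "min_prevalence": config.min_prevalence,
        },
        "n_permutations": config.n_permutations,
        "rarefaction_depth": config.rarefaction_depth,
        "network_rank": config.network_rank,
        "inputs": {},
        "outputs": {},
        "warnings": [],
    }
    ss = np.random.SeedSequence(config.seed)
    seed_rarefy, seed_anosim, seed_modularity = (
        int(np.random.default_rng(child).integers(2**31)) for child in ss.spawn(3)
    )
    manifest["derived_seeds"] = {
        "rarefy": seed_rarefy, "anosim": seed_anosim, "modularity": seed_modularity,
    }

    # ---- load ---------------------------------------------------------
    try:
        table, metadata, abundance = _load_inputs(config)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError("load", str(exc)) from exc
    for key, path in (
        ("count_table", config.count_table_path),
        ("metadata", config.metadata_path),
        ("abundance", config.abundance_path),
    ):
        if path is not None:
            manifest["inputs"][key] = {"path": path, "sha256": _sha256(Path(path))}
    if config.simulate is not None:
        manifest["inputs"]["simulate"] = config.simulate.to_dict()

    missing_meta = [s for s in table.sample_ids if s not in metadata.index]
    if missing_meta:
        raise PipelineError("load", f"samples without metadata rows: {missing_meta}")

    # ---- rarefy -------------------------------------------------------
    try:
        depth = (
            int(table.sample_sums.min())
            if config.rarefaction_depth == "min-sample"
            else int(config.rarefaction_depth)
        )
        rarefied = rarefy(table, depth, seed=seed_rarefy, drop_shallow=True)
    except Exception as exc:
        raise PipelineError("rarefy", str(exc)) from exc
    manifest["rarefaction_depth_used"] = depth

    # ---- alpha diversity ---------------------------------------------
    try:
        alpha = alpha_diversity(rarefied)
    except Exception as exc:
        raise PipelineError("diversity", str(exc)) from exc
    alpha_path = out / "alpha_diversity.tsv"
    alpha.to_csv(alpha_path, sep="\t", index=False)
    manifest["outputs"]["alpha_diversity"] = str(alpha_path)

    areas = sorted(metadata.loc[metadata["sample_id"].isin(rarefied.sample_ids), "area"].unique())
    if rarefied.taxonomy is not None and not rarefied.taxonomy.isna().any():
        genus_table = aggregate_to_rank(rarefied, config.network_rank)
    else:
        genus_table = rarefied
        manifest["warnings"].append("no taxonomy: skipping rank aggregation")
    composition = relative_abundance(genus_table)

    for area in areas:
        area_samples = [
            s for s in rarefied.sample_ids if metadata.loc[s, "area"] == area
        ]
        # ---- RS/RL ----------------------------------------------------
        try:
            results = []
            if abundance is not None:
                results.append(
                    rs_rl_profile(abundance, metadata, area, variable_name="abundance")
                )
            for metric in _ALPHA_METRICS:
                results.append(
                    rs_rl_profile(alpha[metric], metadata, area, variable_name=metric)
                )
            area_comp = composition.subset_samples(area_samples)
            top = (
                area_comp.proportions.mean(axis=1)
                .sort_values(ascending=False)
                .head(config.top_k_taxa)
                .index.tolist()
            )
            results.extend(taxon_rs_rl(composition, metadata, area, top))
        except Exception as exc:
            raise PipelineError("resilience", f"area {area}: {exc}") from exc
        for r in results:
            if np.isnan(r.rl):
                msg = f"RL undefined for {r.variable_name!r} in area {area} (C0 = P0)"
                logger.warning(msg)
                manifest["warnings"].append(msg)
        rsrl_path = out / f"rsrl_{area}.tsv"
        results_frame(results).to_csv(rsrl_path, sep="\t", index=False, na_rep="NA")
        manifest["outputs"][f"rsrl_{area}"] = str(rsrl_path)

        # ---- ANOSIM ---------------------------------------------------
        try:
            dm = bray_curtis_matrix(rarefied.subset_samples(area_samples))
            anosim_df = pairwise_anosim(
                dm,
                metadata.loc[area_samples, "group"],
                n_permutations=config.n_permutations,
                seed=seed_anosim,
            )
        except Exception as exc:
            raise PipelineError("anosim", f"area {area}: {exc}") from exc
        anosim_df.insert(0, "area", area)
        anosim_path = out / f"anosim_{area}.tsv"
        anosim_df.to_csv(anosim_path, sep="\t", index=False)
        manifest["outputs"][f"anosim_{area}"] = str(anosim_path)

        # ---- network --------------------------------------------------
        try:
            area_counts = genus_table.subset_samples(area_samples)
            filtered = filter_network_taxa(area_counts, min_prevalence=config.min_prevalence)
            dropped = [t for t in filtered.taxon_ids
                       if (filtered.counts.loc[t] == filtered.counts.loc[t].iloc[0]).all()]
            corr = spearman_matrix(relative_abundance(filtered))
            net = build_network(
                corr, rho_min=config.rho_min, p_max=config.p_max,
                taxonomy=genus_table.taxonomy,
            )
            topo = topology_summary(net, modularity_seed=seed_modularity)
        except Exception as exc:
            raise PipelineError("network", f"area {area}: {exc}") from exc
        if dropped:
            manifest["warnings"].append(
                f"area {area}: constant taxa with undefined correlations: {dropped}"
            )
        gexf_path = out / f"network_{area}.gexf"
        edges_path = out / f"network_{area}_edges.tsv"
        topo_path = out / f"topology_{area}.tsv"
        export_network(net, gexf_path, "gexf")
        export_network(net, edges_path, "edge_tsv")
        topo.to_frame().to_csv(topo_path, sep="\t", index=False)
        manifest["outputs"][f"network_{area}"] = str(gexf_path)
        manifest["outputs"][f"network_{area}_edges"] = str(edges_path)
        manifest["outputs"][f"topology_{area}"] = str(topo_path)

    manifest["output_checksums"] = {
        key: _sha256(Path(p)) for key, p in manifest["outputs"].items()
        if not p.endswith(".gexf")  # GEXF embeds a last-modified date
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
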