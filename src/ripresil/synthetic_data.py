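"""Synthetic two-area, three-group community datasets with known truth.

The generator emulates a riparian disturbance study: two study areas (a
natural area "NA" and an anthropogenic area "AA"), each sampled in three
disturbance groups — reference (never flooded), flooding (currently
flooded) and recovery (previously flooded, re-exposed) — with 4/13/7
samples per group by default.  Each sample is a fixed-depth rarefied
genus-level count vector drawn multinomially from logistic-normal latent
proportions: expected genus proportions are a shared rank-abundance
baseline multiplied by (area, group)-specific fold-changes and
renormalised, then perturbed by per-genus log-normal noise.  Pairs of
genera can carry planted correlations via shared latent factors with a
configurable loading; a per-sample total 16S copy number (qPCR-style,
copies per g dry-weight soil) is drawn log-normally around per-group
means.  All expected resistance/resilience indices and planted
correlation signs are available analytically as a :class:`GroundTruth`,
so downstream estimators can be checked for parameter recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .resilience import resilience_index, resistance_index
from .tables_io import CountTable, GROUPS

__all__ = [
    "GroupEffect",
    "PlantedEdge",
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "ground_truth_rs_rl",
    "write_dataset",
]

# (genus, phylum) roster for the default 24-genus community; ammonia
# oxidisers lead the rank-abundance curve, methanogens respond to flooding.
_DEFAULT_GENERA: tuple[tuple[str, str], ...] = (
    ("Nitrososphaera", "Thaumarchaeota"),
    ("Nitrosopumilus", "Thaumarchaeota"),
    ("Nitrosotalea", "Thaumarchaeota"),
    ("Methanobacterium", "Euryarchaeota"),
    ("Methanosaeta", "Euryarchaeota"),
    ("Methanosarcina", "Euryarchaeota"),
    ("Methanoregula", "Euryarchaeota"),
    ("Methanocella", "Euryarchaeota"),
    ("Methanolinea", "Euryarchaeota"),
    ("Methanobrevibacter", "Euryarchaeota"),
    ("Methanomassiliicoccus", "Euryarchaeota"),
    ("Halobacterium", "Euryarchaeota"),
    ("Thermoplasma", "Euryarchaeota"),
    ("Ferroplasma", "Euryarchaeota"),
    ("Bathyarchaeia_gen1", "Bathyarchaeota"),
    ("Bathyarchaeia_gen2", "Bathyarchaeota"),
    ("Bathyarchaeia_gen3", "Bathyarchaeota"),
    ("Woesearchaeia_gen1", "Nanoarchaeota"),
    ("Woesearchaeia_gen2", "Nanoarchaeota"),
    ("Aenigmarchaeum", "Aenigmarchaeota"),
    ("Micrarchaeum", "Micrarchaeota"),
    ("Nitrosocaldus", "Thaumarchaeota"),
    ("Parvarchaeum", "Parvarchaeota"),
    ("Altiarchaeum", "Altiarchaeota"),
)

_AOA = ("Nitrososphaera", "Nitrosopumilus", "Nitrosotalea")
_METHANOGENS = (
    "Methanobacterium", "Methanosaeta", "Methanosarcina", "Methanoregula",
    "Methanocella", "Methanolinea", "Methanobrevibacter", "Methanomassiliicoccus",
)


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative fold-change on the expected proportion of a genus set."""

    area: str
    group: str
    genera: tuple[str, ...]
    fold: float


@dataclass(frozen=True)
class PlantedEdge:
    """A genus pair with a planted Spearman correlation sign (+1 or -1)."""

    genus_a: str
    genus_b: str
    sign: int


def _default_group_effects() -> tuple[GroupEffect, ...]:
    # Flooding floods both areas identically: methanogens bloom, ammonia
    # oxidisers collapse.  Recovery in NA returns close to the reference;
    # recovery in AA stays displaced (the anthropogenic-pollution motif).
    effects = []
    for area in ("NA", "AA"):
        effects += [
            GroupEffect(area, "flooding", _METHANOGENS, 10.0),
            GroupEffect(area, "flooding", _AOA, 0.08),
        ]
    effects += [
        GroupEffect("NA", "recovery", _METHANOGENS, 2.0),
        GroupEffect("NA", "recovery", _AOA, 0.8),
        GroupEffect("AA", "recovery", _METHANOGENS, 5.0),
        GroupEffect("AA", "recovery", _AOA, 0.3),
    ]
    return tuple(effects)


def _default_abundance_means() -> dict[tuple[str, str], float]:
    # Group-mean total 16S copies per g dry-weight soil.
    return {
        ("NA", "reference"): 8.6e8,
        ("NA", "flooding"): 1.9e9,
        ("NA", "recovery"): 4.6e8,
        ("AA", "reference"): 3.2e8,
        ("AA", "flooding"): 1.2e9,
        ("AA", "recovery"): 2.1e8,
    }


def _default_planted_edges() -> tuple[PlantedEdge, ...]:
    return (
        PlantedEdge("Bathyarchaeia_gen1", "Bathyarchaeia_gen2", +1),
        PlantedEdge("Woesearchaeia_gen1", "Woesearchaeia_gen2", +1),
        PlantedEdge("Thermoplasma", "Ferroplasma", -1),
    )


@dataclass
class SyntheticConfig:
    """Study-design parameters for :func:`generate_dataset`.

    Defaults mirror the emulated design: two areas, 4 reference / 13
    flooding / 7 recovery samples each, 24 genera, and samples at a fixed
    rarefied depth of 20,826 reads.
    """

    areas: tuple[str, ...] = ("NA", "AA")
    n_reference: int = 4
    n_flooding: int = 13
    n_recovery: int = 7
    n_genera: int = 24
    sequencing_depth: int = 20826
    #: per-genus log expected baseline abundance; None -> geometric
    #: rank-abundance series -0.45 * rank.
    baseline_log_mean: tuple[float, ...] | None = None
    #: log-sd of the per-genus latent noise (scalar applied to all genera).
    genus_log_sd: float = 0.3
    group_effects: tuple[GroupEffect, ...] | None = None
    abundance_means: dict = field(default_factory=_default_abundance_means)
    abundance_cv: float = 0.5
    planted_edges: tuple[PlantedEdge, ...] | None = None
    edge_loading: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        # Defaults adapt to the genus roster: effects/edges that reference
        # genera beyond n_genera are dropped rather than rejected.
        roster = set(self.genus_names())
        if self.group_effects is None:
            self.group_effects = tuple(
                GroupEffect(e.area, e.group,
                            tuple(g for g in e.genera if g in roster), e.fold)
                for e in _default_group_effects()
                if any(g in roster for g in e.genera)
            )
        if self.planted_edges is None:
            self.planted_edges = tuple(
                e for e in _default_planted_edges()
                if e.genus_a in roster and e.genus_b in roster
            )

    # ------------------------------------------------------------------
    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def group_sizes(self) -> dict[str, int]:
        return {
            "reference": self.n_reference,
            "flooding": self.n_flooding,
            "recovery": self.n_recovery,
        }

    def genus_names(self) -> list[str]:
        names = [g for g, _ in _DEFAULT_GENERA[: self.n_genera]]
        names += [f"Genus_{k:02d}" for k in range(len(names), self.n_genera)]
        return names

    def lineages(self) -> pd.Series:
        phyla = {g: p for g, p in _DEFAULT_GENERA}
        out = {}
        for g in self.genus_names():
            phylum = phyla.get(g, "Euryarchaeota")
            out[g] = f"Archaea;{phylum};{phylum}_class;{phylum}_order;{phylum}_family;{g}"
        return pd.Series(out)

    def baseline_proportions(self) -> np.ndarray:
        if self.baseline_log_mean is not None:
            logm = np.asarray(self.baseline_log_mean, dtype=float)
        else:
            logm = -0.45 * np.arange(self.n_genera, dtype=float)
        w = np.exp(logm)
        return w / w.sum()

    def validate(self) -> None:
        if self.n_areas < 1:
            raise ValueError("need at least one study area")
        for name, size in self.group_sizes.items():
            if size < 1:
                raise ValueError(f"group size for {name!r} must be >= 1")
        if self.sequencing_depth < 100:
            raise ValueError("sequencing_depth must be >= 100")
        if self.n_genera < 2:
            raise ValueError("need at least two genera")
        if self.baseline_log_mean is not None and len(self.baseline_log_mean) != self.n_genera:
            raise ValueError("baseline_log_mean length must equal n_genera")
        if self.genus_log_sd < 0:
            raise ValueError("genus_log_sd must be non-negative")
        if not 0 <= self.edge_loading <= 1:
            raise ValueError("edge_loading must lie in [0, 1]")
        if self.abundance_cv < 0:
            raise ValueError("abundance_cv must be non-negative")
        names = set(self.genus_names())
        for eff in self.group_effects:
            if eff.fold <= 0:
                raise ValueError(f"fold-change must be positive: {eff}")
            if eff.group not in GROUPS:
                raise ValueError(f"unknown group in effect: {eff}")
            unknown = set(eff.genera) - names
            if unknown:
                raise ValueError(f"group effect references unknown genera: {unknown}")
        for edge in self.planted_edges:
            if edge.genus_a == edge.genus_b:
                raise ValueError(f"planted self-pair: {edge}")
            if edge.genus_a not in names or edge.genus_b not in names:
                raise ValueError(f"planted edge references unknown genera: {edge}")
            if edge.sign not in (-1, 1):
                raise ValueError(f"planted sign must be +1 or -1: {edge}")
        for area in self.areas:
            for group in GROUPS:
                if (area, group) not in self.abundance_means:
                    raise ValueError(f"abundance mean missing for {(area, group)}")

    # ------------------------------------------------------------------
    def expected_proportions(self, area: str, group: str) -> pd.Series:
        """Configured expected genus proportions (baseline x folds, renormalised)."""
        names = self.genus_names()
        w = self.baseline_proportions().copy()
        for eff in self.group_effects:
            if eff.area == area and eff.group == group:
                for genus in eff.genera:
                    w[names.index(genus)] *= eff.fold
        return pd.Series(w / w.sum(), index=names)

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=int(seed))

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "areas": list(self.areas),
            "n_reference": self.n_reference,
            "n_flooding": self.n_flooding,
            "n_recovery": self.n_recovery,
            "n_genera": self.n_genera,
            "sequencing_depth": self.sequencing_depth,
            "baseline_log_mean": (
                None if self.baseline_log_mean is None else list(self.baseline_log_mean)
            ),
            "genus_log_sd": self.genus_log_sd,
            "group_effects": [
                {"area": e.area, "group": e.group, "genera": list(e.genera), "fold": e.fold}
                for e in self.group_effects
            ],
            "abundance_means": {
                a: {g: self.abundance_means[(a, g)] for g in GROUPS} for a in self.areas
            },
            "abundance_cv": self.abundance_cv,
            "planted_edges": [
                {"genus_a": e.genus_a, "genus_b": e.genus_b, "sign": e.sign}
                for e in self.planted_edges
            ],
            "edge_loading": self.edge_loading,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticConfig":
        kwargs = dict(doc)
        if "areas" in kwargs:
            kwargs["areas"] = tuple(kwargs["areas"])
        if kwargs.get("baseline_log_mean") is not None:
            kwargs["baseline_log_mean"] = tuple(kwargs["baseline_log_mean"])
        if "group_effects" in kwargs:
            kwargs["group_effects"] = tuple(
                GroupEffect(e["area"], e["group"], tuple(e["genera"]), float(e["fold"]))
                for e in kwargs["group_effects"]
            )
        if "planted_edges" in kwargs:
            kwargs["planted_edges"] = tuple(
                PlantedEdge(e["genus_a"], e["genus_b"], int(e["sign"]))
                for e in kwargs["planted_edges"]
            )
        if "abundance_means" in kwargs:
            nested = kwargs["abundance_means"]
            kwargs["abundance_means"] = {
                (a, g): float(v) for a, groups in nested.items() for g, v in groups.items()
            }
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Analytic expectations implied by a :class:`SyntheticConfig`.

    Expected RS/RL per variable and area are pure arithmetic on the
    configured group means — no sampling — so estimator output can be
    compared against them.
    """

    abundance_rs_rl: dict[str, tuple[float, float]]
    genus_rs_rl: dict[str, dict[str, tuple[float, float]]]
    expected_proportions: dict[tuple[str, str], pd.Series]
    correlation_signs: dict[tuple[str, str], int]

    def to_json(self, path) -> None:
        doc = {
            "abundance_rs_rl": {
                a: {"rs": rs, "rl": None if math.isnan(rl) else rl}
                for a, (rs, rl) in self.abundance_rs_rl.items()
            },
            "genus_rs_rl": {
                a: {
                    g: {"rs": rs, "rl": None if math.isnan(rl) else rl}
                    for g, (rs, rl) in per.items()
                }
                for a, per in self.genus_rs_rl.items()
            },
            "expected_proportions": {
                f"{a}/{g}": series.to_dict()
                for (a, g), series in self.expected_proportions.items()
            },
            "correlation_signs": {f"{a}|{b}": s for (a, b), s in self.correlation_signs.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


@dataclass
class SyntheticDataset:
    table: CountTable
    metadata: pd.DataFrame
    abundance: pd.Series
    truth: GroundTruth
    config: SyntheticConfig


def ground_truth_rs_rl(config: SyntheticConfig) -> GroundTruth:
    """Expected RS/RL (and planted signs) from configured means; no sampling."""
    config.validate()
    abundance = {}
    for area in config.areas:
        c0 = config.abundance_means[(area, "reference")]
        p0 = config.abundance_means[(area, "flooding")]
        px = config.abundance_means[(area, "recovery")]
        abundance[area] = (resistance_index(c0, p0), resilience_index(c0, p0, px))

    proportions = {
        (area, group): config.expected_proportions(area, group)
        for area in config.areas
        for group in GROUPS
    }
    genus = {}
    for area in config.areas:
        per = {}
        for g in config.genus_names():
            c0 = proportions[(area, "reference")][g]
            p0 = proportions[(area, "flooding")][g]
            px = proportions[(area, "recovery")][g]
            per[g] = (resistance_index(c0, p0), resilience_index(c0, p0, px))
        genus[area] = per

    signs = {(e.genus_a, e.genus_b): e.sign for e in config.planted_edges}
    return GroundTruth(
        abundance_rs_rl=abundance,
        genus_rs_rl=genus,
        expected_proportions=proportions,
        correlation_signs=signs,
    )


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a full dataset (counts, metadata, qPCR series) plus its truth.

    Per sample: latent log-normal perturbations (with shared factors for
    planted edges) are applied to the group's expected proportions, the
    result renormalised, and counts drawn multinomially at the configured
    depth, so every column sums to ``sequencing_depth`` exactly.  Total
    abundance is log-normal around the configured (area, group) mean.
    Identical seeds give bit-identical datasets: every sample has its own
    deterministic substream of the global seed.
    """
    config.validate()
    truth = ground_truth_rs_rl(config)
    names = config.genus_names()
    idx = {g: k for k, g in enumerate(names)}
    sd = float(config.genus_log_sd)
    loading = float(config.edge_loading)
    resid = math.sqrt(1.0 - loading**2)

    sample_plan = [
        (area, group, i)
        for area in config.areas
        for group in GROUPS
        for i in range(config.group_sizes[group])
    ]
    streams = np.random.SeedSequence(config.seed).spawn(len(sample_plan))

    sigma_ab = math.sqrt(math.log(1.0 + config.abundance_cv**2))
    columns, meta_rows, abundances, ids = [], [], [], []
    for (area, group, i), stream in zip(sample_plan, streams):
        rng = np.random.default_rng(stream)
        sample_id = f"{area}_{group}_{i + 1:02d}"
        p_exp = config.expected_proportions(area, group).to_numpy()

        z = rng.standard_normal(config.n_genera)
        for edge in config.planted_edges:
            f = rng.standard_normal()
            a, b = idx[edge.genus_a], idx[edge.genus_b]
            z[a] = loading * f + resid * z[a]
            z[b] = edge.sign * loading * f + resid * z[b]
        latent = p_exp * np.exp(sd * z - 0.5 * sd**2)
        latent /= latent.sum()
        columns.append(rng.multinomial(config.sequencing_depth, latent))

        mean_ab = config.abundance_means[(area, group)]
        if config.abundance_cv == 0:
            ab = mean_ab
        else:
            mu = math.log(mean_ab) - 0.5 * sigma_ab**2
            ab = float(rng.lognormal(mu, sigma_ab))
        abundances.append(ab)

        elevation = {"reference": 175.5, "flooding": 150.0 + 2.0 * i,
                     "recovery": 165.0 + 1.0 * i}[group]
        duration = {"reference": 0.0, "flooding": 273.0 - 15.0 * i,
                    "recovery": 120.0 + 10.0 * i}[group]
        meta_rows.append(
            {
                "sample_id": sample_id,
                "area": area,
                "group": group,
                "elevation_m": elevation,
                "flooding_duration_days": duration,
            }
        )
        ids.append(sample_id)

    counts = pd.DataFrame(
        np.column_stack(columns), index=pd.Index(names, name="taxon_id"), columns=ids
    )
    table = CountTable(counts, config.lineages())
    metadata = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    abundance = pd.Series(abundances, index=ids, name="abundance")
    return SyntheticDataset(table, metadata, abundance, truth, config)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write counts/metadata/abundance TSVs and the truth JSON to ``outdir``."""
    from pathlib import Path

    from .tables_io import write_abundance_series, write_count_table, write_sample_metadata

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": str(out / "counts.tsv"),
        "metadata": str(out / "metadata.tsv"),
        "abundance": str(out / "abundance.tsv"),
        "ground_truth": str(out / "ground_truth.json"),
        "config": str(out / "config.json"),
    }
    write_count_table(dataset.table, paths["counts"])
    write_sample_metadata(dataset.metadata, paths["metadata"])
    write_abundance_series(dataset.abundance, paths["abundance"])
    dataset.truth.to_json(paths["ground_truth"])
    with open(paths["config"], "w") as fh:
        json.dump(dataset.config.to_dict(), fh, indent=1)
    return paths
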