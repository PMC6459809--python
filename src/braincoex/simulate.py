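"""Synthetic expression datasets with known ground truth.

The generator emulates the statistical structure of a two-genotype,
seven-brain-region microarray study (12 mice per genotype per region):
block-correlated gene modules driven by per-module latent factors,
region-specific baseline profiles, genotype effects restricted to subsets
of regions, additive Gaussian noise, simulated detection p-values, and
optionally planted outlier samples.

Model for a gene g in module m, sample s (log2-like scale)::

    x_gs = baseline_m(region_s) + effect_m(region_s) * [genotype_s == selected]
           + loading_m * F_m(s) + noise_sd * eps_gs

with F_m(s) ~ N(0, 1) a per-module per-sample latent factor and eps iid
standard normal.  The within-module Pearson correlation is therefore
loading^2 / (loading^2 + noise_sd^2) in expectation.  A module may also mix
a shared cross-module signal into its factor (``cross_module_loading``),
creating a "bridge" module correlated with every other module.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import (CONTROL, SELECTED, ExpressionDataset, GeneSetCollection,
                       OrthologMap)

#: the seven brain regions of the study design this generator emulates
DEFAULT_REGIONS = ("PFC", "AcbC", "AcbSh", "BNST", "BLA", "CeA", "VTA")


@dataclass
class ModuleSpec:
    """One planted coexpression module.

    region_baseline
        per-region baseline shift of the module's genes (log2 units);
        regions not listed default to 0.
    genotype_effect
        per-region signed log2 shift applied to the selected genotype.
    cross_module_loading
        in [0, 1); fraction of the module factor's variance drawn from the
        standardized mean of all other modules' factors (bridge modules).
    """

    module_id: str
    size: int
    factor_loading: float
    cell_type: str | None = None
    region_baseline: dict[str, float] = field(default_factory=dict)
    genotype_effect: dict[str, float] = field(default_factory=dict)
    cross_module_loading: float = 0.0


@dataclass
class SyntheticConfig:
    n_genes: int
    modules: list[ModuleSpec] = field(default_factory=list)
    regions: tuple[str, ...] = DEFAULT_REGIONS
    genotypes: tuple[str, ...] = (SELECTED, CONTROL)
    n_replicates: int = 12
    noise_sd: float = 0.6
    baseline: float = 8.0
    #: sd of fixed per-gene baseline offsets (the large gene-to-gene
    #: abundance spread of real log-scale expression data; constant
    #: across samples, so correlations and group contrasts are untouched)
    gene_baseline_sd: float = 1.5
    #: fraction of genes simulated as "absent" (undetected) in a random
    #: subset of regions
    absent_fraction: float = 0.0
    #: number of planted outlier samples; each gets independent per-gene
    #: noise of sd ``outlier_shift`` added (scrambling its expression
    #: ranks, so the corruption survives quantile normalization)
    n_outlier_samples: int = 0
    outlier_shift: float = 3.0
    #: balance latent factors across genotype x region cells (the factor
    #: models non-genotype biological variation, so it is made orthogonal
    #: to the design in-sample; disable for raw iid factors)
    balance_factors: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = sum(m.size for m in self.modules)
        if sizes > self.n_genes:
            raise ValueError(
                f"module sizes sum to {sizes} > n_genes = {self.n_genes}")
        ids = [m.module_id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise ValueError("module ids must be unique")
        for m in self.modules:
            if not 0.0 < m.factor_loading < 1.0:
                raise ValueError(
                    f"factor_loading must be in (0, 1); module {m.module_id} "
                    f"has {m.factor_loading}")
            if not 0.0 <= m.cross_module_loading < 1.0:
                raise ValueError("cross_module_loading must be in [0, 1)")
            for r in list(m.region_baseline) + list(m.genotype_effect):
                if r not in self.regions:
                    raise ValueError(
                        f"module {m.module_id} references unknown region {r!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    @property
    def n_background(self) -> int:
        return self.n_genes - sum(m.size for m in self.modules)

    @property
    def background_fraction(self) -> float:
        return self.n_background / self.n_genes

    @property
    def n_samples(self) -> int:
        return len(self.regions) * len(self.genotypes) * self.n_replicates

    # -- YAML round trip (CLI) --------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["regions"] = list(self.regions)
        d["genotypes"] = list(self.genotypes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["modules"] = [ModuleSpec(**m) for m in d.get("modules", [])]
        d["regions"] = tuple(d.get("regions", DEFAULT_REGIONS))
        d["genotypes"] = tuple(d.get("genotypes", (SELECTED, CONTROL)))
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator knows about what it planted."""

    #: gene id -> module id ("background" for unassigned noise genes)
    gene_module: dict[str, str]
    #: gene id -> cell-type tag (only for genes in tagged modules)
    gene_cell_type: dict[str, str]
    #: (gene id, region) -> true log2 effect (selected - control); absent
    #: entries mean no effect
    true_effects: dict[tuple[str, str], float]
    #: sample id -> (genotype, region)
    sample_map: dict[str, tuple[str, str]]
    #: planted outlier sample ids
    outlier_samples: list[str]
    #: per-module latent factor values, modules x samples
    factors: pd.DataFrame
    #: per-module total systematic sample signal (region baseline +
    #: genotype effect + loading x factor), modules x samples; this is the
    #: profile a module eigengene estimates
    module_signal: pd.DataFrame
    #: (gene id, region) pairs simulated as undetected
    absent: set[tuple[str, str]]

    def module_genes(self, module_id: str) -> list[str]:
        return [g for g, m in self.gene_module.items() if m == module_id]

    def true_deg_set(self, region: str) -> set[str]:
        return {g for (g, r) in self.true_effects if r == region}

    def module_ids(self) -> list[str]:
        seen = dict.fromkeys(self.gene_module.values())
        return [m for m in seen if m != "background"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_module": self.gene_module,
            "gene_cell_type": self.gene_cell_type,
            "true_effects": [[g, r, e] for (g, r), e in self.true_effects.items()],
            "sample_map": {s: list(gr) for s, gr in self.sample_map.items()},
            "outlier_samples": self.outlier_samples,
            "factors": {
                "index": list(self.factors.index),
                "columns": list(self.factors.columns),
                "values": self.factors.to_numpy().tolist(),
            },
            "module_signal": {
                "index": list(self.module_signal.index),
                "columns": list(self.module_signal.columns),
                "values": self.module_signal.to_numpy().tolist(),
            },
            "absent": [[g, r] for g, r in sorted(self.absent)],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            gene_module=d["gene_module"],
            gene_cell_type=d["gene_cell_type"],
            true_effects={(g, r): e for g, r, e in d["true_effects"]},
            sample_map={s: tuple(gr) for s, gr in d["sample_map"].items()},
            outlier_samples=d["outlier_samples"],
            factors=pd.DataFrame(
                d["factors"]["values"], index=d["factors"]["index"],
                columns=d["factors"]["columns"]),
            module_signal=pd.DataFrame(
                d["module_signal"]["values"],
                index=d["module_signal"]["index"],
                columns=d["module_signal"]["columns"]),
            absent={(g, r) for g, r in d["absent"]},
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------
def _sample_layout(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for region in config.regions:
        for genotype in config.genotypes:
            for rep in range(1, config.n_replicates + 1):
                rows.append((f"{region}_{genotype}_{rep:02d}", genotype, region))
    meta = pd.DataFrame(rows, columns=["sample_id", "genotype", "region"])
    return meta.set_index("sample_id")


def generate_dataset(config: SyntheticConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate one expression dataset plus its ground truth.

    Deterministic: identical config (including seed) gives byte-identical
    output.  One global stream is seeded from ``config.seed``; per-module
    streams are derived deterministically from (seed, module index).
    """
    meta = _sample_layout(config)
    n_samples = len(meta)
    rng = np.random.default_rng(config.seed)

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    gene_module: dict[str, str] = {}
    gene_cell_type: dict[str, str] = {}
    pos = 0
    module_rows: dict[str, slice] = {}
    for m in config.modules:
        module_rows[m.module_id] = slice(pos, pos + m.size)
        for g in gene_ids[pos:pos + m.size]:
            gene_module[g] = m.module_id
            if m.cell_type:
                gene_cell_type[g] = m.cell_type
        pos += m.size
    for g in gene_ids[pos:]:
        gene_module[g] = "background"

    # latent factors: own stream per module so module lists can be edited
    # without perturbing the other modules' draws
    own = np.empty((len(config.modules), n_samples))
    for j, m in enumerate(config.modules):
        sub = np.random.default_rng([config.seed, j])
        own[j] = sub.standard_normal(n_samples)
    factors = own.copy()
    for j, m in enumerate(config.modules):
        c = m.cross_module_loading
        if c > 0 and len(config.modules) > 1:
            others = [i for i in range(len(config.modules)) if i != j]
            shared = own[others].sum(axis=0) / np.sqrt(len(others))
            factors[j] = c * shared + np.sqrt(1 - c * c) * own[j]
    if config.balance_factors and factors.size:
        # remove each genotype x region cell mean, then restore unit scale:
        # the coherent part of a module factor would otherwise masquerade
        # as a genotype or region effect at finite n
        cell = (meta["region"] + "|" + meta["genotype"]).to_numpy()
        for c_lab in np.unique(cell):
            cols = cell == c_lab
            factors[:, cols] -= factors[:, cols].mean(axis=1, keepdims=True)
        sd = factors.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        factors /= sd
    factors_df = pd.DataFrame(
        factors, index=[m.module_id for m in config.modules], columns=meta.index)

    region_arr = meta["region"].to_numpy()
    selected_mask = (meta["genotype"] == SELECTED).to_numpy()

    gene_offsets = config.gene_baseline_sd * rng.standard_normal(
        config.n_genes)
    x = (config.baseline + gene_offsets[:, None]
         + config.noise_sd * rng.standard_normal(
             (config.n_genes, n_samples)))
    true_effects: dict[tuple[str, str], float] = {}
    signal = np.zeros((len(config.modules), n_samples))
    for j, m in enumerate(config.modules):
        rows = module_rows[m.module_id]
        shift = np.zeros(n_samples)
        for r, b in m.region_baseline.items():
            shift[region_arr == r] += b
        for r, e in m.genotype_effect.items():
            if e != 0.0:
                shift[(region_arr == r) & selected_mask] += e
                for g in gene_ids[rows]:
                    true_effects[(g, r)] = e
        signal[j] = shift + m.factor_loading * factors[j]
        x[rows] += signal[j]

    # planted outlier samples: shift every gene of a sample
    outliers: list[str] = []
    if config.n_outlier_samples:
        idx = rng.choice(n_samples, size=config.n_outlier_samples, replace=False)
        for s in sorted(idx):
            x[:, s] += config.outlier_shift * rng.standard_normal(
                config.n_genes)
            outliers.append(meta.index[s])

    values = pd.DataFrame(x, index=gene_ids, columns=meta.index)

    # detection p-values: Beta(0.1, 10) for present, Uniform(0,1) for absent
    absent: set[tuple[str, str]] = set()
    det = rng.beta(0.1, 10.0, size=(config.n_genes, n_samples))
    if config.absent_fraction > 0:
        n_abs = int(round(config.absent_fraction * config.n_genes))
        abs_genes = rng.choice(config.n_genes, size=n_abs, replace=False)
        for gi in abs_genes:
            n_regions_abs = int(rng.integers(1, len(config.regions) + 1))
            regs = rng.choice(len(config.regions), size=n_regions_abs,
                              replace=False)
            for ri in regs:
                r = config.regions[ri]
                cols = region_arr == r
                det[gi, cols] = rng.uniform(size=cols.sum())
                absent.add((gene_ids[gi], r))
    detection = pd.DataFrame(det, index=gene_ids, columns=meta.index)

    ds = ExpressionDataset(values=values, metadata=meta, detection=detection)
    truth = GroundTruth(
        gene_module=gene_module,
        gene_cell_type=gene_cell_type,
        true_effects=true_effects,
        sample_map={s: (meta.loc[s, "genotype"], meta.loc[s, "region"])
                    for s in meta.index},
        outlier_samples=outliers,
        factors=factors_df,
        module_signal=pd.DataFrame(
            signal, index=[m.module_id for m in config.modules],
            columns=meta.index),
        absent=absent,
    )
    return ds, truth


def generate_marker_and_geneset_collections(
    truth: GroundTruth,
    contamination: float = 0.2,
    n_decoy_sets: int = 5,
    decoy_size: int = 100,
    seed: int = 0,
) -> GeneSetCollection:
    """Build cell-type marker sets plus random decoy sets from ground truth.

    One marker set per cell-type tag: the tagged module's genes plus
    ``contamination`` x module size random genes from outside the module.
    Decoy sets are drawn uniformly from the gene universe.
    """
    tags = sorted(set(truth.gene_cell_type.values()))
    rng = np.random.default_rng(seed)
    universe = sorted(truth.gene_module)
    coll = GeneSetCollection()
    for tag in tags:
        members = sorted(g for g, t in truth.gene_cell_type.items() if t == tag)
        pool = [g for g in universe if g not in set(members)]
        n_extra = int(round(contamination * len(members)))
        extra = list(rng.choice(pool, size=min(n_extra, len(pool)),
                                replace=False)) if n_extra else []
        coll.add(f"markers_{tag}", members + extra,
                 description=f"synthetic {tag} marker set", category="cell_type")
    for i in range(n_decoy_sets):
        decoy = list(rng.choice(universe, size=min(decoy_size, len(universe)),
                                replace=False))
        coll.add(f"decoy_{i:02d}", decoy,
                 description="random decoy set", category="decoy")
    return coll


def generate_species_pair(
    config: SyntheticConfig,
    id_prefixes: tuple[str, str] = ("ms", "hs"),
    drop_fraction: float = 0.0,
    partner_seed: int | None = None,
) -> tuple[ExpressionDataset, ExpressionDataset, OrthologMap]:
    """Two datasets sharing module structure, linked by an ortholog table.

    The second dataset is regenerated with independent noise and factors
    (``partner_seed``; defaults to ``config.seed + 1``) and renamed gene
    ids.  A ``drop_fraction`` of genes is removed from the ortholog map to
    emulate unmapped orthologs.  With ``partner_seed == config.seed`` the
    two matrices are identical up to id renaming.
    """
    ds_a, _ = generate_dataset(config)
    seed_b = config.seed + 1 if partner_seed is None else partner_seed
    ds_b, _ = generate_dataset(dataclasses.replace(config, seed=seed_b))

    pa, pb = id_prefixes

    def _prefixed(ds, prefix):
        if not prefix:
            return ds
        rename = {g: f"{prefix}_{g}" for g in ds.genes}
        return dataclasses.replace(
            ds, values=ds.values.rename(index=rename),
            detection=ds.detection.rename(index=rename))

    def _name(prefix, g):
        return f"{prefix}_{g}" if prefix else g

    ds_a = _prefixed(ds_a, pa)
    ds_b = _prefixed(ds_b, pb)
    pairs = [(_name(pa, g), _name(pb, g)) for g in
             (f"G{i:05d}" for i in range(config.n_genes))]
    if drop_fraction > 0:
        rng = np.random.default_rng([config.seed, 9999])
        n_keep = len(pairs) - int(round(drop_fraction * len(pairs)))
        keep = sorted(rng.choice(len(pairs), size=n_keep, replace=False))
        pairs = [pairs[i] for i in keep]
    return ds_a, ds_b, OrthologMap(pairs=pairs)


# ---------------------------------------------------------------------------
# standard configurations
# ---------------------------------------------------------------------------
def benchmark_config(seed: int = 0, n_outlier_samples: int = 0) -> SyntheticConfig:
    """The standard module-recovery benchmark.

    168 samples (2 genotypes x 7 regions x 12 replicates), 3,000 genes,
    8 planted modules with sizes 100-400, factor loading 0.8 and noise sd
    0.6 (within-module correlation 0.64).  Three modules carry cell-type
    tags with region baselines sketching the tissue pattern of those cell
    populations; several modules carry genotype effects restricted to
    regions of the extended amygdala and its inputs; one module is flat
    across regions (housekeeping-like).

    Genotype effects are balanced per region (equal numbers of up- and
    down-shifted genes) so that quantile normalization across samples does
    not redistribute planted shifts onto unaffected genes, mirroring real
    transcriptomes where regulation is bidirectional and modest in extent.
    """
    mods = [
        ModuleSpec("M1", 400, 0.8, cell_type="neuron",
                   region_baseline={"PFC": 1.0, "BLA": 1.0},
                   genotype_effect={"BLA": 1.0, "CeA": 1.0, "AcbSh": 1.0}),
        ModuleSpec("M2", 350, 0.8, cell_type="astrocyte",
                   region_baseline={"BNST": 0.8, "VTA": 0.6}),
        ModuleSpec("M3", 300, 0.8, cell_type="oligodendrocyte",
                   region_baseline={"BNST": 1.2, "VTA": 1.0},
                   genotype_effect={"PFC": -1.0, "AcbC": -1.0}),
        ModuleSpec("M4", 250, 0.8,
                   region_baseline={"AcbC": 0.8, "AcbSh": 0.8},
                   genotype_effect={"BLA": -1.0, "CeA": -1.0, "AcbSh": -1.0}),
        ModuleSpec("M5", 200, 0.8,  # housekeeping-like: flat profile
                   genotype_effect={"PFC": 1.0, "AcbC": 1.0}),
        ModuleSpec("M6", 150, 0.8, region_baseline={"VTA": 1.0},
                   genotype_effect={"BLA": -1.0, "CeA": -1.0, "AcbSh": -1.0}),
        ModuleSpec("M7", 120, 0.8, region_baseline={"CeA": 0.7, "BLA": 0.5}),
        ModuleSpec("M8", 100, 0.8, region_baseline={"PFC": -0.8},
                   genotype_effect={"PFC": 1.0, "AcbC": 1.0}),
    ]
    return SyntheticConfig(n_genes=3000, modules=mods, noise_sd=0.6,
                           absent_fraction=0.05, seed=seed,
                           n_outlier_samples=n_outlier_samples)


def de_power_config(seed: int = 0) -> SyntheticConfig:
    """Scenario for differential-expression power and module flagging.

    Planted log2 effect 1.0 at noise sd 0.5; modest factor loading (0.3) so
    the per-gene residual sd is dominated by the noise term (total sd
    ~0.58, standardized effect ~1.7 at n = 12/group).
    """
    mods = []
    effect_regions = [("BLA", 1.0), ("CeA", 1.0), ("AcbSh", -1.0), ("BNST", 1.0)]
    for i in range(4):
        r, e = effect_regions[i]
        mods.append(ModuleSpec(f"E{i + 1}", 60, 0.3,
                               genotype_effect={r: e}))
    for i in range(6):
        mods.append(ModuleSpec(f"N{i + 1}", 60, 0.3))
    return SyntheticConfig(n_genes=1200, modules=mods, noise_sd=0.5, seed=seed)


def null_config(seed: int = 0, n_genes: int = 2900) -> SyntheticConfig:
    """No genotype effects anywhere: for type-I error calibration."""
    return SyntheticConfig(n_genes=n_genes, modules=[], noise_sd=0.5, seed=seed)


def bridge_config(seed: int = 0) -> SyntheticConfig:
    """Scenario for hub-module scoring: one bridge module whose factor mixes
    the shared signal of all other modules.

    Modules are small relative to the gene universe so that, under the
    default edge rule (top 1% of adjacencies), inter-module adjacencies can
    enter the retained edge set.
    """
    mods = [ModuleSpec("BRIDGE", 60, 0.8, cross_module_loading=0.95)]
    for i in range(5):
        mods.append(ModuleSpec(f"M{i + 1}", 60, 0.8))
    return SyntheticConfig(n_genes=2000, modules=mods, noise_sd=0.5,
                           n_replicates=12, seed=seed)
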