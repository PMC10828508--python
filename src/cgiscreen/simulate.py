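"""Seeded generator of pooled CRISPR time-course screen counts.

The generator emulates the design of a compressed chemical-genetic screen:
1011 genes x 3 guides, technical triplicates, samples collected every 3 days
from T0 to T18, and ~1000x per-guide read coverage. Each guide starts from a
lognormal baseline abundance; its log2 abundance moves by (gene fitness +
guide effect) per passage in every arm and additionally by the gene's planted
chemical-genetic effect delta per passage in the compound arm, so the
expected CGI at timepoint t is delta * (t / passage_days). Read counts are
negative-binomial around the depth-scaled relative abundances (dispersion 0
means noise-free expected counts).

The library fixture is synthetic: the gene roster mixes DNA-damage-response
gene symbols from the published literature with generated filler symbols, as
the real targeted library table is not redistributable here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CountMatrix, LibraryDefinition, SampleSheet, ValidationError
from .qc import essential_dropout_auc

__all__ = [
    "SimConfig",
    "SimTruth",
    "synthetic_library",
    "simulate_screen",
    "twofold_preset",
    "preset_config",
    "recovery_report",
]

# DDR / replication / chromatin gene symbols named in the screening literature;
# used to give the synthetic library a realistic roster.
_KNOWN_GENES = [
    "RAD1", "HUS1", "RAD17", "BRCA1", "BRCA2", "RAD51B", "RAD51D", "XRCC1",
    "XRCC2", "XRCC3", "MRE11", "RAD50", "NBN", "EME1", "MUS81", "RAD54L",
    "CYB5R4", "TIPRL", "PPP2R4", "GINS4", "MCM4", "MCM6", "MCM10", "ORC2",
    "DOT1L", "EED", "SUZ12", "LCMT1", "KMT2A", "POLE3", "POLE4", "FEN1",
    "DNA2", "LIG1", "FANCA", "FANCB", "FANCC", "FANCD2", "FANCF", "FANCG",
    "FANCI", "FANCM", "PARP1", "ATM", "ATR", "CHEK1", "CHEK2", "TOP1",
    "RRM1", "RRM2", "TUBB", "PSMB5", "BLM", "WRN", "RECQL5", "EXO1",
    "RAD52", "PALB2", "BARD1", "RNASEH2A", "RNASEH2B", "POLB", "APEX1",
    "LIG4", "PRKDC", "XRCC4", "NHEJ1", "POLQ", "REV3L", "RAD18",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic screen."""

    seed: int
    n_genes: int = 1011
    guides_per_gene: int = 3
    timepoints: tuple = (0, 3, 6, 9, 12, 15, 18)
    replicates: tuple = ("A", "B", "C")
    compounds: tuple = ("CPT",)
    control_label: str = "DMSO"
    depth_per_sample: float = 3.03e6  # ~1000x over 3033 guides
    frac_essential: float = 55 / 1011  # matches the essential-standard share
    essential_fitness_mean: float = -0.7  # log2 per passage
    essential_fitness_sd: float = 0.2
    nonessential_fitness_sd: float = 0.15  # gene-to-gene fitness spread
    guide_noise_sd: float = 0.1  # guide-specific fitness offset, log2/passage
    baseline_log2_sd: float = 0.5  # library representation spread
    n_cgi_genes: int = 50
    cgi_effect_range: tuple = (0.1, 0.4)  # |delta|, log2 per passage
    nb_dispersion: float = 0.01
    passage_days: int = 3

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.guides_per_gene <= 0:
            raise ValidationError("n_genes and guides_per_gene must be positive")
        if self.depth_per_sample <= 0:
            raise ValidationError("depth_per_sample must be positive")
        if self.n_cgi_genes > self.n_genes:
            raise ValidationError("n_cgi_genes exceeds n_genes")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")


@dataclass(frozen=True)
class SimTruth:
    """Planted parameters of a simulated screen.

    ``effect_mode`` is "per_passage" (expected CGI = delta * passages, the
    general model) or "constant" (expected CGI = delta at every collected
    timepoint, used by the definitional twofold presets).
    """

    guides: pd.DataFrame  # guide_id, gene, baseline_log2, guide_effect
    genes: pd.DataFrame  # gene, essential, fitness
    effects: pd.DataFrame  # gene, compound, delta
    passage_days: int = 3
    effect_mode: str = "per_passage"

    def expected_cgi(self, compound: str, timepoint: int) -> pd.Series:
        delta = (
            self.effects[self.effects["compound"] == compound]
            .set_index("gene")["delta"]
            .reindex(self.genes["gene"], fill_value=0.0)
            .astype(float)
        )
        if self.effect_mode == "constant":
            return delta
        return delta * (timepoint / self.passage_days)


def synthetic_library(
    n_genes: int = 1011, guides_per_gene: int = 3
) -> LibraryDefinition:
    """Synthetic stand-in for the targeted sgRNA library table.

    Produces ``n_genes`` gene symbols (known DDR symbols first, then generated
    SYG#### fillers) with ``guides_per_gene`` guides each, named
    ``<gene>_g<i>``.
    """
    genes = list(_KNOWN_GENES[:n_genes])
    genes += [f"SYG{i:04d}" for i in range(1, n_genes - len(genes) + 1)]
    records = [
        {"guide_id": f"{gene}_g{i}", "gene": gene}
        for gene in genes
        for i in range(1, guides_per_gene + 1)
    ]
    return LibraryDefinition(pd.DataFrame.from_records(records))


def _sample_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with the given mean; dispersion 0 = noise-free."""
    if dispersion == 0:
        return np.rint(mean).astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape=shape, scale=mean * dispersion)
    return rng.poisson(lam).astype(np.int64)


def _sample_sheet(cfg: SimConfig) -> SampleSheet:
    rows = [{"sample_id": "T0_pool", "condition": cfg.control_label,
             "timepoint": 0, "replicate": "pool"}]
    for cond in (cfg.control_label, *cfg.compounds):
        for t in cfg.timepoints:
            if t == 0:
                continue
            for rep in cfg.replicates:
                rows.append({"sample_id": f"{cond}_T{t}_{rep}", "condition": cond,
                             "timepoint": t, "replicate": rep})
    return SampleSheet(pd.DataFrame(rows))


def simulate_screen(
    cfg: SimConfig,
) -> tuple[CountMatrix, SampleSheet, LibraryDefinition, SimTruth]:
    """Generate a full screen: counts, sample sheet, library and truth."""
    rng = np.random.default_rng(cfg.seed)
    lib = synthetic_library(cfg.n_genes, cfg.guides_per_gene)
    genes = lib.genes
    n_guides = len(lib.guide_ids)

    n_essential = int(round(cfg.frac_essential * cfg.n_genes))
    essential_idx = rng.choice(cfg.n_genes, size=n_essential, replace=False)
    essential = np.zeros(cfg.n_genes, dtype=bool)
    essential[essential_idx] = True
    fitness = np.where(
        essential,
        rng.normal(cfg.essential_fitness_mean, cfg.essential_fitness_sd, cfg.n_genes),
        rng.normal(0.0, cfg.nonessential_fitness_sd, cfg.n_genes),
    )
    gene_table = pd.DataFrame({"gene": genes, "essential": essential, "fitness": fitness})

    nonessential_idx = np.flatnonzero(~essential)
    if cfg.n_cgi_genes > len(nonessential_idx):
        raise ValidationError("not enough non-essential genes to plant CGI effects")
    effect_rows = []
    lo, hi = cfg.cgi_effect_range
    for compound in cfg.compounds:
        chosen = rng.choice(nonessential_idx, size=cfg.n_cgi_genes, replace=False)
        magnitude = rng.uniform(lo, hi, size=cfg.n_cgi_genes)
        sign = rng.choice([-1.0, 1.0], size=cfg.n_cgi_genes)
        for i, g in enumerate(chosen):
            effect_rows.append(
                {"gene": genes[g], "compound": compound, "delta": sign[i] * magnitude[i]}
            )
    effects = pd.DataFrame(effect_rows, columns=["gene", "compound", "delta"])

    guide_gene = lib.gene_of.reindex(lib.guide_ids)
    gene_index = {g: i for i, g in enumerate(genes)}
    gidx = np.array([gene_index[g] for g in guide_gene])
    baseline = rng.normal(0.0, cfg.baseline_log2_sd, n_guides)
    guide_effect = rng.normal(0.0, cfg.guide_noise_sd, n_guides)
    guide_table = pd.DataFrame(
        {
            "guide_id": lib.guide_ids,
            "gene": guide_gene.to_numpy(),
            "baseline_log2": baseline,
            "guide_effect": guide_effect,
        }
    )

    delta_by_gene = {c: np.zeros(cfg.n_genes) for c in cfg.compounds}
    for row in effects.itertuples(index=False):
        delta_by_gene[row.compound][gene_index[row.gene]] = row.delta

    sheet = _sample_sheet(cfg)
    drift = fitness[gidx] + guide_effect  # log2 per passage, both arms
    columns = {}
    for row in sheet.table.itertuples(index=False):
        k = row.timepoint / cfg.passage_days
        log2_abund = baseline + k * drift
        if row.condition != cfg.control_label:
            log2_abund = log2_abund + k * delta_by_gene[row.condition][gidx]
        weights = np.exp2(log2_abund)
        mean = cfg.depth_per_sample * weights / weights.sum()
        columns[row.sample_id] = _sample_counts(rng, mean, cfg.nb_dispersion)
    counts = CountMatrix(pd.DataFrame(columns, index=lib.guide_ids))

    truth = SimTruth(
        guides=guide_table,
        genes=gene_table,
        effects=effects,
        passage_days=cfg.passage_days,
    )
    return counts, sheet, lib, truth


def preset_config(name: str, seed: int) -> SimConfig:
    """Named study conditions: "default" (50 planted CGI genes) or "null"."""
    if name == "default":
        return SimConfig(seed=seed)
    if name == "null":
        return SimConfig(seed=seed, n_cgi_genes=0)
    raise ValidationError(f"unknown preset {name!r}")


def twofold_preset(
    seed: int,
    factor: float = 0.5,
    n_genes: int = 1011,
    guides_per_gene: int = 3,
) -> tuple[CountMatrix, SampleSheet, LibraryDefinition, SimTruth]:
    """Definitional fixture: one gene's treated counts scaled by a constant.

    The planted gene's compound-arm counts equal its control-arm trajectory
    multiplied by ``factor`` at every collected timepoint, with zero guide
    noise and noise-free counts, so its true CGI is log2(factor) at every
    timepoint (-1 for factor 0.5, +1 for factor 2).
    """
    if factor <= 0:
        raise ValidationError("factor must be positive")
    cfg = SimConfig(
        seed=seed,
        n_genes=n_genes,
        guides_per_gene=guides_per_gene,
        n_cgi_genes=0,
        guide_noise_sd=0.0,
        nb_dispersion=0.0,
    )
    rng = np.random.default_rng(cfg.seed)
    lib = synthetic_library(cfg.n_genes, cfg.guides_per_gene)
    genes = lib.genes
    n_guides = len(lib.guide_ids)

    n_essential = int(round(cfg.frac_essential * cfg.n_genes))
    essential_idx = rng.choice(cfg.n_genes, size=n_essential, replace=False)
    essential = np.zeros(cfg.n_genes, dtype=bool)
    essential[essential_idx] = True
    fitness = np.where(
        essential,
        rng.normal(cfg.essential_fitness_mean, cfg.essential_fitness_sd, cfg.n_genes),
        rng.normal(0.0, cfg.nonessential_fitness_sd, cfg.n_genes),
    )
    planted = genes[int(rng.choice(np.flatnonzero(~essential)))]

    guide_gene = lib.gene_of.reindex(lib.guide_ids)
    gene_index = {g: i for i, g in enumerate(genes)}
    gidx = np.array([gene_index[g] for g in guide_gene])
    baseline = rng.normal(0.0, cfg.baseline_log2_sd, n_guides)
    planted_mask = (guide_gene == planted).to_numpy()

    sheet = _sample_sheet(cfg)
    drift = fitness[gidx]
    columns = {}
    for row in sheet.table.itertuples(index=False):
        k = row.timepoint / cfg.passage_days
        log2_abund = baseline + k * drift
        if row.condition != cfg.control_label and row.timepoint > 0:
            log2_abund = log2_abund + np.where(planted_mask, np.log2(factor), 0.0)
        weights = np.exp2(log2_abund)
        mean = cfg.depth_per_sample * weights / weights.sum()
        columns[row.sample_id] = _sample_counts(rng, mean, cfg.nb_dispersion)
    counts = CountMatrix(pd.DataFrame(columns, index=lib.guide_ids))

    truth = SimTruth(
        guides=pd.DataFrame(
            {
                "guide_id": lib.guide_ids,
                "gene": guide_gene.to_numpy(),
                "baseline_log2": baseline,
                "guide_effect": 0.0,
            }
        ),
        genes=pd.DataFrame({"gene": genes, "essential": essential, "fitness": fitness}),
        effects=pd.DataFrame(
            [{"gene": planted, "compound": cfg.compounds[0], "delta": float(np.log2(factor))}]
        ),
        passage_days=cfg.passage_days,
        effect_mode="constant",
    )
    return counts, sheet, lib, truth


def recovery_report(
    truth: SimTruth,
    scored: pd.DataFrame,
    gene_fitness: pd.DataFrame | None = None,
    control_label: str = "DMSO",
    cgi_cutoff: float = 0.7,
    fdr_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Compare estimated CGIs and hit calls with the planted truth.

    Per (compound, timepoint): Pearson r between expected and estimated CGI,
    the fraction of delta = 0 genes called as hits (false-hit fraction), and,
    when ``gene_fitness`` (a gene x (condition, timepoint, replicate) LFC
    frame) is supplied, the essential-dropout AUC against the planted
    essential flags using the replicate-mean control LFC.
    """
    truth_genes = set(truth.genes["gene"])
    if set(scored["gene"]) != truth_genes:
        raise ValidationError("scored table and truth cover different gene universes")
    essential = set(truth.genes.loc[truth.genes["essential"], "gene"])
    rows = []
    for (compound, timepoint), g in scored.groupby(["compound", "timepoint"]):
        expected = truth.expected_cgi(compound, int(timepoint))
        est = g.set_index("gene")["cgi"].reindex(expected.index)
        mask = est.notna()
        if expected[mask].std() > 0 and est[mask].std() > 0:
            r = float(np.corrcoef(expected[mask], est[mask])[0, 1])
        else:
            r = np.nan  # no planted spread (e.g. null config)
        null_genes = set(expected.index[expected == 0.0])
        null_rows = g[g["gene"].isin(null_genes)]
        false_hits = float((null_rows["hit"] != 0).mean()) if len(null_rows) else np.nan
        row = {
            "compound": compound,
            "timepoint": int(timepoint),
            "pearson_r": r,
            "false_hit_fraction": false_hits,
        }
        if gene_fitness is not None:
            ctrl = gene_fitness.T.groupby(level=["condition", "timepoint"]).mean().T
            lfc = ctrl[(control_label, int(timepoint))]
            row["auc_essential"] = essential_dropout_auc(lfc, essential)
        rows.append(row)
    return pd.DataFrame(rows)
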