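"""Synthetic-data generators with planted ground truth.

Every generator is a pure function of its configuration and seed, and
emulates one input class of the convergence pipeline:

* knockout screens: per-(KO, cell type) differential-expression tables
  with a planted set of shared-direction convergent genes,
* Gaussian populations over bulk + cell-type expression with GRN-sparse
  precision structure and a deconvolution constraint,
* toy ontologies with true-path-propagated annotations,
* long-format larval behavior tables with batch random effects,
* gRNA count tables with scramble controls across sorted fractions.

Two small preprocessing operators on expression matrices are housed here
too: the low-expression filter and the bin-matched module score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pertconv import lnctp as _lnctp
from pertconv.meta import DEGTable
from pertconv.semsim import Ontology

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Perturbation screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Study conditions for a simulated knockout screen.

    The default shape mirrors a pooled screen of nine knockouts profiled in
    four cell-type contexts.  Standard errors are ``noise_sd / sqrt(per_ko_n)``
    with per-gene lognormal jitter (sd 0.2) so inverse-variance and
    sample-size weighting differ testably.  A planted convergent gene draws
    one effect magnitude from Normal(effect_size_mean, effect_size_sd),
    shared (with its sign) across every KO in the designated cell type, so
    planted heterogeneity stays at the measurement-noise level the
    convergence definition tolerates.
    """

    n_kos: int = 9
    n_genes: int = 2000
    cell_types: tuple = ("NPC", "iGLUT_immature", "iGLUT_mature", "iGABA_mature")
    n_convergent_true: int = 100
    effect_size_mean: float = 1.0
    effect_size_sd: float = 0.2
    noise_sd: float = 0.5
    per_ko_n: int = 20
    convergent_cell_type: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_kos <= 0 or self.n_genes <= 0:
            raise ConfigError("counts must be positive")
        if self.n_convergent_true > self.n_genes:
            raise ConfigError("n_convergent_true must be <= n_genes")
        if self.n_convergent_true < 0:
            raise ConfigError("n_convergent_true must be >= 0")
        if self.effect_size_sd < 0 or self.noise_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if self.per_ko_n < 2:
            raise ConfigError("per_ko_n must be >= 2")
        if self.convergent_cell_type is None:
            self.convergent_cell_type = self.cell_types[0]
        if self.convergent_cell_type not in self.cell_types:
            raise ConfigError("convergent_cell_type must be one of cell_types")


def simulate_perturbation_screen(
    config: ScreenSimConfig,
) -> tuple[list[DEGTable], pd.DataFrame]:
    """Simulate per-(KO, cell type) DEG tables with planted convergent genes.

    Returns the tables and a truth frame (index gene) with columns
    ``convergent`` (bool) and ``sign`` (+1/-1, 0 for non-planted genes).
    Non-planted genes carry a zero true effect; their observed log2FCs are
    pure noise with independent random signs across KOs.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    kos = [f"KO{i+1:02d}" for i in range(config.n_kos)]

    planted = rng.choice(config.n_genes, size=config.n_convergent_true, replace=False)
    signs = np.zeros(config.n_genes, dtype=int)
    magnitudes = np.zeros(config.n_genes)
    if config.n_convergent_true:
        signs[planted] = rng.choice([-1, 1], size=config.n_convergent_true)
        draw = rng.normal(
            config.effect_size_mean, config.effect_size_sd, size=config.n_convergent_true
        )
        magnitudes[planted] = np.abs(draw)

    tables = []
    for cell_type in config.cell_types:
        convergent_here = cell_type == config.convergent_cell_type
        for ko in kos:
            se = (
                config.noise_sd
                / np.sqrt(config.per_ko_n)
                * rng.lognormal(mean=0.0, sigma=0.2, size=config.n_genes)
            )
            true = signs * magnitudes if convergent_here else np.zeros(config.n_genes)
            log2fc = true + rng.normal(0.0, se)
            z = log2fc / se
            pvalue = 2.0 * stats.norm.sf(np.abs(z))
            tables.append(
                DEGTable(
                    ko_id=ko,
                    cell_type=cell_type,
                    data=pd.DataFrame(
                        {
                            "gene_id": genes,
                            "log2fc": log2fc,
                            "se": se,
                            "pvalue": pvalue,
                            "n": config.per_ko_n,
                        }
                    ),
                )
            )

    truth = pd.DataFrame(
        {"convergent": signs != 0, "sign": signs},
        index=pd.Index(genes, name="gene_id"),
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Gaussian population with GRN structure
# ---------------------------------------------------------------------------

def simulate_lnctp_population(
    panel,
    grn: dict,
    n_individuals: int,
    lambda_: float,
    fractions,
    seed: int | None = None,
) -> tuple[pd.DataFrame, "_lnctp.LnctpModel"]:
    """Sample a population from the GRN-structured Gaussian energy model.

    Returns (samples, generating model); samples are individuals x
    (context, gene) with contexts bulk plus the cell types named in
    ``grn``.  The generating model is returned for recovery tests.
    """
    model = _lnctp.assemble_model(
        panel=panel, grn_edges=grn, lambda_=lambda_, cell_fractions=fractions
    )
    samples = _lnctp.sample_model(model, n=n_individuals, seed=seed)
    return samples, model


# ---------------------------------------------------------------------------
# Toy ontology
# ---------------------------------------------------------------------------

def simulate_ontology(
    n_terms: int,
    max_depth: int,
    n_genes: int,
    seed: int | None = None,
    namespace: str = "synthetic",
) -> Ontology:
    """Random rooted DAG with true-path-propagated gene annotations.

    Term 0 is the root; each later term attaches to 1-2 existing terms of
    depth < ``max_depth``.  Each gene gets 1-3 direct annotations (closure
    to ancestors happens inside :class:`~pertconv.semsim.Ontology`), and
    every gene is annotated to the root.
    """
    if n_terms < 1:
        raise ConfigError("need at least the root term")
    rng = np.random.default_rng(seed)
    terms = [f"T{i:04d}" for i in range(n_terms)]
    parents: dict[str, set] = {terms[0]: set()}
    depth = {terms[0]: 0}
    for t in terms[1:]:
        eligible = [u for u in parents if depth[u] < max_depth]
        if not eligible:
            eligible = [terms[0]]
        n_par = 1 if len(eligible) == 1 else int(rng.integers(1, 3))
        chosen = rng.choice(eligible, size=min(n_par, len(eligible)), replace=False)
        parents[t] = set(chosen)
        depth[t] = max(depth[c] for c in chosen) + 1

    genes = [f"g{i:05d}" for i in range(n_genes)]
    annotations = {}
    for g in genes:
        n_ann = int(rng.integers(1, 4))
        direct = set(rng.choice(terms, size=min(n_ann, len(terms)), replace=False))
        direct.add(terms[0])
        annotations[g] = direct
    return Ontology(parents=parents, annotations=annotations, namespace=namespace)


# ---------------------------------------------------------------------------
# Behavior tables
# ---------------------------------------------------------------------------

def default_behavior_parameters() -> list[str]:
    """The 24 sleep-wake and visual-startle parameter labels."""
    sleep = [
        "total_activity", "total_sleep", "waking_activity",
        "rest_bouts", "sleep_length", "sleep_latency",
    ]
    startle = [
        "startle_intensity_avg", "post_stim_activity", "first_stim_activity",
        "stim_vs_post_activity", "first_stim_intensity", "final_stim_intensity",
    ]
    return (
        [f"day_{p}" for p in sleep]
        + [f"night_{p}" for p in sleep]
        + [f"vsr_off_{p}" for p in startle]
        + [f"vsr_on_{p}" for p in startle]
    )


def simulate_behavior_table(
    n_per_group: int,
    parameters=None,
    genotype_effects: dict | None = None,
    drug_effects: dict | None = None,
    n_batches: int = 3,
    batch_sd: float = 0.5,
    residual_sd: float = 1.0,
    include_drug_groups: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Long-format larval behavior records with planted group effects.

    Groups: control+vehicle and mutant+vehicle always; mutant+drug when
    ``include_drug_groups``.  Values are baseline 0 plus genotype shift
    (mutant groups), drug shift (drug groups), a Gaussian batch intercept
    per (batch, parameter) and Gaussian residual noise.
    """
    if n_per_group < 3:
        raise ConfigError("n_per_group must be >= 3")
    params = list(parameters) if parameters is not None else default_behavior_parameters()
    genotype_effects = genotype_effects or {}
    drug_effects = drug_effects or {}
    rng = np.random.default_rng(seed)
    batches = [f"batch{b+1}" for b in range(n_batches)]
    batch_fx = {
        (b, p): rng.normal(0.0, batch_sd) for b in batches for p in params
    }

    groups = [("control", "vehicle"), ("mutant", "vehicle")]
    if include_drug_groups:
        groups.append(("mutant", "drug"))

    rows = []
    larva_counter = 0
    for genotype, treatment in groups:
        for _ in range(n_per_group):
            larva = f"larva{larva_counter:04d}"
            larva_counter += 1
            batch = batches[int(rng.integers(0, n_batches))]
            for p in params:
                value = batch_fx[(batch, p)] + rng.normal(0.0, residual_sd)
                if genotype == "mutant":
                    value += genotype_effects.get(p, 0.0)
                if treatment == "drug":
                    value += drug_effects.get(p, 0.0)
                rows.append(
                    {
                        "larva_id": larva,
                        "genotype": genotype,
                        "treatment": treatment,
                        "batch_date": batch,
                        "parameter": p,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gRNA counts
# ---------------------------------------------------------------------------

def simulate_grna_counts(
    genes,
    grnas_per_gene: int = 4,
    scramble_frac: float = 0.1,
    fractions=("high", "low"),
    depth: int = 1_000_000,
    planted_gene_shifts: dict | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial gRNA counts across sorted fractions with scramble controls.

    ``planted_gene_shifts`` maps (gene, fraction) -> log2 shift applied to
    the gene's guides in that sample.  Returns (counts: gRNA x sample,
    annotation: gene_id + scramble flag per gRNA).
    """
    if scramble_frac <= 0:
        raise ConfigError("scramble_frac must be > 0")
    genes = list(genes)
    planted_gene_shifts = planted_gene_shifts or {}
    rng = np.random.default_rng(seed)

    grna_ids, grna_gene = [], []
    for g in genes:
        for i in range(grnas_per_gene):
            grna_ids.append(f"{g}_sg{i+1}")
            grna_gene.append(g)
    n_targeting = len(grna_ids)
    n_scramble = max(1, round(scramble_frac * n_targeting / (1.0 - scramble_frac)))
    for i in range(n_scramble):
        grna_ids.append(f"scramble_sg{i+1}")
        grna_gene.append(None)

    base = rng.lognormal(mean=0.0, sigma=0.25, size=len(grna_ids))
    counts = {}
    for sample in fractions:
        weights = base.copy()
        for idx, g in enumerate(grna_gene):
            if g is not None and (g, sample) in planted_gene_shifts:
                weights[idx] *= 2.0 ** planted_gene_shifts[(g, sample)]
        probs = weights / weights.sum()
        counts[sample] = rng.multinomial(depth, probs)
    count_df = pd.DataFrame(counts, index=pd.Index(grna_ids, name="grna_id"))
    annot = pd.DataFrame(
        {
            "gene_id": [g if g is not None else "" for g in grna_gene],
            "scramble": [g is None for g in grna_gene],
        },
        index=count_df.index,
    )
    return count_df, annot


# ---------------------------------------------------------------------------
# Expression-matrix operators
# ---------------------------------------------------------------------------

def filter_low_expression(
    counts: pd.DataFrame,
    min_count: int = 2,
    min_frac_samples: float = 0.90,
) -> pd.DataFrame:
    """Drop lowly expressed genes from a genes x samples count matrix.

    A gene is removed iff the fraction of samples with count < ``min_count``
    is >= ``min_frac_samples`` (ties at the boundary remove).  Survivor
    order is preserved.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    frac_low = (counts < min_count).mean(axis=1)
    keep = frac_low < min_frac_samples
    out = counts.loc[keep]
    if out.empty:
        warnings.warn("low-expression filter removed every gene")
    return out


def module_score(
    expr: pd.DataFrame,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int | None = None,
    bin_on: pd.Series | None = None,
) -> pd.Series:
    """Expression-bin-matched module score per sample.

    ``expr`` is genes x samples.  The score is the mean expression of the
    gene set minus the mean of control genes drawn (``n_ctrl`` per set
    gene, with replacement) from equal-frequency bins of average
    expression, the convention of cell-cycle-style module scoring.
    ``bin_on`` optionally supplies the per-gene averages used for binning
    (e.g. a baseline profile); default is the matrix's own row means.
    """
    gene_set = [g for g in gene_set]
    if not gene_set:
        raise ValueError("gene_set must be nonempty")
    missing = set(gene_set) - set(expr.index)
    if missing:
        raise ValueError(f"gene_set members missing from expression: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    avg = bin_on.reindex(expr.index) if bin_on is not None else expr.mean(axis=1)
    n_bins_eff = min(n_bins, avg.nunique())
    bins = pd.qcut(avg.rank(method="first"), q=n_bins_eff, labels=False)
    in_set = avg.index.isin(gene_set)
    bin_members = {
        b: avg.index[(bins == b) & ~in_set].to_numpy() for b in range(n_bins_eff)
    }

    ctrl_genes: list[str] = []
    for g in gene_set:
        pool = bin_members[int(bins.loc[g])]
        if len(pool) == 0:  # bin exhausted by the set itself
            pool = avg.index[~in_set].to_numpy()
        ctrl_genes.extend(rng.choice(pool, size=n_ctrl, replace=True))
    set_mean = expr.loc[gene_set].mean(axis=0)
    ctrl_mean = expr.loc[ctrl_genes].mean(axis=0)
    return set_mean - ctrl_mean
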