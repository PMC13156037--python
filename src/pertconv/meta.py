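"""Meta-analysis of differential expression across knockout perturbations.

Convergent genes are those differentially expressed with a significant,
heterogeneity-free and direction-consistent effect across *every* knockout
in a perturbation set.  The default combination rule is the sample-size
weighted (signed Stouffer) Z, with an inverse-variance pass used for the
pooled effect estimate and Cochran's Q heterogeneity test.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300

DEG_COLUMNS = ["gene_id", "log2fc", "se", "pvalue", "n"]


@dataclass
class DEGTable:
    """Per-perturbation differential-expression summary for one cell type.

    ``data`` holds one row per gene with columns ``gene_id``, ``log2fc``,
    ``se`` (> 0), ``pvalue`` and ``n`` (sample size behind the contrast).
    """

    ko_id: str
    cell_type: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DEG_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"DEGTable missing columns: {missing}")
        if self.data["gene_id"].duplicated().any():
            raise ValueError("DEGTable has duplicated gene ids")
        if (self.data["se"] <= 0).any():
            raise ValueError("DEGTable requires se > 0 for every gene")
        pv = self.data["pvalue"]
        if ((pv < 0) | (pv > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("gene_id")


@dataclass
class MetaResult:
    """Gene-wise meta-analysis summary plus the per-study sign matrix."""

    table: pd.DataFrame  # index gene; z_meta, p_meta, q_value, beta_meta,
    #                      cochran_q, p_het, n_studies, direction_consistent, sign
    signs: pd.DataFrame  # gene x study sign of log2fc (0 where log2fc == 0)
    method: str = "sample_size"
    dropped_genes: list = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def _signed_z(pvalue: np.ndarray, log2fc: np.ndarray) -> np.ndarray:
    """Two-sided p plus effect sign -> signed normal quantile."""
    p = np.clip(pvalue, _P_FLOOR, 1.0)
    z = stats.norm.isf(p / 2.0)
    return np.sign(log2fc) * z


def meta_analyze(
    tables: list[DEGTable],
    method: str = "sample_size",
    allow_single: bool = False,
) -> MetaResult:
    """Combine per-knockout DEG tables into one meta-analysis.

    Parameters
    ----------
    tables
        DEG tables over one gene universe (genes missing from any table are
        dropped and logged).
    method
        ``"sample_size"``: signed Stouffer with weights w_i = sqrt(n_i),
        z_meta = sum(w_i Z_i) / sqrt(sum(w_i^2)).
        ``"inverse_variance"``: pooled effect beta_hat = sum(b_i/se_i^2) /
        sum(1/se_i^2), z from beta_hat / se_pooled.
    allow_single
        Permit a degenerate single-table call (identity pass-through).

    Cochran's Q is always computed on the effect scale with inverse-variance
    weights: Q = sum((b_i - beta_hat_IV)^2 / se_i^2), df = k - 1.  BH FDR is
    applied to p_meta over the analyzed genes.
    """
    if method not in ("sample_size", "inverse_variance"):
        raise ValueError(f"unknown method {method!r}")
    if len(tables) < 2 and not allow_single:
        raise ValueError("need >= 2 tables (pass allow_single=True to override)")

    frames = {t.ko_id: t.indexed() for t in tables}
    if len(frames) != len(tables):
        raise ValueError("duplicate ko_id among tables")

    counts = pd.Series(0, index=pd.Index([], name="gene_id"), dtype=int)
    for df in frames.values():
        counts = counts.add(pd.Series(1, index=df.index), fill_value=0)
    min_k = 1 if allow_single and len(tables) == 1 else 2
    keep = counts.index[counts >= min_k]
    # restrict to genes present in *all* tables: the convergence definition
    # requires a direction in every perturbation
    shared = counts.index[counts == len(tables)]
    dropped = sorted(set(counts.index) - set(shared))
    if dropped:
        logger.warning("dropping %d genes absent from >=1 table", len(dropped))
    genes = shared.sort_values() if len(shared) else keep.sort_values()

    ko_ids = sorted(frames)
    beta = np.column_stack([frames[k].loc[genes, "log2fc"].to_numpy(float) for k in ko_ids])
    se = np.column_stack([frames[k].loc[genes, "se"].to_numpy(float) for k in ko_ids])
    pval = np.column_stack([frames[k].loc[genes, "pvalue"].to_numpy(float) for k in ko_ids])
    nobs = np.column_stack([frames[k].loc[genes, "n"].to_numpy(float) for k in ko_ids])
    if (se <= 0).any():
        raise ValueError("se must be > 0")

    k = len(ko_ids)
    w_iv = 1.0 / se**2
    beta_iv = (beta * w_iv).sum(axis=1) / w_iv.sum(axis=1)

    if method == "sample_size":
        z_i = _signed_z(pval, beta)
        w = np.sqrt(nobs)
        z_meta = (w * z_i).sum(axis=1) / np.sqrt((w**2).sum(axis=1))
        beta_meta = beta_iv
    else:
        se_pooled = np.sqrt(1.0 / w_iv.sum(axis=1))
        z_meta = beta_iv / se_pooled
        beta_meta = beta_iv

    p_meta = 2.0 * stats.norm.sf(np.abs(z_meta))
    p_meta = np.clip(p_meta, _P_FLOOR, 1.0)

    if k >= 2:
        q_stat = (w_iv * (beta - beta_iv[:, None]) ** 2).sum(axis=1)
        p_het = stats.chi2.sf(q_stat, df=k - 1)
        p_het = np.where(q_stat <= 0, 1.0, p_het)
    else:
        q_stat = np.zeros(len(genes))
        p_het = np.ones(len(genes))

    q_value = bh_adjust(p_meta)

    signs = np.sign(beta)
    consistent = (signs == signs[:, [0]]).all(axis=1) & (signs[:, 0] != 0)
    call_sign = np.where(consistent, signs[:, 0], 0).astype(int)

    table = pd.DataFrame(
        {
            "z_meta": z_meta,
            "p_meta": p_meta,
            "q_value": q_value,
            "beta_meta": beta_meta,
            "cochran_q": q_stat,
            "p_het": p_het,
            "n_studies": k,
            "direction_consistent": consistent,
            "sign": call_sign,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    sign_df = pd.DataFrame(signs.astype(int), index=table.index, columns=ko_ids)
    return MetaResult(table=table, signs=sign_df, method=method, dropped_genes=dropped)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-stable)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_convergent(
    meta: MetaResult,
    fdr_max: float = 0.05,
    phet_min: float = 0.05,
) -> pd.DataFrame:
    """Call convergent genes from a meta-analysis.

    A gene is convergent iff FDR-adjusted p_meta < ``fdr_max``, Cochran's Q
    p_het > ``phet_min``, and every per-study log2FC carries the identical
    nonzero sign.  Returns the called subset of the meta table (with sign).
    """
    t = meta.table
    mask = (t["q_value"] < fdr_max) & (t["p_het"] > phet_min) & t["direction_consistent"]
    return t.loc[mask, ["z_meta", "q_value", "p_het", "sign"]].copy()


def convergence_ratio(n_convergent: int, deg_counts) -> float:
    """Gene-level convergence: n convergent genes over mean per-KO DEG count.

    Returns NaN (with a warning) when the mean DEG count is zero.
    """
    counts = np.asarray(list(deg_counts), dtype=float)
    if counts.size == 0:
        raise ValueError("deg_counts must be nonempty")
    mean = counts.mean()
    if mean == 0:
        warnings.warn("mean DEG count is 0; convergence ratio undefined")
        return float("nan")
    return float(n_convergent) / mean


def enumerate_ko_subsets(
    ko_ids,
    min_size: int = 2,
    max_size: int | None = None,
    sample: int | None = None,
    seed: int | None = None,
) -> list[tuple]:
    """All KO subsets with min_size <= |S| <= max_size, lexicographic.

    ``sample`` optionally down-samples (without replacement, seeded) to that
    many subsets while preserving lexicographic order.
    """
    ids = sorted(ko_ids)
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if max_size is None:
        max_size = len(ids)
    if max_size > len(ids):
        raise ValueError("max_size exceeds number of KOs")
    subsets: list[tuple] = []
    for size in range(min_size, max_size + 1):
        subsets.extend(itertools.combinations(ids, size))
    if sample is not None and sample < len(subsets):
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(len(subsets), size=sample, replace=False))
        subsets = [subsets[i] for i in pick]
    return subsets


def rrho_map(
    ranked_a: pd.Series,
    ranked_b: pd.Series,
    step: int | None = None,
) -> pd.DataFrame:
    """Rank-rank hypergeometric overlap map of signed -log10 p-values.

    Both inputs map gene -> signed score over the same universe.  Genes are
    ranked by descending score; for each threshold pair (i*step, j*step) the
    hypergeometric overlap p of the two top sets is computed.  Positive
    scores mark overlap above expectation (concordant quadrants), negative
    scores overlap below expectation.
    """
    if set(ranked_a.index) != set(ranked_b.index):
        raise ValueError("rankings must cover the same gene universe")
    n = len(ranked_a)
    if step is None:
        step = int(np.ceil(n / 100))
    if step <= 0:
        raise ValueError("step must be positive")

    order_a = ranked_a.sort_values(ascending=False, kind="mergesort").index
    order_b = ranked_b.sort_values(ascending=False, kind="mergesort").index
    rank_in_b = pd.Series(np.arange(n), index=order_b)
    pos_a_in_b = rank_in_b.loc[order_a].to_numpy()

    thresholds = np.arange(step, n + 1, step)
    scores = np.empty((len(thresholds), len(thresholds)))
    for ii, i in enumerate(thresholds):
        ranks_b_of_top_a = np.sort(pos_a_in_b[:i])
        for jj, j in enumerate(thresholds):
            k_overlap = int(np.searchsorted(ranks_b_of_top_a, j, side="left"))
            expected = i * j / n
            if k_overlap >= expected:
                p = stats.hypergeom.sf(k_overlap - 1, n, i, j)
                sgn = 1.0
            else:
                p = stats.hypergeom.cdf(k_overlap, n, i, j)
                sgn = -1.0
            scores[ii, jj] = sgn * -np.log10(max(p, _P_FLOOR))
    return pd.DataFrame(scores, index=thresholds, columns=thresholds)


def correlate_profiles(
    logfc_matrix: pd.DataFrame,
    p_matrix: pd.DataFrame,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Pearson correlation between perturbation log2FC profiles.

    For each pair of perturbations the correlation is taken over the union
    of genes nominally significant (p < ``p_max``) in either member; pairs
    with fewer than 3 such genes get NaN.
    """
    if not logfc_matrix.index.equals(p_matrix.index) or not logfc_matrix.columns.equals(
        p_matrix.columns
    ):
        raise ValueError("logfc and p matrices must share index and columns")
    perts = list(logfc_matrix.columns)
    out = pd.DataFrame(np.eye(len(perts)), index=perts, columns=perts)
    sig = p_matrix < p_max
    for a, b in itertools.combinations(perts, 2):
        mask = (sig[a] | sig[b]).to_numpy()
        if mask.sum() < 3:
            r = np.nan
        else:
            x = logfc_matrix.loc[mask, a].to_numpy(float)
            y = logfc_matrix.loc[mask, b].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                r = np.nan
            else:
                r = float(stats.pearsonr(x, y).statistic)
        out.loc[a, b] = out.loc[b, a] = r
    return out
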