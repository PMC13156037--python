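"""Enrichment machinery: over-representation, preranked GSEA, BH FDR.

The preranked GSEA statistic is the weighted Kolmogorov-Smirnov running
sum: set members add |score|^p (normalized to the set total), non-members
subtract 1/(N - Nh); the enrichment score is the signed extremum, the
leading edge the members up to it, the p-value comes from gene-label
permutation and NES normalizes by the mean |permuted ES| of the same sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pertconv.meta import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_id: str
    overlap: int
    enrichment_ratio: float = float("nan")
    es: float = float("nan")
    nes: float = float("nan")
    p: float = float("nan")
    fdr: float = float("nan")
    leading_edge: list = field(default_factory=list)


def hypergeom_ora(query, gene_set, background, set_id: str = "set") -> EnrichmentResult:
    """One-sided upper-tail hypergeometric over-representation test.

    ``query`` and ``gene_set`` must be subsets of ``background``; the
    enrichment ratio is observed over expected overlap.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    q, s = set(query), set(gene_set)
    if q - bg or s - bg:
        raise ValueError("query and gene_set must be subsets of background")
    n_bg, n_q, n_s = len(bg), len(q), len(s)
    k = len(q & s)
    expected = n_q * n_s / n_bg
    ratio = k / expected if expected > 0 else float("nan")
    p = float(stats.hypergeom.sf(k - 1, n_bg, n_s, n_q))
    return EnrichmentResult(
        set_id=set_id, overlap=k, enrichment_ratio=ratio, p=p,
        leading_edge=sorted(q & s),
    )


def _es_walk(in_set: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    """Running-sum extremum and its position for a membership indicator.

    ``weights`` are the per-position hit increments (already |score|^p);
    misses decrement by 1/(N - Nh).
    """
    n = len(in_set)
    nh = int(in_set.sum())
    if nh == 0 or nh == n:
        return 0.0, 0
    hit_total = weights[in_set].sum()
    if hit_total <= 0:
        # degenerate all-zero scores: fall back to unweighted steps
        inc = np.where(in_set, 1.0 / nh, -1.0 / (n - nh))
    else:
        inc = np.where(in_set, weights / hit_total, -1.0 / (n - nh))
    path = np.cumsum(inc)
    imax = int(np.argmax(path))
    imin = int(np.argmin(path))
    if path[imax] >= -path[imin]:
        return float(path[imax]), imax
    return float(path[imin]), imin


def gsea_preranked(
    ranked: pd.Series,
    gene_set,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    set_id: str = "set",
) -> EnrichmentResult:
    """Preranked GSEA of one gene set against a signed ranking.

    ``ranked`` maps gene -> signed score; genes are walked in descending
    score order.  Requires >= 3 set members in the ranking (else skipped,
    returned with NaN statistics and a log message).  The permutation p is
    one-sided against same-sign permuted ES.
    """
    order = ranked.sort_values(ascending=False, kind="mergesort")
    genes = order.index.to_numpy()
    scores = order.to_numpy(float)
    member = np.isin(genes, list(gene_set))
    nh = int(member.sum())
    if nh < 3:
        logger.warning("gene set %s has <3 members in the ranking; skipped", set_id)
        return EnrichmentResult(set_id=set_id, overlap=nh)

    weights = np.abs(scores) ** weight_p
    es, pos = _es_walk(member, weights)

    if es > 0:
        lead_mask = member & (np.arange(len(genes)) <= pos)
    else:
        lead_mask = member & (np.arange(len(genes)) >= pos)
    leading = [g for g in genes[lead_mask]]

    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_perm)
    idx = np.arange(len(genes))
    for b in range(n_perm):
        hit_idx = rng.choice(idx, size=nh, replace=False)
        pm = np.zeros(len(genes), dtype=bool)
        pm[hit_idx] = True
        perm_es[b], _ = _es_walk(pm, weights)

    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    if len(same_sign) == 0:
        p = 1.0 / (n_perm + 1)
        nes = float("nan")
    else:
        p = (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (len(same_sign) + 1)
        nes = es / np.mean(np.abs(same_sign))
    return EnrichmentResult(
        set_id=set_id, overlap=nh, es=es, nes=float(nes), p=float(p),
        leading_edge=leading,
    )


def gsea_collection(
    ranked: pd.Series,
    gene_sets: dict,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """GSEA over a collection with BH FDR across the tested sets."""
    results = []
    for i, (name, members) in enumerate(sorted(gene_sets.items())):
        sub_seed = None if seed is None else seed + i
        results.append(
            gsea_preranked(ranked, members, weight_p, n_perm, sub_seed, set_id=name)
        )
    df = pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "overlap": [r.overlap for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p for r in results],
            "leading_edge": [r.leading_edge for r in results],
        }
    ).set_index("set_id")
    tested = df["p"].notna()
    df["fdr"] = np.nan
    if tested.any():
        df.loc[tested, "fdr"] = bh_adjust(df.loc[tested, "p"].to_numpy())
    return df


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (stable under input order)."""
    return bh_adjust(np.asarray(pvalues, dtype=float))


def downsample_enrichment(
    query,
    gene_sets: dict,
    background,
    sizes=(100, 250, 500, 750, 1000),
    reps: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Robustness of ORA to gene-set size: seeded subsamples per (set, size).

    Sets smaller than a requested size are skipped for that size (logged).
    Returns one row per (set, size, rep) with the subsampled ORA overlap
    and p-value.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name in sorted(gene_sets):
        members = sorted(gene_sets[name])
        for size in sizes:
            if len(members) < size:
                logger.info("set %s smaller than %d; skipped", name, size)
                continue
            for rep in range(reps):
                sub = rng.choice(members, size=size, replace=False)
                res = hypergeom_ora(query, sub, background, set_id=name)
                rows.append(
                    {
                        "set_id": name,
                        "size": size,
                        "rep": rep,
                        "overlap": res.overlap,
                        "enrichment_ratio": res.enrichment_ratio,
                        "p": res.p,
                    }
                )
    return pd.DataFrame(rows)
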