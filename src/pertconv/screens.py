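"""gRNA abundance normalization and gene-level log2 fold changes.

Sorted-fraction (e.g. mitochondrial-membrane-potential FACS) and
condition-contrast (e.g. induced vs uninduced organoid) screens share the
same contract: per-sample gRNA counts are normalized to the summed counts
of the scramble (nontargeting) guides, summed per gene after dropping
low-efficiency guides, and compared as log2 ratios.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def normalize_to_scramble(counts: pd.DataFrame, scramble_mask: pd.Series) -> pd.DataFrame:
    """Divide each gRNA count by its sample's summed scramble counts.

    ``counts`` is gRNA x sample; ``scramble_mask`` flags scramble gRNAs by
    index.  Depth-invariant by construction.  Raises when a sample has a
    zero scramble total.
    """
    mask = scramble_mask.reindex(counts.index).fillna(False).astype(bool)
    totals = counts.loc[mask].sum(axis=0)
    bad = totals.index[totals <= 0]
    if len(bad):
        raise ValueError(f"zero scramble total in sample(s): {list(bad)}")
    return counts.div(totals, axis=1)


def gene_abundance(
    normalized: pd.DataFrame,
    grna_to_gene: pd.Series,
    efficiencies: pd.Series | None = None,
    efficiency_min: float = 0.05,
) -> pd.DataFrame:
    """Sum normalized abundances of retained gRNAs per gene.

    Guides with editing efficiency strictly below ``efficiency_min`` are
    excluded when efficiencies are provided.  Genes losing all their guides
    are dropped (logged).
    """
    targeting = normalized.loc[normalized.index.intersection(grna_to_gene.index)]
    unmapped = normalized.index.difference(grna_to_gene.index)
    if len(unmapped):
        logger.info("%d gRNAs without gene mapping ignored", len(unmapped))
    keep = targeting.index
    if efficiencies is not None:
        eff = efficiencies.reindex(keep)
        keep = keep[(eff >= efficiency_min) | eff.isna()]
        dropped = targeting.index.difference(keep)
        if len(dropped):
            logger.info("excluded %d low-efficiency gRNAs", len(dropped))
    retained = targeting.loc[keep]
    out = retained.groupby(grna_to_gene.reindex(keep)).sum()
    lost = set(grna_to_gene.unique()) - set(out.index)
    if lost:
        logger.warning("genes with zero retained gRNAs: %s", sorted(lost))
    out.index.name = "gene_id"
    return out


def fraction_log2fc(
    abund_high: pd.DataFrame | pd.Series,
    abund_low: pd.DataFrame | pd.Series,
    pseudo: float = 1e-9,
) -> pd.Series:
    """log2 of high-fraction over low-fraction gene abundance.

    Replicate columns are averaged on the log scale; the pseudo-count guards
    division on the (already normalized) abundance scale.
    """
    high = pd.DataFrame(abund_high)
    low = pd.DataFrame(abund_low)
    genes = high.index.intersection(low.index)
    lh = np.log2(high.loc[genes] + pseudo).mean(axis=1)
    ll = np.log2(low.loc[genes] + pseudo).mean(axis=1)
    return lh - ll


def condition_log2fc(
    abund_a: pd.DataFrame,
    abund_b: pd.DataFrame,
    pseudo: float = 1e-9,
) -> pd.Series:
    """Mean over paired replicates of per-gene log2(a / b).

    Replicates are paired positionally (column order); requires equal
    replicate counts in both conditions.
    """
    a = pd.DataFrame(abund_a)
    b = pd.DataFrame(abund_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("conditions must have matching replicate counts")
    genes = a.index.intersection(b.index)
    ratios = [
        np.log2((a.loc[genes].iloc[:, i] + pseudo) / (b.loc[genes].iloc[:, i] + pseudo))
        for i in range(a.shape[1])
    ]
    return pd.concat(ratios, axis=1).mean(axis=1)
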