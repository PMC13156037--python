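"""Ontology-based semantic similarity between genes and knockout sets.

Information content (IC) is the negative natural log of a term's annotation
frequency over the corpus; term similarity defaults to Lin's measure
(2 * IC of the maximum-IC common ancestor over the sum of the two term
ICs); gene-pair similarity is the best-match average (BMA) over the two
term sets; knockout-set similarity averages over gene pairs.  A brain
co-expression score (mean pairwise Pearson correlation over a reference
expression matrix) completes the predictor feature set.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class Ontology:
    """A rooted DAG of terms with ancestor-closed gene annotations.

    Parameters
    ----------
    parents
        term -> set of parent terms; the root has no parents.
    annotations
        gene -> set of directly assigned terms.  ``__post_init__``
        propagates annotations to all ancestors (true-path rule).
    namespace
        Label such as "BP", "CC", "MF" or "synthetic".
    """

    parents: dict[str, set]
    annotations: dict[str, set]
    namespace: str = "synthetic"
    _ancestors: dict = field(default_factory=dict, repr=False)
    _ic: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.parents = {t: set(p) for t, p in self.parents.items()}
        for ps in list(self.parents.values()):
            for p in ps:
                self.parents.setdefault(p, set())
        self._check_acyclic()
        self.annotations = {
            g: self._close(set(ts)) for g, ts in self.annotations.items()
        }
        self._compute_ic()

    # -- structure -----------------------------------------------------
    @property
    def terms(self) -> list[str]:
        return sorted(self.parents)

    @property
    def roots(self) -> list[str]:
        return sorted(t for t, ps in self.parents.items() if not ps)

    def ancestors(self, term: str) -> set:
        """All ancestors of ``term`` including itself."""
        if term in self._ancestors:
            return self._ancestors[term]
        out = {term}
        for p in self.parents[term]:
            out |= self.ancestors(p)
        self._ancestors[term] = out
        return out

    def _close(self, terms: set) -> set:
        out: set = set()
        for t in terms:
            if t not in self.parents:
                raise KeyError(f"annotation to unknown term {t!r}")
            out |= self.ancestors(t)
        return out

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str) -> None:
            if state.get(t) == 1:
                raise ValueError(f"ontology contains a cycle through {t!r}")
            if state.get(t) == 2:
                return
            state[t] = 1
            for p in self.parents[t]:
                visit(p)
            state[t] = 2

        for t in self.parents:
            visit(t)

    # -- information content -------------------------------------------
    def _compute_ic(self) -> None:
        n_total = len(self.annotations)
        counts: dict[str, int] = {t: 0 for t in self.parents}
        for ts in self.annotations.values():
            for t in ts:
                counts[t] += 1
        self._ic = {}
        for t, c in counts.items():
            if c > 0 and n_total > 0:
                self._ic[t] = -math.log(c / n_total)
        # terms annotating no gene have undefined IC and are absent

    @property
    def ic(self) -> dict[str, float]:
        """IC per term; terms with zero annotated genes are excluded."""
        return dict(self._ic)


def information_content(ontology: Ontology) -> dict[str, float]:
    """ic(t) = -log(n_genes_annotated(t) / n_genes_total), natural log."""
    return ontology.ic


def term_similarity(
    ontology: Ontology, t1: str, t2: str, method: str = "lin"
) -> float:
    """Similarity in [0, 1] between two terms with defined IC.

    ``lin``: 2*IC(MICA) / (IC(t1) + IC(t2)) with MICA the maximum-IC common
    ancestor.  ``resnik``: IC(MICA) normalized by the corpus maximum IC.
    When both term ICs are zero the similarity is 1 for identical terms and
    0 otherwise.
    """
    ic = ontology.ic
    if t1 not in ic or t2 not in ic:
        raise KeyError("both terms must have defined IC")
    common = ontology.ancestors(t1) & ontology.ancestors(t2)
    ic_mica = max((ic[t] for t in common if t in ic), default=0.0)
    if method == "lin":
        denom = ic[t1] + ic[t2]
        if denom == 0:
            return 1.0 if t1 == t2 else 0.0
        return 2.0 * ic_mica / denom
    if method == "resnik":
        ic_max = max(ic.values())
        if ic_max == 0:
            return 1.0 if t1 == t2 else 0.0
        return ic_mica / ic_max
    raise ValueError(f"unknown method {method!r}")


def _bma(sims: np.ndarray) -> float:
    """Best-match average of a pairwise similarity matrix (rows A, cols B)."""
    row_best = sims.max(axis=1)
    col_best = sims.max(axis=0)
    return float((row_best.mean() + col_best.mean()) / 2.0)


def _informative_terms(ontology: Ontology, gene: str) -> list[str]:
    """Annotated terms with strictly positive IC (the root carries none)."""
    ic = ontology.ic
    return sorted(
        t for t in ontology.annotations.get(gene, set()) if ic.get(t, 0.0) > 0.0
    )


def gene_pair_similarity(
    g1: str, g2: str, ontology: Ontology, method: str = "lin"
) -> float:
    """BMA similarity between the informative term sets of two genes."""
    t1 = _informative_terms(ontology, g1)
    t2 = _informative_terms(ontology, g2)
    if not t1 or not t2:
        return float("nan")
    sims = np.array(
        [[term_similarity(ontology, a, b, method) for b in t2] for a in t1]
    )
    return _bma(sims)


def geneset_similarity(
    genes_a,
    genes_b,
    ontology: Ontology,
    aggregation: str = "bma",
    method: str = "lin",
) -> float:
    """Similarity in [0, 1] between two gene sets.

    Gene-pair similarities are BMA over term sets; set similarity is the
    mean over all cross pairs (a, b) in A x B.  Genes without any annotated
    term of defined IC are dropped with a log message; NaN when all genes
    in either set are unannotated.
    """
    if aggregation != "bma":
        raise ValueError("only BMA aggregation is supported")
    a = [g for g in genes_a if _informative_terms(ontology, g)]
    b = [g for g in genes_b if _informative_terms(ontology, g)]
    if len(a) < len(list(genes_a)) or len(b) < len(list(genes_b)):
        logger.warning("dropped unannotated genes from similarity computation")
    if not a or not b:
        return float("nan")
    vals = [gene_pair_similarity(x, y, ontology, method) for x in a for y in b]
    return float(np.mean(vals))


def ko_set_similarity(
    ko_genes, ontology: Ontology, method: str = "lin"
) -> float:
    """Mean BMA similarity over all unordered gene pairs in a knockout set."""
    annotated = [g for g in ko_genes if _informative_terms(ontology, g)]
    if len(annotated) < 2:
        return float("nan")
    vals = [
        gene_pair_similarity(a, b, ontology, method)
        for a, b in itertools.combinations(sorted(annotated), 2)
    ]
    return float(np.mean(vals))


def brain_coexpression_score(ko_genes, reference_expr: pd.DataFrame) -> float:
    """Mean pairwise Pearson correlation between KO genes' expression vectors.

    ``reference_expr`` is gene x sample.  Genes absent from the reference are
    dropped with a warning; NaN when fewer than 2 remain.
    """
    present = [g for g in ko_genes if g in reference_expr.index]
    if len(present) < len(list(ko_genes)):
        logger.warning("KO genes absent from reference expression were dropped")
    if len(present) < 2:
        return float("nan")
    rs = []
    for a, b in itertools.combinations(sorted(present), 2):
        x = reference_expr.loc[a].to_numpy(float)
        y = reference_expr.loc[b].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        rs.append(stats.pearsonr(x, y).statistic)
    if not rs:
        return float("nan")
    return float(np.mean(rs))


@dataclass
class SimilarityFeatures:
    """Predictor features for one knockout set in one cell type."""

    bp_score: float
    cc_score: float
    mf_score: float
    brain_expr_corr: float
    n_kos: int
    cell_type: str

    def as_dict(self) -> dict:
        return {
            "bp_score": self.bp_score,
            "cc_score": self.cc_score,
            "mf_score": self.mf_score,
            "brain_expr_corr": self.brain_expr_corr,
            "n_kos": self.n_kos,
            "cell_type": self.cell_type,
        }


def ko_similarity_features(
    ko_set,
    ontologies: dict[str, Ontology],
    reference_expr: pd.DataFrame,
    cell_type: str,
    method: str = "lin",
) -> SimilarityFeatures:
    """Assemble the similarity feature vector for a knockout set.

    ``ontologies`` maps namespace ("BP", "CC", "MF") to an :class:`Ontology`;
    missing namespaces yield NaN features, which downstream imputation
    handles.
    """
    ko = sorted(ko_set)

    def ns_score(ns: str) -> float:
        if ns not in ontologies:
            return float("nan")
        return ko_set_similarity(ko, ontologies[ns], method)

    return SimilarityFeatures(
        bp_score=ns_score("BP"),
        cc_score=ns_score("CC"),
        mf_score=ns_score("MF"),
        brain_expr_corr=brain_coexpression_score(ko, reference_expr),
        n_kos=len(ko),
        cell_type=cell_type,
    )
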