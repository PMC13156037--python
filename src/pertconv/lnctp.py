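"""Gaussian energy model for in silico knockouts over bulk + cell-type expression.

The model places a multivariate Gaussian over the concatenated expression
vector (bulk context followed by C cell-type contexts, G genes each).  Its
precision matrix is assembled from GRN-masked interaction blocks per
context plus a deconvolution penalty of weight lambda coupling each bulk
gene to the cell-fraction-weighted sum of its cell-type copies:

    E(x) = 1/2 x' P x - eta' x,
    P = blockdiag(B_0, ..., B_C) + 2*lambda * sum_g v_g v_g',

where B_c carries unit diagonal plus GRN-edge off-diagonals and
v_g[bulk, g] = 1, v_g[c, g] = -f_c.  An in silico knockout clamps one
(context, gene) coordinate at sign*k; because the energy is quadratic, the
clamp limit is exact Gaussian conditioning on the partitioned precision.
The in silico log fold change is Delta = E[x] before minus after clamping.

Convergence across a perturbation set is called by a two-tailed one-sample
sign test on the Delta entries with |Delta| >= tau (default 0.3); at the
default alpha = 0.1 at least five sign-consistent perturbations are needed
for a call.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BULK = "bulk"


class ModelAssemblyError(RuntimeError):
    pass


@dataclass
class LnctpModel:
    """Assembled joint Gaussian over (1 + C) x G expression coordinates.

    ``precision`` is symmetric positive definite over coordinates ordered
    bulk genes first, then each cell type's genes in panel order.  ``mean``
    may be a single vector or an individuals x coordinates matrix when
    per-individual (genotype) biases are present.
    """

    panel: list[str]
    cell_types: list[str]
    precision: np.ndarray
    mean: np.ndarray
    lambda_: float
    fractions: np.ndarray
    support: np.ndarray | None = None  # boolean mask of allowed off-diagonals
    metadata: dict = field(default_factory=dict)

    @property
    def contexts(self) -> list[str]:
        return [BULK] + list(self.cell_types)

    @property
    def n_coords(self) -> int:
        return len(self.contexts) * len(self.panel)

    def coord_index(self, context: str, gene: str) -> int:
        ci = self.contexts.index(context)
        gi = self.panel.index(gene)
        return ci * len(self.panel) + gi

    def coord_labels(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_product(
            [self.contexts, self.panel], names=["context", "gene"]
        )

    def mean_matrix(self) -> np.ndarray:
        """Means as (n_individuals, n_coords); a shared mean becomes one row."""
        m = np.asarray(self.mean, dtype=float)
        return m[None, :] if m.ndim == 1 else m

    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)


@dataclass
class PerturbationSpec:
    """One clamped in silico knockout."""

    context: str
    gene: str
    k: float = 2.0
    sign: int = -1
    estimator: str = "closed_form"
    n_samples: int = 2000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if self.estimator not in ("closed_form", "sampling"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


@dataclass
class DeltaResult:
    """Expected expression before minus after clamping, per coordinate."""

    deltas: pd.Series  # MultiIndex (context, gene)
    target: tuple[str, str]
    clamp_value: float
    standard_errors: pd.Series | None = None


def _load_to_pd(p: np.ndarray, max_tries: int = 12) -> np.ndarray:
    """Ensure positive definiteness by escalating diagonal loading."""
    eps = 0.0
    base = np.mean(np.diag(p)) if p.size else 1.0
    for attempt in range(max_tries):
        try:
            np.linalg.cholesky(p + eps * np.eye(p.shape[0]))
            if eps > 0:
                logger.warning("applied diagonal loading %.3g to reach PD", eps)
            return p + eps * np.eye(p.shape[0])
        except np.linalg.LinAlgError:
            eps = base * 10.0 ** (attempt - 8)
    w = np.linalg.eigvalsh(p)
    raise ModelAssemblyError(
        f"precision irreparably indefinite; min eigenvalue {w.min():.4g}"
    )


def assemble_model(
    panel,
    grn_edges: dict,
    lambda_: float,
    cell_fractions,
    biases: dict | None = None,
    genotype_offsets: np.ndarray | None = None,
    diag: float = 1.0,
) -> LnctpModel:
    """Build the joint precision from per-context GRNs and the deconvolution term.

    Parameters
    ----------
    panel
        Gene ids (G).
    grn_edges
        context -> iterable of (gene_a, gene_b, weight).  Contexts are
        "bulk" plus the cell-type labels; absent contexts get empty GRNs.
        A positive weight induces positive partial correlation (the
        off-diagonal precision entry is -weight).
    lambda_
        Deconvolution weight (>= 0) tying bulk to fraction-weighted
        cell-type expression.
    cell_fractions
        Per-cell-type proportions, >= 0, summing to 1 (within 1e-9).
    biases
        Optional (context, gene) -> linear bias eta; the model mean is
        P^{-1} eta.
    genotype_offsets
        Optional individuals x G matrix of per-individual additive shifts
        to the bulk means.
    """
    panel = list(panel)
    g = len(panel)
    fractions = np.asarray(list(cell_fractions), dtype=float)
    cell_types = [c for c in grn_edges if c != BULK]
    if len(fractions) != len(cell_types):
        raise ValueError("one fraction per cell type required")
    if cell_types and ((fractions < 0).any() or abs(fractions.sum() - 1.0) > 1e-9):
        raise ValueError("fractions must be >= 0 and sum to 1")
    contexts = [BULK] + cell_types
    n = len(contexts) * g
    gene_pos = {gname: i for i, gname in enumerate(panel)}

    p = np.zeros((n, n))
    support = np.zeros((n, n), dtype=bool)
    for ci, ctx in enumerate(contexts):
        off = ci * g
        p[off : off + g, off : off + g] += diag * np.eye(g)
        for a, b, w in grn_edges.get(ctx, []):
            if a not in gene_pos or b not in gene_pos:
                raise ValueError(f"GRN edge ({a}, {b}) references gene outside panel")
            ia, ib = off + gene_pos[a], off + gene_pos[b]
            p[ia, ib] += -w
            p[ib, ia] += -w
            support[ia, ib] = support[ib, ia] = True

    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    if lambda_ > 0 and cell_types:
        for gi in range(g):
            v = np.zeros(n)
            v[gi] = 1.0
            for ci, _ in enumerate(cell_types):
                v[(ci + 1) * g + gi] = -fractions[ci]
            p += 2.0 * lambda_ * np.outer(v, v)
            nz = np.flatnonzero(v)
            for ia, ib in itertools.combinations(nz, 2):
                support[ia, ib] = support[ib, ia] = True

    p = _load_to_pd(p)

    eta = np.zeros(n)
    if biases:
        tmp_contexts = {c: i for i, c in enumerate(contexts)}
        for (ctx, gene), val in biases.items():
            eta[tmp_contexts[ctx] * g + gene_pos[gene]] = val
    mean = np.linalg.solve(p, eta)
    if genotype_offsets is not None:
        offs = np.asarray(genotype_offsets, dtype=float)
        if offs.shape[1] != g:
            raise ValueError("genotype offsets must be individuals x G")
        means = np.tile(mean, (offs.shape[0], 1))
        means[:, :g] += offs
        mean = means

    return LnctpModel(
        panel=panel,
        cell_types=cell_types,
        precision=p,
        mean=mean,
        lambda_=lambda_,
        fractions=fractions,
        support=support,
        metadata={"diag": diag},
    )


def sample_model(model: LnctpModel, n: int, seed: int | None = None) -> pd.DataFrame:
    """Draw n individuals from the model (exact, via precision Cholesky)."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(model.precision)
    z = rng.standard_normal((n, model.n_coords))
    # x = mean + L^{-T} z has covariance P^{-1}
    dev = np.linalg.solve(L.T, z.T).T
    means = model.mean_matrix()
    if means.shape[0] == 1:
        x = means + dev
    else:
        if means.shape[0] != n:
            raise ValueError("per-individual means require n == n_individuals")
        x = means + dev
    return pd.DataFrame(x, columns=model.coord_labels())


# ---------------------------------------------------------------------------
# Perturbation (clamped conditioning)
# ---------------------------------------------------------------------------

def perturb(model: LnctpModel, spec: PerturbationSpec) -> DeltaResult:
    """In silico knockout: clamp one coordinate and report Delta per coordinate.

    Delta = E[x] (unperturbed) - E[x | x_target = sign*k]; at the clamped
    coordinate this equals baseline mean - sign*k exactly.  With
    per-individual means, Delta is averaged over individuals.  The
    ``sampling`` estimator draws i.i.d. from the exact conditional Gaussian
    and reports Monte-Carlo standard errors.
    """
    j = model.coord_index(spec.context, spec.gene)
    p = model.precision
    if p[j, j] <= 0:
        raise ValueError("clamped coordinate has nonpositive marginal precision")
    v = spec.sign * spec.k
    n = model.n_coords
    rest = np.array([i for i in range(n) if i != j])
    p_aa = p[np.ix_(rest, rest)]
    p_aj = p[rest, j]

    means = model.mean_matrix()
    deltas = np.zeros((means.shape[0], n))
    ses = None

    # conditional mean: mu_A - P_AA^{-1} p_Aj (v - mu_j)
    shift_dir = np.linalg.solve(p_aa, p_aj)  # independent of individual
    for i, mu in enumerate(means):
        gap = v - mu[j]
        cond_mean = mu[rest] - shift_dir * gap
        deltas[i, rest] = mu[rest] - cond_mean  # = shift_dir * gap
        deltas[i, j] = mu[j] - v

    delta = deltas.mean(axis=0)

    if spec.estimator == "sampling":
        rng = np.random.default_rng(spec.seed)
        L = np.linalg.cholesky(p_aa)
        draws = np.linalg.solve(L.T, rng.standard_normal((spec.n_samples, n - 1)).T).T
        # centered draws have the conditional covariance P_AA^{-1};
        # MC delta = mean - mean(cond samples) per individual, averaged
        mc = np.zeros(n)
        se = np.zeros(n)
        sd = draws.std(axis=0, ddof=1) / np.sqrt(spec.n_samples)
        acc = np.zeros(n - 1)
        for mu in means:
            gap = v - mu[j]
            cond_mean = mu[rest] - shift_dir * gap
            samples = cond_mean + draws
            acc += mu[rest] - samples.mean(axis=0)
        mc[rest] = acc / means.shape[0]
        mc[j] = delta[j]
        se[rest] = sd
        delta = mc
        ses = pd.Series(se, index=model.coord_labels())

    series = pd.Series(delta, index=model.coord_labels())
    return DeltaResult(
        deltas=series,
        target=(spec.context, spec.gene),
        clamp_value=v,
        standard_errors=ses,
    )


def perturb_set(
    model: LnctpModel,
    targets,
    k: float = 2.0,
    sign: int = -1,
    estimator: str = "closed_form",
    n_samples: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Delta matrix over a perturbation set S (rows: targets, cols: coords)."""
    rows = {}
    for idx, (ctx, gene) in enumerate(targets):
        sp_seed = None if seed is None else seed + idx
        spec = PerturbationSpec(
            context=ctx, gene=gene, k=k, sign=sign,
            estimator=estimator, n_samples=n_samples, seed=sp_seed,
        )
        rows[(ctx, gene)] = perturb(model, spec).deltas
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Sign-test convergence
# ---------------------------------------------------------------------------

def sign_test_pvalue(n_pos: int, n_qualifying: int) -> float:
    """Exact two-tailed one-sample sign test against a fair coin."""
    if n_qualifying == 0:
        return 1.0
    return float(stats.binomtest(n_pos, n_qualifying, 0.5).pvalue)


def call_insilico_convergent(
    deltas: pd.DataFrame,
    tau: float = 0.3,
    alpha: float = 0.1,
    min_testable: int = 5,
) -> pd.DataFrame:
    """Call in silico convergent (context, gene) coordinates from Delta^S.

    Per coordinate, entries with |Delta| >= tau qualify; the two-tailed
    sign test asks whether qualifying signs deviate from a fair coin.
    Convergent iff testable (n_qualifying >= ``min_testable``; below five
    qualifying entries the two-tailed p cannot reach 0.1) and p < alpha.
    """
    if len(deltas) < 2:
        raise ValueError("need a perturbation set of size >= 2")
    records = []
    for coord in deltas.columns:
        vals = deltas[coord].to_numpy(float)
        qual = vals[np.abs(vals) >= tau]
        n_q = len(qual)
        n_pos = int((qual > 0).sum())
        p = sign_test_pvalue(n_pos, n_q)
        testable = n_q >= min_testable
        convergent = bool(testable and p < alpha)
        sign = 0
        if n_q:
            sign = 1 if n_pos * 2 > n_q else (-1 if n_pos * 2 < n_q else 0)
        records.append(
            {
                "context": coord[0],
                "gene": coord[1],
                "n_qualifying": n_q,
                "n_positive": n_pos,
                "p_sign": p,
                "testable": testable,
                "convergent": convergent,
                "sign": sign,
            }
        )
    return pd.DataFrame(records).set_index(["context", "gene"])


def compare_convergent_sets(set_a, set_b, universe) -> dict:
    """Overlap, two-sided hypergeometric (Fisher exact) p, and Jaccard."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a) & universe, set(set_b) & universe
    if set(set_a) - universe or set(set_b) - universe:
        raise ValueError("sets must be subsets of the universe")
    inter = len(a & b)
    union = len(a | b)
    table = [
        [inter, len(a) - inter],
        [len(b) - inter, len(universe) - union],
    ]
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    return {
        "overlap": inter,
        "p_hypergeom": p,
        "jaccard": inter / union if union else 0.0,
    }


# ---------------------------------------------------------------------------
# Semantic distance between enriched-term lists
# ---------------------------------------------------------------------------

def leading_edge_jaccard(genes_a, genes_b) -> float:
    """s(t1, t2) = |G1 n G2| / |G1 u G2| over leading-edge gene sets."""
    a, b = set(genes_a), set(genes_b)
    union = a | b
    if not union:
        return float("nan")
    return len(a & b) / len(union)


def semantic_distance_test(terms_a: dict, terms_b: dict) -> dict:
    """Between-set vs within-set leading-edge similarity (one-sided rank-sum).

    ``terms_a``/``terms_b`` map enriched term id -> leading-edge gene set.
    Tests whether between-set pairwise Jaccards are smaller than the pooled
    within-set Jaccards (Mann-Whitney U, alternative "less").  Returns NaN
    p when either list has fewer than 2 terms.
    """
    if len(terms_a) < 2 or len(terms_b) < 2:
        return {"p": float("nan"), "between": [], "within": []}
    between = [
        leading_edge_jaccard(ga, gb)
        for ga in terms_a.values()
        for gb in terms_b.values()
    ]
    within = [
        leading_edge_jaccard(terms_a[t1], terms_a[t2])
        for t1, t2 in itertools.combinations(sorted(terms_a), 2)
    ] + [
        leading_edge_jaccard(terms_b[t1], terms_b[t2])
        for t1, t2 in itertools.combinations(sorted(terms_b), 2)
    ]
    if np.ptp(between + within) == 0:
        p = 1.0
    else:
        p = float(
            stats.mannwhitneyu(between, within, alternative="less").pvalue
        )
    return {"p": p, "between": between, "within": within}


# ---------------------------------------------------------------------------
# Reduced-model fitting (node-wise ridge pseudolikelihood)
# ---------------------------------------------------------------------------

def fit_reduced_model(
    expression: pd.DataFrame,
    support: np.ndarray | dict,
    ridge: float = 1e-3,
    model_template: LnctpModel | None = None,
) -> LnctpModel:
    """Fit a reduced model (no genotype term) to expression samples.

    Each coordinate is ridge-regressed on its support neighbors; the
    precision estimate sets P_jj = 1/sigma_j^2, P_jk = -beta_jk/sigma_j^2,
    symmetrized by averaging the (j, k) and (k, j) estimates.  Off-support
    entries are exactly zero.  Means come from sample means.  Deterministic.

    Parameters
    ----------
    expression
        samples x coordinates (MultiIndex (context, gene) columns, as
        produced by :func:`sample_model`).
    support
        Boolean n x n adjacency of allowed interactions, or an
        :class:`LnctpModel` support mask via ``model_template``.
    """
    x = expression.to_numpy(float)
    n_samples, n_coords = x.shape
    if isinstance(support, dict):
        raise TypeError("pass a boolean adjacency matrix")
    adj = np.asarray(support, dtype=bool)
    if adj.shape != (n_coords, n_coords):
        raise ValueError("support shape mismatch")
    if n_samples < 2 * n_coords:
        logger.warning("n_samples < 2 x coordinates; fit may be unstable")
    if (x.std(axis=0) == 0).any():
        raise ValueError("zero-variance column in expression")

    mu = x.mean(axis=0)
    xc = x - mu
    prec = np.zeros((n_coords, n_coords))
    asym = np.zeros((n_coords, n_coords))
    for j in range(n_coords):
        nbrs = np.flatnonzero(adj[j])
        y = xc[:, j]
        if len(nbrs) == 0:
            resid_var = y.var(ddof=1)
            prec[j, j] = 1.0 / resid_var
            continue
        a = xc[:, nbrs]
        gram = a.T @ a + ridge * np.eye(len(nbrs))
        beta = np.linalg.solve(gram, a.T @ y)
        resid = y - a @ beta
        dof = max(n_samples - len(nbrs) - 1, 1)
        resid_var = float(resid @ resid) / dof
        prec[j, j] = 1.0 / resid_var
        asym[j, nbrs] = -beta / resid_var
    off = (asym + asym.T) / 2.0
    off[~adj] = 0.0
    prec = prec * np.eye(n_coords) + off
    prec = _load_to_pd(prec)

    if model_template is not None:
        panel, cell_types = model_template.panel, model_template.cell_types
        lam, frac = model_template.lambda_, model_template.fractions
    else:
        contexts = expression.columns.get_level_values(0).unique().tolist()
        panel = expression.columns.get_level_values(1).unique().tolist()
        cell_types = [c for c in contexts if c != BULK]
        lam, frac = 0.0, np.array([])
    return LnctpModel(
        panel=list(panel),
        cell_types=list(cell_types),
        precision=prec,
        mean=mu,
        lambda_=lam,
        fractions=np.asarray(frac, dtype=float),
        support=adj,
        metadata={"ridge": ridge, "fit": "nodewise_ridge"},
    )
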