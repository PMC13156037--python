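"""Behavioral fingerprinting, drug matching and rescue classification.

Larval behavior tables are long-format records of 24 sleep-wake and
visual-startle parameters.  Per parameter, a linear mixed model (random
intercept per experiment date) contrasts mutant against control; the
fingerprint is the vector of signed -log10 p-values.  Drugs are matched by
Pearson correlation of fingerprints, transcriptomic reversal is scored by
CMap-style WTCS/NCS, and a drug's effect on each mutant-affected parameter
is classified into five rescue categories.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from pertconv.enrichment import _es_walk

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300

RESCUE_CATEGORIES = (
    "exacerbated",
    "unchanged",
    "partial_rescue",
    "rescued",
    "over_corrected",
)


# ---------------------------------------------------------------------------
# Mixed-model effects and fingerprints
# ---------------------------------------------------------------------------

def fit_behavior_effect(
    table: pd.DataFrame,
    parameter: str,
    contrast: str = "mutant",
) -> tuple[float, float]:
    """Group effect (beta) and Wald p for one behavioral parameter.

    ``contrast="mutant"`` compares mutant+vehicle against control+vehicle;
    ``contrast="mutant_drug"`` compares mutant+drug against control+vehicle.
    The model is value ~ group with a random intercept per batch date;
    single-batch data falls back to OLS (logged).  Groups with zero pooled
    variance return beta with p = 1 (degenerate).
    """
    sub = table[table["parameter"] == parameter]
    base = sub[(sub["genotype"] == "control") & (sub["treatment"] == "vehicle")]
    if contrast == "mutant":
        case = sub[(sub["genotype"] == "mutant") & (sub["treatment"] == "vehicle")]
    elif contrast == "mutant_drug":
        case = sub[(sub["genotype"] == "mutant") & (sub["treatment"] == "drug")]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    if len(base) < 3 or len(case) < 3:
        raise ValueError("need >= 3 larvae per contrasted group")

    df = pd.concat([base.assign(group=0.0), case.assign(group=1.0)])
    beta_naive = case["value"].mean() - base["value"].mean()
    if df["value"].nunique() == 1 or (base["value"].std() == 0 and case["value"].std() == 0):
        return float(beta_naive), 1.0

    n_batches = df["batch_date"].nunique()
    if n_batches < 2:
        logger.info("single batch for %s; falling back to OLS", parameter)
        return _ols_effect(df)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("value ~ group", df, groups=df["batch_date"])
            fit = model.fit(reml=True, method="lbfgs")
        beta = float(fit.params["group"])
        p = float(fit.pvalues["group"])
        if not np.isfinite(p):
            return _ols_effect(df)
        return beta, p
    except Exception:  # singular fits on degenerate batches
        logger.warning("mixed model failed for %s; OLS fallback", parameter)
        return _ols_effect(df)


def _ols_effect(df: pd.DataFrame) -> tuple[float, float]:
    x = sm.add_constant(df["group"].to_numpy(float))
    fit = sm.OLS(df["value"].to_numpy(float), x).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


@dataclass
class Fingerprint:
    """Per-parameter effect sizes and signed -log10 p-values."""

    table: pd.DataFrame  # index parameter; beta, p, signed_score
    label: str = ""

    @property
    def signed_scores(self) -> pd.Series:
        return self.table["signed_score"]


def behavioral_fingerprint(
    table: pd.DataFrame,
    contrast: str = "mutant",
    parameters=None,
    label: str = "",
) -> Fingerprint:
    """Fingerprint over the behavioral parameters present in the table.

    Missing parameters (relative to ``parameters`` when given) are flagged
    with NaN rows.  Signed score = sign(beta) * -log10(p), with p floored
    at 1e-300.
    """
    observed = sorted(table["parameter"].unique())
    wanted = sorted(parameters) if parameters is not None else observed
    rows = {}
    for param in wanted:
        if param not in observed:
            logger.warning("parameter %s missing from table", param)
            rows[param] = (np.nan, np.nan, np.nan)
            continue
        beta, p = fit_behavior_effect(table, param, contrast=contrast)
        score = np.sign(beta) * -np.log10(max(p, _P_FLOOR))
        rows[param] = (beta, p, score)
    out = pd.DataFrame(rows, index=["beta", "p", "signed_score"]).T
    out.index.name = "parameter"
    return Fingerprint(table=out, label=label)


# ---------------------------------------------------------------------------
# Clustering and drug matching
# ---------------------------------------------------------------------------

def cluster_mutants(fingerprints: pd.DataFrame, k: int | None = None):
    """Correlation matrix and average-linkage clustering of mutant fingerprints.

    ``fingerprints`` is mutant x parameter signed scores.  Distance is
    1 - Pearson r; constant fingerprints get NaN correlations and are held
    out of the dendrogram.  Returns (corr, linkage matrix, labels-or-None).
    """
    if len(fingerprints) < 2:
        raise ValueError("need >= 2 mutants")
    x = fingerprints.to_numpy(float)
    sd = x.std(axis=1)
    corr = pd.DataFrame(
        np.corrcoef(x), index=fingerprints.index, columns=fingerprints.index
    )
    flat = sd == 0
    corr.loc[flat, :] = np.nan
    corr.loc[:, flat] = np.nan
    usable = corr.index[~flat]
    if len(usable) < 2:
        return corr, None, None
    sub = corr.loc[usable, usable].to_numpy()
    dist = np.clip(1.0 - sub, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = None
    if k is not None:
        lab = fcluster(z, t=k, criterion="maxclust")
        labels = pd.Series(lab, index=usable, name="cluster")
    return corr, z, labels


def match_drugs(
    mutant_fp: pd.Series,
    drug_fps: pd.DataFrame,
    r_abs_min: float = 0.5,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Drugs whose fingerprints (anti-)correlate with a mutant fingerprint.

    Pearson r over the shared parameters with the t-statistic p-value;
    ``correlate`` when r > r_abs_min and p < p_max, ``anti-correlate`` when
    r < -r_abs_min and p < p_max.  Pairs sharing < 3 parameters get NaN.
    """
    rows = []
    for drug in drug_fps.index:
        shared = mutant_fp.index.intersection(drug_fps.columns)
        x = mutant_fp.loc[shared].to_numpy(float)
        y = drug_fps.loc[drug, shared].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            rows.append({"drug": drug, "r": np.nan, "p": np.nan, "match": "missing"})
            continue
        res = stats.pearsonr(x[ok], y[ok])
        r, p = float(res.statistic), float(res.pvalue)
        if r > r_abs_min and p < p_max:
            match = "correlate"
        elif r < -r_abs_min and p < p_max:
            match = "anti-correlate"
        else:
            match = "none"
        rows.append({"drug": drug, "r": r, "p": p, "match": match})
    return pd.DataFrame(rows).set_index("drug")


# ---------------------------------------------------------------------------
# CMap-style signature reversal
# ---------------------------------------------------------------------------

@dataclass
class RankedSignature:
    """A full gene ranking (differential-expression scores) for one signature."""

    signature_id: str
    group_id: str
    scores: pd.Series  # gene -> DE score; ranking = descending order
    is_null: bool = False


def _weighted_es(scores_sorted: np.ndarray, member: np.ndarray) -> float:
    es, _ = _es_walk(member, np.abs(scores_sorted))
    return es


def wtcs(signature: RankedSignature, query_up, query_down) -> float:
    """Weighted two-sided connectivity score of a query against a signature.

    ES_up and ES_down are weighted KS enrichment scores of the up and down
    query sets on the signature ranking; WTCS = (ES_up - ES_down)/2 when
    the two have opposite signs (or one is zero), else 0.
    """
    up, down = set(query_up), set(query_down)
    if up & down:
        raise ValueError("query up/down sets must be disjoint")
    order = signature.scores.sort_values(ascending=False, kind="mergesort")
    genes = order.index.to_numpy()
    vals = order.to_numpy(float)
    m_up = np.isin(genes, list(up))
    m_down = np.isin(genes, list(down))
    if not m_up.any() or not m_down.any():
        raise ValueError("each query set must intersect the signature universe")
    es_up = _weighted_es(vals, m_up)
    es_down = _weighted_es(vals, m_down)
    if es_up * es_down < 0 or es_up == 0 or es_down == 0:
        return (es_up - es_down) / 2.0
    return 0.0


def cmap_query(
    query_up,
    query_down,
    signatures: list[RankedSignature],
    ncs_reverser_max: float = -1.0,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Score every signature against an up/down query.

    NCS divides each signature's WTCS by the absolute mean of same-sign
    WTCS values within its perturbation group (sign preserved; NaN for a
    group with no same-sign values).  FDR is the fraction of null (vehicle)
    signatures whose |NCS| meets or exceeds the reference |NCS|.  A
    signature is flagged a reverser when NCS <= ``ncs_reverser_max`` and
    FDR <= ``fdr_max``.
    """
    rows = []
    for sig in signatures:
        rows.append(
            {
                "signature_id": sig.signature_id,
                "group_id": sig.group_id,
                "is_null": sig.is_null,
                "wtcs": wtcs(sig, query_up, query_down),
            }
        )
    df = pd.DataFrame(rows).set_index("signature_id")

    ncs = pd.Series(np.nan, index=df.index)
    for _, grp in df.groupby("group_id"):
        for sign in (1, -1):
            mask = np.sign(grp["wtcs"]) == sign
            if mask.any():
                denom = abs(grp.loc[mask, "wtcs"].mean())
                if denom > 0:
                    ncs.loc[grp.index[mask]] = grp.loc[mask, "wtcs"] / denom
        zero = grp["wtcs"] == 0
        ncs.loc[grp.index[zero]] = 0.0
    df["ncs"] = ncs

    null_ncs = df.loc[df["is_null"], "ncs"].abs().dropna().to_numpy()
    fdrs = []
    for sid, row in df.iterrows():
        if row["is_null"] or not np.isfinite(row["ncs"]):
            fdrs.append(np.nan)
        elif len(null_ncs) == 0:
            fdrs.append(0.0)
        else:
            fdrs.append(float(np.mean(null_ncs >= abs(row["ncs"]))))
    df["fdr"] = fdrs
    df["reverser"] = (
        (df["ncs"] <= ncs_reverser_max) & (df["fdr"] <= fdr_max) & ~df["is_null"]
    )
    return df


# ---------------------------------------------------------------------------
# Five-category rescue classification
# ---------------------------------------------------------------------------

@dataclass
class RescueCall:
    parameter: str
    category: str | None
    mut_beta: float
    mut_p: float
    drug_beta: float
    drug_p: float


def classify_rescue(
    mut: tuple[float, float],
    drug: tuple[float, float],
    alpha: float = 0.06,
    parameter: str = "",
) -> RescueCall:
    """Classify a drug's effect on one mutant-affected behavioral parameter.

    Only parameters where the mutant-vs-control p is below ``alpha`` are
    classified.  In precedence order: ``rescued`` (drug contrast no longer
    significant), ``over_corrected`` (significant, opposite direction),
    ``partial_rescue`` (significant, same direction, smaller magnitude),
    ``exacerbated`` (p no larger than the mutant's, same direction, larger
    magnitude), else ``unchanged``.
    """
    mut_beta, mut_p = mut
    drug_beta, drug_p = drug
    call = lambda cat: RescueCall(  # noqa: E731
        parameter=parameter, category=cat,
        mut_beta=mut_beta, mut_p=mut_p, drug_beta=drug_beta, drug_p=drug_p,
    )
    if not np.isfinite(mut_p) or mut_p >= alpha:
        return call(None)
    if not np.isfinite(drug_p):
        return call(None)
    if drug_p >= alpha:
        return call("rescued")
    if np.sign(drug_beta) != np.sign(mut_beta):
        return call("over_corrected")
    if abs(drug_beta) < abs(mut_beta):
        return call("partial_rescue")
    if drug_p <= mut_p and abs(drug_beta) > abs(mut_beta):
        return call("exacerbated")
    return call("unchanged")


def rescue_profile(
    table: pd.DataFrame,
    parameters=None,
    alpha: float = 0.06,
) -> pd.DataFrame:
    """Classify every parameter of a mutant x drug behavior table.

    The table must contain control+vehicle, mutant+vehicle and mutant+drug
    larvae; both contrasts are fitted per parameter and passed to
    :func:`classify_rescue`.
    """
    mut_fp = behavioral_fingerprint(table, contrast="mutant", parameters=parameters)
    drug_fp = behavioral_fingerprint(table, contrast="mutant_drug", parameters=parameters)
    rows = []
    for param in mut_fp.table.index:
        m = mut_fp.table.loc[param]
        d = drug_fp.table.loc[param]
        res = classify_rescue(
            (m["beta"], m["p"]), (d["beta"], d["p"]), alpha=alpha, parameter=param
        )
        rows.append(
            {
                "parameter": param,
                "category": res.category,
                "mut_beta": res.mut_beta,
                "mut_p": res.mut_p,
                "drug_beta": res.drug_beta,
                "drug_p": res.drug_p,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
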