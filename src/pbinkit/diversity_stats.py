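"""Alpha- and beta-diversity statistics linking phage and bacterial diversity.

Bacterial alpha diversity per interaction module combines Faith's
phylogenetic diversity (PD) with strain-level nucleotide diversity: the
within-module diversity of a sample is PD of the module's present bOTUs
multiplied by their mean genome-wide pi.  Viral alpha diversity is the
richness of present vOTUs of the module.  Beta-diversity association is
tested with rank-based Mantel tests (10,000 permutations, one-sided greater
by default), module-matched across every (bacterial module, viral module)
pair with Benjamini-Hochberg correction, and alpha-diversity association
with Pearson/Spearman correlations and a robust (Huber M-estimation) linear
model of viral richness on PD and mean pi with sandwich standard errors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from skbio.stats.distance import mantel as _skbio_mantel
from statsmodels.stats.multitest import multipletests

from .profiles import DistanceMatrix

__all__ = [
    "MantelResult",
    "RegressionResult",
    "faith_pd",
    "within_module_diversity",
    "diversity_records",
    "mantel",
    "module_matched_correlations",
    "between_module_alpha_correlation",
    "within_module_alpha_correlation",
    "regress_richness",
    "hostrange_prevalence",
    "modules_passing_filter",
]


@dataclass
class MantelResult:
    statistic: float
    p_value: float
    n_samples: int
    n_permutations: int
    label_x: str = ""
    label_y: str = ""


@dataclass
class RegressionResult:
    """Per-predictor robust-regression summary (slope, SE, Wald z, p)."""

    table: pd.DataFrame  # index = predictor, columns = slope, se, z, p

    def slope(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "slope"])


# ---------------------------------------------------------------------------
# Faith's phylogenetic diversity
# ---------------------------------------------------------------------------

def faith_pd(
    tree: dendropy.Tree,
    present_tips: Sequence[str],
    include_root_path: bool = True,
) -> float:
    """Faith's PD: total branch length of the subtree spanning the present tips.

    With ``include_root_path`` (the default, matching the common rooted
    convention) the path from the subtree to the root is included, so a
    single tip scores its root-to-tip distance.  An empty tip set scores 0.
    """
    present = set(present_tips)
    if not present:
        return 0.0
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = present - tip_labels
    if unknown:
        raise ValueError(f"tips not in the tree: {sorted(unknown)}")
    # an edge is counted when its subtree contains at least one present tip
    # and (unless the root path is included) its complement does too
    total = 0.0
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        leaves_below = {l.taxon.label for l in node.leaf_iter()}
        below = len(leaves_below & present)
        if below == 0:
            continue
        if not include_root_path and below == len(present):
            continue  # edge on the root side of the spanning subtree
        total += node.edge.length or 0.0
    return total


# ---------------------------------------------------------------------------
# Within-module diversity records
# ---------------------------------------------------------------------------

def within_module_diversity(
    sample_id: str,
    module_id: int,
    module_botus: Sequence[str],
    module_votus: Sequence[str],
    presence_botu: pd.DataFrame,
    presence_votu: pd.DataFrame,
    genome_pi_values: Mapping[tuple[str, str], float],
    tree: dendropy.Tree,
) -> dict | None:
    """One DiversityRecord: PD, mean pi, PD x pi composite, viral richness.

    mean pi is the unweighted mean of genome-wide pi over the module's bOTUs
    present in the sample (bOTUs with missing pi are excluded from the
    mean); PD spans those same present tips.  Returns None when none of the
    module's bacteria are present in the sample.
    """
    present = [
        b
        for b in module_botus
        if b in presence_botu.columns and bool(presence_botu.loc[sample_id, b])
    ]
    if not present:
        return None
    pis = [
        genome_pi_values.get((sample_id, b), float("nan"))
        for b in present
    ]
    pis_ok = [p for p in pis if not np.isnan(p)]
    mean_pi = float(np.mean(pis_ok)) if pis_ok else float("nan")
    pd_val = faith_pd(tree, present)
    richness = int(
        sum(
            bool(presence_votu.loc[sample_id, v])
            for v in module_votus
            if v in presence_votu.columns
        )
    )
    return {
        "sample_id": sample_id,
        "module_id": module_id,
        "pd": pd_val,
        "mean_pi": mean_pi,
        "composite": pd_val * mean_pi if not np.isnan(mean_pi) else float("nan"),
        "viral_richness": richness,
        "n_botus_present": len(present),
        "n_pi_missing": len(pis) - len(pis_ok),
    }


def diversity_records(
    botu_modules: Mapping[str, int],
    votu_modules: Mapping[str, int],
    presence_botu: pd.DataFrame,
    presence_votu: pd.DataFrame,
    genome_pi_values: Mapping[tuple[str, str], float],
    tree: dendropy.Tree,
) -> pd.DataFrame:
    """DiversityRecords for every sample x module combination."""
    modules = sorted(set(botu_modules.values()))
    rows = []
    for module in modules:
        mb = sorted(b for b, m in botu_modules.items() if m == module)
        mv = sorted(v for v, m in votu_modules.items() if m == module)
        for sample in presence_botu.index:
            rec = within_module_diversity(
                sample, module, mb, mv, presence_botu, presence_votu,
                genome_pi_values, tree,
            )
            if rec is not None:
                rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 10_000,
    seed: int | None = None,
    method: str = "spearman",
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test between two distance matrices over shared samples.

    The statistic is the rank (Spearman) correlation over the lower-triangle
    entries by default; the permutation p-value uses simultaneous row/column
    permutation of one matrix with the +1 correction.  Default alternative
    is one-sided "greater" (testing for positive association).
    """
    common = [s for s in d1.labels if s in set(d2.labels)]
    if len(common) < 4:
        raise ValueError("mantel test needs at least 4 shared samples")
    m1 = d1.data.loc[common, common].to_numpy()
    m2 = d2.data.loc[common, common].to_numpy()
    if np.isnan(m1).any() or np.isnan(m2).any():
        raise ValueError("mantel test requires complete distance matrices")
    stat, p, n = _skbio_mantel(
        m1,
        m2,
        method=method,
        permutations=n_permutations,
        alternative=alternative,
        seed=seed,
    )
    return MantelResult(
        statistic=float(stat),
        p_value=float(p),
        n_samples=int(n),
        n_permutations=n_permutations,
        label_x=d1.metric,
        label_y=d2.metric,
    )


def mantel_statistic(d1: DistanceMatrix, d2: DistanceMatrix, method: str = "spearman") -> float:
    """Mantel correlation statistic only (no permutation test).

    A constant distance vector (e.g. a level at which every sample pair is
    equally dissimilar) has no defined correlation; NaN is returned.
    """
    common = [s for s in d1.labels if s in set(d2.labels)]
    m1 = d1.data.loc[common, common].to_numpy()
    m2 = d2.data.loc[common, common].to_numpy()
    iu = np.triu_indices(len(common), k=1)
    x, y = m1[iu], m2[iu]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    if method == "spearman":
        return float(scipy.stats.spearmanr(x, y).statistic)
    return float(scipy.stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Module-matched beta-diversity correlations
# ---------------------------------------------------------------------------

def modules_passing_filter(
    botu_modules: Mapping[str, int],
    votu_modules: Mapping[str, int],
    presence_botu: pd.DataFrame,
    presence_votu: pd.DataFrame,
    min_bees: int = 15,
) -> list[int]:
    """Modules whose bacteria AND phages are each present in >= min_bees samples."""
    out = []
    for module in sorted(set(botu_modules.values())):
        mb = [b for b, m in botu_modules.items() if m == module and b in presence_botu.columns]
        mv = [v for v, m in votu_modules.items() if m == module and v in presence_votu.columns]
        n_bac = int((presence_botu[mb].sum(axis=1) > 0).sum()) if mb else 0
        n_vir = int((presence_votu[mv].sum(axis=1) > 0).sum()) if mv else 0
        if n_bac >= min_bees and n_vir >= min_bees:
            out.append(module)
    return out


def module_matched_correlations(
    strain_distances: Mapping[int, DistanceMatrix],
    votu_distances: Mapping[int, DistanceMatrix],
    modules: Sequence[int],
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mantel statistics for every (bacterial module, viral module) pair.

    Returns a table with the rank Mantel statistic, permutation p, BH-adjusted
    p, and a same_module flag; comparing the statistic distribution for
    matched (i == j) vs crossed (i != j) pairs tests whether beta-diversity
    coupling follows the interaction-network structure.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for bi, vj in itertools.product(modules, repeat=2):
        db, dv = strain_distances.get(bi), votu_distances.get(vj)
        if db is None or dv is None:
            continue
        common = [s for s in db.labels if s in set(dv.labels)]
        if len(common) < 4:
            continue
        sub_b = DistanceMatrix(db.data.loc[common, common], db.metric, db.params)
        sub_v = DistanceMatrix(dv.data.loc[common, common], dv.metric, dv.params)
        res = mantel(
            sub_b,
            sub_v,
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31)),
        )
        rows.append(
            {
                "bacterial_module": bi,
                "viral_module": vj,
                "same_module": bi == vj,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_samples": res.n_samples,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Alpha-diversity correlations
# ---------------------------------------------------------------------------

def between_module_alpha_correlation(records: pd.DataFrame) -> dict:
    """Pearson correlation of per-module mean composite diversity vs richness.

    Per module, the mean (across bees) of PD x pi and of viral richness are
    computed; the product-moment correlation across modules is returned with
    its two-sided p-value and the per-module means and SDs.
    """
    agg = records.groupby("module_id").agg(
        mean_composite=("composite", "mean"),
        sd_composite=("composite", "std"),
        mean_richness=("viral_richness", "mean"),
        sd_richness=("viral_richness", "std"),
        n_bees=("sample_id", "nunique"),
    )
    if len(agg) < 3:
        raise ValueError("between-module correlation needs at least 3 modules")
    r, p = scipy.stats.pearsonr(agg["mean_composite"], agg["mean_richness"])
    return {"r": float(r), "p_value": float(p), "per_module": agg}


def within_module_alpha_correlation(records: pd.DataFrame, module: int) -> dict:
    """Spearman correlation of composite diversity vs richness across bees."""
    sub = records[records["module_id"] == module].dropna(subset=["composite"])
    x = sub["composite"].to_numpy()
    y = sub["viral_richness"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in composite diversity or richness")
    rho, p = scipy.stats.spearmanr(x, y)
    return {"module_id": module, "rho": float(rho), "p_value": float(p), "n": len(sub)}


# ---------------------------------------------------------------------------
# Robust regression of viral richness on PD and mean pi
# ---------------------------------------------------------------------------

def regress_richness(records: pd.DataFrame, min_samples: int = 10) -> RegressionResult:
    """Huber M-estimation of richness ~ PD + mean_pi with sandwich SEs.

    Fits a robust linear model (Huber weighting) of viral richness on PD and
    mean nucleotide diversity jointly, then computes heteroskedasticity-
    consistent covariance from the converged psi-weights, reporting per-
    predictor Wald z statistics and two-sided normal p-values.
    """
    sub = records.dropna(subset=["pd", "mean_pi", "viral_richness"])
    if len(sub) < min_samples:
        raise ValueError(f"need at least {min_samples} complete records, have {len(sub)}")
    X = sub[["pd", "mean_pi"]].to_numpy(dtype=float)
    if np.linalg.cond(np.column_stack([np.ones(len(X)), X])) > 1e10 or np.any(
        X.std(axis=0) == 0
    ):
        raise ValueError("collinear or constant predictors")
    y = sub["viral_richness"].to_numpy(dtype=float)
    exog = sm.add_constant(X)
    fit = sm.RLM(y, exog, M=sm.robust.norms.HuberT()).fit()
    resid = y - exog @ fit.params
    # psi-weights at the solution; sandwich covariance of the M-estimator
    w = fit.weights
    bread = np.linalg.inv(exog.T @ (w[:, None] * exog))
    meat = exog.T @ (((w * resid) ** 2)[:, None] * exog)
    cov = bread @ meat @ bread
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fit.params / se
    p = 2 * scipy.stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {"slope": fit.params, "se": se, "z": z, "p": p},
        index=["intercept", "pd", "mean_pi"],
    )
    return RegressionResult(table=table)


# ---------------------------------------------------------------------------
# Host range vs prevalence
# ---------------------------------------------------------------------------

def hostrange_prevalence(
    network,
    presence_votu: pd.DataFrame,
    votu_modules: Mapping[str, int],
    botu_modules: Mapping[str, int],
) -> pd.DataFrame:
    """Per-module rank correlation of vOTU host range with prevalence.

    Host range counts the bOTUs of the vOTU's own module it is linked to;
    prevalence counts the samples where the vOTU is present.  Modules with
    fewer than 3 vOTUs are skipped; a constant host range or prevalence
    yields an undefined (NaN) correlation.
    """
    rows = []
    df = network.to_dataframe()
    for module in sorted(set(votu_modules.values())):
        votus = [
            v for v, m in votu_modules.items() if m == module and v in df.columns
        ]
        if len(votus) < 3:
            continue
        mod_botus = [b for b, m in botu_modules.items() if m == module and b in df.index]
        hr = df.loc[mod_botus, votus].sum(axis=0)
        prev = presence_votu[
            [v for v in votus if v in presence_votu.columns]
        ].sum(axis=0).reindex(votus).fillna(0)
        if hr.nunique() <= 1 or prev.nunique() <= 1:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = scipy.stats.spearmanr(hr, prev)
        rows.append(
            {
                "module_id": module,
                "n_votus": len(votus),
                "rho": float(rho) if rho == rho else float("nan"),
                "p_value": float(p) if p == p else float("nan"),
            }
        )
    return pd.DataFrame(rows)
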