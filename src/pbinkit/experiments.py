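"""Replicate simulation studies over the synthetic generator.

These drive the package's calibration and recovery checks: the phage-strain
coupling study (do beta-diversity correlations follow the interaction-module
structure, and is the strain level more informative than the species level?)
and the type-I-error study of the nestedness test.

The coupled study condition is fixed as: five strains per bacterial OTU at
50% per-sample occupancy (a species is then absent from only ~3% of samples,
reproducing the contrast between conserved species-level and variable
strain-level composition), no phage dropout, no edge noise and no
cross-module edges, so phage occurrence is a deterministic function of
host-strain occurrence.  The decoupled arm permutes each vOTU's presence
across samples, preserving prevalence while severing the host linkage.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import profiles
from .diversity_stats import mantel_statistic
from .synthetic_data import SynthConfig, Synthesizer

__all__ = [
    "coupling_replicate",
    "run_coupling_study",
    "run_gradient_study",
    "COUPLED_CONDITIONS",
    "GRADIENT_CONDITIONS",
]

COUPLED_CONDITIONS = dict(
    strains_per_botu=5,
    strain_occupancy=0.5,
    phage_dropout=0.0,
    edge_noise=0.0,
    cross_module_rate=0.0,
    n_samples=30,
    phages_per_module=10,
    genome_length=600,
)


def _distance_or_none(presence: pd.DataFrame, metric: str):
    if presence.empty or presence.to_numpy().sum() == 0:
        return None
    dm = profiles.jaccard(presence, metric)
    if np.isnan(dm.condensed()).any():
        return None
    return dm


def coupling_replicate(seed: int, decoupled: bool = False, **overrides) -> dict | None:
    """One replicate of the coupling study; returns summary statistics.

    Computes the rank Mantel statistic between the strain-level (popANI
    99.9%) bacterial distance matrix and the vOTU distance matrix, overall
    and for every (bacterial module, viral module) pair, plus species- and
    genus-level comparisons.  Returns None when a distance matrix is
    degenerate (an all-absent feature set), which does not occur under the
    coupled conditions at the default scale.
    """
    params = dict(COUPLED_CONDITIONS)
    params.update(overrides)
    cfg = SynthConfig(seed=seed, **params)
    syn = Synthesizer(cfg)
    _, truth = syn.generate_pbin()
    coverage, alleles, votu_presence = syn.generate_community()

    if decoupled:
        rng = np.random.default_rng(seed + 10_000)
        shuffled = votu_presence.copy()
        for v in shuffled.columns:
            shuffled[v] = rng.permutation(shuffled[v].to_numpy())
        votu_presence = shuffled

    pres_botu = profiles.call_presence(coverage[coverage["kind"] == "botu"], "botu")
    genus_map = {b: f"Genus{truth.botu_modules[b]}" for b in truth.botus}
    pres_genus = profiles.call_presence(
        coverage[coverage["kind"] == "botu"], "genus", botu_genus=genus_map
    )
    pop = profiles.popani_all_pairs(alleles)
    d_strain = profiles.strain_jaccard(pres_botu, pop, threshold=99.9)
    d_species = profiles.jaccard(pres_botu, "species")
    d_genus = _distance_or_none(pres_genus, "genus")
    d_votu = _distance_or_none(votu_presence.astype(int), "votu")
    if d_votu is None or np.isnan(d_strain.condensed()).any():
        return None

    out = {
        "seed": seed,
        "strain_stat": mantel_statistic(d_strain, d_votu),
        "species_stat": mantel_statistic(d_species, d_votu),
        "genus_stat": mantel_statistic(d_genus, d_votu) if d_genus is not None else np.nan,
    }

    modules = sorted(set(truth.botu_modules.values()))
    same, diff = [], []
    for bi, vj in itertools.product(modules, repeat=2):
        mb = [b for b, m in truth.botu_modules.items() if m == bi]
        mv = [v for v, m in truth.votu_modules.items() if m == vj]
        db = profiles.strain_jaccard(pres_botu[mb], pop, threshold=99.9)
        dv = _distance_or_none(votu_presence[mv].astype(int), f"votu_m{vj}")
        if dv is None or np.isnan(db.condensed()).any():
            continue
        stat = mantel_statistic(db, dv)
        (same if bi == vj else diff).append(stat)
    out["mean_same"] = float(np.mean(same)) if same else np.nan
    out["mean_diff"] = float(np.mean(diff)) if diff else np.nan
    return out


GRADIENT_CONDITIONS = dict(
    n_modules=5,
    bacteria_per_module=4,
    phages_per_module=8,
    strains_per_botu=4,
    strain_occupancy=0.5,
    occupancy_gradient=0.3,
    phage_dropout=0.0,
    n_samples=25,
    genome_length=400,
)


def run_gradient_study(seed: int, **overrides) -> dict:
    """Between/within-module alpha-diversity study on a planted gradient.

    Five modules span strain occupancies 0.2..0.8, so modules differ in both
    strain-level diversity and sustained phage richness.  Returns the
    between-module Pearson correlation of module-mean composite diversity
    (PD x pi) vs module-mean viral richness, the per-module within-module
    Spearman correlations, and the fraction of per-module robust-regression
    pi slopes that are positive.
    """
    import dendropy

    from .diversity_stats import (
        between_module_alpha_correlation,
        diversity_records,
        regress_richness,
        within_module_alpha_correlation,
    )

    params = dict(GRADIENT_CONDITIONS)
    params.update(overrides)
    cfg = SynthConfig(seed=seed, **params)
    syn = Synthesizer(cfg)
    _, truth = syn.generate_pbin()
    tree = dendropy.Tree.get(data=syn.generate_tree(), schema="newick")
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = leaf.taxon.label.replace(" ", "_")
    coverage, alleles, votu_presence = syn.generate_community()
    pres_botu = profiles.call_presence(coverage[coverage["kind"] == "botu"], "botu")
    gpi = {
        (s, b): profiles.genome_pi(t)
        for (s, b), t in alleles.groupby(["sample_id", "botu_id"])
    }
    records = diversity_records(
        truth.botu_modules, truth.votu_modules,
        pres_botu, votu_presence.astype(int), gpi, tree,
    )
    between = between_module_alpha_correlation(records)
    within, positive_slopes, n_regressed = [], 0, 0
    for mod in sorted(set(truth.botu_modules.values())):
        try:
            within.append(within_module_alpha_correlation(records, mod)["rho"])
        except ValueError:
            pass
        try:
            reg = regress_richness(records[records["module_id"] == mod])
            positive_slopes += reg.slope("mean_pi") > 0
            n_regressed += 1
        except ValueError:
            pass
    return {
        "between_r": between["r"],
        "between_p": between["p_value"],
        "within_rho": within,
        "frac_positive_pi_slopes": positive_slopes / max(n_regressed, 1),
        "n_modules": len(set(truth.botu_modules.values())),
        "n_regressed": n_regressed,
    }


def run_coupling_study(
    n_replicates: int = 50, seed: int = 0, decoupled: bool = False, **overrides
) -> pd.DataFrame:
    """Replicated coupling study; one row per successful replicate."""
    rows = []
    rng = np.random.default_rng(seed)
    while len(rows) < n_replicates:
        rep = coupling_replicate(int(rng.integers(2**31)), decoupled=decoupled, **overrides)
        if rep is not None:
            rows.append(rep)
    return pd.DataFrame(rows)
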