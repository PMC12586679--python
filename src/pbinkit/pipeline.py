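"""End-to-end orchestration: simulate -> screen -> link -> network -> profile -> stats.

A single structured configuration drives every stage; all thresholds are
surfaced as configuration keys with the standard defaults (spacer mismatch
budget 2; homology ANI 90 / AF 50 / prophage AF 80; vOTU clustering 95/85;
bOTU clustering 95; presence 5x / 0.5 / 0.7; pi coverage floor 5; popANI
threshold 99.9; 1000 null networks; 10,000 Mantel permutations; 15-bee
module filter).  Every stochastic stage consumes a seed derived
deterministically from the master seed, each stage writes immutable TSV
outputs, and a manifest records the configuration hash, per-file checksums
and wall-clock time per stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import diversity_stats, linkage, pbin, profiles, vcontig_screen
from .synthetic_data import SynthConfig, Synthesizer

__all__ = ["DEFAULTS", "validate_config", "run_all", "derive_seed"]

DEFAULTS: dict = {
    "spacer_max_mismatches": 2,
    "homology_min_ani": 90.0,
    "homology_min_af": 50.0,
    "prophage_min_af": 80.0,
    "votu_ani_threshold": 95.0,
    "votu_af_threshold": 85.0,
    "botu_ani_threshold": 95.0,
    "presence_min_median_cov": 5.0,
    "presence_min_breadth_botu": 0.5,
    "presence_min_breadth_votu": 0.7,
    "pi_min_coverage": 5,
    "popani_threshold": 99.9,
    "popani_sweep": [96.0, 97.0, 98.0, 99.0, 99.5, 99.9, 99.99],
    "n_null": 1000,
    "mantel_permutations": 10_000,
    "min_bees": 15,
    "lp_brim_restarts": 20,
    "crispr_min_locus_fraction": 0.10,
}

_RANGES = {
    "popani_threshold": (0.0, 100.0),
    "homology_min_ani": (0.0, 100.0),
    "homology_min_af": (0.0, 100.0),
    "prophage_min_af": (0.0, 100.0),
    "votu_ani_threshold": (0.0, 100.0),
    "votu_af_threshold": (0.0, 100.0),
    "botu_ani_threshold": (0.0, 100.0),
    "presence_min_breadth_botu": (0.0, 1.0),
    "presence_min_breadth_votu": (0.0, 1.0),
    "crispr_min_locus_fraction": (0.0, 1.0),
}

_DEPRECATED = {"ani_cutoff", "popani_cutoff", "n_permutations"}


def derive_seed(master: int, stage: int) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    ss = np.random.SeedSequence(entropy=(int(master), int(stage)))
    return int(ss.generate_state(1)[0] % (2**31))


def validate_config(config: dict) -> dict:
    """Fill defaults, check ranges, reject deprecated keys.

    Raises ValueError with one line per violation.  A ``seed`` is mandatory.
    """
    errors = []
    cfg = dict(DEFAULTS)
    for key, value in config.items():
        if key in _DEPRECATED:
            errors.append(f"deprecated key {key!r}; see DEFAULTS for the current name")
            continue
        cfg[key] = value
    if "seed" not in cfg or cfg.get("seed") is None:
        errors.append("missing mandatory key 'seed'")
    for key, (lo, hi) in _RANGES.items():
        v = cfg.get(key)
        if v is not None and not lo <= float(v) <= hi:
            errors.append(f"{key}={v} outside [{lo}, {hi}]")
    for key in ("n_null", "mantel_permutations", "min_bees", "lp_brim_restarts",
                "spacer_max_mismatches", "pi_min_coverage"):
        if int(cfg[key]) < 0:
            errors.append(f"{key} must be non-negative")
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, cfg: dict):
        canonical = json.dumps(cfg, sort_keys=True, default=str)
        self.data = {
            "config_hash": hashlib.sha256(canonical.encode()).hexdigest(),
            "stages": [],
        }

    def record(self, stage: str, outputs: list[Path], seconds: float, note: str = "") -> None:
        self.data["stages"].append(
            {
                "stage": stage,
                "seconds": round(seconds, 3),
                "note": note,
                "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
            }
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def _botu_label(representative: str) -> str:
    """OTU label from its representative genome id (generator scheme: '<botu>.gN')."""
    return representative.rsplit(".g", 1)[0]


def run_all(config: dict, outdir: str | Path, stop_after: str | None = None) -> dict:
    """Execute the full pipeline from a validated configuration.

    Runs simulate (when a ``synthetic`` block is present) then screen, link,
    network, profile and stats, writing every intermediate table under
    ``outdir``.  Returns the manifest dictionary (also written to
    manifest.json).  Stages fail fast with stage-labeled errors; an empty
    reconstructed network short-circuits the network and stats stages with a
    logged reason.
    """
    cfg = validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(cfg)
    results: dict = {"config": cfg}

    # ---- simulate ---------------------------------------------------------
    t0 = time.time()
    syn_block = dict(cfg.get("synthetic", {}))
    syn_block.setdefault("seed", derive_seed(cfg["seed"], 1))
    syn = Synthesizer(SynthConfig(**syn_block))
    art = syn.run()
    truth = art["truth"]
    input_paths = syn.write_inputs(out / "inputs", artifacts=art)
    manifest.record("simulate", list(input_paths.values()), time.time() - t0)
    results["truth"] = truth
    if stop_after == "simulate":
        manifest.write(out / "manifest.json")
        results["manifest"] = manifest.data
        return results

    # ---- screen -----------------------------------------------------------
    t0 = time.time()
    screened = vcontig_screen.screen_table(art["tool_scores"])
    p_screen = out / "screened_contigs.tsv"
    screened.to_csv(p_screen, sep="\t", index=False)
    retained_contigs = set(screened.loc[screened["retained"], "contig_id"])
    manifest.record("screen", [p_screen], time.time() - t0,
                    note=f"{len(retained_contigs)} contigs retained")
    results["screened"] = screened
    if stop_after == "screen":
        manifest.write(out / "manifest.json")
        results["manifest"] = manifest.data
        return results

    # ---- link -------------------------------------------------------------
    t0 = time.time()
    genome_records = {
        g: linkage.GenomeRecord(
            genome_id=g, kind="bMAG", genus=f"Genus{truth.botu_modules[b]}",
            length=truth.genome_lengths[g], completeness=95.0, contamination=2.0,
            has_crispr_locus=True,
        )
        for g, b in truth.genome_to_botu.items()
    }
    bact_assign = linkage.cluster_genomes(
        art["bacterial_ani"],
        genome_ids=sorted(truth.genome_to_botu),
        ani_threshold=cfg["botu_ani_threshold"],
        mode="single",
        lengths=truth.genome_lengths,
        otu_prefix="bOTU",
    )
    # relabel clusters by their representative's planted bOTU id so that
    # downstream tables (coverage, alleles) keyed by bOTU line up
    relabel = {otu: _botu_label(rep) for otu, rep in bact_assign.representatives.items()}
    bact_assign = linkage.OTUAssignment(
        {g: relabel[o] for g, o in bact_assign.genome_to_otu.items()},
        {relabel[o]: rep for o, rep in bact_assign.representatives.items()},
    )
    p_otu = out / "botu_assignments.tsv"
    bact_assign.to_dataframe().to_csv(p_otu, sep="\t", index=False)

    spacers_kept = linkage.filter_spacers(
        art["spacers"], bact_assign, genome_records,
        min_locus_fraction=cfg["crispr_min_locus_fraction"],
    )
    viral_seqs = {v: s for v, s in art["viral_seqs"].items() if v in retained_contigs}
    matches = linkage.match_spacers(
        spacers_kept, viral_seqs, max_mismatches=cfg["spacer_max_mismatches"]
    )
    p_matches = out / "spacer_matches.tsv"
    pd.DataFrame([vars(m) for m in matches]).to_csv(p_matches, sep="\t", index=False)

    hom_links = linkage.link_by_homology(
        art["homology"],
        min_ani=cfg["homology_min_ani"],
        min_af=cfg["homology_min_af"],
        prophage_af=cfg["prophage_min_af"],
    )
    core_genera = sorted({r.genus for r in genome_records.values()})
    votu_map = {v: v for v in viral_seqs}  # one vMAG per vOTU in the generator
    # genome-level evidence edges feed the genome-level network; the same
    # evidence aggregated at the OTU level gives the bOTU x vOTU edge list
    spacer_by_id = {sp.spacer_id: sp for sp in spacers_kept}
    genome_edges = set()
    for m in matches:
        if m.target_contig_id in votu_map:
            genome_edges.add((spacer_by_id[m.spacer_id].source_genome_id, m.target_contig_id))
    for row in hom_links.itertuples(index=False):
        if row.vmag_id in votu_map and row.genome_id in genome_records:
            genome_edges.add((row.genome_id, row.vmag_id))
    links, host_class = linkage.build_host_assignments(
        matches, spacer_by_id, hom_links, votu_map, bact_assign,
        otu_genus={_botu_label(rep): genome_records[rep].genus
                   for rep in bact_assign.representatives.values()},
        core_genera=core_genera,
    )
    p_links = out / "host_links.tsv"
    pd.DataFrame([vars(l) for l in links]).to_csv(p_links, sep="\t", index=False)
    manifest.record("link", [p_otu, p_matches, p_links], time.time() - t0,
                    note=f"{len(links)} vOTU-bOTU links")
    results["links"] = links
    if stop_after == "link":
        manifest.write(out / "manifest.json")
        results["manifest"] = manifest.data
        return results

    # ---- network ----------------------------------------------------------
    t0 = time.time()
    if not genome_edges:
        manifest.record("network", [], time.time() - t0,
                        note="zero edges reconstructed; network and stats stages skipped")
        results["network"] = None
        manifest.write(out / "manifest.json")
        results["manifest"] = manifest.data
        return results
    genome_net = pbin.BipartiteNetwork.from_edges(sorted(genome_edges))
    partition = pbin.lp_brim(
        genome_net, n_restarts=cfg["lp_brim_restarts"],
        seed=derive_seed(cfg["seed"], 2),
    )
    botu_modules = pbin.assign_modules_majority(
        partition, {g: bact_assign.genome_to_otu[g] for g in genome_net.row_labels},
        network=genome_net,
    )
    votu_modules = {v: partition.col_modules[v] for v in genome_net.col_labels}
    network = linkage.links_to_network(links)
    p_net = out / "interaction_network.tsv"
    network.write_tsv(p_net)
    p_part = out / "module_partition.tsv"
    pd.DataFrame(
        [(b, "bOTU", m) for b, m in sorted(botu_modules.items())]
        + [(v, "vOTU", m) for v, m in sorted(votu_modules.items())],
        columns=["node", "side", "module"],
    ).to_csv(p_part, sep="\t", index=False)

    nest_rows = []
    testable = []
    for mod in sorted(set(botu_modules.values())):
        rows = [b for b, m in botu_modules.items() if m == mod and b in network.row_labels]
        cols = [v for v, m in votu_modules.items() if m == mod and v in network.col_labels]
        if len(rows) >= 2 and len(cols) >= 2:
            testable.append((mod, rows, cols))
    for mod, rows, cols in testable:
        sub = network.subnetwork(rows, cols)
        res = pbin.nestedness_test(
            sub.matrix, n_null=cfg["n_null"],
            seed=derive_seed(cfg["seed"], 100 + mod),
            n_modules_tested=len(testable), module=mod,
        )
        nest_rows.append(
            {
                "module": mod, "n_botus": len(rows), "n_votus": len(cols),
                "nodf": res.observed_nodf, "null_mean": res.null_mean,
                "null_ci_low": res.null_ci[0], "null_ci_high": res.null_ci[1],
                "p_value": res.p_value, "p_adjusted": res.p_adjusted,
            }
        )
    p_nest = out / "nestedness.tsv"
    pd.DataFrame(nest_rows).to_csv(p_nest, sep="\t", index=False)

    # module purity of local neighborhoods in the proteome-sharedness network
    proteome = art.get("proteome_edges")
    purity_df = pd.DataFrame(columns=["node", "neighborhood_size", "purity"])
    if proteome is not None and len(proteome):
        purity = pbin.neighborhood_purity(
            list(zip(proteome["node_a"], proteome["node_b"])), votu_modules
        )
        purity_df = pd.DataFrame([vars(p) for p in purity])
    p_purity = out / "neighborhood_purity.tsv"
    purity_df.to_csv(p_purity, sep="\t", index=False)

    manifest.record(
        "network", [p_net, p_part, p_nest, p_purity], time.time() - t0,
        note=f"Q={partition.q:.4f}, {partition.n_modules} modules",
    )
    results.update(
        network=network, partition=partition,
        botu_modules=botu_modules, votu_modules=votu_modules,
        nestedness=pd.DataFrame(nest_rows),
        neighborhood_purity=purity_df,
    )
    if stop_after == "network":
        manifest.write(out / "manifest.json")
        results["manifest"] = manifest.data
        return results

    # ---- profile ----------------------------------------------------------
    t0 = time.time()
    coverage = art["coverage"]
    botu_genus = {b: f"Genus{truth.botu_modules[b]}" for b in truth.botus}
    pres_botu = profiles.call_presence(
        coverage[coverage["kind"] == "botu"], "botu",
        min_median_cov=cfg["presence_min_median_cov"],
        min_breadth_botu=cfg["presence_min_breadth_botu"],
    )
    pres_genus = profiles.call_presence(
        coverage[coverage["kind"] == "botu"], "genus", botu_genus=botu_genus,
        min_median_cov=cfg["presence_min_median_cov"],
        min_breadth_botu=cfg["presence_min_breadth_botu"],
    )
    pres_votu = profiles.call_presence(
        coverage[coverage["kind"] == "votu"], "votu",
        min_breadth_votu=cfg["presence_min_breadth_votu"],
    )
    pres_votu = pres_votu[[c for c in pres_votu.columns if c in retained_contigs]]

    gpi = {
        (s, b): profiles.genome_pi(t, min_coverage=cfg["pi_min_coverage"])
        for (s, b), t in art["alleles"].groupby(["sample_id", "botu_id"])
    }
    p_pi = out / "genome_pi.tsv"
    pd.DataFrame(
        [(s, b, v) for (s, b), v in sorted(gpi.items())],
        columns=["sample_id", "botu_id", "pi"],
    ).to_csv(p_pi, sep="\t", index=False)

    pop = profiles.popani_all_pairs(art["alleles"], min_cov=cfg["pi_min_coverage"])
    p_pop = out / "popani.tsv"
    pop.to_csv(p_pop, sep="\t", index=False)

    d_genus = profiles.jaccard(pres_genus, "genus_jaccard")
    d_species = profiles.jaccard(pres_botu, "species_jaccard")
    d_votu = profiles.jaccard(pres_votu, "votu_jaccard")
    d_strain = profiles.strain_jaccard(pres_botu, pop, threshold=cfg["popani_threshold"])
    dist_paths = []
    for name, dm in [
        ("genus", d_genus), ("species", d_species), ("votu", d_votu), ("strain", d_strain),
    ]:
        p = out / f"distance_{name}.tsv"
        dm.write_tsv(p)
        dist_paths.append(p)

    sweep = profiles.threshold_sweep(pres_botu, pop, thresholds=cfg["popani_sweep"])
    sweep_rows = []
    for thr in sorted(sweep):
        dmat = sweep[thr].data
        for i, x in enumerate(dmat.index):
            for y in dmat.columns[i + 1 :]:
                sweep_rows.append((thr, x, y, dmat.loc[x, y]))
    p_sweep = out / "strain_distance_sweep.tsv"
    pd.DataFrame(
        sweep_rows, columns=["popani_threshold", "sample_x", "sample_y", "distance"]
    ).to_csv(p_sweep, sep="\t", index=False)
    manifest.record("profile", [p_pi, p_pop, p_sweep, *dist_paths], time.time() - t0)
    results.update(
        presence_botu=pres_botu, presence_genus=pres_genus, presence_votu=pres_votu,
        genome_pi=gpi, popani=pop,
        distances={"genus": d_genus, "species": d_species,
                   "votu": d_votu, "strain": d_strain},
    )
    if stop_after == "profile":
        manifest.write(out / "manifest.json")
        results["manifest"] = manifest.data
        return results

    # ---- stats ------------------------------------------------------------
    t0 = time.time()
    tree = dendropy.Tree.get(data=truth.tree_newick, schema="newick")
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = leaf.taxon.label.replace(" ", "_")
    records = diversity_stats.diversity_records(
        botu_modules, votu_modules, pres_botu, pres_votu, gpi, tree
    )
    p_rec = out / "diversity_records.tsv"
    records.to_csv(p_rec, sep="\t", index=False)

    passing = diversity_stats.modules_passing_filter(
        botu_modules, votu_modules, pres_botu, pres_votu, min_bees=cfg["min_bees"]
    )
    stats_out = {"modules_passing_filter": passing}

    mantel_seed = derive_seed(cfg["seed"], 3)
    beta_rows = []
    for name, dm in [("genus", d_genus), ("species", d_species), ("strain", d_strain)]:
        try:
            res = diversity_stats.mantel(
                dm, d_votu, n_permutations=cfg["mantel_permutations"], seed=mantel_seed
            )
            beta_rows.append(
                {"level": name, "statistic": res.statistic,
                 "p_value": res.p_value, "n": res.n_samples}
            )
        except ValueError as exc:
            beta_rows.append({"level": name, "statistic": float("nan"),
                              "p_value": float("nan"), "n": 0, "note": str(exc)})
    p_beta = out / "beta_correlations.tsv"
    pd.DataFrame(beta_rows).to_csv(p_beta, sep="\t", index=False)
    stats_out["beta"] = pd.DataFrame(beta_rows)

    strain_by_mod, votu_by_mod = {}, {}
    for mod in passing:
        mb = [b for b, m in botu_modules.items() if m == mod and b in pres_botu.columns]
        mv = [v for v, m in votu_modules.items() if m == mod and v in pres_votu.columns]
        keep_b = pres_botu.index[(pres_botu[mb].sum(axis=1) > 0)]
        keep_v = pres_votu.index[(pres_votu[mv].sum(axis=1) > 0)]
        common = [s for s in pres_botu.index if s in set(keep_b) and s in set(keep_v)]
        if len(common) < 4:
            continue
        strain_by_mod[mod] = profiles.strain_jaccard(
            pres_botu.loc[common, mb], pop, threshold=cfg["popani_threshold"]
        )
        votu_by_mod[mod] = profiles.jaccard(pres_votu.loc[common, mv], f"votu_m{mod}")
    matched = diversity_stats.module_matched_correlations(
        strain_by_mod, votu_by_mod, sorted(strain_by_mod),
        n_permutations=cfg["mantel_permutations"], seed=derive_seed(cfg["seed"], 4),
    )
    p_matched = out / "module_matched_mantel.tsv"
    matched.to_csv(p_matched, sep="\t", index=False)
    stats_out["matched"] = matched

    stats_paths = [p_rec, p_beta, p_matched]
    rec_pass = records[records["module_id"].isin(passing)]
    if len(passing) >= 3:
        between = diversity_stats.between_module_alpha_correlation(rec_pass)
        stats_out["between_module"] = between
        p_btw = out / "between_module_alpha.tsv"
        between["per_module"].assign(pearson_r=between["r"], p_value=between["p_value"]).to_csv(
            p_btw, sep="\t"
        )
        stats_paths.append(p_btw)

    within_rows, regress_frames = [], []
    for mod in passing:
        try:
            within_rows.append(diversity_stats.within_module_alpha_correlation(rec_pass, mod))
        except ValueError as exc:
            within_rows.append({"module_id": mod, "rho": float("nan"),
                                "p_value": float("nan"), "n": 0, "note": str(exc)})
        sub = rec_pass[rec_pass["module_id"] == mod]
        try:
            reg = diversity_stats.regress_richness(sub)
            regress_frames.append(reg.table.assign(module_id=mod))
        except ValueError:
            pass
    p_within = out / "within_module_alpha.tsv"
    pd.DataFrame(within_rows).to_csv(p_within, sep="\t", index=False)
    stats_paths.append(p_within)
    stats_out["within_module"] = pd.DataFrame(within_rows)
    if regress_frames:
        p_reg = out / "regression_table.tsv"
        pd.concat(regress_frames).to_csv(p_reg, sep="\t", index_label="predictor")
        stats_paths.append(p_reg)
        stats_out["regression"] = pd.concat(regress_frames)

    hr = diversity_stats.hostrange_prevalence(network, pres_votu, votu_modules, botu_modules)
    p_hr = out / "hostrange_prevalence.tsv"
    hr.to_csv(p_hr, sep="\t", index=False)
    stats_paths.append(p_hr)
    stats_out["hostrange"] = hr

    manifest.record("stats", stats_paths, time.time() - t0)
    results["stats"] = stats_out

    manifest.write(out / "manifest.json")
    results["manifest"] = manifest.data
    return results
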