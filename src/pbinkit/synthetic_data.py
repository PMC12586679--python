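"""Synthetic phage-bacteria community generator with planted ground truth.

Every input the analysis pipeline consumes can be generated here with
parameter-controlled structure:

* a modular bipartite interaction network whose within-module blocks are
  nested by construction (a rank-threshold fill curve with shape theta,
  optionally degraded by symmetric Bernoulli noise and cross-module edges);
* a module-monophyletic bacterial phylogeny with exponential branch lengths;
* per-sample strain pools per bacterial OTU whose allele-count tables yield
  controllable nucleotide diversity (pi) and popANI, with phage occurrence
  coupled to host-strain occurrence through a nested strain-susceptibility
  map (strain rank k is susceptible to the k broadest phages of its module,
  scaled to the module size);
* CRISPR-spacer and genome-homology evidence consistent with the planted
  network (plus optional labeled decoys); and
* per-contig detector score tables with a known expected retained set.

Identical configurations (including the seed) give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .linkage import SpacerRecord, reverse_complement
from .pbin import BipartiteNetwork

__all__ = ["SynthConfig", "GroundTruth", "Synthesizer"]

_BASES = np.array(list("ACGT"))
SPACER_LENGTH = 32  # typical CRISPR spacer length; any fixed length works


@dataclass
class SynthConfig:
    """Parameters of the planted community; defaults give the demo scale.

    ``nestedness_shape`` (theta) controls the within-module fill curve
    (1 = strict triangle); ``edge_noise`` flips within-module cells,
    ``cross_module_rate`` switches on off-module cells.  ``strain_occupancy``
    is the per-strain per-sample presence probability, ``phage_dropout`` the
    probability a phage is missed despite a susceptible host strain being
    present.  A nonzero ``occupancy_gradient`` g plants a between-module
    diversity gradient: module m uses occupancy scaled by
    1 + g*(m - (M+1)/2), clipped to [0.02, 0.98], so strain-richer modules
    also sustain more phages.  ``snv_rate`` is the fraction of genome positions variable
    between strains; ``mean_coverage`` the Poisson read depth per position
    (it must sit well above the 5x presence cutoff for the planted presence
    pattern to be recoverable).
    """

    n_modules: int = 3
    bacteria_per_module: int = 6
    phages_per_module: int = 8
    strains_per_botu: int = 3
    n_samples: int = 20
    nestedness_shape: float = 1.0
    edge_noise: float = 0.0
    cross_module_rate: float = 0.0
    strain_occupancy: float = 0.5
    occupancy_gradient: float = 0.0
    phage_dropout: float = 0.1
    genome_length: int = 1000
    snv_rate: float = 0.02
    mean_coverage: float = 50.0
    evidence_crispr_prob: float = 1.0
    evidence_homology_prob: float = 1.0
    genomes_per_botu: int = 2
    viral_genome_length: int = 12_000
    n_decoy_spacers: int = 0
    n_decoy_homology: int = 0
    n_junk_contigs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "edge_noise",
            "cross_module_rate",
            "strain_occupancy",
            "phage_dropout",
            "snv_rate",
            "evidence_crispr_prob",
            "evidence_homology_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be a probability in [0, 1]")
        for name in (
            "n_modules",
            "bacteria_per_module",
            "phages_per_module",
            "strains_per_botu",
            "n_samples",
            "genome_length",
            "genomes_per_botu",
            "viral_genome_length",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.nestedness_shape <= 0:
            raise ValueError("nestedness_shape must be positive")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the master seed."""
        return np.random.default_rng(np.random.SeedSequence(entropy=(self.seed, stage)))


@dataclass
class GroundTruth:
    """Planted structure against which every pipeline stage can be scored."""

    config: SynthConfig
    botus: list[str] = field(default_factory=list)
    votus: list[str] = field(default_factory=list)
    botu_modules: dict[str, int] = field(default_factory=dict)
    votu_modules: dict[str, int] = field(default_factory=dict)
    noise_free_matrix: pd.DataFrame | None = None
    interaction: pd.DataFrame | None = None
    # susceptibility[(botu, votu)] = set of susceptible strain ranks (1-based)
    susceptibility: dict[tuple[str, str], frozenset] = field(default_factory=dict)
    genome_to_botu: dict[str, str] = field(default_factory=dict)
    genome_lengths: dict[str, int] = field(default_factory=dict)
    strain_alleles: dict[str, np.ndarray] = field(default_factory=dict)
    occupancy: dict[tuple[str, str], tuple] = field(default_factory=dict)
    true_pi: dict[tuple[str, str], float] = field(default_factory=dict)
    votu_presence: pd.DataFrame | None = None
    viral_seqs: dict[str, str] = field(default_factory=dict)
    evidence_ledger: pd.DataFrame | None = None
    expected_retained: set[str] = field(default_factory=set)
    tree_newick: str | None = None

    @property
    def true_edges(self) -> set[tuple[str, str]]:
        """Realized (bOTU, vOTU) edges of the planted network."""
        df = self.interaction
        return {
            (b, v)
            for b in df.index
            for v in df.columns
            if df.loc[b, v] == 1
        }


class Synthesizer:
    """Stateful generator: call the generate_* methods in order, or run()."""

    def __init__(self, config: SynthConfig):
        self.config = config
        self.truth = GroundTruth(config=config)

    # ------------------------------------------------------------------
    # 1. bipartite interaction network
    # ------------------------------------------------------------------
    def generate_pbin(self) -> tuple[BipartiteNetwork, GroundTruth]:
        """Plant the modular, within-module-nested interaction matrix.

        Within module m with B bacteria and P phages, the phage of rank j
        infects bacteria of ranks 1..max(1, round(B * (1-(j-1)/P)**theta)).
        Each within-module cell is then flipped with probability edge_noise
        and each cross-module cell switched on with probability
        cross_module_rate.
        """
        cfg = self.config
        rng = cfg.rng(1)
        B, P, M = cfg.bacteria_per_module, cfg.phages_per_module, cfg.n_modules
        botus, votus = [], []
        for m in range(1, M + 1):
            botus += [f"bOTU_m{m}_{b:02d}" for b in range(1, B + 1)]
            votus += [f"vOTU_m{m}_{p:02d}" for p in range(1, P + 1)]
        self.truth.botus, self.truth.votus = botus, votus
        self.truth.botu_modules = {b: int(b.split("_m")[1].split("_")[0]) for b in botus}
        self.truth.votu_modules = {v: int(v.split("_m")[1].split("_")[0]) for v in votus}

        A = np.zeros((M * B, M * P), dtype=np.int8)
        module_of_row = np.repeat(np.arange(M), B)
        module_of_col = np.repeat(np.arange(M), P)
        for m in range(M):
            for j in range(1, P + 1):  # phage rank within module
                depth = max(1, round(B * (1 - (j - 1) / P) ** cfg.nestedness_shape))
                rows = m * B + np.arange(depth)
                A[rows, m * P + (j - 1)] = 1
            if A[m * B : (m + 1) * B, m * P : (m + 1) * P].sum() == 0:
                raise ValueError(f"module {m + 1} would have zero edges")
        clean = A.copy()
        self.truth.noise_free_matrix = pd.DataFrame(clean, index=botus, columns=votus)

        within = module_of_row[:, None] == module_of_col[None, :]
        flips = rng.random(A.shape) < cfg.edge_noise
        A = np.where(within & flips, 1 - A, A)
        cross_on = rng.random(A.shape) < cfg.cross_module_rate
        A = np.where(~within & cross_on, 1, A).astype(np.int8)
        self.truth.interaction = pd.DataFrame(A, index=botus, columns=votus)

        # nested strain susceptibility: strain rank k of a host is susceptible
        # to the ceil(k * P / S) broadest phages of its module; off-module
        # (noise) edges are reachable by every strain
        S = cfg.strains_per_botu
        for bi, b in enumerate(botus):
            for vi, v in enumerate(votus):
                if A[bi, vi] != 1:
                    continue
                if self.truth.botu_modules[b] == self.truth.votu_modules[v]:
                    j = int(v.split("_")[-1])  # phage rank, 1 = broadest
                    strains = frozenset(
                        k for k in range(1, S + 1) if j <= int(np.ceil(k * P / S))
                    )
                    if not strains:
                        strains = frozenset({S})
                else:
                    strains = frozenset(range(1, S + 1))
                self.truth.susceptibility[(b, v)] = strains

        # bacterial genomes: genomes_per_botu members per bOTU
        for b in botus:
            for g in range(1, cfg.genomes_per_botu + 1):
                gid = f"{b}.g{g}"
                self.truth.genome_to_botu[gid] = b
                self.truth.genome_lengths[gid] = int(rng.integers(1_800_000, 2_400_000))
        network = BipartiteNetwork.from_dataframe(self.truth.interaction)
        return network, self.truth

    # ------------------------------------------------------------------
    # 2. module-monophyletic phylogeny
    # ------------------------------------------------------------------
    def generate_tree(self, mean_branch_length: float = 0.1) -> str:
        """Random binary tree whose planted modules are monophyletic clades."""
        if not self.truth.botus:
            raise ValueError("generate_pbin must run first")
        rng = self.config.rng(2)

        def _exp() -> float:
            return float(rng.exponential(mean_branch_length))

        def _join(subtrees: list[str]) -> str:
            subtrees = list(subtrees)
            order = rng.permutation(len(subtrees))
            subtrees = [subtrees[i] for i in order]
            while len(subtrees) > 1:
                a = subtrees.pop()
                b = subtrees.pop()
                subtrees.append(f"({a}:{_exp():.6f},{b}:{_exp():.6f})")
            return subtrees[0]

        clades = []
        for m in range(1, self.config.n_modules + 1):
            tips = [b for b in self.truth.botus if self.truth.botu_modules[b] == m]
            clades.append(_join(tips))
        newick = _join(clades) + ";"
        self.truth.tree_newick = newick
        return newick

    # ------------------------------------------------------------------
    # 3. community: occupancy, allele tables, coverage, phage presence
    # ------------------------------------------------------------------
    def generate_community(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        """Per-sample strain pools, allele-count tables and coverage summaries.

        Each bOTU's strains are drawn independently per sample with
        probability strain_occupancy; present strains get Dirichlet(1)
        relative abundances.  Allele counts at each genome position are
        multinomial over the pooled strain alleles at Poisson(mean_coverage)
        depth.  A vOTU is truly present when at least one susceptible host
        strain is present and a Bernoulli(1 - phage_dropout) trial succeeds.
        Returns (coverage_summaries, allele_table, votu_presence).
        """
        cfg = self.config
        truth = self.truth
        if truth.interaction is None:
            raise ValueError("generate_pbin must run first")
        rng = cfg.rng(3)
        L, S = cfg.genome_length, cfg.strains_per_botu
        samples = [f"bee_{i:03d}" for i in range(1, cfg.n_samples + 1)]

        # strain haplotypes: reference is strain 1's allele; a planted variant
        # position carries one alternative allele in a random nonempty subset
        # of strains 2..S
        n_var = int(round(cfg.snv_rate * L))
        for b in truth.botus:
            alleles = np.tile(rng.integers(0, 4, size=L, dtype=np.int8), (S, 1))
            var_pos = rng.choice(L, size=n_var, replace=False)
            for pos in var_pos:
                alt = (alleles[0, pos] + rng.integers(1, 4)) % 4
                if S == 1:
                    continue
                carriers = np.flatnonzero(rng.random(S - 1) < 0.5) + 1
                if carriers.size == 0:
                    carriers = np.array([int(rng.integers(1, S))])
                alleles[carriers, pos] = alt
            truth.strain_alleles[b] = alleles

        mid = (cfg.n_modules + 1) / 2.0

        def occupancy_of(botu: str) -> float:
            scale = 1.0 + cfg.occupancy_gradient * (truth.botu_modules[botu] - mid)
            return float(np.clip(cfg.strain_occupancy * scale, 0.02, 0.98))

        cov_rows, allele_frames = [], []
        for s in samples:
            for b in truth.botus:
                present = np.flatnonzero(rng.random(S) < occupancy_of(b))
                if present.size == 0:
                    truth.occupancy[(s, b)] = (present, np.array([]))
                    truth.true_pi[(s, b)] = float("nan")
                    cov_rows.append((s, b, "botu", 0.0, 0.0))
                    continue
                w = rng.dirichlet(np.ones(present.size))
                truth.occupancy[(s, b)] = (present, w)
                alleles = truth.strain_alleles[b][present]  # (n_present, L)
                freq = np.zeros((L, 4))
                for si, ws in zip(range(present.size), w):
                    np.add.at(freq, (np.arange(L), alleles[si]), ws)
                freq /= freq.sum(axis=1, keepdims=True)
                truth.true_pi[(s, b)] = float((1.0 - (freq**2).sum(axis=1)).mean())
                depth = rng.poisson(cfg.mean_coverage, size=L)
                counts = rng.multinomial(depth, freq)
                allele_frames.append(
                    pd.DataFrame(
                        {
                            "sample_id": s,
                            "botu_id": b,
                            "position": np.arange(1, L + 1),
                            "n_A": counts[:, 0],
                            "n_C": counts[:, 1],
                            "n_G": counts[:, 2],
                            "n_T": counts[:, 3],
                        }
                    )
                )
                cov_rows.append(
                    (s, b, "botu", float(np.median(depth)), float((depth > 0).mean()))
                )

        # phage occurrence coupled to susceptible-strain occurrence
        presence = pd.DataFrame(0, index=samples, columns=truth.votus, dtype=int)
        for s in samples:
            for v in truth.votus:
                hosts = [key for key in truth.susceptibility if key[1] == v]
                has_host = any(
                    bool(
                        set(truth.occupancy[(s, b)][0] + 1)
                        & truth.susceptibility[(b, v)]
                    )
                    for b, _ in hosts
                )
                if has_host and rng.random() >= cfg.phage_dropout:
                    presence.loc[s, v] = 1
        truth.votu_presence = presence
        for s in samples:
            for v in truth.votus:
                if presence.loc[s, v]:
                    cov_rows.append(
                        (s, v, "votu", float(cfg.mean_coverage), float(rng.uniform(0.75, 1.0)))
                    )
                else:
                    cov_rows.append((s, v, "votu", 0.0, float(rng.uniform(0.0, 0.6))))

        coverage = pd.DataFrame(
            cov_rows,
            columns=["sample_id", "feature_id", "kind", "median_coverage", "breadth"],
        )
        alleles_df = (
            pd.concat(allele_frames, ignore_index=True)
            if allele_frames
            else pd.DataFrame(
                columns=["sample_id", "botu_id", "position", "n_A", "n_C", "n_G", "n_T"]
            )
        )
        return coverage, alleles_df, presence

    # ------------------------------------------------------------------
    # 4. evidence: spacers, viral sequences, homology, pairwise ANI tables
    # ------------------------------------------------------------------
    def generate_evidence(self) -> tuple[list[SpacerRecord], dict[str, str], pd.DataFrame]:
        """Spacer records, viral genome sequences and homology rows.

        Every realized network edge is materialized as a CRISPR spacer (a
        random 32-mer copied from the phage genome into a spacer of one of
        the host bOTU's genomes, with 0-2 planted mismatches) with
        probability evidence_crispr_prob, and/or as a homology row with
        ANI ~ U(90.5, 99.5) and AF ~ U(55, 100) with probability
        evidence_homology_prob.  Decoy spacers carry exactly 3 mismatches
        and decoy homology rows fall below the linkage thresholds; both are
        labeled in the evidence ledger.
        """
        cfg = self.config
        truth = self.truth
        if truth.interaction is None:
            raise ValueError("generate_pbin must run first")
        rng = cfg.rng(4)

        for v in truth.votus:
            truth.viral_seqs[v] = "".join(
                _BASES[rng.integers(0, 4, size=cfg.viral_genome_length)]
            )

        def genomes_of(botu: str) -> list[str]:
            return sorted(g for g, b in truth.genome_to_botu.items() if b == botu)

        def plant_spacer(votu: str, n_mismatches: int) -> str:
            seq = truth.viral_seqs[votu]
            start = int(rng.integers(0, len(seq) - SPACER_LENGTH))
            proto = list(seq[start : start + SPACER_LENGTH])
            for pos in rng.choice(SPACER_LENGTH, size=n_mismatches, replace=False):
                proto[pos] = str(
                    rng.choice([b for b in "ACGT" if b != proto[pos]])
                )
            spacer = "".join(proto)
            if rng.random() < 0.5:
                spacer = reverse_complement(spacer)
            return spacer

        spacers: list[SpacerRecord] = []
        hom_rows, ledger = [], []
        sp_idx = 0
        for b, v in sorted(truth.true_edges):
            got_crispr = rng.random() < cfg.evidence_crispr_prob
            got_hom = rng.random() < cfg.evidence_homology_prob
            if got_crispr:
                sp_idx += 1
                src = str(rng.choice(genomes_of(b)))
                nm = int(rng.integers(0, 3))
                spacers.append(
                    SpacerRecord(
                        spacer_id=f"sp_{sp_idx:04d}",
                        sequence=plant_spacer(v, nm),
                        source_genome_id=src,
                        evidence_level=4,
                    )
                )
                ledger.append(("crispr", f"sp_{sp_idx:04d}", b, v, nm, False))
            if got_hom:
                src = str(rng.choice(genomes_of(b)))
                ani = float(rng.uniform(90.5, 99.5))
                af = float(rng.uniform(55.0, 100.0))
                hom_rows.append((v, src, ani, af))
                ledger.append(("homology", f"{v}|{src}", b, v, None, False))

        non_edges = [
            (b, v)
            for b in truth.botus
            for v in truth.votus
            if (b, v) not in truth.true_edges
        ]
        for i in range(cfg.n_decoy_spacers):
            b, v = non_edges[int(rng.integers(len(non_edges)))]
            sp_idx += 1
            spacers.append(
                SpacerRecord(
                    spacer_id=f"sp_{sp_idx:04d}",
                    sequence=plant_spacer(v, 3),
                    source_genome_id=str(rng.choice(genomes_of(b))),
                    evidence_level=4,
                )
            )
            ledger.append(("crispr", f"sp_{sp_idx:04d}", b, v, 3, True))
        for i in range(cfg.n_decoy_homology):
            b, v = non_edges[int(rng.integers(len(non_edges)))]
            src = str(rng.choice(genomes_of(b)))
            if rng.random() < 0.5:
                ani, af = float(rng.uniform(80.0, 89.5)), float(rng.uniform(55.0, 100.0))
            else:
                ani, af = float(rng.uniform(90.5, 99.5)), float(rng.uniform(10.0, 45.0))
            hom_rows.append((v, src, ani, af))
            ledger.append(("homology", f"{v}|{src}", b, v, None, True))

        homology = pd.DataFrame(
            hom_rows, columns=["query_id", "target_id", "ani", "af"]
        )
        truth.evidence_ledger = pd.DataFrame(
            ledger,
            columns=["kind", "record_id", "botu_id", "votu_id", "mismatches", "is_decoy"],
        )
        return spacers, truth.viral_seqs, homology

    def generate_proteome_edges(
        self, p_within: float = 0.6, p_between: float = 0.02
    ) -> pd.DataFrame:
        """Proteome-sharedness edge list among vOTUs.

        Phages of the same module share proteins with probability p_within,
        across modules with probability p_between — emulating the structure
        of a gene-sharing network whose clusters align with the interaction
        modules.
        """
        rng = self.config.rng(7)
        rows = []
        votus = self.truth.votus
        for i, a in enumerate(votus):
            for b in votus[i + 1 :]:
                same = self.truth.votu_modules[a] == self.truth.votu_modules[b]
                if rng.random() < (p_within if same else p_between):
                    rows.append((a, b, float(rng.uniform(0.1, 1.0))))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    def bacterial_ani_table(self) -> pd.DataFrame:
        """Pairwise ANI/AF rows clustering genomes of the same bOTU together."""
        rng = self.config.rng(5)
        rows = []
        by_botu: dict[str, list[str]] = {}
        for g, b in self.truth.genome_to_botu.items():
            by_botu.setdefault(b, []).append(g)
        for b, genomes in sorted(by_botu.items()):
            genomes = sorted(genomes)
            for i, gi in enumerate(genomes):
                for gj in genomes[i + 1 :]:
                    rows.append(
                        (gi, gj, float(rng.uniform(96.5, 99.9)), float(rng.uniform(90, 100)))
                    )
        return pd.DataFrame(rows, columns=["query_id", "target_id", "ani", "af"])

    # ------------------------------------------------------------------
    # 5. detector score tables
    # ------------------------------------------------------------------
    def generate_tool_scores(self) -> pd.DataFrame:
        """Raw detector scores plus length/kmer/quality metadata per contig.

        Every planted vOTU contig is given scores that survive the consensus
        screen; ``n_junk_contigs`` additional contigs cycle through three
        failure modes (too short, called by one tool at its lowest band,
        kmer contamination), and the expected retained set is recorded in
        the ground truth.
        """
        cfg = self.config
        truth = self.truth
        rng = cfg.rng(6)
        rows = []
        for v in truth.votus:
            rows.append(
                {
                    "contig_id": v,
                    "detector_a": float(rng.uniform(0.81, 0.99)),
                    "detector_b": str(rng.choice(["medium", "high"])),
                    "detector_c": float(rng.uniform(10.5, 25.0)),
                    "length": cfg.viral_genome_length,
                    "kmer_freq": float(rng.uniform(1.0, 1.1)),
                    "quality_tier": str(rng.choice(["medium", "high"])),
                    "lysogenic": bool(rng.random() < 0.2),
                    "provirus": False,
                }
            )
            truth.expected_retained.add(v)
        failure_modes = ["short", "lowscore", "contaminated"]
        for i in range(cfg.n_junk_contigs):
            mode = failure_modes[i % 3]
            row = {
                "contig_id": f"junk_{mode}_{i:02d}",
                "detector_a": float(rng.uniform(0.81, 0.99)),
                "detector_b": "high",
                "detector_c": float(rng.uniform(10.5, 25.0)),
                "length": cfg.viral_genome_length,
                "kmer_freq": 1.05,
                "quality_tier": "medium",
                "lysogenic": False,
                "provirus": False,
            }
            if mode == "short":
                row["length"] = 9_999
            elif mode == "lowscore":
                row.update({"detector_a": 0.3, "detector_b": None, "detector_c": None})
            else:
                row["kmer_freq"] = 1.3
            rows.append(row)
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    def run(self) -> dict:
        """Generate everything in order; returns all artifacts keyed by name."""
        network, truth = self.generate_pbin()
        tree = self.generate_tree()
        coverage, alleles, votu_presence = self.generate_community()
        spacers, viral_seqs, homology = self.generate_evidence()
        return {
            "network": network,
            "truth": truth,
            "tree_newick": tree,
            "coverage": coverage,
            "alleles": alleles,
            "votu_presence": votu_presence,
            "spacers": spacers,
            "viral_seqs": viral_seqs,
            "homology": homology,
            "bacterial_ani": self.bacterial_ani_table(),
            "proteome_edges": self.generate_proteome_edges(),
            "tool_scores": self.generate_tool_scores(),
        }

    # ------------------------------------------------------------------
    def write_inputs(self, outdir: str | Path, artifacts: dict | None = None) -> dict[str, Path]:
        """Write every pipeline input plus a ground-truth manifest as text files."""
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        art = artifacts if artifacts is not None else self.run()
        paths: dict[str, Path] = {}

        paths["tree"] = out / "bacteria.nwk"
        paths["tree"].write_text(art["tree_newick"] + "\n")

        paths["viral_fasta"] = out / "viral_genomes.fasta"
        SeqIO.write(
            [SeqRecord(Seq(s), id=v, description="") for v, s in art["viral_seqs"].items()],
            paths["viral_fasta"],
            "fasta",
        )
        paths["spacer_fasta"] = out / "spacers.fasta"
        SeqIO.write(
            [
                SeqRecord(
                    Seq(sp.sequence),
                    id=sp.spacer_id,
                    description=(
                        f"source={sp.source_genome_id} array={sp.array_id} "
                        f"evidence_level={sp.evidence_level}"
                    ),
                )
                for sp in art["spacers"]
            ],
            paths["spacer_fasta"],
            "fasta",
        )

        for key, name in [
            ("coverage", "coverage_summaries.tsv"),
            ("alleles", "allele_tables.tsv"),
            ("homology", "homology.tsv"),
            ("bacterial_ani", "bacterial_ani.tsv"),
            ("proteome_edges", "proteome_edges.tsv"),
            ("tool_scores", "tool_scores.tsv"),
        ]:
            paths[key] = out / name
            art[key].to_csv(paths[key], sep="\t", index=False)

        paths["interaction"] = out / "true_interactions.tsv"
        art["network"].write_tsv(paths["interaction"])

        truth = art["truth"]
        manifest = {
            "seed": self.config.seed,
            "config": asdict(self.config),
            "botu_modules": truth.botu_modules,
            "votu_modules": truth.votu_modules,
            "genome_to_botu": truth.genome_to_botu,
            "expected_retained": sorted(truth.expected_retained),
            "true_edges": sorted(map(list, truth.true_edges)),
            "votu_presence": truth.votu_presence.to_dict(),
            "true_pi": {f"{s}|{b}": v for (s, b), v in truth.true_pi.items()},
        }
        paths["manifest"] = out / "ground_truth.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return paths
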