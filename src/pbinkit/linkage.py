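"""Phage-host linkage: OTU clustering, CRISPR spacer matching, homology rules.

Genomes are clustered into species-level OTUs from pairwise ANI/alignment-
fraction tables (95% ANI for bacteria; 95% ANI + 85% AF, single linkage, for
viruses).  CRISPR spacers are filtered on array evidence level and on the
fraction of CRISPR-positive bMAGs in their bOTU, then matched full-length
against viral sequences allowing at most 2 mismatches on either strand.
Genome homology links require ANI > 90% and AF > 50% of the viral query;
AF > 80% additionally marks the phage as an integrated prophage.  Spacer and
homology evidence is finally aggregated into a vOTU x bOTU edge list with
per-edge evidence labels and a core/non-core host classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeRecord",
    "OTUAssignment",
    "SpacerRecord",
    "SpacerMatch",
    "HostLink",
    "cluster_genomes",
    "filter_spacers",
    "match_spacers",
    "link_by_homology",
    "build_host_assignments",
]

QUALITY_ORDER = ["not-determined", "low", "medium", "high", "complete"]


@dataclass
class GenomeRecord:
    genome_id: str
    kind: str  # bMAG | isolate | vMAG
    genus: str | None = None
    length: int = 0
    completeness: float | None = None
    contamination: float | None = None
    quality_tier: str | None = None
    has_crispr_locus: bool = False

    def bacterial_retained(self) -> bool:
        """Bacterial MAG quality gate: completeness >= 75%, contamination < 10%."""
        if self.kind == "isolate":
            return True
        if self.completeness is None or self.contamination is None:
            return False
        return self.completeness >= 75 and self.contamination < 10


@dataclass
class OTUAssignment:
    genome_to_otu: dict[str, str]
    representatives: dict[str, str]

    def members(self, otu_id: str) -> list[str]:
        return sorted(g for g, o in self.genome_to_otu.items() if o == otu_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (g, o, self.representatives[o])
                for g, o in sorted(self.genome_to_otu.items())
            ],
            columns=["genome_id", "otu_id", "representative"],
        )


@dataclass
class SpacerRecord:
    spacer_id: str
    sequence: str
    source_genome_id: str
    evidence_level: int = 4
    array_id: str = "array_1"

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise ValueError(f"spacer {self.spacer_id}: invalid sequence")


@dataclass
class SpacerMatch:
    spacer_id: str
    target_contig_id: str
    position: int  # 1-based start on the target, forward coordinates
    strand: str  # "+" or "-"
    mismatches: int


@dataclass
class HostLink:
    votu_id: str
    botu_id: str
    evidence: str  # crispr | homology | both
    prophage: bool = False
    host_class: str = "unassigned"


# ---------------------------------------------------------------------------
# OTU clustering from pairwise ANI/AF tables
# ---------------------------------------------------------------------------

def _symmetrize(similarities: pd.DataFrame) -> dict[tuple[str, str], tuple[float, float]]:
    """Take the max of the two directions for every unordered genome pair."""
    pairs: dict[tuple[str, str], tuple[float, float]] = {}
    for q, t, ani, af in similarities[["query_id", "target_id", "ani", "af"]].itertuples(index=False):
        if q == t:
            continue
        key = (q, t) if q < t else (t, q)
        prev = pairs.get(key, (-np.inf, -np.inf))
        pairs[key] = (max(prev[0], float(ani)), max(prev[1], float(af)))
    return pairs


def cluster_genomes(
    similarities: pd.DataFrame,
    genome_ids: Sequence[str],
    ani_threshold: float = 95.0,
    af_threshold: float = 0.0,
    mode: str = "single",
    quality: Mapping[str, str] | None = None,
    lengths: Mapping[str, int] | None = None,
    otu_prefix: str = "OTU",
) -> OTUAssignment:
    """Cluster genomes into OTUs at ANI/AF thresholds.

    ``single``: connected components of the graph whose edges satisfy
    ani >= ani_threshold AND af >= af_threshold.  ``average``: agglomerative
    merging on mean pairwise ANI/AF, stopping when no cluster pair passes
    both thresholds on average (absent pairs count as similarity 0).
    The representative of each OTU is the longest genome within the best
    quality tier present, ties broken by lexicographic id.
    """
    genome_ids = list(dict.fromkeys(genome_ids))
    known = set(genome_ids)
    bad = set(similarities["query_id"]).union(similarities["target_id"]) - known
    if bad:
        raise ValueError(f"similarity table references unknown genomes: {sorted(bad)[:5]}")
    pairs = _symmetrize(similarities)

    if mode == "single":
        parent = {g: g for g in genome_ids}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (a, b), (ani, af) in pairs.items():
            if ani >= ani_threshold and af >= af_threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        clusters: dict[str, list[str]] = {}
        for g in genome_ids:
            clusters.setdefault(find(g), []).append(g)
        groups = [sorted(v) for v in clusters.values()]
    elif mode == "average":
        groups = [[g] for g in genome_ids]
        while True:
            best = None
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    anis, afs = [], []
                    for a in groups[i]:
                        for b in groups[j]:
                            key = (a, b) if a < b else (b, a)
                            ani, af = pairs.get(key, (0.0, 0.0))
                            anis.append(ani)
                            afs.append(af)
                    m_ani, m_af = float(np.mean(anis)), float(np.mean(afs))
                    if m_ani >= ani_threshold and m_af >= af_threshold:
                        if best is None or m_ani > best[0]:
                            best = (m_ani, i, j)
            if best is None:
                break
            _, i, j = best
            groups[i] = sorted(groups[i] + groups[j])
            del groups[j]
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")

    lengths = lengths or {}
    quality = quality or {}

    def representative(members: list[str]) -> str:
        def tier(g: str) -> int:
            t = quality.get(g)
            return QUALITY_ORDER.index(t) if t in QUALITY_ORDER else 0

        best_tier = max(tier(g) for g in members)
        pool = [g for g in members if tier(g) == best_tier]
        max_len = max(lengths.get(g, 0) for g in pool)
        return sorted(g for g in pool if lengths.get(g, 0) == max_len)[0]

    groups.sort(key=lambda ms: ms[0])
    g2o, reps = {}, {}
    for idx, members in enumerate(groups, start=1):
        otu = f"{otu_prefix}_{idx:04d}"
        reps[otu] = representative(members)
        for g in members:
            g2o[g] = otu
    return OTUAssignment(g2o, reps)


# ---------------------------------------------------------------------------
# Spacer filtering
# ---------------------------------------------------------------------------

def filter_spacers(
    spacers: Iterable[SpacerRecord],
    assignment: OTUAssignment,
    genomes: Mapping[str, GenomeRecord],
    min_locus_fraction: float = 0.10,
) -> list[SpacerRecord]:
    """Retain evidence-level-4 spacers from credible CRISPR arrays.

    A spacer sourced from a bMAG is discarded when fewer than 10% of the
    bMAGs in its bOTU carry a CRISPR-Cas locus (a signature of the array
    having been mis-binned).  Isolate genomes are exempt from the fraction
    rule and excluded from both its numerator and denominator, since binning
    error cannot affect them.
    """
    frac_cache: dict[str, float] = {}

    def locus_fraction(otu: str) -> float:
        if otu not in frac_cache:
            bmags = [
                g
                for g in assignment.members(otu)
                if genomes[g].kind == "bMAG"
            ]
            if not bmags:
                frac_cache[otu] = 1.0
            else:
                frac_cache[otu] = sum(genomes[g].has_crispr_locus for g in bmags) / len(bmags)
        return frac_cache[otu]

    kept = []
    for sp in spacers:
        if sp.evidence_level != 4:
            continue
        src = genomes[sp.source_genome_id]
        if src.kind == "bMAG":
            otu = assignment.genome_to_otu[sp.source_genome_id]
            if locus_fraction(otu) < min_locus_fraction:
                continue
        kept.append(sp)
    return kept


# ---------------------------------------------------------------------------
# Spacer-to-protospacer matching
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    # N (or any non-ACGT symbol) encodes to a value that never equals a base,
    # so it always counts as a mismatch.
    lut = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _scan_one_strand(spacer: np.ndarray, target: np.ndarray, max_mismatches: int) -> np.ndarray:
    """Hamming distance of the spacer against every window of the target."""
    L, k = len(target), len(spacer)
    if k > L:
        return np.empty((0, 2), dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(target, k)
    # a position with code 4 (N) on either side never matches
    mism = (windows != spacer[None, :]).sum(axis=1)
    hits = np.flatnonzero(mism <= max_mismatches)
    return np.stack([hits, mism[hits]], axis=1) if hits.size else np.empty((0, 2), dtype=np.int64)


def match_spacers(
    spacers: Iterable[SpacerRecord],
    targets: Mapping[str, str],
    max_mismatches: int = 2,
) -> list[SpacerMatch]:
    """Full-length ungapped scan of each spacer against each viral sequence.

    Every window (on either strand) whose Hamming distance to the spacer is
    at most ``max_mismatches`` is reported; N counts as a mismatch.  Reported
    positions are 1-based starts in forward-strand coordinates of the target.
    """
    enc_targets = {cid: _encode(seq.upper()) for cid, seq in targets.items()}
    out: list[SpacerMatch] = []
    for sp in spacers:
        fwd = _encode(sp.sequence)
        rev = _encode(reverse_complement(sp.sequence))
        k = len(fwd)
        for cid, tgt in enc_targets.items():
            for strand, probe in (("+", fwd), ("-", rev)):
                for pos0, mism in _scan_one_strand(probe, tgt, max_mismatches):
                    out.append(
                        SpacerMatch(
                            spacer_id=sp.spacer_id,
                            target_contig_id=cid,
                            position=int(pos0) + 1,
                            strand=strand,
                            mismatches=int(mism),
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# Genome homology links
# ---------------------------------------------------------------------------

def link_by_homology(
    similarities: pd.DataFrame,
    min_ani: float = 90.0,
    min_af: float = 50.0,
    prophage_af: float = 80.0,
) -> pd.DataFrame:
    """Viral-query vs bacterial-genome homology links.

    A link requires ANI > min_ani and AF > min_af (strict, AF measured on
    the viral query); AF > prophage_af additionally flags the phage as an
    integrated prophage.  Returns columns: vmag_id, genome_id, ani, af,
    prophage.
    """
    df = similarities.rename(columns={"query_id": "vmag_id", "target_id": "genome_id"})
    keep = (df["ani"] > min_ani) & (df["af"] > min_af)
    out = df.loc[keep, ["vmag_id", "genome_id", "ani", "af"]].copy()
    out["prophage"] = (out["ani"] > min_ani) & (out["af"] > prophage_af)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Host assignment
# ---------------------------------------------------------------------------

def build_host_assignments(
    spacer_matches: Iterable[SpacerMatch],
    spacers: Mapping[str, SpacerRecord],
    homology_links: pd.DataFrame,
    viral_assignment: OTUAssignment | Mapping[str, str],
    bacterial_assignment: OTUAssignment | Mapping[str, str],
    otu_genus: Mapping[str, str],
    core_genera: Sequence[str],
) -> tuple[list[HostLink], dict[str, str]]:
    """Aggregate spacer and homology evidence into vOTU x bOTU links.

    A vOTU-bOTU edge exists when any member vMAG is targeted by a spacer from
    any member genome of the bOTU, or shows a qualifying homology link to one.
    Each vOTU is classed "core" if any linked bOTU belongs to a core genus,
    "non-core" if it is linked only outside the core list, and "unassigned"
    with no links; only core vOTUs enter the downstream interaction network.
    """
    v2o = viral_assignment.genome_to_otu if isinstance(viral_assignment, OTUAssignment) else dict(viral_assignment)
    b2o = bacterial_assignment.genome_to_otu if isinstance(bacterial_assignment, OTUAssignment) else dict(bacterial_assignment)

    crispr_edges: set[tuple[str, str]] = set()
    for m in spacer_matches:
        sp = spacers[m.spacer_id]
        votu = v2o.get(m.target_contig_id)
        botu = b2o.get(sp.source_genome_id)
        if votu is not None and botu is not None:
            crispr_edges.add((votu, botu))

    homology_edges: set[tuple[str, str]] = set()
    prophage_edges: set[tuple[str, str]] = set()
    for row in homology_links.itertuples(index=False):
        votu = v2o.get(row.vmag_id)
        botu = b2o.get(row.genome_id)
        if votu is None or botu is None:
            continue
        homology_edges.add((votu, botu))
        if row.prophage:
            prophage_edges.add((votu, botu))

    links: list[HostLink] = []
    all_votus = sorted(set(v2o.values()))
    host_class: dict[str, str] = {}
    for votu in all_votus:
        edges = {e for e in crispr_edges | homology_edges if e[0] == votu}
        if not edges:
            host_class[votu] = "unassigned"
            continue
        genera = {otu_genus.get(botu) for _, botu in edges}
        host_class[votu] = "core" if genera & set(core_genera) else "non-core"
        for votu_id, botu in sorted(edges):
            in_c = (votu_id, botu) in crispr_edges
            in_h = (votu_id, botu) in homology_edges
            links.append(
                HostLink(
                    votu_id=votu_id,
                    botu_id=botu,
                    evidence="both" if (in_c and in_h) else ("crispr" if in_c else "homology"),
                    prophage=(votu_id, botu) in prophage_edges,
                    host_class=host_class[votu],
                )
            )
    return links, host_class


def links_to_network(links: Iterable[HostLink], core_only: bool = True):
    """Build the binary interaction network from host links (core hosts only)."""
    from .pbin import BipartiteNetwork

    kept = [l for l in links if (not core_only or l.host_class == "core")]
    edges = [(l.botu_id, l.votu_id) for l in kept]
    evidence = {(l.botu_id, l.votu_id): l.evidence for l in kept}
    return BipartiteNetwork.from_edges(edges, evidence=evidence)
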