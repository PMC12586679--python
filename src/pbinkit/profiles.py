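"""Presence/absence calling and strain-resolved diversity from read profiles.

Presence of a bacterial OTU in a sample requires median coverage > 5x and
breadth > 0.5; a viral OTU requires breadth >= 0.7.  Per-site nucleotide
diversity is pi = 1 - sum of squared base frequencies, computed at positions
covered by at least 5 reads and averaged over the genome per sample.
Pairwise popANI compares the same genome across two samples, counting a
position identical when the samples share at least one detected allele
(detection: >= 2 reads and >= 5% frequency).  Sample-by-sample dissimilarity
is Jaccard at the genus/species/vOTU level and, at the strain level, the
fraction of bOTUs not shared at a popANI threshold (default 99.9%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "call_presence",
    "site_pi",
    "genome_pi",
    "popani",
    "popani_all_pairs",
    "strain_jaccard",
    "jaccard",
    "threshold_sweep",
]

BASES = ["A", "C", "G", "T"]
COUNT_COLS = ["n_A", "n_C", "n_G", "n_T"]


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix with provenance.

    ``data`` is a square pandas DataFrame (zero diagonal, values in [0, 1],
    NaN marking undefined pairs); ``metric`` names the dissimilarity and
    ``params`` records its parameters (e.g. the popANI threshold).
    """

    data: pd.DataFrame
    metric: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = self.data
        if list(d.index) != list(d.columns):
            raise ValueError("distance matrix must have identical row and column labels")
        arr = d.to_numpy(dtype=float)
        if not np.allclose(np.nan_to_num(arr), np.nan_to_num(arr.T)):
            raise ValueError("distance matrix must be symmetric")
        np.fill_diagonal(arr, 0.0)
        self.data = pd.DataFrame(arr, index=d.index, columns=d.columns)

    @property
    def labels(self) -> list[str]:
        return list(self.data.index)

    def condensed(self) -> np.ndarray:
        arr = self.data.to_numpy()
        iu = np.triu_indices_from(arr, k=1)
        return arr[iu]

    def write_tsv(self, path) -> None:
        """Square TSV plus a '<path>.json' sidecar naming metric and parameters."""
        import json
        from pathlib import Path

        self.data.to_csv(path, sep="\t", index_label="sample")
        Path(f"{path}.json").write_text(
            json.dumps({"metric": self.metric, "params": self.params}, sort_keys=True)
        )

    def to_skbio(self):
        from skbio import DistanceMatrix as SkbioDM

        return SkbioDM(self.data.to_numpy(), ids=self.labels)


# ---------------------------------------------------------------------------
# Presence calling
# ---------------------------------------------------------------------------

def call_presence(
    coverage: pd.DataFrame,
    feature_kind: str,
    botu_genus: Mapping[str, str] | None = None,
    min_median_cov: float = 5.0,
    min_breadth_botu: float = 0.5,
    min_breadth_votu: float = 0.7,
) -> pd.DataFrame:
    """Binary presence matrix (samples x features) from coverage summaries.

    bOTU present iff median coverage > 5x AND breadth > 0.5 (both strict);
    vOTU present iff breadth >= 0.7; genus presence is the union of the
    presence of its bOTUs (requires ``botu_genus``).
    """
    required = {"sample_id", "feature_id", "median_coverage", "breadth"}
    if not required <= set(coverage.columns):
        raise ValueError(f"coverage table must have columns {sorted(required)}")
    cov = coverage.copy()
    if feature_kind in ("botu", "genus"):
        cov["present"] = (cov["median_coverage"] > min_median_cov) & (
            cov["breadth"] > min_breadth_botu
        )
    elif feature_kind == "votu":
        cov["present"] = cov["breadth"] >= min_breadth_votu
    else:
        raise ValueError(f"unknown feature kind {feature_kind!r}")
    mat = (
        cov.pivot_table(index="sample_id", columns="feature_id", values="present", aggfunc="any")
        .fillna(False)
        .astype(int)
    )
    mat.index.name = "sample_id"
    if feature_kind == "genus":
        if botu_genus is None:
            raise ValueError("genus presence requires a bOTU -> genus map")
        genus = pd.Series({b: g for b, g in botu_genus.items() if b in mat.columns})
        mat = mat.T.groupby(genus).any().T.astype(int)
    return mat


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def site_pi(n_a, n_c, n_g, n_t) -> float | np.ndarray:
    """Per-site nucleotide diversity: 1 - (f_A^2 + f_C^2 + f_G^2 + f_T^2).

    Ranges from 0 (monomorphic) to 0.75 (all four bases at equal frequency).
    Accepts scalars or aligned arrays.
    """
    counts = np.stack(
        [np.asarray(x, dtype=float) for x in (n_a, n_c, n_g, n_t)], axis=-1
    )
    total = counts.sum(axis=-1)
    if np.any(total == 0):
        raise ValueError("site_pi is undefined at zero coverage")
    freqs = counts / total[..., None]
    pi = 1.0 - (freqs**2).sum(axis=-1)
    return float(pi) if pi.ndim == 0 else pi


def genome_pi(allele_table: pd.DataFrame, min_coverage: int = 5) -> float:
    """Genome-average nucleotide diversity for one sample x bOTU.

    Sites covered by fewer than ``min_coverage`` reads are excluded from
    both numerator and denominator; with no qualifying site the result is
    NaN (missing), which is distinct from 0 (monomorphic).
    """
    counts = allele_table[COUNT_COLS].to_numpy(dtype=float)
    cov = counts.sum(axis=1)
    ok = cov >= min_coverage
    if not ok.any():
        return float("nan")
    freqs = counts[ok] / cov[ok, None]
    return float((1.0 - (freqs**2).sum(axis=1)).mean())


# ---------------------------------------------------------------------------
# popANI
# ---------------------------------------------------------------------------

def _detected_alleles(counts: np.ndarray, min_reads: int = 2, min_freq: float = 0.05) -> np.ndarray:
    """Boolean (positions x 4) matrix of detected alleles."""
    cov = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(cov > 0, counts / cov, 0.0)
    return (counts >= min_reads) & (freq >= min_freq)


def popani(
    table_x: pd.DataFrame,
    table_y: pd.DataFrame,
    min_cov: int = 5,
    min_reads: int = 2,
    min_freq: float = 0.05,
) -> tuple[float, int]:
    """Population ANI of one bOTU between two samples.

    Positions covered by >= min_cov reads in both samples are compared; a
    position is identical when the two samples share at least one detected
    allele (>= min_reads reads and >= min_freq frequency).  Returns
    (popANI as a percentage, number of positions compared); popANI is NaN
    when no position qualifies.
    """
    x = table_x.set_index("position")[COUNT_COLS]
    y = table_y.set_index("position")[COUNT_COLS]
    common = x.index.intersection(y.index)
    cx = x.loc[common].to_numpy(dtype=float)
    cy = y.loc[common].to_numpy(dtype=float)
    ok = (cx.sum(axis=1) >= min_cov) & (cy.sum(axis=1) >= min_cov)
    n_compared = int(ok.sum())
    if n_compared == 0:
        return float("nan"), 0
    ax = _detected_alleles(cx[ok], min_reads, min_freq)
    ay = _detected_alleles(cy[ok], min_reads, min_freq)
    identical = (ax & ay).any(axis=1)
    return 100.0 * float(identical.sum()) / n_compared, n_compared


def popani_all_pairs(
    allele_tables: pd.DataFrame,
    min_cov: int = 5,
    min_reads: int = 2,
    min_freq: float = 0.05,
) -> pd.DataFrame:
    """popANI for every (bOTU, sample pair) in a long allele table.

    ``allele_tables`` has columns sample_id, botu_id, position, n_A..n_T.
    Returns columns: botu_id, sample_x, sample_y, popani, n_compared.
    Implemented with a vectorized per-bOTU all-pairs comparison.
    """
    rows = []
    for botu, sub in allele_tables.groupby("botu_id"):
        piv = {
            s: t.set_index("position")[COUNT_COLS]
            for s, t in sub.groupby("sample_id")
        }
        samples = sorted(piv)
        positions = sorted(set().union(*[set(p.index) for p in piv.values()]))
        pos_index = pd.Index(positions)
        counts = np.zeros((len(samples), len(positions), 4))
        for si, s in enumerate(samples):
            t = piv[s].reindex(pos_index, fill_value=0)
            counts[si] = t.to_numpy(dtype=float)
        cov = counts.sum(axis=2)
        det = (counts >= min_reads) & (
            counts >= min_freq * np.maximum(cov, 1e-12)[:, :, None]
        )
        covered = cov >= min_cov
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                both = covered[i] & covered[j]
                n_cmp = int(both.sum())
                if n_cmp == 0:
                    ani = float("nan")
                else:
                    ident = (det[i][both] & det[j][both]).any(axis=1)
                    ani = 100.0 * float(ident.sum()) / n_cmp
                rows.append((botu, samples[i], samples[j], ani, n_cmp))
    return pd.DataFrame(
        rows, columns=["botu_id", "sample_x", "sample_y", "popani", "n_compared"]
    )


# ---------------------------------------------------------------------------
# Dissimilarity matrices
# ---------------------------------------------------------------------------

def jaccard(presence: pd.DataFrame, metric_name: str = "jaccard") -> DistanceMatrix:
    """Pairwise Jaccard dissimilarity (1 - |intersection| / |union|).

    ``presence`` is a binary samples x features matrix.  Pairs whose union
    of features is empty are undefined (NaN).
    """
    X = presence.to_numpy(dtype=bool)
    inter = (X[:, None, :] & X[None, :, :]).sum(axis=2).astype(float)
    union = (X[:, None, :] | X[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, 1.0 - inter / union, np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        pd.DataFrame(d, index=presence.index, columns=presence.index),
        metric=metric_name,
    )


def strain_jaccard(
    presence_botu: pd.DataFrame,
    popani_table: pd.DataFrame,
    threshold: float = 99.9,
) -> DistanceMatrix:
    """Strain-level dissimilarity: fraction of bOTUs not shared at the strain level.

    For a sample pair, the denominator is the union of bOTUs present in
    either sample; a bOTU counts as shared only when present in both samples
    AND its popANI between the two samples meets the threshold.  Undefined
    (NaN) for pairs whose union is empty.
    """
    samples = list(presence_botu.index)
    lookup: dict[tuple[str, str, str], float] = {}
    for r in popani_table.itertuples(index=False):
        lookup[(r.botu_id, r.sample_x, r.sample_y)] = r.popani
        lookup[(r.botu_id, r.sample_y, r.sample_x)] = r.popani
    P = presence_botu.astype(bool)
    d = np.zeros((len(samples), len(samples)))
    for i, x in enumerate(samples):
        for j in range(i + 1, len(samples)):
            y = samples[j]
            px, py = P.loc[x], P.loc[y]
            union = px | py
            n_union = int(union.sum())
            if n_union == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            shared = 0
            for botu in P.columns[px & py]:
                ani = lookup.get((botu, x, y), float("nan"))
                if not np.isnan(ani) and ani >= threshold:
                    shared += 1
            d[i, j] = d[j, i] = 1.0 - shared / n_union
    return DistanceMatrix(
        pd.DataFrame(d, index=samples, columns=samples),
        metric="strain_jaccard",
        params={"popani_threshold": threshold},
    )


def threshold_sweep(
    presence_botu: pd.DataFrame,
    popani_table: pd.DataFrame,
    thresholds: Sequence[float] = (96.0, 97.0, 98.0, 99.0, 99.5, 99.9, 99.99),
) -> dict[float, DistanceMatrix]:
    """Strain-level dissimilarity across a range of popANI thresholds.

    Distances are monotone non-decreasing in the threshold by construction
    (a higher bar for strain sharedness can only shrink the shared set).
    """
    return {t: strain_jaccard(presence_botu, popani_table, threshold=t) for t in thresholds}
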