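"""Consensus confidence scoring and filtering of candidate viral contigs.

Three virus-detection tools are summarized per contig into an integer
confidence score 0..3 each (0 = not called by the tool), the three scores
are averaged and rounded to the nearest integer (ties round up), and a
contig is retained when its final score is at least 1.  Retained contigs
are then filtered on length (>= 10 kb), kmer frequency (<= 1.1, higher
values indicating contamination), and draft quality (at least "low"), and
labeled temperate when any lysogeny signal (lysogenic call or provirus
call) is present, putative-lytic otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ToolScoreRecord",
    "ContigMeta",
    "bin_tool_score",
    "combined_score",
    "filter_vmags",
    "screen_table",
]

QUALITY_TIERS = ["not-determined", "low", "medium", "high", "complete"]

MISSING = None


@dataclass
class ToolScoreRecord:
    """Raw per-contig outputs of the three virus detectors.

    detector_a: continuous score in [0, 1] (or None when the tool made no
    call); detector_b: draft-quality category low/medium/high (or None);
    detector_c: non-negative continuous score (or None).
    """

    contig_id: str
    detector_a: float | None = None
    detector_b: str | None = None
    detector_c: float | None = None


@dataclass
class ContigMeta:
    contig_id: str
    length: int
    kmer_freq: float
    quality_tier: str
    lysogenic: bool = False
    provirus: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.contig_id}: length must be positive")
        if self.kmer_freq < 1:
            raise ValueError(f"{self.contig_id}: kmer frequency must be >= 1")
        if self.quality_tier not in QUALITY_TIERS:
            raise ValueError(f"{self.contig_id}: unknown quality tier {self.quality_tier!r}")


def bin_tool_score(detector: str, raw) -> int:
    """Bin one detector's raw output into an integer confidence 0..3.

    detector_a: < 0.5 -> 1, [0.5, 0.8] -> 2, > 0.8 -> 3.
    detector_b: low -> 1, medium -> 2, high -> 3.
    detector_c: < 5 -> 1, [5, 10] -> 2, > 10 -> 3.
    A missing call (None/NaN) scores 0 for that tool; "between x and y"
    bands are read as closed intervals.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return 0
    if detector == "detector_a":
        raw = float(raw)
        if not 0.0 <= raw <= 1.0:
            raise ValueError(f"detector_a score {raw} outside [0, 1]")
        if raw < 0.5:
            return 1
        if raw <= 0.8:
            return 2
        return 3
    if detector == "detector_b":
        tiers = {"low": 1, "medium": 2, "high": 3}
        if raw not in tiers:
            raise ValueError(f"detector_b category {raw!r} not in {sorted(tiers)}")
        return tiers[raw]
    if detector == "detector_c":
        raw = float(raw)
        if raw < 0:
            raise ValueError(f"detector_c score {raw} must be non-negative")
        if raw < 5:
            return 1
        if raw <= 10:
            return 2
        return 3
    raise ValueError(f"unknown detector {detector!r}")


def combined_score(s1: int, s2: int, s3: int) -> tuple[int, bool]:
    """Average the three binned scores, round to nearest integer (half up).

    Returns (final_score, retained); a contig is retained iff the final
    score is at least 1.
    """
    for s in (s1, s2, s3):
        if s not in (0, 1, 2, 3):
            raise ValueError(f"binned score {s} outside 0..3")
    mean = (s1 + s2 + s3) / 3.0
    final = math.floor(mean + 0.5)  # ties (x.5) round up
    return final, final >= 1


def filter_vmags(
    metas: list[ContigMeta],
    scores: dict[str, tuple[int, bool]],
    min_length: int = 10_000,
    max_kmer_freq: float = 1.1,
) -> pd.DataFrame:
    """Apply size/contamination/quality filters and assign a lifestyle label.

    A contig survives iff it was score-retained, length >= min_length,
    kmer_freq <= max_kmer_freq (both boundaries inclusive: the removal rules
    are strict "< 10 kb" and "> 1.1"), and quality tier at least "low".
    Survivors are labeled "temperate" when any lysogeny flag is set and
    "putative-lytic" otherwise.
    """
    meta_by_id = {m.contig_id: m for m in metas}
    for cid in scores:
        if scores[cid][1] and cid not in meta_by_id:
            raise ValueError(f"contig {cid} has a retained score but no metadata")
    rows = []
    for m in metas:
        final, score_ok = scores.get(m.contig_id, (0, False))
        retained = (
            score_ok
            and m.length >= min_length
            and m.kmer_freq <= max_kmer_freq
            and QUALITY_TIERS.index(m.quality_tier) >= QUALITY_TIERS.index("low")
        )
        lifestyle = "temperate" if (m.lysogenic or m.provirus) else "putative-lytic"
        rows.append(
            {
                "contig_id": m.contig_id,
                "final_score": final,
                "length": m.length,
                "kmer_freq": m.kmer_freq,
                "quality_tier": m.quality_tier,
                "retained": retained,
                "lifestyle": lifestyle if retained else None,
            }
        )
    return pd.DataFrame(rows)


def screen_table(table: pd.DataFrame) -> pd.DataFrame:
    """Run the full screen on a raw tool-score table.

    Expects columns: contig_id, detector_a, detector_b, detector_c, length,
    kmer_freq, quality_tier, lysogenic, provirus.  Returns the table with
    binned scores, the final consensus score, the retain decision and the
    lifestyle label appended.
    """
    out = table.copy()
    binned = {}
    for det in ("detector_a", "detector_b", "detector_c"):
        out[f"{det}_bin"] = [
            bin_tool_score(det, v if not pd.isna(v) else None) for v in table[det]
        ]
    scores = {}
    finals = []
    for _, row in out.iterrows():
        final, keep = combined_score(
            row["detector_a_bin"], row["detector_b_bin"], row["detector_c_bin"]
        )
        scores[row["contig_id"]] = (final, keep)
        finals.append(final)
    out["final_score"] = finals
    metas = [
        ContigMeta(
            contig_id=row["contig_id"],
            length=int(row["length"]),
            kmer_freq=float(row["kmer_freq"]),
            quality_tier=str(row["quality_tier"]),
            lysogenic=bool(row["lysogenic"]),
            provirus=bool(row["provirus"]),
        )
        for _, row in table.iterrows()
    ]
    filt = filter_vmags(metas, scores).set_index("contig_id")
    out["retained"] = out["contig_id"].map(filt["retained"]).astype(bool)
    out["lifestyle"] = out["contig_id"].map(filt["lifestyle"])
    return out
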