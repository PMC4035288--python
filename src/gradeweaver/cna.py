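"""Gene-level copy-number alteration calls from segmented data.

Segments are classified as gain / loss / neutral by thresholding the
segment value, either on the absolute copy-number scale (diploid = 2;
gain at CN >= 2.5, loss at CN <= 1.5 by default) or on the log2-ratio
scale (gain at >= +0.3, loss at <= -0.3).  A gene is gained or lost in
a sample iff its interval overlaps (>= 1 bp, half-open coordinates)
any segment of that class; a gene overlapping both a gain and a loss
segment in the same sample is marked ``conflict`` and excluded from
frequency counts.  Per-grade alteration frequencies feed the top-K
selection (default K = 6000) ranked by the dominant alteration
frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneModel, SampleTable, SegmentRecord

__all__ = [
    "CnaThresholds",
    "classify_segment",
    "gene_alteration_status",
    "alteration_frequencies",
    "select_top_altered",
]

log = logging.getLogger(__name__)

GAIN, LOSS, NEUTRAL, CONFLICT = "gain", "loss", "neutral", "conflict"


@dataclass(frozen=True)
class CnaThresholds:
    mode: str = "absolute"          # "absolute" (CN units) or "log2ratio"
    gain_thr: float | None = None
    loss_thr: float | None = None

    def resolved(self) -> tuple[float, float]:
        if self.mode == "absolute":
            gain = 2.5 if self.gain_thr is None else self.gain_thr
            loss = 1.5 if self.loss_thr is None else self.loss_thr
            ref = 2.0
        elif self.mode == "log2ratio":
            gain = 0.3 if self.gain_thr is None else self.gain_thr
            loss = -0.3 if self.loss_thr is None else self.loss_thr
            ref = 0.0
        else:
            raise ValueError(f"unknown copy-number mode {self.mode!r}")
        if not (loss < ref < gain):
            raise ValueError(
                f"thresholds must satisfy loss_thr < {ref} < gain_thr, got {loss}, {gain}"
            )
        return gain, loss


def classify_segment(
    copy_number: float,
    mode: str = "absolute",
    gain_thr: float | None = None,
    loss_thr: float | None = None,
) -> str:
    """Classify a single segment value as gain / loss / neutral."""
    gain, loss = CnaThresholds(mode, gain_thr, loss_thr).resolved()
    if copy_number >= gain:
        return GAIN
    if copy_number <= loss:
        return LOSS
    return NEUTRAL


def gene_alteration_status(
    genes: Sequence[GeneModel],
    segments: Iterable[SegmentRecord],
    thresholds: CnaThresholds = CnaThresholds(),
) -> pd.DataFrame:
    """Per sample x gene status table (gain/loss/neutral/conflict).

    Index: sample ids; columns: gene symbols.  Genes with no covering
    altered segment are neutral.  Overlap is any shared base under
    half-open coordinates; strand is ignored.
    """
    gain, loss = thresholds.resolved()
    # interval trees per (sample, chrom), only for non-neutral segments
    trees: dict[tuple[str, str], IntervalTree] = {}
    sample_ids: list[str] = []
    seen = set()
    for seg in segments:
        if seg.sample_id not in seen:
            seen.add(seg.sample_id)
            sample_ids.append(seg.sample_id)
        if seg.copy_number >= gain:
            cls = GAIN
        elif seg.copy_number <= loss:
            cls = LOSS
        else:
            continue
        trees.setdefault((seg.sample_id, seg.chrom), IntervalTree()).addi(
            seg.start, seg.end, cls
        )

    gene_names = [g.gene for g in genes]
    status = pd.DataFrame(NEUTRAL, index=sample_ids, columns=gene_names, dtype=object)
    n_conflict = 0
    for g in genes:
        for sid in sample_ids:
            tree = trees.get((sid, g.chrom))
            if tree is None:
                continue
            hits = {iv.data for iv in tree.overlap(g.start, g.end)}
            if not hits:
                continue
            if len(hits) == 2:
                status.at[sid, g.gene] = CONFLICT
                n_conflict += 1
            else:
                status.at[sid, g.gene] = next(iter(hits))
    if n_conflict:
        log.info("excluded %d conflicting gene/sample copy-number calls", n_conflict)
    return status


def alteration_frequencies(
    status: pd.DataFrame, sample_table: SampleTable, grade: str
) -> pd.DataFrame:
    """Per-gene gain/loss counts and frequencies over one grade's samples.

    Conflict calls contribute to neither count.  Samples of the grade
    absent from the status table count as neutral (no segments).
    """
    grade_ids = sample_table.ids_of_grade(grade)
    if not grade_ids:
        raise ValueError(f"no samples of grade {grade!r}")
    present = [s for s in grade_ids if s in status.index]
    n = len(grade_ids)
    if present:
        sub = status.loc[present]
        gain_count = (sub == GAIN).sum(axis=0)
        loss_count = (sub == LOSS).sum(axis=0)
    else:
        gain_count = pd.Series(0, index=status.columns)
        loss_count = pd.Series(0, index=status.columns)
    out = pd.DataFrame(
        {
            "gene": status.columns,
            "gain_count": gain_count.to_numpy(),
            "loss_count": loss_count.to_numpy(),
            "n_samples": n,
        }
    )
    out["gain_freq"] = out["gain_count"] / n
    out["loss_freq"] = out["loss_count"] / n
    return out


def select_top_altered(freq: pd.DataFrame, K: int = 6000) -> tuple[set, set]:
    """Top-K altered genes split into (amplified, deleted) sets.

    Genes are ranked by max(gain_freq, loss_freq) descending, ties
    broken by lexical gene id; a selected gene is amplified when its
    gain frequency is at least its loss frequency, deleted otherwise.
    Genes with no alteration are never selected; a shortfall against K
    is logged, not an error.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    f = freq.copy()
    f["dominant"] = f[["gain_freq", "loss_freq"]].max(axis=1)
    altered = f[f["dominant"] > 0].sort_values(
        ["dominant", "gene"], ascending=[False, True], kind="stable"
    )
    if len(altered) < K:
        log.info("only %d altered genes available for top-%d selection", len(altered), K)
    chosen = altered.head(K)
    amplified = set(chosen.loc[chosen["gain_freq"] >= chosen["loss_freq"], "gene"])
    deleted = set(chosen.loc[chosen["gain_freq"] < chosen["loss_freq"], "gene"])
    return amplified, deleted
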