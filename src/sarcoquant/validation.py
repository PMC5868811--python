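"""Scoring a segmentation against synthetic ground truth.

A detected fibre matches a true fibre when its centroid falls inside the true
polygon (evaluated on the ground-truth interior raster).  Recall is computed
over *tissue-interior* true fibres — those not flagged ``on_tissue_edge`` —
because a fibre at the tissue margin whose rim gap faces the surround has no
bounding neighbour rim and genuinely reads as damaged; precision counts every
accepted object that fails to match any true fibre as a false positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import SegmentationResult
from .synthetic import GroundTruth


@dataclass
class DetectionScores:
    recall: float
    precision: float
    n_true_interior: int
    n_accepted: int
    n_matched: int
    matches: dict[int, int]  # accepted label -> true fibre id


def detection_scores(
    result: SegmentationResult,
    truth: GroundTruth,
    gap_exclusion_fraction: float = 0.20,
) -> DetectionScores:
    """Recall/precision of accepted fibres versus ground-truth fibres.

    The recall denominator excludes fibres whose true gap fraction reaches
    ``gap_exclusion_fraction``: the protocol *requires* rejecting those, so
    counting them as detection misses would penalise correct behaviour.
    """
    labels = result.labels
    interior = truth.interior_labels
    h, w = interior.shape
    interior_true = {
        f.fibre_id
        for f in truth.fibres
        if not f.on_tissue_edge and f.gap_fraction < gap_exclusion_fraction
    }
    accepted_ids = [int(i) for i in np.unique(labels) if i > 0]
    matches: dict[int, int] = {}
    hit_true: set[int] = set()
    if accepted_ids:
        centroids = ndimage.center_of_mass(
            np.ones_like(labels), labels=labels, index=accepted_ids
        )
        for lab, (cr, cc) in zip(accepted_ids, centroids):
            r = int(np.clip(round(cr), 0, h - 1))
            c = int(np.clip(round(cc), 0, w - 1))
            tid = int(interior[r, c])
            if tid > 0 and tid not in hit_true:
                matches[lab] = tid
                hit_true.add(tid)
    n_true = len(interior_true)
    n_acc = len(accepted_ids)
    n_interior_hit = len(hit_true & interior_true)
    return DetectionScores(
        recall=n_interior_hit / n_true if n_true else float("nan"),
        precision=len(matches) / n_acc if n_acc else float("nan"),
        n_true_interior=n_true,
        n_accepted=n_acc,
        n_matched=n_interior_hit,
        matches=matches,
    )


def candidate_truth_table(result: SegmentationResult, truth: GroundTruth) -> pd.DataFrame:
    """Per-candidate table joining measured quantities with ground truth.

    A candidate is assigned to the true fibre covering the majority (>50%) of
    its pixels; candidates mostly outside every fibre polygon (interstitial
    slivers, distractor debris) carry true id 0.  Columns: candidate_id,
    true_id, rejection_reason, rim_completeness, true_gap_fraction,
    on_tissue_edge, overlap_fraction.
    """
    interior = truth.interior_labels
    by_id = {f.fibre_id: f for f in truth.fibres}
    rows = []
    for cand in result.label_map.candidates:
        covered = interior[cand.bbox][cand.mask]
        tid, frac = 0, 0.0
        if covered.size:
            counts = np.bincount(covered.ravel())
            if len(counts) > 1:
                best = int(np.argmax(counts[1:])) + 1
                frac = counts[best] / covered.size
                if frac > 0.5:
                    tid = best
        f = by_id.get(tid)
        rows.append(
            {
                "candidate_id": cand.id,
                "true_id": tid,
                "rejection_reason": cand.rejection_reason,
                "rim_completeness": cand.rim_completeness,
                "true_gap_fraction": f.gap_fraction if f else np.nan,
                "on_tissue_edge": f.on_tissue_edge if f else True,
                "overlap_fraction": frac,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "candidate_id",
            "true_id",
            "rejection_reason",
            "rim_completeness",
            "true_gap_fraction",
            "on_tissue_edge",
            "overlap_fraction",
        ],
    )


def recovery_correlation(
    table: pd.DataFrame, result: SegmentationResult, truth: GroundTruth
) -> tuple[float, int]:
    """Pearson r between measured ring means and true rim intensities.

    ``table`` is the per-fibre table over ``result``'s accepted labels.
    Returns (r, number of matched fibres).
    """
    scores = detection_scores(result, truth)
    meas, true = [], []
    by_id = {f.fibre_id: f for f in truth.fibres}
    table_by_fid = dict(zip(table["fibre_id"].astype(int), table["sarc_mean_target"]))
    for lab, tid in scores.matches.items():
        if lab in table_by_fid:
            meas.append(table_by_fid[lab])
            true.append(by_id[tid].rim_intensity_target)
    if len(meas) < 3:
        return float("nan"), len(meas)
    r = float(np.corrcoef(meas, true)[0, 1])
    return r, len(meas)
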