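"""Fibre segmentation: tissue detection, candidates, the 20% gap rule, filters."""

import copy

import numpy as np
import pytest

from sarcoquant import (
    SectionImage,
    SegmentationParams,
    apply_gap_rule,
    detect_tissue,
    segment_section,
)
from sarcoquant.segmentation import FibreCandidate, _split_component
from sarcoquant.validation import candidate_truth_table, detection_scores


def _dummy_candidate(cid, completeness):
    mask = np.ones((5, 5), dtype=bool)
    return FibreCandidate(
        id=cid,
        bbox=(slice(0, 5), slice(0, 5)),
        mask=mask,
        boundary=np.zeros((12, 2)),
        area_px=25,
        area_um2=1000.0,
        solidity=1.0,
        centroid=(2.0, 2.0),
        touches_border=False,
        rim_completeness=completeness,
    )


class TestTissue:
    def test_blank_noise_image_empty_mask(self, rng):
        img = np.clip(rng.normal(600, 300, (256, 256)), 0, None).astype(np.uint16)
        sec = SectionImage({"membrane": img, "target": img}, pixel_size_um=0.5)
        with pytest.warns(UserWarning, match="empty tissue"):
            mask = detect_tissue(sec)
        assert not mask.any()

    def test_constant_image_empty_mask(self):
        img = np.full((64, 64), 500, np.uint16)
        sec = SectionImage({"membrane": img, "target": img}, pixel_size_um=0.5)
        with pytest.warns(UserWarning, match="empty tissue"):
            assert not detect_tissue(sec).any()

    def test_tissue_covers_true_fibres(self, clean_segmented):
        result, _, truth = clean_segmented
        fp = truth.interior_labels > 0
        coverage = (result.tissue_mask & fp).sum() / fp.sum()
        assert coverage >= 0.99

    def test_tissue_mask_bounded(self, clean_segmented):
        result, section, _ = clean_segmented
        assert result.tissue_mask.sum() <= section.shape[0] * section.shape[1]


class TestGapRule:
    def test_threshold_cases(self):
        """90% complete retained; 75% rejected; exactly 80% rejected."""
        cands = [
            _dummy_candidate(1, 0.90),
            _dummy_candidate(2, 0.75),
            _dummy_candidate(3, 0.80),
        ]
        apply_gap_rule(cands, SegmentationParams())
        assert cands[0].rejection_reason == "none"
        assert cands[1].rejection_reason == "gap_gt_threshold"
        assert cands[2].rejection_reason == "gap_gt_threshold"  # boundary case

    def test_does_not_override_prior_reason(self):
        cand = _dummy_candidate(1, 0.10)
        cand.rejection_reason = "too_small"
        apply_gap_rule([cand], SegmentationParams())
        assert cand.rejection_reason == "too_small"

    def test_completeness_in_unit_interval(self, gap_segmented):
        result, _, _ = gap_segmented
        vals = [
            c.rim_completeness
            for c in result.label_map.candidates
            if c.rim_completeness is not None
        ]
        assert vals and all(0.0 <= v <= 1.0 for v in vals)

    def test_complete_rims_read_complete(self, clean_segmented):
        result, _, _ = clean_segmented
        accepted = [c for c in result.label_map.candidates if c.accepted]
        assert accepted
        assert all(c.rim_completeness >= 0.99 for c in accepted)

    def test_measured_gap_tracks_true_gap(self, gap_segmented):
        """Measured missing fraction approximates the rendered gap fraction."""
        result, _, truth = gap_segmented
        table = candidate_truth_table(result, truth)
        interior = {f.fibre_id for f in truth.fibres if not f.on_tissue_edge}
        rows = table[
            table.true_id.isin(interior)
            & (table.overlap_fraction > 0.3)
            & table.rim_completeness.notna()
        ]
        assert len(rows) > 50
        err = (1.0 - rows.rim_completeness) - rows.true_gap_fraction
        assert abs(err.mean()) < 0.01
        assert np.abs(err).max() < 0.05

    def test_gap_point_three_reads_seventy_percent(self, gap_segmented):
        """A 30% rim gap measures as ~70% completeness (noise-free)."""
        result, _, truth = gap_segmented
        table = candidate_truth_table(result, truth)
        interior = {f.fibre_id for f in truth.fibres if not f.on_tissue_edge}
        rows = table[
            table.true_id.isin(interior)
            & table.rim_completeness.notna()
            & (table.true_gap_fraction > 0.25)
            & (table.true_gap_fraction < 0.35)
        ]
        assert len(rows) >= 3
        err = rows.rim_completeness - (1.0 - rows.true_gap_fraction)
        assert abs(err.median()) <= 0.02

    def test_monotone_in_exclusion_fraction(self, gap_segmented):
        """Lowering the exclusion fraction never accepts more fibres."""
        result, _, _ = gap_segmented
        counts = []
        for frac in (0.30, 0.20, 0.10, 0.05):
            cands = copy.deepcopy(result.label_map.candidates)
            for c in cands:
                if c.rejection_reason == "gap_gt_threshold":
                    c.rejection_reason = "none"
            apply_gap_rule(cands, SegmentationParams(gap_exclusion_fraction=frac))
            counts.append(sum(c.accepted for c in cands))
        assert counts == sorted(counts, reverse=True)


class TestStructureFilters:
    def test_distractors_never_accepted(self, distractor_segmented):
        result, _, truth = distractor_segmented
        labels = result.labels
        hits = np.unique(labels[truth.distractor_labels > 0])
        assert set(hits.tolist()) <= {0}

    def test_fold_rejected_interior_bright(self, distractor_segmented):
        result, _, truth = distractor_segmented
        fold_ids = {d.distractor_id for d in truth.distractors if d.kind == "fold"}
        assert fold_ids
        fold_mask = np.isin(truth.distractor_labels, list(fold_ids))
        reasons = set()
        for cand in result.label_map.candidates:
            r, c = (int(round(x)) for x in cand.centroid)
            if fold_mask[r, c]:
                reasons.add(cand.rejection_reason)
        assert "interior_bright" in reasons

    def test_vessel_lumen_rejected_too_small(self, distractor_segmented):
        result, _, truth = distractor_segmented
        vessel_ids = {d.distractor_id for d in truth.distractors if d.kind == "vessel"}
        vmask = np.isin(truth.distractor_labels, list(vessel_ids))
        reasons = {
            cand.rejection_reason
            for cand in result.label_map.candidates
            if vmask[int(round(cand.centroid[0])), int(round(cand.centroid[1]))]
        }
        assert reasons <= {"too_small", "distractor_shape", "low_solidity"}

    def test_detection_on_default_conditions(self, distractor_segmented):
        result, _, truth = distractor_segmented
        scores = detection_scores(result, truth)
        assert scores.recall >= 0.99
        assert scores.precision >= 0.99

    def test_border_touching_rejected_on_cropped_section(self, clean_section):
        """Cropping a section cuts fibres; cut fibres are excluded as border."""
        _, section, _ = clean_section
        crop = SectionImage(
            {role: arr[300:900, 300:900] for role, arr in section.channels.items()},
            pixel_size_um=section.pixel_size_um,
            bit_depth=section.bit_depth,
        )
        result = segment_section(crop)
        border = [
            c for c in result.label_map.candidates if c.rejection_reason == "border"
        ]
        assert border
        accepted = [c for c in result.label_map.candidates if c.accepted]
        h, w = crop.shape
        for cand in accepted:
            assert cand.bbox[0].start > 0 and cand.bbox[1].start > 0
            assert cand.bbox[0].stop < h and cand.bbox[1].stop < w


class TestLabels:
    def test_labels_contiguous_and_disjoint(self, clean_segmented):
        result, _, truth = clean_segmented
        labels = result.labels
        ids = np.unique(labels)
        ids = ids[ids > 0]
        assert list(ids) == list(range(1, len(ids) + 1))
        assert len(ids) == truth.n_fibres

    def test_accepted_set_matches_ground_truth(self, clean_segmented):
        result, _, truth = clean_segmented
        scores = detection_scores(result, truth)
        assert scores.n_accepted == truth.n_fibres
        assert scores.recall == 1.0 and scores.precision == 1.0

    def test_blank_section_zero_fibres(self, rng):
        img = np.clip(rng.normal(600, 300, (256, 256)), 0, None).astype(np.uint16)
        sec = SectionImage({"membrane": img, "target": img}, pixel_size_um=0.5)
        with pytest.warns(UserWarning, match="empty tissue"):
            result = segment_section(sec)
        assert result.label_map.n_fibres == 0
        assert not result.labels.any()


def test_watershed_splits_dumbbell():
    """An oversized two-lobed component splits into its two lobes."""
    mask = np.zeros((60, 110), dtype=bool)
    yy, xx = np.mgrid[:60, :110]
    mask |= (yy - 30) ** 2 + (xx - 30) ** 2 <= 22**2
    mask |= (yy - 30) ** 2 + (xx - 80) ** 2 <= 22**2
    parts = _split_component(mask, min_distance_px=10)
    assert parts.max() == 2
    assert (parts > 0).sum() == mask.sum()
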