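"""Stepwise phased sharing: carrier-haplotype identification, segment
extension against a naive maximal-matching-run oracle, all-pairs results
and cross-panel matching."""

import numpy as np
import pytest

import founderhap as fh
from founderhap.panels import MISSING, PanelError
from founderhap.phased import NoInformativeOverlapError, extend_shared

from conftest import make_phased_panel


def naive_segment(ha, hb, focal_idx, strict=False):
    """Independent oracle: the maximal contiguous run of indices containing
    ``focal_idx`` in which the two haplotypes never carry two called,
    unequal alleles (under strict policy: and are never missing)."""
    n = len(ha)

    def stop(i):
        a, b = ha[i], hb[i]
        if a == MISSING or b == MISSING:
            return strict
        return a != b

    left = focal_idx
    while left - 1 >= 0 and not stop(left - 1):
        left -= 1
    right = focal_idx
    while right + 1 < n and not stop(right + 1):
        right += 1
    return left, right


def run_extend(haps, focal_idx, **kw):
    panel = make_phased_panel(haps)
    a, b = fh.CarrierHaplotype("S1", 0), fh.CarrierHaplotype("S1", 1)
    if panel.n_samples > 1:
        b = fh.CarrierHaplotype("S2", 0)
    return panel, extend_shared(panel, focal_idx, a, b, **kw)


class TestIdentifyCarrierHaplotypes:
    def _panel(self):
        # sites: focal at index 1 (alt is the risk allele)
        return make_phased_panel(
            [
                [0, 0, 1], [1, 1, 0],  # S1: het, risk on hap1
                [0, 1, 0], [1, 1, 1],  # S2: hom risk
                [0, 0, 0], [1, 0, 1],  # S3: no risk allele
            ]
        )

    def test_het_carrier_yields_risk_haplotype(self, focal_alt_site):
        panel = self._panel()
        haps = fh.identify_carrier_haplotypes(panel, focal_alt_site(panel, 1), ["S1"])
        assert haps == [fh.CarrierHaplotype("S1", 1)]

    def test_homozygous_carrier_contributes_both_haplotypes(self, focal_alt_site):
        panel = self._panel()
        haps = fh.identify_carrier_haplotypes(panel, focal_alt_site(panel, 1), ["S2"])
        assert haps == [fh.CarrierHaplotype("S2", 0), fh.CarrierHaplotype("S2", 1)]

    def test_discordant_sample_excluded_with_warning(self, focal_alt_site, caplog):
        panel = self._panel()
        with caplog.at_level("WARNING"):
            haps = fh.identify_carrier_haplotypes(
                panel, focal_alt_site(panel, 1), ["S1", "S3"]
            )
        assert haps == [fh.CarrierHaplotype("S1", 1)]
        assert "S3" in caplog.text

    def test_all_discordant_is_fatal(self, focal_alt_site):
        panel = self._panel()
        with pytest.raises(PanelError, match="discordant"):
            fh.identify_carrier_haplotypes(panel, focal_alt_site(panel, 1), ["S3"])

    def test_focal_absent_is_fatal(self):
        panel = self._panel()
        missing = fh.FocalVariant(fh.VariantSite("17", 999, ".", "A", "G"), "alt")
        with pytest.raises(PanelError, match="not present"):
            fh.identify_carrier_haplotypes(panel, missing, ["S1"])


class TestExtendShared:
    def test_mismatch_flanks_delimit_segment(self):
        # 9 sites at 100..900, focal at index 4 (pos 500); haplotypes equal
        # at indices 1..7, unequal at 0 and 8
        ha = [0, 1, 0, 1, 1, 0, 0, 1, 0]
        hb = [1, 1, 0, 1, 1, 0, 0, 1, 1]
        _, seg = run_extend([ha, [0] * 9, hb, [0] * 9], 4)
        assert (seg.left_idx, seg.right_idx) == (1, 7)
        assert (seg.left_pos, seg.right_pos) == (200, 800)
        assert seg.n_variants == 7 and seg.length_bp == 600
        assert (seg.left_stop_pos, seg.right_stop_pos) == (100, 900)

    def test_identical_haplotypes_span_whole_panel(self):
        h = [0, 1, 1, 0, 1]
        _, seg = run_extend([h, [0] * 5, h, [1] * 5], 2)
        assert (seg.left_idx, seg.right_idx) == (0, 4)
        assert seg.left_stop_pos is None and seg.right_stop_pos is None

    def test_adjacent_mismatches_give_focal_only_segment(self):
        ha = [0, 1, 0]
        hb = [1, 1, 1]
        _, seg = run_extend([ha, [0] * 3, hb, [0] * 3], 1)
        assert seg.n_variants == 1 and seg.length_bp == 0
        assert seg.left_pos == seg.right_pos == 200

    def test_focal_conflict_is_fatal(self):
        with pytest.raises(PanelError, match="focal"):
            run_extend([[0, 1, 0], [0] * 3, [0, 0, 0], [0] * 3], 1)

    def test_missing_policies(self):
        ha = [1, MISSING, 1, 1, 0]
        hb = [1, 1, 1, 1, 1]
        _, seg = run_extend([ha, [0] * 5, hb, [0] * 5], 2)
        assert (seg.left_idx, seg.right_idx) == (0, 3)
        assert seg.n_missing_skipped == 1
        _, seg = run_extend([ha, [0] * 5, hb, [0] * 5], 2, missing_policy="strict")
        assert (seg.left_idx, seg.right_idx) == (2, 3)
        assert seg.n_missing_skipped == 0

    def test_matches_naive_oracle_on_random_panels(self):
        rng = np.random.default_rng(42)
        for _ in range(400):
            n = int(rng.integers(2, 60))
            haps = rng.integers(0, 2, size=(4, n)).astype(np.int8)
            haps[rng.random(haps.shape) < 0.15] = MISSING
            focal = int(rng.integers(0, n))
            ha, hb = haps[0], haps[2]
            # make the focal site compatible
            if ha[focal] != MISSING and hb[focal] != MISSING and ha[focal] != hb[focal]:
                hb[focal] = ha[focal]
            for strict in (False, True):
                if strict and (ha[focal] == MISSING or hb[focal] == MISSING):
                    continue
                panel, seg = run_extend(
                    haps, focal,
                    missing_policy="strict" if strict else "noninformative",
                )
                assert (seg.left_idx, seg.right_idx) == naive_segment(ha, hb, focal, strict)

    def test_symmetric_in_haplotype_order(self):
        rng = np.random.default_rng(7)
        haps = rng.integers(0, 2, size=(4, 30)).astype(np.int8)
        haps[rng.random(haps.shape) < 0.2] = MISSING
        haps[:, 15] = 1
        panel = make_phased_panel(haps)
        a, b = fh.CarrierHaplotype("S1", 0), fh.CarrierHaplotype("S2", 0)
        s1 = extend_shared(panel, 15, a, b)
        s2 = extend_shared(panel, 15, b, a)
        assert (s1.left_idx, s1.right_idx, s1.n_missing_skipped) == (
            s2.left_idx, s2.right_idx, s2.n_missing_skipped
        )


class TestAllPairsSharing:
    def _three_carrier_panel(self):
        base = np.array([0, 1, 0, 1, 1, 0, 1], dtype=np.int8)
        rows = []
        for k in range(3):
            hap = base.copy()
            hap[k] = 1 - hap[k]  # distinct flank mismatches per carrier
            rows.extend([hap, np.zeros(7, dtype=np.int8)])
        haps = np.array(rows)
        haps[:, 3] = [1, 0] * 3  # risk allele on hap0 of each sample at focal idx 3
        return make_phased_panel(haps)

    def test_three_haplotypes_give_three_segments(self, focal_alt_site):
        panel = self._three_carrier_panel()
        focal = focal_alt_site(panel, 3)
        haps = fh.identify_carrier_haplotypes(panel, focal, ["S1", "S2", "S3"])
        res = fh.all_pairs_sharing(panel, focal, haps)
        assert len(res.segments) == 3
        assert res.shortest.length_bp == min(s.length_bp for s in res.segments)

    def test_same_sample_pair_excluded(self, focal_alt_site):
        haps = np.array(
            [[0, 1, 0], [0, 1, 0], [1, 1, 1], [0, 0, 1]], dtype=np.int8
        )  # S1 hom risk at idx 1, S2 het
        panel = make_phased_panel(haps)
        focal = focal_alt_site(panel, 1)
        ch = fh.identify_carrier_haplotypes(panel, focal, ["S1", "S2"])
        assert len(ch) == 3
        res = fh.all_pairs_sharing(panel, focal, ch)
        pairs = {(a.sample, a.hap_index, b.sample, b.hap_index)
                 for a, b in (s.pair for s in res.segments)}
        assert ("S1", 0, "S1", 1, ) not in {(p[0], p[1], p[2], p[3]) for p in pairs}
        assert len(res.segments) == 2

    def test_fewer_than_two_haplotypes_fatal(self, focal_alt_site):
        panel = self._three_carrier_panel()
        focal = focal_alt_site(panel, 3)
        with pytest.raises(PanelError, match="at least 2"):
            fh.all_pairs_sharing(panel, focal, [fh.CarrierHaplotype("S1", 0)])

    def test_core_equals_independent_intersection(self, demo_sim_exact, demo_sharing_exact):
        # simulated 20-carrier panel: recompute the closed intersection of
        # all 190 pairwise intervals directly from the segment list
        res = demo_sharing_exact
        assert len(res.segments) == 190
        left = max(s.left_pos for s in res.segments)
        right = min(s.right_pos for s in res.segments)
        assert (res.core.left_pos, res.core.right_pos) == (left, right)
        assert res.core.length_bp == right - left

    def test_core_never_lengthens_with_more_carriers(self, demo_sim_exact):
        res = demo_sim_exact
        panel = res.phased["all"]
        haps = fh.identify_carrier_haplotypes(panel, res.focal, res.carriers)
        lengths = []
        for k in (2, 5, 10, len(haps)):
            r = fh.all_pairs_sharing(panel, res.focal, haps[:k])
            lengths.append(r.core.length_bp)
        assert all(b <= a for a, b in zip(lengths, lengths[1:]))


class TestMatchAcrossPanels:
    def _panels_and_segments(self):
        rng = np.random.default_rng(5)
        hap = rng.integers(0, 2, size=20).astype(np.int8)
        rows_a = [hap, np.zeros(20, np.int8), hap, np.ones(20, np.int8)]
        panel_a = make_phased_panel(np.array(rows_a))
        panel_b = make_phased_panel(np.array(rows_a))
        seg = fh.SharedSegment(
            pair=(fh.CarrierHaplotype("S1", 0), fh.CarrierHaplotype("S2", 0)),
            chrom="17", left_idx=0, right_idx=19, left_pos=100, right_pos=2000,
            n_variants=20, length_bp=1900,
        )
        return panel_a, seg, panel_b, seg

    def test_identical_haplotypes_match(self):
        pa, sa, pb, sb = self._panels_and_segments()
        res = fh.match_across_panels(pa, sa, pb, sb)
        assert res.match and res.n_compared == 20 and res.first_conflict_pos is None

    def test_single_conflict_reported(self):
        pa, sa, pb, sb = self._panels_and_segments()
        pb.alleles[0, 0, 7] = 1 - pb.alleles[0, 0, 7]
        pb.alleles[1, 0, 7] = pb.alleles[0, 0, 7]
        res = fh.match_across_panels(pa, sa, pb, sb)
        assert not res.match and res.first_conflict_pos == 800

    def test_all_missing_overlap_is_distinct_error(self):
        pa, sa, pb, sb = self._panels_and_segments()
        pb.alleles[:] = MISSING
        with pytest.raises(NoInformativeOverlapError):
            fh.match_across_panels(pa, sa, pb, sb)
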