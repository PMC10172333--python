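"""Stepwise shared-haplotype delimitation around a focal variant on phased data.

Starting from the focal site, variants are added one at a time in each
direction; the shared segment for a pair of carrier haplotypes ends at the
last variant at which they still match (the *inner* bound).  The positions
of the first mismatching variants on either side are retained so the outer
span can be recovered.  Applied to all pairs of carrier haplotypes this
yields the pairwise segments, the shortest of them, and the core interval
shared by every pair — a variant-level picture of the founder haplotype.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .panels import (
    MISSING,
    FocalVariant,
    GeneticMap,
    PanelError,
    PhasedPanel,
)

log = logging.getLogger("founderhap.phased")

MissingPolicy = Literal["noninformative", "strict"]


@dataclass(frozen=True, order=True)
class CarrierHaplotype:
    """One phased haplotype of a carrier: which of the sample's two
    haplotypes bears the risk allele at the focal site."""

    sample: str
    hap_index: int  # 0 or 1

    @property
    def label(self) -> str:
        return f"{self.sample}/h{self.hap_index}"


@dataclass
class SharedSegment:
    """Closed interval around the focal site over which two carrier
    haplotypes match at every non-missing variant."""

    pair: tuple[CarrierHaplotype, CarrierHaplotype]
    chrom: str
    left_idx: int
    right_idx: int
    left_pos: int
    right_pos: int
    n_variants: int
    length_bp: int
    length_cm: float | None = None
    n_missing_skipped: int = 0
    #: positions of the first mismatching variant beyond each boundary
    #: (None when the segment runs to the panel end on that side)
    left_stop_pos: int | None = None
    right_stop_pos: int | None = None

    def to_row(self) -> dict:
        a, b = self.pair
        return {
            "pair_id_1": a.sample, "hap_1": a.hap_index,
            "pair_id_2": b.sample, "hap_2": b.hap_index,
            "chrom": self.chrom,
            "left_pos": self.left_pos, "right_pos": self.right_pos,
            "n_variants": self.n_variants, "length_bp": self.length_bp,
            "length_cM": "" if self.length_cm is None else self.length_cm,
        }


@dataclass
class CoreInterval:
    """Closed intersection of all pairwise shared segments."""

    chrom: str
    left_pos: int
    right_pos: int
    left_idx: int
    right_idx: int
    n_variants: int
    length_bp: int
    length_cm: float | None = None


@dataclass
class SharingResult:
    segments: list[SharedSegment]
    shortest: SharedSegment
    core: CoreInterval
    carrier_haplotypes: list[CarrierHaplotype] = field(default_factory=list)


@dataclass
class MatchResult:
    """Verdict of a cross-panel haplotype comparison."""

    match: bool
    n_compared: int
    first_conflict_pos: int | None = None


class NoInformativeOverlapError(PanelError):
    """The two segments overlap in no site informative in both panels."""


def identify_carrier_haplotypes(
    panel: PhasedPanel, focal: FocalVariant, carriers: Sequence[str]
) -> list[CarrierHaplotype]:
    """Resolve which phased haplotype of each listed carrier bears the risk allele.

    Heterozygous carriers contribute the single risk-bearing haplotype;
    homozygous-risk carriers contribute both.  Listed samples without the
    risk allele at the focal site (including missing calls) are discordant:
    they are excluded with a warning and the rest are processed.
    """
    fidx = panel.site_index(focal)
    risk = focal.risk_code
    out: list[CarrierHaplotype] = []
    discordant: list[str] = []
    for sample in carriers:
        a = panel.alleles[panel.sample_index(sample), :, fidx]
        hits = [h for h in (0, 1) if a[h] == risk]
        if not hits:
            discordant.append(sample)
            continue
        out.extend(CarrierHaplotype(sample, h) for h in hits)
    if discordant:
        log.warning(
            "%d listed carrier(s) lack the risk allele at the focal site and were "
            "excluded: %s", len(discordant), ", ".join(discordant)
        )
    if not out:
        raise PanelError("all listed carriers are discordant at the focal site")
    return sorted(out)


def extend_shared(
    panel: PhasedPanel,
    focal_idx: int,
    hap_a: CarrierHaplotype,
    hap_b: CarrierHaplotype,
    missing_policy: MissingPolicy = "noninformative",
    gmap: GeneticMap | None = None,
) -> SharedSegment:
    """Grow the shared segment of two haplotypes outward from the focal site.

    In each direction independently, one variant at a time is appended
    until the haplotypes carry two non-missing, unequal alleles (a STOP).
    Under the default ``noninformative`` policy a site where either allele
    is missing is included and counted in ``n_missing_skipped``; under
    ``strict`` it is a STOP.  Panel ends truncate the search naturally.
    """
    ha = panel.alleles[panel.sample_index(hap_a.sample), hap_a.hap_index]
    hb = panel.alleles[panel.sample_index(hap_b.sample), hap_b.hap_index]
    fa, fb = int(ha[focal_idx]), int(hb[focal_idx])
    if fa != MISSING and fb != MISSING and fa != fb:
        raise PanelError(
            f"haplotypes {hap_a.label} and {hap_b.label} conflict at the focal "
            "site itself — phase or carrier assignment is inconsistent"
        )
    n_missing = 1 if (fa == MISSING or fb == MISSING) else 0
    strict = missing_policy == "strict"

    def _grow(step: int) -> tuple[int, int | None, int]:
        idx = focal_idx
        miss = 0
        i = focal_idx + step
        while 0 <= i < panel.n_sites:
            a, b = int(ha[i]), int(hb[i])
            if a == MISSING or b == MISSING:
                if strict:
                    return idx, None, miss
                miss += 1
            elif a != b:
                return idx, int(panel.sites[i].pos), miss
            idx = i
            i += step
        return idx, None, miss

    left_idx, left_stop, miss_l = _grow(-1)
    right_idx, right_stop, miss_r = _grow(+1)
    left_pos = int(panel.sites[left_idx].pos)
    right_pos = int(panel.sites[right_idx].pos)
    return SharedSegment(
        pair=(hap_a, hap_b),
        chrom=panel.chrom,
        left_idx=left_idx,
        right_idx=right_idx,
        left_pos=left_pos,
        right_pos=right_pos,
        n_variants=right_idx - left_idx + 1,
        length_bp=right_pos - left_pos,
        length_cm=None if gmap is None else gmap.cm_between(left_pos, right_pos),
        n_missing_skipped=n_missing + miss_l + miss_r,
        left_stop_pos=left_stop,
        right_stop_pos=right_stop,
    )


def all_pairs_sharing(
    panel: PhasedPanel,
    focal: FocalVariant,
    carrier_haps: Sequence[CarrierHaplotype],
    missing_policy: MissingPolicy = "noninformative",
    gmap: GeneticMap | None = None,
) -> SharingResult:
    """Pairwise shared segments over all carrier haplotypes, with the
    shortest segment and the core interval shared by every pair.

    Pairs of haplotypes from the same sample (a homozygous carrier's two
    haplotypes) are excluded — they are not inter-individual evidence.
    Pair order, and the tie-break for the shortest segment, are
    lexicographic by (sample, hap_index) so output is byte-stable.
    """
    haps = sorted(set(carrier_haps))
    if len(haps) < 2:
        raise PanelError("need at least 2 carrier haplotypes for pairwise sharing")
    fidx = panel.site_index(focal)
    segments = [
        extend_shared(panel, fidx, a, b, missing_policy, gmap)
        for a, b in itertools.combinations(haps, 2)
        if a.sample != b.sample
    ]
    if not segments:
        raise PanelError("all carrier haplotype pairs are same-sample pairs")
    shortest = min(segments, key=lambda s: (s.length_bp, s.pair))
    li = max(s.left_idx for s in segments)
    ri = min(s.right_idx for s in segments)
    lp = int(panel.sites[li].pos)
    rp = int(panel.sites[ri].pos)
    core = CoreInterval(
        chrom=panel.chrom,
        left_pos=lp,
        right_pos=rp,
        left_idx=li,
        right_idx=ri,
        n_variants=ri - li + 1,
        length_bp=rp - lp,
        length_cm=None if gmap is None else gmap.cm_between(lp, rp),
    )
    return SharingResult(segments=segments, shortest=shortest, core=core,
                         carrier_haplotypes=haps)


def representative_haplotype(panel: PhasedPanel, segment: SharedSegment) -> np.ndarray:
    """Consensus allele sequence of a shared segment over the whole panel.

    Within the segment the two haplotypes agree wherever both are called,
    so the consensus takes whichever allele is non-missing; outside the
    segment the first haplotype is used (callers should only consume
    in-segment sites).
    """
    a = panel.alleles[panel.sample_index(segment.pair[0].sample), segment.pair[0].hap_index]
    b = panel.alleles[panel.sample_index(segment.pair[1].sample), segment.pair[1].hap_index]
    return np.where(a != MISSING, a, b)


def match_across_panels(
    panel_a: PhasedPanel,
    segment_a: SharedSegment,
    panel_b: PhasedPanel,
    segment_b: SharedSegment,
) -> MatchResult:
    """Compare two shared haplotypes across two already-intersected panels.

    Both panels must hold the same harmonized site list (see
    ``panels.intersect_panels``).  Over the sites lying inside *both*
    segments, the representative haplotype sequences are compared;
    the verdict is a match iff no site carries two non-missing, unequal
    alleles.  ``n_compared`` counts the in-segment sites informative
    (non-missing) in both panels; zero such sites is an error, not a
    match verdict.
    """
    pos_a = panel_a.positions
    pos_b = panel_b.positions
    if panel_a.n_sites != panel_b.n_sites or not np.array_equal(pos_a, pos_b):
        raise PanelError("panels must be intersected/harmonized before matching")
    rep_a = representative_haplotype(panel_a, segment_a)
    rep_b = representative_haplotype(panel_b, segment_b)
    left = max(segment_a.left_pos, segment_b.left_pos)
    right = min(segment_a.right_pos, segment_b.right_pos)
    in_seg = (pos_a >= left) & (pos_a <= right)
    informative = in_seg & (rep_a != MISSING) & (rep_b != MISSING)
    n_compared = int(informative.sum())
    if n_compared == 0:
        raise NoInformativeOverlapError(
            "no informative overlap: the segments share no site called in both panels"
        )
    conflicts = informative & (rep_a != rep_b)
    if conflicts.any():
        first = int(pos_a[np.flatnonzero(conflicts)[0]])
        return MatchResult(match=False, n_compared=n_compared, first_conflict_pos=first)
    return MatchResult(match=True, n_compared=n_compared)
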