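"""Opposing-homozygote bound on haplotype sharing for unphased genotypes.

Two samples that are homozygous for different alleles at a site cannot
share a haplotype there under any phasing.  Scanning outward from the
focal variant, the nearest opposing-homozygote site on each side therefore
bounds the region over which the pair could share a haplotype.  This is an
upper bound, not a detection: heterozygous, concordant-homozygous and
missing sites can never prove non-sharing, so they never terminate the
scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .panels import MISSING, FocalVariant, GenotypePanel, PanelError

log = logging.getLogger("founderhap.unphased")


@dataclass
class BoundSegment:
    """Sharing bound for one unphased sample pair around the focal site.

    ``left_bound_pos`` / ``right_bound_pos`` are the positions of the
    nearest opposing-homozygote sites, or the terminal panel positions
    with the corresponding ``*_open`` flag set when no opposing homozygote
    exists before the panel end.  ``n_variants_between`` counts sites at
    which sharing remains possible: strictly inside a closed (opposing)
    bound, inclusive of an open terminal bound.
    """

    sample_a: str
    sample_b: str
    chrom: str
    left_bound_pos: int
    right_bound_pos: int
    left_open: bool
    right_open: bool
    n_variants_between: int
    length_bp: int
    n_missing_inside: int = 0

    def to_row(self) -> dict:
        return {
            "pair_id_1": self.sample_a, "hap_1": "",
            "pair_id_2": self.sample_b, "hap_2": "",
            "chrom": self.chrom,
            "left_pos": self.left_bound_pos, "right_pos": self.right_bound_pos,
            "n_variants": self.n_variants_between, "length_bp": self.length_bp,
            "length_cM": "",
        }


def opposing_homozygote_scan(
    panel: GenotypePanel,
    focal: FocalVariant,
    sample_a: str,
    sample_b: str,
) -> BoundSegment:
    """Bound the shareable region around the focal site for one sample pair.

    Moving one variant at a time away from the focal site, a direction
    terminates at the first site where one dosage is 0 and the other 2
    (both called).  Missing dosages are non-informative: they are counted
    but never terminate.  If a direction reaches the panel end the bound
    is the terminal site position and the open flag is set.
    """
    if sample_a == sample_b:
        raise PanelError("opposing-homozygote scan needs two distinct samples")
    fidx = panel.site_index(focal)
    da = panel.dosages[panel.sample_index(sample_a)]
    db = panel.dosages[panel.sample_index(sample_b)]
    pos = panel.positions
    n_missing = 0

    def _scan(step: int) -> tuple[int, bool]:
        nonlocal n_missing
        i = fidx + step
        while 0 <= i < panel.n_sites:
            a, b = int(da[i]), int(db[i])
            if a == MISSING or b == MISSING:
                n_missing += 1
            elif {a, b} == {0, 2}:
                return i, False
            i += step
        return (0 if step < 0 else panel.n_sites - 1), True

    li, left_open = _scan(-1)
    ri, right_open = _scan(+1)
    lo = li + (0 if left_open else 1)  # first index where sharing is possible
    hi = ri - (0 if right_open else 1)  # last such index
    return BoundSegment(
        sample_a=sample_a,
        sample_b=sample_b,
        chrom=panel.chrom,
        left_bound_pos=int(pos[li]),
        right_bound_pos=int(pos[ri]),
        left_open=left_open,
        right_open=right_open,
        n_variants_between=max(0, hi - lo + 1),
        length_bp=int(pos[ri] - pos[li]),
        n_missing_inside=n_missing,
    )


def consensus_bound(
    panel: GenotypePanel,
    focal: FocalVariant,
    samples: Sequence[str],
) -> BoundSegment:
    """Intersection of all pairwise bounds over a set of samples.

    The consensus left bound is the right-most pairwise left bound (and
    symmetrically on the right); a side is open only if the binding
    pairwise side is open.  Pair labels are replaced by a summary label.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise PanelError("consensus bound needs at least 2 samples")
    bounds = [
        opposing_homozygote_scan(panel, focal, a, b)
        for i, a in enumerate(samples)
        for b in samples[i + 1:]
    ]
    left = max(bounds, key=lambda s: s.left_bound_pos)
    right = min(bounds, key=lambda s: s.right_bound_pos)
    pos = panel.positions
    li = int(pos.searchsorted(left.left_bound_pos))
    ri = int(pos.searchsorted(right.right_bound_pos))
    lo = li + (0 if left.left_open else 1)
    hi = ri - (0 if right.right_open else 1)
    return BoundSegment(
        sample_a=f"consensus({len(samples)})",
        sample_b="",
        chrom=panel.chrom,
        left_bound_pos=left.left_bound_pos,
        right_bound_pos=right.right_bound_pos,
        left_open=left.left_open,
        right_open=right.right_open,
        n_variants_between=max(0, hi - lo + 1),
        length_bp=int(right.right_bound_pos - left.left_bound_pos),
        n_missing_inside=max(b.n_missing_inside for b in bounds),
    )
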