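"""Panel I/O and the in-memory data model shared by every analysis stage.

A *panel* is an ordered list of biallelic SNV sites on one chromosome
together with per-sample allele data: either phased haplotype sequences
(:class:`PhasedPanel`) or unphased alt-allele dosages
(:class:`GenotypePanel`).  Allele codes are 0 (ref), 1 (alt) and
:data:`MISSING` (-1).  All coordinates are 1-based and all reported
intervals are closed ``[left_pos, right_pos]``; the base-pair length of a
closed interval is defined as ``right_pos - left_pos`` (the distance
spanned between the boundary variants).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger("founderhap.panels")

#: Sentinel for a missing allele call or dosage.
MISSING: int = -1

_SNV_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: Allele pairs whose strand cannot be resolved from the codes alone.
_AMBIGUOUS_PAIRS = frozenset({frozenset(("A", "T")), frozenset(("C", "G"))})


class PanelError(ValueError):
    """Fatal problem with panel contents or panel-level preconditions."""


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNV: chromosome, 1-based position, id, ref and alt."""

    chrom: str
    pos: int
    vid: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise PanelError(f"variant position must be >= 1, got {self.pos}")
        if self.ref not in _SNV_ALLELES or self.alt not in _SNV_ALLELES:
            raise PanelError(
                f"{self.chrom}:{self.pos} is not a biallelic SNV "
                f"({self.ref}>{self.alt})"
            )
        if self.ref == self.alt:
            raise PanelError(f"{self.chrom}:{self.pos} ref equals alt")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FocalVariant:
    """The rare variant whose carriers anchor the haplotype search.

    ``risk_allele`` names which allele ("ref" or "alt") defines carriers;
    for a rare pathogenic variant this is almost always "alt".
    """

    site: VariantSite
    risk_allele: str = "alt"

    def __post_init__(self) -> None:
        if self.risk_allele not in ("ref", "alt"):
            raise PanelError(f"risk_allele must be 'ref' or 'alt', got {self.risk_allele!r}")

    @property
    def risk_code(self) -> int:
        """Allele code (0/1) of the risk allele."""
        return 1 if self.risk_allele == "alt" else 0

    @classmethod
    def from_string(cls, spec: str, risk_allele: str = "alt") -> "FocalVariant":
        """Parse a ``chrom:pos:ref:alt`` specification string."""
        parts = spec.split(":")
        if len(parts) != 4:
            raise PanelError(f"focal variant spec must be chrom:pos:ref:alt, got {spec!r}")
        chrom, pos, ref, alt = parts
        return cls(VariantSite(chrom, int(pos), ".", ref.upper(), alt.upper()), risk_allele)


def _check_sites(sites: Sequence[VariantSite]) -> None:
    if not sites:
        raise PanelError("panel has no sites")
    chroms = {s.chrom for s in sites}
    if len(chroms) > 1:
        raise PanelError(
            f"panel spans multiple chromosomes {sorted(chroms)}; "
            "restrict to one chromosome (use a region filter)"
        )
    pos = [s.pos for s in sites]
    if any(b <= a for a, b in zip(pos, pos[1:])):
        raise PanelError("site positions must be strictly increasing")


class _PanelBase:
    sites: list[VariantSite]
    samples: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chrom(self) -> str:
        return self.sites[0].chrom

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([s.pos for s in self.sites], dtype=np.int64)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise PanelError(f"sample {sample!r} not in panel") from None

    def site_index(self, focal: FocalVariant) -> int:
        """Index of the focal site, matched on chrom+pos+ref+alt."""
        key = focal.site.key
        for i, s in enumerate(self.sites):
            if s.key == key:
                return i
        raise PanelError(
            f"focal variant {key[0]}:{key[1]}:{key[2]}:{key[3]} not present in panel"
        )


@dataclass
class PhasedPanel(_PanelBase):
    """Phased haplotypes: ``alleles[sample, hap, site]`` in {0, 1, -1}."""

    sites: list[VariantSite]
    samples: list[str]
    alleles: np.ndarray  # (n_samples, 2, n_sites) int8

    def __post_init__(self) -> None:
        _check_sites(self.sites)
        if len(set(self.samples)) != len(self.samples):
            raise PanelError("duplicate sample identifiers")
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        expect = (len(self.samples), 2, len(self.sites))
        if self.alleles.shape != expect:
            raise PanelError(f"allele array shape {self.alleles.shape} != {expect}")

    def haplotype(self, sample: str, hap_index: int) -> np.ndarray:
        return self.alleles[self.sample_index(sample), hap_index]

    def subset_sites(self, idx: Sequence[int]) -> "PhasedPanel":
        idx = np.asarray(idx, dtype=np.intp)
        return PhasedPanel(
            [self.sites[i] for i in idx], list(self.samples), self.alleles[:, :, idx]
        )

    def subset_samples(self, keep: Sequence[str]) -> "PhasedPanel":
        rows = [self.sample_index(s) for s in keep]
        return PhasedPanel(list(self.sites), list(keep), self.alleles[rows])

    def to_genotype_panel(self) -> "GenotypePanel":
        """Collapse phase to dosages; any missing allele makes the dosage missing."""
        a = self.alleles
        dos = a.sum(axis=1).astype(np.int8)
        dos[(a == MISSING).any(axis=1)] = MISSING
        return GenotypePanel(list(self.sites), list(self.samples), dos)


@dataclass
class GenotypePanel(_PanelBase):
    """Unphased genotypes: ``dosages[sample, site]`` = alt-allele count in {0,1,2,-1}."""

    sites: list[VariantSite]
    samples: list[str]
    dosages: np.ndarray  # (n_samples, n_sites) int8

    def __post_init__(self) -> None:
        _check_sites(self.sites)
        if len(set(self.samples)) != len(self.samples):
            raise PanelError("duplicate sample identifiers")
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        expect = (len(self.samples), len(self.sites))
        if self.dosages.shape != expect:
            raise PanelError(f"dosage array shape {self.dosages.shape} != {expect}")

    def subset_sites(self, idx: Sequence[int]) -> "GenotypePanel":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypePanel(
            [self.sites[i] for i in idx], list(self.samples), self.dosages[:, idx]
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypePanel":
        rows = [self.sample_index(s) for s in keep]
        return GenotypePanel(list(self.sites), list(keep), self.dosages[rows])


@dataclass(frozen=True)
class GeneticMap:
    """Piecewise-linear genetic map: cumulative cM as a function of bp.

    Queries outside the anchor range are clamped to the terminal anchor
    values, so the map never extrapolates.
    """

    anchor_pos: np.ndarray  # strictly increasing bp
    anchor_cm: np.ndarray  # non-decreasing cM

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor_pos", np.asarray(self.anchor_pos, dtype=np.float64))
        object.__setattr__(self, "anchor_cm", np.asarray(self.anchor_cm, dtype=np.float64))
        if self.anchor_pos.ndim != 1 or self.anchor_pos.size < 1:
            raise PanelError("genetic map needs at least one anchor")
        if np.any(np.diff(self.anchor_pos) <= 0):
            raise PanelError("genetic map positions must be strictly increasing")
        if np.any(np.diff(self.anchor_cm) < 0):
            raise PanelError("genetic map cM must be non-decreasing")

    @classmethod
    def uniform(cls, chrom_length_bp: int, rate_cm_per_mb: float) -> "GeneticMap":
        """Constant-rate map from position 1 to the chromosome end."""
        total_cm = (chrom_length_bp - 1) / 1e6 * rate_cm_per_mb
        return cls(np.array([1.0, float(chrom_length_bp)]), np.array([0.0, total_cm]))

    def cm_at(self, pos):
        """Interpolated cM at bp position(s); clamped beyond the anchors."""
        return np.interp(pos, self.anchor_pos, self.anchor_cm)

    def pos_at(self, cm):
        """Inverse lookup: bp position at cumulative cM (left-most on plateaus)."""
        return np.interp(cm, self.anchor_cm, self.anchor_pos)

    @property
    def total_cm(self) -> float:
        return float(self.anchor_cm[-1] - self.anchor_cm[0])

    def cm_between(self, left_pos, right_pos) -> float:
        return float(self.cm_at(right_pos) - self.cm_at(left_pos))


# ---------------------------------------------------------------------------
# readers


def _iter_vcf(path: str | Path, region: str | None):
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise PanelError(f"cannot read VCF {path}: {exc}") from exc
    it = vcf(region) if region else vcf
    return vcf, it


def _retain_record(variant, seen_pos: set, stats: dict) -> bool:
    """Common biallelic-SNV / duplicate-position filter for both readers."""
    if len(variant.ALT) != 1:
        stats["multiallelic"] += 1
        return False
    ref, alt = variant.REF.upper(), variant.ALT[0].upper()
    if ref not in _SNV_ALLELES or alt not in _SNV_ALLELES:
        stats["non_snv"] += 1
        return False
    if (variant.CHROM, variant.POS) in seen_pos:
        stats["duplicate_pos"] += 1
        return False
    return True


def read_phased_vcf(path: str | Path, region: str | None = None) -> PhasedPanel:
    """Read phased biallelic SNVs from a VCF into a :class:`PhasedPanel`.

    A record is dropped panel-wide if any sample has an unphased
    heterozygous genotype (``0/1``): keeping it would leave that sample's
    haplotype assignment ambiguous while the panel requires identical site
    support for every haplotype sequence.  Unphased homozygotes are
    accepted (their phase is unambiguous) and missing alleles are
    preserved as missing.  Multi-allelic and non-SNV records are dropped,
    as are records duplicating an earlier position (first record wins).
    """
    vcf, it = _iter_vcf(path, region)
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    cols: list[np.ndarray] = []
    seen: set = set()
    stats = {"multiallelic": 0, "non_snv": 0, "duplicate_pos": 0, "unphased": 0}
    for variant in it:
        if not _retain_record(variant, seen, stats):
            continue
        geno = variant.genotypes  # [[a0, a1, phased], ...]
        col = np.full((len(samples), 2), MISSING, dtype=np.int8)
        ok = True
        for i, g in enumerate(geno):
            a0, a1 = g[0], g[1]
            if a0 < 0 and a1 < 0:
                continue  # fully missing stays missing; separator irrelevant
            if not g[2]:
                if a0 >= 0 and a1 >= 0 and a0 != a1:
                    ok = False  # genuinely ambiguous unphased het
                    break
                if a0 < 0 or a1 < 0:
                    continue  # half-call without phase: haplotype unknown
                col[i, 0], col[i, 1] = a0, a1
            else:
                col[i, 0] = a0 if a0 >= 0 else MISSING
                col[i, 1] = a1 if a1 >= 0 else MISSING
        if not ok:
            stats["unphased"] += 1
            continue
        seen.add((variant.CHROM, variant.POS))
        sites.append(VariantSite(variant.CHROM, variant.POS, variant.ID or ".", variant.REF.upper(), variant.ALT[0].upper()))
        cols.append(col)
    dropped = {k: v for k, v in stats.items() if v}
    if dropped:
        log.warning("read_phased_vcf(%s): dropped records %s", path, dropped)
    if not sites:
        raise PanelError(
            f"no phased biallelic SNV records retained from {path}"
            + (f" region {region}" if region else "")
        )
    alleles = np.stack(cols, axis=2)  # (samples, 2, sites)
    return PhasedPanel(sites, samples, alleles)


def read_genotype_vcf(path: str | Path, region: str | None = None) -> GenotypePanel:
    """Read biallelic SNVs from a VCF as an alt-dosage matrix.

    Half-missing genotypes (e.g. ``./1``) become missing; phase is ignored.
    """
    vcf, it = _iter_vcf(path, region)
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    cols: list[np.ndarray] = []
    seen: set = set()
    stats = {"multiallelic": 0, "non_snv": 0, "duplicate_pos": 0, "unphased": 0}
    for variant in it:
        if not _retain_record(variant, seen, stats):
            continue
        seen.add((variant.CHROM, variant.POS))
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, g in enumerate(variant.genotypes):
            a0, a1 = g[0], g[1]
            if a0 >= 0 and a1 >= 0:
                col[i] = a0 + a1
        sites.append(VariantSite(variant.CHROM, variant.POS, variant.ID or ".", variant.REF.upper(), variant.ALT[0].upper()))
        cols.append(col)
    dropped = {k: v for k, v in stats.items() if v}
    if dropped:
        log.warning("read_genotype_vcf(%s): dropped records %s", path, dropped)
    if not sites:
        raise PanelError(f"no biallelic SNV records retained from {path}")
    return GenotypePanel(sites, samples, np.stack(cols, axis=1))


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a 3-column genetic map: position, rate (cM/Mb), cumulative cM.

    Lines starting with ``#`` and a non-numeric header line are skipped.
    """
    pos: list[float] = []
    cm: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise PanelError(f"genetic map line has <3 columns: {line!r}")
            try:
                p, c = float(parts[0]), float(parts[2])
            except ValueError:
                if not pos:
                    continue  # tolerate a single header line
                raise PanelError(f"non-numeric genetic map line: {line!r}") from None
            pos.append(p)
            cm.append(c)
    if not pos:
        raise PanelError(f"no anchors in genetic map {path}")
    return GeneticMap(np.asarray(pos), np.asarray(cm))


def read_carrier_list(path: str | Path) -> list[str]:
    """One sample ID per line; blank lines and ``#`` comments ignored."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


# ---------------------------------------------------------------------------
# panel intersection / harmonization


def _flip_codes(panel, idx: np.ndarray):
    """Invert allele codes (0<->1) at the given site indices, in place."""
    if isinstance(panel, PhasedPanel):
        block = panel.alleles[:, :, idx]
        nz = block != MISSING
        block[nz] = 1 - block[nz]
        panel.alleles[:, :, idx] = block
    else:
        block = panel.dosages[:, idx]
        nz = block != MISSING
        block[nz] = 2 - block[nz]
        panel.dosages[:, idx] = block


def intersect_panels(panel_a, panel_b):
    """Restrict two panels to their shared, allele-harmonizable sites.

    Sites are matched on chrom+pos.  Alleles are harmonized against panel
    A: identical ref/alt pass through; ref/alt swapped in B flips B's
    allele codes; a strand (complement) difference relabels silently; a
    combined strand+swap flips codes.  Strand-ambiguous sites (A/T, C/G)
    are kept only when the alleles match exactly — any other configuration
    is unresolvable and the site is dropped.

    Returns ``(panel_a', panel_b', n_shared_sites)`` with site order
    preserved.  An empty harmonized intersection is fatal.
    """
    if panel_a.chrom != panel_b.chrom:
        raise PanelError(
            f"panels are on different chromosomes ({panel_a.chrom} vs {panel_b.chrom})"
        )
    b_by_pos = {s.pos: j for j, s in enumerate(panel_b.sites)}
    keep_a: list[int] = []
    keep_b: list[int] = []
    flip_b: list[int] = []  # positions *within the kept list* needing a code flip
    n_dropped = 0
    for i, sa in enumerate(panel_a.sites):
        j = b_by_pos.get(sa.pos)
        if j is None:
            continue
        sb = panel_b.sites[j]
        pair_a = frozenset((sa.ref, sa.alt))
        ambiguous = pair_a in _AMBIGUOUS_PAIRS
        if (sb.ref, sb.alt) == (sa.ref, sa.alt):
            action = "keep"
        elif ambiguous:
            n_dropped += 1
            continue
        elif (sb.ref, sb.alt) == (sa.alt, sa.ref):
            action = "flip"
        elif (sb.ref, sb.alt) == (_COMPLEMENT[sa.ref], _COMPLEMENT[sa.alt]):
            action = "keep"  # strand relabel only
        elif (sb.ref, sb.alt) == (_COMPLEMENT[sa.alt], _COMPLEMENT[sa.ref]):
            action = "flip"
        else:
            n_dropped += 1
            continue
        if action == "flip":
            flip_b.append(len(keep_a))
        keep_a.append(i)
        keep_b.append(j)
    if n_dropped:
        log.warning("intersect_panels: dropped %d unharmonizable site(s)", n_dropped)
    if not keep_a:
        raise PanelError("panels share no harmonizable sites")
    out_a = panel_a.subset_sites(keep_a)
    out_b = panel_b.subset_sites(keep_b)
    if flip_b:
        _flip_codes(out_b, np.asarray(flip_b, dtype=np.intp))
        # after flipping codes, B's site labels take A's ref/alt
        out_b.sites = [
            replace(out_b.sites[k], ref=out_a.sites[k].ref, alt=out_a.sites[k].alt)
            if k in set(flip_b) else out_b.sites[k]
            for k in range(len(out_b.sites))
        ]
    return out_a, out_b, len(keep_a)


# ---------------------------------------------------------------------------
# writers


def _gt_string(a0: int, a1: int, sep: str) -> str:
    s0 = "." if a0 == MISSING else str(a0)
    s1 = "." if a1 == MISSING else str(a1)
    return f"{s0}{sep}{s1}"


_DOSAGE_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _vcf_header(chrom: str, max_pos: int, samples: Sequence[str]) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=founderhap",
        f"##contig=<ID={chrom},length={max_pos + 1}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    return "\n".join(lines) + "\n"


def write_phased_vcf(panel: PhasedPanel, path: str | Path) -> None:
    """Write a phased panel as an uncompressed VCF (``|`` separator)."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(panel.chrom, int(panel.positions[-1]), panel.samples))
        for k, site in enumerate(panel.sites):
            gts = "\t".join(
                _gt_string(panel.alleles[i, 0, k], panel.alleles[i, 1, k], "|")
                for i in range(panel.n_samples)
            )
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.vid}\t{site.ref}\t{site.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_genotype_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a dosage panel as an uncompressed unphased VCF."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(panel.chrom, int(panel.positions[-1]), panel.samples))
        for k, site in enumerate(panel.sites):
            gts = "\t".join(
                _DOSAGE_GT[int(panel.dosages[i, k])] for i in range(panel.n_samples)
            )
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.vid}\t{site.ref}\t{site.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


_SEGMENT_COLUMNS = [
    "pair_id_1", "hap_1", "pair_id_2", "hap_2", "chrom",
    "left_pos", "right_pos", "n_variants", "length_bp", "length_cM",
]


def write_segments_tsv(segments: Iterable, path: str | Path) -> None:
    """Write shared segments (or sharing bounds) as a TSV.

    Accepts any objects exposing ``to_row()`` returning a dict with the
    standard segment columns; ``length_cM`` is left empty when no genetic
    map was supplied.
    """
    rows = [seg.to_row() for seg in segments]
    df = pd.DataFrame(rows, columns=_SEGMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_segments_tsv(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_segments_tsv` output."""
    return pd.read_csv(path, sep="\t")


def write_summary_json(results: dict, path: str | Path) -> None:
    """Deterministic JSON summary: sorted keys, fixed indentation, no timestamps."""
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, Path):
        return str(obj)
    return obj
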