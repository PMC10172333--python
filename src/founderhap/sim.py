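"""Pedigree gene-dropping simulator with exact identity-by-descent truth.

A focal risk allele is placed on one haplotype of one founder and dropped
through an arbitrary pedigree.  Each meiosis draws a crossover count from
Poisson(map length in Morgans) with crossover positions uniform on the
genetic map (Haldane's model, no interference) and transmits the
recombined haplotype.  Founder-origin labels are propagated exactly
alongside the alleles, so for every pair of sampled haplotypes the true
IBD segment around the focal position is known.  Observed panels apply a
symmetric allele-flip genotyping error and per-genotype missingness after
the truth is recorded, and may be ascertained onto several "chips"
(marker subsets with partial overlap) to emulate cross-cohort genotyping.

Background founder haplotypes are site-wise independent draws from the
configured allele frequencies (no background linkage disequilibrium);
chance sharing is controlled through those frequencies and the marker
density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .panels import (
    MISSING,
    FocalVariant,
    GeneticMap,
    GenotypePanel,
    PanelError,
    PhasedPanel,
    VariantSite,
)
from .phased import SharingResult

log = logging.getLogger("founderhap.sim")

HapKey = tuple[str, int]  # (individual id, haplotype index)
OriginInterval = tuple[float, float, HapKey]  # half-open [start, end) -> founder hap


class PedigreeError(PanelError):
    pass


@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None = None
    mother: str | None = None
    sex: int = 0  # 1 male, 2 female, 0 unknown

    def __post_init__(self) -> None:
        if (self.father is None) != (self.mother is None):
            raise PedigreeError(f"{self.iid}: both parents must be present or both absent")

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass
class PedigreeSpec:
    """A pedigree as a list of individuals; founders have no parents."""

    individuals: list[Individual]

    def __post_init__(self) -> None:
        ids = [ind.iid for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate individual ids in pedigree")
        self.by_id: dict[str, Individual] = {ind.iid: ind for ind in self.individuals}
        for ind in self.individuals:
            for p in (ind.father, ind.mother):
                if p is not None and p not in self.by_id:
                    raise PedigreeError(f"{ind.iid}: parent {p} not in pedigree")
        self._topo = self._topological_order()

    def _topological_order(self) -> list[Individual]:
        order: list[Individual] = []
        state: dict[str, int] = {}

        def visit(iid: str, stack: list[str]) -> None:
            st = state.get(iid, 0)
            if st == 1:
                raise PedigreeError(f"pedigree cycle involving {' -> '.join(stack + [iid])}")
            if st == 2:
                return
            state[iid] = 1
            ind = self.by_id[iid]
            if not ind.is_founder:
                visit(ind.father, stack + [iid])
                visit(ind.mother, stack + [iid])
            state[iid] = 2
            order.append(ind)

        for ind in self.individuals:
            visit(ind.iid, [])
        return order

    @property
    def founders(self) -> list[Individual]:
        return [i for i in self.individuals if i.is_founder]

    @property
    def topological(self) -> list[Individual]:
        return list(self._topo)

    def ancestors_on_carrier_path(self, target: str, founder: str) -> list[str]:
        """One lineage path founder -> target through the pedigree (ids, inclusive).

        When both parents lead to the founder the father's line is taken,
        so the path is deterministic.
        """
        memo: dict[str, list[str] | None] = {}

        def path(iid: str) -> list[str] | None:
            if iid == founder:
                return [iid]
            if iid in memo:
                return memo[iid]
            ind = self.by_id[iid]
            res = None
            if not ind.is_founder:
                for parent in (ind.father, ind.mother):
                    sub = path(parent)
                    if sub is not None:
                        res = sub + [iid]
                        break
            memo[iid] = res
            return res

        p = path(target)
        if p is None:
            raise PedigreeError(f"{target} does not descend from {founder}")
        return p


def read_pedigree(path: str | Path) -> PedigreeSpec:
    """Read a .fam-like text pedigree: ``id father mother sex`` per line,
    ``0`` meaning no parent; ``#`` comments allowed."""
    inds: list[Individual] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise PedigreeError(f"pedigree line has <3 columns: {line!r}")
            iid, fa, mo = parts[:3]
            sex = int(parts[3]) if len(parts) > 3 else 0
            inds.append(
                Individual(iid, None if fa == "0" else fa, None if mo == "0" else mo, sex)
            )
    return PedigreeSpec(inds)


def write_pedigree(ped: PedigreeSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# id father mother sex (0 = founder/unknown)\n")
        for ind in ped.individuals:
            fh.write(f"{ind.iid}\t{ind.father or 0}\t{ind.mother or 0}\t{ind.sex}\n")


@dataclass(frozen=True)
class ChipSpec:
    """A genotyping chip: the subset of simulated markers it assays."""

    name: str
    marker_indices: tuple[int, ...]


@dataclass
class SimConfig:
    """Parameters of one gene-dropping run.

    Rates are per-call: ``error_rate`` is the probability that an observed
    allele call is flipped (symmetric), ``missing_rate`` the probability
    that a genotype (both alleles) is set missing.  ``condition_on`` lists
    individuals whose descent of the focal allele is conditioned on
    (each meiosis on the lineage path is rejection-sampled until it
    transmits the focal founder haplotype at the focal position) —
    emulating ascertained carriers without biasing recombination.
    """

    n_markers: int
    chrom_length_bp: int
    focal_pos: int
    focal_founder_id: str
    founder_hap_index: int = 0
    chrom: str = "17"
    genetic_map: GeneticMap | None = None
    rate_cm_per_mb: float = 1.0
    marker_af: float | tuple[float, float] = (0.1, 0.5)
    error_rate: float = 0.0
    missing_rate: float = 0.0
    chips: list[ChipSpec] | None = None
    sampled_ids: list[str] | None = None
    condition_on: list[str] = field(default_factory=list)
    focal_ref: str = "T"
    focal_alt: str = "C"
    focal_vid: str = "focal"
    seed: int = 0

    def resolved_map(self) -> GeneticMap:
        if self.genetic_map is not None:
            return self.genetic_map
        return GeneticMap.uniform(self.chrom_length_bp, self.rate_cm_per_mb)

    def validate(self, pedigree: PedigreeSpec) -> None:
        if not 0 <= self.error_rate <= 1 or not 0 <= self.missing_rate <= 1:
            raise PanelError("error_rate and missing_rate must lie in [0, 1]")
        if not 1 <= self.focal_pos <= self.chrom_length_bp:
            raise PanelError("focal_pos outside the chromosome")
        if self.n_markers < 1:
            raise PanelError("need at least one marker")
        ff = pedigree.by_id.get(self.focal_founder_id)
        if ff is None:
            raise PedigreeError(f"focal founder {self.focal_founder_id} not in pedigree")
        if not ff.is_founder:
            raise PedigreeError(f"{self.focal_founder_id} is not a founder")
        if self.founder_hap_index not in (0, 1):
            raise PanelError("founder_hap_index must be 0 or 1")
        if self.chips:
            names = [c.name for c in self.chips]
            if len(set(names)) != len(names):
                raise PanelError("duplicate chip names")
            for c in self.chips:
                if not c.marker_indices:
                    raise PanelError(f"chip {c.name} has no markers")
                if min(c.marker_indices) < 0 or max(c.marker_indices) >= self.n_markers:
                    raise PanelError(f"chip {c.name} indexes markers outside the panel")
        if self.sampled_ids is not None:
            missing = [s for s in self.sampled_ids if s not in pedigree.by_id]
            if missing:
                raise PedigreeError(f"sampled ids not in pedigree: {missing[:5]}")
        for c in self.condition_on:
            pedigree.ancestors_on_carrier_path(c, self.focal_founder_id)


@dataclass
class TruthRecord:
    """Exact founder origins and pairwise true IBD around the focal site."""

    chrom: str
    chrom_length_bp: int
    focal_pos: int
    focal_label: HapKey
    origins: dict[HapKey, list[OriginInterval]]
    carrier_haplotypes: list[HapKey]

    def origin_at(self, hap: HapKey, pos: float) -> HapKey:
        for start, end, label in self.origins[hap]:
            if start <= pos < end:
                return label
        raise PanelError(f"position {pos} outside origin intervals of {hap}")

    def focal_interval(self, hap: HapKey) -> tuple[float, float] | None:
        """Maximal interval around the focal position descending from the
        focal founder haplotype, or None if this haplotype does not carry it."""
        if hap not in self.origins:
            raise PanelError(
                f"haplotype {hap} has no truth record — truth and sharing "
                "result come from different simulations?"
            )
        for start, end, label in self.origins[hap]:
            if start <= self.focal_pos < end:
                return (start, end) if label == self.focal_label else None
        return None

    def true_ibd_segment(self, hap_a: HapKey, hap_b: HapKey) -> tuple[float, float] | None:
        """Maximal interval where both haplotypes descend from the focal
        founder haplotype (always contains the focal position)."""
        ia, ib = self.focal_interval(hap_a), self.focal_interval(hap_b)
        if ia is None or ib is None:
            return None
        return (max(ia[0], ib[0]), min(ia[1], ib[1]))


@dataclass
class SimResult:
    sites: list[VariantSite]
    phased: dict[str, PhasedPanel]
    genotypes: dict[str, GenotypePanel]
    carriers: list[str]
    truth: TruthRecord
    focal: FocalVariant
    config: SimConfig
    pedigree: PedigreeSpec


def _merge_origins(intervals: list[OriginInterval]) -> list[OriginInterval]:
    out: list[OriginInterval] = []
    for iv in intervals:
        if out and out[-1][2] == iv[2] and out[-1][1] == iv[0]:
            out[-1] = (out[-1][0], iv[1], iv[2])
        else:
            out.append(iv)
    return out


def _clip_origins(
    intervals: list[OriginInterval], lo: float, hi: float
) -> list[OriginInterval]:
    out = []
    for start, end, label in intervals:
        s, e = max(start, lo), min(end, hi)
        if s < e:
            out.append((s, e, label))
    return out


def _origin_label_at(intervals: list[OriginInterval], pos: float) -> HapKey:
    for start, end, label in intervals:
        if start <= pos < end:
            return label
    raise PanelError(f"position {pos} not covered by origin intervals")


class _Drop:
    """Internal gene-dropping engine for one simulation run."""

    def __init__(self, pedigree: PedigreeSpec, config: SimConfig, rng: np.random.Generator):
        self.ped = pedigree
        self.cfg = config
        self.rng = rng
        self.gmap = config.resolved_map()
        self.total_cm = self.gmap.total_cm
        self.marker_pos = self._draw_marker_positions()
        self.focal_idx = int(np.searchsorted(self.marker_pos, config.focal_pos))
        self.afs = self._draw_afs()
        self.alleles: dict[str, np.ndarray] = {}  # iid -> (2, n_markers) int8
        self.origins: dict[HapKey, list[OriginInterval]] = {}
        self.focal_label: HapKey = (config.focal_founder_id, config.founder_hap_index)
        self.must_carry = self._must_carry_sets()

    def _draw_marker_positions(self) -> np.ndarray:
        cfg = self.cfg
        need = cfg.n_markers - 1
        pool = self.rng.integers(1, cfg.chrom_length_bp + 1, size=max(4 * cfg.n_markers, 64))
        pool = np.unique(pool)
        pool = pool[pool != cfg.focal_pos]
        if pool.size < need:
            raise PanelError("chromosome too short for the requested marker count")
        chosen = self.rng.permutation(pool)[:need]
        return np.sort(np.concatenate([chosen, [cfg.focal_pos]])).astype(np.int64)

    def _draw_afs(self) -> np.ndarray:
        cfg = self.cfg
        if isinstance(cfg.marker_af, (int, float)):
            afs = np.full(cfg.n_markers, float(cfg.marker_af))
        else:
            lo, hi = cfg.marker_af
            afs = self.rng.uniform(lo, hi, size=cfg.n_markers)
        afs[self.focal_idx] = 0.0  # the focal allele exists only on the founder haplotype
        return afs

    def _must_carry_sets(self) -> dict[str, str]:
        """Map of individual -> the parent whose gamete must carry the focal allele."""
        forced: dict[str, str] = {}
        for target in self.cfg.condition_on:
            path = self.ped.ancestors_on_carrier_path(target, self.cfg.focal_founder_id)
            for parent, child in zip(path, path[1:]):
                prev = forced.get(child)
                if prev is not None and prev != parent:
                    raise PedigreeError(
                        f"{child}: conflicting conditioned transmission paths"
                    )
                forced[child] = parent
        return forced

    def _founder_haplotypes(self, ind: Individual) -> None:
        n = self.cfg.n_markers
        haps = (self.rng.random((2, n)) < self.afs).astype(np.int8)
        if ind.iid == self.cfg.focal_founder_id:
            haps[self.cfg.founder_hap_index, self.focal_idx] = 1
        self.alleles[ind.iid] = haps
        hi = float(self.cfg.chrom_length_bp) + 1.0
        for h in (0, 1):
            self.origins[(ind.iid, h)] = [(1.0, hi, (ind.iid, h))]

    def _gamete(self, parent: str, condition_focal: bool):
        """One meiosis from ``parent``; optionally rejection-sampled so the
        transmitted haplotype carries the focal founder origin at focal_pos."""
        cfg, rng = self.cfg, self.rng
        morgans = self.total_cm / 100.0
        par_origins = (self.origins[(parent, 0)], self.origins[(parent, 1)])
        for _ in range(100_000):
            k = int(rng.poisson(morgans))
            if k:
                xs = np.sort(self.gmap.pos_at(rng.uniform(0.0, self.total_cm, size=k)))
            else:
                xs = np.empty(0)
            s0 = int(rng.integers(2))
            if condition_focal:
                src = (s0 + int(np.searchsorted(xs, cfg.focal_pos, side="right"))) % 2
                if _origin_label_at(par_origins[src], cfg.focal_pos) != self.focal_label:
                    continue
            break
        else:  # pragma: no cover - unreachable with a carrier parent
            raise PanelError(f"conditioning on transmission from {parent} failed")
        # per-marker source haplotype and alleles
        src_per_marker = (s0 + np.searchsorted(xs, self.marker_pos, side="right")) % 2
        par_alleles = self.alleles[parent]
        alleles = np.where(src_per_marker == 0, par_alleles[0], par_alleles[1]).astype(np.int8)
        # composed origin intervals
        bounds = np.concatenate([[1.0], xs, [float(cfg.chrom_length_bp) + 1.0]])
        origins: list[OriginInterval] = []
        for j in range(len(bounds) - 1):
            src = (s0 + j) % 2
            origins.extend(_clip_origins(par_origins[src], bounds[j], bounds[j + 1]))
        return alleles, _merge_origins(origins)

    def run(self) -> None:
        for ind in self.ped.topological:
            if ind.is_founder:
                self._founder_haplotypes(ind)
                continue
            forced_parent = self.must_carry.get(ind.iid)
            haps = np.empty((2, self.cfg.n_markers), dtype=np.int8)
            for h, parent in ((0, ind.father), (1, ind.mother)):
                alleles, origins = self._gamete(parent, condition_focal=(parent == forced_parent))
                haps[h] = alleles
                self.origins[(ind.iid, h)] = origins
            self.alleles[ind.iid] = haps


def simulate(pedigree: PedigreeSpec, config: SimConfig) -> SimResult:
    """Gene-drop the pedigree and emit observed panels plus exact truth.

    Identical ``(pedigree, config)`` — the seed lives in the config —
    produce identical output, down to the bytes of any written VCF.
    """
    config.validate(pedigree)
    rng = np.random.default_rng(config.seed)
    drop = _Drop(pedigree, config, rng)
    drop.run()

    sampled = config.sampled_ids or [ind.iid for ind in pedigree.individuals]
    true_alleles = np.stack([drop.alleles[iid] for iid in sampled])  # (n, 2, m)

    carrier_haps = [
        (iid, h)
        for iid in sampled
        for h in (0, 1)
        if _origin_label_at(drop.origins[(iid, h)], config.focal_pos) == drop.focal_label
    ]
    carriers = sorted({iid for iid, _ in carrier_haps})

    truth = TruthRecord(
        chrom=config.chrom,
        chrom_length_bp=config.chrom_length_bp,
        focal_pos=config.focal_pos,
        focal_label=drop.focal_label,
        origins=drop.origins,
        carrier_haplotypes=sorted(carrier_haps),
    )

    # observation layer: symmetric allele flips, then per-genotype missingness
    observed = true_alleles.copy()
    if config.error_rate > 0:
        flip = rng.random(observed.shape) < config.error_rate
        observed[flip] = 1 - observed[flip]
    if config.missing_rate > 0:
        miss = rng.random((observed.shape[0], observed.shape[2])) < config.missing_rate
        observed[np.repeat(miss[:, None, :], 2, axis=1)] = MISSING

    sites = [
        VariantSite(config.chrom, int(p), f"snp{i + 1}", "A", "G")
        if i != drop.focal_idx
        else VariantSite(config.chrom, int(p), config.focal_vid, config.focal_ref, config.focal_alt)
        for i, p in enumerate(drop.marker_pos)
    ]
    focal = FocalVariant(sites[drop.focal_idx], "alt")

    chips = config.chips or [ChipSpec("all", tuple(range(config.n_markers)))]
    phased: dict[str, PhasedPanel] = {}
    genotypes: dict[str, GenotypePanel] = {}
    for chip in chips:
        idx = np.asarray(sorted(chip.marker_indices), dtype=np.intp)
        sub_sites = [sites[i] for i in idx]
        sub = observed[:, :, idx]
        panel = PhasedPanel(sub_sites, list(sampled), sub)
        phased[chip.name] = panel
        genotypes[chip.name] = panel.to_genotype_panel()

    return SimResult(
        sites=sites,
        phased=phased,
        genotypes=genotypes,
        carriers=carriers,
        truth=truth,
        focal=focal,
        config=config,
        pedigree=pedigree,
    )


def write_truth_tsv(truth: TruthRecord, path: str | Path) -> None:
    """Founder-origin intervals as a BED-like TSV.

    Coordinates are 1-based closed (matching the rest of the artifact, and
    stated in the header); the half-open internal representation is
    converted on output.
    """
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based, closed intervals\n")
        fh.write("haplotype_id\tchrom\tstart\tend\tfounder_origin\n")
        for (iid, h), intervals in sorted(truth.origins.items()):
            for start, end, (fid, fh_idx) in intervals:
                fh.write(
                    f"{iid}/h{h}\t{truth.chrom}\t{int(np.ceil(start))}"
                    f"\t{int(np.floor(end - 1))}\t{fid}/h{fh_idx}\n"
                )


def evaluate_recovery(
    truth: TruthRecord,
    result: SharingResult,
    marker_positions: np.ndarray,
    gmap: GeneticMap | None = None,
) -> list[dict]:
    """Compare detected pairwise segments with the simulated truth.

    The continuous true IBD interval is clipped to the marker grid (the
    outermost markers it contains) before comparison, since detection can
    only resolve boundaries at genotyped sites.  Returns one record per
    pair: containment flag (detected ⊇ truth), boundary excesses and the
    detected/true length ratio.
    """
    pos = np.asarray(marker_positions)
    records: list[dict] = []
    for seg in result.segments:
        a, b = seg.pair
        key_a, key_b = (a.sample, a.hap_index), (b.sample, b.hap_index)
        ibd = truth.true_ibd_segment(key_a, key_b)
        if ibd is None:
            raise PanelError(
                f"pair {a.label},{b.label} has no true IBD segment: "
                "truth and sharing result come from different simulations?"
            )
        inside = pos[(pos >= ibd[0]) & (pos < ibd[1])]
        if inside.size == 0:
            raise PanelError("true IBD segment contains no marker (panel too sparse)")
        t_left, t_right = int(inside[0]), int(inside[-1])
        contained = seg.left_pos <= t_left and seg.right_pos >= t_right
        true_len = t_right - t_left
        rec = {
            "pair": (a.label, b.label),
            "contained": bool(contained),
            "left_excess_bp": t_left - seg.left_pos,
            "right_excess_bp": seg.right_pos - t_right,
            "true_length_bp": true_len,
            "detected_length_bp": seg.length_bp,
            "length_ratio": (seg.length_bp / true_len) if true_len > 0 else np.inf,
        }
        if gmap is not None:
            rec["left_excess_cm"] = gmap.cm_between(seg.left_pos, t_left)
            rec["right_excess_cm"] = gmap.cm_between(t_right, seg.right_pos)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# packaged pedigrees


def chain_pair_pedigree(n_left: int, n_right: int) -> tuple[PedigreeSpec, str, str]:
    """Founder couple with two descendant lines of ``n_left`` and
    ``n_right`` meioses; returns (pedigree, left leaf id, right leaf id).

    The two leaves are separated from the shared founder by
    ``n_left + n_right`` meioses — the classic setup for studying IBD
    segment length around a conditioned locus.
    """
    if n_left < 1 or n_right < 1:
        raise PedigreeError("each line needs at least one meiosis")
    inds = [Individual("F0", sex=1), Individual("F0S", sex=2)]

    def build(side: str, n: int) -> str:
        prev_f, prev_m = "F0", "F0S"
        child = ""
        for g in range(1, n + 1):
            child = f"{side}{g}"
            inds.append(Individual(child, prev_f, prev_m, sex=1))
            if g < n:
                spouse = f"{side}{g}S"
                inds.append(Individual(spouse, sex=2))
                prev_f, prev_m = child, spouse
        return child

    left = build("A", n_left)
    right = build("B", n_right)
    return PedigreeSpec(inds), left, right


def westray_demo_pedigree(
    n_kindreds: int = 5, n_background: int = 2000
) -> tuple[PedigreeSpec, list[str], list[str]]:
    """Five interlinked kindreds descending from one founder couple, eight
    generations deep, with four sampled carrier-generation members per
    kindred plus a panel of unrelated background individuals.

    Returns (pedigree, carrier leaf ids, background ids).
    """
    inds = [Individual("K0_F", sex=1), Individual("K0_M", sex=2)]
    leaves: list[str] = []
    for k in range(1, n_kindreds + 1):
        # generation 1: one child of the founder couple per kindred
        prev_f, prev_m = "K0_F", "K0_M"
        for g in range(1, 7):
            child = f"K{k}_G{g}"
            spouse = f"K{k}_G{g}S"
            inds.append(Individual(child, prev_f, prev_m, sex=1))
            inds.append(Individual(spouse, sex=2))
            prev_f, prev_m = child, spouse
        for branch in ("a", "b"):
            b7 = f"K{k}_G7{branch}"
            b7s = f"K{k}_G7{branch}S"
            inds.append(Individual(b7, prev_f, prev_m, sex=1))
            inds.append(Individual(b7s, sex=2))
            for j in (1, 2):
                leaf = f"K{k}_G8{branch}{j}"
                inds.append(Individual(leaf, b7, b7s, sex=1 + (j % 2)))
                leaves.append(leaf)
    background = [f"BG{i:04d}" for i in range(1, n_background + 1)]
    inds.extend(Individual(b, sex=1 + (i % 2)) for i, b in enumerate(background))
    return PedigreeSpec(inds), leaves, background


def westray_demo(
    seed: int = 17,
    n_background: int = 2000,
    n_markers: int = 2000,
    error_rate: float = 0.001,
    missing_rate: float = 0.002,
) -> tuple[PedigreeSpec, SimConfig]:
    """The packaged demonstration scenario: a founder variant enriched in a
    small isolate cohort.

    Twenty conditioned carriers across five kindreds (descending from a
    single founder couple eight generations up) are sampled alongside
    ~2000 unrelated non-carriers, on an 80 Mb chromosome-17-like region at
    1 cM/Mb with the focal variant near 41.2 Mb — so the sampled carrier
    frequency is ~1%, at the scale the analysis is designed for.
    """
    ped, leaves, background = westray_demo_pedigree(5, n_background)
    cfg = SimConfig(
        n_markers=n_markers,
        chrom_length_bp=80_000_000,
        focal_pos=41_196_408,
        focal_founder_id="K0_F",
        founder_hap_index=0,
        chrom="17",
        rate_cm_per_mb=1.0,
        marker_af=(0.1, 0.5),
        error_rate=error_rate,
        missing_rate=missing_rate,
        sampled_ids=leaves + background,
        condition_on=list(leaves),
        seed=seed,
    )
    return ped, cfg


# ---------------------------------------------------------------------------
# config file support


def config_from_mapping(data: Mapping, pedigree: PedigreeSpec) -> SimConfig:
    """Build a SimConfig from a plain mapping (parsed YAML)."""
    kwargs = dict(data)
    chips = kwargs.pop("chips", None)
    if chips:
        kwargs["chips"] = [
            ChipSpec(name, tuple(int(i) for i in idx)) for name, idx in chips.items()
        ]
    af = kwargs.get("marker_af")
    if isinstance(af, (list, tuple)):
        kwargs["marker_af"] = (float(af[0]), float(af[1]))
    cfg = SimConfig(**kwargs)
    cfg.validate(pedigree)
    return cfg


def read_sim_config(path: str | Path, pedigree: PedigreeSpec) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise PanelError(f"simulation config {path} is not a key-value mapping")
    return config_from_mapping(data, pedigree)
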