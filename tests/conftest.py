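"""Shared fixtures: hand-built panels, VCF text fixtures and the packaged
demonstration simulation (run once per session at zero error so the exact
containment properties hold)."""

from __future__ import annotations

import numpy as np
import pytest

from founderhap import (
    FocalVariant,
    PhasedPanel,
    VariantSite,
    all_pairs_sharing,
    identify_carrier_haplotypes,
    simulate,
    westray_demo,
)


def make_phased_panel(haps, positions=None, chrom="17", refalt=None):
    """Build a PhasedPanel from per-haplotype allele rows.

    ``haps`` is a sequence of (sample, hap_index agnostic) allele rows,
    grouped in consecutive pairs per sample: haps[2*i] and haps[2*i+1]
    are sample ``S{i+1}``'s two haplotypes.
    """
    haps = np.asarray(haps, dtype=np.int8)
    assert haps.shape[0] % 2 == 0
    n_samples, n_sites = haps.shape[0] // 2, haps.shape[1]
    if positions is None:
        positions = [100 * (i + 1) for i in range(n_sites)]
    if refalt is None:
        refalt = [("A", "G")] * n_sites
    sites = [
        VariantSite(chrom, int(p), f"v{i + 1}", refalt[i][0], refalt[i][1])
        for i, p in enumerate(positions)
    ]
    samples = [f"S{i + 1}" for i in range(n_samples)]
    return PhasedPanel(sites, samples, haps.reshape(n_samples, 2, n_sites))


@pytest.fixture
def focal_alt_site():
    def make(panel: PhasedPanel, idx: int) -> FocalVariant:
        return FocalVariant(panel.sites[idx], "alt")

    return make


@pytest.fixture(scope="session")
def demo_sim_exact():
    """The packaged westray_demo scenario with error and missingness off:
    detection and truth must then nest exactly."""
    ped, cfg = westray_demo(seed=3, error_rate=0.0, missing_rate=0.0)
    return simulate(ped, cfg)


@pytest.fixture(scope="session")
def demo_sharing_exact(demo_sim_exact):
    res = demo_sim_exact
    panel = res.phased["all"]
    haps = identify_carrier_haplotypes(panel, res.focal, res.carriers)
    return all_pairs_sharing(panel, res.focal, haps)


@pytest.fixture
def write_vcf(tmp_path):
    """Write raw VCF body lines (CHROM..samples columns) with a minimal header."""

    def make(body_rows: list[str], samples: list[str], name: str = "fixture.vcf"):
        path = tmp_path / name
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        path.write_text(header + "".join(row + "\n" for row in body_rows))
        return path

    return make
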