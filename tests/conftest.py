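"""Shared fixtures: small hand-written VCFs and simulation config factories."""

from __future__ import annotations

import textwrap
from typing import Dict, List

import pytest

from sweepscan.variant_io import GroupAssignment

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=1000000>
    ##contig=<ID=chr2,length=1000000>
    ##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
    ##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">
    """
)


def write_vcf(path, records: List[str], samples: List[str]) -> str:
    """Write a plain-text VCF from pre-formatted record lines."""
    header = VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
    header += "\t".join(samples) + "\n"
    path = str(path)
    with open(path, "w") as fh:
        fh.write(header)
        for rec in records:
            fh.write(rec.rstrip("\n") + "\n")
    return path


def ad_record(
    chrom: str,
    pos: int,
    depths: List[tuple],
    ref: str = "A",
    alt: str = "C",
    mq: float | None = 60,
    dp: int | None = None,
    gts: List[str] | None = None,
) -> str:
    """One GT:DP:AD record line from per-sample (ref_depth, alt_depth)."""
    if dp is None:
        dp = sum(r + a for r, a in depths)
    info = f"DP={dp}" if mq is None else f"MQ={mq};DP={dp}"
    fields = [chrom, str(pos), ".", ref, alt, ".", "PASS", info, "GT:DP:AD"]
    for i, (r, a) in enumerate(depths):
        if gts is not None:
            gt = gts[i]
        elif r + a == 0:
            gt = "./."
        elif a == 0:
            gt = "0/0"
        elif r == 0:
            gt = "1/1"
        else:
            gt = "0/1"
        fields.append(f"{gt}:{r + a}:{r},{a}")
    return "\t".join(fields)


@pytest.fixture
def two_pool_assignment() -> GroupAssignment:
    return GroupAssignment(
        sample_to_group={"p1": "farmed", "p2": "farmed", "w1": "wild", "w2": "wild"},
        group_modes={"farmed": "pooled", "wild": "pooled"},
    )


def sim_and_scan(out_root, cfg: dict, seed: int, **scan_kwargs):
    """Simulate one dataset and scan it; returns (sim paths, scan result)."""
    import os

    from sweepscan.cli import run_scan, run_simulate

    sim_dir = os.path.join(str(out_root), f"sim_{seed}")
    paths = run_simulate(cfg, seed, sim_dir)
    res = run_scan(
        paths["vcf"],
        paths["groups_tsv"],
        paths["chroms"],
        os.path.join(str(out_root), f"scan_{seed}"),
        **scan_kwargs,
    )
    return paths, res


def base_sim_config(
    chrom_mb: Dict[str, int] | None = None,
    sweeps: List[dict] | None = None,
    divergence: float = 0.06,
    snp_density: float = 1 / 500,
) -> dict:
    """Simulation config dict mirroring the pooled two-group study design:
    4 farmed pools (22 diploids, 22x) vs 6 wild pools (20 diploids, 22x)."""
    chroms = chrom_mb or {"chr1": 5_000_000, "chr2": 5_000_000}
    return {
        "chromosomes": chroms,
        "snp_density": snp_density,
        "error_rate": 0.001,
        "groups": [
            {
                "name": "farmed",
                "mode": "pooled",
                "n_pools": 4,
                "diploids": 22,
                "depth": 22,
                "divergence": divergence,
            },
            {
                "name": "wild",
                "mode": "pooled",
                "n_pools": 6,
                "diploids": 20,
                "depth": 22,
                "divergence": divergence,
            },
        ],
        "sweeps": sweeps or [],
    }
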