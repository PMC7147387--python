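"""Synthetic pool-seq / individual-seq VCF generator.

Generates biallelic SNPs with the statistical structure the scan assumes:
Poisson-placed sites, per-group allele frequencies diverged from a shared
ancestral frequency under the Balding-Nichols model (group frequency ~
Beta(p0*(1-F)/F, (1-p0)*(1-F)/F)), binomial read sampling, and embedded
sweep regions where one group's frequencies are pushed to fixation. Output
is a plain-text VCF 4.2 (GT:DP:AD) plus a BED of ground-truth sweep
intervals, byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from sweepscan.errors import ConfigurationError

DEFAULT_SNP_DENSITY = 1.0 / 500.0
DEFAULT_DIVERGENCE = 0.06  # per-group F giving pairwise WC FST ~ 0.065
DEFAULT_FREQ_RANGE = (0.05, 0.95)


@dataclass(frozen=True)
class SweepSpec:
    """One embedded sweep: SNPs inside [start, end] (1-based inclusive) on
    ``chrom`` are driven to fixation in ``group`` with probability ``f``,
    toward the ancestral major allele."""

    chrom: str
    start: int
    end: int
    group: str
    f: float

    def __post_init__(self) -> None:
        if not 0 <= self.f <= 1:
            raise ConfigurationError(f"sweep fixation fraction f={self.f} not in [0,1]")
        if self.start < 1 or self.end < self.start:
            raise ConfigurationError(
                f"invalid sweep interval {self.chrom}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class TruthRegion:
    """Ground-truth sweep interval, one per SweepSpec."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    group: str
    f: float

    def to_bed_fields(self) -> Tuple[str, int, int, str, str]:
        return (self.chrom, self.start - 1, self.end, self.group, f"{self.f:g}")


@dataclass(frozen=True)
class PoolSpec:
    name: str
    n_diploids: int = 20
    mean_depth: float = 22.0

    def __post_init__(self) -> None:
        if self.n_diploids < 1:
            raise ConfigurationError(f"pool {self.name!r}: n_diploids must be >= 1")
        if self.mean_depth <= 0:
            raise ConfigurationError(f"pool {self.name!r}: mean_depth must be > 0")


@dataclass(frozen=True)
class GroupSpec:
    """One population group: a list of pools, or a count of individuals."""

    name: str
    mode: str = "pooled"  # "pooled" | "individual"
    divergence: float = DEFAULT_DIVERGENCE  # Balding-Nichols F
    pools: Tuple[PoolSpec, ...] = ()
    n_individuals: int = 0
    mean_depth: float = 6.0  # per-individual depth in individual mode

    def __post_init__(self) -> None:
        if self.mode not in ("pooled", "individual"):
            raise ConfigurationError(f"group {self.name!r}: unknown mode {self.mode!r}")
        if not 0 <= self.divergence < 1:
            raise ConfigurationError(
                f"group {self.name!r}: divergence F must satisfy 0 <= F < 1"
            )
        if self.mode == "pooled" and not self.pools:
            raise ConfigurationError(f"group {self.name!r}: pooled mode needs pools")
        if self.mode == "individual":
            if self.n_individuals < 1:
                raise ConfigurationError(
                    f"group {self.name!r}: individual mode needs n_individuals >= 1"
                )
            if self.mean_depth <= 0:
                raise ConfigurationError(
                    f"group {self.name!r}: mean_depth must be > 0"
                )

    @property
    def sample_names(self) -> List[str]:
        if self.mode == "pooled":
            return [p.name for p in self.pools]
        return [f"{self.name}_ind{i + 1}" for i in range(self.n_individuals)]


@dataclass(frozen=True)
class SimulationConfig:
    chromosomes: Mapping[str, int]
    groups: Tuple[GroupSpec, ...]
    snp_density: float = DEFAULT_SNP_DENSITY
    freq_range: Tuple[float, float] = DEFAULT_FREQ_RANGE
    error_rate: float = 0.0
    sweeps: Tuple[SweepSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ConfigurationError("at least one chromosome is required")
        for c, length in self.chromosomes.items():
            if length <= 0:
                raise ConfigurationError(f"chromosome {c!r} has length {length}")
        if self.snp_density <= 0:
            raise ConfigurationError("snp_density must be > 0")
        lo, hi = self.freq_range
        if not (0 <= lo < hi <= 1):
            raise ConfigurationError(f"invalid freq_range {self.freq_range}")
        if not 0 <= self.error_rate < 0.5:
            raise ConfigurationError("error_rate must satisfy 0 <= eps < 0.5")
        if not self.groups:
            raise ConfigurationError("at least one group is required")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ConfigurationError("group names must be unique")
        group_names = set(names)
        for s in self.sweeps:
            if s.chrom not in self.chromosomes:
                raise ConfigurationError(f"sweep on unknown chromosome {s.chrom!r}")
            if s.end > self.chromosomes[s.chrom]:
                raise ConfigurationError(
                    f"sweep {s.chrom}:{s.start}-{s.end} exceeds chromosome length"
                )
            if s.group not in group_names:
                raise ConfigurationError(f"sweep targets unknown group {s.group!r}")
        # overlapping sweeps on the same group make the truth ambiguous
        by_group: Dict[str, List[SweepSpec]] = {}
        for s in self.sweeps:
            by_group.setdefault((s.group, s.chrom), []).append(s)  # type: ignore[arg-type]
        for key, specs in by_group.items():
            specs = sorted(specs, key=lambda s: s.start)
            for a, b in zip(specs, specs[1:]):
                if b.start <= a.end:
                    raise ConfigurationError(
                        f"overlapping sweeps for group {key[0]!r} on {key[1]}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )

    @property
    def sample_names(self) -> List[str]:
        out: List[str] = []
        for g in self.groups:
            out.extend(g.sample_names)
        return out

    def truth_regions(self) -> List[TruthRegion]:
        return [
            TruthRegion(s.chrom, s.start, s.end, s.group, s.f) for s in self.sweeps
        ]


def make_pools(
    group: str, n_pools: int, n_diploids: int, mean_depth: float
) -> Tuple[PoolSpec, ...]:
    """Convenience constructor for n identical pools."""
    return tuple(
        PoolSpec(f"{group}_pool{i + 1}", n_diploids, mean_depth)
        for i in range(n_pools)
    )


# ---------------------------------------------------------------------------
# Simulation stages
# ---------------------------------------------------------------------------


def simulate_site_frequencies(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw SNP positions and per-group allele frequencies.

    Positions are a Poisson process at ``snp_density`` per chromosome
    (sorted, deduplicated); the ancestral alternate-allele frequency p0 is
    uniform on ``freq_range``; each group's frequency is Balding-Nichols
    around p0 with that group's F (F = 0 reproduces p0 exactly).

    Returns a frame with columns ``chrom, pos, p0`` and one ``freq_<group>``
    column per group.
    """
    chroms: List[str] = []
    positions: List[np.ndarray] = []
    for chrom, length in config.chromosomes.items():
        n = rng.poisson(config.snp_density * length)
        pos = np.unique(rng.integers(1, length + 1, size=n))
        chroms.extend([chrom] * pos.size)
        positions.append(pos)
    pos_all = (
        np.concatenate(positions) if positions else np.zeros(0, dtype=np.int64)
    )
    lo, hi = config.freq_range
    p0 = rng.uniform(lo, hi, size=pos_all.size)
    df = pd.DataFrame({"chrom": chroms, "pos": pos_all, "p0": p0})
    for g in config.groups:
        F = g.divergence
        if F == 0:
            df[f"freq_{g.name}"] = p0.copy()
        else:
            a = p0 * (1 - F) / F
            b = (1 - p0) * (1 - F) / F
            df[f"freq_{g.name}"] = rng.beta(a, b)
    return df


def apply_sweep(
    sites: pd.DataFrame,
    sweeps: Sequence[SweepSpec],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Push in-sweep SNPs of the target group toward fixation.

    Each SNP inside a sweep interval is, with probability f, set to the
    ancestral major allele's fixed frequency (1 if p0 >= 0.5 else 0) in
    the target group; everything else is untouched. Returns a copy.
    """
    out = sites.copy()
    for s in sweeps:
        col = f"freq_{s.group}"
        if col not in out.columns:
            raise ConfigurationError(f"sweep targets unknown group {s.group!r}")
        in_region = (
            (out["chrom"] == s.chrom)
            & (out["pos"] >= s.start)
            & (out["pos"] <= s.end)
        ).to_numpy()
        hit = in_region & (rng.random(len(out)) < s.f)
        fixed_to = np.where(out["p0"].to_numpy() >= 0.5, 1.0, 0.0)
        vals = out[col].to_numpy(copy=True)
        vals[hit] = fixed_to[hit]
        out[col] = vals
    return out


def sample_pool_reads(
    sites: pd.DataFrame,
    group: GroupSpec,
    rng: np.random.Generator,
    error_rate: float = 0.0,
) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """Two-stage pool-seq read sampling for one pooled group.

    For each pool: the pool's allele composition is Binomial(2N, freq)/2N
    (a finite sample of 2N chromosomes), site depth is Poisson(mean
    depth), and alternate reads are Binomial(depth, composition) with each
    read flipped with probability ``error_rate``. Depth 0 encodes missing.

    Returns (sample names, ref depth matrix, alt depth matrix), matrices
    shaped (n_sites, n_pools).
    """
    n_sites = len(sites)
    names = [p.name for p in group.pools]
    ref = np.zeros((n_sites, len(names)), dtype=np.int64)
    alt = np.zeros((n_sites, len(names)), dtype=np.int64)
    freq = sites[f"freq_{group.name}"].to_numpy()
    eps = error_rate
    for j, pool in enumerate(group.pools):
        two_n = 2 * pool.n_diploids
        comp = rng.binomial(two_n, freq) / two_n
        depth = rng.poisson(pool.mean_depth, size=n_sites)
        p_eff = comp * (1 - eps) + (1 - comp) * eps
        alt[:, j] = rng.binomial(depth, p_eff)
        ref[:, j] = depth - alt[:, j]
    return names, ref, alt


def sample_individual_genotypes(
    sites: pd.DataFrame,
    group: GroupSpec,
    rng: np.random.Generator,
    error_rate: float = 0.0,
) -> Tuple[List[str], np.ndarray, np.ndarray, np.ndarray]:
    """Hardy-Weinberg genotypes plus read depths for one individual group.

    Genotype (alt-allele dosage) ~ Binomial(2, freq); per-individual site
    depth ~ Poisson(mean depth); allele depths binomial given the genotype
    with read error ``error_rate``. Depth 0 marks a missing call
    (genotype -1 in the returned matrix).

    Returns (names, genotype matrix with -1 for missing, ref depths, alt
    depths), matrices shaped (n_sites, n_individuals).
    """
    n_sites = len(sites)
    names = group.sample_names
    n_ind = len(names)
    freq = sites[f"freq_{group.name}"].to_numpy()
    eps = error_rate
    gt = np.zeros((n_sites, n_ind), dtype=np.int64)
    ref = np.zeros((n_sites, n_ind), dtype=np.int64)
    alt = np.zeros((n_sites, n_ind), dtype=np.int64)
    for j in range(n_ind):
        g = rng.binomial(2, freq)
        depth = rng.poisson(group.mean_depth, size=n_sites)
        p_true = g / 2.0
        p_eff = p_true * (1 - eps) + (1 - p_true) * eps
        a = rng.binomial(depth, p_eff)
        alt[:, j] = a
        ref[:, j] = depth - a
        gt[:, j] = np.where(depth > 0, g, -1)
    return names, gt, ref, alt


@dataclass
class SimulatedDataset:
    """In-memory result of a full simulation run."""

    config: SimulationConfig
    sites: pd.DataFrame
    sample_names: List[str]
    sample_group: List[str]
    genotypes: np.ndarray  # (n_sites, n_samples); -1 missing; pools: presence code
    ref_depths: np.ndarray
    alt_depths: np.ndarray
    truth: List[TruthRegion] = field(default_factory=list)


def simulate_dataset(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedDataset:
    """Run all simulation stages for one configuration."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sites = simulate_site_frequencies(config, rng)
    sites = apply_sweep(sites, config.sweeps, rng)
    names_all: List[str] = []
    group_all: List[str] = []
    gt_blocks: List[np.ndarray] = []
    ref_blocks: List[np.ndarray] = []
    alt_blocks: List[np.ndarray] = []
    for g in config.groups:
        if g.mode == "pooled":
            names, ref, alt = sample_pool_reads(sites, g, rng, config.error_rate)
            # pseudo-genotype from allele presence, for the GT column
            gt = np.full(ref.shape, -1, dtype=np.int64)
            has = (ref + alt) > 0
            gt[has & (alt == 0)] = 0
            gt[has & (ref > 0) & (alt > 0)] = 1
            gt[has & (ref == 0) & (alt > 0)] = 2
        else:
            names, gt, ref, alt = sample_individual_genotypes(
                sites, g, rng, config.error_rate
            )
        names_all.extend(names)
        group_all.extend([g.name] * len(names))
        gt_blocks.append(gt)
        ref_blocks.append(ref)
        alt_blocks.append(alt)
    n_sites = len(sites)
    empty = np.zeros((n_sites, 0), dtype=np.int64)
    return SimulatedDataset(
        config=config,
        sites=sites,
        sample_names=names_all,
        sample_group=group_all,
        genotypes=np.hstack(gt_blocks) if gt_blocks else empty,
        ref_depths=np.hstack(ref_blocks) if ref_blocks else empty,
        alt_depths=np.hstack(alt_blocks) if alt_blocks else empty,
        truth=config.truth_regions(),
    )


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

_GT_CODE = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_simulated_vcf(
    dataset: SimulatedDataset,
    vcf_path: str,
    bed_path: Optional[str] = None,
) -> None:
    """Write a VCF 4.2 (GT:DP:AD per sample) and an optional truth BED.

    REF is always A, ALT always C; site INFO carries MQ=60 and the
    aggregate DP so downstream filters have something to act on. Output is
    deterministic given the dataset.
    """
    cfg = dataset.config
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan-simulate\n")
        for chrom, length in cfg.chromosomes.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allele read depths (ref,alt)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.sample_names)
            + "\n"
        )
        ref_m = dataset.ref_depths
        alt_m = dataset.alt_depths
        gt_m = dataset.genotypes
        chroms = dataset.sites["chrom"].to_numpy()
        poss = dataset.sites["pos"].to_numpy()
        for i in range(len(dataset.sites)):
            dp_total = int(ref_m[i].sum() + alt_m[i].sum())
            cols = [
                str(chroms[i]),
                str(int(poss[i])),
                ".",
                "A",
                "C",
                ".",
                "PASS",
                f"MQ=60;DP={dp_total}",
                "GT:DP:AD",
            ]
            for j in range(len(dataset.sample_names)):
                r, a = int(ref_m[i, j]), int(alt_m[i, j])
                cols.append(f"{_GT_CODE[int(gt_m[i, j])]}:{r + a}:{r},{a}")
            fh.write("\t".join(cols) + "\n")
    if bed_path is not None:
        write_truth_bed(dataset.truth, bed_path)


def write_truth_bed(truth: Sequence[TruthRegion], path: str) -> None:
    """BED3+2 (chrom, 0-based start, end, group, f) of true sweep intervals."""
    with open(path, "w") as fh:
        for t in truth:
            fh.write("\t".join(str(x) for x in t.to_bed_fields()) + "\n")


def read_truth_bed(path: str) -> List[TruthRegion]:
    out: List[TruthRegion] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, group, f = line.split("\t")[:5]
            out.append(TruthRegion(chrom, int(start) + 1, int(end), group, float(f)))
    return out


def write_chrom_lengths(chromosomes: Mapping[str, int], path: str) -> None:
    """2-column TSV of chromosome lengths, readable as a .fai substitute."""
    with open(path, "w") as fh:
        for chrom, length in chromosomes.items():
            fh.write(f"{chrom}\t{length}\n")


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["chromosomes"] = dict(config.chromosomes)
    return d


def config_from_dict(d: Mapping) -> SimulationConfig:
    """Build a config from a plain dict (parsed YAML/JSON)."""
    groups = []
    for g in d.get("groups", []):
        g = dict(g)
        mode = g.get("mode", "pooled")
        if mode == "pooled":
            if "pools" in g and g["pools"] and isinstance(g["pools"][0], Mapping):
                pools = tuple(
                    PoolSpec(
                        p.get("name", f"{g['name']}_pool{i + 1}"),
                        int(p.get("diploids", 20)),
                        float(p.get("depth", 22.0)),
                    )
                    for i, p in enumerate(g["pools"])
                )
            else:
                pools = make_pools(
                    g["name"],
                    int(g.get("n_pools", 1)),
                    int(g.get("diploids", 20)),
                    float(g.get("depth", 22.0)),
                )
            groups.append(
                GroupSpec(
                    name=g["name"],
                    mode="pooled",
                    divergence=float(g.get("divergence", DEFAULT_DIVERGENCE)),
                    pools=pools,
                )
            )
        else:
            groups.append(
                GroupSpec(
                    name=g["name"],
                    mode="individual",
                    divergence=float(g.get("divergence", DEFAULT_DIVERGENCE)),
                    n_individuals=int(g.get("individuals", g.get("n_individuals", 0))),
                    mean_depth=float(g.get("depth", 6.0)),
                )
            )
    sweeps = tuple(
        SweepSpec(
            chrom=s["chrom"],
            start=int(s["start"]),
            end=int(s["end"]),
            group=s["group"],
            f=float(s.get("f", 1.0)),
        )
        for s in d.get("sweeps", [])
    )
    return SimulationConfig(
        chromosomes={str(k): int(v) for k, v in d["chromosomes"].items()},
        groups=tuple(groups),
        snp_density=float(d.get("snp_density", DEFAULT_SNP_DENSITY)),
        freq_range=tuple(d.get("freq_range", DEFAULT_FREQ_RANGE)),  # type: ignore[arg-type]
        error_rate=float(d.get("error_rate", 0.0)),
        sweeps=sweeps,
        seed=int(d.get("seed", 0)),
    )
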