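"""Read multi-sample VCFs, apply site filters, and derive per-group
major/minor allele read counts.

Two sample modes are supported per group: ``pooled`` (allele counts from
the AD read depths of each pool) and ``individual`` (AD when present,
otherwise GT-derived pseudo-counts of 2 allele observations per called
diploid genotype).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Tuple

import numpy as np
from cyvcf2 import VCF

from sweepscan.errors import InputError

logger = logging.getLogger(__name__)

FILTER_RULES = ("allele_class", "mq", "dp", "call_rate")

DEFAULT_THRESHOLDS = {"mq_min": 50.0, "dp_min": 5, "call_rate_min": 0.90}


@dataclass
class GroupAssignment:
    """Maps each VCF sample to a group and records each group's mode."""

    sample_to_group: Dict[str, str]
    group_modes: Dict[str, str]  # group -> "pooled" | "individual"

    def __post_init__(self) -> None:
        for g, mode in self.group_modes.items():
            if mode not in ("pooled", "individual"):
                raise InputError(
                    f"group {g!r}: mode must be 'pooled' or 'individual', "
                    f"got {mode!r}"
                )
        used = set(self.sample_to_group.values())
        for g in self.group_modes:
            if g not in used:
                raise InputError(f"group {g!r} has no samples assigned")
        for s, g in self.sample_to_group.items():
            if g not in self.group_modes:
                raise InputError(f"sample {s!r} assigned to unknown group {g!r}")

    @property
    def groups(self) -> List[str]:
        seen: List[str] = []
        for g in self.sample_to_group.values():
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of(self, group: str) -> List[str]:
        return [s for s, g in self.sample_to_group.items() if g == group]

    @classmethod
    def from_tsv(cls, path: str) -> "GroupAssignment":
        """Parse a 2-3 column TSV: sample, group[, mode]. Mode defaults to
        ``pooled`` and must be consistent within a group."""
        s2g: Dict[str, str] = {}
        modes: Dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise InputError(
                        f"{path}:{lineno}: expected sample<TAB>group[<TAB>mode]"
                    )
                sample, group = parts[0], parts[1]
                mode = parts[2] if len(parts) > 2 else "pooled"
                if sample in s2g:
                    raise InputError(f"{path}:{lineno}: duplicate sample {sample!r}")
                if group in modes and modes[group] != mode:
                    raise InputError(
                        f"{path}:{lineno}: group {group!r} declared with "
                        f"conflicting modes {modes[group]!r} and {mode!r}"
                    )
                s2g[sample] = group
                modes[group] = mode
        if not s2g:
            raise InputError(f"no sample assignments found in {path}")
        return cls(s2g, modes)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for sample, group in self.sample_to_group.items():
                fh.write(f"{sample}\t{group}\t{self.group_modes[group]}\n")


@dataclass
class VariantSite:
    """One VCF record reduced to what the scan needs."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    mq: float | None
    depth: int  # site aggregate depth
    ref_depths: np.ndarray  # per sample, GT pseudo-counts in individual mode
    alt_depths: np.ndarray
    callable_mask: np.ndarray  # per sample
    is_biallelic_snp: bool
    samples: Tuple[str, ...] = field(repr=False, default=())


@dataclass(frozen=True)
class GroupAlleleCounts:
    """Within-group read counts of the most/least abundant allele at a site."""

    group: str
    n_maj: int
    n_min: int
    major_allele: str  # "ref" or "alt"; ties resolve to "ref"
    informative: bool


def read_sites(
    vcf_path: str, assignment: GroupAssignment
) -> Iterator[VariantSite]:
    """Stream :class:`VariantSite` records from a VCF in coordinate order.

    Pooled-mode samples require a FORMAT/AD field; individual-mode samples
    use AD when present, else GT pseudo-counts (each called diploid
    contributes 2 allele observations). Raises :class:`InputError` when a
    VCF sample is missing from the assignment or a required FORMAT field
    is absent for the declared mode.
    """
    vcf = VCF(vcf_path, gts012=True)
    samples = tuple(vcf.samples)
    for s in samples:
        if s not in assignment.sample_to_group:
            raise InputError(
                f"sample {s!r} in {vcf_path} is not present in the group "
                f"assignment"
            )
    sample_mode = np.array(
        [
            assignment.group_modes[assignment.sample_to_group[s]]
            for s in samples
        ]
    )
    pooled_mask = sample_mode == "pooled"
    n = len(samples)
    warned_gt_pseudo = False

    for v in vcf:
        biallelic = (
            len(v.ALT) == 1
            and len(v.REF) == 1
            and len(v.ALT[0]) == 1
            and v.REF[0] in "ACGT"
            and v.ALT[0] in "ACGT"
        )
        ref_d = np.zeros(n, dtype=np.int64)
        alt_d = np.zeros(n, dtype=np.int64)
        callable_mask = np.zeros(n, dtype=bool)

        ad = None
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is not None and ad.shape[1] >= 2:
            ref_col = np.where(ad[:, 0] >= 0, ad[:, 0], 0).astype(np.int64)
            alt_col = np.where(ad[:, 1] >= 0, ad[:, 1], 0).astype(np.int64)
        else:
            if np.any(pooled_mask):
                bad = samples[int(np.nonzero(pooled_mask)[0][0])]
                raise InputError(
                    f"{vcf_path}: record {v.CHROM}:{v.POS} lacks FORMAT/AD "
                    f"required for pooled-mode sample {bad!r}"
                )
            ref_col = alt_col = None

        gts = v.gt_types  # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 missing
        for i in range(n):
            if sample_mode[i] == "pooled":
                ref_d[i] = ref_col[i]
                alt_d[i] = alt_col[i]
                callable_mask[i] = (ref_d[i] + alt_d[i]) > 0
            else:
                called = gts[i] != 3
                if ref_col is not None and (ref_col[i] + alt_col[i]) > 0:
                    ref_d[i] = ref_col[i]
                    alt_d[i] = alt_col[i]
                elif called:
                    # GT pseudo-counts: 2 allele observations per call
                    alt_alleles = int(gts[i])
                    ref_d[i] = 2 - alt_alleles
                    alt_d[i] = alt_alleles
                    if not warned_gt_pseudo:
                        logger.warning(
                            "using GT-derived pseudo-counts (2 per called "
                            "genotype) for individual-mode samples without AD"
                        )
                        warned_gt_pseudo = True
                callable_mask[i] = called
        mq = v.INFO.get("MQ")
        dp = v.INFO.get("DP")
        depth = int(dp) if dp is not None else int(ref_d.sum() + alt_d.sum())
        yield VariantSite(
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alt=v.ALT[0] if v.ALT else ".",
            mq=float(mq) if mq is not None else None,
            depth=depth,
            ref_depths=ref_d,
            alt_depths=alt_d,
            callable_mask=callable_mask,
            is_biallelic_snp=biallelic,
            samples=samples,
        )


def filter_sites(
    sites: Iterable[VariantSite],
    mq_min: float = 50.0,
    dp_min: int = 5,
    call_rate_min: float = 0.90,
) -> Tuple[List[VariantSite], Dict[str, int]]:
    """Apply the site filters; return retained sites and a drop tally.

    Rules, in order of first failure: non-biallelic-SNP allele class,
    mapping quality < ``mq_min``, site depth < ``dp_min``, and call rate
    not exceeding ``call_rate_min`` (strict: a call rate exactly at the
    threshold is dropped). Sites lacking an MQ annotation pass the MQ rule
    (warned once).
    """
    for t in (mq_min, dp_min, call_rate_min):
        if not np.isfinite(t):
            raise InputError("filter thresholds must be finite")
    tally = {rule: 0 for rule in FILTER_RULES}
    retained: List[VariantSite] = []
    warned_mq = False
    for site in sites:
        if not site.is_biallelic_snp:
            tally["allele_class"] += 1
            continue
        if site.mq is None:
            if not warned_mq:
                logger.warning(
                    "site MQ annotation absent; MQ filter passes such sites"
                )
                warned_mq = True
        elif site.mq < mq_min:
            tally["mq"] += 1
            continue
        if site.depth < dp_min:
            tally["dp"] += 1
            continue
        n = site.callable_mask.size
        if n == 0 or site.callable_mask.sum() / n <= call_rate_min:
            tally["call_rate"] += 1
            continue
        retained.append(site)
    return retained, tally


def group_counts(
    site: VariantSite, assignment: GroupAssignment
) -> Dict[str, GroupAlleleCounts]:
    """Per-group (n_MAJ, n_MIN) at one site.

    Ref and alt reads are summed over the group's samples; the larger sum
    is n_MAJ. The major allele may differ between groups at the same site.
    Ties count as n_MAJ = n_MIN with the major label set to "ref".
    """
    out: Dict[str, GroupAlleleCounts] = {}
    sample_groups = [assignment.sample_to_group[s] for s in site.samples]
    for g in assignment.groups:
        mask = np.array([sg == g for sg in sample_groups])
        ref_sum = int(site.ref_depths[mask].sum())
        alt_sum = int(site.alt_depths[mask].sum())
        if alt_sum > ref_sum:
            n_maj, n_min, major = alt_sum, ref_sum, "alt"
        else:
            n_maj, n_min, major = ref_sum, alt_sum, "ref"
        out[g] = GroupAlleleCounts(
            group=g,
            n_maj=n_maj,
            n_min=n_min,
            major_allele=major,
            informative=(n_maj + n_min) > 0,
        )
    return out


def group_count_arrays(
    sites: List[VariantSite], assignment: GroupAssignment
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Vectorized per-group summed (ref, alt) read counts over all sites."""
    groups = assignment.groups
    if not sites:
        return (
            {g: np.zeros(0, dtype=np.int64) for g in groups},
            {g: np.zeros(0, dtype=np.int64) for g in groups},
        )
    samples = sites[0].samples
    masks = {
        g: np.array([assignment.sample_to_group[s] == g for s in samples])
        for g in groups
    }
    ref_mat = np.stack([s.ref_depths for s in sites])
    alt_mat = np.stack([s.alt_depths for s in sites])
    ref = {g: ref_mat[:, m].sum(axis=1) for g, m in masks.items()}
    alt = {g: alt_mat[:, m].sum(axis=1) for g, m in masks.items()}
    return ref, alt
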