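"""Synthetic inputs: genomes, methylation tracks, genetic maps, VCFs, FASTQ.

Every input format the toolkit consumes can be generated here, deterministic
per seed, so the full pipeline is exercisable without any reference data.
The VCF generator is constructive: it emits, alongside the VCF, a truth table
flagging each record against the standard hard filters (QUAL, MQ, scaffold,
indel, biallelic, missing rate, heterozygosity), computed from the
generation-time quantities rather than by re-parsing the file — so filter
tests compare against an exact, independent ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .digestion import Genome, MethylationTrack, xopen

__all__ = [
    "GenomeSpec",
    "VcfSpec",
    "make_genome",
    "make_methylation",
    "make_consensus_map",
    "write_consensus_map",
    "read_consensus_map",
    "make_vcf",
    "make_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters for an i.i.d. random genome.

    ``gc`` may be a single fraction or a (start, end) pair giving a linear
    GC gradient along each sequence (useful for emulating the GC
    heterogeneity that makes single-GC-class cutters uneven).
    """

    n_sequences: int = 1
    length: Union[int, Sequence[int]] = 1_000_000
    gc: Union[float, tuple[float, float]] = 0.5
    seed: int = 0
    name_prefix: str = "chr"

    def __post_init__(self) -> None:
        lengths = self.lengths
        if len(lengths) != self.n_sequences or any(l <= 0 for l in lengths):
            raise ValueError("lengths must be positive, one per sequence")
        gcs = self.gc if isinstance(self.gc, tuple) else (self.gc,)
        if any(not 0.0 <= g <= 1.0 for g in gcs):
            raise ValueError("GC fraction must be in [0, 1]")

    @property
    def lengths(self) -> list[int]:
        if isinstance(self.length, int):
            return [self.length] * self.n_sequences
        return list(self.length)


def _draw_sequence(rng: np.random.Generator, length: int,
                   gc: Union[float, tuple[float, float]]) -> str:
    if isinstance(gc, tuple):
        # Linear gradient: per-base GC probability interpolated along the
        # sequence; A/T and G/C split evenly within their class.
        g = np.linspace(gc[0], gc[1], length)
        u = rng.random(length)
        v = rng.random(length)
        # class: GC with prob g; within class pick first/second base
        is_gc = u < g
        idx = np.where(is_gc, np.where(v < 0.5, 2, 1), np.where(v < 0.5, 0, 3))
    else:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def make_genome(spec: GenomeSpec) -> Genome:
    """Generate an i.i.d. random genome with the spec's GC composition."""
    rng = np.random.default_rng(spec.seed)
    seqs = {}
    for i, length in enumerate(spec.lengths, 1):
        seqs[f"{spec.name_prefix}{i}"] = _draw_sequence(rng, length, spec.gc)
    return Genome(seqs)


def make_methylation(
    genome: Genome, cpg_fraction: float, seed: int = 0
) -> MethylationTrack:
    """Mark each CpG cytosine methylated independently with ``cpg_fraction``.

    Both cytosines of a CpG duplex (the top-strand C and the bottom-strand C
    paired with the following G) are drawn independently, emulating the
    mostly-but-not-perfectly symmetric methylation of plant/animal CpG.
    """
    if not 0.0 <= cpg_fraction <= 1.0:
        raise ValueError("cpg_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    positions: list[tuple[str, int]] = []
    for sid, seq in genome:
        start = 0
        while True:
            i = seq.find("CG", start)
            if i < 0:
                break
            if cpg_fraction >= 1.0 or rng.random() < cpg_fraction:
                positions.append((sid, i))        # top-strand C
            if cpg_fraction >= 1.0 or rng.random() < cpg_fraction:
                positions.append((sid, i + 1))    # bottom-strand C (under the G)
            start = i + 1
    return MethylationTrack.from_positions(genome, positions)


MAP_COLUMNS = ["marker_id", "chrom", "pos_bp", "pos_cM"]


def make_consensus_map(
    chrom_lengths: dict[str, int],
    anchors_per_chrom: int = 50,
    cm_per_mb: float = 2.5,
    seed: int = 0,
    jitter_cm: float = 0.0,
) -> pd.DataFrame:
    """Generate a monotone bp -> cM anchor table per chromosome.

    Anchors are evenly spaced from 0 to the chromosome end; cM positions
    follow the linear ``cm_per_mb`` rate plus truncated jitter that never
    breaks monotonicity.  With ``jitter_cm = 0`` the map is exactly linear,
    so the cM span of a chromosome is cm_per_mb x length / 1e6.
    """
    if cm_per_mb <= 0:
        raise ValueError("cm_per_mb must be positive")
    if anchors_per_chrom < 2:
        raise ValueError("need at least 2 anchors per chromosome")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in chrom_lengths.items():
        bp = np.linspace(0, length, anchors_per_chrom).astype(np.int64)
        bp = np.unique(bp)
        cm = cm_per_mb * bp / 1e6
        if jitter_cm > 0:
            # Truncate jitter to < half the smallest inter-anchor cM step so
            # order is preserved by construction.
            steps = np.diff(cm)
            bound = 0.49 * steps.min() if len(steps) else 0.0
            eps = np.clip(rng.normal(0, jitter_cm, size=len(cm)), -bound, bound)
            eps[0] = max(eps[0], -cm[0])  # keep cM >= 0
            cm = cm + eps
            cm = np.maximum.accumulate(cm)
        for j, (b, c) in enumerate(zip(bp, cm), 1):
            rows.append((f"{chrom}_m{j}", chrom, int(b), float(c)))
    return pd.DataFrame(rows, columns=MAP_COLUMNS)


def write_consensus_map(cmap: pd.DataFrame, path: Union[str, Path]) -> None:
    cmap.to_csv(path, sep="\t", index=False)


def read_consensus_map(path: Union[str, Path]) -> pd.DataFrame:
    cmap = pd.read_csv(path, sep="\t")
    missing = set(MAP_COLUMNS) - set(cmap.columns)
    if missing:
        raise ValueError(f"consensus map missing columns {sorted(missing)}")
    for chrom, grp in cmap.groupby("chrom"):
        g = grp.sort_values("pos_bp")
        if not g["pos_cM"].is_monotonic_increasing:
            raise ValueError(f"consensus map not monotone on {chrom}")
    return cmap


@dataclass(frozen=True)
class VcfSpec:
    """Parameters for a synthetic VCF with constructive filter truth.

    Distribution knobs are kept simple: QUAL and MQ are drawn uniformly from
    stated ranges (choose ranges straddling the filter thresholds to exercise
    both outcomes), per-site missing rates from a uniform range, site MAF
    from a uniform range, and fixed fractions of sites are made indels,
    multiallelic, or placed on unassembled scaffolds.
    """

    n_samples: int = 16
    n_sites: int = 1000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 50_000_000, "chr2": 40_000_000}
    )
    missing_range: tuple[float, float] = (0.0, 0.9)
    het_rate: float = 0.05
    maf_range: tuple[float, float] = (0.05, 0.5)
    indel_fraction: float = 0.1
    multiallelic_fraction: float = 0.05
    scaffold_fraction: float = 0.05
    qual_range: tuple[float, float] = (0.0, 60.0)
    mq_range: tuple[float, float] = (10.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.missing_range, self.maf_range):
            if not (0.0 <= r[0] <= r[1] <= 1.0):
                raise ValueError(f"invalid rate range {r}")
        for f in (self.het_rate, self.indel_fraction,
                  self.multiallelic_fraction, self.scaffold_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.n_samples < 1 or self.n_sites < 1:
            raise ValueError("need >= 1 sample and >= 1 site")


_ALLELES = "ACGT"

# Default hard-filter thresholds used for the constructive truth flags;
# mirror markers.FilterConfig defaults.
_TRUTH_THRESHOLDS = dict(min_qual=10.0, min_mq=30.0, max_missing=0.8, max_het=0.1)


def _truth_reason(qual, mq, scaffold, is_indel, n_alts, missing_rate, het_rate):
    t = _TRUTH_THRESHOLDS
    if qual < t["min_qual"]:
        return "low_qual"
    if mq < t["min_mq"]:
        return "low_mq"
    if scaffold:
        return "scaffold"
    if is_indel:
        return "indel"
    if n_alts != 1:
        return "multiallelic"
    if missing_rate >= t["max_missing"]:
        return "missing"
    if het_rate >= t["max_het"]:
        return "het"
    return "pass"


def make_vcf(
    spec: VcfSpec,
    vcf_path: Union[str, Path],
    truth_path: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Write a synthetic VCF 4.2 and return its per-record truth table.

    The truth table (also written to ``truth_path`` as TSV when given) has
    one row per record with the realised QUAL/MQ/type/missing/het values and
    the first-failing-filter reason code ("pass" if retained), computed from
    the generator's own state.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = list(spec.chrom_lengths)
    scaffold_names = [f"scaffold_{i}" for i in range(1, 4)]

    # Assign sites to chromosomes/scaffolds, then unique sorted positions.
    site_chrom = []
    for _ in range(spec.n_sites):
        if rng.random() < spec.scaffold_fraction:
            site_chrom.append(rng.choice(scaffold_names))
        else:
            site_chrom.append(chroms[int(rng.integers(len(chroms)))])
    positions: dict[str, np.ndarray] = {}
    for chrom in set(site_chrom):
        n = site_chrom.count(chrom)
        length = spec.chrom_lengths.get(chrom, 1_000_000)
        if n >= length:
            raise ValueError(f"more sites than positions on {chrom}")
        chosen: set[int] = set()
        while len(chosen) < n:  # rejection sampling; site density is low
            chosen.update(int(p) for p in rng.integers(1, length, size=n - len(chosen)))
        positions[chrom] = np.sort(np.fromiter(chosen, dtype=np.int64))  # 1-based

    order = sorted(range(spec.n_sites), key=lambda i: (site_chrom[i],))
    taken = {c: 0 for c in positions}

    header_lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in chroms:
        header_lines.append(f"##contig=<ID={chrom},length={spec.chrom_lengths[chrom]}>")
    for s in scaffold_names:
        header_lines.append(f"##contig=<ID={s},length=1000000>")
    samples = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
    header_lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )

    rows = []
    body = []
    for rank, i in enumerate(order):
        chrom = site_chrom[i]
        pos = int(positions[chrom][taken[chrom]])
        taken[chrom] += 1
        scaffold = chrom.startswith("scaffold")
        # round to the precision written to the VCF so the truth flags are
        # computed on exactly the values a reader will see
        qual = round(float(rng.uniform(*spec.qual_range)), 2)
        mq = round(float(rng.uniform(*spec.mq_range)), 2)
        u = rng.random()
        is_indel = u < spec.indel_fraction
        is_multi = (not is_indel) and u < spec.indel_fraction + spec.multiallelic_fraction
        ref_i = int(rng.integers(4))
        ref = _ALLELES[ref_i]
        alt_pool = [a for a in _ALLELES if a != ref]
        if is_indel:
            # insertion or deletion of one base
            if rng.random() < 0.5:
                alts = [ref + alt_pool[int(rng.integers(3))]]
            else:
                ref = ref + alt_pool[int(rng.integers(3))]
                alts = [ref[0]]
        elif is_multi:
            alts = list(rng.choice(alt_pool, size=2, replace=False))
        else:
            alts = [alt_pool[int(rng.integers(3))]]
        n_alts = len(alts)

        maf = float(rng.uniform(*spec.maf_range))
        miss_p = float(rng.uniform(*spec.missing_range))
        gts = []
        n_missing = n_het = 0
        for _s in range(spec.n_samples):
            if rng.random() < miss_p:
                gts.append("./.")
                n_missing += 1
            elif rng.random() < spec.het_rate:
                gts.append("0/1")
                n_het += 1
            else:
                # homozygous; alt homozygote with prob ~ maf
                if rng.random() < maf:
                    a = 1 if n_alts == 1 else int(rng.integers(1, n_alts + 1))
                    gts.append(f"{a}/{a}")
                else:
                    gts.append("0/0")
        n_called = spec.n_samples - n_missing
        missing_rate = n_missing / spec.n_samples
        het_rate = n_het / n_called if n_called else 0.0
        reason = _truth_reason(
            qual, mq, scaffold, is_indel, n_alts, missing_rate, het_rate
        )
        vid = f"site{rank + 1}"
        body.append(
            f"{chrom}\t{pos}\t{vid}\t{ref}\t{','.join(alts)}\t{qual:.2f}\t.\t"
            f"MQ={mq:.2f}\tGT\t" + "\t".join(gts)
        )
        rows.append(
            dict(
                id=vid, chrom=chrom, pos=pos, qual=round(qual, 2), mq=round(mq, 2),
                is_indel=is_indel, n_alts=n_alts,
                missing_rate=missing_rate, het_rate=het_rate,
                reason=reason, passed=reason == "pass",
            )
        )

    with xopen(vcf_path, "wt") as fh:
        fh.write("\n".join(header_lines) + "\n")
        fh.write("\n".join(body) + "\n")
    truth = pd.DataFrame(rows)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


def make_fastq(
    path: Union[str, Path],
    n_records: int,
    read_length: int = 100,
    seed: int = 0,
) -> None:
    """Write a synthetic FASTQ of uniform-random reads (constant quality)."""
    rng = np.random.default_rng(seed)
    with xopen(path, "wt") as fh:
        for i in range(n_records):
            seq = _BASES[rng.integers(0, 4, size=read_length)].tobytes().decode()
            fh.write(f"@read{i + 1}\n{seq}\n+\n{'I' * read_length}\n")
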