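"""Variant filtering and marker-distribution / diversity diagnostics.

Covers the post-calling half of a GBS protocol evaluation: hard-filtering a
VCF (quality, mapping quality, scaffolds, indels, biallelicity, missing
rate, heterozygosity), marker densities and gap inventories on physical (bp)
and genetic (cM) coordinates, per-site diversity statistics (missing, het,
MAF, nucleotide diversity), identity-by-state pairwise distances, and
polymorphic-marker counts for candidate biparental crosses.

VCF positions are 1-based throughout this module (VCF convention); the
digestion half of the package is 0-based, and the two never mix coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "FilterConfig",
    "GapReport",
    "MarkerReport",
    "DiversityStats",
    "read_vcf",
    "filter_variants",
    "density_and_gaps",
    "assign_genetic_positions",
    "genetic_density_and_gaps",
    "diversity_stats",
    "ibs_distance_matrix",
    "count_polymorphic_pair",
]

MISSING = -1  # allele code for a missing call


@dataclass(frozen=True)
class VariantRecord:
    """One VCF record with diploid genotypes as an (n_samples, 2) array."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: Optional[float]
    mq: Optional[float]
    genotypes: np.ndarray  # int8/int16, MISSING (-1) for no call

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (VCF convention)")
        if not self.ref or any(not a for a in self.alts):
            raise ValueError("allele strings must be non-empty")
        gt = np.asarray(self.genotypes)
        if gt.ndim != 2 or gt.shape[1] != 2:
            raise ValueError("genotypes must have shape (n_samples, 2)")
        object.__setattr__(self, "genotypes", gt)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        return (self.genotypes < 0).any(axis=1)

    @property
    def missing_rate(self) -> float:
        return float(self.missing_mask.mean())

    @property
    def het_rate(self) -> float:
        """Heterozygosity among non-missing calls (0 if none are called)."""
        called = self.genotypes[~self.missing_mask]
        if len(called) == 0:
            return 0.0
        return float((called[:, 0] != called[:, 1]).mean())

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or any(len(a) != 1 for a in self.alts)


def read_vcf(path: Union[str, Path]) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF into VariantRecord objects; returns (records, sample names)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    for v in vcf:
        gts = np.array([g[:2] for g in v.genotypes], dtype=np.int16)
        mq = v.INFO.get("MQ")
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                qual=v.QUAL,
                mq=float(mq) if mq is not None else None,
                genotypes=gts,
            )
        )
    vcf.close()
    return records, samples


@dataclass(frozen=True)
class FilterConfig:
    """Hard-filter thresholds for SNP retention.

    Defaults implement the common GBS post-calling filter: drop QUAL < 10 or
    MQ < 30, unassembled scaffolds and indels, keep only biallelic markers
    with missing rate < 0.8 and site heterozygosity < 0.1 (strict
    inequalities on retention).  ``qual_mq_mode`` selects whether a record
    fails when either quality rule trips ("either", default) or only when
    both do ("both").
    """

    min_qual: float = 10.0
    min_mq: float = 30.0
    max_missing_rate: float = 0.8
    max_het_rate: float = 0.1
    allowed_chromosomes: Optional[frozenset[str]] = None
    scaffold_pattern: str = "scaffold"
    biallelic_only: bool = True
    drop_indels: bool = True
    qual_mq_mode: str = "either"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must be in [0, 1]")
        if not 0.0 <= self.max_het_rate <= 1.0:
            raise ValueError("max_het_rate must be in [0, 1]")
        if self.min_qual < 0 or self.min_mq < 0:
            raise ValueError("quality thresholds must be >= 0")
        if self.qual_mq_mode not in ("either", "both"):
            raise ValueError("qual_mq_mode must be 'either' or 'both'")
        if self.allowed_chromosomes is not None:
            object.__setattr__(
                self, "allowed_chromosomes", frozenset(self.allowed_chromosomes)
            )

    def chrom_allowed(self, chrom: str) -> bool:
        if self.allowed_chromosomes is not None:
            return chrom in self.allowed_chromosomes
        return self.scaffold_pattern.lower() not in chrom.lower()


def _first_reason(rec: VariantRecord, cfg: FilterConfig) -> str:
    """First failing rule, in the order QUAL, MQ, chrom, indel, biallelic,
    missing, het; 'pass' if none fail.  Missing QUAL/MQ fail (conservative)."""
    qual_fail = rec.qual is None or rec.qual < cfg.min_qual
    mq_fail = rec.mq is None or rec.mq < cfg.min_mq
    if cfg.qual_mq_mode == "both":
        if qual_fail and mq_fail:
            return "low_qual_mq"
    else:
        if qual_fail:
            return "low_qual"
        if mq_fail:
            return "low_mq"
    if not cfg.chrom_allowed(rec.chrom):
        return "scaffold"
    if cfg.drop_indels and rec.is_indel:
        return "indel"
    if cfg.biallelic_only and len(rec.alts) != 1:
        return "multiallelic"
    if rec.missing_rate >= cfg.max_missing_rate:
        return "missing"
    if rec.het_rate >= cfg.max_het_rate:
        return "het"
    return "pass"


def filter_variants(
    records: Sequence[VariantRecord], config: FilterConfig = FilterConfig()
) -> tuple[list[VariantRecord], list[str]]:
    """Apply the hard filters; returns (retained records, per-record reasons).

    The reasons list is parallel to the input and holds the first failing
    rule code, or "pass" for retained records.
    """
    reasons = [_first_reason(r, config) for r in records]
    retained = [r for r, why in zip(records, reasons) if why == "pass"]
    return retained, reasons


@dataclass
class GapReport:
    """Gaps (consecutive-marker distances > threshold) at one threshold."""

    threshold: float
    count: int
    gaps: list[tuple[str, float, float, float]]  # (chrom, left, right, size)


@dataclass
class MarkerReport:
    """Marker counts, densities and gap inventories on one coordinate system."""

    unit: str  # "bp" or "cM"
    n_markers: int
    total_span: float
    density: float  # markers per Mb (physical) or per cM (genetic)
    per_chromosome: pd.DataFrame
    gap_reports: dict[float, GapReport]

    def gap_count(self, threshold: float) -> int:
        return self.gap_reports[threshold].count


def _gap_scan(
    positions_by_chrom: dict[str, np.ndarray],
    spans: dict[str, float],
    thresholds: Sequence[float],
    include_ends: bool,
) -> dict[float, GapReport]:
    reports: dict[float, GapReport] = {}
    for thr in thresholds:
        gaps = []
        for chrom, pos in positions_by_chrom.items():
            if len(pos) == 0:
                continue
            pts = pos.astype(float)
            if include_ends:
                pts = np.concatenate([[0.0], pts, [float(spans[chrom])]])
            diffs = np.diff(pts)
            for i in np.nonzero(diffs > thr)[0]:
                gaps.append((chrom, float(pts[i]), float(pts[i + 1]), float(diffs[i])))
        reports[thr] = GapReport(threshold=thr, count=len(gaps), gaps=gaps)
    return reports


def _density_report(
    positions_by_chrom: dict[str, np.ndarray],
    spans: dict[str, float],
    thresholds: Sequence[float],
    include_ends: bool,
    unit: str,
    density_scale: float,
) -> MarkerReport:
    norm: dict[str, np.ndarray] = {}
    for chrom, pos in positions_by_chrom.items():
        arr = np.asarray(pos, dtype=float)
        if len(arr):
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"positions on {chrom} must be sorted")
            if np.any(np.diff(arr) == 0):
                raise ValueError(f"duplicate positions on {chrom}")
            if chrom not in spans:
                raise ValueError(f"no span given for {chrom}")
            if arr[-1] > spans[chrom]:
                raise ValueError(
                    f"marker at {arr[-1]} beyond {chrom} span {spans[chrom]}"
                )
        norm[chrom] = arr
    n_total = sum(len(a) for a in norm.values())
    total_span = float(sum(spans.values()))
    if total_span <= 0:
        raise ValueError("total span must be positive")
    density = n_total / (total_span / density_scale)
    rows = []
    for chrom in spans:
        pos = norm.get(chrom, np.array([]))
        rows.append(
            dict(
                chrom=chrom,
                n_markers=len(pos),
                span=spans[chrom],
                density=len(pos) / (spans[chrom] / density_scale),
            )
        )
    per_chrom = pd.DataFrame(rows)
    gap_reports = _gap_scan(norm, spans, thresholds, include_ends)
    counts = [gap_reports[t].count for t in sorted(gap_reports)]
    assert counts == sorted(counts, reverse=True), "gap counts must be anti-monotone"
    return MarkerReport(
        unit=unit,
        n_markers=n_total,
        total_span=total_span,
        density=density,
        per_chromosome=per_chrom,
        gap_reports=gap_reports,
    )


def density_and_gaps(
    positions_by_chrom: dict[str, Sequence[int]],
    chrom_lengths: dict[str, int],
    thresholds: Sequence[float] = (5e6, 10e6),
    include_ends: bool = False,
) -> MarkerReport:
    """Physical-map marker density (SNP/Mb) and gap inventory.

    A gap is a distance between consecutive markers on one chromosome
    strictly greater than the threshold.  By default distances from
    chromosome ends to the terminal markers are not counted
    (``include_ends=True`` adds them).
    """
    pos = {c: np.asarray(p, dtype=np.int64) for c, p in positions_by_chrom.items()}
    spans = {c: float(l) for c, l in chrom_lengths.items()}
    return _density_report(pos, spans, thresholds, include_ends, "bp", 1e6)


def genetic_density_and_gaps(
    cm_by_chrom: dict[str, Sequence[float]],
    map_spans: dict[str, float],
    thresholds: Sequence[float] = (10.0, 20.0),
    include_ends: bool = False,
) -> MarkerReport:
    """Genetic-map marker density (SNP/cM) and gap inventory; cM coordinates."""
    pos = {c: np.asarray(sorted(p), dtype=float) for c, p in cm_by_chrom.items()}
    spans = {c: float(s) for c, s in map_spans.items()}
    return _density_report(pos, spans, thresholds, include_ends, "cM", 1.0)


def assign_genetic_positions(
    markers: dict[str, Sequence[int]],
    consensus_map: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each marker the cM of its nearest map anchor (by |bp| distance).

    Ties (marker exactly midway between two anchors) resolve toward the
    smaller-bp anchor.  Markers on chromosomes absent from the map are
    returned with ``placed=False`` and NaN cM.
    """
    out_rows = []
    anchors = {
        chrom: grp.sort_values("pos_bp")[["pos_bp", "pos_cM"]].to_numpy()
        for chrom, grp in consensus_map.groupby("chrom")
    }
    for chrom, positions in markers.items():
        pos_arr = np.asarray(positions, dtype=np.int64)
        if chrom not in anchors:
            for p in pos_arr:
                out_rows.append(dict(chrom=chrom, pos_bp=int(p), pos_cM=np.nan, placed=False))
            continue
        a_bp = anchors[chrom][:, 0]
        a_cm = anchors[chrom][:, 1]
        idx = np.searchsorted(a_bp, pos_arr)
        for p, i in zip(pos_arr, idx):
            if i == 0:
                j = 0
            elif i == len(a_bp):
                j = len(a_bp) - 1
            else:
                left, right = a_bp[i - 1], a_bp[i]
                # tie (equidistant) goes to the smaller-bp anchor
                j = i - 1 if (p - left) <= (right - p) else i
            out_rows.append(
                dict(chrom=chrom, pos_bp=int(p), pos_cM=float(a_cm[j]), placed=True)
            )
    return pd.DataFrame(out_rows)


@dataclass
class DiversityStats:
    """Genome-wide diversity summary over filtered sites."""

    missing_rate: float          # fraction of missing calls, all sites x samples
    het_rate: float              # heterozygous fraction among non-missing calls
    mean_maf: float              # mean per-site minor-allele frequency
    mean_pi: float               # mean per-site nucleotide diversity
    n_sites: int
    n_sites_skipped: int         # all-missing sites excluded from MAF/pi


def diversity_stats(records: Sequence[VariantRecord]) -> DiversityStats:
    """Missing/het rates, mean MAF and mean per-site nucleotide diversity.

    Per site, allele frequency p is computed from non-missing alleles; the
    nucleotide diversity uses the small-sample-corrected estimator
    pi = 2 p (1-p) n / (n-1) with n the number of non-missing alleles.
    All-missing sites contribute to the missing rate but are skipped for
    MAF/pi (logged).
    """
    if not records:
        raise ValueError("need at least one record")
    if records[0].n_samples < 2:
        raise ValueError("need at least two samples")
    n_missing = n_calls = n_het = n_nonmissing_calls = 0
    mafs, pis = [], []
    skipped = 0
    for rec in records:
        miss = rec.missing_mask
        n_calls += rec.n_samples
        n_missing += int(miss.sum())
        called = rec.genotypes[~miss]
        n_nonmissing_calls += len(called)
        if len(called) == 0:
            skipped += 1
            continue
        n_het += int((called[:, 0] != called[:, 1]).sum())
        alleles = called.ravel()
        n = len(alleles)
        p_alt = float((alleles > 0).mean())
        maf = min(p_alt, 1.0 - p_alt)
        mafs.append(maf)
        if n > 1:
            pis.append(2.0 * p_alt * (1.0 - p_alt) * n / (n - 1))
        else:
            pis.append(0.0)
    if skipped:
        logger.info("diversity_stats: %d all-missing sites skipped for MAF/pi", skipped)
    return DiversityStats(
        missing_rate=n_missing / n_calls,
        het_rate=(n_het / n_nonmissing_calls) if n_nonmissing_calls else 0.0,
        mean_maf=float(np.mean(mafs)) if mafs else 0.0,
        mean_pi=float(np.mean(pis)) if pis else 0.0,
        n_sites=len(records),
        n_sites_skipped=skipped,
    )


def _shared_alleles(g1: np.ndarray, g2: np.ndarray) -> int:
    """Number of alleles shared between two diploid genotypes (0, 1 or 2),
    counting multiset intersection: AA vs AT -> 1, AT vs AT -> 2."""
    a, b = sorted(g1.tolist()), sorted(g2.tolist())
    shared = 0
    i = j = 0
    while i < 2 and j < 2:
        if a[i] == b[j]:
            shared += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return shared


def ibs_distance_matrix(
    records: Sequence[VariantRecord], samples: Sequence[str]
) -> pd.DataFrame:
    """Pairwise identity-by-state distances: 1 - mean shared-allele fraction.

    distance(a, b) averages (shared alleles)/2 over sites where both samples
    are called, subtracted from 1.  Pairs with no comparable site are NaN.
    The diagonal is 0 and the matrix symmetric by construction.
    """
    n = len(samples)
    if n < 2:
        raise ValueError("need at least two samples")
    sim_sum = np.zeros((n, n))
    comparable = np.zeros((n, n), dtype=np.int64)
    for rec in records:
        gt = rec.genotypes
        called = ~rec.missing_mask
        idx = np.nonzero(called)[0]
        for ii in range(len(idx)):
            for jj in range(ii + 1, len(idx)):
                a, b = idx[ii], idx[jj]
                s = _shared_alleles(gt[a], gt[b]) / 2.0
                sim_sum[a, b] += s
                comparable[a, b] += 1
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            if comparable[a, b] == 0:
                dist[a, b] = dist[b, a] = np.nan
            else:
                d = 1.0 - sim_sum[a, b] / comparable[a, b]
                dist[a, b] = dist[b, a] = d
    return pd.DataFrame(dist, index=list(samples), columns=list(samples))


def count_polymorphic_pair(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    sample_a: str,
    sample_b: str,
    genome_length: Optional[int] = None,
    map_length_cm: Optional[float] = None,
) -> dict:
    """Markers discriminating two accessions: both called, genotypes differ.

    This is the usable marker count for a biparental cross between the two.
    Densities per Mb / per cM are included when the respective span is given.
    """
    try:
        ia, ib = list(samples).index(sample_a), list(samples).index(sample_b)
    except ValueError as e:
        raise KeyError(f"unknown sample: {e}")
    count = 0
    for rec in records:
        ga, gb = rec.genotypes[ia], rec.genotypes[ib]
        if (ga < 0).any() or (gb < 0).any():
            continue
        if sorted(ga.tolist()) != sorted(gb.tolist()):
            count += 1
    out = {"sample_a": sample_a, "sample_b": sample_b, "polymorphic_count": count}
    if genome_length:
        out["per_mb"] = count / (genome_length / 1e6)
    if map_length_cm:
        out["per_cm"] = count / map_length_cm
    return out
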