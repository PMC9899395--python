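"""Library-selection model, read budgets and read-sampling simulation.

The three-enzyme GBS selection rule: a fragment is sequenced only if one end
was cut by a rare cutter whose overhang matches the 5' adapter (PstI or NsiI
by default), the other end by the frequent cutter matching the 3' adapter
(MspI), and its length falls inside the size-selection window (50-350 bp by
default).  From the selected fragment count F and a per-sample read budget N
the expected per-fragment depth is lambda = N/F; under a Poisson model the
dropout (missing-genotype) probability at a locus is exp(-lambda), and
P(depth < d) is the Poisson CDF at d-1.  These closed forms drive the
multiplexing arithmetic; :func:`simulate_reads` provides the exact
multinomial forward model for cross-checking them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .digestion import Fragment, TERMINUS, xopen

__all__ = [
    "LibraryDesign",
    "LibraryPrediction",
    "BudgetResult",
    "ReadSimulation",
    "select_fragments",
    "predict_library",
    "wgs_depth",
    "budget",
    "reads_for_target_depth",
    "percent_reduction",
    "simulate_reads",
    "subsample_fastq",
]


@dataclass(frozen=True)
class LibraryDesign:
    """Adapter compatibility and size selection for a GBS library.

    ``rare_set`` are the enzymes whose common overhang matches the 5'
    adapter; ``frequent_cutter`` matches the 3' adapter.  ``size_window`` is
    the inclusive insert-length interval kept by size selection;
    ``adapter_extension`` is added to the insert length before windowing for
    users whose window is quoted on the adapter-ligated molecule.
    """

    rare_set: frozenset[str] = frozenset({"PstI", "NsiI"})
    frequent_cutter: str = "MspI"
    size_window: tuple[int, int] = (50, 350)
    adapter_extension: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rare_set", frozenset(self.rare_set))
        if not self.rare_set:
            # single-enzyme protocol (classic one-cutter GBS): both adapters
            # ligate to the frequent cutter's overhang
            object.__setattr__(self, "rare_set", frozenset({self.frequent_cutter}))
        if self.frequent_cutter in self.rare_set and len(self.rare_set) > 1:
            raise ValueError(
                "frequent_cutter may coincide with rare_set only in the "
                "single-enzyme case"
            )
        lo, hi = self.size_window
        if lo < 1 or lo > hi:
            raise ValueError(f"invalid size window [{lo}, {hi}]")
        if self.adapter_extension < 0:
            raise ValueError("adapter_extension must be >= 0")

    @property
    def single_enzyme(self) -> bool:
        return self.rare_set == frozenset({self.frequent_cutter})


@dataclass
class LibraryPrediction:
    """Predicted library content for a fragment set under a design."""

    fragment_count: int
    captured_bases: int
    genome_length: int
    coverage_fraction: float
    per_sequence: dict[str, dict[str, float]]
    pair_counts: dict[str, int]       # e.g. {"PstI--MspI": 123, ...}
    pair_proportions: dict[str, float]


@dataclass
class BudgetResult:
    """Read-budget arithmetic for one reads-per-sample choice."""

    reads_per_sample: int
    fragment_count: int
    expected_depth: float            # lambda = N / F
    dropout_probability: float       # P(depth = 0) = exp(-lambda)
    min_depth: int
    p_below_min_depth: float         # P(depth < d), Poisson CDF at d-1
    multiplex_capacity: Optional[int] = None


def _known_enzymes(fragments: Iterable[Fragment]) -> set[str]:
    names = set()
    for fr in fragments:
        names.add(fr.left_label)
        names.add(fr.right_label)
    names.discard(TERMINUS)
    return names


def select_fragments(
    fragments: Sequence[Fragment], design: LibraryDesign
) -> list[Fragment]:
    """Apply adapter compatibility and size selection to a fragment set.

    Retains exactly the fragments with one end in ``design.rare_set`` and the
    other equal to ``design.frequent_cutter`` (either orientation), whose
    insert length plus ``adapter_extension`` lies inside ``size_window``.
    Terminus-ended, rare-rare and frequent-frequent fragments are excluded:
    they never receive both adapters.
    """
    known = _known_enzymes(fragments)
    missing = (design.rare_set | {design.frequent_cutter}) - known
    if fragments and missing == design.rare_set | {design.frequent_cutter}:
        # All design enzymes absent from the digest is almost certainly a
        # mismatched enzyme set; a partial overlap is legitimate (an enzyme
        # may simply never cut).
        raise ValueError(
            f"design enzymes {sorted(missing)} do not appear in the fragment set"
        )
    lo, hi = design.size_window
    selected = []
    for fr in fragments:
        ends = (fr.left_label, fr.right_label)
        rare_then_freq = ends[0] in design.rare_set and ends[1] == design.frequent_cutter
        freq_then_rare = ends[1] in design.rare_set and ends[0] == design.frequent_cutter
        if not (rare_then_freq or freq_then_rare):
            continue
        if lo <= fr.length + design.adapter_extension <= hi:
            selected.append(fr)
    return selected


def _pair_key(fr: Fragment, design: LibraryDesign) -> str:
    rare = fr.left_label if fr.left_label in design.rare_set else fr.right_label
    return f"{rare}--{design.frequent_cutter}"


def predict_library(
    fragments: Sequence[Fragment],
    design: LibraryDesign,
    genome_length: int,
) -> LibraryPrediction:
    """Predict genome coverage and end-pair composition of the library.

    ``coverage_fraction`` is the summed insert length of selected fragments
    divided by the genome length — the fraction of the genome the protocol
    captures.  Pair proportions split the library into rare-cutter classes
    (e.g. PstI--MspI vs NsiI--MspI), the composition the design aims to
    balance across GC/methylation compartments.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    selected = select_fragments(fragments, design)
    captured = sum(fr.length for fr in selected)
    per_seq: dict[str, dict[str, float]] = {}
    pair_counts: dict[str, int] = {f"{r}--{design.frequent_cutter}": 0 for r in sorted(design.rare_set)}
    for fr in selected:
        d = per_seq.setdefault(fr.sequence_id, {"fragment_count": 0, "captured_bases": 0})
        d["fragment_count"] += 1
        d["captured_bases"] += fr.length
        pair_counts[_pair_key(fr, design)] += 1
    total = len(selected)
    proportions = {
        k: (v / total if total else 0.0) for k, v in pair_counts.items()
    }
    return LibraryPrediction(
        fragment_count=total,
        captured_bases=captured,
        genome_length=genome_length,
        coverage_fraction=captured / genome_length,
        per_sequence=per_seq,
        pair_counts=pair_counts,
        pair_proportions=proportions,
    )


def wgs_depth(reads: int, read_length: int, genome_length: int) -> float:
    """Mean fold coverage of whole-genome shotgun sequencing.

    reads x read_length / genome_length; e.g. one million 100-bp reads give
    0.1X on a 1 Gb genome — the skim-sequencing regime a reduced-
    representation design is competing against.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if reads < 0 or read_length < 0:
        raise ValueError("reads and read_length must be non-negative")
    return reads * read_length / genome_length


def budget(
    fragment_count: int,
    reads_per_sample: int,
    min_depth: int = 2,
    run_capacity: Optional[int] = None,
) -> BudgetResult:
    """Poisson read-budget arithmetic for a selected fragment set.

    With N reads spread over F fragments the per-fragment depth is
    lambda = N/F; dropout (zero reads at a fragment) has probability
    exp(-lambda) and P(depth < min_depth) is the Poisson CDF at
    min_depth - 1.  ``multiplex_capacity`` is floor(run_capacity / N).
    """
    if fragment_count <= 0:
        raise ValueError("fragment_count must be positive")
    if reads_per_sample < 0:
        raise ValueError("reads_per_sample must be >= 0")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    lam = reads_per_sample / fragment_count
    dropout = math.exp(-lam)
    p_below = float(stats.poisson.cdf(min_depth - 1, lam)) if lam > 0 else 1.0
    capacity = None
    if run_capacity is not None:
        if reads_per_sample == 0:
            raise ValueError("run capacity undefined at zero reads per sample")
        capacity = int(run_capacity // reads_per_sample)
    return BudgetResult(
        reads_per_sample=reads_per_sample,
        fragment_count=fragment_count,
        expected_depth=lam,
        dropout_probability=dropout,
        min_depth=min_depth,
        p_below_min_depth=p_below,
        multiplex_capacity=capacity,
    )


def reads_for_target_depth(fragment_count: int, target_depth: float) -> int:
    """Inverse budget: reads per sample needed for a target mean depth.

    Returns ceil(target_depth x F), the smallest N with N/F >= target_depth.
    """
    if fragment_count <= 0:
        raise ValueError("fragment_count must be positive")
    if target_depth < 0:
        raise ValueError("target_depth must be >= 0")
    return math.ceil(target_depth * fragment_count)


def percent_reduction(old_reads: int, new_reads: int) -> int:
    """Percentage reduction in reads per sample, rounded half away from zero.

    percent_reduction(1_200_000, 100_000) == 92; (1_400_000, 200_000) == 86.
    """
    if old_reads <= 0:
        raise ValueError("old_reads must be positive")
    x = 100.0 * (1.0 - new_reads / old_reads)
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ReadSimulation:
    """Per-fragment read counts from a multinomial sampling model."""

    counts: np.ndarray
    mean_depth: float
    zero_fraction: float
    min_depth: int
    below_min_depth_fraction: float


def simulate_reads(
    selected: Union[Sequence[Fragment], int],
    n_reads: int,
    bias_dispersion: float = 0.0,
    min_depth: int = 2,
    seed: int = 0,
) -> ReadSimulation:
    """Draw per-fragment read counts for one sample.

    Fragment sampling weights are uniform when ``bias_dispersion`` is 0,
    otherwise log-normal with sigma = bias_dispersion (renormalised) to
    emulate amplification bias; counts are multinomial(n_reads, weights).
    ``selected`` may be a fragment list or simply the fragment count.
    Deterministic given the seed.
    """
    n_frag = selected if isinstance(selected, int) else len(selected)
    if n_frag <= 0:
        raise ValueError("need at least one selected fragment")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if bias_dispersion < 0:
        raise ValueError("bias_dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    if bias_dispersion == 0:
        weights = np.full(n_frag, 1.0 / n_frag)
    else:
        weights = rng.lognormal(mean=0.0, sigma=bias_dispersion, size=n_frag)
        weights /= weights.sum()
    counts = rng.multinomial(n_reads, weights)
    return ReadSimulation(
        counts=counts,
        mean_depth=float(counts.mean()),
        zero_fraction=float(np.mean(counts == 0)),
        min_depth=min_depth,
        below_min_depth_fraction=float(np.mean(counts < min_depth)),
    )


def _parse_fastq(handle: IO) -> list[tuple[str, str, str, str]]:
    records = []
    lines = []
    for raw in handle:
        lines.append(raw.rstrip("\n"))
        if len(lines) == 4:
            head, seq, plus, qual = lines
            idx = len(records)
            if not head.startswith("@"):
                raise ValueError(f"record {idx}: header does not start with '@'")
            if not plus.startswith("+"):
                raise ValueError(f"record {idx}: separator line does not start with '+'")
            if len(seq) != len(qual):
                raise ValueError(f"record {idx}: sequence/quality length mismatch")
            records.append((head, seq, plus, qual))
            lines = []
    if lines:
        raise ValueError(f"record {len(records)}: truncated record (got {len(lines)} lines)")
    return records


def subsample_fastq(
    source: Union[str, Path, IO],
    k: int,
    seed: int = 0,
    out: Optional[Union[str, Path, IO]] = None,
) -> Optional[list[str]]:
    """Uniform, order-preserving sample of ``min(k, total)`` FASTQ records.

    Sampling is without replacement and deterministic for identical
    (input, k, seed).  When ``out`` is given the sample is written there
    (gzip-transparent) and None is returned; otherwise the selected records
    are returned as a list of 4-line strings.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if isinstance(source, (str, Path)):
        with xopen(source) as fh:
            records = _parse_fastq(fh)
    else:
        records = _parse_fastq(source)
    n = len(records)
    take = min(k, n)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=take, replace=False)) if take else np.array([], int)
    chosen = ["\n".join(records[i]) + "\n" for i in idx]
    if out is None:
        return chosen
    if isinstance(out, (str, Path)):
        with xopen(out, "wt") as fh:
            fh.writelines(chosen)
    else:
        out.writelines(chosen)
    return None
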