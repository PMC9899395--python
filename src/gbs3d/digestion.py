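"""In-silico restriction digestion: site scanning and fragment assembly.

Scans a genome's top strand for the IUPAC recognition sites of one or more
(palindromic) enzymes, optionally suppressing sites blocked by cytosine
methylation, and cuts each sequence into fragments labelled at both ends by
the enzyme that produced the boundary.  Fragment end labels are what the
library-selection model keys on: only rare-cutter/frequent-cutter fragments
receive both sequencing adapters.

All coordinates are 0-based, half-open.  A cut site's ``coordinate`` is the
position the cut falls *before*, i.e. ``site_start + cut_offset``.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, NamedTuple, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

from .enzymes import Enzyme, IUPAC_EXPANSIONS, is_palindromic

logger = logging.getLogger(__name__)

__all__ = [
    "TERMINUS",
    "Genome",
    "MethylationTrack",
    "CutSite",
    "Fragment",
    "find_cut_sites",
    "digest",
    "evaluate_combinations",
    "write_fragments_bed",
    "write_cut_sites_bed",
]

#: End label used for chromosome termini (no enzyme cut the boundary).
TERMINUS = "TERMINUS"

_VALID_BASES = set("ACGTN")


def xopen(path: Union[str, Path], mode: str = "rt") -> IO:
    """Open a file, transparently decompressing ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class Genome:
    """An ordered collection of named sequences over the ACGTN alphabet."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        norm: dict[str, str] = {}
        for sid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"sequence {sid!r} is empty")
            seq = seq.upper()
            extra = set(seq) - _VALID_BASES
            if extra:
                # Ambiguity codes in references are rare; treat them as N.
                logger.warning(
                    "sequence %s: %d non-ACGTN characters replaced by N",
                    sid, sum(seq.count(c) for c in extra),
                )
                seq = re.sub(f"[{''.join(re.escape(c) for c in extra)}]", "N", seq)
            norm[sid] = seq
        self.sequences = norm

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {sid: len(seq) for sid, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __getitem__(self, sid: str) -> str:
        return self.sequences[sid]

    def __iter__(self):
        return iter(self.sequences.items())

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "Genome":
        with xopen(path) as fh:
            seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
        if not seqs:
            raise ValueError(f"no sequences found in {path}")
        return cls(seqs)

    def to_fasta(self, path: Union[str, Path], width: int = 80) -> None:
        with xopen(path, "wt") as fh:
            for sid, seq in self.sequences.items():
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


class MethylationTrack:
    """Positions of methylated cytosines, strand-aware.

    Input positions may point at a top-strand ``C`` or at a ``G`` whose
    paired bottom-strand base is the methylated cytosine; both encodings are
    accepted and normalised to (sequence_id, position, strand) records.  For
    blocking decisions only the position matters: a fully methylation-
    sensitive enzyme is blocked whenever any methylated cytosine (either
    strand) falls inside the matched duplex site.
    """

    def __init__(self, records: Iterable[tuple[str, int, str]] = ()) -> None:
        self._records: set[tuple[str, int, str]] = set(records)
        self._by_seq: dict[str, np.ndarray] = {}
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        by_seq: dict[str, set[int]] = {}
        for sid, pos, _strand in self._records:
            by_seq.setdefault(sid, set()).add(pos)
        self._by_seq = {
            sid: np.array(sorted(ps), dtype=np.int64) for sid, ps in by_seq.items()
        }

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, key: tuple[str, int]) -> bool:
        sid, pos = key
        arr = self._by_seq.get(sid)
        if arr is None:
            return False
        i = int(np.searchsorted(arr, pos))
        return i < len(arr) and arr[i] == pos

    def any_in(self, sid: str, start: int, end: int) -> bool:
        """True if any methylated cytosine lies in [start, end)."""
        arr = self._by_seq.get(sid)
        if arr is None or len(arr) == 0:
            return False
        i = int(np.searchsorted(arr, start))
        return i < len(arr) and arr[i] < end

    @classmethod
    def from_positions(
        cls, genome: Genome, positions: Iterable[tuple[str, int]]
    ) -> "MethylationTrack":
        """Normalise (sequence_id, pos) pairs against the genome.

        Positions on a C are top-strand records; on a G, bottom-strand
        records (the methylated C is the paired base).  Anything else is
        rejected.
        """
        records = []
        for sid, pos in positions:
            seq = genome[sid]
            if not 0 <= pos < len(seq):
                raise ValueError(f"methylation position {sid}:{pos} out of bounds")
            base = seq[pos]
            if base == "C":
                records.append((sid, pos, "+"))
            elif base == "G":
                records.append((sid, pos, "-"))
            else:
                raise ValueError(
                    f"methylation position {sid}:{pos} is {base}, not C or G"
                )
        return cls(records)

    @classmethod
    def from_bed(cls, path: Union[str, Path], genome: Genome) -> "MethylationTrack":
        """Read a 3-column BED (sequence_id, pos, pos+1), 0-based half-open."""
        positions = []
        with xopen(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: expected >= 3 BED columns")
                sid, start, end = parts[0], int(parts[1]), int(parts[2])
                if end != start + 1:
                    raise ValueError(
                        f"{path}:{ln}: per-cytosine BED requires end == start+1"
                    )
                positions.append((sid, start))
        return cls.from_positions(genome, positions)

    def to_bed(self, path: Union[str, Path]) -> None:
        with xopen(path, "wt") as fh:
            for sid, pos, strand in sorted(self._records):
                fh.write(f"{sid}\t{pos}\t{pos + 1}\t.\t0\t{strand}\n")


class CutSite(NamedTuple):
    """A single top-strand cleavage event."""

    sequence_id: str
    coordinate: int  # cut falls between coordinate-1 and coordinate
    enzyme_name: str
    site_start: int  # 0-based start of the recognition match


@dataclass(frozen=True)
class Fragment:
    """A digestion product: a half-open genomic interval with end labels."""

    sequence_id: str
    start: int
    end: int
    left_label: str
    right_label: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty fragment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def labels(self) -> frozenset[str]:
        return frozenset((self.left_label, self.right_label))


def _site_regex(site: str) -> re.Pattern[str]:
    # Lookahead so overlapping matches each yield a cut site.  Character
    # classes list concrete bases only, so windows containing N never match.
    body = "".join(
        c if len(IUPAC_EXPANSIONS[c]) == 1 else f"[{IUPAC_EXPANSIONS[c]}]"
        for c in site
    )
    return re.compile(f"(?=({body}))")


def find_cut_sites(
    genome: Genome,
    enzymes: Sequence[Enzyme],
    methylation: Optional[MethylationTrack] = None,
    partial_block_probability: float = 0.5,
    seed: int = 0,
) -> list[CutSite]:
    """Scan the top strand for every enzyme's recognition site.

    Methylation handling: enzymes with ``full`` sensitivity are suppressed at
    any site containing a methylated cytosine (either strand); ``partial``
    sensitivity suppresses each site independently with
    ``partial_block_probability`` (seeded); ``none`` is never suppressed.

    Only palindromic enzymes are supported — for those, top-strand scanning
    sees every duplex site, so nothing is lost.

    Returns cut sites sorted by (sequence order, coordinate); coincident
    coordinates from different enzymes are retained as distinct records.
    """
    if not 0.0 <= partial_block_probability <= 1.0:
        raise ValueError("partial_block_probability must be in [0, 1]")
    for enz in enzymes:
        if not is_palindromic(enz):
            raise ValueError(
                f"enzyme {enz.name} has non-palindromic site {enz.site}; "
                "only palindromic sites are supported"
            )
    rng = np.random.default_rng(seed)
    seq_order = {sid: i for i, sid in enumerate(genome.ids)}
    enz_order = {e.name: i for i, e in enumerate(enzymes)}
    sites: list[CutSite] = []
    for sid, seq in genome:
        for enz in enzymes:
            pattern = _site_regex(enz.site)
            L = len(enz.site)
            for m in pattern.finditer(seq):
                start = m.start()
                if methylation is not None and enz.methylation_sensitivity != "none":
                    if enz.methylation_sensitivity == "full":
                        if methylation.any_in(sid, start, start + L):
                            continue
                    else:  # partial
                        if methylation.any_in(sid, start, start + L):
                            if rng.random() < partial_block_probability:
                                continue
                coord = start + enz.cut_offset
                if not 0 <= coord <= len(seq):
                    raise AssertionError(
                        f"cut coordinate {coord} out of range on {sid}"
                    )
                sites.append(CutSite(sid, coord, enz.name, start))
    sites.sort(
        key=lambda s: (seq_order[s.sequence_id], s.coordinate, enz_order[s.enzyme_name])
    )
    return sites


def digest(genome: Genome, cut_sites: Sequence[CutSite]) -> list[Fragment]:
    """Cut each sequence at the given sites and return the tiling fragments.

    Per sequence of length L with distinct cut coordinates c1 < ... < ck this
    yields k+1 fragments [0,c1), [c1,c2), ..., [ck,L); boundary labels come
    from the cutting enzyme, with TERMINUS at the sequence ends.  When two
    enzymes cut at the identical coordinate the first-listed one labels the
    boundary and a warning is logged.  Cuts at coordinate 0 or L split off
    empty fragments and are ignored as boundaries.
    """
    by_seq: dict[str, list[CutSite]] = {sid: [] for sid in genome.ids}
    for cs in cut_sites:
        if cs.sequence_id not in by_seq:
            raise ValueError(f"cut site on unknown sequence {cs.sequence_id!r}")
        lst = by_seq[cs.sequence_id]
        if lst and cs.coordinate < lst[-1].coordinate:
            raise ValueError("cut sites must be sorted by coordinate per sequence")
        lst.append(cs)

    fragments: list[Fragment] = []
    for sid, seq in genome:
        L = len(seq)
        boundaries: list[tuple[int, str]] = []
        seen_at: dict[int, str] = {}
        for cs in by_seq[sid]:
            if not 0 <= cs.coordinate <= L:
                raise ValueError(f"cut coordinate {cs.coordinate} out of [0, {L}]")
            if cs.coordinate in seen_at:
                if seen_at[cs.coordinate] != cs.enzyme_name:
                    logger.warning(
                        "coincident cut at %s:%d: keeping %s over %s (registry order)",
                        sid, cs.coordinate, seen_at[cs.coordinate], cs.enzyme_name,
                    )
                continue
            seen_at[cs.coordinate] = cs.enzyme_name
            if 0 < cs.coordinate < L:
                boundaries.append((cs.coordinate, cs.enzyme_name))
        prev, prev_label = 0, TERMINUS
        for coord, enz_name in boundaries:
            fragments.append(Fragment(sid, prev, coord, prev_label, enz_name))
            prev, prev_label = coord, enz_name
        fragments.append(Fragment(sid, prev, L, prev_label, TERMINUS))
    return fragments


def evaluate_combinations(
    genome: Genome,
    combinations: Sequence[Sequence[Enzyme]],
    methylation: Optional[MethylationTrack] = None,
    partial_block_probability: float = 0.5,
    seed: int = 0,
) -> list[dict]:
    """Digest the genome with each enzyme combination and tabulate counts.

    For each combination reports total cut sites, per-enzyme cut sites,
    fragment count and mean fragment length, genome-wide and per sequence.
    When a methylation track is given, raw (methylation-ignorant) counts are
    reported alongside the methylation-aware ones.
    """
    if not combinations:
        raise ValueError("no enzyme combinations given")
    reports: list[dict] = []
    for combo in combinations:
        if not combo:
            raise ValueError("empty enzyme combination")
        sites = find_cut_sites(
            genome, combo, methylation, partial_block_probability, seed
        )
        frags = digest(genome, sites)
        per_enzyme = {e.name: 0 for e in combo}
        per_seq_sites: dict[str, int] = {sid: 0 for sid in genome.ids}
        for cs in sites:
            per_enzyme[cs.enzyme_name] += 1
            per_seq_sites[cs.sequence_id] += 1
        per_seq_frags: dict[str, list[int]] = {sid: [] for sid in genome.ids}
        for fr in frags:
            per_seq_frags[fr.sequence_id].append(fr.length)
        report = {
            "combination": "+".join(e.name for e in combo),
            "cut_sites_total": len(sites),
            "cut_sites_per_enzyme": per_enzyme,
            "fragment_count": len(frags),
            "mean_fragment_length": genome.total_length / len(frags),
            "per_sequence": {
                sid: {
                    "cut_sites": per_seq_sites[sid],
                    "fragment_count": len(per_seq_frags[sid]),
                    "mean_fragment_length": (
                        sum(per_seq_frags[sid]) / len(per_seq_frags[sid])
                    ),
                }
                for sid in genome.ids
            },
        }
        if methylation is not None:
            raw = find_cut_sites(genome, combo, None)
            raw_per_enzyme = {e.name: 0 for e in combo}
            for cs in raw:
                raw_per_enzyme[cs.enzyme_name] += 1
            report["cut_sites_total_raw"] = len(raw)
            report["cut_sites_per_enzyme_raw"] = raw_per_enzyme
        reports.append(report)
    return reports


def write_cut_sites_bed(cut_sites: Iterable[CutSite], path: Union[str, Path]) -> None:
    """Write cut sites as BED6 (zero-length feature at the cut coordinate)."""
    with xopen(path, "wt") as fh:
        for cs in cut_sites:
            fh.write(
                f"{cs.sequence_id}\t{cs.coordinate}\t{cs.coordinate}"
                f"\t{cs.enzyme_name}\t0\t+\n"
            )


def write_fragments_bed(fragments: Iterable[Fragment], path: Union[str, Path]) -> None:
    """Write fragments as BED6; name = left/right labels, score = length."""
    with xopen(path, "wt") as fh:
        for fr in fragments:
            fh.write(
                f"{fr.sequence_id}\t{fr.start}\t{fr.end}"
                f"\t{fr.left_label}--{fr.right_label}\t{fr.length}\t+\n"
            )


def read_fragments_bed(path: Union[str, Path]) -> list[Fragment]:
    """Read fragments written by :func:`write_fragments_bed`."""
    frags: list[Fragment] = []
    with xopen(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected >= 4 BED columns")
            labels = parts[3].split("--")
            if len(labels) != 2:
                raise ValueError(f"{path}:{ln}: fragment name must be left--right")
            frags.append(
                Fragment(parts[0], int(parts[1]), int(parts[2]), labels[0], labels[1])
            )
    return frags
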