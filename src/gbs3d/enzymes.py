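"""Restriction-enzyme definitions and closed-form cutting arithmetic.

A reduced-representation protocol lives or dies by its enzymes: the length
and GC content of the recognition site set the expected cutting frequency on
random DNA, and methylation sensitivity decides which genomic compartments
are sampled at all.  This module defines the :class:`Enzyme` type, a registry
of the enzymes used in three-enzyme GBS designs, and the IUPAC-site
arithmetic (GC content, match probability, expected spacing, palindromy)
used to choose between them.

Coordinates follow the asterisk convention for cut marks: ``CTGCA*G`` means
the top strand is cleaved after 5 bases of the site, i.e. ``cut_offset=5``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Union

__all__ = [
    "IUPAC_EXPANSIONS",
    "Enzyme",
    "EnzymeRegistry",
    "builtin_registry",
    "gc_content",
    "gc_fraction_exact",
    "match_probability",
    "expected_spacing",
    "is_palindromic",
    "reverse_complement_iupac",
]

#: Expansion of every IUPAC nucleotide code into the concrete bases it matches.
IUPAC_EXPANSIONS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: Complement on IUPAC codes (W and S are self-complementary, R pairs with Y, ...).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

METHYLATION_LEVELS = ("none", "partial", "full")


def _validate_site(site: str) -> str:
    if not site:
        raise ValueError("recognition site must be non-empty")
    site = site.upper()
    bad = set(site) - set(IUPAC_EXPANSIONS)
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in site {site!r}")
    return site


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme with an IUPAC recognition site.

    Parameters
    ----------
    name
        Short identifier, e.g. ``"PstI"``.
    site
        Recognition site over the IUPAC alphabet, uppercase.
    cut_offset
        Bases of the site left of the top-strand cut (the position of the
        asterisk in ``CTGCA*G``); in ``[0, len(site)]``.
    methylation_sensitivity
        ``"none"``, ``"partial"`` or ``"full"`` — whether cytosine
        methylation within the site blocks cleavage.
    """

    name: str
    site: str
    cut_offset: int
    methylation_sensitivity: str = "none"

    def __post_init__(self) -> None:
        site = _validate_site(self.site)
        if len(site) < 3:
            raise ValueError(f"site {site!r} shorter than 3 bases")
        object.__setattr__(self, "site", site)
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside [0, {len(site)}] for {self.name}"
            )
        if self.methylation_sensitivity not in METHYLATION_LEVELS:
            raise ValueError(
                f"methylation_sensitivity must be one of {METHYLATION_LEVELS}"
            )

    def __len__(self) -> int:
        return len(self.site)


SiteLike = Union[Enzyme, str]


def _site_of(enzyme_or_site: SiteLike) -> str:
    if isinstance(enzyme_or_site, Enzyme):
        return enzyme_or_site.site
    return _validate_site(enzyme_or_site)


def gc_fraction_exact(enzyme_or_site: SiteLike) -> float:
    """Mean probability over site positions that the base is G or C.

    Each IUPAC code contributes the fraction of its expansions that are G/C
    (``W`` → 0, ``S`` → 1, ``N`` → 0.5).
    """
    site = _site_of(enzyme_or_site)
    per_pos = [
        sum(b in "GC" for b in IUPAC_EXPANSIONS[c]) / len(IUPAC_EXPANSIONS[c])
        for c in site
    ]
    return sum(per_pos) / len(per_pos)


def gc_content(enzyme_or_site: SiteLike) -> int:
    """GC content of the recognition site as an integer percentage.

    Truncated toward zero, matching the convention under which ``CTGCAG``
    is quoted as 66% and ``ATGCAT`` as 33%.
    """
    return math.floor(100 * gc_fraction_exact(enzyme_or_site))


def match_probability(enzyme_or_site: SiteLike) -> float:
    """Per-position probability the site matches i.i.d. uniform DNA.

    Equals (number of concrete ACGT words matching the IUPAC site) / 4**L.
    For palindromic sites this is the top-strand match probability per
    position.
    """
    site = _site_of(enzyme_or_site)
    prob = 1.0
    for c in site:
        prob *= len(IUPAC_EXPANSIONS[c]) / 4.0
    return prob


def expected_spacing(enzyme_or_site: SiteLike) -> float:
    """Expected distance in bp between successive site starts on random DNA.

    The reciprocal of :func:`match_probability`; e.g. 4096 bp for a 6-bp
    unambiguous cutter, 512 bp for a 5-bp site with one two-fold ambiguity.
    """
    p = match_probability(enzyme_or_site)
    if p <= 0.0:
        raise ValueError("site has zero match probability")
    return 1.0 / p


def reverse_complement_iupac(site: str) -> str:
    """Reverse complement of an IUPAC string, complementing ambiguity codes."""
    site = _validate_site(site)
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(site))


def is_palindromic(enzyme_or_site: SiteLike) -> bool:
    """True iff the site equals its own IUPAC reverse complement."""
    site = _site_of(enzyme_or_site)
    return site == reverse_complement_iupac(site)


class EnzymeRegistry:
    """Ordered, name-unique collection of :class:`Enzyme` objects.

    Registry order is meaningful: when two enzymes cut at the same genomic
    coordinate the first-listed enzyme labels the boundary.
    """

    def __init__(self, enzymes: Iterable[Enzyme] = ()) -> None:
        self._enzymes: dict[str, Enzyme] = {}
        for enz in enzymes:
            self.add(enz)

    def add(self, enzyme: Enzyme) -> None:
        if enzyme.name in self._enzymes:
            raise ValueError(f"duplicate enzyme name {enzyme.name!r}")
        self._enzymes[enzyme.name] = enzyme

    def get(self, name: str) -> Enzyme:
        try:
            return self._enzymes[name]
        except KeyError:
            raise KeyError(f"unknown enzyme {name!r}; known: {list(self._enzymes)}")

    def __getitem__(self, name: str) -> Enzyme:
        return self.get(name)

    def __contains__(self, name: str) -> bool:
        return name in self._enzymes

    def __iter__(self) -> Iterator[Enzyme]:
        return iter(self._enzymes.values())

    def __len__(self) -> int:
        return len(self._enzymes)

    @property
    def names(self) -> list[str]:
        return list(self._enzymes)

    def resolve(self, names: Iterable[str]) -> list[Enzyme]:
        """Look up several enzymes by name, preserving the given order."""
        return [self.get(n) for n in names]

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "EnzymeRegistry":
        """Load a registry from a TSV with columns
        name, site, cut_offset, methylation_sensitivity."""
        reg = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["name", "site", "cut_offset", "methylation_sensitivity"]
            if header != expected:
                raise ValueError(f"bad registry header {header}; expected {expected}")
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                name, site, offset, sens = line.split("\t")
                reg.add(Enzyme(name, site, int(offset), sens))
        return reg


def builtin_registry() -> EnzymeRegistry:
    """The packaged registry: ApeKI, the 3D-GBS trio (PstI, NsiI, MspI) and
    the six alternative cutters spanning 33/66/100% site GC."""
    with resources.as_file(resources.files("gbs3d.data") / "enzymes.tsv") as p:
        return EnzymeRegistry.from_tsv(p)
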