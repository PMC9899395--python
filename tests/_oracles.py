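"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: site scanning is done by
expanding the IUPAC site into every concrete ACGT word and substring-
searching each; gap and nearest-anchor computations are exhaustive scans.
"""

from itertools import product

from gbs3d.enzymes import IUPAC_EXPANSIONS


def expand_iupac(site: str) -> list[str]:
    """All concrete ACGT words matching an IUPAC site."""
    return ["".join(w) for w in product(*(IUPAC_EXPANSIONS[c] for c in site))]


def naive_cut_sites(sequence: str, site: str, cut_offset: int) -> list[tuple[int, int]]:
    """(site_start, cut_coordinate) pairs via word expansion + substring search."""
    hits = set()
    for word in expand_iupac(site):
        start = sequence.find(word)
        while start != -1:
            hits.add(start)
            start = sequence.find(word, start + 1)
    return sorted((s, s + cut_offset) for s in hits)


def brute_force_gaps(positions, threshold) -> int:
    """Count consecutive-marker distances strictly above threshold."""
    pos = sorted(positions)
    return sum(1 for a, b in zip(pos, pos[1:]) if b - a > threshold)


def brute_force_nearest(anchors_bp, anchors_cm, query) -> float:
    """cM of the anchor with minimal |bp| distance; ties to smaller bp."""
    best = None
    for bp, cm in sorted(zip(anchors_bp, anchors_cm)):
        d = abs(query - bp)
        if best is None or d < best[0]:
            best = (d, cm)
    return best[1]


def brute_force_match_count(site: str) -> int:
    """Number of concrete words matching the site, by full 4**L enumeration."""
    words = ["".join(w) for w in product("ACGT", repeat=len(site))]
    expansions = set(expand_iupac(site))
    return sum(w in expansions for w in words)


def brute_force_gc_fraction(site: str) -> float:
    """Mean GC fraction over all concrete words matching the site."""
    words = expand_iupac(site)
    return sum(sum(b in "GC" for b in w) for w in words) / (len(words) * len(site))
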