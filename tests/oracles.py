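"""Independent brute-force re-implementations used as oracles in tests.

Everything here is written from the counting rules alone, with naive loops
and slicing, and must stay independent of the package's implementation.
"""

from __future__ import annotations

import re
from statistics import median


def brute_sequon_positions(sequence: str, exclude_proline_x: bool = False) -> list[int]:
    """1-based N positions of NX[STC] motifs via regex lookahead."""
    pat = r"N(?=[^P][STC])" if exclude_proline_x else r"N(?=.[STC])"
    return [m.start() + 1 for m in re.finditer(pat, sequence)]


def brute_offsets(peptide: str, protein: str) -> list[int]:
    """All 1-based exact-match offsets by character comparison."""
    out = []
    for start in range(len(protein) - len(peptide) + 1):
        if all(protein[start + k] == peptide[k] for k in range(len(peptide))):
            out.append(start + 1)
    return out


def brute_assignment(
    peptide: str,
    deamid_positions: list[int],
    group: list[str],
    proteome: dict[str, str],
) -> tuple[str, set[tuple[int, str]]] | None:
    """Rules (ii)+(iii) from scratch.

    Returns (assigned accession, {(protein position, motif class)}), or None
    when no group member contains the peptide.
    """
    candidates = sorted(a for a in group if a in proteome and brute_offsets(peptide, proteome[a]))
    if not candidates:
        return None
    assigned = candidates[0]
    seq = proteome[assigned]
    sequons = set(brute_sequon_positions(seq))
    per_offset: list[set[tuple[int, str]]] = []
    for off in brute_offsets(peptide, seq):
        sites = set()
        for p in deamid_positions:
            pos = off + p - 1
            if pos in sequons:
                sites.add((pos, "NX" + seq[pos + 1]))
        per_offset.append(sites)
    best = max(len(s) for s in per_offset)
    kept: set[tuple[int, str]] = set()
    for sites in per_offset:
        if len(sites) == best:
            kept |= sites
    return assigned, kept


def brute_census(site_sets_by_group: dict[tuple[str, ...], set[tuple[str, int]]]) -> dict:
    groups = {k: v for k, v in site_sets_by_group.items() if v}
    counts = [len(v) for v in groups.values()]
    all_sites = set().union(*groups.values()) if groups else set()
    return {
        "n_sites": len(all_sites),
        "n_protein_groups": len(groups),
        "median_sites_per_group": float(median(counts)) if counts else None,
    }


def brute_intersections(presence: dict[str, set[str]]) -> dict[frozenset, int]:
    """Exclusive intersection counts by enumerating every protein."""
    counts: dict[frozenset, int] = {}
    for _, pops in presence.items():
        key = frozenset(pops)
        counts[key] = counts.get(key, 0) + 1
    return counts
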