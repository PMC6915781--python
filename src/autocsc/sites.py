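"""Glycosite identification, mapping and counting.

N-linked glycosylation occurs at asparagines in the NX[STC] sequon.  PNGase F
release of the glycan converts the asparagine to aspartate (+0.98 Da
deamidation), so a formerly glycosylated site is evidenced by a deamidated N
sitting on a sequon.  This module filters peptide observations for that
signature, maps them onto protein coordinates, and counts unique glycosites
under three rules:

(i)   only peptides whose deamidated N conforms to the NX[STC] consensus are
      considered;
(ii)  non-proteotypic peptides are assigned to a single protein of their
      group — deterministically, the lexicographically smallest accession
      containing the peptide;
(iii) a peptide matching multiple positions within that protein keeps all
      positions, unless one mapping yields strictly more consensus-matching
      deamidated asparagines, in which case only the maximal mappings are kept.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

from autocsc.io import AnnotationRecord, PeptideObservation, ProteinRecord

logger = logging.getLogger("autocsc")

DEFAULT_THIRD_RESIDUES = "STC"
DEFAULT_CONTAMINANT_PREFIXES = ("CON_", "CONT_", "REV_")


@dataclass(frozen=True, order=True)
class SequonSite:
    """An NX[STC] motif inside a sequence; position is the 1-based N index."""

    position: int
    motif_class: str  # "NXS" | "NXT" | "NXC"


@dataclass(frozen=True, order=True)
class GlycoSite:
    """A glycosylated asparagine in protein coordinates (1-based)."""

    accession: str
    position: int
    motif_class: str


@dataclass
class SiteAssignment:
    """The glycosites one peptide observation contributes."""

    peptide: PeptideObservation
    sites: list[GlycoSite]
    proteotypic: bool
    group_specific: bool
    assigned_accession: str


@dataclass
class SiteCensus:
    n_sites: int
    n_protein_groups: int
    sites_per_group: dict[tuple[str, ...], int]
    median_sites_per_group: float | None

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "n_protein_groups": self.n_protein_groups,
            "median_sites_per_group": self.median_sites_per_group,
            "sites_per_group": {
                ";".join(k): v for k, v in sorted(self.sites_per_group.items())
            },
        }


class UnmappablePeptideError(ValueError):
    """Peptide not found in any accession of its declared protein group."""


class Proteome:
    """A set of protein records with peptide-lookup helpers."""

    def __init__(self, records: Iterable[ProteinRecord]) -> None:
        self.records: dict[str, ProteinRecord] = {}
        for rec in records:
            if rec.accession in self.records:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            self.records[rec.accession] = rec

    def __contains__(self, accession: str) -> bool:
        return accession in self.records

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self.records[accession]

    def accessions_containing(self, peptide: str) -> list[str]:
        """All accessions whose sequence contains the peptide exactly.

        I and L are deliberately not equated: search engines emit
        database-resolved sequences.
        """
        return [a for a, r in self.records.items() if peptide in r.sequence]


# ---------------------------------------------------------------------------
# sequon scanning
# ---------------------------------------------------------------------------


def scan_sequons(
    sequence: str,
    exclude_proline_x: bool = False,
    third_residues: str = DEFAULT_THIRD_RESIDUES,
) -> list[SequonSite]:
    """All (possibly overlapping) NX[STC] motifs in a sequence.

    Returns 1-based N positions; an N within two residues of the C-terminus
    cannot match.  With ``exclude_proline_x`` the conventional X != P
    restriction is applied (off by default: the counting rules use the
    literal NX[STC] consensus).
    """
    sites: list[SequonSite] = []
    for i in range(len(sequence) - 2):
        if sequence[i] != "N":
            continue
        if exclude_proline_x and sequence[i + 1] == "P":
            continue
        third = sequence[i + 2]
        if third in third_residues:
            sites.append(SequonSite(position=i + 1, motif_class="NX" + third))
    return sites


def _sequon_at(
    sequence: str,
    position: int,
    exclude_proline_x: bool,
    third_residues: str,
) -> str | None:
    """Motif class if a sequon holds at 1-based `position`, else None."""
    i = position - 1
    if i < 0 or i + 2 >= len(sequence) or sequence[i] != "N":
        return None
    if exclude_proline_x and sequence[i + 1] == "P":
        return None
    third = sequence[i + 2]
    return "NX" + third if third in third_residues else None


# ---------------------------------------------------------------------------
# peptide filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterResult:
    retained: list[PeptideObservation] = field(default_factory=list)
    removed: list[PeptideObservation] = field(default_factory=list)
    unmappable: list[PeptideObservation] = field(default_factory=list)

    def __iter__(self):
        return iter(self.retained)


def filter_glycopeptides(
    observations: Sequence[PeptideObservation],
    proteome: Proteome | Iterable[ProteinRecord],
    q_threshold: float = 0.01,
    contaminant_prefixes: Sequence[str] = DEFAULT_CONTAMINANT_PREFIXES,
    exclude_proline_x: bool = False,
    third_residues: str = DEFAULT_THIRD_RESIDUES,
) -> FilterResult:
    """Retain formerly N-glycosylated peptides.

    An observation is retained when (a) its q-value, if present, is at or
    below ``q_threshold`` (identification FDR <= 1% by default), and (b) at
    least one deamidation sits on an asparagine whose NX[STC] sequon holds —
    evaluated within the peptide when the +1/+2 residues are inside it, and
    in protein context otherwise.  Contaminant accessions (by configurable
    prefix) are dropped from groups; observations whose group becomes empty
    are removed.  Observations needing protein context whose peptide cannot
    be located in any listed accession go to ``unmappable`` rather than being
    silently dropped.
    """
    if not isinstance(proteome, Proteome):
        proteome = Proteome(proteome)
    result = FilterResult()
    for obs in observations:
        group = [
            a
            for a in obs.protein_accessions
            if not any(a.startswith(p) for p in contaminant_prefixes)
        ]
        if not group:
            result.removed.append(obs)
            continue
        if obs.q_value is not None and obs.q_value > q_threshold:
            result.removed.append(obs)
            continue

        peptide = obs.peptide_sequence
        npos = obs.deamidated_positions("N")
        ok = False
        needs_context = False
        located: list[tuple[str, int]] | None = None  # (accession, offset)
        for p in npos:
            if p + 2 <= len(peptide):
                if _sequon_at(peptide, p, exclude_proline_x, third_residues):
                    ok = True
                    break
            else:
                needs_context = True
                if located is None:
                    located = [
                        (acc, off)
                        for acc in group
                        if acc in proteome
                        for off in locate_peptide(peptide, proteome[acc])
                    ]
                for acc, off in located:
                    prot_pos = off + p - 1
                    if _sequon_at(
                        proteome[acc].sequence, prot_pos,
                        exclude_proline_x, third_residues,
                    ):
                        ok = True
                        break
                if ok:
                    break
        if ok:
            result.retained.append(obs)
        elif needs_context and located is not None and not located:
            result.unmappable.append(obs)
        else:
            result.removed.append(obs)
    return result


# ---------------------------------------------------------------------------
# peptide -> protein mapping
# ---------------------------------------------------------------------------


def locate_peptide(peptide_sequence: str, protein: ProteinRecord | str) -> list[int]:
    """All 1-based start offsets of exact (possibly overlapping) matches."""
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    offsets: list[int] = []
    start = seq.find(peptide_sequence)
    while start != -1:
        offsets.append(start + 1)
        start = seq.find(peptide_sequence, start + 1)
    return offsets


def map_glycosites(
    obs: PeptideObservation,
    proteome: Proteome | Iterable[ProteinRecord],
    exclude_proline_x: bool = False,
    third_residues: str = DEFAULT_THIRD_RESIDUES,
) -> SiteAssignment:
    """Map one filtered observation onto protein glycosites (rules ii + iii).

    Raises :class:`UnmappablePeptideError` when no accession of the declared
    group contains the peptide.
    """
    if not isinstance(proteome, Proteome):
        proteome = Proteome(proteome)
    peptide = obs.peptide_sequence
    all_matching = proteome.accessions_containing(peptide)
    in_group = sorted(a for a in all_matching if a in obs.protein_accessions)
    if not in_group:
        raise UnmappablePeptideError(
            f"peptide {peptide!r} not found in group {obs.protein_accessions}"
        )
    proteotypic = len(all_matching) == 1
    group_specific = set(all_matching) <= set(obs.protein_accessions)
    assigned = in_group[0]  # rule (ii): deterministic "arbitrary" choice
    protein = proteome[assigned]

    npos = obs.deamidated_positions("N")
    offsets = locate_peptide(peptide, protein)
    per_offset: list[tuple[int, list[GlycoSite]]] = []
    for off in offsets:
        sites: list[GlycoSite] = []
        for p in npos:
            prot_pos = off + p - 1
            motif = _sequon_at(
                protein.sequence, prot_pos, exclude_proline_x, third_residues
            )
            if motif:
                sites.append(GlycoSite(assigned, prot_pos, motif))
        per_offset.append((off, sites))
    # rule (iii): keep only offsets with the maximal consensus-site count
    best = max((len(s) for _, s in per_offset), default=0)
    kept = [s for _, sites in per_offset if len(sites) == best for s in sites]
    return SiteAssignment(
        peptide=obs,
        sites=sorted(set(kept)),
        proteotypic=proteotypic,
        group_specific=group_specific,
        assigned_accession=assigned,
    )


def assign_sites(
    observations: Sequence[PeptideObservation],
    proteome: Proteome | Iterable[ProteinRecord],
    **kwargs,
) -> tuple[list[SiteAssignment], list[PeptideObservation]]:
    """Map many observations; unmappable ones are collected, not raised."""
    if not isinstance(proteome, Proteome):
        proteome = Proteome(proteome)
    assignments: list[SiteAssignment] = []
    unmappable: list[PeptideObservation] = []
    for obs in observations:
        try:
            assignments.append(map_glycosites(obs, proteome, **kwargs))
        except UnmappablePeptideError:
            unmappable.append(obs)
    if unmappable:
        logger.warning("%d observation(s) unmappable to their group", len(unmappable))
    return assignments, unmappable


# ---------------------------------------------------------------------------
# censuses and annotation comparison
# ---------------------------------------------------------------------------


def census(
    assignments: Sequence[SiteAssignment],
    proteotypic_only: bool = False,
) -> SiteCensus:
    """Count unique glycosites and protein groups.

    Sites are unique (accession, position) pairs; protein groups are keyed by
    the sorted accession tuple of the observation's group.  Peptides mapping
    into multiple protein groups (not group-specific) are excluded, so group
    site sets stay disjoint.  The median is over groups with at least one
    site, and is None for an empty census.
    """
    per_group: dict[tuple[str, ...], set[tuple[str, int]]] = defaultdict(set)
    for a in assignments:
        if not a.group_specific:
            continue
        if proteotypic_only and not a.proteotypic:
            continue
        if not a.sites:
            continue
        key = tuple(sorted(a.peptide.protein_accessions))
        per_group[key].update((s.accession, s.position) for s in a.sites)
    sites_per_group = {k: len(v) for k, v in per_group.items()}
    all_sites = set().union(*per_group.values()) if per_group else set()
    return SiteCensus(
        n_sites=len(all_sites),
        n_protein_groups=len(per_group),
        sites_per_group=sites_per_group,
        median_sites_per_group=(
            float(median(sites_per_group.values())) if sites_per_group else None
        ),
    )


def unique_sites(assignments: Sequence[SiteAssignment], proteotypic_only: bool = False) -> list[GlycoSite]:
    """Deduplicated glycosites across assignments (group-specific only)."""
    out: set[GlycoSite] = set()
    for a in assignments:
        if not a.group_specific:
            continue
        if proteotypic_only and not a.proteotypic:
            continue
        out.update(a.sites)
    return sorted(out)


def compare_to_annotation(
    sites: Sequence[GlycoSite],
    annotation: Sequence[AnnotationRecord],
) -> dict[str, int]:
    """Compare observed glycosites against UniProt-style annotation.

    A site is novel iff its (accession, position) is absent from annotation.
    ``annotated_not_observed`` restricts annotation rows to proteins with at
    least one observed site, mirroring how site-level annotation coverage is
    reported for the identified surfaceome only.
    """
    observed = {(s.accession, s.position) for s in sites}
    observed_proteins = {acc for acc, _ in observed}
    ann = {(r.accession, r.position): r.evidence for r in annotation}
    novel = sum(1 for key in observed if key not in ann)
    confirmed_exp = sum(1 for key in observed if ann.get(key) == "experimental")
    confirmed_pred = sum(1 for key in observed if ann.get(key) == "predicted")
    annotated_not_observed = sum(
        1
        for (acc, pos) in ann
        if acc in observed_proteins and (acc, pos) not in observed
    )
    return {
        "novel": novel,
        "confirmed_experimental": confirmed_exp,
        "confirmed_predicted": confirmed_pred,
        "annotated_not_observed": annotated_not_observed,
    }
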