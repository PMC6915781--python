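"""Synthetic proteomes and glycopeptide reports with known ground truth.

The generator emulates what the pipeline consumes from a real cell-surface
capture experiment: a protein database, a peptide-level report of
in-silico-digested tryptic (and semi-tryptic) peptides with deamidation marks
at true sequon asparagines plus decoy deamidations at non-sequon asparagines,
log-normal intensity noise over a replicate design, and a UniProt-style
annotation table.  Every artefact is deterministic per seed and carries the
bookkeeping needed to compare pipeline output against the truth exactly.

Scale defaults mirror a single surfaceome experiment: a few hundred
glycoproteins with a median of about two sequons each, four biological
replicates per condition, and log-normal intensity noise at a linear CV of
roughly 0.28 — the reproducibility a well-automated enrichment achieves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from autocsc.io import (
    AnnotationRecord,
    Modification,
    PeptideObservation,
    ProteinRecord,
    SampleDesign,
)
from autocsc.quant import QuantMatrix
from autocsc.sites import GlycoSite, locate_peptide, scan_sequons

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues allowed at the X position of planted sequons (X != P keeps the
#: planted truth valid under either proline convention)
SEQUON_X = "".join(c for c in AMINO_ACIDS if c != "P")
THIRD_CHOICES = ("S", "T", "C")
THIRD_WEIGHTS = (0.45, 0.45, 0.10)  # NXC sequons are rare in vivo

MIN_PEPTIDE_LEN = 6
MAX_PEPTIDE_LEN = 30

def sigma_log2_for_cv(cv: float) -> float:
    """log2-scale sd of a log-normal whose linear CV is `cv`
    (CV = sqrt(exp(sigma_ln^2) - 1))."""
    return math.sqrt(math.log1p(cv * cv)) / math.log(2.0)


#: default intensity noise: the linear CV a well-automated enrichment reaches
DEFAULT_NOISE_SIGMA = sigma_log2_for_cv(0.28)


def cv_for_sigma_log2(sigma: float) -> float:
    return math.sqrt(math.expm1((sigma * math.log(2.0)) ** 2))


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------


def _break_incidental_sequons(seq: list[str], planted: set[int], rng: np.random.Generator) -> None:
    """Mutate away any sequon that was not planted, leaving planted ones intact.

    Keeps the planted sites the exact truth census.  Positions are 0-based
    indices of N.  Replacement residues avoid N/S/T/C (and P) so a mutation
    can neither recreate a sequon nor disturb a planted one.
    """
    protected = {q for p in planted for q in (p, p + 1, p + 2)}
    third_mut = [c for c in AMINO_ACIDS if c not in "STCN"]
    n_mut = [c for c in AMINO_ACIDS if c not in "NSTCP"]
    for _ in range(50):
        dirty = False
        for s in scan_sequons("".join(seq)):
            i = s.position - 1
            if i in planted:
                continue
            j = i + 2
            if j not in protected:
                seq[j] = str(rng.choice(third_mut))
            else:
                # the third residue belongs to a planted sequon: remove the
                # incidental N itself (never a planted N, so always safe)
                seq[i] = str(rng.choice(n_mut))
            dirty = True
        if not dirty:
            return
    raise RuntimeError("could not remove incidental sequons")


def generate_proteome(
    n_proteins: int = 200,
    length_range: tuple[int, int] = (300, 600),
    sequon_density: float = 0.005,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[GlycoSite]]:
    """Random protein sequences with NX[STC] sequons planted at a controlled
    density (sequons per residue).

    Incidental sequons arising by chance are broken by point mutation, so the
    returned site list is exactly the set of sequons present (verified by a
    final rescan).  Deterministic per seed.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if not 0.0 <= sequon_density <= 1.0:
        raise ValueError("sequon_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth: list[GlycoSite] = []
    for i in range(n_proteins):
        accession = f"SYN{i:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        n_sites = int(round(sequon_density * length))
        if 3 * n_sites > length:
            raise ValueError(
                f"sequon_density {sequon_density} infeasible for length {length}"
            )
        seq = [str(c) for c in rng.choice(list(AMINO_ACIDS), size=length)]
        # non-overlapping plant positions, away from the C-terminus
        planted: set[int] = set()
        candidates = rng.permutation(max(length - 2, 0))
        for pos in candidates:
            if len(planted) == n_sites:
                break
            if all(abs(pos - p) >= 3 for p in planted):
                planted.add(int(pos))
        for pos in sorted(planted):
            seq[pos] = "N"
            seq[pos + 1] = str(rng.choice(list(SEQUON_X)))
            seq[pos + 2] = str(rng.choice(THIRD_CHOICES, p=THIRD_WEIGHTS))
        _break_incidental_sequons(seq, planted, rng)
        sequence = "".join(seq)
        found = scan_sequons(sequence)
        assert {s.position - 1 for s in found} == planted
        records.append(ProteinRecord(accession, sequence, "synthetic protein"))
        truth.extend(
            GlycoSite(accession, s.position, s.motif_class) for s in found
        )
    return records, sorted(truth)


# ---------------------------------------------------------------------------
# truth container
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic experiment."""

    proteome: list[ProteinRecord]
    true_sites: list[GlycoSite]
    true_protein_abundance: pd.DataFrame  # protein x condition, log2
    noise_sigma: float
    decoy_fraction: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "noise_sigma": self.noise_sigma,
            "decoy_fraction": self.decoy_fraction,
            "true_sites": [
                [s.accession, s.position, s.motif_class] for s in self.true_sites
            ],
            "true_protein_abundance": {
                "index": list(self.true_protein_abundance.index),
                "columns": list(self.true_protein_abundance.columns),
                "values": self.true_protein_abundance.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def make_truth(
    n_proteins: int = 200,
    length_range: tuple[int, int] = (300, 600),
    sequon_density: float = 0.005,
    conditions: Sequence[str] = ("A", "B"),
    abundance_mean: float = 20.0,
    abundance_sd: float = 2.0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    decoy_fraction: float = 0.05,
    log2fc: float = 0.0,
    frac_changed: float = 0.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Build a full ground truth: proteome, sites and per-condition log2
    protein abundances.

    Baseline abundances are normal(abundance_mean, abundance_sd) in log2
    space, equal across conditions; a ``frac_changed`` subset of proteins is
    shifted by +-``log2fc`` in every condition after the first.
    """
    records, sites = generate_proteome(n_proteins, length_range, sequon_density, seed)
    rng = np.random.default_rng(seed + 1)
    accs = [r.accession for r in records]
    base = rng.normal(abundance_mean, abundance_sd, size=len(accs))
    table = pd.DataFrame(
        {c: base.copy() for c in conditions}, index=accs, dtype=float
    )
    if frac_changed > 0 and log2fc != 0 and len(conditions) > 1:
        n_changed = int(round(frac_changed * len(accs)))
        changed = rng.choice(len(accs), size=n_changed, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_changed)
        for c in list(conditions)[1:]:
            table.loc[np.array(accs)[changed], c] += signs * log2fc
    return SyntheticTruth(
        proteome=records,
        true_sites=sites,
        true_protein_abundance=table,
        noise_sigma=noise_sigma,
        decoy_fraction=decoy_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------


def digest(
    sequence: str,
    max_missed_cleavages: int = 2,
    suppress_proline: bool = False,
) -> list[tuple[int, str]]:
    """In-silico tryptic digestion: cleave after K/R, up to
    ``max_missed_cleavages`` missed cleavages.

    Returns (1-based start offset, peptide) pairs, unfiltered by length.
    With ``suppress_proline`` cleavage before P is suppressed (off by
    default, mirroring common search-engine settings).
    """
    cut_after = [
        i
        for i, ch in enumerate(sequence)
        if ch in "KR"
        and not (suppress_proline and i + 1 < len(sequence) and sequence[i + 1] == "P")
    ]
    boundaries = [0] + [i + 1 for i in cut_after]
    if boundaries[-1] != len(sequence):
        boundaries.append(len(sequence))
    peptides: list[tuple[int, str]] = []
    n_frag = len(boundaries) - 1
    for i in range(n_frag):
        for j in range(i + 1, min(i + 2 + max_missed_cleavages, n_frag + 1)):
            start, end = boundaries[i], boundaries[j]
            peptides.append((start + 1, sequence[start:end]))
    return peptides


# ---------------------------------------------------------------------------
# report generation
# ---------------------------------------------------------------------------


@dataclass
class ReportBundle:
    """A synthetic peptide report plus the bookkeeping to verify it."""

    observations: list[PeptideObservation]
    design: SampleDesign
    reported_sites: list[GlycoSite]  # truth restricted to emitted peptides
    n_decoys: int
    feature_log2: pd.DataFrame = field(repr=False, default=None)  # feature x run truth


def generate_report(
    truth: SyntheticTruth,
    n_bioreps: int = 4,
    n_techreps: int = 1,
    missing_rate: float = 0.05,
    semi_tryptic_fraction: float = 0.1,
    max_missed_cleavages: int = 2,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> ReportBundle:
    """Emulate a glycopeptide identification/quantification report.

    Every detectable peptide (length ``min_len``..``max_len`` after optional
    semi-tryptic trimming) covering a true site is reported with deamidation
    at the site(s); a ``truth.decoy_fraction`` share of all deamidations is
    additionally planted on non-sequon asparagines of sequon-free peptides.
    Glycopeptides that are not protein-specific (occurring in another protein
    or at multiple loci of their own) are withheld, mirroring the
    "only protein group specific" proteotypicity filter, so
    ``reported_sites`` is the exact site census any correct pipeline must
    recover from a noise-free report.
    Run intensities are 2^(true protein log2 abundance + N(0, noise_sigma)),
    removed at ``missing_rate``.  Deterministic per ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed + 2)
    conditions = list(truth.true_protein_abundance.columns)
    design_rows = []
    for c in conditions:
        for b in range(1, n_bioreps + 1):
            for t in range(1, n_techreps + 1):
                design_rows.append((f"{c}_b{b}_t{t}", c, f"b{b}", f"t{t}"))
    design = SampleDesign.from_rows(design_rows)
    run_conditions = {row[0]: row[1] for row in design_rows}

    sites_by_acc: dict[str, list[int]] = {}
    for s in truth.true_sites:
        sites_by_acc.setdefault(s.accession, []).append(s.position)
    site_class = {(s.accession, s.position): s.motif_class for s in truth.true_sites}

    glyco: list[tuple[str, str, list[int], list[tuple[int, str]]]] = []
    decoy_pool: list[tuple[str, str, int]] = []  # (accession, peptide, N pos in peptide)
    reported: set[GlycoSite] = set()

    for rec in truth.proteome:
        if len(rec.sequence) < min_len:
            continue
        acc_sites = sites_by_acc.get(rec.accession, [])
        for start, pep in digest(rec.sequence, max_missed_cleavages):
            if rng.random() < semi_tryptic_fraction and len(pep) > min_len:
                # one semi-tryptic terminus: trim 1-3 residues off one end
                trim = int(rng.integers(1, min(4, len(pep) - min_len + 1)))
                if rng.random() < 0.5:
                    pep, start = pep[trim:], start + trim
                else:
                    pep = pep[:-trim]
            if not (min_len <= len(pep) <= max_len):
                continue
            end = start + len(pep) - 1
            covered = [p for p in acc_sites if start <= p <= end]
            if covered:
                hosts = [
                    r.accession for r in truth.proteome if pep in r.sequence
                ]
                if hosts != [rec.accession] or len(locate_peptide(pep, rec.sequence)) > 1:
                    continue  # not proteotypic: withheld
                glyco.append((rec.accession, pep, [p - start + 1 for p in covered], []))
                reported.update(
                    GlycoSite(rec.accession, p, site_class[(rec.accession, p)])
                    for p in covered
                )
            else:
                ns = [i + 1 for i, ch in enumerate(pep) if ch == "N"]
                if ns:
                    decoy_pool.append((rec.accession, pep, int(rng.choice(ns))))

    d = truth.decoy_fraction
    n_decoys = int(round(len(glyco) * d / (1.0 - d))) if d > 0 else 0
    n_decoys = min(n_decoys, len(decoy_pool))
    decoy_idx = (
        rng.choice(len(decoy_pool), size=n_decoys, replace=False) if n_decoys else []
    )

    proteome_by_acc = {r.accession: r.sequence for r in truth.proteome}
    runs = design.run_ids
    observations: list[PeptideObservation] = []
    feature_rows: dict[str, dict[str, float]] = {}

    def emit(acc: str, pep: str, deamid_pep_positions: list[int]) -> None:
        prot_log2 = truth.true_protein_abundance.loc[acc]
        feature_offset = float(rng.normal(0.0, 1.0))
        intensities: dict[str, float] = {}
        log2_truth: dict[str, float] = {}
        for run in runs:
            value = (
                float(prot_log2[run_conditions[run]])
                + feature_offset
                + float(rng.normal(0.0, truth.noise_sigma))
            )
            log2_truth[run] = value
            if rng.random() >= missing_rate:
                intensities[run] = float(2.0**value)
        group = sorted(a for a, s in proteome_by_acc.items() if pep in s) or [acc]
        mods = [
            Modification(position=p, kind="Deamidated (N)", delta_mass=0.98)
            for p in deamid_pep_positions
        ]
        observations.append(
            PeptideObservation(
                peptide_sequence=pep,
                modifications=mods,
                protein_accessions=group,
                score=float(rng.uniform(1.0, 10.0)),
                q_value=float(rng.uniform(0.0, 0.009)),
                intensities=intensities,
            )
        )
        fid = f"{pep}@{','.join(map(str, deamid_pep_positions))}"
        feature_rows.setdefault(fid, log2_truth)

    for acc, pep, pep_positions, _ in glyco:
        emit(acc, pep, pep_positions)
    for i in decoy_idx:
        acc, pep, npos = decoy_pool[int(i)]
        emit(acc, pep, [npos])

    feature_log2 = pd.DataFrame.from_dict(feature_rows, orient="index", columns=runs)
    return ReportBundle(
        observations=observations,
        design=design,
        reported_sites=sorted(reported),
        n_decoys=n_decoys,
        feature_log2=feature_log2,
    )


# ---------------------------------------------------------------------------
# annotation generation
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTruth:
    records: list[AnnotationRecord]
    experimental: list[GlycoSite]
    predicted: list[GlycoSite]
    extra: list[AnnotationRecord]  # annotated sites never truly glycosylated

    def expected_comparison(self, observed_sites: Sequence[GlycoSite]) -> dict[str, int]:
        """What compare_to_annotation must return for `observed_sites`."""
        observed = {(s.accession, s.position) for s in observed_sites}
        observed_proteins = {a for a, _ in observed}
        exp = {(s.accession, s.position) for s in self.experimental}
        pred = {(s.accession, s.position) for s in self.predicted}
        extra = {(r.accession, r.position) for r in self.extra}
        annotated = exp | pred | extra
        return {
            "novel": len(observed - annotated),
            "confirmed_experimental": len(observed & exp),
            "confirmed_predicted": len(observed & pred),
            "annotated_not_observed": sum(
                1 for (a, p) in annotated
                if a in observed_proteins and (a, p) not in observed
            ),
        }


def generate_annotation(
    truth: SyntheticTruth,
    frac_experimental: float = 0.1,
    frac_predicted: float = 0.75,
    frac_extra: float = 0.2,
    seed: int | None = None,
) -> AnnotationTruth:
    """UniProt-style annotation table sampled from the true sites.

    Disjoint fractions of true sites are labelled experimental and predicted
    (defaults mirror a database where most site annotation is computational);
    ``frac_extra`` (relative to the number of true sites) extra rows annotate
    positions that are never truly glycosylated.
    """
    if frac_experimental + frac_predicted > 1.0 + 1e-9:
        raise ValueError("frac_experimental + frac_predicted must be <= 1")
    rng = np.random.default_rng(truth.seed + 3 if seed is None else seed)
    sites = list(truth.true_sites)
    order = rng.permutation(len(sites))
    n_exp = int(round(frac_experimental * len(sites)))
    n_pred = int(round(frac_predicted * len(sites)))
    n_pred = min(n_pred, len(sites) - n_exp)
    experimental = [sites[i] for i in order[:n_exp]]
    predicted = [sites[i] for i in order[n_exp : n_exp + n_pred]]

    true_keys = {(s.accession, s.position) for s in sites}
    lengths = {r.accession: len(r.sequence) for r in truth.proteome}
    accs = sorted(lengths)
    extra: list[AnnotationRecord] = []
    n_extra = int(round(frac_extra * len(sites)))
    guard = 0
    seen: set[tuple[str, int]] = set(true_keys)
    while len(extra) < n_extra and guard < 100 * max(n_extra, 1):
        guard += 1
        acc = accs[int(rng.integers(len(accs)))]
        pos = int(rng.integers(1, lengths[acc] + 1))
        if (acc, pos) in seen:
            continue
        seen.add((acc, pos))
        evidence = "predicted" if rng.random() < 0.84 else "experimental"
        extra.append(AnnotationRecord(acc, pos, evidence))

    records = (
        [AnnotationRecord(s.accession, s.position, "experimental") for s in experimental]
        + [AnnotationRecord(s.accession, s.position, "predicted") for s in predicted]
        + extra
    )
    records.sort(key=lambda r: (r.accession, r.position))
    return AnnotationTruth(
        records=records, experimental=experimental, predicted=predicted, extra=extra
    )


# ---------------------------------------------------------------------------
# differential-abundance matrix
# ---------------------------------------------------------------------------


def generate_differential_matrix(
    n_proteins: int = 500,
    frac_changed: float = 0.1,
    log2fc: float = 2.0,
    sigma: float = 0.3,
    n_replicates: int = 4,
    abundance_mean: float = 20.0,
    abundance_sd: float = 2.0,
    seed: int = 0,
) -> tuple[QuantMatrix, np.ndarray]:
    """Protein x run log2 matrix for two conditions with planted changes.

    A ``frac_changed`` subset of proteins differs by +-``log2fc`` between
    conditions A and B; per-replicate noise is N(0, sigma) in log2 space.
    Returns the matrix and the boolean truly-changed mask.
    """
    rng = np.random.default_rng(seed)
    proteins = [f"PROT{i:04d}" for i in range(n_proteins)]
    base = rng.normal(abundance_mean, abundance_sd, size=n_proteins)
    changed = np.zeros(n_proteins, dtype=bool)
    n_changed = int(round(frac_changed * n_proteins))
    idx = rng.choice(n_proteins, size=n_changed, replace=False)
    changed[idx] = True
    signs = rng.choice([-1.0, 1.0], size=n_proteins)
    shift = np.where(changed, signs * log2fc, 0.0)
    rows = []
    design_rows = []
    run_ids = []
    for cond in ("A", "B"):
        for b in range(1, n_replicates + 1):
            run_ids.append(f"{cond}_b{b}")
            design_rows.append((f"{cond}_b{b}", cond, f"b{b}", "t1"))
    for i in range(n_proteins):
        mean_a, mean_b = base[i], base[i] + shift[i]
        vals = np.concatenate(
            [
                rng.normal(mean_a, sigma, size=n_replicates),
                rng.normal(mean_b, sigma, size=n_replicates),
            ]
        )
        rows.append(vals)
    values = pd.DataFrame(np.array(rows), index=proteins, columns=run_ids)
    design = SampleDesign.from_rows(design_rows)
    return QuantMatrix(values=values, design=design, scale="log2"), changed
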