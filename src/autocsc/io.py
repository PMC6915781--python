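"""Readers and writers for the pipeline's external tables and sequence files.

All protein coordinates are 1-based (UniProt convention); positions inside a
peptide are 1-based as well.  A missing intensity is encoded as absent, never
zero: zeros found in input intensity columns are converted to missing with a
logged warning, so that CVs and log-transforms stay well defined.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("autocsc")

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: |delta_mass - 0.98| tolerance (Da) used when a modification carries only a
#: numeric mass shift and no name.
DEAMIDATION_DELTA = 0.98
DEAMIDATION_TOL = 0.02


class ParseError(ValueError):
    """Raised for malformed input files; message names the file and line."""


class SchemaError(ValueError):
    """Raised when a table is missing mandatory columns."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: the coordinate frame for glycosites."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be nonempty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be nonempty")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.accession}: invalid residue(s) {sorted(bad)}"
            )


@dataclass(frozen=True)
class Modification:
    """A localized modification: 1-based position in the peptide, a kind
    string (e.g. ``"Deamidated (N)"``) and an optional mass delta in Da."""

    position: int
    kind: str = ""
    delta_mass: float | None = None

    def is_deamidation(self) -> bool:
        if self.kind and "deamid" in self.kind.lower():
            return True
        if self.delta_mass is not None:
            return abs(self.delta_mass - DEAMIDATION_DELTA) <= DEAMIDATION_TOL
        return False


@dataclass
class PeptideObservation:
    """One row of a peptide identification/quantification report."""

    peptide_sequence: str
    modifications: list[Modification] = field(default_factory=list)
    protein_accessions: list[str] = field(default_factory=list)
    score: float | None = None
    q_value: float | None = None
    intensities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.protein_accessions:
            raise ValueError(
                f"peptide {self.peptide_sequence!r}: empty protein group"
            )
        n = len(self.peptide_sequence)
        for mod in self.modifications:
            if not 1 <= mod.position <= n:
                raise ValueError(
                    f"peptide {self.peptide_sequence!r}: modification position "
                    f"{mod.position} outside 1..{n}"
                )
        if self.q_value is not None and not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value {self.q_value} outside [0, 1]")

    def deamidated_positions(self, residue: str = "N") -> list[int]:
        """1-based peptide positions carrying a deamidation on `residue`."""
        return sorted(
            {
                m.position
                for m in self.modifications
                if m.is_deamidation()
                and self.peptide_sequence[m.position - 1] == residue
            }
        )


class SampleDesign:
    """Run -> (condition, biological replicate, technical replicate) table."""

    COLUMNS = ("run_id", "condition", "biological_replicate", "technical_replicate")

    def __init__(self, table: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise SchemaError(
                f"design table missing columns {missing}; found {list(table.columns)}"
            )
        table = table[list(self.COLUMNS)].astype(str)
        dup = table["run_id"][table["run_id"].duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicate run_id(s) in design: {sorted(set(dup))}")
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str, str]]) -> "SampleDesign":
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @property
    def run_ids(self) -> list[str]:
        return list(self.table["run_id"])

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    def runs_for_condition(self, condition: str) -> list[str]:
        sel = self.table[self.table["condition"] == condition]
        return list(sel["run_id"])

    def technical_groups(self) -> dict[tuple[str, str], list[str]]:
        """(condition, biological_replicate) -> ordered run ids."""
        groups: dict[tuple[str, str], list[str]] = {}
        for row in self.table.itertuples(index=False):
            groups.setdefault((row.condition, row.biological_replicate), []).append(
                row.run_id
            )
        return groups

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleDesign) and self.table.equals(other.table)


@dataclass(frozen=True)
class AnnotationRecord:
    """UniProt-style glycosylation site annotation."""

    accession: str
    position: int
    evidence: str  # "experimental" | "predicted"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"{self.accession}: annotation positions are 1-based, got "
                f"{self.position}"
            )
        if self.evidence not in ("experimental", "predicted"):
            raise ValueError(f"unknown evidence class {self.evidence!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_SP_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


def _accession_from_header(header: str) -> tuple[str, str]:
    token = header.split(None, 1)
    first = token[0]
    description = token[1] if len(token) > 1 else ""
    m = _SP_HEADER.match(first)
    if m:
        return m.group(1), description
    return first, description


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file.

    The accession is the first whitespace-delimited header token; UniProt
    ``sp|ACC|NAME`` (and ``tr|``) headers are unwrapped to ``ACC``.  Malformed
    headers, empty sequences and duplicate accessions raise :class:`ParseError`
    naming the offending line.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        accession, description = _accession_from_header(header)
        sequence = "".join(chunks).upper()
        if not sequence:
            raise ParseError(f"{path}:{header_line}: entry {accession!r} has empty sequence")
        if accession in seen:
            raise ParseError(f"{path}:{header_line}: duplicate accession {accession!r}")
        try:
            rec = ProteinRecord(accession, sequence, description)
        except ValueError as exc:
            raise ParseError(f"{path}:{header_line}: {exc}") from exc
        seen.add(accession)
        records.append(rec)
        header, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}:{line_no}: empty FASTA header")
                header_line = line_no
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{line_no}: sequence data before first header"
                    )
                chunks.append(line)
        flush(line_no=header_line)
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.accession}{desc}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# peptide report
# ---------------------------------------------------------------------------


@dataclass
class ReportDialect:
    """Column mapping for a peptide report TSV.

    Two modification encodings are supported:

    * inline brackets in the sequence column: ``"N[+0.98]GSIK"``;
    * a separate column with entries like ``"Deamidated (N)@3; Oxidation (M)@5"``
      or the short form ``"Deamidated@3"``.

    ``intensity_columns`` lists the per-run intensity columns explicitly; run
    ids are the column names.
    """

    sequence: str = "peptide_sequence"
    modifications: str | None = "modifications"
    accessions: str = "protein_accessions"
    score: str | None = "score"
    q_value: str | None = "q_value"
    intensity_columns: list[str] = field(default_factory=list)
    accession_separator: str = ";"


_INLINE_MOD = re.compile(r"\[([+-]?\d+(?:\.\d+)?)\]")
_COLUMN_MOD = re.compile(r"^\s*(?P<kind>[^@]+?)\s*@\s*(?P<pos>\d+)\s*$")


def parse_inline_sequence(raw: str) -> tuple[str, list[Modification]]:
    """Split ``"N[+0.98]GSIK"`` into a bare sequence and its modifications."""
    mods: list[Modification] = []
    bare: list[str] = []
    pos = 0
    i = 0
    while i < len(raw):
        ch = raw[i]
        if ch == "[":
            m = _INLINE_MOD.match(raw, i)
            if not m:
                raise ParseError(f"unparseable inline modification in {raw!r}")
            if pos == 0:
                raise ParseError(f"modification before first residue in {raw!r}")
            mods.append(Modification(position=pos, delta_mass=float(m.group(1))))
            i = m.end()
        else:
            bare.append(ch)
            pos += 1
            i += 1
    return "".join(bare).upper(), mods


def parse_modification_column(raw: str) -> list[Modification]:
    """Parse ``"Deamidated (N)@3; Oxidation (M)@5"`` style entries."""
    mods: list[Modification] = []
    for part in raw.split(";"):
        part = part.strip()
        if not part:
            continue
        m = _COLUMN_MOD.match(part)
        if not m:
            raise ParseError(f"unparseable modification entry {part!r}")
        mods.append(Modification(position=int(m.group("pos")), kind=m.group("kind")))
    return mods


def _parse_float(value: str) -> float | None:
    value = value.strip()
    if value in ("", "NA", "NaN", "nan", "None"):
        return None
    return float(value)


def read_peptide_report(
    path: str | Path, dialect: ReportDialect
) -> list[PeptideObservation]:
    """Read a peptide identification/quantification report TSV.

    Zero intensities are treated as missing (warned); ``NA``/empty cells are
    missing.  Missing mandatory columns raise :class:`SchemaError` listing
    expected vs. found columns.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        found = reader.fieldnames or []
        mandatory = [dialect.sequence, dialect.accessions] + list(
            dialect.intensity_columns
        )
        missing = [c for c in mandatory if c not in found]
        if missing:
            raise SchemaError(
                f"{path}: missing mandatory column(s) {missing}; found {found}"
            )
        observations: list[PeptideObservation] = []
        n_zero = 0
        for line_no, row in enumerate(reader, start=2):
            raw_seq = row[dialect.sequence].strip()
            seq, mods = parse_inline_sequence(raw_seq)
            if dialect.modifications and dialect.modifications in row:
                cell = (row[dialect.modifications] or "").strip()
                if cell:
                    mods = mods + parse_modification_column(cell)
            accessions = [
                a.strip()
                for a in row[dialect.accessions].split(dialect.accession_separator)
                if a.strip()
            ]
            score = (
                _parse_float(row[dialect.score])
                if dialect.score and dialect.score in row
                else None
            )
            q_value = (
                _parse_float(row[dialect.q_value])
                if dialect.q_value and dialect.q_value in row
                else None
            )
            intensities: dict[str, float] = {}
            for col in dialect.intensity_columns:
                val = _parse_float(row[col])
                if val is None:
                    continue
                if val == 0.0:
                    n_zero += 1
                    continue
                if val < 0:
                    raise ParseError(f"{path}:{line_no}: negative intensity {val}")
                intensities[col] = val
            try:
                obs = PeptideObservation(
                    peptide_sequence=seq,
                    modifications=mods,
                    protein_accessions=accessions,
                    score=score,
                    q_value=q_value,
                    intensities=intensities,
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{line_no}: {exc}") from exc
            observations.append(obs)
    if n_zero:
        logger.warning(
            "%s: %d zero intensities treated as missing", path, n_zero
        )
    return observations


def write_peptide_report(
    observations: Sequence[PeptideObservation],
    path: str | Path,
    run_ids: Sequence[str],
    dialect: ReportDialect | None = None,
) -> ReportDialect:
    """Write observations as a TSV readable by :func:`read_peptide_report`.

    Returns the dialect describing the written file.
    """
    dialect = dialect or ReportDialect(intensity_columns=list(run_ids))
    dialect.intensity_columns = list(run_ids)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [dialect.sequence, dialect.modifications, dialect.accessions,
             dialect.score, dialect.q_value] + list(run_ids)
        )
        for obs in observations:
            mods = "; ".join(
                f"{m.kind or f'[{m.delta_mass:+g}]'}@{m.position}"
                for m in obs.modifications
            )
            row = [
                obs.peptide_sequence,
                mods,
                dialect.accession_separator.join(obs.protein_accessions),
                "" if obs.score is None else repr(obs.score),
                "" if obs.q_value is None else repr(obs.q_value),
            ]
            for run in run_ids:
                v = obs.intensities.get(run)
                row.append("NA" if v is None else repr(v))
            writer.writerow(row)
    return dialect


# ---------------------------------------------------------------------------
# design / annotation / generic matrices
# ---------------------------------------------------------------------------


def read_design(path: str | Path) -> SampleDesign:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return SampleDesign(table)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> list[AnnotationRecord]:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ("accession", "position", "evidence") if c not in table.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; found {list(table.columns)}"
        )
    records: list[AnnotationRecord] = []
    seen: set[tuple[str, int]] = set()
    for line_no, row in enumerate(table.itertuples(index=False), start=2):
        try:
            rec = AnnotationRecord(str(row.accession), int(row.position), str(row.evidence))
        except ValueError as exc:
            raise ParseError(f"{path}:{line_no}: {exc}") from exc
        key = (rec.accession, rec.position)
        if key in seen:
            raise ParseError(f"{path}:{line_no}: duplicate annotation for {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_annotation(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.accession, r.position, r.evidence) for r in records],
        columns=["accession", "position", "evidence"],
    ).to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a protein x runs (or protein x populations) TSV with the row id
    in the first column.  Empty cells / ``NA`` become missing."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    out = matrix.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", na_rep="NA")
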