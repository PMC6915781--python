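"""Label-free quantification: replicate consolidation, normalization,
protein rollup, CV reproducibility and differential abundance.

The rollup chain mirrors a standard DIA label-free workflow: feature
intensities are log2-transformed, run medians are equalized, and protein
abundance is the overall-plus-column effect of a Tukey median polish over the
protein's feature x run submatrix.  Differential abundance is a two-sided
Welch t-test on log2 protein abundances with Benjamini-Hochberg adjustment;
a protein is called significant at |fold-change| > 1.5 and adjusted p < 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from autocsc.io import PeptideObservation, SampleDesign

logger = logging.getLogger("autocsc")

FC_THRESHOLD = 1.5
ALPHA = 0.05
ZERO_VARIANCE_EPS = 1e-9


@dataclass
class QuantMatrix:
    """Features-or-proteins x runs abundance table with design metadata.

    ``scale`` is "linear" (raw intensities) or "log2"; operations declare the
    scale they require and refuse mismatches.
    """

    values: pd.DataFrame  # rows x run columns, NaN = missing
    design: SampleDesign
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        unknown = [c for c in self.values.columns if c not in set(self.design.run_ids)]
        if unknown:
            raise ValueError(f"columns not in design: {unknown}")

    def require_scale(self, scale: str) -> None:
        if self.scale != scale:
            raise ValueError(f"operation requires {scale} scale, matrix is {self.scale}")

    def to_log2(self) -> "QuantMatrix":
        if self.scale == "log2":
            return self
        if (self.values <= 0).any().any():
            raise ValueError("non-positive intensities cannot be log2-transformed")
        return replace(self, values=np.log2(self.values), scale="log2")

    def to_linear(self) -> "QuantMatrix":
        if self.scale == "linear":
            return self
        return replace(self, values=2.0 ** self.values, scale="linear")


def matrix_from_observations(
    observations: Sequence[PeptideObservation],
    design: SampleDesign,
) -> tuple[QuantMatrix, dict[str, str]]:
    """Build a linear-scale feature x run matrix from peptide observations.

    Feature ids are ``peptide[@deamidated-positions]``; duplicate features
    (same peptide, same modification positions) are merged by summing run
    intensities.  Returns the matrix and a feature -> assigned-protein map
    (first accession of the group; refine with a proper site assignment when
    a proteome is available).
    """
    runs = design.run_ids
    rows: dict[str, dict[str, float]] = {}
    feature_to_protein: dict[str, str] = {}
    for obs in observations:
        sites = ",".join(str(p) for p in obs.deamidated_positions("N"))
        fid = f"{obs.peptide_sequence}@{sites}" if sites else obs.peptide_sequence
        row = rows.setdefault(fid, {})
        for run, v in obs.intensities.items():
            row[run] = row.get(run, 0.0) + v
        feature_to_protein.setdefault(fid, sorted(obs.protein_accessions)[0])
    values = pd.DataFrame.from_dict(rows, orient="index", columns=runs)
    values = values.reindex(columns=runs)
    return QuantMatrix(values=values, design=design, scale="linear"), feature_to_protein


# ---------------------------------------------------------------------------
# consolidation / normalization / rollup
# ---------------------------------------------------------------------------


def consolidate_technical_replicates(m: QuantMatrix) -> QuantMatrix:
    """Median-collapse technical replicates per biological replicate.

    Output has one column per (condition, biological replicate), named
    ``condition:biological_replicate``; medians ignore missing values and a
    biological replicate with all technical replicates missing stays missing.
    """
    m.require_scale("log2")
    groups = m.design.technical_groups()
    cols: dict[str, pd.Series] = {}
    design_rows: list[tuple[str, str, str, str]] = []
    for (condition, biorep), runs in groups.items():
        runs = [r for r in runs if r in m.values.columns]
        new_id = f"{condition}:{biorep}"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            cols[new_id] = m.values[runs].median(axis=1, skipna=True)
        design_rows.append((new_id, condition, biorep, "1"))
    values = pd.DataFrame(cols)
    return QuantMatrix(
        values=values,
        design=SampleDesign.from_rows(design_rows),
        scale="log2",
    )


def normalize_median(m: QuantMatrix) -> QuantMatrix:
    """Equalize run medians (log2 scale).

    Every run with >= 2 non-missing values is shifted so its median equals
    the global median of run medians; runs with fewer values are left
    unshifted with a warning, and an all-missing run is an error.
    """
    m.require_scale("log2")
    counts = m.values.notna().sum(axis=0)
    empty = [c for c in m.values.columns if counts[c] == 0]
    if empty:
        raise ValueError(f"run(s) with no values: {empty}")
    usable = [c for c in m.values.columns if counts[c] >= 2]
    skipped = [c for c in m.values.columns if c not in usable]
    if skipped:
        logger.warning("runs with < 2 values not normalized: %s", skipped)
    medians = m.values[usable].median(axis=0, skipna=True)
    target = float(np.median(medians.to_numpy()))
    shifted = m.values.copy()
    for c in usable:
        shift = target - medians[c]
        shifted[c] = shifted[c] + shift
        logger.debug("normalize_median: run %s shifted by %+.4f", c, shift)
    return replace(m, values=shifted)


def median_polish(
    x: np.ndarray, max_iter: int = 20, tol: float = 1e-10
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """NaN-aware Tukey median polish.

    Decomposes ``x`` into overall + row + column effects + residuals by
    alternately sweeping out row and column medians.  Returns
    (overall, row_effects, col_effects, residuals).
    """
    x = np.asarray(x, dtype=float)
    nrow, ncol = x.shape
    overall = 0.0
    row_eff = np.zeros(nrow)
    col_eff = np.zeros(ncol)
    resid = x.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for _ in range(max_iter):
            rdelta = np.nanmedian(resid, axis=1)
            rdelta = np.where(np.isnan(rdelta), 0.0, rdelta)
            resid -= rdelta[:, None]
            row_eff += rdelta
            delta = np.nanmedian(col_eff)
            col_eff -= delta
            overall += delta
            cdelta = np.nanmedian(resid, axis=0)
            cdelta = np.where(np.isnan(cdelta), 0.0, cdelta)
            resid -= cdelta[None, :]
            col_eff += cdelta
            delta = np.nanmedian(row_eff)
            row_eff -= delta
            overall += delta
            moved = max(np.max(np.abs(rdelta)), np.max(np.abs(cdelta)))
            if moved <= tol:
                break
    return overall, row_eff, col_eff, resid


def rollup_protein(
    m: QuantMatrix, feature_to_protein: Mapping[str, str]
) -> QuantMatrix:
    """Roll feature abundances up to protein abundances (log2 scale).

    Per protein, abundance in a run is overall + column effect of a Tukey
    median polish over the protein's feature x run submatrix; single-feature
    proteins pass through unchanged.  Runs in which none of the protein's
    features were observed stay missing.  Features absent from the map are
    dropped; a protein left without features is absent from the output.
    """
    m.require_scale("log2")
    by_protein: dict[str, list[str]] = {}
    for fid in m.values.index:
        prot = feature_to_protein.get(fid)
        if prot is not None:
            by_protein.setdefault(prot, []).append(fid)
    rows: dict[str, np.ndarray] = {}
    for prot in sorted(by_protein):
        sub = m.values.loc[by_protein[prot]]
        if len(sub) == 1:
            abundance = sub.iloc[0].to_numpy(dtype=float)
        else:
            overall, _, col_eff, _ = median_polish(sub.to_numpy(dtype=float))
            abundance = overall + col_eff
            observed = sub.notna().any(axis=0).to_numpy()
            abundance = np.where(observed, abundance, np.nan)
        rows[prot] = abundance
    values = pd.DataFrame.from_dict(rows, orient="index", columns=m.values.columns)
    return QuantMatrix(values=values, design=m.design, scale="log2")


# ---------------------------------------------------------------------------
# reproducibility / differential abundance / recovery
# ---------------------------------------------------------------------------


@dataclass
class CVSummary:
    per_feature_cv: dict[str, float]
    median_cv: float | None
    n_features: int


def compute_cv(m: QuantMatrix, group: Sequence[str]) -> CVSummary:
    """Per-feature coefficient of variation over a run group (linear scale).

    CV = sample standard deviation / mean over the feature's non-missing
    intensities in the group; features need >= 2 values to qualify.  The
    summary median is over all qualifying features.
    """
    m.require_scale("linear")
    group = list(group)
    if len(group) < 2:
        raise ValueError("CV group needs at least 2 runs")
    missing_runs = [r for r in group if r not in m.values.columns]
    if missing_runs:
        raise ValueError(f"runs not in matrix: {missing_runs}")
    sub = m.values[group]
    n = sub.notna().sum(axis=1)
    mean = sub.mean(axis=1, skipna=True)
    sd = sub.std(axis=1, ddof=1, skipna=True)
    cv = (sd / mean)[n >= 2].dropna()
    return CVSummary(
        per_feature_cv=cv.to_dict(),
        median_cv=float(cv.median()) if len(cv) else None,
        n_features=int(len(cv)),
    )


@dataclass
class DifferentialResult:
    protein: str
    log2_fold_change: float
    p_value: float | None
    adjusted_p: float | None
    significant: bool
    n_a: int = 0
    n_b: int = 0
    tested: bool = True
    zero_variance: bool = False


def _welch(xa: np.ndarray, xb: np.ndarray) -> tuple[float, bool]:
    """Two-sided Welch t-test p-value with a zero-variance epsilon guard."""
    na, nb = len(xa), len(xb)
    va, vb = np.var(xa, ddof=1), np.var(xb, ddof=1)
    se2 = va / na + vb / nb
    zero_var = False
    if se2 <= 0.0:
        se2 = ZERO_VARIANCE_EPS
        zero_var = True
        df = na + nb - 2
    else:
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = (np.mean(xa) - np.mean(xb)) / np.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(p), zero_var


def differential_test(
    m: QuantMatrix,
    condition_a: str,
    condition_b: str,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
) -> list[DifferentialResult]:
    """Welch two-sided t-test per protein on log2 abundances.

    log2FC = mean(a) - mean(b); Benjamini-Hochberg adjustment across all
    tested proteins; a protein is significant iff |linear fold-change| >
    ``fc_threshold`` (i.e. |log2FC| > log2(fc_threshold)) and adjusted
    p < ``alpha``.  Proteins with < 2 observed values in either condition are
    reported untested and excluded from the BH family.  A zero-variance pair
    gets an epsilon-stabilized variance and is flagged.
    """
    m.require_scale("log2")
    runs_a = [r for r in m.design.runs_for_condition(condition_a) if r in m.values.columns]
    runs_b = [r for r in m.design.runs_for_condition(condition_b) if r in m.values.columns]
    if not runs_a or not runs_b:
        raise ValueError(f"no runs for conditions {condition_a!r} / {condition_b!r}")
    results: list[DifferentialResult] = []
    for protein, row in m.values.iterrows():
        xa = row[runs_a].dropna().to_numpy(dtype=float)
        xb = row[runs_b].dropna().to_numpy(dtype=float)
        log2fc = (
            float(np.mean(xa) - np.mean(xb)) if len(xa) and len(xb) else float("nan")
        )
        if len(xa) < 2 or len(xb) < 2:
            results.append(
                DifferentialResult(
                    protein=str(protein), log2_fold_change=log2fc,
                    p_value=None, adjusted_p=None, significant=False,
                    n_a=len(xa), n_b=len(xb), tested=False,
                )
            )
            continue
        p, zero_var = _welch(xa, xb)
        results.append(
            DifferentialResult(
                protein=str(protein), log2_fold_change=log2fc,
                p_value=p, adjusted_p=None, significant=False,
                n_a=len(xa), n_b=len(xb), tested=True, zero_variance=zero_var,
            )
        )
    tested = [r for r in results if r.tested]
    if tested:
        _, adjusted, _, _ = multipletests(
            [r.p_value for r in tested], method="fdr_bh"
        )
        log2_thr = np.log2(fc_threshold)
        for r, adj in zip(tested, adjusted):
            r.adjusted_p = float(adj)
            r.significant = bool(abs(r.log2_fold_change) > log2_thr and adj < alpha)
    return results


def recovery_fraction(
    census_by_level: Mapping[object, float | Sequence[float]],
    reference_level: object,
) -> dict[object, float]:
    """Fraction of reference-level protein count recovered at each input level.

    Counts may be scalars or per-replicate sequences; the reference count is
    the median over its replicates, and each level's fraction is the median
    of per-replicate count / reference-count ratios.
    """
    if reference_level not in census_by_level:
        raise ValueError(f"reference level {reference_level!r} missing")

    def as_array(v) -> np.ndarray:
        return np.atleast_1d(np.asarray(v, dtype=float))

    ref = float(np.median(as_array(census_by_level[reference_level])))
    if ref <= 0:
        raise ValueError("reference count must be > 0")
    return {
        level: float(np.median(as_array(counts) / ref))
        for level, counts in census_by_level.items()
    }
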