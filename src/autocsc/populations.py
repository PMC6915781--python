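"""Cross-population surfaceome comparison.

Presence/intersection counts (the numbers behind an UpSet plot), row-wise
z-scores for abundance heatmaps, and per-protein cross-modality Spearman
correlation with the limit-of-detection imputation rule: when exactly one of
the two modalities lacks a value for a population, that value is set to 0
(abundance below the limit of detection); populations missing in both are
dropped, and a protein needs at least four populations left to be correlated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from autocsc.io import SampleDesign
from autocsc.quant import QuantMatrix

logger = logging.getLogger("autocsc")

MIN_POPULATIONS = 4


def presence_matrix(protein_values: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Protein x population boolean table.

    A protein is present in a population iff it was quantified (non-missing)
    in at least one run of that population (populations are the design's
    conditions).  Proteins present nowhere are dropped.
    """
    cols: dict[str, pd.Series] = {}
    for condition in design.conditions:
        runs = [r for r in design.runs_for_condition(condition) if r in protein_values.columns]
        cols[condition] = protein_values[runs].notna().any(axis=1)
    presence = pd.DataFrame(cols)
    return presence[presence.any(axis=1)]


def intersections(presence: pd.DataFrame) -> dict[frozenset, int]:
    """Exclusive intersection counts over population subsets.

    Each protein is counted in exactly the subset of populations where it is
    present, so counts sum to the number of proteins.  Only non-empty
    subsets appear in the result.
    """
    if presence.shape[1] < 1:
        raise ValueError("need at least one population")
    if len(presence) and not presence.any(axis=1).all():
        raise ValueError("every protein must be present in >= 1 population")
    counts: dict[frozenset, int] = {}
    populations = list(presence.columns)
    for _, row in presence.iterrows():
        key = frozenset(p for p in populations if row[p])
        counts[key] = counts.get(key, 0) + 1
    return counts


def zscore_rows(values: pd.DataFrame | QuantMatrix) -> pd.DataFrame:
    """Row-wise z-scores ((x - row mean) / row sd, sample sd) over
    non-missing entries; missing stays missing.

    Rows with zero sd are emitted as all-zero with a warning; rows with < 2
    non-missing values are an error.
    """
    if isinstance(values, QuantMatrix):
        values.require_scale("log2")
        values = values.values
    n = values.notna().sum(axis=1)
    if (n < 2).any():
        bad = list(values.index[n < 2])
        raise ValueError(f"rows with < 2 non-missing values: {bad}")
    mean = values.mean(axis=1, skipna=True)
    sd = values.std(axis=1, ddof=1, skipna=True)
    zero_sd = sd == 0
    if zero_sd.any():
        logger.warning(
            "%d constant row(s) z-scored to zero", int(zero_sd.sum())
        )
    sd = sd.replace(0.0, np.nan)
    z = values.sub(mean, axis=0).div(sd, axis=0)
    z.loc[zero_sd] = values.loc[zero_sd] * 0.0  # NaN propagates, values -> 0
    return z


@dataclass
class CorrelationResult:
    protein: str
    rho: float
    n_populations_used: int
    modality_pair: tuple[str, str]


@dataclass
class SpearmanSummary:
    results: list[CorrelationResult]
    average_rho: float | None
    skipped: list[str]  # proteins failing the >= min_populations rule


def cross_modality_spearman(
    a: pd.DataFrame,
    b: pd.DataFrame,
    min_populations: int = MIN_POPULATIONS,
    modality_pair: tuple[str, str] = ("csc", "flow"),
) -> SpearmanSummary:
    """Per-protein Spearman correlation between two protein x population tables.

    Shared proteins and populations (by label) are used.  Per protein and
    population: a value missing in exactly one modality is imputed as 0 in
    that modality; populations missing in both are dropped.  Proteins with
    fewer than ``min_populations`` populations left are skipped and listed.
    Ties are handled with average ranks; the summary is the unweighted mean
    of per-protein rho values.
    """
    proteins = [p for p in a.index if p in set(b.index)]
    populations = [c for c in a.columns if c in set(b.columns)]
    if not populations:
        raise ValueError("no shared populations between modalities")
    results: list[CorrelationResult] = []
    skipped: list[str] = []
    for prot in proteins:
        va = a.loc[prot, populations].to_numpy(dtype=float)
        vb = b.loc[prot, populations].to_numpy(dtype=float)
        miss_a, miss_b = np.isnan(va), np.isnan(vb)
        keep = ~(miss_a & miss_b)
        va = np.where(miss_a, 0.0, va)[keep]
        vb = np.where(miss_b, 0.0, vb)[keep]
        if len(va) < min_populations:
            skipped.append(str(prot))
            continue
        rho = stats.spearmanr(va, vb).statistic
        if np.isnan(rho):  # constant vector after imputation
            skipped.append(str(prot))
            continue
        results.append(
            CorrelationResult(
                protein=str(prot),
                rho=float(rho),
                n_populations_used=int(len(va)),
                modality_pair=modality_pair,
            )
        )
    average = float(np.mean([r.rho for r in results])) if results else None
    return SpearmanSummary(results=results, average_rho=average, skipped=skipped)
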