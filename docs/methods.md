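# Methods

## Background and model

N-linked glycosylation occurs on asparagines within the consensus sequon
N-X-S/T (rarely N-X-C). In a cell surface capture experiment, surface
glycans are tagged and their glycopeptides enriched; PNGase F then releases
the peptides by cleaving the glycan, converting the glycosylated asparagine
to aspartate. The residual +0.98 Da deamidation is the evidence that a
specific asparagine — identified by protein accession and 1-based residue
position — was glycosylated. The package's job is everything downstream of
the search engine: deciding which deamidated peptides are genuine formerly
glycosylated peptides, projecting them onto protein coordinates, counting
unique sites and protein groups, quantifying, and comparing populations.

## Glycopeptide filter

A peptide observation is retained when

1. its identification q-value (when present) is ≤ `q_threshold`
   (default 0.01, i.e. 1 % FDR);
2. at least one deamidation sits on an asparagine whose `NX[STC]` sequon
   holds. The motif is checked inside the peptide when the +1/+2 residues
   are inside it; when the asparagine lies within two residues of the
   peptide C-terminus, the peptide is located in its protein(s) and the
   motif is completed from protein context. Peptides needing context that
   cannot be located in any group member are routed to an `unmappable`
   report rather than silently dropped;
3. its protein group is not purely contaminants (configurable accession
   prefixes, default `CON_`/`CONT_`/`REV_`).

Deamidation is recognised by a kind string containing "deamid"
(case-insensitive) or, when only a numeric shift is given, by
|Δm − 0.98 Da| ≤ 0.02 Da. The reader tolerates deamidation annotations on
any residue (search engines sometimes configure the modification on
arginine); the filter only credits asparagines.

Two deliberate conventions, each switchable:

* **Proline at X.** The default motif is the literal `NX[STC]` — proline is
  allowed at X. The conventional X ≠ P restriction is available via
  `exclude_proline_x` but off by default so that filtering and counting use
  one consistent motif definition.
* **NXC.** Counting and filtering both accept C as the third residue by
  default (`third_residues="STC"`); restricting to `"ST"` is a parameter.

## Site mapping and counting rules

1. Only sequon-conforming deamidated asparagines produce sites.
2. A peptide whose sequence occurs in more than one accession of its group
   is assigned to a single protein. The choice is made deterministic: the
   lexicographically smallest accession containing the peptide, so censuses
   are reproducible run to run.
3. Within the assigned protein, a peptide matching at several offsets keeps
   all offsets unless one offset yields strictly more sequon-conforming
   deamidated asparagines; then only the maximal offsets are kept. Ties keep
   every maximal offset.

Proteotypicity is recomputed against the supplied proteome (exact unique
substring match; I and L are *not* equated, since search engines emit
database-resolved sequences). Peptides that also match accessions outside
their declared group are flagged non-group-specific and excluded from
censuses, mirroring a "protein group specific" extraction filter. Censuses
key protein groups by the sorted accession tuple, count unique
(accession, position) pairs, and report the median sites per group over
groups with ≥ 1 site (undefined for an empty census).

Annotation comparison marks a site novel iff its (accession, position) is
absent from the annotation table; annotated-but-unobserved sites are counted
only on proteins with at least one observed site, since site-level coverage
is meaningful only for the identified part of the surfaceome.

## Quantification

All operations are scale-tagged (`linear` vs `log2`) and refuse mismatched
input.

* **Consolidation**: technical replicates collapse to their median
  (missing-ignoring) per biological replicate, on log2 values.
* **Normalization**: each run with ≥ 2 values is shifted so its median
  equals the median of run medians. Idempotent by construction; an
  all-missing run is an error, a run with one value is left unshifted with a
  warning.
* **Rollup**: per protein, a NaN-aware Tukey median polish over the
  feature × run submatrix; protein abundance per run is overall + column
  effect (20 sweeps, tolerance 1e-10). Single-feature proteins pass
  through; runs without any observed feature stay missing. Median polish was
  chosen because it removes per-feature offsets (ionization efficiency)
  robustly; replicating any particular statistical package's output is a
  non-goal.
* **CV**: computed on linear intensities (sd/mean, sample sd, ≥ 2 values per
  feature); the summary is the median over qualifying features. A log2-scale
  CV is available as an explicit option.
* **Differential abundance**: Welch two-sided t-test per protein on log2
  abundances, log2FC = mean(a) − mean(b), BH adjustment over all tested
  proteins; significant iff |log2FC| > log2(1.5) and adjusted p < 0.05.
  Proteins with < 2 observed values in a condition are reported untested and
  excluded from the BH family; no imputation is performed. A zero-variance
  pair receives an epsilon (1e-9) on the squared standard error and
  residual-style degrees of freedom, and is flagged, rather than emitting
  p = 0.
* **Recovery**: dilution-series counts divided by the reference-level count;
  medians over replicates on both sides.

## Population comparison

Presence means quantified (non-missing) in ≥ 1 run of a population.
Intersection counts are exclusive — each protein counts in exactly the
subset of populations where it is present, so counts sum to the number of
proteins. Row z-scores use the sample sd over non-missing entries; constant
rows are emitted as zeros with a warning. Cross-modality Spearman applies
the limit-of-detection rule per protein and population *before* ranking: a
value present in exactly one modality sets the other to 0, both-missing
populations are dropped, and proteins with < 4 populations left are skipped
and listed. Ties get average ranks; the summary is the unweighted mean of
per-protein rho.

## Synthetic data

The generator emulates the pipeline's inputs, not spectra: no retention
time, ionization or spectrum-level modelling, and no missingness structure
beyond independent dropout — so passing tests demonstrate correctness of the
downstream logic, not search-engine performance on real data.

* **Proteome**: random sequences (uniform over the 20 canonical residues),
  lengths 300–600, with sequons planted at a controlled density
  (default 0.005 sites/residue ≈ 1–3 per protein, the scale of observed
  surface-protein site counts, median 2 per group). Incidental sequons
  arising by chance are removed by point mutation, so the planted list *is*
  the complete truth (asserted by a rescan). Planted X avoids proline so
  truth is valid under either proline convention.
* **Report**: tryptic digestion (cleave after K/R, ≤ 2 missed cleavages, no
  proline suppression by default), optional semi-tryptic trimming of one
  terminus, detectability window 6–30 residues. Every detectable peptide
  covering a true site is reported with deamidation at the site;
  a configurable fraction of all deamidations are decoys planted on
  non-sequon asparagines of sequon-free peptides. Non-protein-specific
  glycopeptides are withheld (the proteotypicity filter applied at the
  source), making `reported_sites` the exact census a correct pipeline must
  recover from a noise-free report. Intensities are
  2^(protein log2 abundance + feature offset + N(0, σ)); σ defaults to the
  log2 sd matching a linear CV of 0.28 via CV = √(exp(σ_ln²) − 1), and
  values drop out independently at `missing_rate` (default 0.05).
  Replicate design defaults to four biological replicates per condition.
* **Annotation**: disjoint fractions of true sites labelled
  experimental/predicted (defaults 0.1/0.75 — most database site annotation
  is computational) plus extra never-observed rows; the sampling record
  computes the exact expected comparison counts.
* **Differential matrix**: baseline log2 abundances N(20, 2), a 10 % subset
  shifted by ±2 log2 units, per-replicate noise N(0, 0.3), 4 replicates per
  condition — the regime where the double threshold should recover nearly
  all changes.

All randomness flows through `numpy.random.default_rng` seeded from a single
integer; sub-seeds are fixed offsets, so every artefact is byte-reproducible
per seed and platform-stable.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen so the whole suite
completes in seconds while keeping estimates stable: 200-protein proteomes
for the closed loop, 1000 randomized cases for the mapping-rule oracle,
~600 features × 10 replicates for CV recovery, 500 proteins × 4 replicates
for differential recovery. The sample CV at n = 10 is biased slightly low
(E[s] ≈ 0.97 σ), which is why the measured median CV sits ~5–8 % below the
generator target; this is a property of the estimator, not an error.

## Known limitations

* "Arbitrary" single-protein assignment is a tie-break convention; counts
  are reproducible but the chosen accession is not biologically privileged.
* The rollup is a simplified stand-in for full mixed-model protein
  inference; between-run correlation structure is ignored.
* Spontaneous (non-enzymatic) deamidation is indistinguishable from PNGase F
  deamidation here; no isotopic-labelling correction is modelled.
* Site-localization ambiguity within a peptide (two sequon asparagines, one
  deamidation) is resolved by trusting the reported modification position.
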