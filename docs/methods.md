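# Methods

This note documents the models, conventions and design choices behind
`isomrm`, in the order data flows through the package.

## Digestion and discrimination

Trypsin is modelled as cleaving C-terminal to every K and R; the sequence
termini are always boundaries. With 0 missed cleavages (the default) the
fragments tile the protein exactly; `max_missed_cleavages = m` adds every
concatenation of up to `m+1` adjacent fragments. The classical proline
exception (no cleavage before P) is available behind a flag but off by
default: for uniqueness analysis the plain after-K/R rule is the
definition of "tryptic peptide", and enabling the exception only changes
which strings are compared, not the logic.

A peptide **discriminates** an isoform group when the set of proteins
containing it — computed over the family *and* the background proteome —
is a non-empty subset of the group. Discrimination is purely
set-theoretic on peptide strings; no alignment is computed, and I/L are
treated as distinct letters (they are distinct residues even though
isobaric; collapsing them would be a mass-spec detectability concern, not
a sequence one, and can be emulated by pre-mapping the input).

Two family members are **indistinguishable** when the symmetric
difference of their digest peptide sets (after the length filter, if one
is applied) is empty; indistinguishability is closed transitively
(union–find) and each resulting group is labelled with the concatenated
member labels. Quantifiability requires at least `min_peptides = 2`
discriminating peptides that also appear in the discovery evidence and
fall within the selection length bounds, default 6–30 residues — typical
targeted-proteomics practice: shorter peptides are rarely unique or
well-behaved in the collision cell, longer ones ionize and transmit
poorly. Bounds apply at selection, not digestion, so indexing remains
exact. Selected peptides are ordered by length then lexicographically so
reports are deterministic.

## Mass arithmetic and transition design

Monoisotopic residue masses are hard-coded from the standard table at
6-decimal precision, with water 18.0105646 Da and proton 1.00727646 Da.
Cysteine carries the fixed carbamidomethyl modification (+57.021464 Da)
reflecting iodoacetamide alkylation during sample preparation. Neutral
peptide mass = Σ residues + water; `m/z = (M + z·m_p)/z`. Fragment
neutrals: `b_k` = first k residues, `y_k` = last k residues + water, so
`neutral(b_k) + neutral(y_{n−k}) = neutral(precursor)` exactly — this
identity is asserted to 1e-6 Da throughout the tests.

In a real assay transitions are ranked by observed intensity in spectral
data; no such data exists at design time here, so the ranking is a
deterministic proxy: y ions before b ions (y ions dominate tryptic CID
spectra), larger ordinals first (larger fragments are more specific),
products below 300 m/z excluded (immonium/noise region). The default of
up to 6 transitions per peptide, 2-minute retention windows, and a
1.5-unit cycle time are configuration values, not physics; the scheduler
simply counts window overlaps on a 0.01-min grid and divides the cycle
time by the concurrency to flag dwell-time violations. The cycle-time
default is taken verbatim from the workflow being modelled and is
deliberately not "corrected".

Precursor charge defaults to 2+ (typical tryptic peptide) and fragment
charge to 1+. No collision-energy optimization, intensity prediction or
iRT calibration is attempted.

## Quantification model

Per sample: transition areas are summed into a peptide AUC *before* the
logarithm (sums of co-eluting transitions are the standard peptide-level
signal); `ln` of a zero sum is undefined, so such peptides are treated as
missing in that sample — never imputed. Group abundance is

```
abundance = mean(ln AUC over target peptides) − mean(ln AUC over control peptides)
```

the log of the ratio of geometric means. "Normalized to" is implemented
as Ln-scale subtraction because it is the only reading that makes the
downstream fold change a well-defined positive ratio and makes the
abundance invariant to any global multiplicative rescaling of a sample.
Three invariances are enforced by tests: rescaling a sample changes no
abundance (to 1e-9); the control protein treated as a target has
abundance exactly 0; swapping condition labels maps every per-donor fold
change f to 1/f.

Per-donor fold change = `exp(abundance_B − abundance_A)`; the study-level
fold change is the **arithmetic** mean of the per-donor ratios (the
convention of reporting "mean of N replicate ratios"), with a geometric
option. Donors missing either condition are excluded with a warning; with
fewer than 3 complete pairs the fold change is still reported but no test
is run (the normality gate is undefined below n = 3).

The loading control is a dataset-level choice: the two study modes mirror
designs where a mitochondrial enzyme is stable across the paired
conditions (capacitation mode) and an axonemal protein is stable across
motility phenotypes (motility mode).

Peak integration is a plain trapezoid over a fixed window; a linear
baseline (chord between the window-edge intensities, floored at 0) is
available behind a flag. No peak picking, RT alignment or interference
detection — the unit of record is the integrated AUC.

## Statistical dispatch

* Paired comparison: Shapiro–Wilk on the vector of paired differences
  (the quantity the paired t assumes normal; applying it per condition is
  a documented alternative we did not take). p ≥ 0.05 → paired *t*;
  otherwise Wilcoxon signed-rank with Pratt zero handling. All-zero
  differences are a degenerate no-signal case reported as p = 1.
* Group contrast: Shapiro–Wilk on pooled within-category residuals and
  Bartlett across categories; both must pass at 0.05 for one-way ANOVA,
  and failing either (the gate that fired is recorded) routes to
  Kruskal–Wallis. A category of size 1 forces the non-parametric branch.
  Pairwise category "fold changes" are `exp(mean_i − mean_j)` because the
  abundances live on the Ln scale; a direct ratio of Ln values would be
  scale-dependent and could be negative.
* Spearman correlation: average ranks for ties; exact two-sided
  permutation p for n ≤ 9 (feasible: 9! rank correlations, vectorized),
  the t approximation above. Constant input is reported as
  "rho undefined" with a reason rather than raised, so screening loops
  survive degenerate groups.
* Percentages are arcsine-square-root transformed
  (`arcsin √(p/100)`) before parametric testing.
* Raw p-values are reported across isoforms by default, matching the
  screening character of an 8-isoform panel; Benjamini–Hochberg
  adjustment is available (`stats.bh_adjust`) but off by default.

The gate level reuses the global α = 0.05; no separate normality α is
defined.

## Synthetic-data model

The generator's defaults define the reference study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_donors` | 6 | paired design size |
| `sigma_donor` | 0.2 | Ln-scale SD of the donor effect, shared across a donor's conditions |
| `sigma_peptide` | 0.3 | Ln-scale SD of the fixed per-peptide response |
| `sigma_residual` | 0.05 | Ln-scale SD of independent measurement error |
| `base_level` | 12 | Ln-scale grand mean (arbitrary units) |
| `n_transitions` | 5 | transitions per peptide, fractions ∝ n+1−k |

The donor effect is shared between a donor's two conditions, which is
what makes the within-donor comparison informative and is the reason the
paired design exists. Transition fractions are a fixed decreasing
sequence rather than random so peptide sums are stable across seeds. The
variance components are chosen for testability — no public raw data
exists to calibrate them against — so passing recovery tests demonstrates
correctness of the estimator under the stated model, not biological
realism. The generator does not emulate interference, matrix effects,
RT drift across samples, or informative dropout; real MRM data can fail
in all of those ways.

Chromatogram rendering draws each transition as a Gaussian of SD
`peak_sigma_min` (default 0.05 min) whose continuous integral equals the
requested area, sampled every 0.005 min over ±4σ, with optional constant
baseline and additive noise; a sampling step ≥ σ is rejected as
undersampling. RT jitter is drawn per (sample, peptide) so a peptide's
transitions co-elute.

For the motility mode, total motility is uniform over a configurable
range, the optional association is a linear Ln-abundance shift per 100
percentage points of motility (0 = the null), and the 3/7/3 category
design labels the lowest-motility tail as the astheno group with the
remainder split randomly between the two high-motility categories —
samples beyond the requested sizes stay unlabelled, as in a cohort where
only a subset fits strict category definitions.

## Problem sizes used in validation

The test suite and the acceptance script run the oracle-equivalence check
on 100–200 random proteins (lengths 20–400), mass identities on 500–1000
random peptides, fold-change recovery on 200 replicates per true fold,
and calibration on 500–1000 paired replicates plus 1000–2000 correlation
and group-contrast replicates. These sizes give Monte-Carlo standard
errors comfortably inside the asserted tolerances (e.g. ±0.01 on a 0.05
rejection rate at 1000 replicates) while keeping a full run in tens of
seconds.

## Known limitations

* Transition ranking is a stated stand-in for intensity-based selection;
  the resulting lists are plausible but not optimized assays.
* Fixed integration windows; any per-sample refinement of peak boundaries
  is out of scope.
* No PTM handling: a modified peptide is a different string and would
  need its own entry.
* Exact Spearman permutation is limited to n ≤ 9 by factorial growth.
* The indistinguishability merge is exact for the digest parameters used
  to build the index; changing digestion parameters requires rebuilding
  the index (enforced by the API shape, not by caching).
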