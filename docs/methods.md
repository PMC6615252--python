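# Methods

## Scope and data model

The package analyses protein-observed NMR titrations: a ¹⁵N-labelled
protein is titrated with an unlabelled peptide ligand and a 2D ¹H-¹⁵N
HSQC is recorded at each ligand:protein molar ratio. The inputs are
per-residue backbone amide shift tables (one per titration point, CSV in
a long or wide dialect) plus a YAML manifest carrying the protein
concentration and the ratio schedule. Missing peaks — prolines, overlap,
exchange broadening — are explicit nulls throughout and never coerced to
0 ppm, because 0 ppm is a legal shift and zeroing missing perturbations
would bias the fits toward weaker apparent binding.

Residue identity across conditions is by residue index after an optional
signed numbering offset (assignment sources for the same protein are
frequently shifted by a residue); residue-type disagreements across
tables warn rather than fail, since renumbered constructs legitimately
disagree at the margins.

## Weighted CSP

Per residue and titration point, relative to the ligand-free (apo)
reference:

Δδ_obs = sqrt(Δδ(¹H_N)² + (Δδ(¹⁵N)/s)²),  s = 5 by default.

The ¹⁵N divisor compensates the larger nitrogen ppm dispersion; 5 is the
conventional weight and is configurable. CSPs are always computed
against apo, not between consecutive points, so each column of a CSP
profile estimates Δδ_max·f_b directly. The statistic is invariant under
sign flips of either shift difference and scales linearly with both.

## Binding isotherm

The observed CSP follows Δδ_obs = Δδ_max · f_b. Two forms of the bound
fraction are implemented:

* **quadratic** (default): exact 1:1 mass balance in *total*
  concentrations, f_b = ((P+L+K) − sqrt((P+L+K)² − 4PL))/(2P). The
  discriminant is mathematically ≥ 0; round-off excursions below zero
  smaller than 1e-12 are clamped, anything larger raises.
* **hyperbolic**: L/(L+K), the dilute limit that treats total ligand as
  free ligand. The two agree within 1% relative whenever P ≤ K/100
  (asserted as a property test); at the design point of this package —
  P = 0.25 mM against K_D of 0.2–2.6 mM — depletion is material and the
  quadratic form is the default.

Concentrations are mM internally; K_D is converted to μM only at
reporting boundaries.

## Per-residue fitting and aggregation

Residue selection is either an explicit list (the classical practice of
fitting residues in and around the binding cleft) or a threshold rule:
endpoint CSP ≥ mean + k·SD over all observed endpoints (k = 1 by
default, sample SD), with zero-valued residues never selected.

Each selected residue's (L, Δδ_obs) curve is fitted for (K_D, Δδ_max) by
`scipy.optimize.least_squares` (trust-region reflective) with bounds
K_D ∈ [1e-3, 1e3] mM and Δδ_max ∈ [0, 10] ppm, unweighted residuals (no
per-point uncertainties are available), and a deterministic multistart
over K_D₀ ∈ {0.05, 0.2, 0.5, 2, 5} mM with Δδ_max initialised at the
endpoint CSP. The lowest-cost start wins, first-come on ties; identical
inputs give bit-identical estimates. Degenerate cases: an all-zero curve
reports "no perturbation"; a K_D pinned to a box bound (e.g. an
instantly saturating curve, which contains no K_D information) is
flagged non-identifiable; both are excluded from aggregation.

The aggregate affinity is the arithmetic mean of the converged
per-residue K_Ds, with the sample standard deviation (n−1) as the error —
the spread of independent single-residue estimates, which is the
convention when no per-point error model exists. With one contributing
residue the spread is undefined and reported as 0 with a note. A global
fit (one shared K_D, per-residue Δδ_max) is available as a non-default
cross-check and agrees with the per-residue average on clean data.

The **partial-saturation flag** is raised when the median endpoint
fraction bound over contributing residues is below 0.8. At the built-in
design (P = 0.25 mM, endpoint ratio 1:30) the weakest scenario
(K_D = 2574 μM) ends at f_b ≈ 0.74 and is flagged; the next weakest
(721 μM, f_b ≈ 0.91) is not. The floor thus separates titrations that
genuinely approached saturation from those extrapolating Δδ_max.

## Differential CSP

Two conditions are compared residue-by-residue with the same weighted
formula applied to the inter-condition differences; the result is
symmetric in the conditions. Residues lacking a complete amide pair in
either condition are reported "not comparable". The default significance
rule adds a **minimum-effect floor** of 0.01 ppm to the mean + 1·SD
threshold. The floor is the design choice that makes the null case
behave: when the two conditions are identical up to noise, the deltas
are half-normal-ish and a purely relative mean + SD cutoff always flags
the upper noise tail (~10–15% of residues), whereas typical HSQC
peak-position noise (≤ a few thousandths of a ppm per axis) keeps every
null delta far below 0.01 ppm. 0.01 ppm is at the low end of cutoffs
used for "meaningful" CSPs in practice; it is a parameter
(`SelectionRule.min_delta`) and the K_D residue-selection rule keeps it
at 0, where the signal population itself inflates the threshold.

The interface patch is the significant set minus a user-supplied
exclusion list (canonical cleft residues, known from prior structural
work, are excluded by the user, not auto-detected).

## Ambiguous restraints

AIR sets hold active/passive residue lists per molecule plus a distance
triple (target, lower subtraction, upper addition; default
2.0/0.0/2.0 Å — the common convention, configurable). Serialisation is
one `assign` block per active residue against the OR-combination of the
partner's active ∪ passive residues, at residue granularity (CSP data
identifies residues, not atoms). The parser accepts hand-written files
in the same grammar and reports malformed input with line numbers;
write→read is the identity on any valid set. Passive residues are
caller-supplied: docking engines that derive passives automatically from
solvent accessibility are expected to do so downstream.

## Synthetic titration generator

Defaults encode the study conditions the analysis targets:

| parameter | default | rationale |
|---|---|---|
| protein concentration | 0.25 mM | midpoint of the typical 0.1–0.5 mM NMR sample range; K_D-comparable so depletion matters |
| molar ratios | 1:0, 1:1, 1:3, 1:5, 1:10, 1:20, 1:30 | standard weak-binding titration schedule (a shorter 1:2…1:10 schedule is used for one built-in scenario) |
| residues | 90, 6 responding | one PDZ-domain-sized protein; a handful of cleft residues respond |
| Δδ_max ranges | ¹H ∈ [0.02, 0.3], ¹⁵N ∈ [0.1, 1.5] ppm | typical HSQC titration amplitudes |
| noise | σ_H = 0.002, σ_N = 0.01 ppm | peak-picking reproducibility of a well-resolved HSQC |
| apo shifts | ¹H ∈ [6, 10], ¹⁵N ∈ [100, 135] ppm | backbone amide spectral region |

Signs of the per-residue shift changes are randomised per axis to
exercise the CSP statistic's sign invariance; non-responding residues
carry noise only, providing the null population the threshold rule
needs; dilution on ligand addition is ignored by default (explicit
per-point protein concentrations are accepted). Generation is fully
deterministic given the seed, and the returned truth object reproduces
exactly under regeneration.

`pdz_scenarios()` provides six ready-made specs with generating K_D
values 286, 721, 211, 2574, 661 and 318 μM — the reported affinities of
the PDZ2/PDZ3 single-domain and tandem titrations with APC- and
PRK2-derived peptides — used as ground truths for round-trip recovery.

What the generator does **not** emulate: exchange broadening and
intermediate/slow exchange, peak overlap geometry, titration-dependent
missingness, correlated noise, baseline drift. Passing recovery tests
therefore demonstrates the estimator machinery is correct under the
stated model, not that real spectra of arbitrary quality will yield
these accuracies; in particular the spread-based errors of real
titrations cannot be reproduced without the original peak lists.

## Structure mapping

Per-residue values are written into the B-factor column (61–66) of
ATOM/HETATM records of a chosen chain, scaled linearly to [0, 99.99] by
the map maximum (raw mode available); unmapped residues get the sentinel
−1.00 ("no data", distinct from a true 0) or are left byte-identical
under the skip policy. Only the six B-factor characters of edited
records change; the output re-parses with identical coordinates.

## Peptide masses

Monoisotopic (default) or average masses from pyteomics residue tables
plus one water; N-terminal acetylation adds 42.0106 Da (monoisotopic).
Default termini are free: vendor-quoted masses of synthetic peptides
commonly match the unmodified monoisotopic sum even for acetylated
products — e.g. the PRK2 dodecapeptide MFRDFDYIADWC computes to
1580.64 g/mol free, matching its quoted value, while the APC peptide
KRHSGSYLVTSV computes to 1332.71 g/mol, 0.02 off its quoted 1332.69
under any standard interpretation. Masses are exact internally and
rounded only for display.

## Problem sizes and determinism

The validation suite uses 90–100-residue proteins, 6–7-point titrations,
50 replicates for noisy-estimator checks and 200 seeds for
differential-CSP specificity — sizes at which the complete suite runs in
well under a minute while the Monte-Carlo rates are stable to the
asserted margins. All randomness flows through explicitly seeded
`numpy` generators; fits are deterministic by construction (fixed
multistart, no stochastic optimisation).
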