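# Methods

## Scope and models

`ubamap` implements the quantitative chain of a solution-NMR interaction
study of a small helical ubiquitin-binding domain: chemical-shift-
perturbation (CSP) mapping, dissociation-constant fitting in the
fast-exchange regime, rotational-correlation-time analysis of
self-association, generation of ambiguous docking restraints, and
geometric analysis of structural models. A synthetic-data layer
generates every input with known ground truth.

### CSP mapping

The combined amide perturbation is Δσ = √(Δσ_H² + (Δσ_N/5)²); the ¹⁵N
scaling factor is fixed at 5 with no per-residue weighting. Profile
statistics (mean, SD with ddof = 0) are computed over quantified,
non-broadened, non-proline residues. Classes: *active* above
mean + 1 SD, *passive* between the mean and mean + 1 SD, *insignificant*
otherwise. Residues whose peaks vanish or whose endpoint/reference
intensity ratio falls below a threshold (default 0.2; no literature
value exists, so it is configurable) are *broadened*: excluded from the
statistics, because their CSP cannot be quantified, but classed active,
because severe exchange broadening at a titration endpoint is itself
interface evidence. Classification is taken at the final (saturating)
titration point. Mutant binding activity is
100·avg(Δσ_mut)/avg(Δσ_wt) over a user-chosen set of well-resolved
resonances; the set is a required input since no canonical list exists.

### Binding model and Kd fit

Titration points are specified by target molar ratios r of total ligand
to total protein. Because both species share the sample volume, the
ratio is independent of dilution, and the cumulative stock volume is
v = r·P₀·V₀/stock; totals then follow as [P]ₜ = P₀V₀/(V₀+v),
[L]ₜ = stock·v/(V₀+v). (For 0.5 mM protein titrated to ratio 5.5 from a
5 mM stock this leaves ~0.32 mM protein at the endpoint — dilution is a
>35% effect and must be modelled.) The complex concentration comes from
the exact 1:1 quadratic, evaluated in the cancellation-free product form
[PL] = 2[P]ₜ[L]ₜ/(s + √(s² − 4[P]ₜ[L]ₜ)), s = [P]ₜ+[L]ₜ+K_d. Under
fast exchange Δσ_obs = Δσ_max·[PL]/[P]ₜ.

The fit shares one K_d across residues with one saturating amplitude
per residue (per-residue fits are available as a diagnostic), minimising
summed squared CSP residuals over all (residue, point) observations with
`scipy.optimize.least_squares`. K_d is parameterised as log₁₀(K_d/µM)
with box bounds [10⁻³, 10⁵] µM; multi-start initialisation spans ±2
decades around the median total ligand concentration. Standard errors
come from the Gauss–Newton covariance at the optimum; the K_d error is
delta-method-propagated from the log scale.

### Self-association

τ_c = √(6T₁/T₂ − 7)/(4πω_N) (valid for 6T₁/T₂ > 7; inputs outside this
range are rejected rather than clipped). Per-sample τ_c, when computed
from per-residue values, uses a 10% trimmed mean over amide peaks — the
aggregation statistic is not standardised in the field, and trimming
discards residues with residual internal motion or exchange
contributions at either tail. The τ_c/mass calibration is a straight
line fitted to monomeric standards (3–20 kDa); linearity is the simplest
model consistent with that range, and inversion warns when
extrapolating.

The dimer model uses K_d = [M]²/[D] with chain conservation
C = [M] + 2[D]; the monomer concentration is evaluated as
[M] = 2C/(1 + √(1 + 8C/K_d)) (conjugate form, ~10⁻¹⁵ relative error in
the dilute limit), and τ_obs = (1−f_D)τ_M + f_D·τ_D with
f_D = 1 − [M]/C. The three parameters (K_d on a log scale, τ_M, and
τ_D = τ_M + Δ with Δ > 0 so the ordering constraint holds throughout)
are fitted by multi-start least squares across K_d decades. τ_M and τ_D
are free rather than fixed from calibration: fixing them would import
calibration error into K_d.

**Identifiability caveat.** At the design conditions (8 concentrations,
0.16–1.9 mM, 0.1 ns noise, K_d ≈ 900 µM) a single fit of this model is
weakly identified: Monte Carlo over seeds shows an interquartile range
of roughly 620–1240 µM, although the estimator is median-unbiased. The
acceptance machinery therefore reports the median over seeded replicates
(301 in the script, sized so the median's own sampling error is a few
percent) rather than a single draw.

### Restraints

Active residues become one `assign` block each; partner clauses are the
or-joined union of the partner's active and passive residues in
ascending residue order, with the distance triple fixed at
`2.0 2.0 0.0` (effective 2.0 Å upper bound, the standard convention for
ambiguous interaction restraints). For a homodimer both segments receive
identical lists. An optional relative-solvent-accessibility filter
(default threshold 40%, off by default) can prune buried residues; it is
off because the classification rules alone define the published
protocol. Writing then parsing a table is the identity.

### Structure geometry

PDB I/O goes through gemmi into a flat atom table; element-based average
masses come from gemmi's element data, peptide masses from Biopython
(average isotopes, residues plus one water; no isotope-labelling
correction).

*Helix axes.* Local axis directions are taken from consecutive Cα
quadruplets by the bisector construction — the bisectors at the two
inner residues are both perpendicular to the local axis, so their cross
product gives its direction — and averaged; the anchor is the
least-squares circle centre of the Cα positions projected normal to the
axis (the raw centroid is biased off-axis for non-integer turn counts).
This estimator is exact on ideal helices down to 5 residues, which is
why it is used for the short 3₁₀ segment as well; a straight-line fit
through so few Cα is biased by several degrees by the incomplete final
turn and is retained only for 4-residue segments. Axes are oriented
N→C so obtuse packing angles (e.g. 138°) are representable; an
undirected option folds angles to [0°, 90°]. Default helix ranges for
the UBA-type bundle: 3₁₀ 368–372, α1 375–381, α2 386–400, α3 407–419,
with PDB numbering taken verbatim.

*Superposition and clustering.* Kabsch superposition via SVD with the
determinant correction (no reflections). Ensembles are clustered on the
pairwise superposed-RMSD matrix by greedy neighbour counting: the model
with the most neighbours within the cutoff (default 5.0 Å) seeds a
cluster, its members are removed, and the process repeats — an emulation
of cutoff-based docking-server clustering (the exact server algorithm is
unpublished); ties break to the lowest model index, and the output
partitions the ensemble.

*Surfaces and clashes.* SASA is Shrake–Rupley with a deterministic
golden-spiral point set (default 960 points, probe 1.4 Å) over
Chothia-style radii (C 1.70, N 1.55, O 1.52, S 1.80 Å); unknown elements
are an error, not a guess. Buried surface is SASA(A)+SASA(B)−SASA(AB).
Contact and clash screening uses heavy-atom distance cutoffs (4.0 /
2.5 Å) with a severe-clash verdict above a configurable pair count
(default 10). Assemblies are built by superposing a complex's receptor
chain onto each protomer of a dimer over shared backbone (residue,
atom-name) pairs and transplanting the ligand chains under fresh chain
ids.

## Synthetic data: what it emulates, and what it does not

The titration generator reproduces two-state fast exchange exactly: free
peak positions uniform in the amide window (¹H 7.9–9.5, ¹⁵N 105–130
ppm), each residue moving along a fixed random direction in the scaled
shift plane by Δσ_max times the bound fraction, with exact
depletion+dilution bookkeeping and Gaussian position noise (defaults
σ_H = 0.002, σ_N = 0.01 ppm — typical digital resolution; no literature
value exists for this study type). Optionally, designated residues
attenuate with the bound fraction to emulate intermediate-exchange
broadening. Default design: 0.5 mM protein, 500 µL, 5 mM stock, 10
ratios 0→5.5 (2.5 mM stock and ratios to 2.5 for the diubiquitin
variant), 15 residues with amplitudes 0.05–0.7 ppm.

The relaxation generator produces the population-weighted τ_c at each
concentration (defaults: 8 points 0.16–1.9 mM, K_d 900 µM, τ_M 4.8 ns,
τ_D 12.1 ns — the pair consistent with endpoint τ_c values of 6.4 and
9.3 ns — σ_τ 0.1 ns, ω_N 60.8 MHz) and back-converts to a consistent
(T₁, T₂) pair by holding T₁ at a nominal 0.5 s and solving the τ_c
formula for T₂, so either analysis route sees the same observable.

Not emulated: spectral lineshapes, peak overlap, intermediate/slow
exchange lineshape distortion, anisotropic diffusion, per-residue
relaxation heterogeneity, NOESY data. Passing tests therefore
demonstrate correctness of the estimators under the stated statistical
model, not robustness to spectral artefacts of real data.

All generators take an explicit seed and are bit-reproducible; with zero
noise their observables equal the forward-model values to numerical
precision.

## Numerical choices and degenerate inputs

- Binding quadratic and monomer concentration in cancellation-free
  forms (agreement with brute-force equilibrium solvers to 1e-10 and
  mass-action self-consistency to 1e-12 are tested).
- Fits reject under-determined inputs explicitly: <3 titration points,
  all-zero CSPs, <4 concentrations or <5-fold range, flat τ_c series.
- τ_c formula inputs with 6T₁/T₂ ≤ 7 are an error.
- Duplicate residue numbers in a peak list are an error; ambiguous peak
  matches (two trajectories claiming one peak) leave both unmatched.
- Degenerate helix directions and <4 Cα segments are errors.

## Problem sizes

Tests and the acceptance script run at desk scale: 10-point × 15-residue
titrations, 8-point relaxation series (301 replicates for the reported
dimer-Kd median; 15 in the corresponding test), 960–3840 SASA points,
ensembles of ≤15 models. The full suite completes in well under a
minute; the acceptance script in ~15 s.

## Known limitations

- Single-site 1:1 and monomer–dimer models only; no cooperative or 2:1
  stoichiometries, no slow/intermediate-exchange lineshape fitting.
- The calibration standards are user-supplied; apparent masses inherit
  whatever bias the supplied line carries.
- The deposited-ensemble geometry checks (interhelical angles of the
  2KNA ensemble, Rg of 1UBQ) require network access to the PDB; without
  it those two tests fail while the same operations are validated on
  constructed ground truth.
- Greedy neighbour-count clustering approximates, but is not guaranteed
  to equal, any particular docking server's clustering.
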