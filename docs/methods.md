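# Methods

## Data selection

Structure-level rules mirror standard crystallographic practice for
hydrogen-sensitive analyses: X-ray structures with resolution *strictly
better* (numerically smaller) than the cutoff (1.2 Å default for
hydrogen-bond work, where hydrogen positions matter; 1.5 Å for dihedral
work, which is insensitive to them), with at least one deposited
hydrogen when required. Structures without a resolution record are
rejected. Atom-level rules keep N, O and H at occupancy ≥ 0.95 — split
conformers essentially never survive this, so every retained atom has an
unambiguous position — and drop HETATM records plus residues named HOH,
DOD or WAT (water and other small molecules). Only the first model of
the deposited asymmetric unit is used; no symmetry expansion.

## Hydrogen-bond candidates

A candidate is any donor–hydrogen–acceptor triplet with donor and
acceptor in {N, O}; the four element combinations (N−H···N, N−H···O,
O−H···O, O−H···N) are analysed separately. Deliberately, *no* covalent
bonding information prunes the candidates: covalently bound and
intra-residue triplets stay in, and the mode clustering is expected to
isolate them as their own motifs. Because deposited hydrogen positions
are often refined at fixed donor distances, only `(d_AH, d_DA)` serve as
clustering descriptors; the pre-filter `d_DH + d_AH ≤ 4.5 Å` removes
unreachable triplets and `d_DH < d_AH` removes the donor/acceptor
relabelling redundancy (the exact tie is discarded). The neighbour
search enumerates, per hydrogen, all donors and acceptors within 4.5 Å
via a KD-tree; since both legs of a surviving triplet are individually
below the sum bound, nothing is missed.

The energy-based reference definition computes the Kabsch–Sander
electrostatic energy `E = 27.888·(1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN)`
kcal/mol over backbone (C=O, N−H) pairs (all four atoms at occupancy
≥ 0.95); pairs below −0.5 kcal/mol count as bonded. Distances at or
below 0.5 Å are treated as singular and excluded. No attempt is made to
reproduce DSSP's bifurcation bookkeeping — only the energy and the
threshold are used.

## Mode clustering

The engine estimates the feature density on a sparse grid and converts
its modes into a Gaussian mixture.

**Grid.** Farthest-point sampling of 2000 points (4000 for dihedral and
descriptor analyses), seeded first pick, ties broken toward the lowest
index. FPS covers the support approximately uniformly, including tails.

**Adaptive KDE.** Each grid point's kernel covariance is the sample
covariance of its nearest `f_loc = 0.15` fraction of the data
(minimum-image displacements for angular dimensions), multiplied by
`bandwidth_scale²`. The density is a sample-smoothing estimate: every
sample is smeared with the kernel of the grid cell it falls in, and this
single fixed density function is evaluated at all grid points. The
alternative "balloon" form (bandwidth of the evaluation point) was
rejected because it inflates the apparent density at outlying grid
points, whose large adaptive bandwidths average over the whole nearby
cluster and turn them into spurious local maxima. Bandwidth scaling
defaults follow the analysis at hand: 0.3 for hydrogen-bond features,
0.15 for 2D dihedrals, 0.30 for 6D/10D windows, 0.20/0.50/0.80 for 2/6/10
reduced descriptor components — deliberately undersmoothing to preserve
multi-modality.

**Quick shift.** Every grid point links to its *nearest* grid point of
strictly higher density within `qs_scale · λᵢ`, where λᵢ is the
geometric-mean standard deviation of the *unscaled* local covariance;
link roots are modes. Two numerical safeguards matter in practice:

* the link length is floored at twice the fourth-nearest grid-neighbour
  distance — the grid cannot support density comparisons below its own
  resolution, and without the floor small groups of tail grid points
  become spurious modes that the weight prune cannot remove;
* after linking, cluster pairs whose saddle density (highest min-density
  over border grid pairs) exceeds `merge_ratio = 0.8` of the weaker
  mode's peak are merged iteratively and deterministically. An
  undersmoothed finite-sample KDE wiggles; dips retaining ≥ 80 % of the
  peak are judged estimation noise, not structure. Genuinely bimodal
  pairs have far deeper valleys. Set `merge_ratio = 0` to disable.

λ uses the unscaled covariance (not the shrunken KDE bandwidth) so the
mode-seeking reach is independent of the deliberate KDE undersmoothing;
the two knobs (`bandwidth_scale`, `qs_scale`) stay orthogonal.

**Mixture.** Each cluster becomes one Gaussian: weight = summed Voronoi
weight (fraction of samples nearest to member grid points), mean and
covariance = density-weighted moments of member grid positions, computed
in minimum-image displacements from the densest member. Near-singular
covariances get a relative ridge `1e-8·trace/d`. Clusters below weight
1e-5 are pruned and the rest renormalised. Identical inputs and seed
give bit-identical models; the text model format round-trips exactly
(floats written with `repr`).

**Periodicity.** Angular dimensions use minimum-image (nearest periodic
copy) displacements everywhere. A fully wrapped kernel would sum over
3^d images and is intractable for 6D/10D windows; for the bandwidths in
use (≪ 360°) the neglected images contribute < 1e-9 relative.

## Motif identifiers and the agreement score

The identifier of mode k is `fₖ(x) = pₖGₖ(x) / (P(x) + ζ)` with
`ζ = 1e-5`; with ζ = 0 the identifiers are posterior responsibilities
and sum to one exactly (computed with max-shifted exponentials for
stability; far-field scores underflow to 0 as intended). For 2D
hydrogen-bond models the bonded mode is the one whose mean is nearest
the reference geometry `(d_AH, d_DA) = (1.82, 2.74) Å`.

The energy-based identifier follows the same posterior form with the
Gaussian replaced by the kernel density of the bonded population:
`f(x) = p_HB·P_HB(x) / (p_HB·P_HB(x) + (1−p_HB)·P_non(x) + ζ)`, where
`p_HB` is the bonded fraction and both conditional densities reuse the
sparse-grid adaptive KDE (each grid point contributing its Voronoi
weight and kernel — a proper normalised density evaluable anywhere).
Fitting refuses a dataset with no bonded pairs rather than silently
returning an identically-zero score. The choice of KDE (over histograms)
for these conditionals is a design decision; it shares one estimator
with the clustering pipeline.

The agreement score between identifiers A and B is evaluated on the
empirical sample measure (no binning):
`δ_AB = (1/λ)·E[f_A f_B]/E[f_A + f_B − f_A f_B]` with
`λ = sqrt(ρ_A ρ_B)`, `ρ_X = E[f_X²]/E[2f_X − f_X²]`. The geometric-mean
normalisation makes δ exactly 1 whenever `f_A = f_B` pointwise (for soft
identifiers a plain product of the two ratios would not), keeps δ
symmetric, and leaves disjoint indicators at 0. Restricted variants drop
triplets whose donor and acceptor share a residue, or additionally are
sequence neighbours (|Δresnum| ≤ 1 within one chain; different chains
are never "nearby"), isolating the intra-residue artifacts that dominate
disagreement between data-driven and heuristic definitions.

## Dihedral features

φᵢ = torsion C(i−1)−N(i)−Cα(i)−C(i), ψᵢ = torsion N(i)−Cα(i)−C(i)−N(i+1),
IUPAC sign, degrees in (−180, 180]. Chain termini, residues with missing
backbone atoms and residues flanking a break (peptide C–N distance
> 2.5 Å) are marked incomplete, never fabricated. Windows of w ∈ {1, 3, 5}
consecutive complete residues give 2w-dimensional features, all periodic
with period 360, labelled by the centre residue. No occupancy rule is
applied to dihedral extraction by default, since torsions do not depend
on hydrogen positions.

## Secondary-structure benchmarking

Labels use the 8-letter alphabet B/E/G/H/I/T/S/C plus X for "no
assignment"; readers exist for classic DSSP output, STRIDE output
(lowercase `b` mapped to B; S never occurs) and a simple TSV. The joint
table accumulates soft cluster probabilities (posteriors, ζ = 0) per
label; a hard-assignment variant exists behind a flag. Clusters map to
strand {B, E}, helix {G, H, I} or coil {C, S, T} by the argmax of
P(y|A), X excluded, exact ties conservatively to coil. Q3 sums the
mapped joint mass; Q8 uses the best single label per cluster; X-labelled
residues are removed before normalisation in both. Q3 ≥ Q8 holds by
construction when both derive from the same table.

## Atomic-density descriptors

Each Cα environment is the sum of Gaussians (width 0.5 Å) on the C, N
and O atoms within 6.0 Å, weighted by a cosine cutoff decaying over the
final 0.5 Å; the central atom is excluded from its own environment. The
density is expanded per species in Löwdin-orthonormalised polynomial
radial functions `(r_c − r)^(n+2)` (n_max = 8) times spherical harmonics
(l_max = 6); the radial integrals against a displaced Gaussian use its
modified-spherical-Bessel closed form, evaluated with exponent-scaled
Bessel functions on a 64-point Gauss–Legendre grid, so the computation
is stable at any neighbour distance. Summing coefficient products over
the harmonic order gives the rotationally invariant power spectrum;
unique species/radial pairs carry a √2 factor so the plain dot product
equals the full overlap kernel. Rotation, translation and same-species
permutation invariance hold to machine precision; these parameters
(supplementary-grade details in the original analyses) are recorded in
output manifests and freely configurable.

Dimensionality reduction is two-stage: farthest-point selection over
descriptor *components* (each represented by its value profile across
sample environments, squared-Euclidean metric — chosen over selecting
representative environments because the purpose is to preserve the span
of the input space for the PCA), then centred PCA persisted as plain
text.

## Supervised baseline

A one-vs-one RBF SVM (C = 1.0, γ = 1/N_f on standardised features, the
scaler fitted on the training split only) predicts 8-state labels from
dihedral windows or reduced descriptors; Q8 is 8-state accuracy, Q3 the
accuracy after grouping predictions and truths into strand/helix/coil.
Default split sizes follow the 50 000/150 000 protocol and shrink
proportionally on smaller pools (warned, never reused). The baseline's
asymptotic accuracy bounds what the representation supports, separating
"the representation cannot see the motif" from "the motif is not a mode
of the data distribution".

## Synthetic study conditions

The generators define the conditions every test and the acceptance
script run at; they emulate the *geometry* of the problem, not its
thermodynamics — no sterics, no energetics, no PDB redundancy biases.

* **Planted mixtures** — seeded Gaussian draws with known components;
  mode recovery runs at means (0,0)/(4,0)/(0,4), isotropic σ = 0.5,
  weights 0.5/0.3/0.2, n = 30 000, a 2000-point grid, bandwidth scale
  0.3, quick-shift scale 1.0.
* **Ideal backbones** — NeRF chain growth at prescribed (φ, ψ) with
  standard bond lengths/angles (N−Cα 1.458, Cα−C 1.525, C−N 1.329 Å,
  ω = 180°), carbonyl O in-plane anti to the next amide and amide H anti
  to the carbonyl O, so helical builds form the i→i+4 hydrogen-bond
  pattern. Zero-noise builds reproduce target dihedrals to machine
  precision; fixed-column PDB output limits round-trip agreement to
  ~0.1°.
* **Hydrogen-bond toys** — isolated donor/H/acceptor groups at
  prescribed distances, 20 Å apart so no cross-group triplet passes the
  reach filter. Three distances determine the donor-centred angle, so a
  prescribed angle is validated, not trusted.
* **Labelled Ramachandran draws** — per-class periodic Gaussians; the
  benchmark condition uses classes H(−60,−45), E(−135,135), C(60,45)
  at σ = 10° (well-separated, Bayes error negligible, so Q3 ≥ 0.95
  certifies the pipeline, not the science of real proteins). The chain
  variant adds Markov run structure (mean run 12 residues) and broader
  classes (σ = 45–50°) so that window context carries real information
  for the supervised monotonicity check.

Passing at these conditions demonstrates correctness of the machinery;
it does not certify behaviour on deposited structures, whose density is
redundancy-biased, heavier-tailed and not a finite Gaussian mixture.

## Problem sizes and numerical notes

Bundled runs are sized for a single CPU: clustering at n ≤ 30 000 with
2000 grid points (O(n·grid) kernel evaluations), agreement scores at
10 000 samples, descriptor invariances at 100 environments with
n_max = 4, l_max = 3 (the invariances are structural, independent of
basis size), SVMs at 2000–3000 training points. Larger corpora run
through the same code paths; `fit_pamm(max_samples=...)` subsamples with
the run's seed and logs it. All stages are deterministic given config
and seed, and every CLI artifact carries a manifest from which it can be
regenerated.

## Known limitations

* The "automatic" bandwidth and quick-shift heuristics of the method's
  reference implementation are realised here as the `f_loc`-based local
  covariance and the floored link rule — a stated stand-in, not a claim
  of formula-level equivalence.
* The saddle-merge ratio (0.8) is a heuristic; data with genuinely
  shallow adjacent modes (valley > 80 % of peak) will see them merged.
* δ values and Q3/Q8 against real DSSP/STRIDE labels depend on the
  structure corpus; the package ships no corpus and makes no claims
  about any particular snapshot.
* mmCIF parsing is delegated to gemmi and lightly exercised; the fixture
  round-trips are PDB-format.
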