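# Methods

## Scope and assumptions

`coronamap` predicts where a folded, globular protein contacts a 15-nm
citrate-capped gold nanoparticle, under the assumptions that (i) adsorption
is mediated by surface side chains, (ii) the protein stays folded and packed
on the surface, and (iii) relative residue affinities measured by host–guest
competition transfer between proteins. The model does not treat
surface-induced unfolding, post-adsorption rearrangement of elongated
proteins, or other surface chemistries; predictions for unstable or
disordered proteins, dilute regimes without full surface coverage, and
non-citrate coatings are expected to degrade accordingly.

## The affinity scale

The scale stores, per residue type, the competitive binding ratio alpha
relative to the glycine host variant, a uniform 0.04 95% confidence interval
and a chemical category. Alphas are dimensionless; cysteine's 5.69 reflects
covalent Au–S anchoring and is the only value above 1. The confidence
intervals are stored but deliberately not propagated into surface scores —
the uniform CI would rescale all scores equally and the downstream decisions
(percentile threshold, patch membership) are rank-based.

Residue molecular volumes (Å³) use Zamyatnin's standard scale (Gly 60.1 …
Trp 227.8). Two subgroup regressions of alpha on volume are canonical:

* aliphatic {G, A, V, I, L, P}: slope ≈ −49 × 10⁻⁴ α/Å³. Methionine is
  excluded as a flagged outlier — its organo-sulfur group interacts
  specifically with gold, inflating alpha above the steric trend.
* polar/aromatic {S, T, Y, W}: slope ≈ −9.6 × 10⁻⁴ α/Å³. Glutamine breaks
  the trend and cysteine binds covalently; both are excluded.

Fits are unweighted ordinary least squares (weighting by the uniform CI
would change nothing); R² is the squared Pearson correlation. The two-point
case returns the exact line with R² = 1 and no slope error.

Disulfide-bonded cysteines must not inherit alpha(C). The default policy
substitutes alpha(Ser) = 0.57 (the isosteric choice); alpha(Ala) and full
exclusion are selectable. Disulfides are detected geometrically: SG–SG
distance ≤ 2.5 Å, greedily matched nearest-first so each cysteine joins at
most one bridge.

## Structures

PDB input goes through Biopython. First model by default (configurable for
NMR ensembles), hydrogens and deuteriums dropped, alternate locations
resolved to the highest-occupancy conformer, water always removed. Non-water
hetero groups (ligands, metals such as the carbonic anhydrase Zn²⁺) are kept
as steric bodies when `keep_het` is on: they shape the surface and the
grid but are never scored for affinity. Author residue numbering is
preserved verbatim because active sites are cited in author numbering.

Van der Waals radii are a single embedded set (C 1.76, N 1.65, O 1.40,
S 1.85, other 1.80 Å). Radius choice shifts absolute SASA by a few percent
but largely cancels in the relative accessibilities, which use the same set
in numerator and reference.

Deterministic toy builders (no randomness anywhere) construct single atoms,
dimers at a chosen separation, extended Gly-X-Gly tripeptides, an
11-residue β-hairpin (strand torsions −139/135 with a type I′ turn) and an
ideal α-helix (−57/−47). Backbones are built by natural-extension-reference-
frame placement with ideal bond lengths/angles; side chains come from
bundled ideal residue templates superposed on the local N/CA/C frame. These
builders are first-class: the Gly-X-Gly conformer defines the full-exposure
reference, and the others are the fixtures for every geometric test.

## Solvent-accessible surface area

Shrake–Rupley with a deterministic golden-spiral (Fibonacci) point set —
960 points per atom by default, probe 1.4 Å. An atom's accessible area is
the fraction of points on its probe-expanded sphere outside every
neighbour's expanded sphere, times the expanded-sphere area. The point set
is fixed in space, so rigid-body motion changes results only within the
quadrature error (< 1% of the total at 960 points; the isolated-sphere error
is below 0.5%, and a two-sphere overlap agrees with the exact spherical-cap
formula to within 2%).

Relative side-chain accessibility divides a residue's side-chain SASA
(non-backbone heavy atoms; for glycine the CA stands in so every residue has
a defined fraction) by the same side chain's area in the extended Gly-X-Gly
tripeptide computed with identical radii, probe and quadrature. Computing
the reference internally rather than adopting a published table keeps
numerator and denominator consistent; the absolute fractions may therefore
differ by a few percent from tables produced by other programs. A frozen
copy of the default-parameter reference ships in the package data and a test
asserts it matches recomputation. Fractions above 1 (unusually open local
geometry) are capped at 1.0 and logged.

## Surface prediction

Per-residue score = alpha × relative accessibility, so score ∈ [0, alpha]
and a buried lysine counts for nothing. Excluded residues — non-standard,
hetero, disulfide-excluded, zero exposure — carry score 0 and are omitted
from grid averaging (they are flagged with the reason in the per-residue
output).

Grid: a cubic lattice (1.5 Å spacing) centered on the bounding box; a point
survives when its distance to the nearest van der Waals *surface* lies in
[1.4, 4.0] Å — a solvent shell one probe radius to ~4 Å off the protein.
Each surviving point averages the scores of residues with at least one
side-chain heavy atom within 8 Å (uniform weighting by default;
inverse-distance optional). Binding is side-chain mediated by construction
of the scale, so backbone proximity does not contribute. Points with no
contributor are dropped.

Thresholding keeps virtual atoms at or above the 75th percentile of the
affinity distribution (ties retained; an absolute-value mode exists).
Retained atoms are clustered into patches by connected components under
pairwise distance ≤ √3 × spacing (the 26-neighbourhood of the lattice),
sorted by mean affinity; components below 3 atoms are kept but flagged
small. None of spacing, shell, cutoff, weighting or threshold are
experimentally determined quantities — they are algorithmic defaults, frozen
in a versioned `RunConfig` whose hash is embedded in every output so
published predictions are bit-reproducible.

Occlusion call: an active-site residue is "in contact" when any of its heavy
atoms lies within 6 Å of an above-threshold virtual atom; the site is
`occluded` when at least half the active-site residues are in contact,
`exposed` otherwise. The 6 Å contact distance is roughly one hydration
shell beyond side-chain reach; the 0.5 fraction makes the call robust to a
single peripheral residue. Both are configurable, and the report always
carries the raw overlap fraction and the minimum patch distance so users
can apply their own cutoffs.

## Binding models

* Competition ratio: alpha = bound_X / bound_G, defined only for
  bound_G > 0; the reciprocal identity alpha(a,b)·alpha(b,a) = 1 is exact.
* Langmuir isotherm λ(c) = λ_free + Δλ_max·c/(K_d + c): trust-region
  nonlinear least squares with deterministic multi-start on K_d (the
  half-saturation concentration, the median and the maximum concentration),
  λ_free from the smallest response and Δλ_max from the range. Requires ≥ 4
  points and a non-flat signal. Note the apparent K_d of slow-desorbing
  systems is close to variant-independent — which is precisely why the
  competition measurement, not the isotherm, defines the scale.
* Biexponential kinetics I(t) = A_f·e^(−t/τ_f) + A_s·e^(−t/τ_s) + offset:
  amplitudes and time constants bounded non-negative, τ_slow initialized
  from the log-linear slope of the trace tail, τ_fast a factor 20 below it,
  order enforced after the fit. A trace is flagged degenerate — and refit
  with a single exponential — when the time constants collapse within a
  factor of 2 or one amplitude falls below 0.1% of the total: both mean the
  data resolve only one decay process. Offsets are fitted per trace, never
  shared.
* Competitive adsorption simulator dθ_i/dt = k_i c_i (1 − Σθ): stiff LSODA
  integration at rtol 10⁻⁹, checked in tests against the closed form
  θ_i = (k_i c_i / K)(1 − e^(−Kt)), K = Σ k_j c_j. It is an interpretive
  aid, not a fitted model: it demonstrates that total bound protein at
  saturation is rate-independent (capacity conservation) while the split
  between competitors follows the rates.

Synthetic generators take explicit seeds (default 20221127) and emulate the
measurement designs: a ten-point titration to 20 µM with ~0.1 nm plasmon
noise, and 5-min sampling to 365 min with ~0.02 normalized-intensity noise,
with true time constants of 5 and 150 min. They produce iid Gaussian noise
on exact model curves — no baseline drift, peak overlap or exchange
broadening — so parameter-recovery tests validate the fitters, not the
spectroscopy.

## Testing strategy and problem sizes

Every geometric operation is checked against an independent oracle: exact
sphere and spherical-cap areas, a second Shrake–Rupley implementation with
matched radii, O(N·M) brute-force grid scoring, union-find clustering, and
closed-form kinetics. Fixtures are small by design (the 11-residue hairpin,
7-residue strands, 960-point quadrature; noisy-recovery tests use 50–100
replicates), which keeps the whole suite and the acceptance script in the
tens of seconds while exercising every code path at full default
resolution. Checks that need externally supplied PDB entries (GB3,
proteinase K, carbonic anhydrase II and the literature enzymes) live in
`scripts/fetch_and_predict.py`; the packaged tests instead verify the same
decision path on engineered structures whose correct answer is known by
construction.

## Known limitations

* The surface-algorithm defaults (grid spacing, shell, 8 Å averaging
  cutoff, 75th-percentile threshold, 6 Å/0.5 occlusion parameters) are
  algorithmic choices, not measured constants; conclusions should be checked
  for robustness when they sit near a cutoff.
* Histidine's alpha is pH-dependent (protonation strengthens binding to the
  anionic citrate layer); the stored value reflects pH 6.5 and no pH model
  is provided.
* The full-exposure reference is self-consistent but not identical to other
  programs' reference tables; relative accessibilities can differ by a few
  percent from NACCESS-style output.
* Patch counts depend on threshold and connectivity choices; patch
  *location* and the occlusion call are the robust outputs.
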