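# Methods

This note records the models implemented in `sedxl`, the assumptions they
make, the defaults and why, and what the synthetic-data validation does and
does not demonstrate.

## Sedimentation transport (sedxl.lamm)

The Lamm equation for an ideal species in a sector cell,

    dc/dt = (1/r) d/dr [ r ( D dc/dr − s ω² r c ) ],

is discretized in conservative finite-volume form on a uniform radial grid
(default 400 cells between the meniscus, default 6.0 cm, and the bottom,
default 7.2 cm). Face fluxes use Scharfetter–Gummel exponential fitting,
which interpolates smoothly between central differencing (diffusion-
dominated faces) and upwinding (advection-dominated faces); this keeps the
scheme oscillation-free at any cell Péclet number, which matters for the
convection-only validation limit where D is nearly zero. Both end faces
carry zero flux, so the sector-weighted mass Σ cᵢ rᵢ Δr is conserved to
round-off (the tests require < 0.1%; the scheme achieves ~1e-14). Time
stepping is Crank–Nicolson with the step bounded by an advective Courant
number of 0.5 at the cell bottom; the tridiagonal system is LU-factorized
once per distinct step size. Non-finite concentrations abort loudly
(`LammInstabilityError`) rather than returning NaN scans.

Species parameters: s is given in Svedberg; D may be supplied directly,
or derived via the Svedberg relation from a molar mass M, or from a
frictional ratio f/f₀ (default 1.4, a moderately elongated globular
protein; default v̄ = 0.73 mL/g). Solvent defaults are water at 20 °C and
no s₂₀,w correction is applied anywhere — the pipeline works in raw
experimental s throughout, matching how fluorescence-AUC binding data are
usually reported.

A closed-form zero-diffusion mode is provided for validation: a step
boundary at r_m·exp(sω²t) with plateau concentration c₀·exp(−2sω²t) (the
radial dilution law). Species with D = 0 are rejected unless this mode is
requested explicitly.

Detection channels are linear: each species contributes
coeff(channel)·c(r,t). A fluorescence channel gives nonzero coefficients
only to species containing the labeled protomer (emulating AU-FDS
detection); an absorbance channel can weight all species.

Reacting systems are simulated in the slow-exchange approximation: the
mass-action equilibrium (free A, free B, AB) is computed first and the
three species then sediment independently. This is appropriate when
distinct free and complex boundaries are experimentally resolved, which is
the regime this package targets; kinetically coupled reaction-boundary
transport (fast exchange) is deliberately out of scope.

## dc/dt analysis (sedxl.dcdt)

Adjacent scan pairs inside a user-selected window are differenced:
Δc/Δt at the common radii, with the pair timestamp t̄ = (tᵢ + tᵢ₊₁)/2.
Each radius maps to s\* = ln(r/r_m)/(ω² t̄). The pair curve is scaled by
the conventional time-derivative transform

    g(s*) = −(Δc/Δt) · ω² t̄² / ln(r/r_m) · (r/r_m)² ,

interpolated onto a common s\* grid (default 400 points spanning the data),
averaged across pairs, floored at zero, and normalized (area = 1 by
default; max = 1 and raw modes are available — raw preserves linearity in
loading). Radii within 0.02 cm of the meniscus are excluded; the outer
limit is clipped where back-diffusion from the bottom is detected (persistent
signal rise near the bottom of the last windowed scan).

Scan-window choice trades resolution against artifacts: early pairs
compress the s\* axis, late pairs pick up back-diffusion. The default
window used by the high-level helpers spans scan fractions 0.5–0.9 of a
run scheduled so the boundary midpoint crosses 12–70% of the column
(by ln-radius). With these defaults, single-species recovery across
2.8–7 S is accurate to ~0.04 S, well inside the ±0.1 S acceptance band,
and two species at 2.8 and 5.3 S are cleanly resolved.

Peaks are characterized by sum-of-Gaussians least squares: seeds from
local maxima ≥ 5% of the global maximum (ties broken toward lower s),
centers bounded inside the grid, three jittered restarts (seeded), best
residual kept. Peaks return sorted by center; "the saturated complex" is
by convention the highest-s (last) peak. The weight-average
∫s·g ds / ∫g ds over a window is available as a robust scalar summary.

## Hydrodynamics and grid decomposition (sedxl.hydro)

Svedberg relations are evaluated in CGS (R = 8.314×10⁷ erg mol⁻¹ K⁻¹,
s internally in seconds): M = sRT/(D(1−v̄ρ)) and its inverse. For a
species of given (s, f/f₀), mass follows from f = (f/f₀)·6πη·R₀ with
R₀ = (3Mv̄/4πN_A)^{1/3}, giving M^{2/3} = s·N_A·prefactor/(1−v̄ρ); these
are exact inverses of each other and are unit-tested as such. v̄ρ ≥ 1
(floating species) raises explicitly.

The grid fit is a deliberately simplified two-dimensional spectrum
analysis: each (s, f/f₀) node is simulated with the experiment's geometry
and scan times (the same solver as the data — no separate approximate
kernel), and all scans are fitted jointly by non-negative least squares.
No iterative grid refinement or Monte Carlo. Nodes carrying ≥ 1% of the
total weight are reported with Svedberg-derived D and M. The grid is
capped at 200 nodes to keep the basis simulation desk-scale; the default
acceptance configuration (25 s-values × 4 f/f₀ values, 30 scans of 240
radial points) runs in ~1 s and recovers a 135 kDa species' mass within
~1% via its dominant node (the 15% acceptance band mainly absorbs grid
resolution when truth falls between nodes).

## Binding analysis (sedxl.binding)

Mass-action speciation uses the closed-form smaller quadratic root,
clamped to [0, min(a,b)], which conserves both totals exactly.

The titration fit models the highest-s fitted peak against **total**
ligand concentration with the rectangular hyperbola
s(c) = s_free + (s_sat − s_free)·c/(K_D + c). Using total rather than
free ligand is an approximation justified by the design this fit is meant
for — receptor (100 nM) far below K_D (µM range) — and mirrors standard
practice for such titrations. Fitting is multi-start least squares
(K_D starts at {0.1, 1, 10}× the median nonzero concentration), with
asymptotic standard errors from the Jacobian. Data with no saturation
curvature (span ≤ 3×rmse, K_D beyond 10× the titrated range, or a
standard error exceeding the estimate) are returned with an `unreliable`
flag and a warning instead of silently reporting a meaningless constant.

Degree of labeling: A_protein = A₂₈₀ − A₅₀₀·CF₂₈₀ and
DOL = A₅₀₀·MW/([protein]·ε_dye) with [protein] in g/L (that reading makes
DOL dimensionless: it equals A₅₀₀ divided by the molar protein
concentration times ε_dye at 1 cm path length). Defaults CF₂₈₀ = 0.09 and
ε_dye = 90,000 M⁻¹cm⁻¹ are the manufacturer values for ATTO 488-class
maleimide dyes. DOL > 5 warns as implausible.

## Crosslink identification (sedxl.digest / linkers / xlsearch)

Digestion: trypsin cleaves after K/R except before P; peptides carry 0–3
missed cleavages by default (a crosslinker-modified lysine is never cut,
so crosslinked peptides necessarily contain missed cleavages), length
6–60 and monoisotopic mass 600–6000 Da by default. Masses are pyteomics
residue sums plus water; no fixed or variable modifications. Linkable
sites are lysines away from a cleavable C-terminus plus the protein
N-terminal α-amine (position-1/2 links occur in practice); Ser/Thr/Tyr
side-reactivity is excluded.

Linker chemistry: the registry carries the residual bridge masses —
BS3 (suberate bridge C₈H₁₀O₂, 138.06808 Da) and DSSG (glutarate bridge
C₅H₄O₂, 96.02113 Da) — with heavy deltas of 12 and 6 deuteriums
respectively at 1.0062767 Da per ²H.

Matching is MS1-only: a hit requires, at one charge (1–6), a light peak
within ±15 ppm of the candidate m/z AND a heavy peak at the linker delta
within the same tolerance, heavy/light intensity ratio in [0.3, 3.3]
(reagents are 1:1 H/D mixes) and co-elution within 0.5 min (optional,
default on). The doublet requirement is what makes MS1-only search
specific; MS2 fragment scoring is out of scope. Score is −|ppm error|.
Each observed peak pair is assigned to at most one candidate: lowest
quantized |ppm|, then target before decoy, then lower mass. The
target-before-decoy tie-break matters because reversed-sequence decoys
conserve residue composition, so decoy pairs can be exactly isobaric with
targets; standard target-decoy competition resolves exact ties to the
target. A corollary of MS1-only search is that exactly isobaric *target*
pairs are indistinguishable in principle; the validation fixtures show
they remain a small minority of assignments.

FDR: decoys are reversed full protein sequences digested and enumerated
identically; a pair is decoy if either peptide is decoy. Hits are ranked
by score, the decoy/target ratio gives the FDR estimate at each threshold,
and q-values are made monotone by a cumulative minimum from the best score
down. Accepted target hits must have q ≤ 0.05 and survive an unconditional
|ppm| < 2 refinement. Reports collapse to unique
(peptide_a, peptide_b, site_a, site_b) rows with a multiplicity count and
an intra/inter tag; the reported site is the most N-terminal linkable
position of each peptide, in 1-based full-protein coordinates (MS1 masses
cannot localize the link within a peptide when several sites are present).

## Structural validation (sedxl.structure)

Crosslinks map onto models via a protein→chain map with optional
per-protein numbering offsets (for models missing leading residues).
Distances are Euclidean Cα–Cα — the convention of crosslink-visualization
tools — and the ceiling (default 30 Å, the practical span of BS3-class
linkers between α-carbons) is inclusive: distance == ceiling is
satisfied. Missing residues flag a link unresolved rather than raising,
and unresolved links are excluded from the satisfied/violated counts.
Restraints export in the CNS/HADDOCK `assign (segid … and resid … and
name CA) (…) d d⁻ d⁺` dialect with d = ceiling and d⁻ = d, d⁺ = 0 (any
distance up to the ceiling satisfies); write∘parse is the identity and
duplicates are collapsed.

## Synthetic data: what it does and does not emulate

The generators reproduce the study conditions: 42,000 rpm, 20 °C,
fluorescence detection of a 300 nM labeled receptor with 2 µM partner
(binding runs), 100 nM receptor titrated with 0–10 µM ligand (affinity
runs), 1:1 heavy/light planted doublet intensities, charges 2+–4+ by
default. Scan geometry (meniscus 6.0 cm, bottom 7.2 cm), scan counts and
loading magnitudes are package defaults declared in config — such values
are instrument bookkeeping that published work rarely reports. All
generators are seeded and byte-deterministic.

Not emulated, hence not demonstrated by passing tests: time- and
radially-invariant systematic noise (instrument baselines), meniscus
artifacts and optical aberrations; fast-exchange reaction boundaries;
concentration-dependent non-ideality; MS2 spectra, retention-time
structure beyond a uniform random gradient position, isotope envelope
shapes (peaks are monoisotopic sticks), and in-source decay; real protein
sequences for the nematode system (not printed in public tables — the
digestion-level fixtures use synthetic sequences, labeled as such).
Parameter-recovery results therefore validate the algorithms'
correctness, not their robustness to every instrumental artifact of real
data.

## Problem sizes and numerical defaults

Test and validation runs use 240–400 radial points, 30–60 scans, grids of
≤ 100 NNLS nodes, 50-seed noise ensembles for robustness checks, and
100-sequence brute-force digestion comparisons; the full suite runs in
about ten seconds and the results script in a few seconds. Gaussian and
hyperbolic fits use tolerances near machine precision with seeded
multi-start; NNLS is scipy's active-set solver; the Scharfetter–Gummel
Bernoulli function B(x) = x/(eˣ−1) switches to its series form below
|x| = 1e-10 and to its asymptotic limits beyond |x| = 500.

## Known limitations

- The dc/dt mode has a small systematic low bias (~0.04 S at 2.8 S with
  default windows) from finite-Δt differencing and diffusion skew; it is
  well inside the ±0.1 S validation band but would matter for
  high-precision s determination.
- The grid fit reports node-resolution-limited masses; truth between grid
  nodes biases the dominant-node estimate by up to half a grid step in s
  (≈ 5% in M at the default spacing).
- MS1-only identification cannot localize the crosslinked residue within
  a peptide, cannot distinguish exactly isobaric pairs, and does not
  support mono-links or loop-links (reported as unsupported).
- The titration fit's total≈free-ligand approximation degrades when the
  receptor concentration approaches K_D.
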