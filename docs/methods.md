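# Methods

This note records the models implemented in `hydrabind`, their
assumptions, the defaults that matter, and the numerical and design
choices made where more than one reasonable option existed.

## Hydration site analysis

**Model.** Binding-site water is summarized as a set of spherical
hydration sites of radius 1.0 Å inside a spherical analysis region
(default radius 8.0 Å around a user-supplied center; a helper computes the
center from a PDB atom selection, so no reference ligand is required).
Each site carries a water occupancy *p* (fraction of frames with at least
one member water, capped at 1) and a total energy per the
inhomogeneous-solvation energy decomposition. Entropic terms are not
computed: the downstream sphere parameterization consumes energies only.

**Clustering.** The greedy density scheme standard in hydration-site
analysis: evaluate, at every observation position, the number of
observations within the site radius; emit the maximizing position as a
site center; remove its members; repeat until the best count falls below
`min_occupancy × n_frames`. Observations are then assigned to the nearest
center within the site radius (each observation counted at most once) and
sites below the occupancy threshold are dropped. Count ties are broken by
the lexicographically smallest candidate position — a tie-break chosen so
the result is both deterministic and invariant under permutation of the
input observations (an index-based tie-break would be order-dependent,
since integer neighbor counts tie routinely). The minimum-occupancy
threshold for accepting a site is not a physically derived quantity; the
default is 0.25 and it is exposed in `ClusterConfig`.

**Site energy.** The default convention is
*E*<sub>total</sub> = ½⟨E_sw⟩ + ½⟨E_ww⟩. The more common alternative
*E*<sub>total</sub> = ⟨E_sw⟩ + ½⟨E_ww⟩ (full solute–water term, halved
water–water term to avoid double counting between water pairs) is
available via `ClusterConfig.e_total_convention = "sw-plus-half-ww"`; the
two differ by ½⟨E_sw⟩ and users comparing against other HSA codes should
check which convention those use. The bulk reference is
*E*<sub>bulk</sub> = −12.24 kcal/mol, the mean per-molecule energy of neat
OPC water; it is configurable for other water models. The site score
(*E*<sub>total</sub> − *E*<sub>bulk</sub>)·*p* is linear in both factors,
which the tests exercise as an invariant.

## Map integration and sphere weights

Maps from different receptor conformations must be expressed in a common
frame before merging (a Kabsch least-squares helper is provided; alignment
quality is the caller's responsibility). Merging processes sites in
decreasing score order; a site joins the first existing cluster whose
running mean center is within `merge_radius` (default 2.0 Å — twice the
site radius, so touching sites merge). The merged score is, by default,
the mean over *contributing* maps: a map with no site near the cluster
does not enter the denominator. The alternative mean-over-all-maps mode
(absent map counts as zero) is selectable, since the choice is a genuine
modeling decision with no unique answer. When one map contributes several
sites to a cluster, that map's contribution is the sum of its member
scores before averaging across maps — this keeps the bookkeeping
conservative. Scores are averaged as final occupancy-weighted products,
not as separately averaged occupancies and energies.

Grouping nearby merged sites onto one hydration sphere assigns the *sum*
of member scores as the sphere strength *h*<sub>s</sub>, and the
carboxylate rule divides a site's weight *equally* over the listed
water-occupied carboxylate spheres (equal split is the simplest rule that
conserves the total exactly; the final share absorbs any floating-point
residue so the sum is bit-exact). Both operations conserve total weight:
Σ *h*<sub>s</sub> = Σ merged scores, tested as an invariant. Mapping
spheres to chemically sensible anchors remains a supervised step — the
package applies recorded assignments and the two stated adjustment rules
rather than attempting unsupervised anchor discovery.

## Enclosed-hydration term

**Placement.** Spheres are positioned purely from receptor internal
coordinates so the energy is translation/rotation invariant: atom-group
centroids, a point on the donor→H axis at a configured distance beyond H,
or sp² lone-pair constructions in the plane of three atoms (configured by
the C–O–site angle, default 120°, the O–site distance, and a ±1 branch
selecting the mirror image). Synthetic fixtures may instead fix a sphere
center explicitly.

**Occupancy.** *w*<sub>s</sub> = *V*<sub>s</sub><sup>free</sup>/*V*<sub>s</sub>,
where the free volume is the part of the sphere not occluded by solute
atoms (the in-principle alternative reading — volume actually occupied by
water — is not computable in an implicit-solvent model, so the unoccluded
volume is used and documented here). It is integrated on a cell-centered
cubic grid (default spacing 0.1 Å) as
*V*<sub>s</sub><sup>exact</sup> × (unoccluded fraction of interior grid
points); scaling the exact sphere volume by the grid *fraction* cancels
the discretization error of the sphere boundary itself, leaving only the
occluder-boundary error, measured at ≤ 0.5 % of *V*<sub>s</sub> against
the analytic two-sphere lens formula at the default spacing. Occluder
effective radii are Bondi van der Waals radii (overridable per element)
plus a configurable probe offset (default 0). The sphere radius defaults
to 1.4 Å (water-sized).

**Switching.** *S* is the cubic smoothstep 3t²−2t³ on
t = (w−lo)/(hi−lo), 0 below `switch_lo` (default 0.1) and 1 above
`switch_hi` (default 0.5) — C¹ with zero slope at both thresholds. The
specific polynomial form and thresholds are package choices (recorded in
all outputs); any C¹ monotone gate with the same thresholds would behave
equivalently in the tested regimes. ΔG<sub>hs</sub> is strictly additive
over spheres (no cross terms), and occlusion is monotone: moving an
occluder toward a sphere center can only decrease *w*<sub>s</sub> and an
unfavorable sphere's contribution — hence adding ligand atoms can only
lower ΔG<sub>hs</sub>, the displacement reward.

The full generalized-Born electrostatic and nonpolar terms of the
surrounding implicit-solvent model are out of scope; where needed they are
accepted as externally supplied scalars.

## Alchemical estimation

**Coupling contract.** Samples are binding energies *u* collected at the
states of a λ schedule under U<sub>λ</sub> = U<sub>0</sub> + λu. The
28-state preset `d3-28` is densely spaced near λ = 0 where du/dλ varies
fastest. U<sub>0</sub> and configurations are never materialized —
samples are inputs, produced by an external MD engine or by the synthetic
generator.

**Soft core.** Divergent repulsive energies near the uncoupled state are
capped by a monotone C¹ transform: identity below u_c (default 100
kcal/mol), then u_c + (u_max−u_c)·tanh[(u−u_c)/(u_max−u_c)] saturating at
u_max (default 300 kcal/mol). The same transform must be (and is) applied
both when generating synthetic samples and when reweighting.

**UWHAM.** The unbinned multistate reweighting equations are solved by
L-BFGS-B minimization of the standard convex objective over the sampled
states, then polished by self-consistent iteration to a dimensionless
tolerance of 1e−10 (≈ 6e−11 kcal/mol at 300 K). States with zero samples
are evaluated by reweighting, which reduces exactly to Zwanzig
exponential averaging when only one state is sampled (tested).
Uncertainties come from the asymptotic covariance of the estimator in its
SVD form, Θ = V S (I − S Vᵀ N V S)⁺ S Vᵀ with W = U S Vᵀ the normalized
weight matrix; var(G_k − G_0) = Θ_kk + Θ_00 − 2Θ_0k. The state-overlap
matrix O<sub>ij</sub> = N<sub>i</sub> Σ<sub>n</sub> W<sub>ni</sub>W<sub>nj</sub>
is returned as a diagnostic and a warning is raised when adjacent overlap
is negligible. Free energies are anchored at G(λ=0) = 0 and are invariant
(up to λ·c) under a constant shift c of all binding energies, tested
explicitly.

**Replica exchange.** Only the swap bookkeeping is modeled: the Metropolis
probability min{1, exp[−β(λ_i−λ_j)(u_j−u_i)]} for exchanging λ values
between replicas, which satisfies detailed balance for the λ-linear
Hamiltonian. A toy simulator demonstrates the bookkeeping on the Gaussian
model, including reservoir resampling of configurations at the uncoupled
state; no receptor conformational reservoirs are generated.

**Standard state and decomposition.**
ΔG<sub>t</sub>° = −k<sub>B</sub>T ln(C°·V<sub>site</sub>) with
V<sub>site</sub> the hard spherical volume of radius 3.5 Å by default and
1 M ≡ 1/1660.54 Å⁻³. The default conversion temperature is 298.15 K
(giving 1.32 kcal/mol at the defaults; at 300 K the same term is 1.33 —
both are supported, and the MD-protocol temperature is a separate,
per-sample-set setting). The soft-wall correction to the restraint volume
is ignored — the hard-volume formula is used as stated. ΔE<sub>b</sub> is
the mean (soft-core-transformed) binding energy at λ = 1 with a
standard-error-of-the-mean uncertainty;
ΔG<sub>reorg</sub>° = ΔG<sub>b</sub>° − ΔE<sub>b</sub> with the two errors
combined in quadrature. The two estimates share underlying data, so the
quadrature propagation neglects their correlation; this is the
conventional treatment and is flagged here as a caveat. Ionization
penalties enter only as an externally supplied scalar added to
ΔG<sub>b</sub>°. Constants: k_B = 0.0019872041 kcal/mol/K.

**Equilibration.** Loaders expose a discard fraction (CLI default 0.5)
that drops the leading portion of each state's samples.

## Synthetic data: what it does and does not emulate

The water-frame generator plants stationary sites: per frame, each site is
occupied independently with its true occupancy; waters sit at the center
plus isotropic Gaussian jitter (default sd 0.3 Å, well under half the site
radius so default fixtures with ≥ 3 Å separations stay resolvable);
energies are drawn from per-site normals *independently of position*.
That is adequate for mean/occupancy recovery but does not emulate spatial
energy gradients within a site, correlated occupancy between sites,
inter-frame correlation, or diffuse non-site water — so passing recovery
tests demonstrates the estimator arithmetic, not robustness to real
trajectory pathologies. The Gaussian alchemy generator draws from the
exact λ-tilted distribution N(μ − λβσ², σ²), for which
ΔG(λ) = λμ − βλ²σ²/2 is exact; real binding-energy distributions are
heavy-tailed near λ = 0, which is precisely what the soft-core cap exists
to handle and which the Gaussian model does not probe. The toy pocket
verifies at generation time that shell atoms leave every planted sphere
above its switching threshold, and records which spheres each nested
ligand set occludes.

Problem sizes used in the test suite — a few thousand frames for site
recovery, 28 states × 5,000 samples for the multistate oracle, 100
randomized single-occluder geometry cases — were chosen so each check's
Monte-Carlo error sits well below its assertion tolerance.

## Degenerate inputs and edge behavior

Empty observation sets or fully out-of-region data yield empty maps (not
errors); sites that lose all member waters are removed with a warning;
non-finite coordinates, occupancies outside [0,1], invalid switching
thresholds, non-positive K_i and empty carboxylate sets are validation
errors. `distribute_carboxylate` guarantees exact conservation of the
total. UWHAM requires at least one sampled state and warns on poor
adjacent-state overlap rather than failing.

## Known limitations

- Anchor-to-chemistry mapping is supervised; no automatic assignment.
- The enclosed-hydration term has no analytic derivatives, so it cannot
  drive MD forces in this form.
- Favorable (h_s < 0) first-shell spheres on the general solute surface
  are outside the implemented scope, as are the continuum electrostatic
  and nonpolar solvation terms.
- Statistical uncertainties assume independent samples; autocorrelated
  trajectories should be subsampled upstream.
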