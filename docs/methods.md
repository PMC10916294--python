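# Methods

## The model

`tham` implements a transferable Hirshfeld atom model: a pipeline that
turns a molecular electron density into per-atom aspherical X-ray form
factors that can be stored in a text databank and transferred to
chemically equivalent atoms in other structures.

The stages are:

1. **Hirshfeld (stockholder) partition.** A molecular density rho(r) is
   divided among its atoms with weights
   w_a(r) = rho_a^sph(r - R_a) / sum_b rho_b^sph(r - R_b), where the
   rho^sph are the spherical reference densities of the promolecule.  Each
   Hirshfeld atom rho_a = w_a * rho integrates to that atom's electron
   population, and the populations sum to the molecular electron count.

2. **Multipole expansion.** Each Hirshfeld atom, sampled on an
   atom-centred product grid oriented by the atom's local frame, is
   projected onto orthonormal real spherical harmonics:
   rho_lm(r_i) = sum_p w_p^ang rho(r_i u_p) y_lm(u_p).  The angular
   weights sum to 4*pi, so the projection is a plain weighted sum.

3. **Hankel-transform form factors.** With the crystallographic
   convention f(S) = int rho exp(2 pi i S.r) d3r, the plane-wave expansion
   gives f(S) = sum_l i^l 4 pi sum_m H_lm(s) y_lm(S_hat), where
   H_lm(s) = int rho_lm(r) j_l(2 pi s r) r^2 dr is evaluated by the radial
   quadrature.  Truncating at L_max replaces an N_ang-point angular sum
   per reflection by (L_max+1)^2 terms, which is where the speed of the
   multipole route comes from.

4. **Databank and transfer.** Atomic densities are expressed in a local
   coordinate frame defined from bonded neighbours (Z along the bond to a
   reference neighbour, Y perpendicular to Z in the plane through a second
   reference, X = Y x Z, right handed), averaged over all occurrences of
   an atom type, and stored as text.  Transfer hands a structure atom its
   type's stored density plus the atom's own frame matrix M (rows = unit
   axes); its form factor at reciprocal vector S is the stored density's
   form factor at M.S.  Because both the projection grids and the transfer
   use the same frame construction, a rigid rotation of a molecule changes
   M but not the stored density — this covariance is tested explicitly.

5. **ADP similarity.** Anisotropic displacement parameters (SPD 3x3
   tensors U, A^2, Cartesian) define zero-mean Gaussian displacement
   PDFs.  The overlapping coefficient OC = int min(p1, p2) d3u is computed
   by splitting into radial and angular parts: along each direction u_hat
   the two Gaussians c_i exp(-q_i r^2/2), q_i = u_hat^T U_i^-1 u_hat,
   cross at most once for r > 0 (r_c^2 = 2 ln(c1/c2)/(q1 - q2)), and the
   piecewise radial integrals of r^2 exp(-q r^2/2) have closed erf forms;
   only the angular sum is numerical (5810 points by default).  The
   rescaled form eta_r = 100 (1 - OC) reads as a percentage difference
   between PDFs.  The Whitten-Spackman index
   S12 = 100 (1 - 2^{3/2} [det(U1^-1) det(U2^-1)]^{1/4}
   / det(U1^-1 + U2^-1)^{1/2}) is closed form; S12(U, 2U) = 8.45
   independently of U, the package's one analytic headline number.

## Synthetic model densities

Real applications of this model family derive rho(r) from quantum
chemical wavefunctions.  This package instead ships analytic model
densities: spherical atoms that are sums of isotropic Gaussians (a compact
core plus a diffuse valence term per element, scaled to the neutral
electron count) and bond-centred Gaussian deformation lobes (a positive
lobe at each bond midpoint, roughly 15% of the local promolecule density,
plus a weaker negative lobe displaced 0.35 A along the bond).  Core
exponents are moderate (16-20 1/A^2) rather than cusp-like: with a
realistic nuclear peak the bond-charge signal would be a vanishing
fraction of the monopole, whereas the fixtures are meant to exercise the
aspherical machinery, so the l >= 1 content is kept above 1e-3 of the
monopole peak by construction.  Three
fixture topologies are provided: water-like, ethanol-like and urea-like.
The seed jitters deformation amplitudes by +-10% reproducibly; geometry
and exponents are fixed.

The point of Gaussians is exact testability: every term has a closed-form
Fourier transform, so the molecular structure factor is known analytically
and the whole pipeline (grids, partition, projection, Hankel transform,
phases) can be checked end to end against it.  What the fixtures do *not*
emulate: nuclear cusps and the sharp core densities of real atoms (which
demand finer radial grids), density tails beyond ~4 A, charge transfer
between atoms, crystal-field polarization, and genuinely diverse chemical
environments per type.  Passing tests therefore demonstrate the
correctness of the machinery, not the transferability accuracy of any
production databank derived from wavefunctions.

## Numerical choices

- **Radial grid**: Mura-Knowles log3 mapping r = -alpha ln(1 - x^3) on
  uniform x_i = i/(n+1), weights carrying the analytic Jacobian.  Default
  n_rad = 75.  The per-element scale alpha is 5.0 A times the ratio of the
  element's covalent radius to carbon's, clamped to [2.5, 7.5] A, so that
  hydrogen and first-row atoms are both well resolved.  For the Gaussian
  model densities this grid reaches ~1e-9 relative accuracy on electron
  counts.
- **Angular grids**: octahedrally symmetric quadratures with the
  point counts of the Lebedev-Laikov family ({6, 26, 110, 302, 590,
  5810}).  The 6- and 26-point grids are the exact classical rational-
  weight rules.  The larger grids are solved in this package from the
  moment equations: orbit parameters and weights of a fixed union of
  octahedral orbits are fitted by damped least squares so that all
  spherical harmonics up to the grid's stated algebraic degree integrate
  exactly (residual < 1e-12); a degree-homotopy with warm starts makes
  the solve deterministic and fast.  The 5810-point grid fixes orbit
  positions (farthest-point layout in the fundamental domain) and solves
  only the weights, a linear problem.  Each shipped grid records its
  degree; projection refuses an L_max that exceeds half that degree.
  Stated degrees are high enough for every documented guarantee but can
  be below the canonical Lebedev degrees for the same point counts.
- **Harmonics**: orthonormal real (tesseral) harmonics without the
  Condon-Shortley phase, evaluated via scipy's complex harmonics; the
  canonical (l, m) order (l ascending, m from -l to +l) is shared by
  projection arrays and databank files.
- **Defaults**: density work uses the 590-point grid (projection of
  L_max = 7 needs degree >= 14 plus headroom for the density's own
  angular content); eta_r uses the 5810-point grid; canonical databank
  truncation is L_max = 7, configurable 0-12.  At L_max = 7 a fixture
  atom's multipole form factor stays within 1e-3 of direct summation;
  the whole-molecule conservation demonstrations run at L_max = 9, where
  the summed transform matches the closed form to better than 1e-4
  relative.
- **Radial interpolation**: spline interpolation is done in the grid's
  uniform mapped coordinate x (r = -alpha ln(1 - x^3)), where the nodes
  are equispaced; a quintic spline there is orders of magnitude more
  accurate than a cubic in r on the stretched outer nodes (population
  drift ~1e-8 instead of ~1e-5 when resampling 75 -> 99 nodes).  Below
  the innermost node the spline's natural extension applies (nodes start
  at ~1e-5 A, so this covers a negligible sliver); beyond the outermost
  node values are zero, logged.  Resampling tolerates an outer overhang
  of up to 15% of the source range (zero-filled: grids of equal scale
  but different node counts overhang each other by a few per cent), and
  refuses larger extrapolation; monopole population drift above 1e-4
  relative is logged as a warning.
- **i^l handling**: complex accumulation; even l contribute to the real
  part and odd l to the imaginary part for real densities, and Friedel
  symmetry f(-S) = f*(S) is exact by construction.
- **OC edge cases**: rays with q1 = q2 take the smaller-prefactor
  Gaussian over the whole ray (either when also c1 = c2); a non-positive
  crossing radius means the ordering never changes for r > 0, decided by
  prefactor, then by decay rate.
- **OC angular convergence**: the radial part is exact, so the only OC
  error is angular quadrature of direction-dependent terms like
  (u^T U^-1 u)^{-3/2}, whose harmonic content grows with the tensor's
  anisotropy.  On the 5810-point grid the identity OC(U, U) = 1 holds to
  ~1e-12 for eigenvalue ratios up to ~9 (generous for real ADPs) and
  degrades to ~1e-8 at ratio 16; pair-comparison accuracy (the 1e-3
  brute-force agreement) is unaffected across the whole tested range.
- **Bond detection**: distance < 1.3 x (sum of covalent radii); atoms
  closer than 0.4 A are an error.
- **Atom typing**: element plus sorted multiset of bonded-neighbour
  elements.  This is deliberately coarser than production multipole-
  databank type grammars (no rings, planarity or second shells): it is
  enough to distinguish the environments in the shipped fixtures and
  keeps typing transparent.  Ambiguous banks (two types with one
  signature) are rejected; untyped atoms are a hard error by default or
  skipped with `--untyped skip`.
- **Frames**: Z reference is the heaviest bonded neighbour element; the
  XZ reference is the next-heaviest neighbour, or for terminal atoms the
  heaviest neighbour of the Z atom.  Candidates resolve by distance, then
  index, so relabeling cannot flip frames.  The XZ element selector is a
  preference, not a guarantee: because a type's second shell can differ
  between occurrences (a hydroxyl H sees H across the O in water but C in
  an alcohol), resolution falls back to any available reference in the
  same search order when the preferred element is absent, with a debug
  log.  Collinear references (< 1 degree) are an error.
- **Averaging**: plain arithmetic mean of multipole coefficient arrays
  per type; fewer than 3 instances logs a warning.
- **Orthogonalization**: a along x, b in the xy plane, used identically
  for coordinates and for converting crystallographic aniso U tensors to
  Cartesian (U_cart = A D U_cif D A^T, D = diag of reciprocal lengths).
- **tsc tables** carry static form factors only; positional phases,
  symmetry expansion beyond P1 and thermal smearing belong to the
  refinement program.

## Configuration surface

Grid sizes (`--n-rad`, `--n-ang`), truncation (`--l-max`), untyped-atom
policy (`--untyped`) and reflection sources (`--hkl` / `--d-min`,
`--friedel`) are CLI options; the library functions expose the same
parameters as keyword arguments.

## Problem sizes used in the shipped checks

Tests and the selftest run fixtures of 3-9 atoms with n_rad = 75,
n_ang = 590 (projection) and 5810 (OC), 30-100 random scattering vectors
with |S| <= 1.5 1/A, and brute-force oracles at 61^3-81^3 Riemann points
or 1e6 Monte-Carlo samples — sizes chosen so the full suite runs in a few
minutes on one core while leaving the quadrature and truncation errors
far from the asserted tolerances.

## Known limitations

- Space group P1 only; no symmetry expansion, no Friedel-pair averaging
  beyond the optional generator flag.
- No thermal smearing or anomalous dispersion in form factors.
- The atom-type grammar cannot distinguish environments that differ only
  beyond the first bonded shell.
- Model densities are Gaussian; quantitative agreement with
  wavefunction-derived atomic densities is out of scope by design.
- The angular grids' algebraic degrees, while sufficient for all stated
  tolerances, are not the maximal degrees achievable at those point
  counts.
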