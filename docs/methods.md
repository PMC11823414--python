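# Methods

This note records the models implemented in `lvcspin`, the conventions and
numerical choices that were genuinely open, and what the synthetic study
conditions do and do not establish.

## Linear vibronic coupling reconstruction

The molecular Hamiltonian is split into a spin-free part (the molecular
Coulomb Hamiltonian, MCH) and a spin–orbit part.  An anchor parametrization
holds, in the MCH eigenbasis at the anchor geometry: eigenvalues `E_m`
(hartree), state gradients `κ^(m)` and interstate coupling vectors `λ^(mn)`
(hartree/bohr, length 3N over all sites), and three Hermitian operator
matrices `V_x, V_y, V_z` (hartree) representing the spatial part of the
mean-field spin–orbit operator.  At displacement `ΔR` the MCH matrix is the
first-order expansion written in the README; it is diagonalised and the
same unitary rotates each `V_α` into the displaced eigenbasis before the
spin–orbit term is assembled as `Σ_α V_α ⊗ S_α`.  Assumptions inherited
from the underlying theory:

* a single spin multiplicity `S` shared by all spin-free states (the
  implemented Wigner–Eckart assembly is the one-multiplicity Kronecker
  product; multi-multiplicity blocks are out of scope);
* the spin–orbit operator matrices are geometry independent — only the
  basis they are expressed in rotates with geometry;
* solvent point charges are ordinary sites: their coordinates enter `ΔR`
  exactly like atomic ones, with no mass weighting anywhere.

**Units.** Internal units are atomic (hartree, bohr, atomic time);
trajectory files are Å and fs, converted on read with 1 Å = 1.8897261246
bohr and 1 atomic time unit = 0.02418884254 fs.

**Basis conventions** (the underlying theory fixes none of these, so they
are fixed here and tested):

* product basis: spin-free-state-major, `M_S` descending within each state
  (`kron(V, S)` ordering);
* term basis `|L S M_L M_S⟩`: `M_L`-major, both projections descending;
* eigenvector determinism: each eigenvector's largest-magnitude component
  is made real-positive, and degenerate columns are ordered by the index
  of their first significant (>1e-8) component, so rotated operators are
  bit-reproducible run to run.

**Basis used for error metrics.** `lvc_hamiltonian` can emit the total
Hamiltonian either in the displaced eigenbasis (the electronic-structure
workflow's representation, default) or in the anchor's fixed product basis
(`basis="reference"`, no rotation).  The two are unitarily equivalent.
Frobenius-error comparisons are done in the fixed representation: the
relative Frobenius norm is not invariant under the *independent*
diagonalisations two different Hamiltonian sources would apply, and the
fixed basis makes the metric compare operators rather than eigenvector
conventions.  At `ΔR = 0` both representations reduce to the anchor
Hamiltonian exactly, which the acceptance suite checks to 1e-12.

## Stevens operators and spin-parameter projection

The 27 extended Stevens operators (k = 2, 4, 6; q = −k…k, including the
negative-q "sine" operators) are generated from the standard
operator-equivalent polynomials `P_kq(J_z)` by the symmetrised products

    O_k^{+q} = 1/4 [P_kq (J₊^q + J₋^q) + h.c. ordering],
    O_k^{−q} = 1/(4i) [P_kq (J₊^q − J₋^q) + ...],   O_k^0 = P_k0(J_z).

Several sign/normalization conventions exist in the literature; this one is
pinned by a golden file of hand-evaluated matrices (`O_2^0` at L = 1 →
diag(1, −2, 1); `O_4^0` at J = 2 → diag(12, −48, 72, −48, 12); the `O_6^0`
diagonal at J = 3; `O_2^2`, `O_2^1` elements).  The polynomials vanish
identically when 2L < k; the builder warns and returns zero matrices so the
corresponding `B_k^q` are reported as unprojectable rather than silently
wrong.

The operator set `{L·S, θ_k O_k^q ⊗ 1}` is orthogonal under the trace
inner product (spin factors are traceless; Stevens operators of different
(k, q) are trace-orthogonal), so the least-squares projection of (λ,
B_k^q) from a Hermitian matrix reduces to trace ratios and round-trips the
forward construction to machine precision.  For matrices not exactly in
the operator span, the Frobenius norm of the residual is returned as a
diagnostic.  The stored `DY_GROUND_THETA` factors are the standard
tabulated ground-multiplet Stevens factors for Dy³⁺ (−2/315, −8/135135,
4/3864861 as exact rationals); synthetic work uses θ_k = 1, which is
equivalent up to a rescaling of `B_k^q` because θ_k multiplies `B_k^q`
identically in build and projection.

**Term-block selection.** Projecting a full product-basis Hamiltonian
requires mapping spin-free states onto `|L M_L⟩` labels.  Synthetic states
carry explicit `M_L` labels, so the (2L+1)(2S+1)-dimensional term block is
selected by label and reordered `M_L`-descending.  The general
angular-momentum-matching route needed for ab-initio states is deliberately
out of scope.

## Propagation

Column-stacking vectorisation is used throughout: `vec(HρI) = (1⊗H)vec(ρ)`,
giving the generator `G = 1⊗H − Hᵀ⊗1` with `d|ρ⟩/dt = −iG|ρ⟩`; the
convention is fixed by a direct commutator oracle test rather than by any
printed Kronecker ordering.  One MD step applies `exp(−iGδt)` with δt = 1 fs
by default.  The exponential-times-vector algorithm divides the step into
`ceil(‖−iGδt‖_∞)` equal substeps (at least one; the norm is taken of the
dimensionless scaled exponent) and accumulates Taylor terms — each obtained
by one application of the exponent to the previous term — until the next
term would change no element by more than the cutoff (default 1e-14 on the
element-wise max; a `max_taylor_terms` bound of 500 turns pathological
norm/cutoff combinations into a convergence error).  For Hamiltonians
beyond a few states the generator is applied matrix-free as
`vec(Hρ − ρH)`, with the exact `‖G‖_∞` computed from rows of H.

Dynamics are performed in the eigenbasis of the t = 0 Hamiltonian.  The
initial state is the Boltzmann density over that Hamiltonian's eigenvalues
(default 300 K, k_B = 3.166811563e-6 hartree/K) with off-diagonal elements
zero.  Evolution is entirely unitary — no dissipation, no ensemble
averaging — so trace, purity and segment-wise energy are conserved; the
propagator logs per-step trace drift, substep counts, and the measured
drift over 1000-step discontinuous series is at the 1e-12 level.
Discontinuities at reparametrization boundaries are accepted as-is; they do
not harm trace conservation, which the acceptance suite verifies across
schedule switches.

## Geometry

Trajectories are extended XYZ (comment line carries `time=<fs>` and
optionally `box=<a b c>` in Å); site label `X` marks a point charge.  Only
orthorhombic boxes are supported.  Unwrapping applies the per-component
minimum-image convention relative to a reference geometry; it only ever
shifts coordinates by whole box edges and is idempotent.  RMSD uses
centroid removal and the Kabsch proper rotation (reflections excluded,
determinant forced +1), no mass weighting, and includes point charges by
default with a mask option for atom-only superposition — the convention
for which sites enter the RMSD is not dictated by the theory, so both are
available and the default is documented here.

## Scheduling

Frames are always assigned to the temporally *nearest* anchor (ties to the
earlier one), because an LVC model predicts backward in time as well as it
does forward.  The adaptive rule walks the trajectory, counting "crossings"
where the Kabsch RMSD to the current reference geometry reaches the
threshold: at odd crossings only the reference geometry moves to the
crossing frame; at even crossings a new anchor is created there.  This
"every other crossing" bookkeeping reflects the backward reach of each
anchor; on trajectories whose RMSD grows monotonically between crossings it
bounds every frame's RMSD to its assigned anchor by twice the threshold.
The threshold comparison uses `rmsd ≥ threshold·(1 − 1e-12)` so that
crossings landing exactly on the threshold value are detected
deterministically in floating point.  A constructed stream whose RMSD grows
at exactly 0.01 Å/fs with a 0.25 Å threshold yields crossings at 25/50/75/
100 fs and anchors at {0, 50, 100} fs.

## Synthetic study conditions

The generator defaults define the conditions every test and the acceptance
script run under; they were chosen once, on physical grounds:

* **Parametrization scales** (`ParamScales`): spin-free energies spread
  over 0.02 hartree (a few thousand cm⁻¹, the span of a low-lying
  lanthanide manifold); gradient and coupling components drawn at 5e-3
  hartree/bohr (inside the −0.13…0.20 range observed for a flexible
  complex); SOC matrix elements at 5e-3 hartree, comparable to a
  lanthanide one-electron spin–orbit constant.  The SOC magnitude matters:
  in real spin–orbit-coupled complexes the SOC term dominates ‖H‖ while
  varying little, which keeps the denominator of the relative error metric
  stable and makes forward/backward error traces nearly symmetric.
* **Quadratic truth**: 4 shared displacement modes with symmetric
  per-state-pair coefficients at 0.04 hartree/bohr² — a sparse stand-in for
  the full second-derivative tensor.  With the default trajectory this
  produces single-anchor errors that grow from zero quadratically and
  saturate around 5–8 % at 100 fs, and sub-1 % errors at 10–20 fs anchor
  spacing.  Because the truth is *exactly* quadratic, re-expanding it about
  any geometry reproduces the same operator (verified to 1e-17), which is
  what makes multi-anchor schedules comparable in a common basis via the
  accumulated orthogonal rotation each reparametrization carries.
* **Trajectories**: three sinusoidal displacement modes (0.12/0.07/0.04 Å
  at 520/760/410 fs) with seeded per-site patterns; over a 100 fs window
  (well under a quarter period) the RMSD from frame 0 grows monotonically
  to ~0.14 Å, the regime in which error and RMSD are strongly
  rank-correlated.

**What the synthetic conditions do not show.**  The generator draws
independent Gaussian couplings and harmonic motion: it has no anharmonic
solvent dynamics, no physically structured crystal field, no correlation
between gradients and the SOC operators, and its quadratic truth omits all
derivatives beyond second order.  Passing tests therefore establish the
*algorithmic* contracts (exactness at the anchor, truncation-order scaling,
conservation laws, scheduling logic) and the qualitative error phenomenology
— not quantitative error magnitudes for any real complex, which depend on
the system's actual electronic structure and must be benchmarked per
system.

## Problem sizes

Default verification sizes were chosen to exercise every code path at
interactive cost: 12 spin-free states with S = 5/2 (72-dimensional product
Hamiltonians, 5184-component vectorised densities, applied matrix-free) and
101 frames for the pipeline studies; the 66-dimensional L = 5, S = 5/2
term for spin-parameter round-trips; 1000-step, 12-dimensional series for
conservation checks.  The full 18-state (108-dimensional) configuration is
generated and validated in the suite as well.

## Known limitations

* One spin multiplicity; no multi-multiplicity spin–orbit blocks.
* Label-based term selection only; no angular-momentum matching for
  ab-initio eigenstates.
* Unitary dynamics only — no Lindblad/dissipative channels, no external
  magnetic field.
* Orthorhombic boxes only; XYZ is the only trajectory format.
* The quadratic ground truth is a diagnostic construction, not a force
  field; energy ordering after displacement is not enforced (states may
  cross, as in reality).
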