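# Methods

This note documents the physical model, the numerical route, the defaults,
and the limits of validity of `gwbse`.

## Model

`gwbse` computes charged and neutral excitations of small closed-shell
molecules in three layers:

1. **Mean-field reference.** A restricted SCF solution (HF, LDA, PBE, or
   PBEH40 — the PBE hybrid with a 40% exact-exchange fraction) provides
   orbitals and eigenvalues. PBEH40 is the recommended starting point for
   quasiparticle self-consistency, where it acts purely as a
   preconditioner.
2. **GW quasiparticles.** The self-energy is the GW approximation,
   `Sigma = iGW`, with the screened interaction `W` from the random phase
   approximation (no vertex, `dW/dG = 0`). Three solution modes:
   - `g0w0`: one-shot perturbative correction of the reference eigenvalues;
   - `evgw`: eigenvalue-only self-consistency (orbitals frozen, all
     occupied and virtual eigenvalues updated until the HOMO moves by less
     than 3 meV between cycles);
   - `qsgw`: quasiparticle self-consistency. The full self-energy matrix is
     restricted to its static (`omega = 0`) limit, Hermitized by discarding
     the anti-Hermitian part,

         H_eff = F[rho] - v_xc - alpha*K_ref + Sigma_x[rho] + (Sigma_c(0) + Sigma_c(0)^T)/2,

     and re-diagonalized until the density matrix is stationary (Frobenius
     change below 5e-9). The Hartree potential and the exchange self-energy
     are rebuilt from the current density each cycle; without the Hartree
     update the fixed point would retain memory of the reference density
     and starting-point independence would be lost. An alternative
     Hermitization (`scheme="kotani"`: Sigma evaluated at the quasiparticle
     energies, symmetrized) is available for comparison.
3. **BSE excitons.** On top of the quasiparticle solution, the
   particle-hole Bethe-Salpeter equation with a statically screened kernel:

       A[ia,jb] = (e_a - e_i) d_ij d_ab + 2 (ia|jb) - W_ij,ab(0)
       B[ia,jb] = 2 (ia|jb) - W_ib,ja(0)

   for closed-shell singlets. Replacing `W -> v` on an HF reference yields
   TD-HF exactly; this limit is what pins the spin/factor conventions of
   the kernel in the test suite (they are asserted against an independent
   dense TD-HF construction, not assumed). The Tamm-Dancoff mode drops `B`.

## Numerical route

**Integrals.** All electron repulsion is factorized through a global
resolution-of-identity: `(pq|rs) ~ sum_L B[L,p,q] B[L,r,s]`. The auxiliary
Coulomb metric is normalized to unit diagonal, diagonalized, and directions
with eigenvalues below `eps_s` (default 5e-3) relative to the largest are
discarded; the retained subspace is orthonormalized so the bare interaction
is the identity matrix. Thresholding the *normalized* metric is deliberate:
linear dependence is a property of the normalized function set, and
thresholding the raw metric would discard weak-but-independent diffuse
channels. The projection preserves positive semidefiniteness of the fitted
Coulomb operator by construction, and discarding directions can only lower
the fitted `(pq|pq)`.

The mean-field engine itself (McMurchie-Davidson Gaussian integrals,
Becke-grid DFT with sympy-generated functional derivatives, DIIS SCF with
RI Coulomb and exchange) lives in `gwbse.qchem` and is validated against
closed-form s-Gaussian integrals and a center-derivative oracle. Basis sets
are generated on the fly as least-squares Gaussian expansions of
Slater-type shells (Slater's-rules exponents; `min` = 3-Gaussian minimal,
`sv` = split-valence with 6-Gaussian cores), and the auxiliary sets are
even-tempered progressions spanning twice the primary exponent range with
angular momenta up to d.

**Imaginary-time/frequency grids.** The polarizability in imaginary time
is a sum of decaying exponentials over the particle-hole gaps, so all grid
machinery only needs to be exact on that kernel family over the system's
gap range. Nodes and weights for the time quadrature
(`sum_k w_k exp(-D t_k) ~ 1/D`) and the frequency quadrature are optimized
by joint least squares in log parameters with analytic Jacobians and
Lawson-style reweighting (near-minimax); the cosine/sine transforms between
the axes and their inverses are per-row near-minimax fits on the same
family. Every grid carries *certified* maximum errors measured on a denser
validation lattice, and several tests assert against those certificates
rather than against fixed constants. Default: 16 points (the protocol value
for production-type runs); the water/N2 fixtures recommend 20 points, which
brings the one-shot quasiparticle error below ~2 meV against the
brute-force spectral oracle. The grid range is snapped to a coarse
logarithmic lattice so that all self-consistency cycles — and all four
reference calculations of the starting-point experiment — share one grid;
shared transforms make residual grid error cancel exactly in spread
measurements.

**Self-energy.** `Sigma_c` is assembled in imaginary time from
`(W - v)(i tau)` (full matrix, as quasiparticle self-consistency requires),
split into even/odd parts, and carried to the frequency axis by the
cosine/sine transforms; the static limit is the even-function time
quadrature. For the diagonal (G0W0/evGW) route the self-energy is sampled
on a dedicated dense continuation mesh (>= 32 points) rather than on the
sparse quadrature nodes: interpolatory Pade models through sparse node sets
can place spurious poles near the quasiparticle energy even with exact
data. The Thiele recursion and evaluation run in 60-digit arithmetic
(mpmath) — the standard remedy for the ill-conditioned divided differences
of self-energies with dense pole structure. Quasiparticle equations are
solved by Newton iteration with a numerically differentiated slope; on
non-convergence the Z-factor linearized value is returned with a warning.

**Davidson solver.** The paired problem is reduced to the symmetric form
`(A-B)^{1/2} (A+B) (A-B)^{1/2}` in the growing subspace (valid because
`A - B` is positive definite for the closed-shell systems in scope — a
Cholesky failure raises immediately). Expansion vectors come from
diagonal-preconditioned residuals of both `(A+B)` and `(A-B)` Ritz
equations; initialization is deterministic (unit vectors on the lowest-gap
pairs), the subspace collapses onto the Ritz vectors beyond 20x the number
of roots, and eigenvalues converge when every root moves less than `tol`
(default 1e-5 Ha) with residual norms below `50*tol`. Dense
materialization is available below an 800-pair guard for oracle tests only.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| `eps_s` | 5e-3 | relative metric-eigenvalue cutoff of the RI projection |
| `n_points` | 16 | imaginary time and frequency nodes (each) |
| `qsgw_conv` | 5e-9 | Frobenius norm of the density-matrix change |
| `evgw_conv_ev` | 3e-3 eV | HOMO change between evGW cycles |
| `mixing` | 0.3 | fraction of the previous H_eff retained per qsGW cycle |
| `max_cycles` | 50 | qsGW/evGW cycle cap (fixtures converge in < 40) |
| `bse.tol` | 1e-5 Ha | Davidson eigenvalue convergence |
| `ph_cutoff` | none | particle-hole transition-energy cutoff (1.5 Ha is the large-system protocol value; at fixture scale the spectrum is sparse and such a cutoff visibly shifts the lowest root, so it is off by default) |
| `weight_threshold` | 0.05 | smallest reported transition weight |
| `ct_threshold` | 0.5 | off-diagonal fragment weight that labels a state CT |
| frozen core | off | drop 1s cores of C/N/O from the correlated window |

## Analysis definitions

Oscillator strengths are length-gauge,
`f = (2/3) Omega sum_u |sqrt(2) (X+Y)^T d_u|^2`. Transition weights are
`X^2` under the `X^T X - Y^T Y = 1` normalization. Fragment decomposition
assigns Loewdin populations of the hole and electron orbitals to fragments
and distributes `X^2 - Y^2` amplitude weights onto (hole-fragment,
electron-fragment) cells, which sum to one per state exactly; a state is
labeled charge transfer when the off-diagonal sum exceeds `ct_threshold`.
An alternative `|X+Y|^2` weight is available behind the `amplitude`
flag. These definitions are the package's own choices — published tables of
this kind rarely state theirs.

## What the fixtures do and do not show

The fixture set (H2, a far-separated H2 dimer, water, N2, ethylene,
formaldehyde; hardcoded geometries) exercises every code path at desk
scale: self-consistency, starting-point independence, solver/oracle
equivalence, dark-state selection rules, and local/CT classification in
the non-interacting-dimer limit. Passing these says the machinery is
internally consistent and matches independent dense oracles; it does not
certify basis-set-converged excitation energies (the generated split-valence
basis is double-zeta quality without polarization), nor behavior for
chromophore-scale systems, charge-tagged species, relativistic cores, or
environmental electrostatics.

## Known limitations

- Gaussian bases generated from Slater fits, not production basis-set
  tables; no f functions, no ZORA relativity, no solvation.
- The RI projection at `eps_s = 5e-3` costs ~1e-3-level absolute accuracy
  in individual repulsion integrals; this is consistent across the whole
  stack (mean field and correlated layers share one fitted tensor), so
  internal equivalences hold far more tightly than absolute energies.
- Analytic continuation degrades for states far from the gap; diagonal
  quasiparticle energies of deep cores should be treated with caution.
- qsGW convergence is plain linear mixing; difficult cases (near-metallic
  gaps) will hit the cycle cap rather than switch to a smarter accelerator.
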