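# gwbse

Quasiparticle self-consistent GW + Bethe-Salpeter (qsGW-BSE) excited states
for small closed-shell molecules, in pure scientific Python.

Optical excitations of molecules are bound electron-hole pairs (excitons).
Predicting them from first principles with TD-DFT depends strongly on the
chosen exchange-correlation kernel; many-body perturbation theory in the
GW-BSE flavor removes most of that arbitrariness — but only if the GW step
itself does not inherit the mean-field starting point. This package
implements the starting-point-free variant: quasiparticle self-consistent
GW, where a static, Hermitian effective Hamiltonian built from the GW
self-energy,

    H_eff = F - v_xc + Sigma_x + (Sigma_c(0) + Sigma_c(0)^T)/2,

is re-diagonalized until the density matrix is stationary, followed by the
singlet particle-hole BSE with a statically screened kernel,

    A[ia,jb] = (e_a - e_i) delta + 2 (ia|jb) - W_ij,ab(0)
    B[ia,jb] = 2 (ia|jb) - W_ib,ja(0),

solved matrix-free for its lowest roots by a paired Davidson algorithm.
One-shot G0W0 and eigenvalue-only self-consistent evGW are included for
comparison, TD-HF is the exact `W -> v` limit of the same solver, and the
analysis layer reports oscillator strengths, dominant particle-hole
transitions, and a fragment-resolved local vs charge-transfer
decomposition of every exciton.

It is aimed at method developers and students who want a compact, fully
inspectable implementation of the low-scaling "space-time" GW machinery —
imaginary-time/frequency grids with certified errors, RPA screening,
Pade analytic continuation, quasiparticle self-consistency — validated
end-to-end against independent dense oracles on built-in small-molecule
fixtures (H2, H2O, N2, ethylene, formaldehyde). It is not a production
quantum-chemistry code: the mean-field backend and its generated
Slater-fit Gaussian bases live in `gwbse.qchem` and are deliberately small.

## Worked example

A TOML file drives the whole pipeline:

```toml
# water.toml
[system]
xyz = "h2o"        # a built-in fixture name, or a path to an XYZ file
basis = "sv"       # generated split-valence Gaussian basis

[gw]
method = "qsgw"    # g0w0 | evgw | qsgw
reference = "PBEH40"

[bse]
n_roots = 4
```

```bash
gwbse run water.toml --out out/
```

prints the character table of the four lowest singlet excitons of water:

```
 state   E (eV)       f  character
     1    8.320  0.0020  [ALL*] 4->5 (1.00)
     2   11.111  0.0000  [ALL*] 4->6 (0.99)
     3   11.927  0.1120  [ALL*] 3->5 (0.98)
     4   14.513  0.1325  [ALL*] 3->6 (0.96)
```

Each row is one exciton: its vertical excitation energy, its length-gauge
oscillator strength, its fragment character (`[ALL*]` = local on the single
default fragment; with an atom-to-fragment map in `[system] fragments`,
charge-transfer states appear as `[A+ -> B-]`), and the dominant
particle-hole transitions with their weights — here the lowest state is a
pure HOMO->LUMO (orbital 4 -> 5) excitation, and the second state is dipole
forbidden (f ~ 0). The converged qsGW HOMO-LUMO gap for this run is
17.858 eV (31 self-consistency cycles; `out/qp.json` holds the full
quasiparticle spectrum, `out/spectrum.csv` the plottable spectrum, and
`out/grid_report.json` the imaginary-axis grid with its certified errors).

The same objects are available as a library:

```python
from gwbse import (BasisSpec, run_mean_field, qsgw_loop,
                   build_bse_operator, davidson_solve, make_fixture)

mol, settings = make_fixture("h2o")
mf = run_mean_field(mol, BasisSpec("sv", "etb"), "PBEH40")
qp = qsgw_loop(mf)                       # starting-point-free quasiparticles
excitons = davidson_solve(build_bse_operator(qp), n_roots=4)
```

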