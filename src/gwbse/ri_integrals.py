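"""Fitted (resolution-of-identity) representation of the Coulomb interaction.

The four-index repulsion integrals are factorized through a global
auxiliary expansion, (pq|rs) ~ sum_L B[L,p,q] B[L,r,s], with the auxiliary
Coulomb metric orthonormalized after discarding near-linear-dependent
directions below the relative threshold ``eps_s``.  In the retained
subspace the bare Coulomb operator is the identity matrix, which simplifies
every downstream screening expression.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system_core import BasisSpec, Molecule, get_fitted_arrays

__all__ = ["FittedIntegrals", "MOBlocks", "build_fitted_integrals", "transform_to_mo"]


@dataclass
class FittedIntegrals:
    """Three-index RI tensor in the orthonormalized auxiliary metric."""

    b_tensor: np.ndarray       # (n_aux_kept, nbf, nbf), symmetric in (p, q)
    n_aux_kept: int
    metric_spectrum: np.ndarray  # eigenvalues of the normalized metric, descending
    eps_s: float

    @property
    def nbf(self):
        return self.b_tensor.shape[1]

    def reconstruct(self, p, q, r, s):
        """Approximate (pq|rs) from the fit."""
        return float(self.b_tensor[:, p, q] @ self.b_tensor[:, r, s])

    def reconstruct_diagonal(self):
        """All fitted (pq|pq); non-negative by construction."""
        d = np.einsum("Lpq,Lpq->pq", self.b_tensor, self.b_tensor)
        return d

    def save(self, path):
        """Optional on-disk cache of the fitted tensor (HDF5)."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("b_tensor", data=self.b_tensor)
            fh.create_dataset("metric_spectrum", data=self.metric_spectrum)
            fh.attrs["eps_s"] = self.eps_s

    @classmethod
    def load(cls, path):
        import h5py

        with h5py.File(path, "r") as fh:
            b = fh["b_tensor"][...]
            spec = fh["metric_spectrum"][...]
            eps = float(fh.attrs["eps_s"])
        return cls(b_tensor=b, n_aux_kept=b.shape[0], metric_spectrum=spec, eps_s=eps)


@dataclass
class MOBlocks:
    """Occupied/virtual blocks of the fitted tensor in the MO basis."""

    b_ov: np.ndarray  # (L, nocc, nvir)
    b_oo: np.ndarray  # (L, nocc, nocc)
    b_vv: np.ndarray  # (L, nvir, nvir)
    b_full: np.ndarray  # (L, nmo, nmo)
    nocc: int

    @property
    def nvir(self):
        return self.b_ov.shape[2]


def build_fitted_integrals(mol: Molecule, basis: BasisSpec, eps_s=5e-3) -> FittedIntegrals:
    """Diagonalize the auxiliary Coulomb metric, discard directions below
    ``eps_s`` (relative to the largest eigenvalue of the diagonally
    normalized metric) and build B in the orthonormalized retained space."""
    B, spectrum, nkept, _, _ = get_fitted_arrays(mol, basis, eps_s)
    return FittedIntegrals(b_tensor=B, n_aux_kept=nkept,
                           metric_spectrum=spectrum, eps_s=float(eps_s))


def transform_to_mo(fitted, mo_coeff, nocc, n_frozen=0) -> MOBlocks:
    """Half-transform B into MO blocks for the active window.

    ``fitted`` may be a FittedIntegrals or a bare (L, nbf, nbf) array.
    Frozen core orbitals are dropped from the occupied window.
    """
    b_ao = fitted.b_tensor if hasattr(fitted, "b_tensor") else np.asarray(fitted)
    if mo_coeff.shape[0] != b_ao.shape[1]:
        raise ValueError(
            f"MO coefficients ({mo_coeff.shape[0]} AOs) do not match the fitted "
            f"tensor ({b_ao.shape[1]} AOs)")
    c_act = mo_coeff[:, n_frozen:]
    half = np.einsum("Lpq,qj->Lpj", b_ao, c_act, optimize=True)
    full = np.einsum("pi,Lpj->Lij", c_act, half, optimize=True)
    no = nocc - n_frozen
    return MOBlocks(b_ov=full[:, :no, no:], b_oo=full[:, :no, :no],
                    b_vv=full[:, no:, no:], b_full=full, nocc=no)
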