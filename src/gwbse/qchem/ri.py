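"""Global resolution-of-identity factorization of the Coulomb interaction.

The auxiliary Coulomb metric (P|Q) is diagonalized; directions with
eigenvalues below ``eps_s`` times the largest eigenvalue are discarded and
the three-center tensor is expressed in the orthonormalized retained
subspace, so that (pq|rs) ~ sum_L B[L,p,q] B[L,r,s] and the bare Coulomb
operator is the identity matrix in the auxiliary indices.
"""
from __future__ import annotations

import numpy as np

from . import integrals

__all__ = ["build_ri_arrays"]

# eigenvalues below this relative floor are always dropped: they carry no
# numerical information and would amplify roundoff
_EPS_FLOOR = 1e-14


def build_ri_arrays(primary, aux, eps_s=5e-3):
    """Return (B[L,p,q], metric eigenvalues, n_kept).

    Raises if the metric has significantly negative eigenvalues, which
    signals a broken auxiliary set.
    """
    if eps_s < 0:
        raise ValueError("eps_s must be non-negative")
    metric = integrals.eri_2c(aux)
    metric = 0.5 * (metric + metric.T)
    # threshold the diagonally-normalized metric: linear dependence is a
    # property of the normalized function set, not of absolute norms
    dn = 1.0 / np.sqrt(np.diag(metric))
    mnorm = metric * np.outer(dn, dn)
    evals, vecs = np.linalg.eigh(mnorm)
    lmax = evals[-1]
    if evals[0] < -1e-8 * lmax:
        raise RuntimeError(
            f"auxiliary Coulomb metric is not positive semidefinite "
            f"(min eigenvalue {evals[0]:.3e}); the auxiliary set is unusable"
        )
    cut = max(eps_s, _EPS_FLOOR) * lmax
    keep = evals >= cut
    X = (dn[:, None] * vecs[:, keep]) / np.sqrt(evals[keep])[None, :]  # (naux, nkept)
    threec = integrals.eri_3c(aux, primary)
    B = np.tensordot(X.T, threec, axes=1)  # (nkept, nbf, nbf)
    B = 0.5 * (B + B.transpose(0, 2, 1))
    return B, evals[::-1].copy(), int(keep.sum())
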