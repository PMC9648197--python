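"""System definition and the mean-field reference layer.

Holds the molecular data model (XYZ input, charge/multiplicity checks,
fragment partitions), the basis specification, and the adapter that runs
the self-consistent-field reference calculation producing a
:class:`MeanFieldSolution`.  Only closed-shell (restricted) references are
supported; open-shell input is rejected rather than spin-averaged.

Units: geometries are held in Angstrom, all electronic-structure quantities
are in Hartree atomic units (1 Ha = 27.211386 eV).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .qchem import basis as _qbasis
from .qchem import ri as _qri
from .qchem import scf as _qscf
from .qchem.basis import ELEMENTS

__all__ = [
    "HARTREE_EV", "ANGSTROM_TO_BOHR",
    "Molecule", "BasisSpec", "MeanFieldSolution", "FragmentPartition",
    "load_molecule", "run_mean_field", "define_fragments", "load_config",
    "InputError", "MalformedCountError", "UnknownElementError", "CoordinateParseError",
]

log = logging.getLogger("gwbse")

HARTREE_EV = 27.211386
ANGSTROM_TO_BOHR = 1.8897259886


class InputError(ValueError):
    """Base class for malformed user input."""


class MalformedCountError(InputError):
    pass


class UnknownElementError(InputError):
    pass


class CoordinateParseError(InputError):
    pass


@dataclass(frozen=True)
class Molecule:
    """A molecule: element symbols, Cartesian coordinates in Angstrom,
    total charge and spin multiplicity (closed shell only)."""

    symbols: tuple
    coords: np.ndarray
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        coords = np.asarray(self.coords, float).reshape(-1, 3)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "symbols", tuple(self.symbols))
        if len(self.symbols) != len(coords):
            raise InputError("number of coordinate rows must equal number of symbols")
        for s in self.symbols:
            if s not in ELEMENTS:
                raise UnknownElementError(f"unknown element symbol {s!r}")
        if self.multiplicity != 1:
            raise InputError("only closed-shell molecules (multiplicity 1) are supported")
        if self.n_electrons % 2 != 0:
            raise InputError("odd electron count is incompatible with a closed shell")

    @property
    def charges(self):
        return np.array([ELEMENTS[s] for s in self.symbols], dtype=float)

    @property
    def n_electrons(self):
        return int(sum(ELEMENTS[s] for s in self.symbols)) - self.charge

    @property
    def natm(self):
        return len(self.symbols)

    @property
    def coords_bohr(self):
        return self.coords * ANGSTROM_TO_BOHR

    def _key(self):
        return (self.symbols, self.coords.tobytes(), self.charge)


@dataclass(frozen=True)
class BasisSpec:
    """Primary/auxiliary basis identifiers resolved by the SCF backend."""

    primary_name: str = "sv"
    auxiliary_name: str = "etb"
    frozen_core: bool = False


@dataclass
class MeanFieldSolution:
    """Converged SCF reference.

    ``vxc`` is the DFT exchange-correlation potential matrix only (zero for
    Hartree-Fock); the scaled exact-exchange part of hybrid references is
    carried separately through ``hyb`` and ``k_matrix`` so that
    Fock - vxc - hyb*K reproduces the Hartree-only potential exactly.
    """

    mo_coeff: np.ndarray
    mo_energy: np.ndarray
    occupations: np.ndarray
    fock: np.ndarray
    vxc: np.ndarray
    reference_tag: str
    overlap: np.ndarray
    hcore: np.ndarray
    k_matrix: np.ndarray
    density: np.ndarray
    hyb: float
    e_tot: float
    molecule: Molecule
    basis_spec: BasisSpec
    _primary_basis: object = field(repr=False, default=None)
    _aux_basis: object = field(repr=False, default=None)

    @property
    def nocc(self):
        return int(round(self.occupations.sum() / 2))

    @property
    def n_frozen(self):
        """Number of frozen (1s) core orbitals when frozen_core is set."""
        if not self.basis_spec.frozen_core:
            return 0
        return int(sum(1 for s in self.molecule.symbols if ELEMENTS[s] > 2))

    @property
    def homo_lumo_gap(self):
        return float(self.mo_energy[self.nocc] - self.mo_energy[self.nocc - 1])


@dataclass(frozen=True)
class FragmentPartition:
    """Assignment of every atom to exactly one named fragment."""

    atom_to_fragment: tuple
    fragment_labels: tuple

    @property
    def n_fragments(self):
        return len(self.fragment_labels)

    def indices(self, label):
        return [i for i, lab in enumerate(self.atom_to_fragment) if lab == label]


# ---------------------------------------------------------------------------
# XYZ input
# ---------------------------------------------------------------------------

def load_molecule(path, charge=0, multiplicity=1) -> Molecule:
    """Read a standard two-header-line XYZ file (coordinates in Angstrom)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise MalformedCountError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise MalformedCountError(f"{path}: first line must be the atom count") from exc
    body = [ln for ln in lines[2 : 2 + count]]
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if count != len(atom_lines) or len(body) < count:
        raise MalformedCountError(
            f"{path}: declared {count} atoms but found {len(atom_lines)} atom lines")
    symbols, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise CoordinateParseError(f"{path}: malformed atom line {ln!r}")
        sym = parts[0].capitalize()
        if sym not in ELEMENTS:
            raise UnknownElementError(f"{path}: unknown element symbol {parts[0]!r}")
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError as exc:
            raise CoordinateParseError(f"{path}: bad coordinates in line {ln!r}") from exc
        symbols.append(sym)
    return Molecule(symbols=tuple(symbols), coords=np.asarray(coords), charge=charge,
                    multiplicity=multiplicity)


# ---------------------------------------------------------------------------
# mean-field adapter
# ---------------------------------------------------------------------------

_ri_cache: dict = {}


def get_fitted_arrays(mol: Molecule, basis: BasisSpec, eps_s=5e-3):
    """(B tensor, metric spectrum, n_kept, primary BasisSet, aux BasisSet),
    cached per geometry/basis/threshold."""
    key = (mol._key(), basis.primary_name, basis.auxiliary_name, float(eps_s))
    if key not in _ri_cache:
        primary = _qbasis.build_basis(mol.charges, mol.coords_bohr, basis.primary_name)
        aux = _qbasis.build_aux_basis(mol.charges, mol.coords_bohr, primary, basis.auxiliary_name)
        if aux.nbf <= primary.nbf:
            raise InputError("auxiliary basis must be larger than the primary basis")
        B, spectrum, nkept = _qri.build_ri_arrays(primary, aux, eps_s=eps_s)
        if len(_ri_cache) > 16:
            _ri_cache.clear()
        _ri_cache[key] = (B, spectrum, nkept, primary, aux)
    return _ri_cache[key]


def run_mean_field(mol: Molecule, basis: BasisSpec, reference_tag: str,
                   eps_s=5e-3) -> MeanFieldSolution:
    """Converge the SCF reference (HF, LDA, PBE or the 40%-exact-exchange
    PBE hybrid PBEH40) for a closed-shell molecule."""
    tag = str(reference_tag).upper()
    B, _, _, primary, aux = get_fitted_arrays(mol, basis, eps_s)
    res = _qscf.run_scf(mol.charges, mol.coords_bohr, primary, B, tag)
    log.info("SCF %s/%s converged: E = %.10f Ha, gap = %.4f eV, %d iterations",
             tag, basis.primary_name, res.e_tot, res.homo_lumo_gap * HARTREE_EV, res.n_iter)
    # split the xc potential: vxc holds the pure DFT part only
    vxc_dft = res.vxc
    return MeanFieldSolution(
        mo_coeff=res.mo_coeff, mo_energy=res.mo_energy, occupations=res.mo_occ,
        fock=res.fock, vxc=vxc_dft, reference_tag=tag,
        overlap=res.overlap, hcore=res.hcore, k_matrix=res.k_matrix,
        density=res.density, hyb=res.hyb, e_tot=res.e_tot,
        molecule=mol, basis_spec=basis, _primary_basis=primary, _aux_basis=aux,
    )


def define_fragments(mol: Molecule, mapping=None) -> FragmentPartition:
    """Build a fragment partition; default is one fragment 'ALL'."""
    if mapping is None:
        return FragmentPartition(atom_to_fragment=("ALL",) * mol.natm, fragment_labels=("ALL",))
    assigned = []
    for i in range(mol.natm):
        if i not in mapping:
            raise InputError(f"fragment mapping misses atom index {i}")
        assigned.append(str(mapping[i]))
    labels = []
    for lab in assigned:
        if lab not in labels:
            labels.append(lab)
    return FragmentPartition(atom_to_fragment=tuple(assigned), fragment_labels=tuple(labels))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

CONFIG_DEFAULTS = {
    "system": {"xyz": None, "charge": 0, "basis": "sv", "aux_basis": "etb",
               "frozen_core": False, "fragments": {}},
    "gw": {"method": "qsgw", "reference": "PBEH40", "n_points": 16,
           "eps_s": 5e-3, "qsgw_conv": 5e-9, "evgw_conv_ev": 3e-3,
           "mixing": 0.3, "max_cycles": 50},
    "bse": {"n_roots": 6, "tol": 1e-5, "ph_cutoff": None, "mode": "BSE"},
    "analysis": {"weight_threshold": 0.05, "ct_threshold": 0.5},
}


def load_config(path):
    """Read a TOML run configuration; unspecified keys take the defaults
    above (grid sizes, thresholds and convergence criteria)."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = {}
    for section, defaults in CONFIG_DEFAULTS.items():
        cfg[section] = dict(defaults)
        for k, v in raw.get(section, {}).items():
            if k not in defaults:
                raise InputError(f"unknown configuration key [{section}] {k}")
            cfg[section][k] = v
    method = str(cfg["gw"]["method"]).lower()
    if method not in ("g0w0", "evgw", "qsgw"):
        raise InputError(f"unknown GW method {method!r}")
    cfg["gw"]["method"] = method
    return cfg
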