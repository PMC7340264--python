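"""Atomic models: PDB I/O, the pre-refinement modification recipes, and RMSDs.

Models carry fractional coordinates, occupancies and isotropic displacement
parameters (ADPs, "B factors", Angstrom^2).  The modification recipes —
random coordinate perturbation with a stated mean displacement, ADP reset
to a mean or explicit value, ADP shift — are what complete cross-validation
uses to erase the memory of a previous free-reflection set before
re-refinement.  All operations are pure: the input model is never mutated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .reflections import UnitCell

__all__ = [
    "Atom",
    "AtomicModel",
    "read_pdb",
    "write_pdb",
    "perturb_coordinates",
    "reset_adp",
    "shift_adp",
    "rmsd_coordinates",
    "rmsd_adp",
]


@dataclass(frozen=True)
class Atom:
    """One scatterer: element, electron count Z, fractional position, occupancy, B."""

    element: str
    z: int
    frac: tuple[float, float, float]
    occupancy: float = 1.0
    b_iso: float = 15.0


@dataclass
class AtomicModel:
    """Ordered collection of atoms in one unit cell.

    Atom order is stable across I/O round-trips; RMSD comparisons pair
    atoms by position in the sequence.
    """

    cell: UnitCell
    elements: list[str]
    z: np.ndarray  # (n,)
    frac: np.ndarray  # (n, 3)
    occupancy: np.ndarray  # (n,)
    b_iso: np.ndarray  # (n,)
    label: str = "model"

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.frac = np.asarray(self.frac, dtype=float).reshape(-1, 3)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        self.b_iso = np.asarray(self.b_iso, dtype=float)
        n = len(self.elements)
        if not (len(self.z) == len(self.frac) == len(self.occupancy) == len(self.b_iso) == n):
            raise ValueError("atom column length mismatch")
        if n and (np.any(self.b_iso <= 0) or np.any(self.z <= 0)):
            raise ValueError("B factors and electron counts must be positive")
        if n and (np.any(self.occupancy < 0) or np.any(self.occupancy > 1)):
            raise ValueError("occupancies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.elements)

    @classmethod
    def from_atoms(cls, cell: UnitCell, atoms: list[Atom], label: str = "model"):
        return cls(
            cell,
            [a.element for a in atoms],
            np.array([a.z for a in atoms]),
            np.array([a.frac for a in atoms]),
            np.array([a.occupancy for a in atoms]),
            np.array([a.b_iso for a in atoms]),
            label,
        )

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(e, int(z), tuple(f), o, b)
            for e, z, f, o, b in zip(
                self.elements, self.z, self.frac, self.occupancy, self.b_iso
            )
        ]

    def cartesian(self) -> np.ndarray:
        """Orthogonal coordinates in Angstrom, (n, 3)."""
        return self.frac @ self.cell.orthogonalization_matrix.T

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            self.cell,
            list(self.elements),
            self.z.copy(),
            self.frac.copy(),
            self.occupancy.copy(),
            self.b_iso.copy(),
            self.label,
        )


# --------------------------------------------------------------------------- #
# PDB I/O (gemmi-backed)
# --------------------------------------------------------------------------- #


def read_pdb(path) -> AtomicModel:
    """Read a PDB file into an :class:`AtomicModel`.

    Requires a CRYST1 record and known element symbols; anisotropic ADPs
    (ANISOU) are rejected — only isotropic models are supported.
    """
    with open(path) as fh:
        text = fh.read()
    if "CRYST1" not in text:
        raise ValueError(f"{path}: missing CRYST1 record (unit cell unknown)")
    if "ANISOU" in text:
        raise ValueError(f"{path}: ANISOU records present; only isotropic ADPs supported")
    st = gemmi.read_pdb_string(text)
    c = st.cell
    cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    fmat = cell.fractionalization_matrix
    elements, zs, fracs, occs, bs = [], [], [], [], []
    for chain in st[0]:
        for res in chain:
            for atom in res:
                el = atom.element
                if el.atomic_number == 0:
                    raise ValueError(
                        f"{path}: unknown element in record "
                        f"{chain.name}/{res.name} {res.seqid.num}/{atom.name}"
                    )
                elements.append(el.name)
                zs.append(el.atomic_number)
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                fracs.append(fmat @ pos)
                occs.append(atom.occ)
                bs.append(atom.b_iso)
    if not elements:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return AtomicModel(
        cell, elements, np.array(zs), np.array(fracs), np.array(occs), np.array(bs)
    )


def write_pdb(model: AtomicModel, path) -> None:
    """Write the model as a PDB file (CRYST1 + one chain of single-atom residues)."""
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*model.cell.to_tuple())
    st.spacegroup_hm = "P 1"
    gm = gemmi.Model("1")
    chain = gemmi.Chain("A")
    cart = model.cartesian()
    for i in range(len(model)):
        res = gemmi.Residue()
        res.name = "DUM"
        res.seqid = gemmi.SeqId(i + 1, " ")
        at = gemmi.Atom()
        at.name = model.elements[i]
        at.element = gemmi.Element(model.elements[i])
        at.pos = gemmi.Position(*cart[i])
        at.occ = float(model.occupancy[i])
        at.b_iso = float(model.b_iso[i])
        res.add_atom(at)
        chain.add_residue(res)
    gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# --------------------------------------------------------------------------- #
# Model modifications
# --------------------------------------------------------------------------- #


def perturb_coordinates(model: AtomicModel, mean_shift: float, seed: int = 0) -> AtomicModel:
    """Displace every atom by a random vector with expected magnitude ``mean_shift``.

    Directions are isotropically random; magnitudes are exponentially
    distributed with mean ``mean_shift`` Angstrom (the recipe fixes only the
    average displacement, so the one-parameter exponential is used).
    Deterministic for a given seed; the cell is unchanged.
    """
    if mean_shift < 0:
        raise ValueError("mean shift must be non-negative")
    out = model.copy()
    if mean_shift == 0 or len(model) == 0:
        return out
    rng = np.random.default_rng(seed)
    direc = rng.normal(size=(len(model), 3))
    direc /= np.linalg.norm(direc, axis=1, keepdims=True)
    mags = rng.exponential(scale=mean_shift, size=len(model))
    shift_cart = direc * mags[:, None]
    out.frac = model.frac + shift_cart @ model.cell.fractionalization_matrix.T
    return out


def reset_adp(model: AtomicModel, mode: str = "mean", value: float | None = None) -> AtomicModel:
    """Set every ADP to the model's mean B (``mode='mean'``) or to ``value``."""
    out = model.copy()
    if mode == "mean":
        target = float(model.b_iso.mean())
    elif mode == "value":
        if value is None or value <= 0:
            raise ValueError("explicit ADP value must be positive")
        target = float(value)
    else:
        raise ValueError("mode must be 'mean' or 'value'")
    if target <= 0:
        raise ValueError("resulting B factor would be non-positive")
    out.b_iso = np.full(len(model), target)
    return out


def shift_adp(model: AtomicModel, delta: float) -> AtomicModel:
    """Add ``delta`` Angstrom^2 to every ADP; the result must stay positive."""
    out = model.copy()
    new_b = model.b_iso + delta
    if np.any(new_b <= 0):
        raise ValueError(f"ADP shift {delta} would make a B factor non-positive")
    out.b_iso = new_b
    return out


# --------------------------------------------------------------------------- #
# RMSD against a reference
# --------------------------------------------------------------------------- #


def _check_paired(model: AtomicModel, reference: AtomicModel):
    if len(model) != len(reference):
        raise ValueError(f"atom count mismatch: {len(model)} vs {len(reference)}")


def rmsd_coordinates(model: AtomicModel, reference: AtomicModel) -> float:
    """Root-mean-square Cartesian displacement over identity-paired atoms.

    No superposition is applied: the compared models share one crystal
    frame.
    """
    _check_paired(model, reference)
    diff = model.cartesian() - reference.cartesian()
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def rmsd_adp(model: AtomicModel, reference: AtomicModel) -> float:
    """Root-mean-square ADP difference, sqrt(mean (B_i - B_i_ref)^2)."""
    _check_paired(model, reference)
    return float(np.sqrt(np.mean((model.b_iso - reference.b_iso) ** 2)))
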