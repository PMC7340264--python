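"""Direct-summation structure factors for point atoms with isotropic B.

The scatterer model is deliberately simple: each atom contributes its full
electron count Z with a Gaussian displacement falloff,

    Fc(h) = sum_j o_j Z_j exp(-B_j / (4 d_h^2)) exp(2 pi i h . x_j),

i.e. constant (resolution-independent) form factors.  This is non-physical
— real atomic form factors decay with resolution — but it preserves every
statistical property the paired-refinement protocol monitors (R factors,
correlations, overfitting behaviour) while keeping an analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AtomicModel
from .reflections import UnitCell, friedel_reduce

__all__ = ["CalcSet", "calc_structure_factors"]


@dataclass
class CalcSet:
    """Calculated complex structure factors on Friedel-reduced indices."""

    cell: UnitCell
    hkl: np.ndarray  # (n, 3) canonical
    f: np.ndarray  # (n,) complex

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.f = np.asarray(self.f, dtype=complex)
        if len(self.hkl) != len(self.f):
            raise ValueError("index/value length mismatch")

    def __len__(self) -> int:
        return len(self.f)

    def amplitudes(self) -> np.ndarray:
        return np.abs(self.f)

    def d_spacings(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    def match(self, hkl) -> np.ndarray:
        """Complex Fc for each requested index (Friedel-reduced lookup).

        Raises ``KeyError`` naming the first index with no calculated value.
        """
        want = friedel_reduce(np.asarray(hkl, dtype=int).reshape(-1, 3))
        left = pd.DataFrame(want, columns=["h", "k", "l"])
        right = pd.DataFrame(self.hkl, columns=["h", "k", "l"])
        right["_ix"] = np.arange(len(right))
        joined = left.merge(right, on=["h", "k", "l"], how="left")
        missing = joined["_ix"].isna()
        if missing.any():
            first = tuple(int(x) for x in want[int(np.nonzero(missing.to_numpy())[0][0])])
            raise KeyError(f"no calculated structure factor for index {first}")
        return self.f[joined["_ix"].to_numpy(dtype=int)]


def calc_structure_factors(model: AtomicModel, hkl, chunk: int = 200_000) -> CalcSet:
    """Exact direct summation of Fc over the given Miller indices.

    Indices are Friedel-reduced; duplicated canonical keys are an error.
    Work is chunked so the (reflections x atoms) intermediate stays small.
    """
    h = friedel_reduce(np.asarray(hkl, dtype=int).reshape(-1, 3))
    if len(h) == 0:
        raise ValueError("empty index list")
    if len(np.unique(h, axis=0)) != len(h):
        raise ValueError("duplicate Miller indices after Friedel reduction")
    d = model.cell.d_spacing(h)
    s2_over4 = 0.25 / d**2
    w = model.occupancy * model.z  # (natoms,)
    f = np.empty(len(h), dtype=complex)
    block = max(1, chunk // max(len(model), 1))
    for lo in range(0, len(h), block):
        hi = min(lo + block, len(h))
        damp = np.exp(-np.outer(s2_over4[lo:hi], model.b_iso))  # (m, natoms)
        phase = np.exp(2j * np.pi * (h[lo:hi] @ model.frac.T))
        f[lo:hi] = (damp * phase) @ w
    return CalcSet(model.cell, h, f)
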