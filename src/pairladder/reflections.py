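"""Reflection data containers, resolution geometry, shell binning and text I/O.

Two kinds of reflection data are handled: *unmerged* intensities (every
individual observation of every reflection, the substrate of merging
statistics) and *merged* data (one record per unique reflection, carrying an
amplitude or intensity, a sigma and a CCP4-style free-reflection flag, the
substrate of refinement).  Symmetry handling is restricted to Friedel
reduction: data are expected in P1 or pre-reduced by upstream processing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ReflectionFileError",
    "UnitCell",
    "ShellScheme",
    "UnmergedSet",
    "MergedSet",
    "friedel_reduce",
    "make_shells",
    "read_merged",
    "write_merged",
    "read_unmerged",
    "enumerate_unique_indices",
]


class ReflectionFileError(ValueError):
    """Raised for malformed reflection files; carries the offending line number."""


# --------------------------------------------------------------------------- #
# Unit cell and resolution geometry
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        # positive-definite metric <=> positive cell volume
        if self._volume_factor() <= 0:
            raise ValueError("cell angles give a non-positive-definite metric")

    def _volume_factor(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    @property
    def volume(self) -> float:
        """Cell volume in cubic Angstrom."""
        return self.a * self.b * self.c * np.sqrt(self._volume_factor())

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix M with fractional -> orthogonal (Angstrom) x = M f.

        Standard convention: a along x, b in the x-y plane.
        """
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v = np.sqrt(self._volume_factor())
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def fractionalization_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization_matrix)

    @property
    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal metric tensor G* such that 1/d^2 = h . G* . h."""
        m = self.orthogonalization_matrix
        g = m.T @ m  # direct metric tensor
        return np.linalg.inv(g)

    def d_spacing(self, hkl) -> float | np.ndarray:
        """Resolution d (Angstrom) of Miller index/indices ``hkl``.

        Accepts a single (h, k, l) triple or an (n, 3) array.  Symmetric in
        Friedel mates.  A zero index has no Bragg plane and raises.
        """
        h = np.asarray(hkl, dtype=float)
        single = h.ndim == 1
        h = np.atleast_2d(h)
        if np.any(np.all(h == 0, axis=1)):
            raise ValueError("d-spacing undefined for the (0,0,0) index")
        gstar = self.reciprocal_metric
        inv_d2 = np.einsum("ni,ij,nj->n", h, gstar, h)
        d = 1.0 / np.sqrt(inv_d2)
        return float(d[0]) if single else d

    def to_tuple(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def friedel_reduce(hkl) -> np.ndarray:
    """Map (h,k,l) and (-h,-k,-l) to one canonical key.

    Canonical form has its first nonzero component positive.  Accepts a
    triple or an (n, 3) integer array; returns the same shape.
    """
    h = np.asarray(hkl, dtype=int)
    single = h.ndim == 1
    h = np.atleast_2d(h)
    if np.any(np.all(h == 0, axis=1)):
        raise ValueError("cannot reduce the (0,0,0) index")
    # sign of first nonzero component per row
    first = np.where(h[:, 0] != 0, h[:, 0], np.where(h[:, 1] != 0, h[:, 1], h[:, 2]))
    out = np.where(first[:, None] < 0, -h, h)
    return out[0] if single else out


# --------------------------------------------------------------------------- #
# Resolution shells
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ShellScheme:
    """Contiguous resolution shells given by strictly descending d-edges.

    Shell ``i`` spans ``edges[i]`` (low-resolution side) down to
    ``edges[i+1]``.  Membership is half-open at the low-resolution edge:
    a reflection with d exactly equal to an interior edge belongs to the
    shell whose *high-resolution* (lower-d) boundary it is, so that
    truncating the data at an edge keeps whole shells.  The outermost
    low-resolution edge is inclusive.
    """

    edges: tuple[float, ...]

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if e.size < 2:
            raise ValueError("need at least two edges for one shell")
        if np.any(np.diff(e) >= 0):
            raise ValueError("shell edges must be strictly decreasing in d")
        if e[-1] <= 0:
            raise ValueError("edges must be positive resolutions")

    @property
    def n_shells(self) -> int:
        return len(self.edges) - 1

    @property
    def d_max(self) -> float:
        return self.edges[0]

    @property
    def d_min(self) -> float:
        return self.edges[-1]

    def bounds(self, i: int) -> tuple[float, float]:
        """(d_upper, d_lower) of shell i."""
        return self.edges[i], self.edges[i + 1]

    def assign(self, d) -> np.ndarray:
        """Shell index per d value; -1 for d outside [d_min, d_max]."""
        d = np.atleast_1d(np.asarray(d, dtype=float))
        asc = np.asarray(self.edges[::-1])  # ascending
        # j = number of ascending edges <= d; shell i spans [edges[i+1], edges[i])
        j = np.searchsorted(asc, d, side="right")
        shell = len(asc) - 1 - j
        shell[d == self.d_max] = 0  # outer edge inclusive
        shell[(d > self.d_max) | (d < self.d_min)] = -1
        return shell


def make_shells(
    d_start: float,
    d_final: float | None = None,
    width: float = 0.05,
    edges: Sequence[float] | None = None,
) -> ShellScheme:
    """Build a shell scheme from ``d_start`` down to ``d_final``.

    Either equal-width shells of ``width`` Angstrom (the last shell is
    truncated at ``d_final``), or explicit descending ``edges`` which
    override the width and ``d_final``.
    """
    if edges is not None:
        full = [float(d_start)] + [float(e) for e in edges]
        return ShellScheme(tuple(full))
    if d_final is None:
        raise ValueError("either d_final or explicit edges are required")
    if not d_start > d_final > 0:
        raise ValueError("require d_start > d_final > 0")
    if width <= 0:
        raise ValueError("shell width must be positive")
    out = [float(d_start)]
    # decimal-exact edge arithmetic: count whole widths, truncate the last
    n_whole = int(np.floor((d_start - d_final) / width + 1e-9))
    for i in range(1, n_whole + 1):
        e = round(d_start - i * width, 10)
        if e > d_final + 1e-9:
            out.append(e)
    out.append(float(d_final))
    return ShellScheme(tuple(out))


# --------------------------------------------------------------------------- #
# Data containers
# --------------------------------------------------------------------------- #


@dataclass
class UnmergedSet:
    """Multiply-observed intensities: one row per observation."""

    cell: UnitCell
    hkl: np.ndarray  # (n, 3) int
    intensity: np.ndarray  # (n,)
    sigma: np.ndarray  # (n,)
    label: str = "unmerged"

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.hkl) == len(self.intensity) == len(self.sigma)):
            raise ValueError("column length mismatch")
        if np.any(self.sigma <= 0):
            raise ValueError("all sigmas must be positive")

    def __len__(self) -> int:
        return len(self.intensity)

    def unique_keys(self) -> np.ndarray:
        return friedel_reduce(self.hkl)

    def d_spacings(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    def select_resolution(self, d_cutoff: float) -> "UnmergedSet":
        """Retain observations with d >= d_cutoff (inclusive boundary)."""
        if d_cutoff <= 0:
            return dataclasses.replace(self)
        keep = self.d_spacings() >= d_cutoff
        return UnmergedSet(
            self.cell, self.hkl[keep], self.intensity[keep], self.sigma[keep], self.label
        )


@dataclass
class MergedSet:
    """Unique reflections with amplitude (kind 'F') or intensity (kind 'I').

    ``flag`` is the CCP4-style free-reflection label, an integer in
    0..flag_count-1; choosing one label as the test set defines one of
    flag_count cross-validation partitions.
    """

    cell: UnitCell
    hkl: np.ndarray
    value: np.ndarray
    sigma: np.ndarray
    flag: np.ndarray
    kind: str = "F"
    flag_count: int | None = None

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.value = np.asarray(self.value, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.flag = np.asarray(self.flag, dtype=int)
        if self.kind not in ("F", "I"):
            raise ValueError("kind must be 'F' (amplitude) or 'I' (intensity)")
        if np.any(self.sigma <= 0):
            raise ValueError("all sigmas must be positive")
        if len(self.hkl):
            keys = friedel_reduce(self.hkl)
            uniq = np.unique(keys, axis=0)
            if len(uniq) != len(keys):
                raise ValueError("duplicate Miller keys after Friedel reduction")
        if self.flag_count is None:
            self.flag_count = int(self.flag.max()) + 1 if len(self.flag) else 1
        if len(self.flag) and (self.flag.min() < 0 or self.flag.max() >= self.flag_count):
            raise ValueError("free flags out of range 0..flag_count-1")

    def __len__(self) -> int:
        return len(self.value)

    def d_spacings(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    def amplitudes(self) -> np.ndarray:
        """|Fo|; intensities are converted by sqrt(max(I, 0))."""
        if self.kind == "F":
            return self.value
        return np.sqrt(np.maximum(self.value, 0.0))

    def free_mask(self, q: int) -> np.ndarray:
        """Boolean mask of the free (test) reflections for free-set label q."""
        if not 0 <= q < self.flag_count:
            raise ValueError(f"free-set label {q} outside 0..{self.flag_count - 1}")
        return self.flag == q

    def select_resolution(self, d_cutoff: float) -> "MergedSet":
        if d_cutoff <= 0:
            return dataclasses.replace(self)
        keep = self.d_spacings() >= d_cutoff
        return MergedSet(
            self.cell,
            self.hkl[keep],
            self.value[keep],
            self.sigma[keep],
            self.flag[keep],
            self.kind,
            self.flag_count,
        )


# --------------------------------------------------------------------------- #
# Text I/O
# --------------------------------------------------------------------------- #

_FMT = "%d %d %d %.10g %.10g %d"


def write_merged(mset: MergedSet, path) -> None:
    """Write the plain-text merged format (see :func:`read_merged`)."""
    c = mset.cell
    with open(path, "w") as fh:
        fh.write(f"# CELL {c.a:.6g} {c.b:.6g} {c.c:.6g} {c.alpha:.6g} {c.beta:.6g} {c.gamma:.6g}\n")
        fh.write(f"# KIND {mset.kind}\n")
        for (h, k, l), v, s, f in zip(mset.hkl, mset.value, mset.sigma, mset.flag):
            fh.write(_FMT % (h, k, l, v, s, f) + "\n")


def read_merged(path) -> MergedSet:
    """Read merged reflection data from a whitespace-separated text file.

    Header lines: ``# CELL a b c alpha beta gamma`` and ``# KIND F|I``;
    data lines: ``h k l value sigma flag``.  flag_count is inferred as
    max(flag) + 1.
    """
    cell = None
    kind = "F"
    hkl, val, sig, flg = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "CELL":
                    if len(parts) != 7:
                        raise ReflectionFileError(f"line {lineno}: CELL needs 6 numbers")
                    cell = UnitCell(*(float(x) for x in parts[1:]))
                elif parts and parts[0] == "KIND":
                    if len(parts) != 2 or parts[1] not in ("F", "I"):
                        raise ReflectionFileError(f"line {lineno}: KIND must be F or I")
                    kind = parts[1]
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ReflectionFileError(f"line {lineno}: expected 'h k l value sigma flag'")
            try:
                h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
                v, s = float(parts[3]), float(parts[4])
                f = int(parts[5])
            except ValueError as exc:
                raise ReflectionFileError(f"line {lineno}: {exc}") from None
            if s <= 0:
                raise ReflectionFileError(f"line {lineno}: sigma must be positive, got {s}")
            hkl.append((h, k, l))
            val.append(v)
            sig.append(s)
            flg.append(f)
    if cell is None:
        raise ReflectionFileError("missing '# CELL a b c alpha beta gamma' header")
    if not hkl:
        raise ReflectionFileError("no reflections in file")
    return MergedSet(cell, np.array(hkl), np.array(val), np.array(sig), np.array(flg), kind)


def read_unmerged(path, cell: UnitCell | None = None, logger=None) -> UnmergedSet:
    """Read unmerged intensities from an XDS-ASCII-style text file.

    Lines starting with ``!`` are headers; data lines supply at least
    ``h k l I sigI``.  The cell is taken from a ``!UNIT_CELL_CONSTANTS=``
    header if present, else from the ``cell`` argument.  Observations with
    sigma <= 0 are dropped (their count is reported via ``logger``);
    negative intensities are retained.
    """
    hkl, ints, sig = [], [], []
    header_cell = None
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("!"):
                if "UNIT_CELL_CONSTANTS=" in line:
                    nums = line.split("=", 1)[1].split()
                    if len(nums) < 6:
                        raise ReflectionFileError(
                            f"line {lineno}: UNIT_CELL_CONSTANTS needs 6 numbers"
                        )
                    header_cell = UnitCell(*(float(x) for x in nums[:6]))
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ReflectionFileError(f"line {lineno}: expected at least 'h k l I sigI'")
            try:
                h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
                i, s = float(parts[3]), float(parts[4])
            except ValueError as exc:
                raise ReflectionFileError(f"line {lineno}: {exc}") from None
            if s <= 0:
                n_dropped += 1
                continue
            hkl.append((h, k, l))
            ints.append(i)
            sig.append(s)
    use_cell = header_cell or cell
    if use_cell is None:
        raise ReflectionFileError(
            "no unit cell: neither a !UNIT_CELL_CONSTANTS= header nor a cell argument"
        )
    if n_dropped and logger is not None:
        logger.warning("dropped %d observations with sigma <= 0", n_dropped)
    if not hkl:
        raise ReflectionFileError("no observations in file")
    out = UnmergedSet(use_cell, np.array(hkl), np.array(ints), np.array(sig))
    out.n_dropped = n_dropped
    return out


# --------------------------------------------------------------------------- #
# Friedel-unique sphere enumeration (completeness denominator, simulation)
# --------------------------------------------------------------------------- #


def enumerate_unique_indices(cell: UnitCell, d_min: float) -> np.ndarray:
    """All Friedel-unique Miller indices with d >= d_min, canonical form.

    The search box uses the general bound |h| <= a/d_min (projection of the
    scattering vector onto each direct axis), then filters by exact d.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hmax = int(np.floor(cell.a / d_min))
    kmax = int(np.floor(cell.b / d_min))
    lmax = int(np.floor(cell.c / d_min))
    hs = np.arange(0, hmax + 1)
    ks = np.arange(-kmax, kmax + 1)
    ls = np.arange(-lmax, lmax + 1)
    grid = np.stack(np.meshgrid(hs, ks, ls, indexing="ij"), axis=-1).reshape(-1, 3)
    # canonical half-sphere: first nonzero component positive
    h, k, l = grid[:, 0], grid[:, 1], grid[:, 2]
    keep = (h > 0) | ((h == 0) & (k > 0)) | ((h == 0) & (k == 0) & (l > 0))
    grid = grid[keep]
    d = cell.d_spacing(grid)
    return grid[d >= d_min]
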