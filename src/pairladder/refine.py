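"""Refinement backends: the contract, the built-in toy engine, an external adapter.

A backend takes a model and merged data truncated at a cutoff and returns a
:class:`RefinementResult`.  The contract's one hard guarantee is that
free-flagged reflections of the active free set never enter the minimized
target — Rfree computed from the result is then an unbiased cross-validation
statistic.

The toy engine minimizes the amplitude least-squares target

    sum_work (|Fo| - k |Fc|)^2

over a global scale k (closed form each cycle), a global ADP shift, and
optionally all atomic coordinates, by damped Gauss-Newton with step-halving.
It is a desk-scale stand-in for a full refinement program: no geometry
restraints, no bulk solvent, no likelihood target — but it reproduces the
overfitting/underfitting phenomenology the paired-refinement protocol
monitors.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import AtomicModel, read_pdb, write_pdb
from .reflections import MergedSet, friedel_reduce, write_merged
from .scattering import CalcSet, calc_structure_factors

__all__ = ["RefinementResult", "ToyEngine", "ExternalEngine", "get_backend"]

logger = logging.getLogger(__name__)

_MIN_B = 0.1  # floor keeping ADPs positive when a global shift is applied


@dataclass
class RefinementResult:
    """Outcome of one refinement at one resolution cutoff."""

    model: AtomicModel
    calc: CalcSet  # Fc for ALL reflections (work + free) with d >= d_cutoff
    trace: np.ndarray  # working residual per cycle, non-increasing
    scale: float
    d_cutoff: float
    n_cycles_run: int
    notes: list = field(default_factory=list)


def _closed_form_scale(fo: np.ndarray, fa: np.ndarray) -> float:
    denom = float(np.sum(fa * fa))
    if denom == 0:
        raise ValueError("all calculated amplitudes are zero; scale undefined")
    return float(np.sum(fo * fa)) / denom


def _fit_scale_bshift(fo, fa, s2_over4):
    """Jointly fit (k, dB) in |Fo| ~ k exp(-dB s^2/4) |Fc| by Gauss-Newton."""
    k = _closed_form_scale(fo, fa)
    db = 0.0
    for _ in range(50):
        atten = np.exp(-db * s2_over4)
        g = atten * fa
        k = _closed_form_scale(fo, g)
        r = fo - k * g
        # columns: d(k g)/dk = g ; d(k g)/d(db) = -k s2/4 g
        j1 = g
        j2 = -k * s2_over4 * g
        a11 = j1 @ j1
        a12 = j1 @ j2
        a22 = j2 @ j2
        b1 = j1 @ r
        b2 = j2 @ r
        det = a11 * a22 - a12 * a12
        if det <= 0 or not np.isfinite(det):
            break
        dk = (a22 * b1 - a12 * b2) / det
        ddb = (a11 * b2 - a12 * b1) / det
        k += dk
        db += ddb
        if abs(dk) < 1e-12 * (1 + abs(k)) and abs(ddb) < 1e-10:
            break
    return k, db


class ToyEngine:
    """Built-in least-squares refinement engine.

    Parameters
    ----------
    refine_coords:
        Refine atomic coordinates (Gauss-Newton) in addition to the global
        scale and ADP shift.
    """

    name = "toy"

    def __init__(self, refine_coords: bool = True):
        self.refine_coords = refine_coords

    def refine(
        self,
        model: AtomicModel,
        merged: MergedSet,
        d_cutoff: float,
        n_cycles: int = 20,
        free_set: int = 0,
        free_excluded: bool = True,
        rtol: float = 1e-8,
    ) -> RefinementResult:
        data = merged.select_resolution(d_cutoff)
        if len(data) == 0:
            raise ValueError(f"no reflections with d >= {d_cutoff}")
        hkl = friedel_reduce(data.hkl)
        fo_all = data.amplitudes()
        if free_excluded:
            work = ~data.free_mask(free_set)
        else:
            work = np.ones(len(data), dtype=bool)
        if not work.any():
            raise ValueError("empty work set: every reflection is free-flagged")
        fo = fo_all[work]
        hkl_w = hkl[work]
        d_w = data.cell.d_spacing(hkl_w)
        s2_over4 = 0.25 / d_w**2
        zocc = model.occupancy * model.z

        # Fc on the work set factorizes into a B-dependent damping term and a
        # coordinate-dependent phase term; each sub-step below changes only
        # one of them, so they are cached separately.
        def damp_of(b_iso):
            return np.exp(-np.outer(s2_over4, b_iso))

        def phase_of(frac):
            return np.exp(2j * np.pi * (hkl_w @ frac.T))

        current = model.copy()
        notes: list[str] = []
        damp = damp_of(current.b_iso)
        phase = phase_of(current.frac)
        t = damp * phase * zocc  # (nwork, natoms) per-atom contributions
        fa = np.abs(t.sum(axis=1))
        k = _closed_form_scale(fo, fa)
        trace = [float(np.sum((fo - k * fa) ** 2))]
        cycles_run = 0

        for _ in range(n_cycles):
            prev = trace[-1]
            # --- global scale + ADP shift -----------------------------------
            _, db = _fit_scale_bshift(fo, fa, s2_over4)
            db = max(db, _MIN_B - float(current.b_iso.min()))
            if db != 0.0:
                b_cand = current.b_iso + db
                damp_cand = damp_of(b_cand)
                t_cand = damp_cand * phase * zocc
                fa_cand = np.abs(t_cand.sum(axis=1))
                k_cand = _closed_form_scale(fo, fa_cand)
                res_cand = float(np.sum((fo - k_cand * fa_cand) ** 2))
                if res_cand <= prev:
                    current.b_iso = b_cand
                    damp, t, fa, k = damp_cand, t_cand, fa_cand, k_cand
            # --- coordinate Gauss-Newton step -------------------------------
            if self.refine_coords and len(current) > 0:
                step = self._coordinate_step(t, hkl_w, fo, k, notes)
                if step is not None:
                    best = float(np.sum((fo - k * fa) ** 2))
                    scale_frac = 1.0
                    for _half in range(8):
                        frac_cand = current.frac + scale_frac * step
                        phase_cand = phase_of(frac_cand)
                        t_cand = damp * phase_cand * zocc
                        fa_cand = np.abs(t_cand.sum(axis=1))
                        k_cand = _closed_form_scale(fo, fa_cand)
                        res_cand = float(np.sum((fo - k_cand * fa_cand) ** 2))
                        if res_cand <= best:
                            current.frac = frac_cand
                            phase, t, fa, k = phase_cand, t_cand, fa_cand, k_cand
                            break
                        scale_frac *= 0.5
            resid = float(np.sum((fo - k * fa) ** 2))
            trace.append(min(resid, prev))
            cycles_run += 1
            if prev - resid < rtol * (1.0 + prev):
                break

        calc = calc_structure_factors(current, hkl)
        return RefinementResult(
            model=current,
            calc=calc,
            trace=np.asarray(trace),
            scale=k,
            d_cutoff=d_cutoff,
            n_cycles_run=cycles_run,
            notes=notes,
        )

    @staticmethod
    def _coordinate_step(t, hkl_w, fo, k, notes):
        """Gauss-Newton step for all fractional coordinates, or None.

        ``t`` holds the per-atom complex contributions to Fc on the work set.
        """
        f = t.sum(axis=1)
        fa = np.abs(f)
        unit = np.where(fa > 1e-12, np.conj(f) / np.maximum(fa, 1e-12), 1.0)
        # d|F|/dx_{j,alpha} = h_alpha * v_{h,j},  v = -2 pi Im(unit * t)
        v = -2.0 * np.pi * np.imag(unit[:, None] * t)
        natoms = t.shape[1]
        n_par = 3 * natoms
        g = np.empty((len(hkl_w), n_par))
        for alpha in range(3):
            g[:, alpha::3] = k * hkl_w[:, alpha : alpha + 1] * v
        r = fo - k * fa
        try:
            gtg = g.T @ g
            gtg[np.diag_indices_from(gtg)] += 1e-10 * np.trace(gtg) / n_par
            delta = np.linalg.solve(gtg, g.T @ r)
        except np.linalg.LinAlgError:
            notes.append("singular normal matrix: coordinate step skipped")
            logger.warning("singular normal matrix; falling back to scale/ADP-only cycle")
            return None
        return delta.reshape(natoms, 3)


_PLACEHOLDERS = ("model_in", "hkl_in", "d_cutoff", "model_out", "fc_out")


class ExternalEngine:
    """Adapter running a user-supplied refinement command.

    The command template must contain the placeholders ``{model_in}``,
    ``{hkl_in}``, ``{d_cutoff}``, ``{model_out}`` and ``{fc_out}``.  The
    external program is expected to write a refined PDB to ``model_out``
    and calculated structure factors to ``fc_out`` as text lines
    ``h k l amplitude phase_deg``.
    """

    name = "external"

    def __init__(self, template: str):
        for ph in _PLACEHOLDERS:
            if "{%s}" % ph not in template:
                raise ValueError(f"command template lacks the {{{ph}}} placeholder")
        try:
            template.format(**{ph: "x" for ph in _PLACEHOLDERS})
        except (KeyError, IndexError) as exc:
            raise ValueError(f"command template has unfilled placeholder: {exc}") from None
        self.template = template

    def refine(
        self,
        model: AtomicModel,
        merged: MergedSet,
        d_cutoff: float,
        n_cycles: int = 20,
        free_set: int = 0,
        free_excluded: bool = True,
        workdir=None,
    ) -> RefinementResult:
        wd = Path(workdir) if workdir is not None else Path.cwd()
        wd.mkdir(parents=True, exist_ok=True)
        model_in = wd / "ext_model_in.pdb"
        hkl_in = wd / "ext_hkl_in.hkl"
        model_out = wd / "ext_model_out.pdb"
        fc_out = wd / "ext_fc_out.txt"
        log_path = wd / "ext_refine.log"
        write_pdb(model, model_in)
        write_merged(merged.select_resolution(d_cutoff), hkl_in)
        cmd = self.template.format(
            model_in=model_in,
            hkl_in=hkl_in,
            d_cutoff=d_cutoff,
            model_out=model_out,
            fc_out=fc_out,
        )
        proc = subprocess.run(
            shlex.split(cmd), capture_output=True, text=True
        )
        log_path.write_text(proc.stdout + "\n" + proc.stderr)
        if proc.returncode != 0:
            raise RuntimeError(
                f"external refinement failed (exit {proc.returncode}); log: {log_path}"
            )
        if not model_out.exists() or not fc_out.exists():
            raise RuntimeError(
                f"external refinement produced no output files; log: {log_path}"
            )
        refined = read_pdb(model_out)
        rows = []
        for line in fc_out.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p = line.split()
            rows.append((int(p[0]), int(p[1]), int(p[2]), float(p[3]), float(p[4])))
        if not rows:
            raise RuntimeError(f"external Fc file {fc_out} is empty")
        arr = np.array(rows)
        f = arr[:, 3] * np.exp(1j * np.radians(arr[:, 4]))
        calc = CalcSet(refined.cell, arr[:, :3].astype(int), f)
        data = merged.select_resolution(d_cutoff)
        work = ~data.free_mask(free_set) if free_excluded else np.ones(len(data), bool)
        fo = data.amplitudes()[work]
        fa = np.abs(calc.match(data.hkl[work]))
        k = _closed_form_scale(fo, fa)
        resid = float(np.sum((fo - k * fa) ** 2))
        return RefinementResult(
            model=refined,
            calc=calc,
            trace=np.array([resid]),
            scale=k,
            d_cutoff=d_cutoff,
            n_cycles_run=n_cycles,
            notes=[f"external backend; log: {log_path}"],
        )


def get_backend(name: str, template: str | None = None, **kwargs):
    """Backend factory used by the CLI: 'toy' or 'external'."""
    if name == "toy":
        return ToyEngine(**kwargs)
    if name == "external":
        if not template:
            raise ValueError("the external backend needs a command template")
        return ExternalEngine(template)
    raise ValueError(f"unknown backend {name!r}")
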