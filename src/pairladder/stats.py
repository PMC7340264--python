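"""Model-vs-data agreement statistics.

Rwork and Rfree are amplitude residuals on the working and held-out (free)
reflections; their difference Rgap = Rfree - Rwork measures overfitting.
CCwork/CCfree are Pearson correlations between experimental and calculated
*intensities* (squared scaled amplitudes).  A single overall least-squares
scale, fitted on the work set only, is applied throughout; per-shell
scaling would absorb exactly the signal paired refinement monitors.

A perfect model scored against pure-noise data gives an R value of about
0.42 (under the intensity-truncation conventions of standard data
reduction); any shell whose Rwork exceeds that level is flagged in the
report as carrying data "worse than noise" for the current model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reflections import MergedSet, ShellScheme, friedel_reduce
from .refine import RefinementResult
from .scattering import CalcSet

__all__ = [
    "AgreementReport",
    "ls_scale",
    "r_value",
    "agreement",
    "paired_r",
    "RANDOM_DATA_R",
]

RANDOM_DATA_R = 0.42  # report flag level: R of a perfect model vs random data


def ls_scale(obs_amplitudes, calc_amplitudes) -> float:
    """Least-squares amplitude scale k = sum|Fo||Fc| / sum|Fc|^2."""
    fo = np.asarray(obs_amplitudes, dtype=float)
    fc = np.asarray(calc_amplitudes, dtype=float)
    if fo.size == 0 or fo.shape != fc.shape:
        raise ValueError("need equal-length nonempty amplitude arrays")
    denom = float(np.sum(fc * fc))
    if denom == 0:
        raise ValueError("all calculated amplitudes are zero")
    return float(np.sum(fo * fc)) / denom


def r_value(obs_amplitudes, calc_amplitudes, k: float) -> float:
    """R = sum| |Fo| - k|Fc| | / sum|Fo|."""
    fo = np.asarray(obs_amplitudes, dtype=float)
    fc = np.asarray(calc_amplitudes, dtype=float)
    if fo.size == 0 or fo.shape != fc.shape:
        raise ValueError("need equal-length nonempty amplitude arrays")
    denom = float(np.sum(fo))
    if denom == 0:
        raise ValueError("sum of observed amplitudes is zero")
    return float(np.sum(np.abs(fo - k * fc))) / denom


def _pearson(x, y):
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class AgreementReport:
    """Agreement of one model with one merged data set at one cutoff."""

    d_cutoff: float
    free_set: int
    scale: float
    r_work: float
    r_free: float  # NaN when the free set is empty
    cc_work: float
    cc_free: float
    n_work: int
    n_free: int
    shells: pd.DataFrame  # per-shell rows, fixed column order
    r_flag_threshold: float = RANDOM_DATA_R

    @property
    def r_gap(self) -> float:
        return self.r_free - self.r_work

    def to_csv(self, path) -> None:
        df = self.shells.copy()
        overall = {
            "d_high": self.shells["d_high"].iloc[0] if len(self.shells) else np.nan,
            "d_low": self.d_cutoff,
            "n_work": self.n_work,
            "n_free": self.n_free,
            "r_work": self.r_work,
            "r_free": self.r_free,
            "r_gap": self.r_gap,
            "cc_work": self.cc_work,
            "cc_free": self.cc_free,
            "flag_worse_than_noise": bool(self.r_work > self.r_flag_threshold),
        }
        df = pd.concat([df, pd.DataFrame([overall], index=["overall"])])
        df.to_csv(path, float_format="%.10g")


SHELL_COLUMNS = [
    "d_high",
    "d_low",
    "n_work",
    "n_free",
    "r_work",
    "r_free",
    "r_gap",
    "cc_work",
    "cc_free",
    "flag_worse_than_noise",
]


def agreement(
    merged: MergedSet,
    calc: CalcSet,
    shells: ShellScheme,
    free_set: int = 0,
    r_flag_threshold: float = RANDOM_DATA_R,
) -> AgreementReport:
    """Score a model's calculated structure factors against merged data.

    The data are truncated to the shell scheme's d_min; ``calc`` must cover
    every surviving index (a missing index raises ``KeyError`` naming it).
    Shells with fewer than three reflections in a set carry NaN
    correlations; an empty free set gives NaN r_free/r_gap.
    """
    data = merged.select_resolution(shells.d_min)
    if len(data) == 0:
        raise ValueError("no reflections at this cutoff")
    fc = np.abs(calc.match(data.hkl))
    fo = data.amplitudes()
    free = data.free_mask(free_set)
    work = ~free
    if not work.any():
        raise ValueError("empty work set")
    k = ls_scale(fo[work], fc[work])

    io = fo**2
    ic = (k * fc) ** 2

    r_work = r_value(fo[work], fc[work], k)
    r_free = r_value(fo[free], fc[free], k) if free.any() else np.nan
    cc_work = _pearson(io[work], ic[work])
    cc_free = _pearson(io[free], ic[free]) if free.any() else np.nan

    shell_ix = shells.assign(data.d_spacings())
    rows = []
    for i in range(shells.n_shells):
        sel = shell_ix == i
        w = sel & work
        f = sel & free
        rw = r_value(fo[w], fc[w], k) if w.any() and fo[w].sum() > 0 else np.nan
        rf = r_value(fo[f], fc[f], k) if f.any() and fo[f].sum() > 0 else np.nan
        rows.append(
            {
                "d_high": shells.bounds(i)[0],
                "d_low": shells.bounds(i)[1],
                "n_work": int(w.sum()),
                "n_free": int(f.sum()),
                "r_work": rw,
                "r_free": rf,
                "r_gap": rf - rw,
                "cc_work": _pearson(io[w], ic[w]) if w.sum() >= 3 else np.nan,
                "cc_free": _pearson(io[f], ic[f]) if f.sum() >= 3 else np.nan,
                "flag_worse_than_noise": bool(rw > r_flag_threshold)
                if not np.isnan(rw)
                else False,
            }
        )
    shell_df = pd.DataFrame(rows, columns=SHELL_COLUMNS)
    shell_df.index = [f"shell_{i}" for i in range(shells.n_shells)]
    return AgreementReport(
        d_cutoff=shells.d_min,
        free_set=free_set,
        scale=k,
        r_work=r_work,
        r_free=r_free,
        cc_work=cc_work,
        cc_free=cc_free,
        n_work=int(work.sum()),
        n_free=int(free.sum()),
        shells=shell_df,
        r_flag_threshold=r_flag_threshold,
    )


def _r_pair_at(result: RefinementResult, merged: MergedSet, d_compare: float, free_set: int):
    """(r_work, r_free) of one refined model against data truncated at d_compare.

    Uses the model's own work-set least-squares scale recomputed on the
    truncated data.
    """
    data = merged.select_resolution(d_compare)
    if len(data) == 0:
        raise ValueError(f"no reflections with d >= {d_compare}")
    if result.d_cutoff > d_compare + 1e-9:
        raise ValueError(
            f"calculated structure factors cover d >= {result.d_cutoff:.3f}, "
            f"insufficient for comparison at {d_compare}"
        )
    fc = np.abs(result.calc.match(data.hkl))
    fo = data.amplitudes()
    free = data.free_mask(free_set)
    work = ~free
    k = ls_scale(fo[work], fc[work])
    rw = r_value(fo[work], fc[work], k)
    rf = r_value(fo[free], fc[free], k) if free.any() else np.nan
    return rw, rf


def paired_r(
    result_low: RefinementResult,
    result_high: RefinementResult,
    merged: MergedSet,
    d_compare: float,
    free_set: int = 0,
) -> tuple[float, float]:
    """Paired model-vs-model comparison at matched resolution.

    Both models are scored against the SAME data truncated at ``d_compare``
    (the lower-resolution cutoff of the pair), each with its own work-set
    scale.  Returns (dR_work, dR_free) = R(high-res model) - R(low-res
    model); negative values mean the added shells improved the model.
    """
    rw_lo, rf_lo = _r_pair_at(result_low, merged, d_compare, free_set)
    rw_hi, rf_hi = _r_pair_at(result_high, merged, d_compare, free_set)
    return rw_hi - rw_lo, rf_hi - rf_lo
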