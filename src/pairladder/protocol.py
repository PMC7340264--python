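"""The paired-refinement ladder and complete cross-validation.

The ladder takes a model previously refined at a starting resolution A and
a sequence of higher-resolution cutoffs A > d1 > d2 > ...  For each
consecutive pair (X, Y) the model is refined against the data to Y and the
resulting model is compared with the X-model — both scored against the
same data truncated at X, so the comparison is valid (R values at
different cutoffs are not comparable).  A drop in Rfree means the added
shell improved the model; a flat Rfree with rising Rwork is usually still
acceptable; a rise in Rfree means the shell hurt.  The tool reports these
statistics and annotations; it never decides or truncates data itself.

Complete cross-validation repeats the whole ladder once per free-reflection
set.  Before each run the model is modified (coordinate perturbation, ADP
reset/shift) to erase the memory of the refinement that used the previous
free set, then re-refined at A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import AtomicModel, perturb_coordinates, reset_adp, shift_adp
from .reflections import MergedSet, ShellScheme, UnmergedSet, make_shells
from .merging import cc_star, merging_table
from .refine import RefinementResult
from .stats import RANDOM_DATA_R, agreement, paired_r

__all__ = [
    "LadderStep",
    "LadderResult",
    "CrossValResult",
    "ModelModifications",
    "run_ladder",
    "run_complete_cv",
    "aggregate_deltas",
    "annotate_step",
]

# Annotation texts for the interpretation rule (reported, never acted on).
ANNOT_IMPROVED = "Rfree decreased: the added shell is beneficial to model quality"
ANNOT_ACCEPTABLE = (
    "Rfree roughly constant while Rwork increased: usually acceptable"
)
ANNOT_WORSE = "Rfree increased: the added shell did not improve the model"
ANNOT_NEUTRAL = "no significant change in R values"


def annotate_step(d_rwork: float, d_rfree: float, tol: float = 5e-4) -> str:
    """Map a paired (dRwork, dRfree) outcome to the interpretation rule."""
    if d_rfree < -tol:
        return ANNOT_IMPROVED
    if d_rfree > tol:
        return ANNOT_WORSE
    if d_rwork > tol:
        return ANNOT_ACCEPTABLE
    return ANNOT_NEUTRAL


@dataclass
class LadderStep:
    """One paired-refinement step X -> Y (X > Y, in Angstrom)."""

    cutoff_from: float  # X
    cutoff_to: float  # Y
    d_rwork: float  # R(Y-model) - R(X-model), both at X
    d_rfree: float
    r_work_at_start: float  # Y-model scored at the starting resolution A
    r_free_at_start: float
    r_gap_at_start: float
    shells: pd.DataFrame  # per-shell cc_work / cc_free / (cc_star) at Y
    annotation: str
    scale: float
    n_cycles_run: int


@dataclass
class LadderResult:
    start_resolution: float
    free_set: int
    steps: list[LadderStep]
    results: list[RefinementResult]  # index 0 = refinement at A
    cutoffs: list[float]
    merging: pd.DataFrame | None = None

    def steps_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cutoff_from": s.cutoff_from,
                "cutoff_to": s.cutoff_to,
                "d_rwork": s.d_rwork,
                "d_rfree": s.d_rfree,
                "r_work_at_start": s.r_work_at_start,
                "r_free_at_start": s.r_free_at_start,
                "r_gap_at_start": s.r_gap_at_start,
                "annotation": s.annotation,
            }
            for s in self.steps
        ]
        return pd.DataFrame(rows)


def _check_cutoffs(cutoffs):
    c = [float(x) for x in cutoffs]
    if len(c) < 2:
        raise ValueError("need a starting resolution and at least one higher cutoff")
    diffs = np.diff(c)
    if np.any(diffs == 0):
        raise ValueError("zero-length ladder step: two equal cutoffs")
    if np.any(diffs > 0):
        raise ValueError("cutoffs must be strictly decreasing (increasing resolution)")
    return c


def run_ladder(
    model_start: AtomicModel,
    merged: MergedSet,
    cutoffs,
    backend,
    unmerged: UnmergedSet | None = None,
    free_set: int = 0,
    n_cycles: int = 20,
    shell_width: float = 0.05,
    cumulative: bool = True,
    merging_seed: int = 0,
) -> LadderResult:
    """Run the paired-refinement ladder.

    ``cutoffs`` starts at the resolution A the input model was refined at
    and descends.  Each step refines at the next cutoff Y (from the
    previous step's model when ``cumulative``, else from the starting
    model), compares with the previous model at X, and scores the Y-model
    at A for the Rgap curve.  Per-shell CC* columns are attached when
    unmerged data are supplied.  No decision is made: the ladder reports.
    """
    cuts = _check_cutoffs(cutoffs)
    a = cuts[0]
    data_a = merged.select_resolution(a)
    if len(data_a) == 0:
        raise ValueError(f"merged data contain no reflections with d >= {a}")

    merging = None
    cc_star_lookup = None
    if unmerged is not None:
        mshells = make_shells(
            max(a, float(np.max(unmerged.d_spacings()))) + 1e-9,
            cuts[-1],
            width=shell_width,
        )
        merging = merging_table(unmerged, mshells, seed=merging_seed)
        cc_star_lookup = mshells, merging

    results = [
        backend.refine(model_start, merged, a, n_cycles=n_cycles, free_set=free_set)
    ]
    steps: list[LadderStep] = []
    for x, y in zip(cuts[:-1], cuts[1:]):
        start_model = results[-1].model if cumulative else results[0].model
        try:
            res_y = backend.refine(
                start_model, merged, y, n_cycles=n_cycles, free_set=free_set
            )
        except Exception as exc:
            raise RuntimeError(f"backend failed at ladder step {x} -> {y}: {exc}") from exc
        drw, drf = paired_r(results[-1], res_y, merged, x, free_set=free_set)
        rep_a = agreement(
            merged, res_y.calc, make_shells(_d_top(merged, a), a, width=shell_width),
            free_set=free_set,
        )
        shells_y = make_shells(_d_top(merged, a), y, width=shell_width)
        rep_y = agreement(merged, res_y.calc, shells_y, free_set=free_set)
        shell_df = rep_y.shells[
            ["d_high", "d_low", "n_work", "n_free", "cc_work", "cc_free",
             "r_work", "flag_worse_than_noise"]
        ].copy()
        if cc_star_lookup is not None:
            mshells, mtable = cc_star_lookup
            ccs = []
            for _, row in shell_df.iterrows():
                mid = 0.5 * (row["d_high"] + row["d_low"])
                ix = int(mshells.assign(np.array([mid]))[0])
                cch = mtable["cc_half"].iloc[ix] if ix >= 0 else np.nan
                ccs.append(cc_star(cch) if not np.isnan(cch) else np.nan)
            shell_df["cc_star"] = ccs
        steps.append(
            LadderStep(
                cutoff_from=x,
                cutoff_to=y,
                d_rwork=drw,
                d_rfree=drf,
                r_work_at_start=rep_a.r_work,
                r_free_at_start=rep_a.r_free,
                r_gap_at_start=rep_a.r_gap,
                shells=shell_df,
                annotation=annotate_step(drw, drf),
                scale=res_y.scale,
                n_cycles_run=res_y.n_cycles_run,
            )
        )
        results.append(res_y)
    return LadderResult(
        start_resolution=a,
        free_set=free_set,
        steps=steps,
        results=results,
        cutoffs=cuts,
        merging=merging,
    )


def _d_top(merged: MergedSet, a: float) -> float:
    """Low-resolution end of the shell scheme: just above the data's largest d."""
    return float(max(a, merged.d_spacings().max())) + 1e-9


@dataclass
class ModelModifications:
    """Pre-refinement model modifications applied per free set in complete CV."""

    perturb_delta: float = 0.25  # Angstrom; 0 disables
    adp_mode: str | None = "mean"  # 'mean', 'value', 'shift' or None
    adp_value: float | None = None
    adp_shift: float = 0.0

    def apply(self, model: AtomicModel, seed: int) -> AtomicModel:
        out = model
        if self.perturb_delta > 0:
            out = perturb_coordinates(out, self.perturb_delta, seed=seed)
        if self.adp_mode == "mean":
            out = reset_adp(out, "mean")
        elif self.adp_mode == "value":
            out = reset_adp(out, "value", self.adp_value)
        elif self.adp_mode == "shift":
            out = shift_adp(out, self.adp_shift)
        elif self.adp_mode is not None:
            raise ValueError(f"unknown ADP modification {self.adp_mode!r}")
        return out


@dataclass
class CrossValResult:
    """Aggregated k-fold (complete) cross-validation over free sets."""

    ladders: list[LadderResult]  # one per free set q = 0..k-1
    summary: pd.DataFrame  # per-step mean/sd/sem and rise/fall counts

    @property
    def k(self) -> int:
        return len(self.ladders)


def aggregate_deltas(per_set_values: np.ndarray) -> pd.DataFrame:
    """Aggregate per-free-set per-step delta values (k x n_steps).

    Returns mean, sample standard deviation (ddof=1), standard error of the
    mean SEM = SD/sqrt(k), and counts of rises (> 0) and falls (< 0) per
    step.
    """
    v = np.asarray(per_set_values, dtype=float)
    if v.ndim != 2:
        raise ValueError("expected a (k, n_steps) array")
    k = v.shape[0]
    sd = v.std(axis=0, ddof=1) if k > 1 else np.full(v.shape[1], np.nan)
    return pd.DataFrame(
        {
            "mean": v.mean(axis=0),
            "sd": sd,
            "sem": sd / np.sqrt(k),
            "n_rise": (v > 0).sum(axis=0),
            "n_fall": (v < 0).sum(axis=0),
        }
    )


def _child_seed(master_seed: int, q: int) -> int:
    """Deterministic per-free-set seed: documented spawn rule."""
    ss = np.random.SeedSequence([int(master_seed), int(q)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_complete_cv(
    model_start: AtomicModel,
    merged: MergedSet,
    cutoffs,
    backend,
    modifications: ModelModifications | None = None,
    unmerged: UnmergedSet | None = None,
    n_cycles: int = 20,
    shell_width: float = 0.05,
    cumulative: bool = True,
    master_seed: int = 0,
) -> CrossValResult:
    """Run the ladder once per free-reflection set and aggregate.

    Requires CCP4-style multi-set flags (flag_count >= 2).  For each free
    set q the model modifications are applied with a per-q derived seed,
    the model is re-refined at the starting resolution inside the ladder,
    and the full ladder is run with q as the test set.
    """
    if merged.flag_count < 2:
        raise ValueError(
            "complete cross-validation needs CCP4-style multi-set free flags "
            f"(flag_count >= 2, got {merged.flag_count}); multiple free "
            "reflection labels must be present in the data"
        )
    mods = modifications or ModelModifications()
    ladders = []
    for q in range(merged.flag_count):
        seed_q = _child_seed(master_seed, q)
        model_q = mods.apply(model_start, seed_q)
        ladders.append(
            run_ladder(
                model_q,
                merged,
                cutoffs,
                backend,
                unmerged=unmerged,
                free_set=q,
                n_cycles=n_cycles,
                shell_width=shell_width,
                cumulative=cumulative,
                merging_seed=seed_q,
            )
        )
    n_steps = len(ladders[0].steps)
    drw = np.array([[s.d_rwork for s in lad.steps] for lad in ladders])
    drf = np.array([[s.d_rfree for s in lad.steps] for lad in ladders])
    rgap = np.array([[s.r_gap_at_start for s in lad.steps] for lad in ladders])
    agg_w = aggregate_deltas(drw)
    agg_f = aggregate_deltas(drf)
    agg_g = aggregate_deltas(rgap)
    summary = pd.DataFrame(
        {
            "cutoff_from": [s.cutoff_from for s in ladders[0].steps],
            "cutoff_to": [s.cutoff_to for s in ladders[0].steps],
            "d_rwork_mean": agg_w["mean"],
            "d_rwork_sd": agg_w["sd"],
            "d_rwork_sem": agg_w["sem"],
            "d_rfree_mean": agg_f["mean"],
            "d_rfree_sd": agg_f["sd"],
            "d_rfree_sem": agg_f["sem"],
            "d_rfree_n_rise": agg_f["n_rise"],
            "d_rfree_n_fall": agg_f["n_fall"],
            "r_gap_mean": agg_g["mean"],
            "r_gap_sd": agg_g["sd"],
            "r_gap_sem": agg_g["sem"],
        }
    )
    return CrossValResult(ladders=ladders, summary=summary)
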