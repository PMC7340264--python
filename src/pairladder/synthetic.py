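"""Synthetic ground-truth models and diffraction data with a planted limit.

The generator builds a known "true" structure in a P1 cell, computes exact
intensities from it, and emits unmerged observations with a controllable
noise model and an *information limit* d_info: beyond it the recorded
intensities are pure noise drawn from the shell's intensity scale, carrying
no signal.  Recovering that planted limit is the headline test of the
paired-refinement protocol — and having the truth in hand lets tests
monitor the convergence of refined models toward it (coordinate and ADP
RMSD), which is impossible with real data.

Simulation is at the intensity level: detector images, partiality and
radiation damage are out of scope because the protocol only ever consumes
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .merging import merge_intensities
from .model import AtomicModel, perturb_coordinates, reset_adp
from .reflections import (
    MergedSet,
    UnitCell,
    UnmergedSet,
    enumerate_unique_indices,
    make_shells,
)
from .scattering import calc_structure_factors

__all__ = ["GeneratorConfig", "generate_truth", "generate_data", "degrade_model"]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic-data experiments.

    Defaults define a desk-scale Wilson-like crystal: 60 carbon point atoms
    in a 15 x 16 x 17 A P1 cell, data to 1.2 A with signal dying at the
    planted d_info = 1.5 A, fourfold multiplicity, 5% relative noise plus
    5% of the shell-mean intensity as an additive sigma floor, and 20
    CCP4-style free-flag sets (each holding 1/20 = 5% of reflections).
    The cell/atom-count pairing puts refinement in the data-limited regime
    of real crystallographic practice (parameters / work reflections of
    roughly 0.1): in a strongly overdetermined fit the per-shell dRfree
    signal paired refinement monitors would vanish below free-set sampling
    noise, which is a property of the regime, not of the protocol.
    """

    cell: UnitCell = field(default_factory=lambda: UnitCell(15.0, 16.0, 17.0))
    n_atoms: int = 60
    b_range: tuple[float, float] = (10.0, 20.0)
    d_min: float = 1.2  # generation limit of the data
    multiplicity: int = 4
    noise_rel: float = 0.05  # a: sigma contribution proportional to |signal|
    noise_shell: float = 0.05  # b: sigma contribution from the shell mean intensity
    d_info: float = 1.5  # planted information limit
    transition: float = 0.05  # width (A) of the signal -> noise crossover
    flag_sets: int = 20  # CCP4-style free-flag labels 0..k-1
    perturb_delta: float = 0.25  # degrade_model coordinate perturbation (A)
    adp_reset: str | None = "mean"  # degrade_model ADP recipe
    adp_value: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.d_info < self.d_min:
            raise ValueError("d_info must be >= d_min")
        if self.flag_sets < 1 or self.multiplicity < 1:
            raise ValueError("flag_sets and multiplicity must be >= 1")


def generate_truth(config: GeneratorConfig, seed: int | None = None) -> AtomicModel:
    """Random carbon-like truth model: uniform positions, B uniform in range."""
    if config.n_atoms <= 0:
        raise ValueError("n_atoms must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frac = rng.uniform(0.0, 1.0, size=(config.n_atoms, 3))
    b = rng.uniform(*config.b_range, size=config.n_atoms)
    return AtomicModel(
        cell=config.cell,
        elements=["C"] * config.n_atoms,
        z=np.full(config.n_atoms, 6.0),
        frac=frac,
        occupancy=np.ones(config.n_atoms),
        b_iso=b,
        label="truth",
    )


def _signal_weight(d: np.ndarray, d_info: float, width: float) -> np.ndarray:
    """Smooth cosine taper: 1 for d >= d_info, 0 beyond d_info - width."""
    if width <= 0:
        return (d >= d_info).astype(float)
    t = np.clip((d_info - d) / width, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def generate_data(
    truth: AtomicModel, config: GeneratorConfig, seed: int | None = None
) -> tuple[MergedSet, UnmergedSet]:
    """Simulate unmerged observations and the merged set derived from them.

    Per Friedel-unique index with d >= d_min, ``multiplicity`` observations

        I_obs = w(d) Itrue + (1 - w(d)) J + eps

    with w the planted-limit taper, J an exponential noise intensity with
    the shell's mean true intensity as scale (drawn independently per
    observation, so half-datasets decorrelate beyond the limit), and eps
    Gaussian with sigma = a |signal| + b <Itrue>_shell.  The merged set
    carries amplitudes |Fo| = sqrt(max(<I>, 0)) and uniform free flags over
    ``flag_sets`` labels.  Noise-free limit (a = b = 0, w = 1, m = 1):
    merged amplitudes equal |Fc| of the truth exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    hkl = enumerate_unique_indices(truth.cell, config.d_min)
    d = truth.cell.d_spacing(hkl)
    i_true = calc_structure_factors(truth, hkl).amplitudes() ** 2
    w = _signal_weight(d, config.d_info, config.transition)

    # shell-mean true intensity, for noise scaling
    shells = make_shells(float(d.max()) + 1e-9, config.d_min, width=0.1)
    ix = shells.assign(d)
    mean_shell = np.empty(shells.n_shells)
    for i in range(shells.n_shells):
        sel = ix == i
        mean_shell[i] = i_true[sel].mean() if sel.any() else i_true.mean()
    i_scale = mean_shell[ix]

    m = config.multiplicity
    n = len(hkl)
    obs_hkl = np.repeat(hkl, m, axis=0)
    w_r = np.repeat(w, m)
    itrue_r = np.repeat(i_true, m)
    iscale_r = np.repeat(i_scale, m)

    j_noise = rng.exponential(scale=1.0, size=n * m) * iscale_r
    signal = w_r * itrue_r + (1.0 - w_r) * j_noise
    sigma_true = config.noise_rel * np.abs(signal) + config.noise_shell * iscale_r
    i_obs = signal + rng.normal(0.0, 1.0, size=n * m) * sigma_true
    # the stored sigma column must be positive even in the noise-free limit
    sigma = np.maximum(sigma_true, 1e-6)

    unmerged = UnmergedSet(truth.cell, obs_hkl, i_obs, sigma, label="synthetic")

    merged_i = merge_intensities(unmerged)
    amp = np.sqrt(np.maximum(merged_i.i_mean, 0.0))
    # amplitude sigma by first-order propagation, floored for weak data
    sig_f = merged_i.sigma / np.maximum(2.0 * amp, 1e-3)
    flags = rng.integers(0, config.flag_sets, size=len(merged_i.hkl))
    merged = MergedSet(
        truth.cell,
        merged_i.hkl,
        amp,
        np.maximum(sig_f, 1e-6),
        flags,
        kind="F",
        flag_count=config.flag_sets,
    )
    return merged, unmerged


def degrade_model(
    truth: AtomicModel, config: GeneratorConfig, seed: int | None = None
) -> AtomicModel:
    """Standard starting model: perturb coordinates, then reset ADPs.

    With the default recipe (mean shift 0.25 A, ADP reset to the mean) this
    mirrors how input models for the protocol are prepared from a refined
    structure.
    """
    s = config.seed if seed is None else seed
    out = perturb_coordinates(truth, config.perturb_delta, seed=s)
    if config.adp_reset == "mean":
        out = reset_adp(out, "mean")
    elif config.adp_reset == "value":
        out = reset_adp(out, "value", config.adp_value)
    elif config.adp_reset is not None:
        raise ValueError(f"unknown ADP reset mode {config.adp_reset!r}")
    out.label = "degraded"
    return out
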