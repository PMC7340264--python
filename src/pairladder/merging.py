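"""Data-quality statistics on unmerged intensities.

Per resolution shell and overall: multiplicity, completeness, <I/sigma>,
the agreement residuals Rmerge / Rmeas / Rpim, the half-dataset correlation
CC1/2 with its significance test, and CC* — the model-independent estimate
of the correlation between the merged data and the (unknown) true signal,

    CC* = sqrt(2 CC1/2 / (1 + CC1/2)).

Uniques observed only once cannot contribute to the R metrics or CC1/2
(the multiplicity-correction factors are undefined at n = 1) but do count
toward completeness and multiplicity.  Missing statistics are carried as
NaN, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reflections import (
    MergedSet,
    ShellScheme,
    UnmergedSet,
    enumerate_unique_indices,
    friedel_reduce,
)

__all__ = [
    "MergedIntensities",
    "merge_intensities",
    "r_metrics",
    "cc_half",
    "cc_significance",
    "cc_star",
    "completeness",
    "merging_table",
    "MERGING_COLUMNS",
]


@dataclass
class MergedIntensities:
    """Per-unique merged intensities: unweighted mean, pooled sigma, multiplicity."""

    hkl: np.ndarray  # (u, 3) canonical
    i_mean: np.ndarray
    sigma: np.ndarray  # sqrt(sum sigma_i^2) / n
    n_obs: np.ndarray

    def __len__(self) -> int:
        return len(self.i_mean)


def _group(uset: UnmergedSet):
    """Sort observations by canonical key; return keys, group starts, counts."""
    keys = friedel_reduce(uset.hkl)
    order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))
    keys = keys[order]
    uniq, start, count = np.unique(keys, axis=0, return_index=True, return_counts=True)
    return uniq, start, count, order


def merge_intensities(uset: UnmergedSet) -> MergedIntensities:
    """Merge Friedel-equivalent observations by unweighted averaging."""
    if len(uset) == 0:
        raise ValueError("cannot merge an empty set")
    uniq, start, count, order = _group(uset)
    i_sorted = uset.intensity[order]
    s_sorted = uset.sigma[order]
    csum_i = np.concatenate([[0.0], np.cumsum(i_sorted)])
    csum_s2 = np.concatenate([[0.0], np.cumsum(s_sorted**2)])
    end = start + count
    i_mean = (csum_i[end] - csum_i[start]) / count
    sigma = np.sqrt(csum_s2[end] - csum_s2[start]) / count
    return MergedIntensities(uniq, i_mean, sigma, count)


def _shell_of_uniques(cell, uniq_hkl, shells: ShellScheme) -> np.ndarray:
    return shells.assign(cell.d_spacing(uniq_hkl))


def _r_sums(i_sorted, start, count):
    """Per-unique |I_i - <I>| deviation sums and intensity sums (n >= 2 only)."""
    n = count
    csum = np.concatenate([[0.0], np.cumsum(i_sorted)])
    end = start + n
    mean = (csum[end] - csum[start]) / n
    dev = np.zeros(len(n))
    isum = csum[end] - csum[start]
    # per-group absolute deviation sums (groups are small; loop over groups
    # only where n >= 2)
    for gi in np.nonzero(n >= 2)[0]:
        seg = i_sorted[start[gi] : end[gi]]
        dev[gi] = np.abs(seg - mean[gi]).sum()
    return mean, dev, isum


def r_metrics(uset: UnmergedSet, shells: ShellScheme) -> pd.DataFrame:
    """Rmerge, Rmeas and Rpim per shell plus a pooled overall row.

    Rmerge = sum_h sum_i |I_i - <I>| / sum_h sum_i I_i over uniques with
    n >= 2; Rmeas multiplies each unique's deviation sum by sqrt(n/(n-1));
    Rpim by sqrt(1/(n-1)).  Shells without any multiply-observed unique get
    NaN.
    """
    uniq, start, count, order = _group(uset)
    i_sorted = uset.intensity[order]
    _, dev, isum = _r_sums(i_sorted, start, count)
    shell_ix = _shell_of_uniques(uset.cell, uniq, shells)
    multi = count >= 2
    fac_meas = np.where(multi, np.sqrt(count / np.maximum(count - 1, 1)), 0.0)
    fac_pim = np.where(multi, np.sqrt(1.0 / np.maximum(count - 1, 1)), 0.0)

    rows = []
    for i in list(range(shells.n_shells)) + [-2]:  # -2 = overall
        sel = multi if i == -2 else (shell_ix == i) & multi
        denom = isum[sel].sum()
        if sel.sum() == 0 or denom == 0:
            rows.append((np.nan, np.nan, np.nan))
            continue
        rows.append(
            (
                dev[sel].sum() / denom,
                (dev[sel] * fac_meas[sel]).sum() / denom,
                (dev[sel] * fac_pim[sel]).sum() / denom,
            )
        )
    return pd.DataFrame(rows, columns=["r_merge", "r_meas", "r_pim"])


def _half_split_means(i_obs, rng, parity):
    """Split one unique's observations into two half means.

    n = 2 is deterministic (first stored observation -> half A), so
    doubly-observed data have a unique, reproducible CC1/2.  Larger even n:
    random halves of n/2.  Odd n: the surplus observation goes to half A or
    B according to ``parity``, which the caller alternates across uniques.
    """
    n = len(i_obs)
    if n == 2:
        return i_obs[0], i_obs[1]
    perm = rng.permutation(n)
    n_a = n // 2 + (n % 2 if parity else 0)
    a = i_obs[perm[:n_a]]
    b = i_obs[perm[n_a:]]
    return a.mean(), b.mean()


def cc_half(uset: UnmergedSet, shells: ShellScheme, seed: int = 0) -> pd.DataFrame:
    """Half-dataset correlation CC1/2 per shell plus overall.

    Observations of each multiply-observed unique are randomly split
    (seeded) into two halves; CC1/2 is the Pearson correlation between the
    two half-mean vectors across uniques.  For multiplicity 2 the split is
    deterministic (one observation per half).  Shells with fewer than three
    contributing uniques, or zero variance in either half, give NaN.
    Returns columns cc_half and n_pairs.
    """
    rng = np.random.default_rng(seed)
    uniq, start, count, order = _group(uset)
    i_sorted = uset.intensity[order]
    shell_ix = _shell_of_uniques(uset.cell, uniq, shells)

    half_a = np.full(len(uniq), np.nan)
    half_b = np.full(len(uniq), np.nan)
    parity = False
    for gi in range(len(uniq)):
        n = count[gi]
        if n < 2:
            continue
        seg = i_sorted[start[gi] : start[gi] + n]
        if n % 2:
            half_a[gi], half_b[gi] = _half_split_means(seg, rng, parity)
            parity = not parity
        else:
            half_a[gi], half_b[gi] = _half_split_means(seg, rng, False)

    rows = []
    for i in list(range(shells.n_shells)) + [-2]:
        sel = ~np.isnan(half_a) if i == -2 else (shell_ix == i) & ~np.isnan(half_a)
        n_pairs = int(sel.sum())
        if n_pairs < 3 or half_a[sel].std() == 0 or half_b[sel].std() == 0:
            rows.append((np.nan, n_pairs))
            continue
        cc = np.corrcoef(half_a[sel], half_b[sel])[0, 1]
        rows.append((cc, n_pairs))
    return pd.DataFrame(rows, columns=["cc_half", "n_pairs"])


def cc_significance(cc: float, n_pairs: int, alpha: float = 0.001):
    """One-sided Student test of CC1/2 > 0 at level ``alpha``.

    t = cc sqrt((n-2)/(1-cc^2)) with n-2 degrees of freedom.  Returns True
    iff p < alpha; None when undefined (n < 3 or cc missing).
    """
    if n_pairs is None or n_pairs < 3 or cc is None or np.isnan(cc):
        return None
    if abs(cc) >= 1.0:
        return cc > 0
    t = cc * np.sqrt((n_pairs - 2) / (1.0 - cc * cc))
    p = sps.t.sf(t, df=n_pairs - 2)
    return bool(p < alpha)


def cc_star(cc_half_value):
    """CC* = sqrt(2 CC1/2 / (1 + CC1/2)); NaN for negative CC1/2.

    Estimates the correlation of the merged data with the true signal.
    CC1/2 <= -1 is outside the statistic's range and raises.
    """
    c = np.asarray(cc_half_value, dtype=float)
    if np.any(c[~np.isnan(c)] <= -1.0):
        raise ValueError("CC1/2 must be > -1")
    with np.errstate(invalid="ignore"):
        out = np.where(c >= 0, np.sqrt(2.0 * c / (1.0 + c)), np.nan)
    return float(out) if np.isscalar(cc_half_value) else out


def completeness(dataset, shells: ShellScheme) -> pd.DataFrame:
    """Percent of the Friedel-unique sphere observed, per shell plus overall.

    The denominator enumerates every Friedel-unique index with d in the
    shell down to the scheme's d_min (P1 sphere; symmetry beyond Friedel is
    not applied).
    """
    if isinstance(dataset, UnmergedSet):
        obs = np.unique(friedel_reduce(dataset.hkl), axis=0)
    elif isinstance(dataset, MergedSet):
        obs = friedel_reduce(dataset.hkl)
    else:
        raise TypeError("expected UnmergedSet or MergedSet")
    cell = dataset.cell
    full = enumerate_unique_indices(cell, shells.d_min)
    full_ix = shells.assign(cell.d_spacing(full))
    obs_ix = shells.assign(cell.d_spacing(obs)) if len(obs) else np.array([], dtype=int)
    rows = []
    for i in list(range(shells.n_shells)) + [-2]:
        n_full = int((full_ix >= 0).sum()) if i == -2 else int((full_ix == i).sum())
        n_obs = int((obs_ix >= 0).sum()) if i == -2 else int((obs_ix == i).sum())
        rows.append(100.0 * n_obs / n_full if n_full else np.nan)
    return pd.DataFrame({"completeness": rows})


MERGING_COLUMNS = [
    "d_high",
    "d_low",
    "n_unique",
    "n_obs",
    "multiplicity",
    "completeness",
    "mean_i_over_sigma",
    "r_merge",
    "r_meas",
    "r_pim",
    "cc_half",
    "cc_half_significant",
    "cc_star",
]


def merging_table(uset: UnmergedSet, shells: ShellScheme, seed: int = 0) -> pd.DataFrame:
    """Full merging-statistics table: one row per shell plus an overall row.

    The overall row pools all shells (d_high/d_low span the whole scheme).
    Deterministic for a given seed.  Column order is fixed
    (:data:`MERGING_COLUMNS`); undefined entries are NaN.
    """
    merged = merge_intensities(uset)
    shell_ix = shells.assign(uset.cell.d_spacing(merged.hkl))
    rmet = r_metrics(uset, shells)
    cch = cc_half(uset, shells, seed=seed)
    comp = completeness(uset, shells)

    rows = []
    for pos, i in enumerate(list(range(shells.n_shells)) + [-2]):
        if i == -2:
            d_hi, d_lo = shells.d_max, shells.d_min
            sel = shell_ix >= 0
        else:
            d_hi, d_lo = shells.bounds(i)
            sel = shell_ix == i
        n_unique = int(sel.sum())
        n_obs = int(merged.n_obs[sel].sum())
        mult = n_obs / n_unique if n_unique else np.nan
        iosig = (
            float(np.mean(merged.i_mean[sel] / merged.sigma[sel])) if n_unique else np.nan
        )
        cc = cch.cc_half.iloc[pos]
        sig = cc_significance(cc, int(cch.n_pairs.iloc[pos]))
        rows.append(
            {
                "d_high": d_hi,
                "d_low": d_lo,
                "n_unique": n_unique,
                "n_obs": n_obs,
                "multiplicity": mult,
                "completeness": comp.completeness.iloc[pos],
                "mean_i_over_sigma": iosig,
                "r_merge": rmet.r_merge.iloc[pos],
                "r_meas": rmet.r_meas.iloc[pos],
                "r_pim": rmet.r_pim.iloc[pos],
                "cc_half": cc,
                "cc_half_significant": sig,
                "cc_star": cc_star(cc) if not np.isnan(cc) else np.nan,
            }
        )
    df = pd.DataFrame(rows, columns=MERGING_COLUMNS)
    df.index = [f"shell_{i}" for i in range(shells.n_shells)] + ["overall"]
    return df
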