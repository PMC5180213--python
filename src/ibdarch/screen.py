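"""Pooled-DNA association screen.

Estimates a minor-allele frequency per pool and SNP from two-channel array
intensities, then tests each SNP for a case-control frequency difference in
each of the nine diagnosis x onset comparisons ({IBD, CD, UC} x {all,
pediatric, adult}), always against the healthy-control pools.

The per-SNP statistic is a pool-size-weighted Welch t-test on pool-level
frequency estimates (pools, not individuals, are the sampling unit of a
pooled GWAS). Failed pools (missing frequency) are dropped, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import TooFewPoolsError
from .simulate import PoolIntensities, PoolSet
from .stats import weighted_welch_test

logger = logging.getLogger(__name__)

__all__ = [
    "Comparison",
    "nine_comparisons",
    "estimate_pool_freq",
    "estimate_pool_frequencies",
    "pooled_association_test",
    "run_screen",
]


@dataclass(frozen=True)
class Comparison:
    """One case-control comparison; controls are always the HC pools."""

    label: str
    diagnoses: tuple[str, ...]
    onsets: tuple[str, ...]

    def case_pool_mask(self, pools: pd.DataFrame) -> np.ndarray:
        return (pools["diagnosis"].isin(self.diagnoses)
                & pools["onset"].isin(self.onsets)).to_numpy()

    def control_pool_mask(self, pools: pd.DataFrame) -> np.ndarray:
        return (pools["diagnosis"] == "HC").to_numpy()


def nine_comparisons() -> list[Comparison]:
    """{IBD, CD, UC} x {all, pediatric, adult} against healthy controls."""
    phenos = {"IBD": ("CD", "UC"), "CD": ("CD",), "UC": ("UC",)}
    onsets = {"all": ("pediatric", "adult"), "pediatric": ("pediatric",), "adult": ("adult",)}
    return [
        Comparison(f"{ph}:{on}", phenos[ph], onsets[on])
        for ph in ("IBD", "CD", "UC")
        for on in ("all", "pediatric", "adult")
    ]


def estimate_pool_freq(intensity_a, intensity_b, k_correction: float = 1.0):
    """Corrected allele fraction ``A / (A + k·B)``, clipped to [0, 1].

    Accepts scalars or arrays. Sites where both channels are zero have no
    signal and return NaN (logged), to be dropped downstream.
    """
    if k_correction <= 0:
        raise ValueError("k_correction must be > 0")
    a = np.asarray(intensity_a, float)
    b = np.asarray(intensity_b, float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("intensities must be non-negative")
    denom = a + k_correction * b
    dead = denom == 0
    if np.any(dead):
        logger.warning("%d pool/site cells with zero total intensity set to missing",
                       int(np.sum(dead)))
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(dead, np.nan, a / np.where(dead, np.nan, denom))
    f = np.clip(f, 0.0, 1.0)
    return float(f) if np.isscalar(intensity_a) and np.isscalar(intensity_b) else f


def estimate_pool_frequencies(
    intensities: PoolIntensities, k_correction: float | None = None
) -> pd.DataFrame:
    """Pools x sites frequency-estimate table (index pool_id, columns site_id).

    ``k_correction`` defaults to the intensities' generating ``k_bias``; pass
    an explicit value to study miscalibrated correction.
    """
    k = intensities.k_bias if k_correction is None else k_correction
    f = estimate_pool_freq(intensities.a, intensities.b, k)
    return pd.DataFrame(f, index=intensities.pool_ids, columns=intensities.site_ids)


def pooled_association_test(
    case_freqs, case_sizes, control_freqs, control_sizes
) -> tuple[float, float, str]:
    """Weighted Welch test of one SNP: returns (statistic, two-sided P, direction).

    ``direction`` is the sign of (weighted case mean - weighted control mean),
    one of ``"+"``, ``"-"``, ``"0"``. Requires >= 2 pools with data per arm.
    """
    cf = np.asarray(case_freqs, float)
    kf = np.asarray(control_freqs, float)
    cw = np.asarray(case_sizes, float)
    kw = np.asarray(control_sizes, float)
    ok_c, ok_k = ~np.isnan(cf), ~np.isnan(kf)
    if ok_c.sum() < 2 or ok_k.sum() < 2:
        raise TooFewPoolsError("need >= 2 pools with data per arm")
    t, p = weighted_welch_test(cf[ok_c], cw[ok_c], kf[ok_k], kw[ok_k])
    delta = np.average(cf[ok_c], weights=cw[ok_c]) - np.average(kf[ok_k], weights=kw[ok_k])
    direction = "+" if delta > 0 else ("-" if delta < 0 else "0")
    return t, p, direction


def run_screen(
    freqs: pd.DataFrame,
    pools: PoolSet,
    comparisons: list[Comparison] | None = None,
) -> pd.DataFrame:
    """Screen every site in every comparison.

    Parameters
    ----------
    freqs:
        Pools x sites frequency estimates (from :func:`estimate_pool_frequencies`
        or a user file with the same shape). NaN marks a failed pool/site cell.
    pools:
        The pool set giving per-pool stratum and size.
    comparisons:
        Defaults to the nine diagnosis x onset comparisons.

    Returns a long table: site_id, comparison, case_freq, ctrl_freq, n_case_pools,
    n_ctrl_pools, stat, p, direction. Sites with < 2 usable pools in either arm
    are dropped (logged). The per-site computation is vectorised but matches
    :func:`pooled_association_test` exactly.
    """
    if comparisons is None:
        comparisons = nine_comparisons()
    pool_meta = pools.pools.set_index("pool_id").loc[freqs.index]
    sizes = pool_meta["n_samples"].to_numpy(float)
    fmat = freqs.to_numpy(float)
    out = []
    for comp in comparisons:
        case_mask = comp.case_pool_mask(pool_meta)
        ctrl_mask = comp.control_pool_mask(pool_meta)
        if case_mask.sum() == 0:
            raise TooFewPoolsError(f"comparison {comp.label} selects no case pools")
        res = _vector_welch(fmat[case_mask], sizes[case_mask],
                            fmat[ctrl_mask], sizes[ctrl_mask])
        res.insert(0, "comparison", comp.label)
        res.insert(0, "site_id", freqs.columns)
        out.append(res)
    table = pd.concat(out, ignore_index=True)
    bad = table["p"].isna()
    if bad.any():
        logger.warning("%d site/comparison rows dropped (<2 usable pools)", int(bad.sum()))
        table = table[~bad].reset_index(drop=True)
    return table


def _vector_welch(cf: np.ndarray, cw: np.ndarray, kf: np.ndarray, kw: np.ndarray) -> pd.DataFrame:
    """Columnwise weighted Welch test; NaN-aware; same formula as stats.weighted_welch_test."""
    res = {}
    for arm, (f, w) in {"case": (cf, cw), "ctrl": (kf, kw)}.items():
        valid = ~np.isnan(f)
        g = valid.sum(axis=0).astype(float)
        wmat = np.where(valid, w[:, None], 0.0)
        sw = wmat.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.nansum(wmat * f, axis=0) / sw
            v = (np.nansum(wmat**2 * (f - m) ** 2, axis=0) / sw**2) * g / (g - 1)
        res[arm] = (m, v, g)
    m1, v1, g1 = res["case"]
    m2, v2, g2 = res["ctrl"]
    usable = (g1 >= 2) & (g2 >= 2)
    delta = m1 - m2
    denom = v1 + v2
    tiny = np.nextafter(0.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = delta / np.sqrt(denom)
        df = denom**2 / (v1**2 / (g1 - 1) + v2**2 / (g2 - 1))
        p = 2.0 * _sps.t.sf(np.abs(t), df)
    zero = delta == 0
    t = np.where(zero, 0.0, t)
    p = np.where(zero, 1.0, p)
    exploded = (~zero) & (denom <= 0)
    t = np.where(exploded, np.sign(delta) * np.inf, t)
    p = np.where(exploded, tiny, p)
    p = np.clip(p, tiny, 1.0)
    p = np.where(usable, p, np.nan)
    direction = np.where(zero, "0", np.where(delta > 0, "+", "-"))
    return pd.DataFrame({
        "case_freq": m1, "ctrl_freq": m2,
        "n_case_pools": g1.astype(int), "n_ctrl_pools": g2.astype(int),
        "stat": t, "p": p, "direction": direction,
    })
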