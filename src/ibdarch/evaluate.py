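"""Calibration and recovery studies for the pipeline's statistics.

These routines re-derive the pipeline's operating characteristics from
scratch — type-I error under simulated global nulls, planted-odds-ratio
recovery at study-like sample sizes, equivalence of the Fisher P-value with
an exhaustive hypergeometric enumeration, and equivalence of the LD-block
scan with a brute-force enumeration of qualifying runs. They are used by the
test suite and the reproduction script, not by the pipeline itself.

All seeds are spawned from a single integer via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd

from . import assoc, burden, screen, select, simulate

# ---------------------------------------------------------------------------
# independent Fisher oracle: exhaustive hypergeometric enumeration
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher P by direct enumeration of the hypergeometric support.

    With margins fixed, P = sum of probabilities of all tables whose
    point probability is <= that of the observed table (with a 1+1e-7
    relative tolerance for floating-point ties). Independent of scipy's
    implementation; used only as an oracle.
    """
    r, s = a + b, c + d
    m = a + c
    n = r + s
    lo, hi = max(0, m - s), min(r, m)
    log_denom = _log_comb(n, m)
    logp = np.array([
        _log_comb(r, x) + _log_comb(s, m - x) - log_denom for x in range(lo, hi + 1)
    ])
    p_obs = logp[a - lo]
    total = float(np.exp(logp[logp <= p_obs + 1e-7]).sum())
    return min(total, 1.0)


def enumerate_tables(max_total: int) -> np.ndarray:
    """All non-negative 2x2 tables with total <= ``max_total``, as an (M, 4) array."""
    grid = np.arange(max_total + 1)
    a, b, c = np.meshgrid(grid, grid, grid, indexing="ij")
    a, b, c = a.ravel(), b.ravel(), c.ravel()
    keep = a + b + c <= max_total
    a, b, c = a[keep], b[keep], c[keep]
    # d ranges freely up to the remaining total; expand vectorised
    rem = max_total - (a + b + c)
    reps = rem + 1
    a = np.repeat(a, reps)
    b = np.repeat(b, reps)
    c = np.repeat(c, reps)
    d = np.concatenate([np.arange(r + 1) for r in rem])
    return np.column_stack([a, b, c, d])


def canonical_tables(max_total: int) -> np.ndarray:
    """One representative per orbit of the row-swap/col-swap/transpose group.

    The two-sided Fisher P is invariant under swapping rows, swapping columns
    and transposing a 2x2 table, so checking one representative per orbit
    covers every table with total <= ``max_total``.
    """
    t = enumerate_tables(max_total)
    a, b, c, d = t.T
    transforms = [
        (a, b, c, d), (c, d, a, b), (b, a, d, c), (d, c, b, a),
        (a, c, b, d), (b, d, a, c), (c, a, d, b), (d, b, c, a),
    ]
    base = max_total + 1
    codes = np.stack([
        ((x * base + y) * base + z) * base + w for x, y, z, w in transforms
    ])
    canon = codes.min(axis=0)
    uniq = np.unique(canon)
    out = np.empty((uniq.size, 4), dtype=np.int64)
    rest = uniq
    for j in range(3, -1, -1):
        out[:, j] = rest % base
        rest = rest // base
    return out


def fisher_oracle_max_abs_dp(max_total: int = 80) -> tuple[float, int]:
    """Max |package Fisher P - enumeration P| over all tables with total <= max_total.

    Comparison runs on canonical orbit representatives (see
    :func:`canonical_tables`); returns (max abs difference, tables covered).
    """
    from .stats import fisher_p

    reps = canonical_tables(max_total)
    n_all = len(enumerate_tables(max_total))
    worst = 0.0
    for a, b, c, d in reps:
        p_impl = fisher_p(int(a), int(b), int(c), int(d))
        p_oracle = 1.0 if ((a == 0 and c == 0) or (b == 0 and d == 0)) \
            else fisher_p_enumeration(int(a), int(b), int(c), int(d))
        worst = max(worst, abs(p_impl - p_oracle))
    return worst, n_all


# ---------------------------------------------------------------------------
# brute-force LD-block oracle
# ---------------------------------------------------------------------------


def find_blocks_bruteforce(results: pd.DataFrame, min_block_size=10, max_gap_bp=30_000,
                           p_member=0.005, p_index=1e-4) -> list[tuple]:
    """O(n^2) enumeration of maximal qualifying runs; oracle for find_blocks.

    For every candidate start site, extend through qualifying sites while each
    consecutive qualifying pair is < max_gap_bp apart; keep maximal runs of
    >= min_block_size whose best P is <= p_index. Returns a list of
    (chrom, member site tuple, index site) triples.
    """
    out = []
    for chrom, grp in results.groupby("chrom", sort=False):
        q = grp[grp["p"] < p_member].reset_index(drop=True)
        n = len(q)
        taken = set()
        for i in range(n):
            if i in taken:
                continue
            run = [i]
            for j in range(i + 1, n):
                if q["pos"][j] - q["pos"][j - 1] < max_gap_bp:
                    run.append(j)
                else:
                    break
            taken.update(run)
            if len(run) < min_block_size:
                continue
            ps = q["p"].iloc[run]
            if ps.min() > p_index:
                continue
            best = ps.min()
            idx = min((q["pos"][k], q["site_id"][k]) for k in run if q["p"][k] == best)
            out.append((str(chrom), tuple(q["site_id"][k] for k in run), idx[1]))
    return out


def random_screen_panel(rng: np.random.Generator, max_sites: int = 500) -> pd.DataFrame:
    """A random single-comparison results table for block-scan property tests.

    Positions have a mix of sub-30 kb spacings and larger gaps; P-values mix
    null-uniform and strongly associated sites so qualifying runs of realistic
    lengths occur.
    """
    n = int(rng.integers(20, max_sites + 1))
    chroms = np.sort(rng.choice(["1", "2"], size=n))
    gaps = rng.choice([2_000, 10_000, 29_999, 30_000, 45_000],
                      size=n, p=[0.45, 0.25, 0.1, 0.1, 0.1])
    pos = np.empty(n, dtype=int)
    for chrom in ("1", "2"):
        mask = chroms == chrom
        pos[mask] = 1 + np.cumsum(gaps[mask])
    df = pd.DataFrame({
        "site_id": [f"s{i:04d}" for i in range(n)],
        "chrom": chroms, "pos": pos,
        "p": 10.0 ** rng.uniform(-6, 0, size=n),
    })
    # densify small P so blocks of >= 10 qualifying sites actually appear
    hot = rng.random(n) < 0.6
    df.loc[hot, "p"] = 10.0 ** rng.uniform(-5, math.log10(0.005), size=int(hot.sum()))
    return df


def block_bruteforce_mismatches(n_panels: int = 200, seed: int = 0,
                                max_sites: int = 500) -> tuple[int, int]:
    """Compare find_blocks with the brute-force oracle on random panels.

    Returns (number of mismatching panels, total blocks found). The fixed
    boundary cases (9 qualifying SNPs -> no block; a 31 kb gap splitting a run)
    are covered by the random gap mixture which includes exact 30 kb gaps.
    """
    rng = np.random.default_rng(seed)
    mismatches = 0
    total_blocks = 0
    for _ in range(n_panels):
        panel = random_screen_panel(rng, max_sites)
        got = select.find_blocks(panel)
        want = find_blocks_bruteforce(panel)
        got_t = [(b.chrom, tuple(b.site_ids), b.index_site) for b in got]
        total_blocks += len(got)
        if got_t != want:
            mismatches += 1
    return mismatches, total_blocks


# ---------------------------------------------------------------------------
# type-I error studies
# ---------------------------------------------------------------------------


def pooled_null_type1(
    n_sites: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    noise_sd: float = 0.02,
) -> tuple[float, int]:
    """Empirical P(P < alpha) of the pooled test under a global null.

    Simulates the full screening arm — study-sized cohort, the 49 + 30 pool
    layout, array intensities — with no planted effects and independent sites
    (so the empirical rate has a plain binomial tolerance), then tests every
    site in the all-onset IBD comparison. Returns (rate, n_sites tested).
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    panel = simulate.build_panel(
        [(f"b{i}", 10, 2_000, 50_000) for i in range(n_sites // 10)],
        ld_rho=0.0, seed=_seed_int(ss[0]),
    )
    cohort = simulate.default_screen_cohort(seed=_seed_int(ss[1]))
    gm = simulate.simulate_genotypes(panel, simulate.EffectSpec(), cohort, _seed_int(ss[2]))
    pools = simulate.build_pools(cohort, seed=_seed_int(ss[2]))
    pi = simulate.simulate_pool_intensities(pools, gm, noise_sd=noise_sd, seed=_seed_int(ss[3]))
    freqs = screen.estimate_pool_frequencies(pi)
    comp = [c for c in screen.nine_comparisons() if c.label == "IBD:all"]
    res = screen.run_screen(freqs, pools, comp)
    return float((res["p"] < alpha).mean()), len(res)


def burden_null_type1(
    n_seeds: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Empirical P(P < alpha) of the gene-set Fisher burden under the null.

    Simulates ``n_seeds`` independent exome cohorts at the study group sizes
    with no planted enrichment and runs the nine contrasts on one gene set;
    the rate is averaged over all contrast rows.
    """
    ss = np.random.SeedSequence(seed).spawn(n_seeds)
    spec = simulate.ExomeSimSpec(gene_sets={"IBD_risk": simulate.default_gene_sets()["IBD_risk"]})
    hits = 0
    rows = 0
    for s in ss:
        table = simulate.simulate_exomes(spec, _seed_int(s))
        res = burden.run_contrasts(table, spec.gene_sets)
        hits += int((res["p"] < alpha).sum())
        rows += len(res)
    return hits / rows, rows


# ---------------------------------------------------------------------------
# planted-OR recovery studies
# ---------------------------------------------------------------------------


def allelic_logor_recovery(
    oratios=(1.2, 1.5, 2.0, 2.5),
    n_cases: int = 750,
    n_controls: int = 934,
    maf: float = 0.25,
    n_seeds: int = 200,
    seed: int = 0,
) -> dict[float, float]:
    """Mean estimated log-OR per planted allelic OR at study-like arm sizes.

    Each replicate simulates one biallelic site (HWE controls, multiplicative
    allelic risk model cases), runs the allelic validation test, and averages
    the estimated log-OR over ``n_seeds`` replicates. Returns
    ``{planted OR: mean log-OR}``.
    """
    panel = simulate.build_panel([("b0", 1, 1_000, 1_000)], mafs=np.array([maf]))
    cohort = simulate.build_cohort(0, n_cases, 0, 0, n_controls)
    out = {}
    for oratio in oratios:
        effects = simulate.EffectSpec.from_dict({"site00000": {"CD:adult": oratio}})
        ss = np.random.SeedSequence([seed, int(round(oratio * 1000))]).spawn(n_seeds)
        logors = []
        for s in ss:
            gm = simulate.simulate_genotypes(panel, effects, cohort, _seed_int(s))
            case = gm.genotypes[(gm.samples["diagnosis"] == "CD").to_numpy(), 0]
            ctrl = gm.genotypes[(gm.samples["diagnosis"] == "HC").to_numpy(), 0]
            rec = assoc.allelic_test(case, ctrl, "site00000", "CD:adult")
            logors.append(math.log(rec.oratio))
        out[oratio] = float(np.mean(logors))
    return out


def burden_logor_recovery(
    planted_or: float = 1.3,
    n_seeds: int = 500,
    seed: int = 0,
    contrast: str = "HC/VEO IBD",
    gene_set: str = "IBD_risk",
) -> float:
    """Mean recovered log-OR for a planted VEO deleterious-enrichment.

    The enrichment is planted in both VEO groups of the ``IBD_risk`` gene set
    at the study's exome group sizes (21 + 22 VEO, 23 + 22 adult, 18 HC);
    recovery is read from the requested contrast row.
    """
    spec = simulate.ExomeSimSpec(
        gene_sets={gene_set: simulate.default_gene_sets()[gene_set]},
        enrichment={gene_set: {"VEO-CD": planted_or, "VEO-UC": planted_or}},
    )
    ss = np.random.SeedSequence(seed).spawn(n_seeds)
    logors = []
    for s in ss:
        table = simulate.simulate_exomes(spec, _seed_int(s))
        res = burden.run_contrasts(table, spec.gene_sets)
        row = res[res["contrast"] == contrast].iloc[0]
        logors.append(math.log(row["oratio"]))
    return float(np.mean(logors))


def hwe_goodness_of_fit_pass_rate(
    n_controls: int = 10_000,
    n_sites: int = 300,
    maf: float = 0.3,
    seed: int = 0,
    p_floor: float = 0.001,
) -> float:
    """Fraction of sites whose control genotype counts fit HWE expectations.

    Chi-square goodness of fit against (q^2, 2pq, p^2) with 2 df; under the
    generator's null essentially all sites should pass at ``p_floor``.
    """
    from scipy import stats as sps

    panel = simulate.build_panel(
        [(f"b{i}", 1, 1_000, 1_000) for i in range(n_sites)],
        mafs=np.full(n_sites, maf), ld_rho=0.0,
    )
    cohort = simulate.build_cohort(0, 0, 0, 0, n_controls)
    gm = simulate.simulate_genotypes(panel, simulate.EffectSpec(), cohort, seed)
    p = maf
    expected = n_controls * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    passes = 0
    for j in range(n_sites):
        counts = np.bincount(gm.genotypes[:, j], minlength=3)
        stat = ((counts - expected) ** 2 / expected).sum()
        if sps.chi2.sf(stat, 2) > p_floor:
            passes += 1
    return passes / n_sites


def _seed_int(ss: np.random.SeedSequence) -> int:
    """A small deterministic integer seed derived from a SeedSequence."""
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))
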