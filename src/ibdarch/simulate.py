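"""Synthetic cohort generation for a two-arm IBD genetic-architecture study.

This module produces every input the downstream pipeline consumes:

* individual biallelic genotypes under Hardy–Weinberg equilibrium (HWE), with
  within-block linkage disequilibrium (LD) induced by a haplotype-copying
  scheme and per-stratum planted allelic odds ratios,
* equimolar DNA pools partitioned by diagnosis x age-at-onset stratum, with
  two-channel array intensities per pool and SNP,
* whole-exome rare-variant tables with per-sample genotypes, reference-panel
  minor allele frequencies (MAFs), consequence classes and a PHRED-scaled
  deleteriousness score, with optional gene-set enrichment of deleterious
  alleles in selected groups.

Genotypes are coded as the minor-allele dosage {0, 1, 2}; -1 marks a missing
call. All randomness flows through :class:`numpy.random.Generator` instances
seeded from one integer, so identical seed + configuration reproduces
bit-identical outputs.

The default cohort layouts mirror a two-stage Polish IBD study design:
a screening cohort of 594 CD (356 pediatric-onset, i.e. diagnosed before 17
years) + 571 UC (311 pediatric) patients and 724 healthy controls pooled into
49 case and 30 control pools, and an enlarged validation cohort of 761 CD /
734 UC / 934 controls. The exome arm contrasts very-early-onset (VEO, onset
before 6 years) children with adult-onset (after 40 years) patients and
controls, with group sizes 21 + 22 VEO, 23 + 22 adult, 18 controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyGeneSetError, EmptyStratumError, UnknownSampleError, UnknownSiteError

logger = logging.getLogger(__name__)

DIAGNOSES = ("CD", "UC", "HC")
ONSETS = ("pediatric", "adult", "not_applicable")

#: consequence classes treated as coding downstream
CODING_CONSEQUENCES = ("frameshift", "stop_gained", "splice", "missense", "synonymous")
LOF_CONSEQUENCES = ("frameshift", "stop_gained", "splice")

PANEL_NAMES = ("1kgp", "esp", "exac")


def stratum_of(diagnosis: str, onset: str) -> str:
    return f"{diagnosis}:{onset}"


# ---------------------------------------------------------------------------
# panel / effects / cohort specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelSpec:
    """Array design: ordered biallelic sites with block structure and MAFs.

    ``sites`` columns: site_id, chrom, pos (1-based), block_id, maf.
    ``ld_rho`` is the within-block haplotype-copying probability in [0, 1]:
    0 gives independent sites, values near 1 give near-perfect LD.
    """

    sites: pd.DataFrame
    ld_rho: float = 0.0

    def __post_init__(self) -> None:
        maf = self.sites["maf"].to_numpy()
        if np.any((maf <= 0) | (maf > 0.5)):
            raise ValueError("all MAFs must lie in (0, 0.5]")
        if not 0.0 <= self.ld_rho <= 1.0:
            raise ValueError("ld_rho must lie in [0, 1]")
        for _, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> pd.Index:
        return pd.Index(self.sites["site_id"])


def build_panel(
    block_layout: list[tuple[str, int, int, int]],
    mafs: np.ndarray | None = None,
    ld_rho: float = 0.0,
    chrom: str = "1",
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | None = None,
) -> PanelSpec:
    """Build a PanelSpec from a block layout.

    Parameters
    ----------
    block_layout:
        List of ``(block_id, n_snps, spacing_bp, gap_bp)``: each block places
        ``n_snps`` sites ``spacing_bp`` apart, followed by a ``gap_bp`` gap
        before the next block. Spacings and gaps must be positive.
    mafs:
        Per-site MAF array in (0, 0.5]; drawn uniformly from ``maf_range``
        (seeded) when omitted.
    """
    rows = []
    pos = 1
    for block_id, n_snps, spacing, gap in block_layout:
        if spacing <= 0 or gap <= 0:
            raise ValueError("spacing and gap must be positive")
        if n_snps < 1:
            raise ValueError("each block needs at least one SNP")
        for _ in range(n_snps):
            rows.append((chrom, pos, str(block_id)))
            pos += spacing
        pos += gap - spacing  # gap measured from last SNP of the block
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "block_id"])
    sites.insert(0, "site_id", [f"site{i:05d}" for i in range(len(sites))])
    if mafs is None:
        rng = np.random.default_rng(seed)
        mafs = rng.uniform(*maf_range, size=len(sites))
    sites["maf"] = np.asarray(mafs, float)
    return PanelSpec(sites=sites, ld_rho=ld_rho)


@dataclass(frozen=True)
class EffectSpec:
    """Planted per-stratum allelic odds ratios.

    ``effects`` columns: site_id, stratum (``"CD:pediatric"`` etc.), oratio,
    risk_allele (``"minor"`` or ``"major"``). Sites/strata absent from the
    table carry OR = 1. Healthy controls are always drawn at the panel MAF.
    """

    effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["site_id", "stratum", "oratio", "risk_allele"]
        )
    )

    def __post_init__(self) -> None:
        if len(self.effects) and np.any(self.effects["oratio"].to_numpy() <= 0):
            raise ValueError("planted odds ratios must be positive")

    @classmethod
    def from_dict(
        cls, effects: dict[str, dict[str, float]], risk_allele: str = "minor"
    ) -> "EffectSpec":
        """``{site_id: {stratum: OR}}`` convenience constructor."""
        rows = [
            (site, stratum, oratio, risk_allele)
            for site, per_stratum in effects.items()
            for stratum, oratio in per_stratum.items()
        ]
        return cls(pd.DataFrame(rows, columns=["site_id", "stratum", "oratio", "risk_allele"]))

    def validate_against(self, panel: PanelSpec) -> None:
        unknown = set(self.effects["site_id"]) - set(panel.site_ids)
        if unknown:
            raise UnknownSiteError(f"effect sites absent from panel: {sorted(unknown)}")

    def tilted_maf(self, panel: PanelSpec, stratum: str) -> np.ndarray:
        """Per-site case allele frequency for one stratum.

        Under the multiplicative allelic risk model with allelic odds ratio
        ``OR``, the case minor-allele frequency satisfies
        ``odds(p') = OR * odds(p)``, i.e. ``p' = OR*p / (1 - p + OR*p)``.
        A ``risk_allele == "major"`` effect is the same tilt with OR inverted.
        """
        p = panel.sites["maf"].to_numpy(float).copy()
        sub = self.effects[self.effects["stratum"] == stratum]
        if len(sub):
            idx = panel.site_ids.get_indexer(sub["site_id"])
            oratio = sub["oratio"].to_numpy(float)
            oratio = np.where(sub["risk_allele"].to_numpy() == "major", 1.0 / oratio, oratio)
            pi = p[idx]
            p[idx] = oratio * pi / (1.0 - pi + oratio * pi)
        return p


def build_cohort(
    n_cd_pediatric: int,
    n_cd_adult: int,
    n_uc_pediatric: int,
    n_uc_adult: int,
    n_hc: int,
    seed: int | None = None,
    prefix: str = "S",
) -> pd.DataFrame:
    """Sample metadata table: sample_id, diagnosis, onset, sex, age_at_onset.

    Pediatric onset means diagnosis before 17 years; ages are drawn uniformly
    (1–16 pediatric, 17–70 adult). Healthy controls (HC) have onset
    ``not_applicable`` and no age at onset.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, float]] = []
    rows += [("CD", "pediatric", rng.integers(1, 17)) for _ in range(n_cd_pediatric)]
    rows += [("CD", "adult", rng.integers(17, 71)) for _ in range(n_cd_adult)]
    rows += [("UC", "pediatric", rng.integers(1, 17)) for _ in range(n_uc_pediatric)]
    rows += [("UC", "adult", rng.integers(17, 71)) for _ in range(n_uc_adult)]
    rows += [("HC", "not_applicable", np.nan) for _ in range(n_hc)]
    cohort = pd.DataFrame(rows, columns=["diagnosis", "onset", "age_at_onset"])
    cohort.insert(0, "sample_id", [f"{prefix}{i:05d}" for i in range(len(cohort))])
    cohort.insert(3, "sex", rng.choice(["F", "M"], size=len(cohort)))
    return cohort


def default_screen_cohort(seed: int | None = None) -> pd.DataFrame:
    """Screening-stage cohort: 594 CD (356 pediatric) + 571 UC (311) + 724 HC."""
    return build_cohort(356, 238, 311, 260, 724, seed=seed, prefix="G")


def default_validation_cohort(seed: int | None = None) -> pd.DataFrame:
    """Validation-stage cohort: 761 CD (424 pediatric) + 734 UC (390) + 934 HC."""
    return build_cohort(424, 337, 390, 344, 934, seed=seed, prefix="V")


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x sites minor-allele dosages plus sample and site metadata."""

    genotypes: np.ndarray  # int8, n_samples x n_sites; -1 = missing
    samples: pd.DataFrame
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        assert self.genotypes.shape == (len(self.samples), len(self.sites))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def site_ids(self) -> pd.Index:
        return pd.Index(self.sites["site_id"])

    def allele_freq(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Per-site minor-allele frequency over (a subset of) samples."""
        g = self.genotypes if sample_mask is None else self.genotypes[sample_mask]
        valid = g >= 0
        n_alleles = 2 * valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(valid, g, 0).sum(axis=0) / np.where(n_alleles == 0, np.nan, n_alleles)

    def strata(self) -> pd.Series:
        return self.samples["diagnosis"] + ":" + self.samples["onset"]


def _draw_haplotypes(
    rng: np.random.Generator,
    n_haplotypes: int,
    p: np.ndarray,
    block_ids: np.ndarray,
    ld_rho: float,
) -> np.ndarray:
    """Haplotype-copying draw: within a block each site's latent uniform is,
    with probability ``ld_rho``, copied from the previous site; the allele is
    1 iff the latent uniform falls below the site's allele frequency. This
    preserves every marginal frequency exactly while inducing positive LD."""
    n_sites = p.size
    u = rng.random((n_haplotypes, n_sites))
    if ld_rho > 0 and n_sites > 1:
        copy = rng.random((n_haplotypes, n_sites)) < ld_rho
        same_block = np.concatenate([[False], block_ids[1:] == block_ids[:-1]])
        for j in range(1, n_sites):
            if same_block[j]:
                u[:, j] = np.where(copy[:, j], u[:, j - 1], u[:, j])
    return (u < p).astype(np.int8)


def simulate_genotypes(
    panel: PanelSpec,
    effects: EffectSpec,
    cohort: pd.DataFrame,
    seed: int | None,
) -> GenotypeMatrix:
    """Draw individual genotypes for a cohort.

    Controls are drawn under HWE at the panel MAF; case strata are drawn at
    the tilted allele frequency implied by their planted allelic odds ratio
    (the multiplicative allelic risk model), with within-block LD from the
    haplotype-copying scheme at ``panel.ld_rho`` in every stratum.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    effects.validate_against(panel)
    rng = np.random.default_rng(seed)
    block_ids = panel.sites["block_id"].to_numpy()
    geno = np.empty((len(cohort), panel.n_sites), dtype=np.int8)
    strata = (cohort["diagnosis"] + ":" + cohort["onset"]).to_numpy()
    for stratum in sorted(set(strata)):  # sorted => draw order is reproducible
        mask = strata == stratum
        p = (
            panel.sites["maf"].to_numpy(float)
            if stratum.startswith("HC")
            else effects.tilted_maf(panel, stratum)
        )
        n = int(mask.sum())
        hap = _draw_haplotypes(rng, 2 * n, p, block_ids, panel.ld_rho)
        geno[mask] = hap[0::2] + hap[1::2]
    return GenotypeMatrix(geno, cohort.reset_index(drop=True), panel.sites.copy())


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


@dataclass
class PoolSet:
    """Stratum-homogeneous partition of samples into pools.

    ``pools`` columns: pool_id, stratum, diagnosis, onset, n_samples.
    ``membership`` columns: sample_id, pool_id (each sample in exactly one pool).
    """

    pools: pd.DataFrame
    membership: pd.DataFrame

    @property
    def n_pools(self) -> int:
        return len(self.pools)


def default_pool_policy() -> dict[str, dict[str, int]]:
    """The two-stage study's pool layout: 49 case pools (9 adult-UC, 16
    pediatric-UC, 10 adult-CD, 14 pediatric-CD) + 30 control pools."""
    return {
        "UC:adult": {"n_pools": 9},
        "UC:pediatric": {"n_pools": 16},
        "CD:adult": {"n_pools": 10},
        "CD:pediatric": {"n_pools": 14},
        "HC:not_applicable": {"n_pools": 30},
    }


def _pool_sizes(n: int, spec: dict[str, int], remainder: str) -> list[int]:
    if "n_pools" in spec:
        k = spec["n_pools"]
        if k < 1:
            raise ValueError("n_pools must be >= 1")
        base, extra = divmod(n, k)
        return [base + (1 if i < extra else 0) for i in range(k)]
    size = spec["pool_size"]
    if size < 1:
        raise ValueError("pool_size must be >= 1")
    k, r = divmod(n, size)
    if k == 0:
        return [n]
    if remainder == "absorb":
        sizes = [size] * k
        sizes[-1] += r
        return sizes
    if remainder == "trailing":  # a final smaller pool holds the remainder
        return [size] * k + ([r] if r else [])
    raise ValueError(f"unknown remainder policy: {remainder!r}")


def build_pools(
    cohort: pd.DataFrame,
    policy: dict[str, dict[str, int]] | None = None,
    seed: int | None = None,
    remainder: str = "absorb",
) -> PoolSet:
    """Partition a cohort into stratum-homogeneous pools.

    ``policy`` maps stratum (``"CD:pediatric"``) to ``{"n_pools": k}`` (k
    near-equal pools) or ``{"pool_size": s}`` (pools of s with the remainder
    handled per ``remainder``: ``"absorb"`` folds it into the last full pool,
    ``"trailing"`` emits a final smaller pool). Sample order within strata is
    shuffled (seeded) before chunking, mimicking equimolar pool assembly.
    """
    if policy is None:
        policy = default_pool_policy()
    rng = np.random.default_rng(seed)
    strata = cohort["diagnosis"] + ":" + cohort["onset"]
    pool_rows, member_rows = [], []
    for stratum in policy:
        ids = cohort.loc[strata == stratum, "sample_id"].to_numpy()
        if len(ids) == 0:
            raise EmptyStratumError(f"pools requested for empty stratum {stratum!r}")
        ids = rng.permutation(ids)
        sizes = _pool_sizes(len(ids), policy[stratum], remainder)
        if sum(sizes) != len(ids):
            raise AssertionError("pool sizes must partition the stratum")
        diagnosis, onset = stratum.split(":", 1)
        start = 0
        for k, size in enumerate(sizes):
            pool_id = f"{stratum}.p{k:02d}"
            pool_rows.append((pool_id, stratum, diagnosis, onset, size))
            member_rows += [(s, pool_id) for s in ids[start : start + size]]
            start += size
    uncovered = set(strata) - set(policy)
    if uncovered:
        logger.warning("strata not covered by pooling policy (samples unpooled): %s",
                       sorted(uncovered))
    return PoolSet(
        pools=pd.DataFrame(
            pool_rows, columns=["pool_id", "stratum", "diagnosis", "onset", "n_samples"]
        ),
        membership=pd.DataFrame(member_rows, columns=["sample_id", "pool_id"]),
    )


# ---------------------------------------------------------------------------
# pooled array intensities
# ---------------------------------------------------------------------------


@dataclass
class PoolIntensities:
    """Two-channel array intensities per pool and site.

    ``a``/``b`` are pools x sites arrays; channel A carries the minor allele.
    ``k_bias`` is the multiplicative heterozygote/channel bias applied to the
    B channel at generation time (1.0 = unbiased)."""

    pool_ids: pd.Index
    site_ids: pd.Index
    a: np.ndarray
    b: np.ndarray
    k_bias: float
    noise_sd: float


def simulate_pool_intensities(
    pools: PoolSet,
    genotypes: GenotypeMatrix,
    noise_sd: float = 0.02,
    k_bias: float = 1.0,
    seed: int | None = None,
) -> PoolIntensities:
    """Two-channel intensities whose corrected A-fraction estimates pool MAF.

    The true pooled minor-allele fraction ``f`` (mean dosage / 2 over pool
    members) receives additive Gaussian noise (sd ``noise_sd``) clipped to
    [0, 1]; channel A reports that fraction and channel B reports
    ``(1 - f) / k_bias``, so the raw A-channel fraction A/(A+B) is the true
    frequency distorted by the heterozygote bias ``k`` and the estimator's
    ``A / (A + k B)`` correction at ``k = k_bias`` removes the distortion.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    if k_bias <= 0:
        raise ValueError("k_bias must be > 0")
    unknown = set(pools.membership["sample_id"]) - set(genotypes.samples["sample_id"])
    if unknown:
        raise UnknownSampleError(f"pool members absent from genotypes: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    sample_pos = pd.Index(genotypes.samples["sample_id"])
    freqs = np.empty((pools.n_pools, len(genotypes.sites)))
    members = pools.membership.groupby("pool_id", sort=False)["sample_id"]
    for i, pool_id in enumerate(pools.pools["pool_id"]):
        rows = sample_pos.get_indexer(members.get_group(pool_id))
        freqs[i] = genotypes.allele_freq(rows)
    noisy = freqs + rng.normal(0.0, noise_sd, size=freqs.shape) if noise_sd else freqs
    noisy = np.clip(noisy, 0.0, 1.0)
    return PoolIntensities(
        pool_ids=pd.Index(pools.pools["pool_id"]),
        site_ids=genotypes.site_ids,
        a=noisy,
        b=(1.0 - noisy) / k_bias,
        k_bias=k_bias,
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# exome simulation
# ---------------------------------------------------------------------------

EXOME_GROUPS = ("VEO-CD", "VEO-UC", "Adult-CD", "Adult-UC", "HC")


@dataclass
class ExomeSimSpec:
    """Whole-exome rare-variant simulation parameters.

    ``enrichment`` maps gene-set name -> group -> planted odds ratio on the
    deleterious-vs-non-deleterious rare-allele mix relative to baseline
    (implemented by scaling deleterious-variant carrier frequencies; for rare
    alleles the expected burden-table odds ratio equals the multiplier).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"VEO-CD": 21, "VEO-UC": 22, "Adult-CD": 23, "Adult-UC": 22, "HC": 18}
    )
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    enrichment: dict[str, dict[str, float]] = field(default_factory=dict)
    variants_per_gene: float = 8.0  # Poisson rate of rare sites per gene
    deleterious_fraction: float = 0.45  # null fraction of rare sites deleterious
    carrier_freq_range: tuple[float, float] = (0.002, 0.02)
    novel_fraction: float = 0.3

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group size must be positive: {g}")
        if self.variants_per_gene < 0:
            raise ValueError("variants_per_gene must be >= 0")
        for s, per_group in self.enrichment.items():
            if any(v <= 0 for v in per_group.values()):
                raise ValueError(f"planted enrichment ORs must be > 0 ({s})")


def default_gene_sets(n_per_set: int = 150) -> dict[str, list[str]]:
    return {
        "IBD_risk": [f"IBD{i:03d}" for i in range(n_per_set)],
        "innate_immunity": [f"INN{i:03d}" for i in range(n_per_set)],
    }


@dataclass
class ExomeVariantTable:
    """Rare-variant records plus a variants x samples genotype matrix.

    ``variants`` columns: var_id, chrom, pos, ref, alt, gene, consequence,
    cadd (NaN = missing), maf_1kgp, maf_esp, maf_exac (NaN = not in panel),
    novel. ``samples`` columns: sample_id, group, diagnosis, onset.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray  # int8, n_variants x n_samples; -1 = missing
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        assert self.genotypes.shape == (len(self.variants), len(self.samples))

    def group_mask(self, group: str | list[str]) -> np.ndarray:
        groups = [group] if isinstance(group, str) else list(group)
        return self.samples["group"].isin(groups).to_numpy()


def _group_meta(group: str) -> tuple[str, str]:
    if group == "HC":
        return "HC", "not_applicable"
    onset, diagnosis = group.split("-", 1)
    return diagnosis, {"VEO": "pediatric", "Adult": "adult"}[onset]


def simulate_exomes(spec: ExomeSimSpec, seed: int | None) -> ExomeVariantTable:
    """Simulate a rare-variant exome table for the five onset groups.

    Each gene receives Poisson(``variants_per_gene``) rare sites; a fraction
    ``deleterious_fraction`` are deleterious (loss-of-function, or missense
    with CADD-PHRED > 10), the rest synonymous or benign missense. Panel MAFs
    are below 2% or absent (novel). Carrier allele frequencies are uniform on
    ``carrier_freq_range``; deleterious variants in enriched (gene-set, group)
    cells have their frequency multiplied by the planted odds ratio.
    """
    rng = np.random.default_rng(seed)
    if not spec.gene_sets:
        raise EmptyGeneSetError("no gene sets supplied")
    for name, genes in spec.gene_sets.items():
        if not genes:
            raise EmptyGeneSetError(f"gene set {name!r} references no genes")
    gene_to_set: dict[str, str] = {}
    for name, genes in spec.gene_sets.items():
        for g in genes:
            gene_to_set.setdefault(g, name)
    genes = sorted(gene_to_set)
    n_per_gene = rng.poisson(spec.variants_per_gene, size=len(genes))
    n_var = int(n_per_gene.sum())
    groups = [g for g in EXOME_GROUPS if g in spec.group_sizes]

    sample_rows = []
    for grp in groups:
        diagnosis, onset = _group_meta(grp)
        for i in range(spec.group_sizes[grp]):
            sample_rows.append((f"{grp}-{i:03d}", grp, diagnosis, onset))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "group", "diagnosis", "onset"])

    if n_var == 0:
        variants = pd.DataFrame(
            columns=["var_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
                     "cadd", "maf_1kgp", "maf_esp", "maf_exac", "novel"]
        )
        return ExomeVariantTable(variants, np.empty((0, len(samples)), np.int8), samples)

    gene_col = np.repeat(genes, n_per_gene)
    deleterious = rng.random(n_var) < spec.deleterious_fraction
    # consequence / CADD consistent with the deleterious flag
    consequence = np.where(rng.random(n_var) < 0.5, "synonymous", "missense").astype(object)
    cadd = rng.uniform(0.0, 9.5, size=n_var)
    lof = deleterious & (rng.random(n_var) < 0.3)
    consequence[lof] = rng.choice(LOF_CONSEQUENCES, size=int(lof.sum()))
    del_mis = deleterious & ~lof
    consequence[del_mis] = "missense"
    cadd[del_mis] = rng.uniform(10.5, 40.0, size=int(del_mis.sum()))
    cadd = np.where(np.char.equal(consequence.astype(str), "synonymous"), np.nan, cadd)

    novel = rng.random(n_var) < spec.novel_fraction
    mafs = {p: rng.uniform(1e-4, 0.019, size=n_var) for p in PANEL_NAMES}
    for p in PANEL_NAMES:
        mafs[p][novel] = np.nan

    base_freq = rng.uniform(*spec.carrier_freq_range, size=n_var)
    bases = np.array(["A", "C", "G", "T"])
    ref = rng.choice(bases, size=n_var)
    alt = np.array([rng.choice(bases[bases != r]) for r in ref])
    alt = np.where(np.char.equal(consequence.astype(str), "frameshift"),
                   np.char.add(ref, alt), alt)
    gene_index = {g: i for i, g in enumerate(genes)}
    pos = np.array([100_000 * (gene_index[g] + 1) for g in gene_col])
    pos = pos + np.concatenate([np.arange(n) for n in n_per_gene if n > 0]) * 37 + 1

    variants = pd.DataFrame({
        "var_id": [f"var{i:05d}" for i in range(n_var)],
        "chrom": "1",
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "gene": gene_col,
        "consequence": consequence.astype(str),
        "cadd": cadd,
        "maf_1kgp": mafs["1kgp"],
        "maf_esp": mafs["esp"],
        "maf_exac": mafs["exac"],
        "novel": novel,
    })

    geno = np.empty((n_var, len(samples)), dtype=np.int8)
    set_col = np.array([gene_to_set[g] for g in gene_col])
    col = 0
    for grp in groups:
        n_g = spec.group_sizes[grp]
        freq = base_freq.copy()
        for set_name, per_group in spec.enrichment.items():
            mult = per_group.get(grp, 1.0)
            if mult != 1.0:
                cell = deleterious & (set_col == set_name)
                freq[cell] = np.minimum(freq[cell] * mult, 0.5)
        geno[:, col : col + n_g] = rng.binomial(2, freq[:, None], size=(n_var, n_g))
        col += n_g
    return ExomeVariantTable(variants, geno, samples)
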