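"""Rare-variant gene-set burden analysis and the recurrent-homozygote screen.

The burden unit is the allele: within a gene set, rare alleles carried by a
group are split into deleterious vs non-deleterious, and two groups are
contrasted with a two-sided Fisher exact test on the resulting 2x2 table
(OR > 1 means deleterious alleles are over-represented in group B of an
"A/B" contrast). Rare means: novel, or below 2% in every reference panel
with data (1000 Genomes, NHLBI ESP European-American, ExAC). Deleterious
means loss-of-function (frameshift / stop-gained / splice) or missense with
CADD-PHRED above 10.

The recurrent-homozygote screen reports deleterious rare variants homozygous
in more than one very-early-onset child while homozygous in no adult patient
and no control (heterozygous carriage elsewhere does not exclude).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyGeneSetError
from .simulate import CODING_CONSEQUENCES, LOF_CONSEQUENCES, ExomeVariantTable
from .stats import test_table

logger = logging.getLogger(__name__)

MAF_THRESHOLD = 0.02
CADD_CUTOFF = 10.0
PANEL_COLUMNS = ("maf_1kgp", "maf_esp", "maf_exac")

#: the nine onset-group contrasts, in reporting order; "A/B" tests whether
#: deleterious rare alleles are enriched in B relative to A
CONTRASTS: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = (
    ("HC/VEO IBD", ("HC",), ("VEO-CD", "VEO-UC")),
    ("HC/Adult IBD", ("HC",), ("Adult-CD", "Adult-UC")),
    ("HC/VEO UC", ("HC",), ("VEO-UC",)),
    ("HC/VEO CD", ("HC",), ("VEO-CD",)),
    ("HC/Adult UC", ("HC",), ("Adult-UC",)),
    ("HC/Adult CD", ("HC",), ("Adult-CD",)),
    ("Adult IBD/VEO IBD", ("Adult-CD", "Adult-UC"), ("VEO-CD", "VEO-UC")),
    ("Adult CD/VEO CD", ("Adult-CD",), ("VEO-CD",)),
    ("Adult UC/VEO UC", ("Adult-UC",), ("VEO-UC",)),
)


@dataclass(frozen=True)
class BurdenResult:
    """One gene-set x contrast Fisher burden row."""

    gene_set: str
    contrast: str
    del_b: int      # deleterious rare alleles in group B
    nondel_b: int
    del_a: int      # deleterious rare alleles in group A
    nondel_a: int
    oratio: float
    ci_lo: float
    ci_hi: float
    p: float


def filter_rare(
    variants: pd.DataFrame,
    maf_threshold: float = MAF_THRESHOLD,
    panel_rule: str = "all",
) -> pd.DataFrame:
    """Keep coding variants that are rare in the reference panels.

    A variant is retained iff its consequence is coding (synonymous retained
    at this stage) and it is novel, or its non-missing panel MAFs satisfy the
    panel rule: ``"all"`` requires every panel with data below ``maf_threshold``
    (strict), ``"any"`` requires at least one. Variants with no panel data and
    no novel flag are treated as novel (logged).
    """
    if not 0 < maf_threshold < 1:
        raise ValueError("maf_threshold must be in (0, 1)")
    if panel_rule not in ("all", "any"):
        raise ValueError("panel_rule must be 'all' or 'any'")
    coding = variants["consequence"].isin(CODING_CONSEQUENCES)
    mafs = variants[list(PANEL_COLUMNS)].to_numpy(float)
    has_data = ~np.isnan(mafs)
    no_data = ~has_data.any(axis=1)
    unflagged = no_data & ~variants["novel"].astype(bool)
    if unflagged.any():
        logger.warning("%d variants with no panel data and no novel flag treated as novel",
                       int(unflagged.sum()))
    below = np.where(has_data, mafs < maf_threshold, panel_rule == "all")
    rare_by_panel = below.all(axis=1) if panel_rule == "all" else below.any(axis=1)
    rare = variants["novel"].astype(bool) | no_data | rare_by_panel
    return variants[coding & rare]


def classify_deleterious(variants: pd.DataFrame, cadd_cutoff: float = CADD_CUTOFF) -> pd.Series:
    """Boolean deleteriousness per variant.

    Loss-of-function consequences are always deleterious; missense is
    deleterious iff CADD-PHRED > ``cadd_cutoff``; synonymous and other classes
    never are. Missense with a missing score counts as non-deleterious (logged).
    """
    lof = variants["consequence"].isin(LOF_CONSEQUENCES)
    missense = variants["consequence"] == "missense"
    cadd = variants["cadd"].to_numpy(float)
    no_score = missense & np.isnan(cadd)
    if no_score.any():
        logger.warning("%d missense variants without CADD score treated as non-deleterious",
                       int(no_score.sum()))
    with np.errstate(invalid="ignore"):
        damaging_missense = missense & (cadd > cadd_cutoff)
    return (lof | damaging_missense.fillna(False)).rename("deleterious")


def burden_table(
    table: ExomeVariantTable,
    rare_variants: pd.DataFrame,
    gene_set: list[str],
    group_a: np.ndarray,
    group_b: np.ndarray,
    cadd_cutoff: float = CADD_CUTOFF,
    unit: str = "alleles",
) -> tuple[int, int, int, int]:
    """Count (del_B, nondel_B, del_A, nondel_A) rare alleles in a gene set.

    ``group_a`` / ``group_b`` are boolean sample masks. ``unit="alleles"``
    counts minor-allele dosage (het 1, hom 2, missing 0); ``unit="carriers"``
    counts individuals carrying at least one allele.
    """
    if len(gene_set) == 0:
        raise EmptyGeneSetError("empty gene set")
    if unit not in ("alleles", "carriers"):
        raise ValueError("unit must be 'alleles' or 'carriers'")
    sub = rare_variants[rare_variants["gene"].isin(gene_set)]
    if len(sub) == 0:
        return (0, 0, 0, 0)
    rows = table.variants.index.get_indexer(sub.index)
    geno = table.genotypes[rows].astype(np.int64)
    geno = np.where(geno > 0, geno, 0)  # missing (-1) contributes nothing
    if unit == "carriers":
        geno = (geno > 0).astype(np.int64)
    deleterious = classify_deleterious(sub, cadd_cutoff).to_numpy()
    counts = []
    for mask in (group_b, group_a):
        totals = geno[:, mask].sum(axis=1)
        counts.append(int(totals[deleterious].sum()))
        counts.append(int(totals[~deleterious].sum()))
    return tuple(counts)  # type: ignore[return-value]


def fisher_burden(counts: tuple[int, int, int, int],
                  gene_set: str = "", contrast: str = "") -> BurdenResult:
    """Fisher exact test of a burden 2x2 (del_B, nondel_B, del_A, nondel_A).

    OR = odds(deleterious | B) / odds(deleterious | A), Haldane-corrected on
    zero cells, with a Woolf 95% CI. An all-zero table yields OR NaN, P = 1.
    """
    tt = test_table(*counts)
    return BurdenResult(
        gene_set=gene_set, contrast=contrast,
        del_b=tt.a, nondel_b=tt.b, del_a=tt.c, nondel_a=tt.d,
        oratio=tt.oratio, ci_lo=tt.ci_lo, ci_hi=tt.ci_hi, p=tt.p,
    )


def run_contrasts(
    table: ExomeVariantTable,
    gene_sets: dict[str, list[str]],
    maf_threshold: float = MAF_THRESHOLD,
    cadd_cutoff: float = CADD_CUTOFF,
    panel_rule: str = "all",
    unit: str = "alleles",
) -> pd.DataFrame:
    """The nine onset-group burden contrasts for each gene set, in table order.

    Requires all five groups (VEO-CD, VEO-UC, Adult-CD, Adult-UC, HC) in the
    sample metadata; a contrast whose group is empty yields NA statistics
    (logged) rather than failing the whole run.
    """
    present = set(table.samples["group"])
    required = {"VEO-CD", "VEO-UC", "Adult-CD", "Adult-UC", "HC"}
    if not required <= present:
        raise ValueError(f"missing exome groups: {sorted(required - present)}")
    rare = filter_rare(table.variants, maf_threshold, panel_rule)
    rows = []
    for set_name, genes in gene_sets.items():
        for label, groups_a, groups_b in CONTRASTS:
            mask_a = table.group_mask(list(groups_a))
            mask_b = table.group_mask(list(groups_b))
            if mask_a.sum() == 0 or mask_b.sum() == 0:
                logger.warning("contrast %s has an empty group; emitting NA", label)
                rows.append(BurdenResult(set_name, label, 0, 0, 0, 0,
                                         np.nan, np.nan, np.nan, np.nan))
                continue
            counts = burden_table(table, rare, genes, mask_a, mask_b,
                                  cadd_cutoff=cadd_cutoff, unit=unit)
            rows.append(fisher_burden(counts, gene_set=set_name, contrast=label))
    return pd.DataFrame([r.__dict__ for r in rows])


def recurrent_homozygotes(
    table: ExomeVariantTable,
    maf_threshold: float = MAF_THRESHOLD,
    cadd_cutoff: float = CADD_CUTOFF,
    min_children: int = 2,
) -> pd.DataFrame:
    """Deleterious rare variants homozygous in >= ``min_children`` VEO children
    and homozygous in zero adult patients and zero controls.

    Heterozygous carriage in adults or controls does not exclude a variant.
    Returns chrom, pos, gene, consequence and the child homozygote count.
    """
    rare = filter_rare(table.variants, maf_threshold)
    deleterious = rare[classify_deleterious(rare, cadd_cutoff)]
    if len(deleterious) == 0:
        return pd.DataFrame(columns=["chrom", "pos", "gene", "consequence", "n_child_hom"])
    rows = table.variants.index.get_indexer(deleterious.index)
    geno = table.genotypes[rows]
    veo = table.samples["onset"].to_numpy() == "pediatric"
    adult = table.samples["onset"].to_numpy() == "adult"
    hc = table.samples["diagnosis"].to_numpy() == "HC"
    hom = geno == 2
    child_hom = hom[:, veo].sum(axis=1)
    keep = (child_hom >= min_children) & (hom[:, adult].sum(axis=1) == 0) \
        & (hom[:, hc].sum(axis=1) == 0)
    out = deleterious.loc[keep, ["chrom", "pos", "gene", "consequence"]].copy()
    out["n_child_hom"] = child_hom[keep]
    return out.sort_values("n_child_hom", ascending=False).reset_index(drop=True)
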