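"""Individual-genotype validation of selected SNPs.

For each selected SNP and each of the nine diagnosis x onset comparisons,
alleles are counted from individual genotypes (a heterozygote contributes one
minor allele, a minor homozygote two), an allelic odds ratio with a Woolf 95%
confidence interval is computed (Haldane–Anscombe +0.5 on zero cells), and
the two-sided P comes from Fisher's exact test on the allele table. Alleles
are treated as independent, the usual convention behind single allelic ORs
(assumes HWE within arms).

Downstream annotations: Bonferroni correction over the SNP x comparison
tests, effect-size classes (small / moderate / strong, risk or protective),
direction-of-effect concordance with the pooled screen, and the
pediatric/adult sharing typology that sections the validated SNPs into
shared, age-unique and partially shared patterns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import MismatchedRecordsError
from .stats import expected_false_positives, test_table  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

NOMINAL_P = 0.05
OR_RISK_WINDOW = 1.2
OR_PROTECTIVE_WINDOW = 0.83

#: effect-size bins (open intervals, boundary values fall to the weaker class)
#: risk:       small 1.2 < OR < 1.5, moderate 1.5 < OR < 2.0, strong OR > 2.0
#: protective: small 0.63 < OR < 0.83, moderate 0.5 < OR < 0.63, strong OR < 0.5
RISK_EDGES = (1.2, 1.5, 2.0)
PROTECTIVE_EDGES = (0.83, 0.63, 0.5)


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP x comparison validation result."""

    site_id: str
    comparison: str
    a: int  # case minor alleles
    b: int  # case major alleles
    c: int  # control minor alleles
    d: int  # control major alleles
    oratio: float
    ci_lo: float
    ci_hi: float
    p: float
    nominal: bool
    corrected: bool = False
    effect_class: str = "none"
    effect_direction: str = ""
    direction: str = "0"


def _allele_counts(genotypes) -> tuple[int, int]:
    g = np.asarray(genotypes)
    g = g[(g >= 0) & ~np.isnan(g.astype(float))].astype(int)
    minor = int(g.sum())
    return minor, 2 * g.size - minor


def allelic_test(case_genotypes, control_genotypes,
                 site_id: str = "", comparison: str = "") -> AssociationRecord:
    """Allelic 2x2 test of one SNP: OR, Woolf CI, Fisher P, flags.

    Genotypes are minor-allele dosages in {0, 1, 2}; negative or NaN values
    are treated as missing calls and dropped. A SNP monomorphic in both arms
    has an undefined OR (NaN) and P = 1.
    """
    a, b = _allele_counts(case_genotypes)
    c, d = _allele_counts(control_genotypes)
    if a + b == 0 or c + d == 0:
        raise ValueError("both arms must contain genotyped samples")
    tt = test_table(a, b, c, d)
    oratio = tt.oratio
    nominal = bool(
        tt.p < NOMINAL_P
        and not np.isnan(oratio)
        and (oratio > OR_RISK_WINDOW or oratio < OR_PROTECTIVE_WINDOW)
    )
    eff_class, eff_dir = classify_effect_size(oratio) if not np.isnan(oratio) else ("none", "")
    direction = "0"
    if not np.isnan(oratio) and oratio != 1.0:
        direction = "+" if oratio > 1.0 else "-"
    return AssociationRecord(
        site_id=site_id, comparison=comparison,
        a=a, b=b, c=c, d=d,
        oratio=oratio, ci_lo=tt.ci_lo, ci_hi=tt.ci_hi, p=tt.p,
        nominal=nominal, effect_class=eff_class, effect_direction=eff_dir,
        direction=direction,
    )


def classify_effect_size(oratio: float) -> tuple[str, str]:
    """Bin an allelic OR into (class, direction).

    class in {none, small, moderate, strong}; direction ``risk`` for OR > 1.2,
    ``protective`` for OR < 0.83, empty for the null window [0.83, 1.2].
    Bins are open intervals; boundary values fall to the weaker class (so
    OR = 1.5 is small, OR = 0.63 is small, OR = 2.0 / 0.5 are moderate).
    """
    if np.isnan(oratio):
        raise ValueError("OR is undefined (NaN)")
    if oratio <= 0:
        raise ValueError("OR must be positive")
    if PROTECTIVE_EDGES[0] <= oratio <= RISK_EDGES[0]:
        return "none", ""
    if oratio > 1.0:
        if oratio > RISK_EDGES[2]:
            return "strong", "risk"
        if oratio > RISK_EDGES[1]:
            return "moderate", "risk"
        return "small", "risk"
    if oratio < PROTECTIVE_EDGES[2]:
        return "strong", "protective"
    if oratio < PROTECTIVE_EDGES[1]:
        return "moderate", "protective"
    return "small", "protective"


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def correct_multiple(
    records: list[AssociationRecord],
    method: str = "bonferroni",
    m: int | None = None,
    alpha: float = 0.05,
) -> tuple[list[AssociationRecord], int]:
    """Set corrected-significance flags: P < alpha / m (Bonferroni).

    ``m`` defaults to the number of records (SNPs x comparisons tested); pass
    the SNP count to correct over SNPs only. A warning is raised when m is
    smaller than the number of tests supplied.
    """
    if method != "bonferroni":
        raise ValueError(f"unsupported correction method: {method!r}")
    if m is None:
        m = len(records)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m < len(records):
        warnings.warn(
            f"correction uses m={m} < {len(records)} tests supplied", stacklevel=2
        )
    cut = alpha / m
    return [replace(r, corrected=bool(r.p < cut)) for r in records], m


def direction_concordance(screen_row: pd.Series, record: AssociationRecord) -> bool | None:
    """True iff the screen's frequency-difference sign matches sign(log OR).

    ``screen_row`` needs site_id, comparison, direction. Indeterminate cases
    (zero difference or OR exactly 1 / undefined) return None and are logged.
    """
    if (screen_row["site_id"] != record.site_id
            or screen_row["comparison"] != record.comparison):
        raise MismatchedRecordsError(
            f"screen {screen_row['site_id']}/{screen_row['comparison']} vs "
            f"validation {record.site_id}/{record.comparison}"
        )
    if screen_row["direction"] == "0" or record.direction == "0":
        logger.info("indeterminate direction for %s/%s", record.site_id, record.comparison)
        return None
    return screen_row["direction"] == record.direction


_PHENOTYPES = ("IBD", "CD", "UC")
_AGES = ("pediatric", "adult")


def sharing_typology(records: list[AssociationRecord]) -> pd.DataFrame:
    """Pediatric/adult sharing pattern per SNP.

    For each SNP, the six {IBD, CD, UC} x {pediatric, adult} cells are graded
    ``corrected`` > ``nominal`` > ``none`` (missing comparisons count as
    none). The category uses corrected-significant cells:

    * ``shared`` — some phenotype corrected-significant in both age strata,
    * ``pediatric_unique`` / ``adult_unique`` — corrected significance in
      exactly one age stratum,
    * ``partial`` — both strata significant but for disjoint phenotypes,
    * ``none`` — no corrected-significant cell.
    """
    status: dict[str, dict[tuple[str, str], str]] = {}
    for r in records:
        pheno, _, onset = r.comparison.partition(":")
        if pheno not in _PHENOTYPES or onset not in _AGES:
            continue
        grade = "corrected" if r.corrected else ("nominal" if r.nominal else "none")
        status.setdefault(r.site_id, {})[(pheno, onset)] = grade
    rows = []
    for site, cells in status.items():
        sig_ped = {ph for ph in _PHENOTYPES if cells.get((ph, "pediatric")) == "corrected"}
        sig_adu = {ph for ph in _PHENOTYPES if cells.get((ph, "adult")) == "corrected"}
        if not sig_ped and not sig_adu:
            category, phenos = "none", ""
        elif sig_ped & sig_adu:
            category, phenos = "shared", ",".join(sorted(sig_ped & sig_adu))
        elif not sig_adu:
            category, phenos = "pediatric_unique", ",".join(sorted(sig_ped))
        elif not sig_ped:
            category, phenos = "adult_unique", ",".join(sorted(sig_adu))
        else:
            category, phenos = "partial", ",".join(sorted(sig_ped | sig_adu))
        row = {"site_id": site, "category": category, "phenotypes": phenos}
        for ph in _PHENOTYPES:
            for age in _AGES:
                row[f"{ph}_{age}"] = cells.get((ph, age), "none")
        rows.append(row)
    cols = ["site_id", "category", "phenotypes"] + [
        f"{ph}_{age}" for ph in _PHENOTYPES for age in _AGES
    ]
    return pd.DataFrame(rows, columns=cols)


def validate_sites(
    genotypes,  # GenotypeMatrix
    site_ids: list[str],
    comparisons=None,
) -> list[AssociationRecord]:
    """Run the allelic test for each selected site in each comparison."""
    from .screen import nine_comparisons

    if comparisons is None:
        comparisons = nine_comparisons()
    idx = genotypes.site_ids.get_indexer(site_ids)
    missing = [s for s, i in zip(site_ids, idx) if i < 0]
    if missing:
        logger.warning("selected sites absent from validation panel, skipped: %s", missing)
    samples = genotypes.samples
    records = []
    for comp in comparisons:
        case_mask = (samples["diagnosis"].isin(comp.diagnoses)
                     & samples["onset"].isin(comp.onsets)).to_numpy()
        ctrl_mask = (samples["diagnosis"] == "HC").to_numpy()
        for site, i in zip(site_ids, idx):
            if i < 0:
                continue
            records.append(
                allelic_test(
                    genotypes.genotypes[case_mask, i],
                    genotypes.genotypes[ctrl_mask, i],
                    site_id=site,
                    comparison=comp.label,
                )
            )
    return records
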