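"""Selection of SNPs for individual-genotype validation.

Three criteria, applied to the pooled-screen results:

1. genome-wide significance: minimum P across the nine comparisons below
   5e-8 (strict),
2. LD blocks: maximal runs of >= 10 SNPs, each associated at P < 0.005, with
   every adjacent pair closer than 30 kb, represented by an "index SNP"
   (the minimum-P member, required to reach P < 1e-4),
3. a curated list (previously reported loci, MHC region), passed through
   with provenance.

Block contiguity is defined purely by adjacent-pair distance and per-SNP P;
no r2 is computed. Rare (MAF < 0.5%) and low-frequency (0.5-5%) selections
are flagged as probable false positives, since cohorts of this size cannot
produce genuine genome-wide signals at those frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UnsortedInputError

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
BLOCK_MIN_SIZE = 10
BLOCK_MAX_GAP_BP = 30_000
BLOCK_P_MEMBER = 0.005
BLOCK_P_INDEX = 1e-4

RARE_MAF = 0.005
LOW_FREQ_MAF = 0.05


@dataclass
class LDBlock:
    """A qualifying run of associated SNPs under one comparison."""

    block_id: str
    comparison: str
    chrom: str
    site_ids: list[str]
    positions: list[int]
    pvalues: list[float]
    index_site: str = field(init=False)
    index_p: float = field(init=False)

    def __post_init__(self) -> None:
        i = int(np.lexsort((self.positions, self.pvalues))[0])  # ties -> smallest pos
        self.index_site = self.site_ids[i]
        self.index_p = float(self.pvalues[i])

    @property
    def n_snps(self) -> int:
        return len(self.site_ids)

    @property
    def span(self) -> tuple[int, int]:
        return (self.positions[0], self.positions[-1])


def select_genomewide(results: pd.DataFrame, threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Sites whose minimum P across comparisons is strictly below ``threshold``.

    ``results`` is the long screen table (site_id, comparison, p, ...).
    Returns one row per selected site with ``min_p`` and the comma-joined
    qualifying comparisons. Empty input yields an empty frame.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if len(results) == 0:
        return pd.DataFrame(columns=["site_id", "min_p", "comparisons"])
    hits = results[results["p"] < threshold]
    if len(hits) == 0:
        return pd.DataFrame(columns=["site_id", "min_p", "comparisons"])
    out = (
        hits.groupby("site_id", sort=False)
        .agg(min_p=("p", "min"), comparisons=("comparison", lambda s: ",".join(sorted(s))))
        .reset_index()
    )
    return out


def find_blocks(
    results: pd.DataFrame,
    min_block_size: int = BLOCK_MIN_SIZE,
    max_gap_bp: int = BLOCK_MAX_GAP_BP,
    p_member: float = BLOCK_P_MEMBER,
    p_index: float = BLOCK_P_INDEX,
) -> list[LDBlock]:
    """LD-block detection for one comparison's results.

    ``results`` columns: site_id, chrom, pos, p (and optionally comparison,
    which must then be single-valued); rows must be sorted by (chrom, pos).

    A block is a maximal run of sites with P < ``p_member`` in which every
    adjacent pair of qualifying sites is < ``max_gap_bp`` apart; runs shorter
    than ``min_block_size`` are discarded, and a run is emitted only if its
    minimum P is <= ``p_index`` (the index SNP must be at least that
    significant). Member, gap and genome-wide thresholds are strict.
    Non-qualifying sites between qualifying ones do not break a run; only
    distance does.
    """
    comparison = ""
    if "comparison" in results.columns and len(results):
        labels = results["comparison"].unique()
        if len(labels) > 1:
            raise ValueError("find_blocks expects a single comparison; got " + str(labels))
        comparison = str(labels[0])
    for _, grp in results.groupby("chrom", sort=False):
        if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
            raise UnsortedInputError("sites must be sorted by (chrom, pos)")
    blocks: list[LDBlock] = []
    for chrom, grp in results.groupby("chrom", sort=False):
        q = grp[grp["p"] < p_member]
        if len(q) == 0:
            continue
        pos = q["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= max_gap_bp) + 1
        for run in np.split(np.arange(len(q)), breaks):
            if len(run) < min_block_size:
                continue
            sub = q.iloc[run]
            if sub["p"].min() > p_index:  # "at least at" 1e-4 -> inclusive
                continue
            blocks.append(
                LDBlock(
                    block_id=f"{comparison or 'blk'}:{chrom}:{int(sub['pos'].iloc[0])}",
                    comparison=comparison,
                    chrom=str(chrom),
                    site_ids=list(sub["site_id"]),
                    positions=[int(x) for x in sub["pos"]],
                    pvalues=[float(x) for x in sub["p"]],
                )
            )
    return blocks


def find_blocks_by_comparison(
    results: pd.DataFrame, sites: pd.DataFrame, **kwargs
) -> list[LDBlock]:
    """Run :func:`find_blocks` per comparison on the long screen table.

    ``sites`` supplies chrom/pos (columns site_id, chrom, pos); a site may
    index blocks under several comparisons.
    """
    merged = results.merge(sites[["site_id", "chrom", "pos"]], on="site_id", how="left")
    blocks: list[LDBlock] = []
    for label in merged["comparison"].unique():
        sub = merged[merged["comparison"] == label].sort_values(["chrom", "pos"])
        blocks.extend(find_blocks(sub, **kwargs))
    return blocks


def blocks_to_frame(blocks: list[LDBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (b.block_id, b.comparison, b.chrom, b.span[0], b.span[1],
             b.n_snps, b.index_site, b.index_p)
            for b in blocks
        ],
        columns=["block_id", "comparison", "chrom", "start", "end",
                 "n_snps", "index_snp", "index_p"],
    )


def classify_maf(maf: float) -> str:
    """rare (< 0.5%), low_frequency (0.5-5%, boundaries inclusive), common (> 5%)."""
    if not 0 <= maf <= 0.5:
        raise ValueError(f"MAF must lie in [0, 0.5], got {maf}")
    if maf < RARE_MAF:
        return "rare"
    if maf <= LOW_FREQ_MAF:
        return "low_frequency"
    return "common"


def flag_probable_false_positives(selected: pd.DataFrame) -> pd.DataFrame:
    """Flag rare/low-frequency selections as probable false positives.

    ``selected`` needs a ``maf`` column (NaN allowed). Adds ``maf_class`` and
    ``flag`` (``suspect`` for rare/low-frequency — under-powered cohorts cannot
    genuinely associate them genome-wide — ``unknown`` for missing MAF, empty
    for common).
    """
    out = selected.copy()
    maf = out["maf"]
    out["maf_class"] = [classify_maf(m) if pd.notna(m) else "" for m in maf]
    out["flag"] = [
        "unknown" if pd.isna(m) else ("suspect" if classify_maf(m) != "common" else "")
        for m in maf
    ]
    return out


def curated_selection(site_ids: list[str], panel_site_ids) -> pd.DataFrame:
    """Pass through a configured list of sites with provenance ``curated``.

    Unknown IDs are logged and skipped, not fatal.
    """
    known = pd.Index(panel_site_ids)
    missing = [s for s in site_ids if s not in known]
    if missing:
        logger.warning("curated sites absent from panel, skipped: %s", missing)
    kept = [s for s in site_ids if s in known]
    return pd.DataFrame({"site_id": kept, "provenance": "curated"})


def combined_selection(
    genomewide: pd.DataFrame,
    blocks: list[LDBlock],
    curated: pd.DataFrame,
    site_mafs: pd.Series | None = None,
) -> pd.DataFrame:
    """Union of the three criteria with provenance and MAF flags.

    Provenance priority when a site qualifies several ways:
    genomewide > block_index > curated (first criterion that selected it).
    """
    frames = []
    if len(genomewide):
        frames.append(pd.DataFrame({"site_id": genomewide["site_id"], "provenance": "genomewide"}))
    if blocks:
        frames.append(pd.DataFrame({
            "site_id": sorted({b.index_site for b in blocks}), "provenance": "block_index"
        }))
    if len(curated):
        frames.append(curated[["site_id", "provenance"]])
    if not frames:
        out = pd.DataFrame(columns=["site_id", "provenance"])
    else:
        out = pd.concat(frames, ignore_index=True).drop_duplicates("site_id", keep="first")
    out = out.reset_index(drop=True)
    if site_mafs is not None:
        out["maf"] = out["site_id"].map(site_mafs)
        out = flag_probable_false_positives(out)
    return out
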