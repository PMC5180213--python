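"""End-to-end orchestration: simulate -> screen -> select -> validate -> burden.

A run is fully specified by a :class:`RunConfig` (one YAML document with a
mandatory seed); identical config + seed reproduces byte-identical outputs.
Every output TSV carries the config hash in a ``#`` header line, and the JSON
run report records per-stage row counts, selection provenance tallies,
significance counts, the sharing typology summary and the burden tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assoc, burden, io, screen, select, simulate
from .errors import ConfigError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "screen", "select", "validate", "burden")


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    seed: int
    out_dir: str = "ibdarch_run"
    stages: tuple[str, ...] = STAGES

    # panel / genotype simulation
    n_blocks: int = 40
    block_size: int = 15
    snp_spacing_bp: int = 2_000
    block_gap_bp: int = 50_000
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: planted effects: {site_id: {stratum: OR}}
    effects: dict = field(default_factory=dict)

    # cohorts (screening and enlarged validation stage)
    screen_cohort: dict = field(default_factory=lambda: {
        "n_cd_pediatric": 356, "n_cd_adult": 238,
        "n_uc_pediatric": 311, "n_uc_adult": 260, "n_hc": 724,
    })
    validation_cohort: dict = field(default_factory=lambda: {
        "n_cd_pediatric": 424, "n_cd_adult": 337,
        "n_uc_pediatric": 390, "n_uc_adult": 344, "n_hc": 934,
    })

    # pooling and array noise
    pool_policy: dict | None = None
    pool_remainder: str = "absorb"
    noise_sd: float = 0.02
    k_bias: float = 1.0

    # selection thresholds
    genomewide_p: float = select.GENOME_WIDE_P
    block_min_size: int = select.BLOCK_MIN_SIZE
    block_max_gap_bp: int = select.BLOCK_MAX_GAP_BP
    block_p_member: float = select.BLOCK_P_MEMBER
    block_p_index: float = select.BLOCK_P_INDEX
    curated_sites: list = field(default_factory=list)

    # validation
    correction_scope: str = "tests"  # "tests" (SNPs x comparisons) or "snps"

    # exome arm
    exome_group_sizes: dict = field(default_factory=lambda: {
        "VEO-CD": 21, "VEO-UC": 22, "Adult-CD": 23, "Adult-UC": 22, "HC": 18,
    })
    exome_enrichment: dict = field(default_factory=dict)
    exome_genes_per_set: int = 150
    maf_threshold: float = burden.MAF_THRESHOLD
    cadd_cutoff: float = burden.CADD_CUTOFF
    panel_rule: str = "all"
    burden_unit: str = "alleles"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not 0 < self.genomewide_p < 1 or not 0 < self.block_p_member < 1:
            raise ConfigError("P thresholds must lie in (0, 1)")
        if not 0 <= self.ld_rho <= 1:
            raise ConfigError("ld_rho must lie in [0, 1]")
        if self.correction_scope not in ("tests", "snps"):
            raise ConfigError("correction_scope must be 'tests' or 'snps'")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = io.load_yaml(path) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def demo(cls, seed: int = 17, out_dir: str = "ibdarch_demo") -> "RunConfig":
        """A small end-to-end run: 600-site panel with planted effects.

        Plants a strong shared IBD locus (block 2), a pediatric-specific CD
        locus (block 12) and an adult-specific UC locus (block 25), each as a
        full LD block so the block-selection criterion fires.
        """
        effects: dict[str, dict[str, float]] = {}
        for base, strata in (
            (2 * 15, {"CD:pediatric": 2.6, "CD:adult": 2.6, "UC:pediatric": 2.6, "UC:adult": 2.6}),
            (12 * 15, {"CD:pediatric": 2.5}),
            (25 * 15, {"UC:adult": 2.5}),
        ):
            for k in range(15):
                effects[f"site{base + k:05d}"] = dict(strata)
        return cls(seed=seed, out_dir=out_dir, effects=effects)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output path excluded)."""
        payload = asdict(self)
        payload.pop("out_dir")
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages in order; returns the run report dict.

    Intermediate artifacts are written under ``out_dir`` (default from the
    config). Seeds for each stage are spawned deterministically from the
    config seed.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seeds = _stage_seeds(config.seed)
    report: dict = {
        "version": __version__,
        "config_hash": chash,
        "seed": config.seed,
        "stages": list(config.stages),
        "counts": {},
    }

    panel = simulate.build_panel(
        [(f"b{i:03d}", config.block_size, config.snp_spacing_bp, config.block_gap_bp)
         for i in range(config.n_blocks)],
        ld_rho=config.ld_rho, maf_range=tuple(config.maf_range), seed=seeds["panel"],
    )
    effects = simulate.EffectSpec.from_dict(config.effects) if config.effects \
        else simulate.EffectSpec()

    screen_results = None
    selection = None
    pools = None

    try:
        if "simulate" in config.stages:
            cohort = simulate.build_cohort(**config.screen_cohort, seed=seeds["cohort"], prefix="G")
            gm = simulate.simulate_genotypes(panel, effects, cohort, seeds["genotypes"])
            pools = simulate.build_pools(cohort, config.pool_policy, seed=seeds["pools"],
                                         remainder=config.pool_remainder)
            intensities = simulate.simulate_pool_intensities(
                pools, gm, noise_sd=config.noise_sd, k_bias=config.k_bias,
                seed=seeds["intensities"],
            )
            io.write_pools(pools, out / "pools.tsv", out / "pool_members.tsv", chash)
            io.write_pool_intensities(intensities, out / "pool_intensities.tsv", chash)
            io.write_table(cohort, out / "screen_cohort.tsv", chash)
            report["counts"]["screen_samples"] = len(cohort)
            report["counts"]["pools"] = pools.n_pools
            report["counts"]["sites"] = panel.n_sites

        if "screen" in config.stages:
            freqs = screen.estimate_pool_frequencies(intensities)
            screen_results = screen.run_screen(freqs, pools)
            io.write_table(screen_results, out / "screen_results.tsv", chash)
            report["counts"]["screen_rows"] = len(screen_results)

        if "select" in config.stages:
            gw = select.select_genomewide(screen_results, config.genomewide_p)
            blocks = select.find_blocks_by_comparison(
                screen_results, panel.sites,
                min_block_size=config.block_min_size,
                max_gap_bp=config.block_max_gap_bp,
                p_member=config.block_p_member,
                p_index=config.block_p_index,
            )
            curated = select.curated_selection(list(config.curated_sites), panel.site_ids)
            site_mafs = panel.sites.set_index("site_id")["maf"]
            selection = select.combined_selection(gw, blocks, curated, site_mafs)
            io.write_table(select.blocks_to_frame(blocks), out / "blocks.tsv", chash)
            io.write_table(selection, out / "selection.tsv", chash)
            report["counts"]["blocks"] = len(blocks)
            report["selection_provenance"] = (
                selection["provenance"].value_counts().to_dict() if len(selection) else {}
            )
            report["counts"]["selected_sites"] = len(selection)

        if "validate" in config.stages:
            vcohort = simulate.build_cohort(**config.validation_cohort,
                                            seed=seeds["vcohort"], prefix="V")
            vgm = simulate.simulate_genotypes(panel, effects, vcohort, seeds["vgenotypes"])
            site_ids = list(selection["site_id"]) if selection is not None else []
            records = assoc.validate_sites(vgm, site_ids)
            m = len({r.site_id for r in records}) if config.correction_scope == "snps" \
                else len(records)
            records, m = assoc.correct_multiple(records, m=max(m, 1))
            vdf = assoc.records_to_frame(records)
            typology = assoc.sharing_typology(records)
            concordance = _screen_concordance(screen_results, records)
            io.write_table(vdf, out / "validation.tsv", chash)
            io.write_table(typology, out / "sharing_typology.tsv", chash)
            report["counts"]["validation_tests"] = len(records)
            report["correction_m"] = m
            report["counts"]["corrected_significant_snps"] = int(
                vdf[vdf["corrected"]]["site_id"].nunique()) if len(vdf) else 0
            report["counts"]["nominal_snps"] = int(
                vdf[vdf["nominal"]]["site_id"].nunique()) if len(vdf) else 0
            report["sharing_typology"] = (
                typology["category"].value_counts().to_dict() if len(typology) else {}
            )
            report["direction_concordance"] = concordance

        if "burden" in config.stages:
            gene_sets = simulate.default_gene_sets(config.exome_genes_per_set)
            espec = simulate.ExomeSimSpec(
                group_sizes=dict(config.exome_group_sizes),
                gene_sets=gene_sets,
                enrichment=config.exome_enrichment,
            )
            etable = simulate.simulate_exomes(espec, seeds["exomes"])
            bdf = burden.run_contrasts(
                etable, gene_sets, maf_threshold=config.maf_threshold,
                cadd_cutoff=config.cadd_cutoff, panel_rule=config.panel_rule,
                unit=config.burden_unit,
            )
            recur = burden.recurrent_homozygotes(etable, config.maf_threshold,
                                                 config.cadd_cutoff)
            io.write_exome_vcf(etable, out / "exome.vcf")
            io.write_exome_tsv(etable, out / "exome_variants.tsv",
                               out / "exome_genotypes.tsv", out / "exome_samples.tsv", chash)
            io.write_gmt(gene_sets, out / "gene_sets.gmt")
            io.write_table(bdf, out / "burden.tsv", chash)
            io.write_table(recur, out / "recurrent_homozygotes.tsv", chash)
            report["counts"]["exome_variants"] = len(etable.variants)
            report["counts"]["burden_rows"] = len(bdf)
            report["counts"]["recurrent_homozygotes"] = len(recur)
            report["burden"] = bdf.to_dict(orient="records")
    except Exception as exc:
        stage = _current_stage(report)
        logger.error("pipeline aborted in stage %r: %s", stage, exc)
        raise

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _current_stage(report: dict) -> str:
    done = report["counts"].keys()
    if "burden_rows" in done:
        return "burden"
    if "validation_tests" in done:
        return "validate"
    if "selected_sites" in done:
        return "select"
    if "screen_rows" in done:
        return "screen"
    return "simulate"


def _screen_concordance(screen_results, records) -> dict:
    """Direction-of-effect agreement between screen and validation."""
    if screen_results is None or not len(records):
        return {"checked": 0, "concordant": 0}
    indexed = screen_results.set_index(["site_id", "comparison"])
    checked = concordant = 0
    for r in records:
        key = (r.site_id, r.comparison)
        if key not in indexed.index:
            continue
        row = indexed.loc[key]
        res = assoc.direction_concordance(
            pd.Series({"site_id": r.site_id, "comparison": r.comparison,
                       "direction": row["direction"]}), r)
        if res is None:
            continue
        checked += 1
        concordant += int(res)
    return {"checked": checked, "concordant": concordant}


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("panel", "cohort", "genotypes", "pools", "intensities",
             "vcohort", "vgenotypes", "exomes")
    ss = np.random.SeedSequence(seed).spawn(len(names))
    return {name: int(s.generate_state(1, np.uint32)[0] % (2**31))
            for name, s in zip(names, ss)}


def summarize(report: dict) -> str:
    """Human-readable run summary keyed to the reporting vocabulary."""
    lines = [
        f"ibdarch {report.get('version', '?')} run (seed {report.get('seed')}, "
        f"config {report.get('config_hash')})",
    ]
    counts = report.get("counts", {})
    for key in sorted(counts):
        lines.append(f"  {key:28s} {counts[key]}")
    if "selection_provenance" in report:
        prov = ", ".join(f"{k}={v}" for k, v in sorted(report["selection_provenance"].items()))
        lines.append(f"  selection provenance         {prov or 'none'}")
    if "correction_m" in report:
        lines.append(f"  Bonferroni m                 {report['correction_m']}")
    if "sharing_typology" in report:
        typ = ", ".join(f"{k}={v}" for k, v in sorted(report["sharing_typology"].items()))
        lines.append(f"  sharing typology             {typ or 'none'}")
    if "direction_concordance" in report:
        dc = report["direction_concordance"]
        lines.append(f"  direction concordance        {dc['concordant']}/{dc['checked']}")
    return "\n".join(lines)
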