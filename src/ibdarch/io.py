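"""Readers and writers for the pipeline's on-disk artifacts.

Tabular artifacts are TSV with an optional ``#`` comment header carrying the
package version and run-config hash. The exome table round-trips through a
minimal VCF (written with pysam, read with cyvcf2) carrying GENE, CSQ, CADD,
MAF_1KGP, MAF_ESP, MAF_EXAC and NOVEL INFO keys plus per-sample GT; gene
sets use GMT (set name, description, genes, tab-separated) or one-gene-per-
line text. Positions are 1-based throughout, as in VCF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .simulate import ExomeVariantTable, GenotypeMatrix, PoolIntensities, PoolSet


def write_table(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash is not None:
            from . import __version__

            fh.write(f"# ibdarch {__version__} config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# --- genotypes -------------------------------------------------------------


def write_genotypes(gm: GenotypeMatrix, geno_path, meta_path, sites_path,
                    config_hash: str | None = None) -> None:
    wide = pd.DataFrame(gm.genotypes, columns=list(gm.site_ids))
    wide.insert(0, "sample_id", gm.samples["sample_id"].to_numpy())
    write_table(wide, geno_path, config_hash)
    write_table(gm.samples, meta_path, config_hash)
    write_table(gm.sites, sites_path, config_hash)


def read_genotypes(geno_path, meta_path, sites_path) -> GenotypeMatrix:
    wide = read_table(geno_path)
    samples = read_table(meta_path)
    sites = read_table(sites_path, dtype={"chrom": str, "block_id": str})
    geno = wide.drop(columns="sample_id").to_numpy(np.int8)
    samples = samples.set_index("sample_id").loc[wide["sample_id"]].reset_index()
    return GenotypeMatrix(geno, samples, sites)


# --- pools -----------------------------------------------------------------


def write_pools(pools: PoolSet, pools_path, membership_path,
                config_hash: str | None = None) -> None:
    write_table(pools.pools, pools_path, config_hash)
    write_table(pools.membership, membership_path, config_hash)


def read_pools(pools_path, membership_path) -> PoolSet:
    return PoolSet(read_table(pools_path), read_table(membership_path))


def write_pool_intensities(pi: PoolIntensities, path, config_hash: str | None = None) -> None:
    """Long format: pool_id, site_id, intensity_a, intensity_b."""
    n_pools, n_sites = pi.a.shape
    df = pd.DataFrame({
        "pool_id": np.repeat(pi.pool_ids, n_sites),
        "site_id": np.tile(pi.site_ids, n_pools),
        "intensity_a": pi.a.ravel(),
        "intensity_b": pi.b.ravel(),
    })
    write_table(df, path, config_hash)


def read_pool_intensities(path, k_bias: float = 1.0, noise_sd: float = float("nan")) -> PoolIntensities:
    df = read_table(path)
    wide_a = df.pivot(index="pool_id", columns="site_id", values="intensity_a")
    wide_b = df.pivot(index="pool_id", columns="site_id", values="intensity_b")
    # preserve file order of first appearance rather than pivot's sort
    pool_order = df["pool_id"].drop_duplicates()
    site_order = df["site_id"].drop_duplicates()
    wide_a = wide_a.loc[pool_order, site_order]
    wide_b = wide_b.loc[pool_order, site_order]
    return PoolIntensities(
        pool_ids=pd.Index(wide_a.index), site_ids=pd.Index(wide_a.columns),
        a=wide_a.to_numpy(), b=wide_b.to_numpy(), k_bias=k_bias, noise_sd=noise_sd,
    )


# --- exome VCF / TSV -------------------------------------------------------

_INFO_FIELDS = (
    ("GENE", "String", "Gene symbol"),
    ("CSQ", "String", "Consequence class"),
    ("CADD", "Float", "CADD PHRED-scaled deleteriousness score"),
    ("MAF_1KGP", "Float", "1000 Genomes minor allele frequency"),
    ("MAF_ESP", "Float", "NHLBI ESP European-American minor allele frequency"),
    ("MAF_EXAC", "Float", "ExAC minor allele frequency"),
    ("NOVEL", "Flag", "Absent from all reference panels"),
)
_MAF_KEYS = {"MAF_1KGP": "maf_1kgp", "MAF_ESP": "maf_esp", "MAF_EXAC": "maf_exac"}


def write_exome_vcf(table: ExomeVariantTable, path) -> None:
    header = pysam.VariantHeader()
    for chrom in pd.unique(table.variants["chrom"]) if len(table.variants) else ["1"]:
        header.contigs.add(str(chrom), length=2_000_000_000)
    for name, typ, desc in _INFO_FIELDS:
        header.info.add(name, "0" if typ == "Flag" else "1", typ, desc)
    header.formats.add("GT", "1", "String", "Genotype")
    for sid in table.samples["sample_id"]:
        header.add_sample(sid)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, row in table.variants.reset_index(drop=True).iterrows():
            rec = vcf.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                alleles=(row["ref"], row["alt"]), id=row["var_id"],
            )
            rec.info["GENE"] = row["gene"]
            rec.info["CSQ"] = row["consequence"]
            if pd.notna(row["cadd"]):
                rec.info["CADD"] = float(row["cadd"])
            if bool(row["novel"]):
                rec.info["NOVEL"] = True
            for key, col in _MAF_KEYS.items():
                if pd.notna(row[col]):
                    rec.info[key] = float(row[col])
            for j, sid in enumerate(table.samples["sample_id"]):
                g = int(table.genotypes[i, j])
                rec.samples[sid]["GT"] = (None, None) if g < 0 else ((g + 1) // 2, g // 2)
            vcf.write(rec)


def read_exome_vcf(path, samples: pd.DataFrame | None = None) -> ExomeVariantTable:
    """Read a minimal annotated VCF into an ExomeVariantTable.

    ``samples`` supplies group/diagnosis/onset metadata per sample_id; if
    omitted, metadata columns are left empty and must be joined later.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, genos = [], []
    for i, v in enumerate(vcf):
        info = dict(v.INFO)
        rows.append({
            "var_id": v.ID or f"var{i:05d}",
            "chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0],
            "gene": info.get("GENE", ""), "consequence": info.get("CSQ", "other"),
            "cadd": float(info["CADD"]) if "CADD" in info else np.nan,
            "maf_1kgp": float(info["MAF_1KGP"]) if "MAF_1KGP" in info else np.nan,
            "maf_esp": float(info["MAF_ESP"]) if "MAF_ESP" in info else np.nan,
            "maf_exac": float(info["MAF_EXAC"]) if "MAF_EXAC" in info else np.nan,
            "novel": bool(info.get("NOVEL", False)),
        })
        gt = np.asarray(v.genotypes)[:, :2].astype(int)
        dosage = np.where((gt < 0).any(axis=1), -1, gt.clip(min=0).sum(axis=1))
        genos.append(dosage.astype(np.int8))
    vcf.close()
    variants = pd.DataFrame(rows, columns=[
        "var_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
        "cadd", "maf_1kgp", "maf_esp", "maf_exac", "novel",
    ])
    geno = np.vstack(genos) if genos else np.empty((0, len(sample_ids)), np.int8)
    if samples is None:
        samples = pd.DataFrame({"sample_id": sample_ids, "group": "",
                                "diagnosis": "", "onset": ""})
    else:
        samples = samples.set_index("sample_id").loc[sample_ids].reset_index()
    return ExomeVariantTable(variants, geno, samples)


def write_exome_tsv(table: ExomeVariantTable, variants_path, genotypes_path, samples_path,
                    config_hash: str | None = None) -> None:
    write_table(table.variants, variants_path, config_hash)
    wide = pd.DataFrame(table.genotypes, columns=list(table.samples["sample_id"]))
    wide.insert(0, "var_id", table.variants["var_id"].to_numpy())
    write_table(wide, genotypes_path, config_hash)
    write_table(table.samples, samples_path, config_hash)


# --- gene sets -------------------------------------------------------------


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "ibdarch"] + list(genes)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        sets[parts[0]] = parts[2:]
    return sets


def read_gene_list(path) -> list[str]:
    """One-gene-per-line text file; blank lines and '#' comments skipped."""
    return [
        ln.strip() for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
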