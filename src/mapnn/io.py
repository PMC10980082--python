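"""File formats: VCF and 012 genotype tables, location CSVs, run configs.

Genotype input is either a VCF (v4.2, diploid biallelic GT records, no
missing calls - mirroring a complete-sites filter) or a plain
tab-separated 012 table with a header row of site positions and one row
per sample.  Both produce identical minor-allele matrices on equivalent
content.  Locations are CSV with columns id, x, y in planar map units and
are aligned to the genotype matrix's sample order on read.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import pathlib
import warnings

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix, minor_allele_code


__all__ = [
    "read_genotypes",
    "read_vcf",
    "read_012",
    "write_vcf",
    "write_012",
    "read_locations",
    "write_locations",
    "RunConfig",
]


def read_genotypes(path):
    """Read a VCF or 012 table into a minor-allele GenotypeMatrix + ids."""
    path = pathlib.Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return read_vcf(path)
    return read_012(path)


def read_vcf(path):
    """Diploid biallelic VCF -> (GenotypeMatrix, sample ids).

    Raises on missing genotypes (naming the site) and on non-biallelic
    records; both phased and unphased GT separators are accepted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    positions = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"non-biallelic site at {variant.CHROM}:{variant.POS}"
            )
        gts = variant.genotype.array()
        alleles = gts[:, :2]
        if np.any(alleles < 0):
            raise ValueError(
                f"missing genotype at {variant.CHROM}:{variant.POS}"
            )
        rows.append(alleles.sum(axis=1))
        positions.append(variant.POS)
    if not rows:
        raise ValueError(f"no variant records in {path}")
    raw = np.column_stack(rows)  # (n_samples, n_sites) alt-allele counts
    return minor_allele_code(raw, positions=np.asarray(positions, float)), samples


def read_012(path):
    """Tab-separated 012 table: header of positions, one row per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    raw = df.to_numpy()
    if np.any(pd.isna(raw)):
        raise ValueError(f"missing genotype entries in {path}")
    positions = np.asarray([float(c) for c in df.columns])
    return minor_allele_code(raw.astype(int), positions=positions), list(df.index)


def write_012(path, gm: GenotypeMatrix, sample_ids) -> None:
    df = pd.DataFrame(
        gm.values,
        index=sample_ids,
        columns=[f"{p:.0f}" for p in gm.positions],
    )
    df.to_csv(path, sep="\t", index_label="id")


def write_vcf(path, gm: GenotypeMatrix, sample_ids, chrom: str = "1") -> None:
    """Write a minimal VCFv4.2 with unphased diploid GT records."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(str(s) for s in sample_ids),
    ]
    codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j in range(gm.n_snps):
        pos = int(round(gm.positions[j])) or 1
        gts = "\t".join(codes[int(g)] for g in gm.values[:, j])
        lines.append(f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}")
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def read_locations(path, sample_ids=None):
    """Location CSV (id, x, y) -> (n, 2) array aligned to ``sample_ids``.

    Extra rows are dropped with a warning; ids missing from the file raise
    an error listing the offenders.
    """
    df = pd.read_csv(path)
    required = {"id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"locations file must have columns {sorted(required)}")
    df["id"] = df["id"].astype(str)
    if sample_ids is None:
        return df[["x", "y"]].to_numpy(float), list(df["id"])
    wanted = [str(s) for s in sample_ids]
    table = df.set_index("id")
    missing = [s for s in wanted if s not in table.index]
    if missing:
        raise ValueError(f"locations missing for samples: {missing}")
    extra = set(table.index) - set(wanted)
    if extra:
        warnings.warn(f"dropping {len(extra)} location rows without genotypes")
    aligned = table.loc[wanted, ["x", "y"]].to_numpy(float)
    return aligned, wanted


def write_locations(path, locations, sample_ids) -> None:
    pd.DataFrame(
        {"id": sample_ids, "x": locations[:, 0], "y": locations[:, 1]}
    ).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Resolved parameters of a full pipeline run; round-trips via YAML."""

    out_dir: str = "runs/demo"
    seed: int = 0
    # maps
    n_maps: int = 5
    width: int = 8
    k_min: float = 4.0
    k_max: float = 40.0
    sigma_min: float = 0.73
    sigma_max: float = 3.08
    max_degree: int = 3
    # simulation
    sigma_m: float = 1.0
    sigma_c: float = 1.0
    lifetime: float = 4.0
    n_generations: int = 100
    burn_in: int = 0
    # sampling / genotypes
    scheme: str = "uniform"
    n_samples: int = 10
    n_snps: int = 200
    # network / training
    k_init: int = 40
    k_extract: int = 40
    feature_width: int = 8
    batch_size: int = 10
    learning_rate: float = 1e-3
    val_frac: float = 0.2
    max_epochs: int = 3
    # bootstrap
    n_bootstrap: int = 0

    def save(self, path) -> None:
        pathlib.Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(pathlib.Path(path).read_text()))
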