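"""Readers and writers for every artefact format.

Canonical interchange formats are plain text: a tab-delimited genotype
matrix (header row of individual ids, first columns marker/chrom/pos_cM,
missing = "NA", population labels on a '#population' comment line), a
three-column map TSV, a long-format phenotype CSV, matrices as TSV with
row/column ids, and JSON for ground truth and reports.  A minimal VCF 4.2
export/import (GT only, unphased) is provided for interoperability.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, GeneticMap, GenotypeMatrix

PHENO_COLUMNS = ["genotype", "population", "condition", "replicate", "block", "trait", "value"]


# ---------------------------------------------------------------------------
# genotype matrix TSV
# ---------------------------------------------------------------------------

def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    path = Path(path)
    tab = genotypes.gmap.table
    with open(path, "w") as fh:
        fh.write("marker\tchrom\tpos_cM\t" + "\t".join(map(str, genotypes.individuals)) + "\n")
        fh.write("#population\t\t\t" + "\t".join(map(str, genotypes.populations)) + "\n")
        for m in range(genotypes.n_markers):
            row = genotypes.genotypes[m]
            calls = "\t".join("NA" if v == MISSING else str(int(v)) for v in row)
            fh.write(
                f"{tab['marker'].iat[m]}\t{tab['chrom'].iat[m]}\t{tab['pos_cM'].iat[m]:.6g}\t{calls}\n"
            )


def read_genotypes(path) -> GenotypeMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        second = fh.readline().rstrip("\n")
    individuals = header[3:]
    if second.startswith("#population"):
        populations = second.split("\t")[3:]
        skiprows = [1]
    else:
        populations = ["pop"] * len(individuals)
        skiprows = []
    df = pd.read_csv(path, sep="\t", skiprows=skiprows, na_values=["NA"])
    gmap = GeneticMap(df[["chrom", "marker", "pos_cM"]])
    calls = df[individuals].to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix(calls, individuals, np.asarray(populations, dtype=object), gmap)


# ---------------------------------------------------------------------------
# genetic map TSV
# ---------------------------------------------------------------------------

def write_map(gmap: GeneticMap, path) -> None:
    gmap.table[["chrom", "marker", "pos_cM"]].to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# phenotypes CSV
# ---------------------------------------------------------------------------

def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno[PHENO_COLUMNS].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
    return df[PHENO_COLUMNS]


# ---------------------------------------------------------------------------
# matrices, lists, reports
# ---------------------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


def write_marker_list(markers, path) -> None:
    Path(path).write_text("\n".join(map(str, markers)) + "\n")


def read_marker_list(path) -> list:
    return [l for l in Path(path).read_text().splitlines() if l]


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"cannot serialise {type(o)}")


# ---------------------------------------------------------------------------
# minimal VCF 4.2 (GT only, unphased)
# ---------------------------------------------------------------------------

_CM_SCALE = 10_000  # cM -> integer bp-like coordinate


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write genotype calls as a minimal VCF 4.2 with unphased GT fields.

    Integer positions are the cM coordinate scaled by 1e4 (1-based); the
    exact cM value is kept in the INFO field ``CM``."""
    tab = genotypes.gmap.table
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Map position in cM">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in genotypes.gmap.chromosomes:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.individuals))
            + "\n"
        )
        for m in range(genotypes.n_markers):
            pos = int(round(tab["pos_cM"].iat[m] * _CM_SCALE)) + 1
            calls = "\t".join(gt_map[int(v)] for v in genotypes.genotypes[m])
            fh.write(
                f"{tab['chrom'].iat[m]}\t{pos}\t{tab['marker'].iat[m]}\tA\tT\t.\t.\t"
                f"CM={tab['pos_cM'].iat[m]:.6g}\tGT\t{calls}\n"
            )


def read_vcf(path, populations=None) -> GenotypeMatrix:
    """Read a GT-only VCF back into a genotype matrix (cyvcf2 backend)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, calls = [], []
    for var in vcf:
        cm = var.INFO.get("CM")
        pos = float(cm) if cm is not None else (var.POS - 1) / _CM_SCALE
        rows.append((var.CHROM, var.ID, pos))
        arr = np.asarray(var.genotypes, dtype=object)
        out = np.empty(len(individuals), dtype=np.int8)
        for j, gt in enumerate(arr):
            a = [x for x in gt[:-1]]
            if any(x < 0 for x in a):
                out[j] = MISSING
            else:
                out[j] = int(sum(a))
        calls.append(out)
    gmap = GeneticMap(pd.DataFrame(rows, columns=["chrom", "marker", "pos_cM"]))
    pops = (
        np.asarray(populations, dtype=object)
        if populations is not None
        else np.repeat("pop", len(individuals))
    )
    return GenotypeMatrix(np.vstack(calls), individuals, pops, gmap)
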