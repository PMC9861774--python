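"""Plain-text genotype and table I/O.

Genotype panels are stored in a transposed-dosage text dialect (one SNP per
row, one column per sample, ``NA`` for missing calls) together with
``.bim``-style variant metadata (chrom, id, cM=0, pos, allele1, allele2) and a
``.fam``-style sample table (id, cohort, sex).  Clinical and follow-up tables
are plain CSV with documented headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import GenotypeMatrix

DOSAGE_SUFFIX = ".dose.tsv"
BIM_SUFFIX = ".bim"
FAM_SUFFIX = ".fam"

#: follow-up CSV header (one row per patient, 2-year observation window)
FOLLOWUP_COLUMNS = [
    "patient_id",
    "relapse_count_2y",
    "new_t2_flag",
    "gdplus_flag",
    "active_t2_count_2y",
    "edss_baseline",
    "edss_2y",
    "months_since_ntz_stop",
]


def write_genotypes(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a genotype panel as ``<prefix>.dose.tsv`` / ``.bim`` / ``.fam``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bim = pd.DataFrame(
        {
            "chrom": gm.variants["chrom"],
            "id": gm.variants["id"],
            "cm": 0,
            "pos": gm.variants["pos"],
            "allele1": gm.variants["allele1"],
            "allele2": gm.variants["allele2"],
        }
    )
    bim.to_csv(Path(str(prefix) + BIM_SUFFIX), sep="\t", header=False, index=False)
    gm.samples.to_csv(Path(str(prefix) + FAM_SUFFIX), sep="\t", index=False)

    with open(str(prefix) + DOSAGE_SUFFIX, "w") as fh:
        fh.write("snp_id\t" + "\t".join(gm.samples["id"].astype(str)) + "\n")
        for j, snp in enumerate(gm.variants["id"]):
            row = gm.dosage[:, j]
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(str(snp) + "\t" + "\t".join(cells) + "\n")


def read_genotypes(prefix: str | Path) -> GenotypeMatrix:
    """Read a genotype panel written by :func:`write_genotypes`."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        Path(str(prefix) + BIM_SUFFIX),
        sep="\t",
        header=None,
        names=["chrom", "id", "cm", "pos", "allele1", "allele2"],
        dtype={"id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(Path(str(prefix) + FAM_SUFFIX), sep="\t", dtype={"id": str})
    dose = pd.read_csv(
        str(prefix) + DOSAGE_SUFFIX, sep="\t", index_col=0, na_values=["NA"]
    )
    variants = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"],
            "allele1": bim["allele1"],
            "allele2": bim["allele2"],
            "minor_allele": bim["allele1"],
        }
    )
    if list(dose.index) != list(variants["id"]):
        raise ValueError("dosage rows do not match .bim variant order")
    if list(dose.columns) != list(fam["id"]):
        raise ValueError("dosage columns do not match .fam sample order")
    return GenotypeMatrix(
        dosage=dose.to_numpy(dtype=float).T, variants=variants, samples=fam
    )


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    clinical.to_csv(path, index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str})


def write_followups(followups: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in FOLLOWUP_COLUMNS if c not in followups.columns]
    if missing:
        raise ValueError(f"follow-up table missing columns {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    followups[FOLLOWUP_COLUMNS].to_csv(path, index=False)


def read_followups(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in FOLLOWUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"follow-up table missing columns {missing}")
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
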