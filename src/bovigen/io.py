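"""Text I/O: PLINK-style .ped/.map, relationship-matrix TSV, trait CSV,
truth JSON, and BED/GFF3 annotation tables.

Dosages are coded against allele "B": genotype ``A A`` -> 0, ``A B`` -> 1,
``B B`` -> 2, ``0 0`` -> missing.  Annotation readers return 1-based
inclusive coordinates (BED's 0-based half-open intervals are converted).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, RelationshipMatrix
from .exceptions import DataError

_ALLELES = {0.0: ("A", "A"), 1.0: ("A", "B"), 2.0: ("B", "B")}


def write_ped_map(genotypes: GenotypeMatrix, pedigree: pd.DataFrame,
                  prefix) -> None:
    """Write <prefix>.ped and <prefix>.map."""
    prefix = Path(prefix)
    gmap = genotypes.snp_map
    gmap_out = pd.DataFrame({
        "chrom": gmap["chrom"], "snp_id": gmap["snp_id"],
        "cm": 0, "pos": gmap["pos"],
    })
    gmap_out.to_csv(prefix.with_suffix(".map"), sep="\t", header=False,
                    index=False)
    ped = pedigree.set_index("animal_id")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, animal in enumerate(genotypes.animal_ids):
            sire = ped.loc[animal, "sire_id"] if animal in ped.index else None
            dam = ped.loc[animal, "dam_id"] if animal in ped.index else None
            row = ["FAM1", str(animal),
                   str(sire) if pd.notna(sire) else "0",
                   str(dam) if pd.notna(dam) else "0",
                   "0", "-9"]
            for d in genotypes.dosages[i]:
                row.extend(_ALLELES.get(d, ("0", "0")))
            fh.write(" ".join(row) + "\n")


def read_ped_map(prefix):
    """Read <prefix>.ped/.map back into (GenotypeMatrix, pedigree)."""
    prefix = Path(prefix)
    gmap = pd.read_csv(prefix.with_suffix(".map"), sep="\t", header=None,
                       names=["chrom", "snp_id", "cm", "pos"])
    snp_map = gmap[["snp_id", "chrom", "pos"]].copy()
    animals, sires, dams, rows = [], [], [], []
    code = {("A", "A"): 0.0, ("A", "B"): 1.0, ("B", "A"): 1.0,
            ("B", "B"): 2.0, ("0", "0"): np.nan}
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * len(snp_map):
                raise DataError(
                    f".ped row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts)} fields, expected {6 + 2 * len(snp_map)}"
                )
            animals.append(parts[1])
            sires.append(parts[2] if parts[2] != "0" else pd.NA)
            dams.append(parts[3] if parts[3] != "0" else pd.NA)
            alleles = parts[6:]
            try:
                rows.append([code[(alleles[2 * j], alleles[2 * j + 1])]
                             for j in range(len(snp_map))])
            except KeyError as exc:
                raise DataError(f"unknown allele pair {exc} in .ped") from exc
    genotypes = GenotypeMatrix(np.array(rows, dtype=float), snp_map,
                               np.array(animals))
    pedigree = pd.DataFrame({"animal_id": animals, "sire_id": sires,
                             "dam_id": dams})
    return genotypes, pedigree


def write_matrix_tsv(mat: RelationshipMatrix, path) -> None:
    pd.DataFrame(mat.values, index=mat.animal_ids,
                 columns=mat.animal_ids).to_csv(path, sep="\t")


def read_matrix_tsv(path, kind: str) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(df.to_numpy(), kind=kind,
                              animal_ids=df.index.to_numpy())


def write_trait_csv(trait_table: pd.DataFrame, path) -> None:
    trait_table.to_csv(path, index=False)


def read_trait_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth_json(truth, config, path) -> None:
    with open(path, "w") as fh:
        json.dump({"config": config.to_dict(), "truth": truth.to_dict()},
                  fh, indent=1)


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> chrom/start/end/name, 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise DataError("BED needs at least chrom/start/end columns")
    out = pd.DataFrame({
        "chrom": df[0].astype(str),
        "start": df[1].astype(int) + 1,
        "end": df[2].astype(int),
        "name": df[3].astype(str) if df.shape[1] > 3 else [
            f"feature{i}" for i in range(len(df))],
    })
    if (out["end"] < out["start"] - 1).any():
        raise DataError("BED interval with end < start")
    return out


def read_gff3(path, feature_types=("gene",)) -> pd.DataFrame:
    """GFF3 (already 1-based inclusive) -> chrom/start/end/name."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"])
    if feature_types:
        df = df[df["type"].isin(feature_types)]
    names = []
    for attr in df["attributes"]:
        fields = dict(kv.split("=", 1) for kv in str(attr).split(";") if "=" in kv)
        names.append(fields.get("Name", fields.get("ID", "?")))
    out = pd.DataFrame({"chrom": df["chrom"].astype(str),
                        "start": df["start"].astype(int),
                        "end": df["end"].astype(int),
                        "name": names})
    if (out["end"] < out["start"]).any():
        raise DataError("GFF3 interval with end < start")
    return out
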