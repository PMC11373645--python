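"""Genotype container and IO: minimal VCF (GT-only) and dosage TSV.

Dosages count copies of the alternate allele (0/1/2), with NaN marking
missing genotypes.  Marker positions are 1-based and strictly increasing
within a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_genotypes", "write_dosage_tsv", "write_vcf"]


@dataclass
class GenotypeMatrix:
    """Taxa x markers alt-allele dosage matrix with marker metadata.

    ``markers`` has columns: marker, chrom, pos, ref, alt.
    ``dosages`` is float (n_taxa, n_markers); NaN = missing genotype.
    """

    taxa: list[str]
    markers: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa IDs")
        if self.dosages.shape != (len(self.taxa), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.markers)} markers"
            )
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per marker, ignoring missing genotypes."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_taxa(self, taxa: Sequence[str]) -> "GenotypeMatrix":
        """Restrict to the given taxa (order as given).

        Raises KeyError listing any requested taxa that are absent.
        """
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise KeyError(f"taxa absent from genotype matrix: {missing[:10]}")
        idx = [index[t] for t in taxa]
        return GenotypeMatrix(list(taxa), self.markers.copy(), self.dosages[idx])


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write markers-as-rows dosage TSV (marker, chrom, pos, ref, alt, <taxa...>)."""
    dos = pd.DataFrame(geno.dosages.T, columns=geno.taxa)
    df = pd.concat([geno.markers.reset_index(drop=True), dos], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta_cols = ["marker", "chrom", "pos", "ref", "alt"]
    taxa = [c for c in df.columns if c not in meta_cols]
    markers = df[meta_cols].copy()
    markers["chrom"] = markers["chrom"].astype(str)
    dos = df[taxa].to_numpy(dtype=float).T
    return GenotypeMatrix(taxa, markers, dos)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype fields.

    Dosage 0 -> 0/0, 1 -> 0/1, 2 -> 1/1, missing -> ./.
    """
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, grp in geno.markers.groupby("chrom", sort=False):
            length = int(grp["pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.taxa) + "\n")
        dos = geno.dosages
        for j, rec in enumerate(geno.markers.itertuples(index=False)):
            gts = [
                "./." if np.isnan(d) else gt_code[float(d)] for d in dos[:, j]
            ]
            fh.write(
                f"{rec.chrom}\t{int(rec.pos)}\t{rec.marker}\t{rec.ref}\t{rec.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    taxa = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    rows = []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN (./.), 3 HOM_ALT
    code = np.array([0.0, 1.0, np.nan, 2.0])
    for i, var in enumerate(vcf):
        if var.ALT is None or len(var.ALT) != 1:
            raise ValueError(f"{path}: record {i + 1} ({var.CHROM}:{var.POS}) is not biallelic")
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(code[var.gt_types])
    markers = pd.DataFrame(
        {"marker": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    dosages = np.asarray(rows, dtype=float).T if rows else np.empty((len(taxa), 0))
    return GenotypeMatrix(taxa, markers, dosages)


def read_genotypes(
    path: str | Path,
    fmt: str | None = None,
    taxa: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Read genotypes from VCF or dosage TSV.

    ``fmt`` is "vcf" or "dosage-tsv"; inferred from the file suffix when
    omitted.  ``taxa`` restricts to a subset (erroring on absent taxa),
    mirroring the intersection step that keeps only taxa present in both
    the phenotype and genotype panels.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "dosage-tsv"
    if fmt == "vcf":
        geno = _read_vcf(path)
    elif fmt == "dosage-tsv":
        geno = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    if taxa is not None:
        geno = geno.subset_taxa(taxa)
    return geno
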