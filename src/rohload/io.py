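"""Reading and writing the pipeline's file formats.

VCF parsing is delegated to cyvcf2; marker tables, segment tables, F_ROH
tables and mutation tables travel as plain TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .roh import GenotypeMatrix

__all__ = ["read_vcf_genotypes", "read_mutation_table", "write_segments",
           "write_froh", "read_segments"]


def read_vcf_genotypes(path, markers_cm: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Load a VCF into a genotype matrix.

    Genotypes are coded by derived(ALT)-allele count (0/1/2, -1 missing).  cM
    positions come from ``markers_cm`` (columns chromosome, bp, cm) when
    given; otherwise the uniform-map convention cm = POS / 1e6 is used, which
    matches simulator output.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    chroms, bps, codes = [], [], []
    for var in vcf:
        chroms.append(var.CHROM)
        bps.append(var.POS)
        # gt_types: 0=hom ref, 1=het, 2=hom alt (cyvcf2 gt_types 3), 3=unknown
        t = var.gt_types
        row = np.full(t.size, -1, dtype=np.int8)
        row[t == 0] = 0
        row[t == 1] = 1
        row[t == 3] = 2
        codes.append(row)
    markers = pd.DataFrame({
        "marker_id": [f"m{i}" for i in range(len(bps))],
        "chromosome": chroms,
        "bp": np.asarray(bps, dtype=np.int64),
    })
    if markers_cm is not None:
        key = markers_cm.set_index(["chromosome", "bp"])["cm"]
        markers["cm"] = [
            key.get((c, b), np.nan) for c, b in zip(markers["chromosome"],
                                                    markers["bp"])]
        if markers["cm"].isna().any():
            raise ValueError("some VCF sites lack a cM position in markers_cm")
    else:
        markers["cm"] = markers["bp"] / 1e6
    calls = (np.vstack(codes).T if codes
             else np.empty((len(individuals), 0), dtype=np.int8))
    return GenotypeMatrix(individuals=individuals, markers=markers, calls=calls)


def read_mutation_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_segments(segments: pd.DataFrame, path) -> None:
    """Write a segment table in a PLINK .hom-like TSV layout."""
    out = segments.rename(columns={
        "individual": "IID", "chromosome": "CHR", "start_cm": "POS1",
        "end_cm": "POS2", "n_snps": "NSNP", "n_het": "NHET"})
    out["KB"] = segments["length_cm"] * 1e3  # cM x 1000, the kb analogue
    cols = ["IID", "CHR", "POS1", "POS2", "KB", "NSNP", "NHET"]
    if "length_class" in segments.columns:
        out["length_class"] = segments["length_class"]
        cols.append("length_class")
    out[cols].to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    out = df.rename(columns={
        "IID": "individual", "CHR": "chromosome", "POS1": "start_cm",
        "POS2": "end_cm", "NSNP": "n_snps", "NHET": "n_het"})
    out["length_cm"] = out["end_cm"] - out["start_cm"]
    out["chromosome"] = out["chromosome"].astype(str)
    return out


def write_froh(froh: pd.DataFrame, path) -> None:
    froh.to_csv(path, sep="\t", index=False)
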