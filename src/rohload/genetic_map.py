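"""Genetic-map handling: cM interpolation and haplotype-age/segment-length conversions.

A linkage map gives genetic positions (centimorgan) for a subset of markers
("anchors") on each chromosome.  Denser marker sets (e.g. an imputed SNP-chip
dataset) are placed on the map by linear interpolation in physical coordinates,
which corresponds to assuming a constant recombination rate between anchors.

The expected genetic length of an identity-by-descent segment whose underlying
haplotypes coalesce ``g`` generations ago is ``L = 100 / (2 g)`` cM; the inverse
gives the expected time to the most recent common ancestor for a segment of a
given length.  These two conversions define the age interpretation of ROH
length classes used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "interpolate_positions",
    "expected_roh_length_cm",
    "expected_mrca_generations",
    "total_map_length",
    "read_map_tsv",
    "read_bim",
]

#: Total sex-averaged autosomal genetic map length (cM) of the Soay sheep
#: linkage map; the default denominator for F_ROH.
SOAY_MAP_LENGTH_CM = 3146.0


@dataclass
class GeneticMap:
    """Per-chromosome anchors mapping physical bp to genetic cM positions.

    Parameters
    ----------
    anchors
        Mapping of chromosome id to a ``(n, 2)`` float array of ``[bp, cm]``
        rows sorted by bp, with non-decreasing cm.  Every chromosome must have
        at least two anchors.
    """

    anchors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, np.ndarray] = {}
        for chrom, arr in self.anchors.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(
                    f"chromosome {chrom!r}: need >= 2 anchors as (n, 2) [bp, cm] rows"
                )
            if np.any(arr[:, 0] <= 0):
                raise ValueError(f"chromosome {chrom!r}: bp positions must be positive")
            if np.any(arr[:, 1] < 0):
                raise ValueError(f"chromosome {chrom!r}: cm positions must be >= 0")
            order = np.argsort(arr[:, 0], kind="stable")
            arr = arr[order]
            if np.any(np.diff(arr[:, 0]) == 0):
                raise ValueError(f"chromosome {chrom!r}: duplicate anchor bp positions")
            if np.any(np.diff(arr[:, 1]) < 0):
                raise ValueError(f"chromosome {chrom!r}: cm must be non-decreasing in bp")
            cleaned[str(chrom)] = arr
        self.anchors = cleaned

    @property
    def chromosomes(self) -> list[str]:
        return list(self.anchors)

    @property
    def total_length_cm(self) -> float:
        return total_map_length(self)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        """Build from a table with ``chromosome``, ``bp``, ``cM`` columns."""
        anchors = {
            str(chrom): grp.sort_values("bp")[["bp", "cM"]].to_numpy(dtype=float)
            for chrom, grp in df.groupby("chromosome", sort=True)
        }
        return cls(anchors)


def read_map_tsv(path) -> GeneticMap:
    """Read a linkage map TSV with header ``marker_id chromosome bp cM``."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = {"chromosome", "bp", "cM"} - set(df.columns)
    if missing:
        raise ValueError(f"map file missing columns: {sorted(missing)}")
    return GeneticMap.from_frame(df)


def read_bim(path) -> pd.DataFrame:
    """Read a PLINK .bim file into a marker table (marker_id, chromosome, bp)."""
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "marker_id", "cm_morgans", "bp", "a1", "a2"],
        dtype={"chromosome": str},
    )
    out = bim[["marker_id", "chromosome", "bp"]].copy()
    return out.sort_values(["chromosome", "bp"], kind="stable").reset_index(drop=True)


def interpolate_positions(gmap: GeneticMap, markers: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``cm`` column of a marker table by linear interpolation in bp.

    Markers between two anchors get the bp-linear interpolation of the flanking
    anchor cM values (equal-cM flanks collapse to that shared value); markers
    before the first anchor of a chromosome get 0 cM; markers after the last
    anchor get the last anchor's cM; markers exactly at an anchor bp keep the
    anchor cM.

    Parameters
    ----------
    gmap
        The genetic map.
    markers
        Table with at least ``chromosome`` and ``bp`` columns, sorted by
        (chromosome, bp).

    Returns
    -------
    pandas.DataFrame
        Copy of ``markers`` with a filled float ``cm`` column.

    Raises
    ------
    KeyError
        If a marker chromosome is absent from the map.
    """
    markers = markers.copy()
    cm = np.empty(len(markers), dtype=float)
    for chrom, grp in markers.groupby("chromosome", sort=False):
        chrom = str(chrom)
        if chrom not in gmap.anchors:
            raise KeyError(f"chromosome {chrom!r} is not present in the genetic map")
        anchors = gmap.anchors[chrom]
        bp = grp["bp"].to_numpy(dtype=float)
        vals = np.interp(bp, anchors[:, 0], anchors[:, 1])
        vals[bp < anchors[0, 0]] = 0.0  # before first anchor: 0 cM by convention
        cm[markers.index.get_indexer(grp.index)] = vals
    markers["cm"] = cm
    return markers


def expected_roh_length_cm(g):
    """Expected genetic length (cM) of an IBD segment with MRCA ``g`` generations ago.

    ``L = 100 / (2 g)``; e.g. 2 cM for g = 25, 12.5 cM for g = 4.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0):
        raise ValueError("generations to MRCA must be > 0")
    out = 100.0 / (2.0 * g)
    return float(out) if out.ndim == 0 else out


def expected_mrca_generations(length_cm):
    """Expected generations to the MRCA for an IBD segment of ``length_cm`` cM.

    Inverse of :func:`expected_roh_length_cm`: ``g = 100 / (2 L)``.
    """
    length_cm = np.asarray(length_cm, dtype=float)
    if np.any(length_cm <= 0):
        raise ValueError("segment length must be > 0 cM")
    out = 100.0 / (2.0 * length_cm)
    return float(out) if out.ndim == 0 else out


def total_map_length(gmap: GeneticMap) -> float:
    """Total map length: sum over chromosomes of the terminal anchor cM."""
    if not gmap.anchors:
        raise ValueError("empty genetic map has no total length")
    return float(sum(arr[-1, 1] for arr in gmap.anchors.values()))
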