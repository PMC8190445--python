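"""Runs-of-homozygosity detection on genetic-map coordinates.

ROH are called with a sliding-window algorithm that mirrors the windowed
scanning of PLINK's ``--homozyg``: cM positions are scaled by 1e6 to integer
pseudo-positions so that thresholds expressed in kb in the PLINK idiom (390 kb,
250 kb gap, density 100 kb/SNP) correspond exactly to 0.39 cM, 0.25 cM and
0.1 cM/SNP.  Detected segments are classified into short / medium / long length
classes whose boundaries (0.39, 1.56, 12.5 cM) correspond to expected
haplotype coalescence times of roughly 128, 32 and 4 generations, and
per-individual inbreeding coefficients F_ROH are computed per class as the
summed segment length divided by the total map length.

Genotype calls are coded ``0`` homozygous reference, ``1`` heterozygous,
``2`` homozygous alternate, ``-1`` missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ROHParams",
    "ROHClassBounds",
    "scale_cm_coordinates",
    "call_roh",
    "classify_segments",
    "compute_froh",
]

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

SEGMENT_COLUMNS = [
    "individual",
    "chromosome",
    "start_cm",
    "end_cm",
    "length_cm",
    "n_snps",
    "n_het",
]


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls over a cM-mapped marker set.

    ``markers`` must contain ``chromosome`` and ``cm`` columns and be sorted by
    chromosome then cm; ``calls`` is an ``(n_individuals, n_markers)`` int8
    array in {0, 1, 2, -1}.
    """

    individuals: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        if "cm" not in self.markers.columns or "chromosome" not in self.markers.columns:
            raise ValueError("markers need 'chromosome' and 'cm' columns")
        for _, grp in self.markers.groupby("chromosome", sort=False):
            if np.any(np.diff(grp["cm"].to_numpy(dtype=float)) < 0):
                raise ValueError("markers must be sorted by cm within each chromosome")


@dataclass
class ROHParams:
    """Detection parameters, defaults matching the PLINK-style command
    ``--homozyg-window-snp 25 --homozyg-snp 25 --homozyg-kb 390 --homozyg-gap 250
    --homozyg-density 100 --homozyg-window-missing 2 --homozyg-het 2
    --homozyg-window-het 2`` on cM*1e6 coordinates."""

    window_snps: int = 25
    min_snps: int = 25
    min_length_cm: float = 0.39
    max_gap_cm: float = 0.25
    max_avg_spacing_cm_per_snp: float = 0.1
    window_het: int = 2
    window_missing: int = 2
    segment_het: int = 2
    window_hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.window_hit_threshold <= 1):
            raise ValueError("window_hit_threshold must be in (0, 1]")
        for name in ("window_snps", "min_snps", "min_length_cm", "max_gap_cm",
                     "max_avg_spacing_cm_per_snp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ROHClassBounds:
    """Length-class boundaries in cM: short [0.39, 1.56), medium [1.56, 12.5],
    long (12.5, inf)."""

    short_min_cm: float = 0.39
    medium_min_cm: float = 1.56
    long_min_cm: float = 12.5

    def __post_init__(self) -> None:
        if not (self.short_min_cm < self.medium_min_cm < self.long_min_cm):
            raise ValueError("class bounds must be strictly increasing")


def scale_cm_coordinates(cm) -> np.ndarray:
    """Integer pseudo-positions ``round(cm * 1e6)`` used for all length, gap and
    density arithmetic (so 0.39 cM maps onto the 390 kb minimum-length idiom)."""
    return np.rint(np.asarray(cm, dtype=float) * 1e6).astype(np.int64)


def _window_hits(g: np.ndarray, p: ROHParams) -> np.ndarray:
    """Boolean hit status of each of the M-W+1 sliding windows of calls ``g``."""
    w = p.window_snps
    het = (g == HET).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    kernel = np.ones(w, dtype=np.int64)
    het_w = np.convolve(het, kernel, mode="valid")
    mis_w = np.convolve(mis, kernel, mode="valid")
    return (het_w <= p.window_het) & (mis_w <= p.window_missing)


def _eligible_markers(g: np.ndarray, p: ROHParams) -> np.ndarray:
    """Markers covered by a >= threshold fraction of hit windows."""
    m = g.size
    w = p.window_snps
    if m < w:
        return np.zeros(m, dtype=bool)
    hits = _window_hits(g, p)
    chits = np.concatenate([[0], np.cumsum(hits)])
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, m - w)
    n_cover = hi - lo + 1
    n_hits = chits[hi + 1] - chits[lo]
    return n_hits >= p.window_hit_threshold * n_cover


def _segments_in_run(run: np.ndarray, g: np.ndarray, ppos: np.ndarray,
                     p: ROHParams) -> list[tuple[int, int]]:
    """Sub-runs of ``run`` (contiguous marker indices) with at most
    ``segment_het`` heterozygous calls.

    Every maximal sub-interval within the heterozygote allowance is a
    candidate; candidates are trimmed to homozygous endpoints, filtered by the
    min-SNP / min-length / density constraints, then accepted longest first
    (ties to the left) dropping overlaps — so an over-contaminated run is
    split at its excess heterozygotes into the longest valid pieces.
    """
    het_rel = np.flatnonzero(g[run] == HET)  # positions within run
    n = run.size
    k = het_rel.size
    t = p.segment_het
    if k <= t:
        windows = [(0, n - 1)]
    else:
        windows = []
        for i in range(-1, k - t):
            lo = int(het_rel[i]) + 1 if i >= 0 else 0
            hi = int(het_rel[i + t + 1]) - 1 if i + t + 1 < k else n - 1
            if lo <= hi:
                windows.append((lo, hi))
    candidates = []
    for a, b in windows:
        while a <= b and g[run[a]] in (HET, MISSING):
            a += 1
        while b >= a and g[run[b]] in (HET, MISSING):
            b -= 1
        if a > b:
            continue
        i, j = int(run[a]), int(run[b])
        n_snps = b - a + 1
        length = int(ppos[j] - ppos[i])
        if (n_snps >= p.min_snps
                and length >= int(round(p.min_length_cm * 1e6))
                and length <= p.max_avg_spacing_cm_per_snp * 1e6 * n_snps):
            candidates.append((i, j, length))
    candidates.sort(key=lambda c: (-c[2], c[0]))
    out: list[tuple[int, int]] = []
    for i, j, _ in candidates:
        if all(j < i2 or i > j2 for i2, j2 in out):
            out.append((i, j))
    out.sort()
    return out


def call_roh(genotypes: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """Detect ROH for every individual on every chromosome.

    The scan proceeds in four steps per individual and chromosome: (1) every
    run of ``window_snps`` consecutive markers forms a window, a window being a
    "hit" when it contains at most ``window_het`` heterozygous and
    ``window_missing`` missing calls; (2) a marker is eligible when at least
    ``window_hit_threshold`` of the windows covering it are hits; (3) maximal
    runs of eligible markers are split where adjacent markers are more than
    ``max_gap_cm`` apart; (4) runs are reduced to sub-runs containing at most
    ``segment_het`` heterozygous calls (greedy, left to right, trimmed to
    homozygous endpoints) and filtered by the minimum-SNP, minimum-length and
    density constraints.

    Returns a segment table sorted by (individual, chromosome, start_cm); the
    span is measured from the first to the last marker of the segment.
    """
    p = params or ROHParams()
    rows: list[tuple] = []
    markers = genotypes.markers
    for chrom, grp in markers.groupby("chromosome", sort=False):
        idx = markers.index.get_indexer(grp.index)
        cm = grp["cm"].to_numpy(dtype=float)
        ppos = scale_cm_coordinates(cm)
        if np.any(np.diff(ppos) < 0):
            raise ValueError(f"markers on chromosome {chrom!r} are not sorted")
        if len(idx) < p.window_snps:
            continue
        gap_break = np.diff(ppos) > int(round(p.max_gap_cm * 1e6))
        for ind_i, ind in enumerate(genotypes.individuals):
            g = genotypes.calls[ind_i, idx]
            elig = _eligible_markers(g, p)
            # maximal eligible runs, split at oversized gaps
            run_list: list[np.ndarray] = []
            pos = np.flatnonzero(elig)
            if pos.size:
                brk = np.flatnonzero((np.diff(pos) > 1) | gap_break[pos[:-1]])
                run_list = np.split(pos, brk + 1)
            for run in run_list:
                for i, j in _segments_in_run(run, g, ppos, p):
                    seg_g = g[i:j + 1]
                    rows.append((
                        ind, str(chrom),
                        float(ppos[i]) / 1e6,
                        float(ppos[j]) / 1e6,
                        float(ppos[j] - ppos[i]) / 1e6,
                        int(j - i + 1),
                        int(np.count_nonzero(seg_g == HET)),
                    ))
    out = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return out.sort_values(["individual", "chromosome", "start_cm"],
                           kind="stable").reset_index(drop=True)


def classify_segments(segments: pd.DataFrame,
                      bounds: ROHClassBounds | None = None) -> pd.DataFrame:
    """Attach a ``length_class`` column (short / medium / long).

    Boundary convention: short = [0.39, 1.56) cM, medium = [1.56, 12.5] cM,
    long = (12.5, inf) cM, so every segment has exactly one class.
    """
    b = bounds or ROHClassBounds()
    segments = segments.copy()
    length = segments["length_cm"].to_numpy(dtype=float)
    if np.any(length < b.short_min_cm - 1e-9):
        raise ValueError(f"segment shorter than {b.short_min_cm} cM; caller should "
                         "have filtered it")
    cls = np.where(length > b.long_min_cm, "long",
                   np.where(length >= b.medium_min_cm, "medium", "short"))
    segments["length_class"] = cls
    return segments


def compute_froh(segments: pd.DataFrame, total_map_cm: float,
                 individuals: list[str] | None = None) -> pd.DataFrame:
    """Per-individual inbreeding coefficients by ROH length class.

    ``f_<class>`` is the summed segment length of that class divided by
    ``total_map_cm`` (3146 cM for the Soay autosomal map); ``f_total`` sums all
    classes.  Individuals with no segments get all-zero coefficients and a
    missing ``mean_roh_length_cm``.
    """
    if total_map_cm <= 0:
        raise ValueError("total_map_cm must be positive")
    if np.any(segments["length_cm"].to_numpy(dtype=float) < 0):
        raise ValueError("negative segment length")
    if "length_class" not in segments.columns:
        raise ValueError("segments must be classified first (classify_segments)")
    if individuals is None:
        individuals = sorted(segments["individual"].unique())
    rows = []
    grouped = dict(tuple(segments.groupby("individual", sort=False)))
    for ind in individuals:
        seg = grouped.get(ind)
        rec = {"individual": ind, "f_long": 0.0, "f_medium": 0.0, "f_short": 0.0,
               "f_total": 0.0, "mean_roh_length_cm": np.nan}
        if seg is not None and len(seg):
            for cls, sub in seg.groupby("length_class", sort=False):
                rec[f"f_{cls}"] = sub["length_cm"].sum() / total_map_cm
            rec["f_total"] = seg["length_cm"].sum() / total_map_cm
            rec["mean_roh_length_cm"] = float(seg["length_cm"].mean())
        rows.append(rec)
    return pd.DataFrame(rows)
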