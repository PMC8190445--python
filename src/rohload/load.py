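"""Mutation-load statistics within ROH length classes.

Combines called ROH segments with a simulated mutation table to measure, per
individual and per length class: (1) the mutation load per cM of ROH — the sum
of selection coefficients of deleterious mutations exposed within the class's
segments divided by the class's total genetic length; (2) the number of such
mutations per cM; and (3) the mean population allele frequency of those
mutations.  Replicate-level summaries average the per-individual statistics
and express classes as percent contrasts against long ROH, the class expected
to carry the youngest, least-purged haplotypes.

By default only mutations *homozygous* for the deleterious allele inside a
segment are counted: ROH mark IBD tracts, and the rare heterozygous calls
tolerated inside them are treated as non-IBD contamination.  Counting any
carried copy instead is available via ``require_homozygous=False``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "mutations_in_roh",
    "mean_frequency",
    "per_individual_load",
    "summarize_replicate",
]

CLASSES = ("long", "medium", "short")


def mutations_in_roh(genotypes: np.ndarray, individuals: list[str],
                     segments: pd.DataFrame, mutation_table: pd.DataFrame,
                     require_homozygous: bool = True) -> pd.DataFrame:
    """Deleterious mutations exposed within each ROH segment.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_sites)`` derived-allele counts aligned with
        ``mutation_table`` rows.
    individuals
        Individual ids in genotype row order (must cover the segment table).
    segments
        Classified ROH table with ``start_cm`` / ``end_cm`` in the same
        coordinate space as the mutation positions (cM = bp / 1e6 under the
        uniform simulated map).
    mutation_table
        Per-site table with ``position_bp``, ``s``, ``kind``, ``frequency``.

    Returns one row per (segment, mutation) pair with the segment's class and
    the mutation's s and frequency.  Segment boundaries are closed intervals.
    """
    pos_cm = mutation_table["position_bp"].to_numpy(dtype=float) / 1e6
    if segments["end_cm"].max() > pos_cm.max() + 1e3:
        raise ValueError("segment coordinates exceed the mutation coordinate "
                         "space; are both on cM = bp/1e6?")
    is_del = (mutation_table["kind"] == "deleterious").to_numpy()
    s = mutation_table["s"].to_numpy(dtype=float)
    freq = mutation_table["frequency"].to_numpy(dtype=float)
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    rows = []
    for seg_i, seg in enumerate(segments.itertuples(index=False)):
        row = ind_index.get(seg.individual)
        if row is None:
            raise KeyError(f"segment individual {seg.individual!r} not in genotypes")
        inside = (pos_cm >= seg.start_cm - 1e-12) & (pos_cm <= seg.end_cm + 1e-12)
        g = genotypes[row]
        carried = (g == 2) if require_homozygous else (g >= 1)
        hit = np.flatnonzero(inside & is_del & carried)
        for m in hit:
            rows.append((seg.individual, seg_i, seg.length_class, int(m),
                         s[m], freq[m]))
    return pd.DataFrame(rows, columns=["individual", "segment", "length_class",
                                       "mutation", "s", "frequency"])


def mean_frequency(hits: pd.DataFrame, length_class: str,
                   weighting: str = "occurrence") -> float:
    """Mean population allele frequency of deleterious mutations in a class.

    ``weighting="occurrence"`` (default) counts each mutation once per
    individual-occurrence, matching the per-individual statistics;
    ``weighting="unique"`` counts each distinct mutation once regardless of
    how many individuals expose it.  Returns NaN when the class is empty.
    """
    sub = hits[hits["length_class"] == length_class]
    if sub.empty:
        return float("nan")
    if weighting == "occurrence":
        return float(sub["frequency"].mean())
    if weighting == "unique":
        return float(sub.drop_duplicates("mutation")["frequency"].mean())
    raise ValueError("weighting must be 'occurrence' or 'unique'")


def per_individual_load(segments: pd.DataFrame, hits: pd.DataFrame,
                        individuals: list[str]) -> pd.DataFrame:
    """Per-individual, per-class load statistics.

    ``load_per_cm`` = (sum of s over exposed mutations in the class) / (total
    class segment length in cM); ``count_per_cm`` likewise for the count.
    Individuals without any segment of a class get missing values for that
    class (load per cM is undefined without ROH), not zeros.
    """
    seg_len = segments.groupby(["individual", "length_class"])["length_cm"].sum()
    agg = hits.groupby(["individual", "length_class"]).agg(
        sum_s=("s", "sum"), n=("s", "size"))
    rows = []
    for ind in individuals:
        for cls in CLASSES:
            key = (ind, cls)
            total_cm = seg_len.get(key, 0.0)
            if total_cm <= 0:
                rows.append((ind, cls, np.nan, np.nan, np.nan))
                continue
            sum_s, n = (agg.loc[key] if key in agg.index else (0.0, 0))
            mean_f = (hits.loc[(hits["individual"] == ind)
                               & (hits["length_class"] == cls), "frequency"].mean()
                      if n else np.nan)
            rows.append((ind, cls, sum_s / total_cm, n / total_cm, mean_f))
    return pd.DataFrame(rows, columns=["individual", "length_class",
                                       "load_per_cm", "count_per_cm",
                                       "mean_allele_frequency"])


def summarize_replicate(stats: pd.DataFrame, replicate: int = 0) -> pd.DataFrame:
    """Class means across individuals plus percent contrasts against long ROH.

    The contrast for class A is ``100 * (1 - mean_A / mean_long)`` for the
    load and count statistics; it is only defined when both class means are.
    Individuals with undefined values for a class are excluded from that
    class's mean.
    """
    rows = []
    means = {}
    for cls in CLASSES:
        sub = stats[stats["length_class"] == cls]
        means[cls] = {
            "load_per_cm": sub["load_per_cm"].mean(),
            "count_per_cm": sub["count_per_cm"].mean(),
            "mean_allele_frequency": sub["mean_allele_frequency"].mean(),
            "n_individuals": int(sub["load_per_cm"].notna().sum()),
        }
    for cls in CLASSES:
        m = means[cls]
        rec = {"replicate": replicate, "length_class": cls, **m}
        for stat in ("load_per_cm", "count_per_cm"):
            base = means["long"][stat]
            val = m[stat]
            rec[f"{stat}_contrast_vs_long_pct"] = (
                100.0 * (1.0 - val / base)
                if np.isfinite(base) and base != 0 and np.isfinite(val) else np.nan)
        rows.append(rec)
    return pd.DataFrame(rows)
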