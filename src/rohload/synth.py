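"""Synthetic inputs for every pipeline stage.

Three generators: survival cohorts with the statistical structure the
inbreeding-depression model assumes (three ROH-class inbreeding coefficients
with realistic means, crossed birth-year and mother random intercepts,
Bernoulli survival from a logit model); genotype fixtures with planted
homozygous segments over a marker map for truth-known caller tests; and
genetic-map fixtures for interpolation tests.

The F_ROH distributions mimic the published Soay means: long ROH cover on
average 1.3% of the genome with a strongly right-skewed, zero-inflated
distribution, medium ROH 21.3% and short ROH 10.7% with roughly symmetric
spreads.  Shape families (zero-inflated gamma, truncated normal) are package
choices; only the means are anchored to the study population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_map import GeneticMap
from .roh import GenotypeMatrix, HET, MISSING

__all__ = ["CohortSpec", "GenotypeFixtureSpec", "generate_cohort",
           "generate_genotype_fixture", "generate_map_fixture"]

# posterior-mean odds ratios per 1% of genome reported for the Soay cohort
DEFAULT_BETAS = {
    "intercept": 2.3,
    "f_long": float(np.log(0.876)),
    "f_medium": float(np.log(0.923)),
    "f_short": float(np.log(0.977)),
    "sex": -0.3,
    "twin": -0.4,
    "mean_roh_length_cm": 0.0,
}


@dataclass
class CohortSpec:
    """Spec for a synthetic survival cohort (defaults mirror the study scale:
    4879 lambs over 39 birth years, ~1100 mothers)."""

    n: int = 4879
    mean_f_long: float = 0.013
    mean_f_medium: float = 0.213
    mean_f_short: float = 0.107
    f_long_zero_prob: float = 0.3
    f_long_gamma_shape: float = 0.8
    sd_f_medium: float = 0.035
    sd_f_short: float = 0.015
    betas: dict = field(default_factory=lambda: dict(DEFAULT_BETAS))
    sigma_birth_year: float = 0.3
    sigma_mother: float = 0.3
    n_birth_years: int = 39
    mothers_per_year: int = 29
    twin_prob: float = 0.15
    sex_prob: float = 0.5
    sd_mean_roh_length: float = 0.2
    mean_mean_roh_length: float = 1.68

    def __post_init__(self) -> None:
        for m in (self.mean_f_long, self.mean_f_medium, self.mean_f_short):
            if not (0 <= m < 1):
                raise ValueError(f"infeasible F_ROH mean {m}")
        if self.mean_f_long + self.mean_f_medium + self.mean_f_short >= 1:
            raise ValueError("class means must sum to < 1")
        for p in (self.f_long_zero_prob, self.twin_prob, self.sex_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")


def _truncnorm(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(spec: CohortSpec, seed: int):
    """Generate a survival cohort and the latent truth used to build it.

    Returns ``(records, truth)``: a DataFrame with columns id, survived, sex,
    twin, birth_year, mother_id, f_long, f_medium, f_short, f_total,
    mean_roh_length_cm, and a dict holding the coefficient vector, group SDs
    and all latent random intercepts.
    """
    rng = np.random.default_rng(seed)
    n = spec.n
    # F_ROH draws; redraw rows whose class sum exceeds 1 (vanishingly rare
    # at the default dispersions)
    f_long = np.zeros(n)
    nonzero = rng.random(n) >= spec.f_long_zero_prob
    gmean = spec.mean_f_long / (1 - spec.f_long_zero_prob)
    f_long[nonzero] = rng.gamma(spec.f_long_gamma_shape,
                                gmean / spec.f_long_gamma_shape,
                                size=int(nonzero.sum()))
    f_long = np.clip(f_long, 0, 1)
    f_medium = _truncnorm(spec.mean_f_medium, spec.sd_f_medium, 0, 1, n, rng)
    f_short = _truncnorm(spec.mean_f_short, spec.sd_f_short, 0, 1, n, rng)
    bad = f_long + f_medium + f_short > 1
    f_long[bad] = spec.mean_f_long

    sex = (rng.random(n) < spec.sex_prob).astype(int)
    twin = (rng.random(n) < spec.twin_prob).astype(int)
    birth_year = rng.integers(0, spec.n_birth_years, size=n)
    mother_within = rng.integers(0, spec.mothers_per_year, size=n)
    mother_id = birth_year * spec.mothers_per_year + mother_within
    mean_len = _truncnorm(spec.mean_mean_roh_length, spec.sd_mean_roh_length,
                          0.39, 50, n, rng)

    a_year = rng.normal(0, spec.sigma_birth_year, size=spec.n_birth_years)
    n_mothers = spec.n_birth_years * spec.mothers_per_year
    a_mother = rng.normal(0, spec.sigma_mother, size=n_mothers)

    b = spec.betas
    eta = (b["intercept"]
           + 100 * f_long * b["f_long"]
           + 100 * f_medium * b["f_medium"]
           + 100 * f_short * b["f_short"]
           + sex * b["sex"] + twin * b["twin"]
           + b.get("mean_roh_length_cm", 0.0) * mean_len
           + a_year[birth_year] + a_mother[mother_id])
    p = 1.0 / (1.0 + np.exp(-eta))
    survived = (rng.random(n) < p).astype(int)

    records = pd.DataFrame({
        "id": [f"ind{i}" for i in range(n)],
        "survived": survived,
        "sex": sex,
        "twin": twin,
        "birth_year": [f"y{y}" for y in birth_year],
        "mother_id": [f"m{m}" for m in mother_id],
        "f_long": f_long,
        "f_medium": f_medium,
        "f_short": f_short,
        "f_total": f_long + f_medium + f_short,
        "mean_roh_length_cm": mean_len,
    })
    truth = {"betas": dict(b), "sigma_birth_year": spec.sigma_birth_year,
             "sigma_mother": spec.sigma_mother, "a_year": a_year,
             "a_mother": a_mother, "eta": eta, "seed": seed}
    return records, truth


@dataclass
class GenotypeFixtureSpec:
    """Spec for genotype fixtures with planted homozygous segments.

    ``segments_per_individual`` planted runs are placed uniformly without
    overlap; each spans ``segment_markers`` consecutive markers and carries
    ``het_contamination`` heterozygous calls in its interior.  Background
    genotypes are heterozygous at ``background_het_rate``, missing at
    ``missing_rate``, otherwise homozygous.  The default background het rate
    (0.55) is a deliberate stress level, not an emulation of real
    heterozygosity: it makes a 25-SNP background window pass the 2-het window
    allowance with probability ~1e-6, so every called segment can be matched
    against a planted one.
    """

    n_individuals: int = 5
    n_markers: int = 1000
    spacing_cm: float = 0.05
    segments_per_individual: int = 1
    segment_markers: int = 100
    het_contamination: int = 0
    background_het_rate: float = 0.55
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        for r in (self.background_het_rate, self.missing_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must be in [0, 1]")
        if self.segment_markers * self.segments_per_individual > self.n_markers:
            raise ValueError("planted segments exceed the marker map span")


def generate_genotype_fixture(spec: GenotypeFixtureSpec, seed: int):
    """Generate genotypes with planted ROH and the truth segment table."""
    rng = np.random.default_rng(seed)
    m = spec.n_markers
    cm = np.arange(m) * spec.spacing_cm
    markers = pd.DataFrame({
        "marker_id": [f"snp{i}" for i in range(m)],
        "chromosome": "1",
        "bp": (cm * 1e6).astype(np.int64) + 1,
        "cm": cm,
    })
    calls = np.where(rng.random((spec.n_individuals, m)) < spec.background_het_rate,
                     HET, rng.integers(0, 2, size=(spec.n_individuals, m)) * 2
                     ).astype(np.int8)
    miss = rng.random((spec.n_individuals, m)) < spec.missing_rate
    calls[miss] = MISSING
    truth_rows = []
    for i in range(spec.n_individuals):
        placed: list[tuple[int, int]] = []
        for _ in range(spec.segments_per_individual):
            for _attempt in range(200):
                start = int(rng.integers(0, m - spec.segment_markers + 1))
                end = start + spec.segment_markers - 1
                if all(end < s or start > e for s, e in placed):
                    placed.append((start, end))
                    break
            else:
                raise RuntimeError("could not place non-overlapping segments")
            start, end = placed[-1]
            calls[i, start:end + 1] = rng.integers(0, 2, size=spec.segment_markers) * 2
            n_het = spec.het_contamination
            if n_het:
                interior = rng.choice(np.arange(start + 2, end - 1), size=n_het,
                                      replace=False)
                calls[i, interior] = HET
            truth_rows.append((f"ind{i}", "1", cm[start], cm[end],
                               spec.segment_markers, n_het))
    truth = pd.DataFrame(truth_rows, columns=["individual", "chromosome",
                                              "start_cm", "end_cm", "n_markers",
                                              "n_het"])
    gm = GenotypeMatrix(individuals=[f"ind{i}" for i in range(spec.n_individuals)],
                        markers=markers, calls=calls)
    return gm, truth


def generate_map_fixture(n_chrom: int, length_cm: float, n_anchors: int,
                         markers_per_chrom: int, seed: int):
    """Random genetic map plus a denser unmapped marker table.

    Anchors sit at sorted random bp with monotone non-decreasing cM from 0 to
    ``length_cm``; markers are denser than anchors for interpolation testing.
    """
    if n_chrom <= 0 or length_cm <= 0 or n_anchors < 2:
        raise ValueError("need positive arguments and >= 2 anchors")
    rng = np.random.default_rng(seed)
    chrom_bp = int(length_cm * 1e6)

    def distinct_sorted(n, hi):
        got = np.unique(rng.integers(1, hi, size=3 * n))
        while got.size < n:
            got = np.unique(np.concatenate([got, rng.integers(1, hi, size=n)]))
        return np.sort(rng.choice(got, size=n, replace=False))

    anchors = {}
    marker_rows = []
    for c in range(1, n_chrom + 1):
        bp = distinct_sorted(n_anchors, chrom_bp)
        cm = np.sort(rng.uniform(0, length_cm, size=n_anchors))
        cm[0], cm[-1] = 0.0, length_cm
        anchors[str(c)] = np.column_stack([bp, cm]).astype(float)
        mbp = distinct_sorted(markers_per_chrom, chrom_bp + 1)
        for i, b in enumerate(mbp):
            marker_rows.append((f"c{c}s{i}", str(c), int(b)))
    markers = pd.DataFrame(marker_rows,
                           columns=["marker_id", "chromosome", "bp"])
    return GeneticMap(anchors), markers
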