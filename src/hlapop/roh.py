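"""Genome-wide homozygosity: ROH fractions, two-cluster stratification and
HLA-homozygosity comparison between strata.

Cohorts from populations with frequent consanguineous unions are bimodal in
runs-of-homozygosity (ROH) burden.  Lacking per-sample pedigree information,
samples are split into high-ROH and low-ROH strata by 2-means clustering of
(total ROH length, ROH segment count); the high-ROH stratum is enriched for
offspring of consanguineous unions, and HLA homozygosity can then be
compared between strata.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import popgen
from .nomenclature import is_missing

logger = logging.getLogger(__name__)

__all__ = [
    "GRCH38_AUTOSOME_BP",
    "genome_fraction",
    "split_roh_clusters",
    "hla_homozygosity_by_cluster",
]

# chr1-22 sequence lengths of GRCh38 (bp)
_GRCH38_CHROM_BP = (
    248956422, 242193529, 198295559, 190214555, 181538259, 170805979,
    159345973, 145138636, 138394717, 133797422, 135086622, 133275309,
    114364328, 107043718, 101991189, 90338345, 83257441, 80373285,
    58617616, 64444167, 46709983, 50818468,
)
GRCH38_AUTOSOME_BP: int = sum(_GRCH38_CHROM_BP)

HIGH = "high-ROH"
LOW = "low-ROH"


def genome_fraction(
    total_roh_bp: float, autosome_bp: float = GRCH38_AUTOSOME_BP
) -> float:
    """Fraction of the autosomal genome covered by ROH.

    Raises
    ------
    ValueError
        If the total exceeds the autosome length (corrupt input) or the
        autosome length is not positive.
    """
    if autosome_bp <= 0:
        raise ValueError("autosome_bp must be positive")
    if total_roh_bp < 0:
        raise ValueError("total_roh_bp must be nonnegative")
    frac = total_roh_bp / autosome_bp
    if frac > 1.0:
        raise ValueError(
            f"total ROH length {total_roh_bp} exceeds autosome length"
        )
    return frac


def split_roh_clusters(
    summaries: pd.DataFrame, seed: Optional[int] = None
) -> pd.Series:
    """2-means stratification of samples into high-ROH / low-ROH.

    Features (total_roh_bp, n_segments) are z-score standardised before
    clustering (their raw scales differ by orders of magnitude); k-means runs
    with 10 seeded restarts and the best inertia is kept.  The cluster with
    the larger mean total ROH length is labeled high-ROH.  Returns a Series
    mapping sample_id to label.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two samples")
    x = summaries[["total_roh_bp", "n_segments"]].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).all():
        raise ValueError("all samples identical: no ROH split exists")
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    assign = km.fit_predict(z)
    mean_total = [
        x[assign == c, 0].mean() if (assign == c).any() else -np.inf
        for c in (0, 1)
    ]
    high_cluster = int(np.argmax(mean_total))
    labels = np.where(assign == high_cluster, HIGH, LOW)
    return pd.Series(labels, index=summaries["sample_id"].astype(str),
                     name="roh_cluster")


def hla_homozygosity_by_cluster(
    genotypes: pd.DataFrame, clusters: pd.Series
) -> pd.DataFrame:
    """Per-locus homozygote proportions in high- vs low-ROH strata, with a
    two-sided Fisher exact p on the 2x2 homozygous/heterozygous x stratum
    table.  A genotype is homozygous iff both two-field alleles are equal;
    genotypes with a missing allele, or from unlabeled samples, are dropped.
    Loci with an empty stratum are skipped with a warning.
    """
    cl = clusters.to_dict()
    rows = []
    for locus in sorted(set(genotypes["locus"])):
        sub = genotypes[genotypes["locus"] == locus]
        tallies = {HIGH: [0, 0], LOW: [0, 0]}  # [homozygous, heterozygous]
        for row in sub.itertuples(index=False):
            lab = cl.get(str(row.sample_id))
            if lab is None:
                continue
            a1, a2 = str(row.allele1), str(row.allele2)
            if is_missing(a1) or is_missing(a2):
                continue
            tallies[lab][0 if a1 == a2 else 1] += 1
        n_high = sum(tallies[HIGH])
        n_low = sum(tallies[LOW])
        if n_high == 0 or n_low == 0:
            logger.warning(
                "locus %s skipped: a stratum has no scored genotypes", locus
            )
            continue
        p = popgen.fisher_exact_2x2([tallies[HIGH], tallies[LOW]])
        rows.append(
            {
                "locus": locus,
                "n_high": n_high,
                "n_low": n_low,
                "prop_hom_high": tallies[HIGH][0] / n_high,
                "prop_hom_low": tallies[LOW][0] / n_low,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
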