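"""Expectation-Maximization estimation of multilocus haplotype frequencies.

Unphased multilocus genotypes are compatible with several haplotype pairs
(one per way of distributing the heterozygous alleles over the two
chromosomes).  Under random mating, an individual's probability of carrying
the unordered pair {h1, h2} is f(h1)^2 when h1 = h2 and 2 f(h1) f(h2)
otherwise.  The EM algorithm alternates: E-step - distribute each
individual's unit weight over its compatible pairs proportional to the
current pair probabilities; M-step - haplotype frequencies become the
normalised expected haplotype counts.  The observed-data log-likelihood is
non-decreasing across iterations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .nomenclature import is_missing

logger = logging.getLogger(__name__)

__all__ = ["HaplotypeFrequencies", "em_haplotypes", "top_haplotypes"]

Haplotype = tuple[str, ...]


@dataclass
class HaplotypeFrequencies:
    loci: tuple[str, ...]
    frequencies: dict[Haplotype, float]
    loglik_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    n_samples_used: int = 0
    n_samples_dropped: int = 0

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else float("nan")


def _sample_genotypes(
    genotypes: pd.DataFrame, loci: Sequence[str]
) -> tuple[list[list[tuple[str, str]]], int]:
    """Per-sample list of per-locus allele pairs, listwise-complete only."""
    per_sample: dict[str, dict[str, tuple[str, str]]] = {}
    for row in genotypes.itertuples(index=False):
        locus = str(row.locus)
        if locus not in loci:
            continue
        a1, a2 = str(row.allele1), str(row.allele2)
        if is_missing(a1) or is_missing(a2):
            continue
        per_sample.setdefault(str(row.sample_id), {})[locus] = (a1, a2)
    kept, dropped = [], 0
    for sample, m in per_sample.items():
        if all(l in m for l in loci):
            kept.append([m[l] for l in loci])
        else:
            dropped += 1
    return kept, dropped


def _expand_pairs(
    geno: list[tuple[str, str]]
) -> list[tuple[Haplotype, Haplotype]]:
    """All distinct unordered haplotype pairs compatible with a genotype."""
    pairs: set[tuple[Haplotype, Haplotype]] = set()
    het = [i for i, (a, b) in enumerate(geno) if a != b]
    # fix the orientation of the first heterozygous locus: halves the
    # enumeration without losing any unordered pair
    free = het[1:]
    for flips in itertools.product((False, True), repeat=len(free)):
        h1, h2 = [], []
        fi = dict(zip(free, flips))
        for i, (a, b) in enumerate(geno):
            if i in fi and fi[i]:
                h1.append(b)
                h2.append(a)
            else:
                h1.append(a)
                h2.append(b)
        pair = tuple(sorted((tuple(h1), tuple(h2))))
        pairs.add(pair)
    return sorted(pairs)


def em_haplotypes(
    genotypes: pd.DataFrame,
    loci: Sequence[str],
    tol: float = 1e-7,
    max_iter: int = 1000,
    seed: Optional[int] = None,
    n_restarts: int = 3,
    prune_below: float = 1e-6,
    max_expansion: int = 100_000,
) -> HaplotypeFrequencies:
    """ML haplotype frequencies over *loci* from unphased genotypes.

    Samples missing any requested locus are dropped listwise (count
    reported).  Initialisation is the linkage-equilibrium product of
    single-locus frequencies with seeded multiplicative jitter; ``n_restarts``
    restarts are run and the best-likelihood solution kept (the unjittered
    product is a saddle point for symmetric double heterozygotes).
    Frequencies below ``prune_below`` are pruned between iterations with
    renormalisation.  Convergence is max |delta f| < tol.
    """
    loci = tuple(loci)
    kept, dropped = _sample_genotypes(genotypes, loci)
    if not kept:
        raise ValueError("no sample has complete genotypes at the requested loci")
    if dropped:
        logger.info("dropped %d samples with missing loci", dropped)

    expansions = [_expand_pairs(g) for g in kept]
    total_pairs = sum(len(e) for e in expansions)
    if total_pairs > max_expansion:
        raise ValueError(
            f"ambiguity expansion ({total_pairs} haplotype pairs) exceeds "
            f"{max_expansion}; consider fewer loci"
        )

    haps = sorted({h for e in expansions for pair in e for h in pair})
    hap_idx = {h: i for i, h in enumerate(haps)}
    nh = len(haps)
    # per-sample arrays of (i1, i2) haplotype indices
    exp_idx = [
        np.array([[hap_idx[a], hap_idx[b]] for a, b in e], dtype=np.int64)
        for e in expansions
    ]

    # linkage-equilibrium initial point
    le = np.ones(nh)
    for li in range(len(loci)):
        col_counts: dict[str, int] = {}
        for g in kept:
            for a in g[li]:
                col_counts[a] = col_counts.get(a, 0) + 1
        tot = sum(col_counts.values())
        for h, i in hap_idx.items():
            le[i] *= col_counts.get(h[li], 0) / tot
    le = np.maximum(le, 1e-300)
    le /= le.sum()

    rng = np.random.default_rng(seed)
    best: Optional[tuple[float, np.ndarray, list[float], int]] = None
    for _ in range(max(1, n_restarts)):
        f = le * (1.0 + 0.05 * (2.0 * rng.random(nh) - 1.0))
        f /= f.sum()
        f, trace, n_iter = _run_em(f, exp_idx, tol, max_iter, prune_below)
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], f, trace, n_iter)

    assert best is not None
    _, f, trace, n_iter = best
    freqs = {
        haps[i]: float(f[i]) for i in np.argsort(-f) if f[i] > 0
    }
    return HaplotypeFrequencies(
        loci=loci,
        frequencies=freqs,
        loglik_trace=trace,
        n_iterations=n_iter,
        n_samples_used=len(kept),
        n_samples_dropped=dropped,
    )


def _run_em(
    f: np.ndarray,
    exp_idx: list[np.ndarray],
    tol: float,
    max_iter: int,
    prune_below: float,
) -> tuple[np.ndarray, list[float], int]:
    n = len(exp_idx)
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        new = np.zeros_like(f)
        loglik = 0.0
        for idx in exp_idx:
            i1, i2 = idx[:, 0], idx[:, 1]
            w = f[i1] * f[i2] * np.where(i1 == i2, 1.0, 2.0)
            tot = w.sum()
            if tot <= 0:
                # all compatible pairs pruned: resurrect uniformly
                w = np.ones(len(idx))
                tot = w.sum()
                loglik += -745.0  # log of ~5e-324, effectively -inf floor
            else:
                loglik += math.log(tot)
            w /= tot
            np.add.at(new, i1, w)
            np.add.at(new, i2, w)
        new /= 2.0 * n
        # monotone up to the tiny perturbation pruning can introduce
        if trace and loglik < trace[-1] - 1e-6 * (1.0 + abs(trace[-1])):
            raise AssertionError("EM log-likelihood decreased")
        trace.append(loglik)
        delta = float(np.max(np.abs(new - f)))
        new[new < prune_below] = 0.0
        s = new.sum()
        f = new / s
        if delta < tol:
            return f, trace, it
    return f, trace, max_iter


def top_haplotypes(
    hf: HaplotypeFrequencies, k: int
) -> list[tuple[Haplotype, float]]:
    """The *k* most frequent haplotypes, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    items = sorted(hf.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
    return items[:k]
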