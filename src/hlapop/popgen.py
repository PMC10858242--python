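"""Locus-level population-genetic statistics for HLA genotype tables.

Implements allele counting and frequencies, observed/expected heterozygosity,
the exact (Guo–Thompson style) Hardy–Weinberg test, the Ewens–Watterson
homozygosity test of neutrality with the normalised deviation Fnd, Fisher's
exact 2x2 test, and the per-allele WGS-vs-WES platform comparison.

Conventions
-----------
Genotype tables are pandas frames with columns ``sample_id, locus, allele1,
allele2, platform`` (allele strings at two-field resolution, ``NA`` for a
missing call).  A missing allele is excluded from both numerator and
denominator of every count.  A homozygote counts once toward genotype-level
denominators and twice toward allele counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .nomenclature import is_missing

__all__ = [
    "LocusCounts",
    "allele_frequencies",
    "heterozygosity",
    "genotype_counts",
    "HWEResult",
    "hwe_exact_test",
    "EWResult",
    "ewens_watterson",
    "sample_neutral_homozygosity",
    "fisher_exact_2x2",
    "compare_platforms",
    "locus_summary",
]


# ---------------------------------------------------------------------------
# counts and frequencies
# ---------------------------------------------------------------------------

@dataclass
class LocusCounts:
    """Allele counts at one locus for one population sample.

    ``n_copies`` is 2n, the number of scored gene copies; ``k`` the number of
    distinct alleles.  ``n_genotypes``/``n_het`` are genotype-level tallies
    over samples where both alleles were scored (used for observed
    heterozygosity).
    """

    locus: str
    counts: dict[str, int]
    n_genotypes: int = 0
    n_het: int = 0

    @property
    def n_copies(self) -> int:
        return sum(self.counts.values())

    @property
    def k(self) -> int:
        return sum(1 for v in self.counts.values() if v > 0)

    @property
    def frequencies(self) -> dict[str, float]:
        tot = self.n_copies
        return {a: c / tot for a, c in self.counts.items() if c > 0}

    def homozygosity(self) -> float:
        """Observed homozygosity F = sum p_i^2 over allele frequencies."""
        p = np.array(list(self.frequencies.values()))
        return float(np.sum(p**2))


def allele_frequencies(genotypes: pd.DataFrame, locus: str) -> LocusCounts:
    """Count alleles at *locus*; frequencies are count / 2n.

    Raises
    ------
    ValueError
        If no scorable allele exists at the locus.
    """
    sub = genotypes[genotypes["locus"] == locus]
    counts: dict[str, int] = {}
    n_geno = 0
    n_het = 0
    for row in sub.itertuples(index=False):
        a1, a2 = str(row.allele1), str(row.allele2)
        present = [a for a in (a1, a2) if not is_missing(a)]
        for a in present:
            counts[a] = counts.get(a, 0) + 1
        if len(present) == 2:
            n_geno += 1
            if a1 != a2:
                n_het += 1
    if not counts:
        raise ValueError(f"no scorable alleles at locus {locus}")
    return LocusCounts(locus, counts, n_genotypes=n_geno, n_het=n_het)


def heterozygosity(c: LocusCounts) -> tuple[float, float, float]:
    """(observed, expected_raw, expected_unbiased) heterozygosity.

    Observed is the fraction of fully scored genotypes that are heterozygous.
    Expected (gene diversity) is ``1 - sum p_i^2``; the unbiased variant
    applies the small-sample factor ``2n/(2n-1)``.
    """
    obs = c.n_het / c.n_genotypes if c.n_genotypes else float("nan")
    raw = 1.0 - c.homozygosity()
    n2 = c.n_copies
    unbiased = n2 / (n2 - 1) * raw if n2 >= 2 else float("nan")
    return obs, raw, unbiased


def genotype_counts(
    genotypes: pd.DataFrame, locus: str
) -> dict[tuple[str, str], int]:
    """Unordered genotype counts at *locus* over fully scored samples."""
    sub = genotypes[genotypes["locus"] == locus]
    out: dict[tuple[str, str], int] = {}
    for row in sub.itertuples(index=False):
        a1, a2 = str(row.allele1), str(row.allele2)
        if is_missing(a1) or is_missing(a2):
            continue
        key = tuple(sorted((a1, a2)))
        out[key] = out.get(key, 0) + 1
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

@dataclass
class HWEResult:
    p_value: float
    se: float          # Monte-Carlo standard error (0 for exact enumeration)
    method: str        # "enumeration", "mcmc" or "degenerate"
    n_steps: int = 0


def _allele_margins(gc: Mapping[tuple[str, str], int]) -> dict[str, int]:
    margins: dict[str, int] = {}
    for (a, b), n in gc.items():
        margins[a] = margins.get(a, 0) + n
        margins[b] = margins.get(b, 0) + n
    return margins


_LOG2 = math.log(2.0)


def _table_term(het: int, cells: Sequence[int]) -> float:
    """Margin-free part of log P(table | allele counts): H log2 - sum log nij!."""
    return het * _LOG2 - float(np.sum(gammaln(np.asarray(cells, dtype=float) + 1.0)))


def _enumerate_tables(margins: Sequence[int]):
    """Yield all genotype tables with the given allele-count margins as dicts
    over upper-triangular cell index pairs.  Feasible for few alleles."""
    k = len(margins)
    cells = [(i, j) for i in range(k) for j in range(i, k)]

    def rec(idx: int, remaining: list[int], acc: dict):
        if idx == len(cells):
            if all(r == 0 for r in remaining):
                yield dict(acc)
            return
        i, j = cells[idx]
        cap = remaining[i] // 2 if i == j else min(remaining[i], remaining[j])
        for n in range(cap, -1, -1):
            remaining[i] -= 2 * n if i == j else n
            if i != j:
                remaining[j] -= n
            acc[(i, j)] = n
            yield from rec(idx + 1, remaining, acc)
            remaining[i] += 2 * n if i == j else n
            if i != j:
                remaining[j] += n
        del acc[(i, j)]

    yield from rec(0, list(margins), {})


def _logsumexp(xs: Sequence[float]) -> float:
    m = max(xs)
    return m + math.log(sum(math.exp(x - m) for x in xs))


def _hwe_enumeration(gc: Mapping[tuple[str, str], int]) -> HWEResult:
    margins_map = _allele_margins(gc)
    alleles = sorted(margins_map)
    idx = {a: i for i, a in enumerate(alleles)}
    margins = [margins_map[a] for a in alleles]
    obs = {
        (min(idx[a], idx[b]), max(idx[a], idx[b])): n
        for (a, b), n in gc.items()
    }
    obs_term = _table_term(
        sum(n for (i, j), n in obs.items() if i != j), list(obs.values())
    )
    log_num: list[float] = []
    log_all: list[float] = []
    for table in _enumerate_tables(margins):
        het = sum(n for (i, j), n in table.items() if i != j)
        t = _table_term(het, list(table.values()))
        log_all.append(t)
        if t <= obs_term + 1e-9:
            log_num.append(t)
    p = math.exp(_logsumexp(log_num) - _logsumexp(log_all)) if log_num else 0.0
    return HWEResult(min(p, 1.0), 0.0, "enumeration")


def _n_tables_bound(margins: Mapping[str, int]) -> int:
    bound = 1
    for v in sorted(margins.values())[:-1]:
        bound *= v + 1
    return bound**2


def _hwe_mcmc(
    gc: Mapping[tuple[str, str], int],
    n_steps: int,
    burn_in: int,
    seed: Optional[int],
) -> HWEResult:
    rng = np.random.default_rng(seed)
    alleles = sorted(_allele_margins(gc))
    idx = {a: i for i, a in enumerate(alleles)}
    pairs = np.array(
        [
            [idx[a], idx[b]]
            for (a, b), n in gc.items()
            for _ in range(n)
        ],
        dtype=np.int64,
    )
    n_ind = len(pairs)
    k = len(alleles)
    counts = np.zeros((k, k), dtype=np.int64)
    for a, b in pairs:
        counts[min(a, b), max(a, b)] += 1

    def cell_term(i: int, j: int) -> float:
        n = int(counts[i, j])
        t = -math.lgamma(n + 1)
        if i != j:
            t += n * _LOG2
        return t

    term = sum(cell_term(i, j) for i in range(k) for j in range(i, k))
    obs_term = term

    total = n_steps + burn_in
    ia = rng.integers(0, n_ind, size=total)
    ib = rng.integers(0, n_ind, size=total)
    sa = rng.integers(0, 2, size=total)
    sb = rng.integers(0, 2, size=total)
    hits = np.empty(n_steps, dtype=bool)

    for step in range(total):
        a, b = ia[step], ib[step]
        if a != b:
            pa, pb = pairs[a], pairs[b]
            x, y = pa[sa[step]], pb[sb[step]]
            if x != y:
                before = [
                    (min(pa[0], pa[1]), max(pa[0], pa[1])),
                    (min(pb[0], pb[1]), max(pb[0], pb[1])),
                ]
                pa[sa[step]], pb[sb[step]] = y, x
                after = [
                    (min(pa[0], pa[1]), max(pa[0], pa[1])),
                    (min(pb[0], pb[1]), max(pb[0], pb[1])),
                ]
                affected = set(before) | set(after)
                for c in affected:
                    term -= cell_term(*c)
                for c in before:
                    counts[c] -= 1
                for c in after:
                    counts[c] += 1
                for c in affected:
                    term += cell_term(*c)
        if step >= burn_in:
            hits[step - burn_in] = term <= obs_term + 1e-9

    p = float(hits.mean())
    nb = min(50, max(2, n_steps // 100))
    width = n_steps // nb
    batch_means = hits[: nb * width].reshape(nb, width).mean(axis=1)
    se = float(batch_means.std(ddof=1) / math.sqrt(nb))
    return HWEResult(p, se, "mcmc", n_steps)


def hwe_exact_test(
    genotype_counts: Mapping[tuple[str, str], int],
    n_steps: int = 100_000,
    burn_in: int = 10_000,
    seed: Optional[int] = None,
    enumeration_limit: int = 200_000,
) -> HWEResult:
    """Exact test of Hardy-Weinberg proportions conditional on allele counts.

    The p-value is the null probability of a genotype table (with the observed
    allele-count margins) no more probable than the observed one.  For two
    alleles, or three alleles with a modest table-count bound, the null
    distribution is enumerated exactly.  Otherwise a seeded Markov chain over
    pairings of the 2n gene copies is run: single gene-copy swaps between
    individuals leave the uniform distribution over slot assignments
    invariant, and a uniform assignment induces exactly the conditional null
    over genotype tables.  The Monte-Carlo standard error is estimated by
    batch means (which absorbs chain autocorrelation).

    A monomorphic locus returns p = 1 directly.
    """
    for key, v in genotype_counts.items():
        if v < 0 or int(v) != v:
            raise ValueError(f"invalid genotype count {v!r} for {key}")
    gc = {k_: int(v) for k_, v in genotype_counts.items() if v > 0}
    margins = _allele_margins(gc)
    if len(margins) <= 1:
        return HWEResult(1.0, 0.0, "degenerate")
    k = len(margins)
    if k == 2 or (k == 3 and _n_tables_bound(margins) <= enumeration_limit):
        return _hwe_enumeration(gc)
    return _hwe_mcmc(gc, n_steps, burn_in, seed)


# ---------------------------------------------------------------------------
# Ewens-Watterson homozygosity test of neutrality
# ---------------------------------------------------------------------------

@dataclass
class EWResult:
    f_obs: float       # observed homozygosity sum p_i^2
    e_f: float         # null expectation of F given (2n, k)
    var_f: float       # null variance of F
    fnd: float         # (f_obs - e_f) / sqrt(var_f)
    p_lower: float     # Pr(F_null <= F_obs): small under balancing selection
    p_upper: float     # Pr(F_null >= F_obs): small under directional selection
    n_reps: int
    k: int
    n_copies: int


def _theta_for_k(n: int, k: int) -> float:
    """Newton-solve E[K] = sum_{i=0}^{n-1} theta/(theta+i) = k.

    The conditional distribution given K = k is theta-free, so theta only
    tunes the rejection-sampler acceptance rate.
    """
    i = np.arange(n, dtype=float)
    theta = float(k)
    for _ in range(100):
        f = float(np.sum(theta / (theta + i))) - k
        fp = float(np.sum(i / (theta + i) ** 2))
        if fp <= 0:
            break
        step = f / fp
        theta = max(theta - step, 1e-9)
        if abs(step) < 1e-10 * max(theta, 1.0):
            break
    return theta


def sample_neutral_homozygosity(
    n: int,
    k: int,
    n_reps: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    max_attempt_factor: int = 2000,
) -> np.ndarray:
    """Draw F = sum (n_i/n)^2 under the neutral Ewens sampling formula
    conditional on sample size *n* (gene copies) and *k* distinct alleles.

    Sampling uses the Feller-coupling representation of the Ewens sampling
    formula: with independent Bernoulli indicators xi_i ~ Bern(theta /
    (theta + i - 1)), i = 1..n, the allele configuration is exactly the set
    of spacings between successive ones in (xi_1, ..., xi_n) closed at
    position n+1, and the allele count K is the number of ones.  Replicates
    whose K differs from *k* are rejected; theta is tuned so E[K] = k, which
    maximises acceptance without affecting the conditional law.
    """
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    if rng is None:
        rng = np.random.default_rng(seed)
    if k == n:  # all singletons: conditional law is a point mass
        return np.full(n_reps, 1.0 / n)
    theta = _theta_for_k(n, k)
    p_one = theta / (theta + np.arange(n, dtype=float))  # xi_1 always one
    out = np.empty(n_reps)
    filled = 0
    attempts = 0
    chunk = int(min(max(2048, n_reps), 20_000))
    while filled < n_reps:
        attempts += chunk
        if attempts > max_attempt_factor * max(n_reps, 1000):
            raise RuntimeError(
                f"conditional-ESF rejection sampler too inefficient for n={n}, k={k}"
            )
        xi = rng.random((chunk, n), dtype=np.float32) < p_one.astype(np.float32)
        n_ones = xi.sum(axis=1)
        for r in np.nonzero(n_ones == k)[0]:
            if filled >= n_reps:
                break
            idx = np.flatnonzero(xi[r])
            sizes = np.diff(np.append(idx, n))
            out[filled] = float(np.sum((sizes / n) ** 2))
            filled += 1
    return out


def ewens_watterson(
    c: LocusCounts,
    n_reps: int = 100_000,
    seed: Optional[int] = None,
) -> EWResult:
    """Ewens-Watterson homozygosity test of neutrality.

    Compares the observed homozygosity F = sum p_i^2 with its null
    distribution under the neutral Ewens sampling formula conditional on the
    number of gene copies and distinct alleles, and reports the normalised
    deviation Fnd = (F_obs - E[F]) / sqrt(Var[F]).  Positive Fnd means excess
    homozygosity (directional selection or inbreeding); negative Fnd means a
    flatter-than-neutral frequency spectrum (balancing selection).
    """
    n, k = c.n_copies, c.k
    f_obs = c.homozygosity()
    if k < 2:
        return EWResult(1.0, 1.0, 0.0, float("nan"), 1.0, 1.0, 0, k, n)
    null = sample_neutral_homozygosity(n, k, n_reps, seed=seed)
    e_f = float(null.mean())
    var_f = float(null.var(ddof=1))
    fnd = (f_obs - e_f) / math.sqrt(var_f) if var_f > 1e-16 else float("nan")
    eps = 1e-12
    p_lower = float(np.mean(null <= f_obs + eps))
    p_upper = float(np.mean(null >= f_obs - eps))
    return EWResult(f_obs, e_f, var_f, fnd, p_lower, p_upper, n_reps, k, n)


# ---------------------------------------------------------------------------
# Fisher exact test and platform comparison
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: Sequence[Sequence[float]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table of nonnegative integers
    (probabilities of hypergeometric tables <= the observed one are summed)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 nonnegative integers")
    return float(stats.fisher_exact(np.round(t).astype(np.int64))[1])


def compare_platforms(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-allele comparison of allele counts between WGS and WES samples.

    For every detected allele at every locus, tests the 2x2 table
    (allele count vs all-other count, by platform) with the Fisher exact test
    and reports per-platform frequencies and their difference.
    """
    platforms = set(genotypes["platform"]) - {"NA"}
    if not {"WGS", "WES"} <= platforms:
        raise ValueError("need both WGS and WES platform labels")
    wgs = genotypes[genotypes["platform"] == "WGS"]
    wes = genotypes[genotypes["platform"] == "WES"]
    rows = []
    for locus in sorted(set(genotypes["locus"])):
        cw = allele_frequencies(wgs, locus).counts
        ce = allele_frequencies(wes, locus).counts
        tot_w, tot_e = sum(cw.values()), sum(ce.values())
        for allele in sorted(set(cw) | set(ce)):
            nw, ne = cw.get(allele, 0), ce.get(allele, 0)
            fw, fe = nw / tot_w, ne / tot_e
            p = fisher_exact_2x2([[nw, tot_w - nw], [ne, tot_e - ne]])
            rows.append(
                {
                    "locus": locus,
                    "allele": allele,
                    "count_WGS": nw,
                    "count_WES": ne,
                    "af_WGS": fw,
                    "af_WES": fe,
                    "delta_af": fw - fe,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def locus_summary(
    genotypes: pd.DataFrame,
    loci: Optional[Sequence[str]] = None,
    hwe_steps: int = 100_000,
    hwe_burn_in: int = 10_000,
    ew_reps: int = 100_000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """One-row-per-locus battery: 2n, k, Ho, He, HWE p, F_obs, E[F], Var[F],
    Fnd and the Ewens-Watterson p-values."""
    if loci is None:
        loci = sorted(set(genotypes["locus"]))
    ss = np.random.SeedSequence(seed)
    rows = []
    for locus, child in zip(loci, ss.spawn(len(list(loci)))):
        s1, s2 = child.spawn(2)
        c = allele_frequencies(genotypes, locus)
        ho, he_raw, he_unb = heterozygosity(c)
        hwe = hwe_exact_test(
            genotype_counts(genotypes, locus),
            n_steps=hwe_steps,
            burn_in=hwe_burn_in,
            seed=s1,
        )
        ew = (
            ewens_watterson(c, n_reps=ew_reps, seed=s2)
            if c.k >= 2
            else None
        )
        rows.append(
            {
                "locus": locus,
                "n_copies": c.n_copies,
                "k": c.k,
                "ho": ho,
                "he": he_raw,
                "he_unbiased": he_unb,
                "hwe_p": hwe.p_value,
                "hwe_se": hwe.se,
                "f_obs": c.homozygosity(),
                "ew_e_f": ew.e_f if ew else float("nan"),
                "ew_var_f": ew.var_f if ew else float("nan"),
                "fnd": ew.fnd if ew else float("nan"),
                "ew_p_lower": ew.p_lower if ew else float("nan"),
                "ew_p_upper": ew.p_upper if ew else float("nan"),
            }
        )
    return pd.DataFrame(rows)
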