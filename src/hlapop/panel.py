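"""Multi-population allele-frequency panels and comparative analyses.

A :class:`PopulationPanel` holds a populations x alleles matrix of two-field
allele frequencies (AFND-export-like input) plus per-population metadata
(region, sample size, typing standard).  On top of it this module provides:

* ``harmonize`` - trim reported alleles to two fields and sum duplicates;
* Nei's Gst and a sample-size-corrected Fst as pairwise distances;
* Saitou-Nei neighbor joining with Newick output;
* PCA of the (column-centred) frequency matrix;
* the double-clustered heatmap preparation (variance / frequency-sum filters
  and agglomerative leaf orders); and
* unique-allele and rare-absent-allele scans against a cohort table.

Corrected-Fst formulas (Nei & Chesser-style, frequencies-only)
--------------------------------------------------------------
For a pair of populations with sample sizes ``n1, n2`` individuals and
per-locus allele frequencies ``p_1i, p_2i``::

    h_j  = 2 n_j / (2 n_j - 1) * (1 - sum_i p_ji^2)   (unbiased within-pop)
    H_S  = (h_1 + h_2) / 2
    x_i  = (p_1i + p_2i) / 2
    n~   = harmonic mean of n_1, n_2
    H_T  = 1 - sum_i x_i^2 + H_S / (4 n~)

The observed-heterozygosity term of the full Nei-Chesser estimator is not
computable from allele-frequency panels and is omitted.  Both Gst and Fst
aggregate over loci as ``sum(H_T - H_S) / sum(H_T)``; the corrected variant
can be marginally negative for near-identical populations and is clamped to
[0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .nomenclature import parse_allele, trim_to_two_fields

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationPanel",
    "harmonize",
    "heatmap_prep",
    "gst_distance",
    "fst_corrected_distance",
    "Tree",
    "neighbor_joining",
    "pca_scores",
    "unique_alleles",
    "rare_absent_scan",
]


@dataclass
class PopulationPanel:
    """Populations x alleles frequency matrix with population metadata.

    ``frequencies`` is indexed by population name; columns are full two-field
    allele names (``A*02:01``).  ``meta`` carries ``region``, ``sample_n``
    and ``standard`` per population.
    """

    frequencies: pd.DataFrame
    meta: pd.DataFrame

    @property
    def populations(self) -> list[str]:
        return list(self.frequencies.index)

    def loci(self) -> list[str]:
        return sorted({c.split("*")[0] for c in self.frequencies.columns})

    def locus_columns(self, locus: str) -> list[str]:
        prefix = f"{locus}*"
        return [c for c in self.frequencies.columns if c.startswith(prefix)]

    def add_population(
        self,
        name: str,
        freqs: Mapping[str, float],
        region: str = "NA",
        sample_n: int = 0,
        standard: str = "NA",
    ) -> "PopulationPanel":
        row = pd.DataFrame(
            [dict(freqs)], index=pd.Index([name], name="population")
        )
        newf = (
            pd.concat([self.frequencies, row]).fillna(0.0).astype(float)
        )
        newm = pd.concat(
            [
                self.meta,
                pd.DataFrame(
                    [{"region": region, "sample_n": sample_n,
                      "standard": standard}],
                    index=pd.Index([name], name="population"),
                ),
            ]
        )
        return PopulationPanel(newf, newm)


def harmonize(
    rows: pd.DataFrame,
    min_n: int = 95,
    gold_only: bool = False,
    apply_filters: bool = False,
) -> PopulationPanel:
    """Build a panel from raw rows, trimming alleles and summing duplicates.

    *rows* has columns ``population, region, sample_n, standard, locus,
    allele, frequency``.  Reported G-group or >2-field names are trimmed to
    two fields and frequencies of identical trimmed alleles in the same
    population are summed.  With ``apply_filters`` populations failing the
    ``sample_n > min_n`` or (if ``gold_only``) the Gold typing-standard
    criterion are dropped; otherwise they are only flagged in ``meta``.
    """
    freqs: dict[str, dict[str, float]] = {}
    meta: dict[str, dict] = {}
    for i, row in enumerate(rows.itertuples(index=False)):
        f = float(row.frequency)
        if not 0.0 <= f <= 1.0:
            raise ValueError(
                f"row {i}: frequency {f} outside [0, 1] "
                f"({row.population}, {row.allele})"
            )
        name = str(row.allele)
        if "*" not in name:
            name = f"{row.locus}*{name}"
        allele = trim_to_two_fields(parse_allele(name))
        col = str(allele)
        pop = str(row.population)
        freqs.setdefault(pop, {})
        freqs[pop][col] = freqs[pop].get(col, 0.0) + f
        meta.setdefault(
            pop,
            {
                "region": str(row.region),
                "sample_n": int(row.sample_n),
                "standard": str(row.standard),
            },
        )
    fdf = pd.DataFrame.from_dict(freqs, orient="index").fillna(0.0)
    fdf.index.name = "population"
    fdf = fdf[sorted(fdf.columns)]
    mdf = pd.DataFrame.from_dict(meta, orient="index")
    mdf.index.name = "population"
    mdf["passes_filters"] = (mdf["sample_n"] > min_n) & (
        (mdf["standard"].str.lower() == "gold") if gold_only else True
    )
    if apply_filters:
        keep = mdf.index[mdf["passes_filters"]]
        fdf, mdf = fdf.loc[keep], mdf.loc[keep]
    return PopulationPanel(fdf, mdf.loc[fdf.index])


def heatmap_prep(
    panel: PopulationPanel,
    var_min: float = 0.001,
    pop_sum_min: float = 0.9,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Filter and order the frequency matrix for a double-clustered heatmap.

    Alleles with variance < ``var_min`` across populations are removed first,
    then populations whose remaining total allele-frequency sum is below
    ``pop_sum_min``.  Row and column orders come from average-linkage
    agglomerative clustering on Euclidean distances.
    """
    m = panel.frequencies
    m = m.loc[:, m.var(axis=0, ddof=0) >= var_min]
    m = m.loc[m.sum(axis=1) >= pop_sum_min]
    if m.empty or m.shape[1] == 0:
        raise ValueError("all rows or columns removed by heatmap filters")

    def leaf_order(mat: np.ndarray, labels: Sequence[str]) -> list[str]:
        if len(labels) < 3:
            return list(labels)
        link = hierarchy.linkage(pdist(mat), method="average")
        return [labels[i] for i in hierarchy.leaves_list(link)]

    row_order = leaf_order(m.values, list(m.index))
    col_order = leaf_order(m.values.T, list(m.columns))
    return m, row_order, col_order


# ---------------------------------------------------------------------------
# Gst / corrected Fst
# ---------------------------------------------------------------------------

def _pair_locus_terms(
    p1: np.ndarray, p2: np.ndarray
) -> tuple[float, float]:
    """(Ht, Hs) for one locus of one population pair, uncorrected (Nei Gst)."""
    hs = 0.5 * ((1.0 - np.sum(p1**2)) + (1.0 - np.sum(p2**2)))
    xbar = 0.5 * (p1 + p2)
    ht = 1.0 - float(np.sum(xbar**2))
    return ht, float(hs)


def _pair_locus_terms_corrected(
    p1: np.ndarray, p2: np.ndarray, n1: float, n2: float
) -> tuple[float, float]:
    """(Ht, Hs) with the sample-size correction documented in the module
    docstring; n1, n2 are numbers of individuals."""
    h1 = 2 * n1 / (2 * n1 - 1) * (1.0 - float(np.sum(p1**2)))
    h2 = 2 * n2 / (2 * n2 - 1) * (1.0 - float(np.sum(p2**2)))
    hs = 0.5 * (h1 + h2)
    xbar = 0.5 * (p1 + p2)
    n_harm = 2.0 / (1.0 / n1 + 1.0 / n2)
    ht = 1.0 - float(np.sum(xbar**2)) + hs / (4.0 * n_harm)
    return ht, hs


def _distance_matrix(
    panel: PopulationPanel,
    loci: Sequence[str],
    corrected: bool,
) -> pd.DataFrame:
    pops = panel.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    cols_per_locus = {}
    for locus in loci:
        cols = panel.locus_columns(locus)
        if not cols:
            raise ValueError(f"locus {locus} absent from panel")
        cols_per_locus[locus] = cols
    if corrected:
        n = panel.meta["sample_n"].astype(float)
        if (n <= 0).any():
            raise ValueError("corrected Fst requires positive sample_n for "
                             "every population")
    d = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            ht_sum = 0.0
            num_sum = 0.0
            for locus, cols in cols_per_locus.items():
                p1 = panel.frequencies.loc[a, cols].to_numpy(dtype=float)
                p2 = panel.frequencies.loc[b, cols].to_numpy(dtype=float)
                if corrected:
                    ht, hs = _pair_locus_terms_corrected(
                        p1, p2, float(n[a]), float(n[b])
                    )
                else:
                    ht, hs = _pair_locus_terms(p1, p2)
                ht_sum += ht
                num_sum += ht - hs
            val = num_sum / ht_sum if ht_sum > 0 else 0.0
            val = min(max(val, 0.0), 1.0)
            d.loc[a, b] = d.loc[b, a] = val
    return d


def gst_distance(
    panel: PopulationPanel, loci: Sequence[str]
) -> pd.DataFrame:
    """Pairwise Nei Gst over *loci*: sum(Ht - Hs) / sum(Ht) per pair, with
    Hs the mean within-population gene diversity and Ht the diversity of the
    pair's mean frequencies."""
    return _distance_matrix(panel, loci, corrected=False)


def fst_corrected_distance(
    panel: PopulationPanel, loci: Sequence[str]
) -> pd.DataFrame:
    """Pairwise sample-size-corrected Fst (formulas in the module docstring);
    population sample sizes come from the panel metadata."""
    return _distance_matrix(panel, loci, corrected=True)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class Tree:
    """Minimal unrooted tree: nodes are ints, leaves carry labels."""

    children: dict[int, list[tuple[int, float]]]
    labels: dict[int, str]
    root: int

    def newick(self) -> str:
        def rec(node: int) -> str:
            kids = self.children.get(node, [])
            if not kids:
                return self.labels[node]
            inner = ",".join(
                f"{rec(c)}:{bl:.17g}" for c, bl in kids
            )
            return f"({inner})"

        return rec(self.root) + ";"

    def leaf_labels(self) -> set[str]:
        return set(self.labels.values())


def neighbor_joining(d: pd.DataFrame) -> Tree:
    """Saitou-Nei neighbor joining of a labeled distance matrix.

    Deterministic: the Q-criterion minimum is tie-broken by label order.
    Negative branch lengths are clamped to zero with the excess transferred
    to the sibling branch (standard NJ post-processing).  The returned tree
    is serialisable to Newick; the final three nodes are joined on an
    unrooted trifurcation.
    """
    labels = list(d.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = d.to_numpy(dtype=float)
    if not np.allclose(dm, dm.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")

    next_id = len(labels)
    active: list[int] = list(range(len(labels)))
    names: dict[int, str] = {i: lab for i, lab in enumerate(labels)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            dist[(i, j)] = dist[(j, i)] = dm[i, j]
    children: dict[int, list[tuple[int, float]]] = {}
    sort_key: dict[int, str] = dict(names)

    def clamp(pair: list[tuple[int, float]]) -> list[tuple[int, float]]:
        (c1, b1), (c2, b2) = pair
        if b1 < 0:
            b2 += b1
            b1 = 0.0
            logger.info("clamped negative NJ branch; excess moved to sibling")
        if b2 < 0:
            b1 += b2
            b2 = 0.0
            logger.info("clamped negative NJ branch; excess moved to sibling")
        return [(c1, max(b1, 0.0)), (c2, max(b2, 0.0))]

    while len(active) > 3:
        r = len(active)
        rowsum = {i: sum(dist[(i, j)] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * dist[(i, j)] - rowsum[i] - rowsum[j]
                key = (q, min(sort_key[i], sort_key[j]),
                       max(sort_key[i], sort_key[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = dist[(i, j)]
        bi = 0.5 * dij + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        bj = dij - bi
        new = next_id
        next_id += 1
        children[new] = clamp([(i, bi), (j, bj)])
        sort_key[new] = min(sort_key[i], sort_key[j])
        for m in active:
            if m in (i, j):
                continue
            dnm = 0.5 * (dist[(i, m)] + dist[(j, m)] - dij)
            dist[(new, m)] = dist[(m, new)] = dnm
        active = [m for m in active if m not in (i, j)] + [new]

    # final trifurcation
    i, j, k = sorted(active, key=lambda m: sort_key[m])
    bi = 0.5 * (dist[(i, j)] + dist[(i, k)] - dist[(j, k)])
    bj = 0.5 * (dist[(i, j)] + dist[(j, k)] - dist[(i, k)])
    bk = 0.5 * (dist[(i, k)] + dist[(j, k)] - dist[(i, j)])
    root = next_id
    children[root] = [
        (i, max(bi, 0.0)), (j, max(bj, 0.0)), (k, max(bk, 0.0))
    ]
    leaf_labels = {m: names[m] for m in names}
    return Tree(children=children, labels=leaf_labels, root=root)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_scores(
    panel: PopulationPanel, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA scores of the column-centred frequency matrix (no scaling:
    frequencies already share a scale, and unit-variance scaling would
    up-weight rare alleles).

    Components are ordered by explained variance; each component's sign is
    fixed by making its largest-magnitude loading positive.  Requesting more
    components than the matrix rank truncates with a warning.  Returns
    (scores frame indexed by population, explained-variance fractions).
    """
    x = panel.frequencies.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two populations")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = max(xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if n_components > rank:
        logger.warning(
            "requested %d components but rank is %d; truncating",
            n_components, rank,
        )
        n_components = max(rank, 1)
    for c in range(n_components):
        pivot = np.argmax(np.abs(vt[c]))
        if vt[c, pivot] < 0:
            vt[c] = -vt[c]
            u[:, c] = -u[:, c]
    scores = u[:, :n_components] * s[:n_components]
    total_var = float(np.sum(s**2))
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(
        n_components
    )
    frame = pd.DataFrame(
        scores,
        index=panel.frequencies.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, evr


# ---------------------------------------------------------------------------
# unique / rare allele scans
# ---------------------------------------------------------------------------

@dataclass
class UniqueAlleleReport:
    cohort_only: dict[str, float]        # allele -> cohort AF
    reference_only: dict[str, float]     # allele -> reference AF
    cohort_max: Optional[tuple[str, float]] = None
    reference_max: Optional[tuple[str, float]] = None


def unique_alleles(
    cohort: Mapping[str, Mapping[str, float]],
    reference: Mapping[str, Mapping[str, float]],
    loci: Sequence[str],
) -> UniqueAlleleReport:
    """Set differences of detected alleles per locus between a cohort and a
    reference frequency table, with each side's maximum-AF representative.

    Both mappings are locus -> {two-field allele name -> frequency}.
    """
    cohort_only: dict[str, float] = {}
    reference_only: dict[str, float] = {}
    for locus in loci:
        c = cohort.get(locus, {})
        r = reference.get(locus, {})
        for a in set(c) - set(r):
            cohort_only[f"{locus}*{a}" if "*" not in a else a] = c[a]
        for a in set(r) - set(c):
            reference_only[f"{locus}*{a}" if "*" not in a else a] = r[a]
    report = UniqueAlleleReport(cohort_only, reference_only)
    if cohort_only:
        report.cohort_max = max(cohort_only.items(), key=lambda kv: kv[1])
    if reference_only:
        report.reference_max = max(
            reference_only.items(), key=lambda kv: kv[1]
        )
    return report


def rare_absent_scan(
    cohort: Mapping[str, Mapping[str, float]],
    panel: PopulationPanel,
    af_max: float = 0.003,
) -> list[tuple[str, float]]:
    """Cohort alleles with 0 < AF < ``af_max`` absent (or all-zero) in every
    panel population.  Allele names must be harmonized on both sides."""
    out = []
    cols = set(panel.frequencies.columns)
    for locus, freqs in cohort.items():
        for a, f in freqs.items():
            if not 0.0 < f < af_max:
                continue
            name = a if "*" in a else f"{locus}*{a}"
            if name not in cols or float(
                panel.frequencies[name].max()
            ) <= 0.0:
                out.append((name, f))
    return sorted(out)
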