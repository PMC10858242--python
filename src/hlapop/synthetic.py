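"""Synthetic cohort generator for end-to-end pipeline testing.

Individual-level HLA data from real cohorts are access-restricted, so every
input the pipeline consumes is generated here with controlled statistical
structure: a haplotype pool over multi-allelic loci (inducing linkage
disequilibrium), diploid samples drawn from it under stratum-specific
inbreeding coefficients, two noisy caller outputs (with configurable
per-locus error rates, G-group reporting and missingness), an error-free
gold-standard subset, a reference allele-frequency table, a synthetic
G-group definition file, and bimodal ROH summaries.

The defaults mirror the cohort structure the pipeline is designed for:
570 samples (~25% WGS, 75% WES), 8 classical HLA loci, a 36-sample
gold-standard subset, and a skewed (Dirichlet 0.5) allele-frequency
spectrum.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .nomenclature import MISSING, GGroupTable, load_g_groups

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_population",
    "simulate_tool_calls",
    "simulate_roh",
    "write_inputs",
    "policy_scenario_config",
]

DEFAULT_LOCI = ("A", "B", "C", "DRB1", "DQA1", "DQB1", "DPA1", "DPB1")

PerLocus = Union[float, str, dict]


def _per_locus(value: PerLocus, locus: str):
    return value.get(locus, value.get("default")) if isinstance(value, dict) else value


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic cohort.

    Error rates and ``error_target`` may be scalars or per-locus dicts.
    ``error_target`` controls which wrong allele a miscall produces:
    ``"uniform"`` (any other allele, equiprobable), ``"rare"`` (the
    lowest-frequency other allele; allele-frequency voting rescues these) or
    ``"top"`` (the highest-frequency other allele; voting is defeated and
    inherits the error).
    """

    loci: tuple[str, ...] = DEFAULT_LOCI
    n_alleles: int = 15
    dirichlet_conc: float = 0.5
    n_haplotypes: int = 60
    n_samples: int = 570
    wgs_fraction: float = 142 / 570
    gold_size: int = 36
    f_low: float = 0.0
    f_high: float = 0.10
    high_fraction: float = 0.30
    tool1_error: PerLocus = 0.04
    tool2_error: PerLocus = 0.02
    error_target: PerLocus = "uniform"
    g_group_prob: float = 0.30
    missing_prob: float = 0.01
    group_every: int = 2
    roh_low_mean_bp: float = 4.0e7
    roh_high_mean_bp: float = 3.5e8
    roh_low_segments: float = 25.0
    roh_high_segments: float = 90.0
    roh_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.gold_size <= self.n_samples:
            raise ValueError("gold_size must be <= n_samples")


def policy_scenario_config(seed: int = 0, **overrides) -> SimConfig:
    """A configuration whose caller-error structure forces the per-locus
    policy {A: vote, DRB1: vote, B/C/DQB1/DPB1: tool_2} by construction:
    at A and DRB1 both tools miscall toward near-zero-AF alleles (so AF
    voting recovers the truth and beats either tool), while at B, C, DQB1
    and DPB1 tool 1 miscalls toward the top-AF allele at five times tool 2's
    rate (so voting inherits tool 1's errors and tool 2 wins)."""
    vote_loci = ("A", "DRB1")
    tool2_loci = ("B", "C", "DQB1", "DPB1")
    cfg = SimConfig(
        loci=vote_loci + tool2_loci,
        n_samples=300,
        gold_size=120,
        tool1_error={**{l: 0.20 for l in vote_loci},
                     **{l: 0.25 for l in tool2_loci}},
        tool2_error={**{l: 0.20 for l in vote_loci},
                     **{l: 0.05 for l in tool2_loci}},
        error_target={**{l: "rare" for l in vote_loci},
                      **{l: "top" for l in tool2_loci}},
        g_group_prob=0.0,
        missing_prob=0.0,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    config: SimConfig
    allele_names: dict[str, list[str]]
    target_freqs: dict[str, np.ndarray]          # Dirichlet draw per locus
    pool: list[tuple[str, ...]]                  # haplotypes (one allele/locus)
    pool_weights: np.ndarray
    samples: pd.DataFrame                        # sample_id, stratum, platform
    hap_indices: np.ndarray                      # (n_samples, 2) into pool
    genotypes: pd.DataFrame                      # genotype TSV dialect
    g_group_lines: list[str]
    g_groups: GGroupTable

    @property
    def allele_freqs(self) -> dict[str, dict[str, float]]:
        """Pool-weighted marginal allele frequencies per locus."""
        out: dict[str, dict[str, float]] = {}
        for li, locus in enumerate(self.config.loci):
            freqs: dict[str, float] = {}
            for hap, w in zip(self.pool, self.pool_weights):
                freqs[hap[li]] = freqs.get(hap[li], 0.0) + float(w)
            out[locus] = freqs
        return out

    def reference_af_table(self) -> pd.DataFrame:
        rows = [
            {"locus": locus, "allele": a, "frequency": f}
            for locus, fr in self.allele_freqs.items()
            for a, f in sorted(fr.items())
        ]
        return pd.DataFrame(rows)

    def haplotype_frequencies(self) -> dict[tuple[str, ...], float]:
        out: dict[tuple[str, ...], float] = {}
        for hap, w in zip(self.pool, self.pool_weights):
            out[hap] = out.get(hap, 0.0) + float(w)
        return out


def _allele_name(i: int) -> str:
    return f"{i + 1:02d}:01"


def _g_group_lines(cfg: SimConfig) -> list[str]:
    """Synthetic group-definition file: every ``group_every``-th allele at
    each locus belongs to a G group with two intron-variant members."""
    lines = ["# synthetic G-group definitions"]
    for locus in cfg.loci:
        for i in range(cfg.n_alleles):
            two = _allele_name(i)
            if cfg.group_every > 0 and i % cfg.group_every == 0:
                lines.append(f"{locus}*;{two}:01/{two}:02;{two}:01G")
            else:
                lines.append(f"{locus}*;{two}:01;")
    return lines


def simulate_population(cfg: SimConfig) -> SimTruth:
    """Draw the population truth: allele spectra, haplotype pool, diploid
    genotypes with stratified inbreeding, platform labels.

    Per locus, target frequencies come from a symmetric Dirichlet
    (concentration ``dirichlet_conc``; 0.5 gives the heavy-tailed spectra
    typical of HLA).  The haplotype pool samples each locus independently
    from the target spectrum and carries Dirichlet(1) weights, inducing
    linkage disequilibrium.  Each sample draws two pool haplotypes; with
    probability F (its stratum's inbreeding coefficient) the second copies
    the first, creating identity-by-descent homozygosity.
    """
    if cfg.n_haplotypes < 1:
        raise ValueError("need at least one haplotype in the pool")
    rng = np.random.default_rng([cfg.seed, 0])
    allele_names = {
        locus: [_allele_name(i) for i in range(cfg.n_alleles)]
        for locus in cfg.loci
    }
    target = {
        locus: rng.dirichlet(np.full(cfg.n_alleles, cfg.dirichlet_conc))
        for locus in cfg.loci
    }
    pool = []
    for _ in range(cfg.n_haplotypes):
        hap = tuple(
            allele_names[locus][rng.choice(cfg.n_alleles, p=target[locus])]
            for locus in cfg.loci
        )
        pool.append(hap)
    weights = rng.dirichlet(np.ones(cfg.n_haplotypes))

    stratum = np.where(
        rng.random(cfg.n_samples) < cfg.high_fraction, "high", "low"
    )
    platform = np.where(
        rng.random(cfg.n_samples) < cfg.wgs_fraction, "WGS", "WES"
    )
    f_by_stratum = {"high": cfg.f_high, "low": cfg.f_low}
    h1 = rng.choice(cfg.n_haplotypes, size=cfg.n_samples, p=weights)
    h2 = rng.choice(cfg.n_haplotypes, size=cfg.n_samples, p=weights)
    ibd = rng.random(cfg.n_samples) < np.array(
        [f_by_stratum[s] for s in stratum]
    )
    h2 = np.where(ibd, h1, h2)

    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    rows = []
    for si, sid in enumerate(sample_ids):
        hap_a, hap_b = pool[h1[si]], pool[h2[si]]
        for li, locus in enumerate(cfg.loci):
            rows.append(
                {
                    "sample_id": sid,
                    "locus": locus,
                    "allele1": hap_a[li],
                    "allele2": hap_b[li],
                    "tool": "truth",
                    "platform": platform[si],
                }
            )
    genotypes = pd.DataFrame(rows)
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "stratum": stratum, "platform": platform}
    )
    lines = _g_group_lines(cfg)
    g_groups = load_g_groups(lines)
    return SimTruth(
        config=cfg,
        allele_names=allele_names,
        target_freqs=target,
        pool=pool,
        pool_weights=weights,
        samples=samples,
        hap_indices=np.column_stack([h1, h2]),
        genotypes=genotypes,
        g_group_lines=lines,
        g_groups=g_groups,
    )


def _error_allele(
    truth_allele: str,
    locus: str,
    freqs: dict[str, float],
    names: list[str],
    mode: str,
    rng: np.random.Generator,
) -> str:
    others = [a for a in names if a != truth_allele]
    if mode == "rare":
        return min(others, key=lambda a: (freqs.get(a, 0.0), a))
    if mode == "top":
        return max(others, key=lambda a: (freqs.get(a, 0.0), a))
    return others[rng.integers(len(others))]


def simulate_tool_calls(
    truth: SimTruth, cfg: Optional[SimConfig] = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Corrupt the truth into two caller outputs plus the gold subset.

    Each allele copy is independently miscalled with the tool's (per-locus)
    error rate, replaced per the locus's ``error_target`` mode; tool 2
    reports the G-group name of a group-member allele with probability
    ``g_group_prob``; each reported allele is dropped to missing with
    probability ``missing_prob``.  The gold standard is the error-free truth
    of the first ``gold_size`` samples.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng([cfg.seed, 1])
    freqs = truth.allele_freqs
    group_name = {
        (locus, _allele_name(i)): f"{_allele_name(i)}:01G"
        for locus in cfg.loci
        for i in range(cfg.n_alleles)
        if cfg.group_every > 0 and i % cfg.group_every == 0
    }

    def corrupt(tool: str, error: PerLocus, groupy: bool) -> pd.DataFrame:
        out = []
        for row in truth.genotypes.itertuples(index=False):
            locus = row.locus
            e = float(_per_locus(error, locus))
            mode = str(_per_locus(cfg.error_target, locus))
            alleles = []
            for a in (row.allele1, row.allele2):
                if rng.random() < e:
                    a = _error_allele(
                        a, locus, freqs[locus],
                        truth.allele_names[locus], mode, rng,
                    )
                if groupy and (locus, a) in group_name and (
                    rng.random() < cfg.g_group_prob
                ):
                    a = group_name[(locus, a)]
                if rng.random() < cfg.missing_prob:
                    a = MISSING
                alleles.append(a)
            out.append(
                {
                    "sample_id": row.sample_id,
                    "locus": locus,
                    "allele1": alleles[0],
                    "allele2": alleles[1],
                    "tool": tool,
                    "platform": row.platform,
                }
            )
        return pd.DataFrame(out)

    calls1 = corrupt("tool_1", cfg.tool1_error, groupy=False)
    calls2 = corrupt("tool_2", cfg.tool2_error, groupy=True)
    gold_ids = set(truth.samples["sample_id"].iloc[: cfg.gold_size])
    gold = truth.genotypes[
        truth.genotypes["sample_id"].isin(gold_ids)
    ].assign(tool="gold")
    return calls1, calls2, gold.reset_index(drop=True)


def simulate_roh(
    truth: SimTruth, cfg: Optional[SimConfig] = None
) -> pd.DataFrame:
    """Bimodal per-sample ROH summaries (lognormal components per stratum).

    High-inbreeding samples draw total length and segment count from the
    high-mean component; with the default parameters the components are well
    separated and 2-means recovers the strata.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng([cfg.seed, 2])
    rows = []
    for row in truth.samples.itertuples(index=False):
        high = row.stratum == "high"
        mean_bp = cfg.roh_high_mean_bp if high else cfg.roh_low_mean_bp
        mean_seg = cfg.roh_high_segments if high else cfg.roh_low_segments
        total = float(
            rng.lognormal(mean=np.log(mean_bp), sigma=cfg.roh_sigma)
        )
        nseg = max(
            1,
            int(round(rng.lognormal(mean=np.log(mean_seg),
                                    sigma=cfg.roh_sigma))),
        )
        rows.append(
            {
                "sample_id": row.sample_id,
                "total_roh_bp": total,
                "n_segments": nseg,
                "platform": row.platform,
            }
        )
    return pd.DataFrame(rows)


def write_inputs(
    truth: SimTruth,
    out_dir: Union[str, Path],
    calls1: Optional[pd.DataFrame] = None,
    calls2: Optional[pd.DataFrame] = None,
    gold: Optional[pd.DataFrame] = None,
    roh: Optional[pd.DataFrame] = None,
) -> dict[str, Path]:
    """Emit all pipeline input files (TSV/CSV/JSON) into *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if calls1 is None or calls2 is None or gold is None:
        calls1, calls2, gold = simulate_tool_calls(truth)
    if roh is None:
        roh = simulate_roh(truth)
    paths = {
        "tool_1": out / "calls_tool1.tsv",
        "tool_2": out / "calls_tool2.tsv",
        "gold": out / "gold.tsv",
        "reference_af": out / "reference_af.tsv",
        "g_groups": out / "g_groups.txt",
        "roh": out / "roh.tsv",
        "truth": out / "truth.json",
    }
    calls1.to_csv(paths["tool_1"], sep="\t", index=False)
    calls2.to_csv(paths["tool_2"], sep="\t", index=False)
    gold.to_csv(paths["gold"], sep="\t", index=False)
    truth.reference_af_table().to_csv(
        paths["reference_af"], sep="\t", index=False
    )
    paths["g_groups"].write_text("\n".join(truth.g_group_lines) + "\n")
    roh.to_csv(paths["roh"], sep="\t", index=False)
    truth_json = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(truth.config).items()
        },
        "allele_freqs": truth.allele_freqs,
        "haplotype_frequencies": {
            "~".join(h): f for h, f in truth.haplotype_frequencies().items()
        },
        "strata": dict(
            zip(truth.samples["sample_id"], truth.samples["stratum"])
        ),
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=1))
    return paths
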