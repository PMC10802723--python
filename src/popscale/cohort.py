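"""Cohort discovery statistics.

Implements the downstream analyses run once variants carry calibrated
scores: enrichment of flagged de-novo mutations over the rate-based
expectation, a Monte-Carlo gene-collapsing test against the mutation-rate
null, Benjamini–Hochberg adjustment, per-patient variant ranking,
gene-level constraint summaries with two-sample KS comparison, and the
interaction-network degree permutation test.

Null model used throughout: over N probands, DNM counts are Poisson with
mean 2·N·Σμ (diploid factor times summed per-haploid rates) and variant
identities are drawn with probability proportional to μ.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, ParameterError
from .mixture import Band, Thresholds, classify
from .types import (
    CohortObservation,
    GeneSet,
    Group,
    Inheritance,
    InteractionGraph,
    MutationRate,
    ScoredVariant,
    VariantKey,
)


@dataclass
class EnrichmentResult:
    band: str
    observed: int
    expected: float
    fold: float
    poisson_p: float
    ci95: Tuple[float, float]


class DiscoveryRoute(str, Enum):
    VARIANT_THRESHOLD = "variant_threshold"
    GENE_COLLAPSING = "gene_collapsing"
    BOTH = "both"
    NONE = "none"


@dataclass
class GeneTestResult:
    gene_id: str
    n_dnms: int
    statistic: float
    p_value: float
    q_value: Optional[float] = None
    discovery_route: DiscoveryRoute = DiscoveryRoute.NONE


@dataclass
class NetworkTestResult:
    mean_degree_base: float
    mean_degree_augmented: float
    permutation_p: float
    n_random: int


# ---------------------------------------------------------------------------
# enrichment


def expected_dnm_count(
    rates: Sequence[MutationRate],
    n_probands: int,
    band_filter: Optional[Callable[[VariantKey], bool]] = None,
) -> float:
    """Expected DNM count over the cohort: 2 · N · Σμ (optionally band-filtered)."""
    if not rates:
        raise ParameterError("empty rate table")
    if n_probands < 1:
        raise ParameterError(f"n_probands must be >= 1, got {n_probands}")
    total = sum(r.mu for r in rates if band_filter is None or band_filter(r.key))
    return 2.0 * n_probands * total


def enrichment_test(observed: int, expected: float, band: str = "") -> EnrichmentResult:
    """Fold enrichment with exact Poisson upper-tail p and 95% CI.

    The CI is the exact (Garwood) interval for a Poisson mean given the
    observed count, divided by the expectation — so it always brackets the
    point estimate observed/expected.
    """
    if expected <= 0:
        raise ParameterError(f"expected must be > 0, got {expected}")
    if observed < 0:
        raise ParameterError(f"observed must be >= 0, got {observed}")
    fold = observed / expected
    p = float(stats.poisson.sf(observed - 1, expected))  # P(X >= observed)
    lo = 0.0 if observed == 0 else float(stats.chi2.ppf(0.025, 2 * observed) / 2.0)
    hi = float(stats.chi2.ppf(0.975, 2 * observed + 2) / 2.0)
    return EnrichmentResult(
        band=band,
        observed=observed,
        expected=expected,
        fold=fold,
        poisson_p=p,
        ci95=(lo / expected, hi / expected),
    )


def band_enrichment(
    cohort: Sequence[CohortObservation],
    scores: Mapping[VariantKey, float],
    rates: Sequence[MutationRate],
    thresholds: Thresholds,
    n_probands: int,
    group: Group = Group.CASE,
) -> List[EnrichmentResult]:
    """Per-band enrichment of observed case DNMs over the rate expectation.

    Expected counts are band-filtered: each rate contributes to the band its
    variant's score falls in, so every possible variant is classified.
    """
    for r in rates:
        if r.key not in scores:
            raise ConsistencyError(f"rate table variant {r.key} has no score")
    results = []
    for band in Band:
        def in_band(k: VariantKey, band=band) -> bool:
            return classify(scores[k], thresholds) == band

        observed = sum(
            1
            for o in cohort
            if o.group == group
            and o.inheritance == Inheritance.DNM
            and o.key in scores
            and classify(scores[o.key], thresholds) == band
        )
        expected = expected_dnm_count(rates, n_probands, band_filter=in_band)
        if expected > 0:
            results.append(enrichment_test(observed, expected, band=band.value))
    return results


# ---------------------------------------------------------------------------
# gene collapsing


def gene_collapsing_test(
    gene_scores: Mapping[VariantKey, float],
    gene_rates: Sequence[MutationRate],
    observed_dnms: Sequence[VariantKey],
    n_probands: int,
    n_sims: int = 10_000,
    seed: int = 0,
    variant_weight: Optional[Callable[[float], float]] = None,
) -> GeneTestResult:
    """Monte-Carlo collapsing test for one gene.

    Statistic T = Σ over observed DNMs of w(score) with w(s) = -s by
    default (more pathogenic scores contribute more).  Under the null the
    gene's DNM count is Poisson(2·N·Σμ) and variant identities are drawn
    with probability ∝ μ; the one-sided Monte-Carlo p uses the add-one
    correction p = (1 + #{T_null >= T_obs}) / (n_sims + 1), so p > 0 always.
    """
    if n_sims < 1000:
        raise ParameterError(f"n_sims must be >= 1000, got {n_sims}")
    if not gene_rates:
        raise ParameterError("empty rate table for gene")
    w = variant_weight or (lambda s: -s)
    for k in observed_dnms:
        if k not in gene_scores:
            raise ConsistencyError(f"observed DNM {k} missing from the score table")
    rate_keys = [r.key for r in gene_rates]
    for k in rate_keys:
        if k not in gene_scores:
            raise ConsistencyError(f"rate-table variant {k} missing from the score table")
    genes = {k.gene_id for k in rate_keys} | {k.gene_id for k in observed_dnms}
    gene_id = sorted(genes)[0] if genes else ""

    mus = np.array([r.mu for r in gene_rates])
    weights = np.array([w(gene_scores[k]) for k in rate_keys])
    lam = 2.0 * n_probands * mus.sum()
    probs = mus / mus.sum()
    t_obs = float(sum(w(gene_scores[k]) for k in observed_dnms))

    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, size=n_sims)
    total = int(counts.sum())
    t_null = np.zeros(n_sims)
    if total > 0:
        draws = rng.choice(len(rate_keys), size=total, p=probs)
        sim_idx = np.repeat(np.arange(n_sims), counts)
        t_null = np.bincount(sim_idx, weights=weights[draws], minlength=n_sims)
    p = (1.0 + float((t_null >= t_obs).sum())) / (n_sims + 1.0)
    return GeneTestResult(
        gene_id=gene_id,
        n_dnms=len(observed_dnms),
        statistic=t_obs,
        p_value=p,
    )


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini–Hochberg step-up q-values with monotonicity enforced."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ParameterError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def collapse_genes(
    cohort: Sequence[CohortObservation],
    scores: Mapping[VariantKey, float],
    rates: Sequence[MutationRate],
    n_probands: int,
    n_sims: int = 10_000,
    seed: int = 0,
    thresholds: Optional[Thresholds] = None,
    q_threshold: float = 0.05,
) -> List[GeneTestResult]:
    """Run the collapsing test for every gene with >= 1 case DNM; BH-adjust.

    ``discovery_route`` marks how each gene would be discovered: a variant
    at or below the severe cutoff (``variant_threshold``), a significant
    collapsing q-value (``gene_collapsing``), both, or neither.
    """
    dnms: Dict[str, List[VariantKey]] = {}
    for o in cohort:
        if o.group == Group.CASE and o.inheritance == Inheritance.DNM:
            dnms.setdefault(o.key.gene_id, []).append(o.key)
    rates_by_gene: Dict[str, List[MutationRate]] = {}
    for r in rates:
        rates_by_gene.setdefault(r.key.gene_id, []).append(r)

    results = []
    for gi, gene in enumerate(sorted(dnms)):
        if gene not in rates_by_gene:
            raise ConsistencyError(f"gene {gene} has observed DNMs but no rates")
        res = gene_collapsing_test(
            scores,
            rates_by_gene[gene],
            dnms[gene],
            n_probands,
            n_sims=n_sims,
            seed=seed + gi,
        )
        res.gene_id = gene
        results.append(res)
    qs = bh_adjust([r.p_value for r in results])
    for res, q in zip(results, qs):
        res.q_value = q
        by_gene_collapse = q < q_threshold
        by_variant = thresholds is not None and any(
            scores[k] <= thresholds.severe_cutoff for k in dnms[res.gene_id]
        )
        if by_variant and by_gene_collapse:
            res.discovery_route = DiscoveryRoute.BOTH
        elif by_variant:
            res.discovery_route = DiscoveryRoute.VARIANT_THRESHOLD
        elif by_gene_collapse:
            res.discovery_route = DiscoveryRoute.GENE_COLLAPSING
        else:
            res.discovery_route = DiscoveryRoute.NONE
    return results


# ---------------------------------------------------------------------------
# patient ranking


def rank_patient_variants(
    cohort: Sequence[CohortObservation],
    scores: Mapping[VariantKey, float],
    severe_cutoff: Optional[float] = None,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Rank each patient's variants by calibrated score, most pathogenic first.

    Ties break lexicographically by (gene, position, alt) for determinism.
    The summary reports, over patients carrying at least one DNM (at or
    below ``severe_cutoff`` when given), the fraction whose single most
    pathogenic variant is a DNM and the fraction with a DNM in the top two.
    """
    unscored = [o.key for o in cohort if o.key not in scores]
    if unscored:
        raise ConsistencyError(
            f"{len(unscored)} cohort variants are unscored, e.g. {unscored[0]}"
        )
    rows = [
        {
            "patient": o.patient_id,
            "gene": o.key.gene_id,
            "position": o.key.protein_position,
            "ref": o.key.ref_aa,
            "alt": o.key.alt_aa,
            "inheritance": o.inheritance.value,
            "group": o.group.value,
            "score": scores[o.key],
        }
        for o in cohort
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df, {"n_eligible": 0, "top_is_dnm": float("nan"),
                    "dnm_in_top2": float("nan")}
    df = df.sort_values(
        ["patient", "score", "gene", "position", "alt"],
        kind="stable",
    ).reset_index(drop=True)
    df["rank"] = df.groupby("patient").cumcount() + 1

    is_dnm = df["inheritance"] == Inheritance.DNM.value
    eligible_dnm = is_dnm if severe_cutoff is None else (
        is_dnm & (df["score"] <= severe_cutoff)
    )
    eligible_patients = set(df.loc[eligible_dnm, "patient"])
    n_top = n_top2 = 0
    for patient, grp in df.groupby("patient"):
        if patient not in eligible_patients:
            continue
        dnm_ranks = grp.loc[grp["inheritance"] == Inheritance.DNM.value, "rank"]
        if (dnm_ranks == 1).any():
            n_top += 1
        if (dnm_ranks <= 2).any():
            n_top2 += 1
    n_elig = len(eligible_patients)
    summary = {
        "n_eligible": n_elig,
        "top_is_dnm": n_top / n_elig if n_elig else float("nan"),
        "dnm_in_top2": n_top2 / n_elig if n_elig else float("nan"),
    }
    return df, summary


# ---------------------------------------------------------------------------
# gene-level constraint


def min_score_per_gene(scores: Sequence[ScoredVariant]) -> Dict[str, float]:
    """Most deleterious (minimum) calibrated score per gene — gene constraint."""
    out: Dict[str, float] = {}
    for v in scores:
        s = v.popeve_score if v.popeve_score is not None else v.mean_base_score()
        if v.key.gene_id not in out or s < out[v.key.gene_id]:
            out[v.key.gene_id] = s
    return out


def ks_compare(set_a: Sequence[float], set_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov D and asymptotic p."""
    if len(set_a) == 0 or len(set_b) == 0:
        raise ParameterError("both samples must be non-empty")
    res = stats.ks_2samp(set_a, set_b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# network permutation test


def network_degree_test(
    graph: InteractionGraph,
    base_set: GeneSet,
    added_set: GeneSet,
    n_random: int = 999,
    seed: int = 0,
) -> NetworkTestResult:
    """Does adding the discovered genes densify the known-gene network?

    Observed statistic: mean node degree of the subgraph induced by
    base ∪ added.  Null: ``n_random`` equal-size gene sets drawn uniformly
    (without replacement) from graph nodes excluding the base set.
    Permutation p uses the add-one correction.
    """
    nodes = graph.nodes
    for name, s in (("base", base_set), ("added", added_set)):
        extra = s.genes - nodes
        if extra:
            raise ParameterError(
                f"{name} set contains genes absent from the graph, e.g. "
                f"{sorted(extra)[0]}"
            )
    if base_set.genes & added_set.genes:
        raise ParameterError("base and added gene sets must be disjoint")
    pool = sorted(nodes - base_set.genes)
    k = len(added_set.genes)
    if k > len(pool):
        raise ParameterError(
            f"added set size {k} exceeds the {len(pool)} non-base graph nodes"
        )

    def mean_degree(gene_iterable) -> float:
        sub = graph.graph.subgraph(gene_iterable)
        n = sub.number_of_nodes()
        return 2.0 * sub.number_of_edges() / n if n else 0.0

    base_deg = mean_degree(base_set.genes)
    obs = mean_degree(base_set.genes | added_set.genes)
    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool, dtype=object)
    exceed = 0
    for _ in range(n_random):
        pick = rng.choice(len(pool_arr), size=k, replace=False)
        if mean_degree(base_set.genes | set(pool_arr[pick])) >= obs:
            exceed += 1
    p = (1.0 + exceed) / (n_random + 1.0)
    return NetworkTestResult(
        mean_degree_base=base_deg,
        mean_degree_augmented=obs,
        permutation_p=p,
        n_random=n_random,
    )
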