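"""Synthetic proteome, population and trio-cohort generators with ground truth.

Every generator is a pure function of its parameters and seed, and emits a
:class:`TruthRecord` carrying the generating quantities (monotone link,
per-gene severity offsets, DNM score-mixture parameters, causal fraction) so
downstream recovery can be checked against closed-form expectations.

The generative model mirrors the structure of real missense data while
staying deliberately simple:

* per gene, a severity offset shifts the score distribution (constrained
  genes sit lower);
* per variant, two base-model scores are drawn from a bivariate normal
  around the gene offset — two imperfectly correlated views of one
  underlying severity, as alignment-based and language-model predictors are
  in practice;
* population presence is Bernoulli through a monotone link on the score,
  emulating purifying selection (very deleterious variants are essentially
  never observed in a healthy cohort);
* case/control trio cohorts receive background de-novo mutations at the
  diploid rate expectation 2·N·Σμ, and a planted fraction of cases
  additionally carry one severe DNM placed on a real generated variant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ParameterError
from .types import (
    CohortObservation,
    Group,
    Inheritance,
    MutationRate,
    PresenceRecord,
    ScoredVariant,
    VariantKey,
    check_correlation,
)

#: amino acids used to synthesise variant identities
_AAS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class TruthRecord:
    """Ground truth behind a synthetic dataset.

    ``link_name``/``link_params`` define the true monotone map g from base
    score to presence logit.  ``mixture_truth`` describes the two-component
    score mixture realised in a simulated cohort's DNMs (component 0 =
    planted severe, component 1 = background).
    """

    link_name: str = "linear"
    link_params: Dict[str, float] = field(default_factory=lambda: {"a": 1.2, "b": 3.0})
    gene_severity: Dict[str, float] = field(default_factory=dict)
    mixture_truth: Optional[Dict[str, List[float]]] = None
    causal_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.causal_fraction is not None and not 0.0 <= self.causal_fraction <= 1.0:
            raise ParameterError(
                f"causal_fraction must be in [0, 1], got {self.causal_fraction}"
            )
        if self.mixture_truth is not None:
            w = self.mixture_truth["weights"]
            if abs(sum(w) - 1.0) > 1e-9:
                raise ParameterError(f"mixture weights must sum to 1, got {w}")
            if any(v <= 0 for v in self.mixture_truth["variances"]):
                raise ParameterError("mixture variances must be > 0")

    def link(self) -> Callable[[np.ndarray], np.ndarray]:
        """Return the true score -> presence-logit function."""
        if self.link_name == "linear":
            a, b = self.link_params["a"], self.link_params["b"]
            return lambda x: a * np.asarray(x, float) + b
        raise ParameterError(f"unknown link {self.link_name!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "link_name": self.link_name,
                    "link_params": self.link_params,
                    "gene_severity": self.gene_severity,
                    "mixture_truth": self.mixture_truth,
                    "causal_fraction": self.causal_fraction,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def _make_keys(rng: np.random.Generator, gene: str, n: int) -> List[VariantKey]:
    """Distinct variant keys within one gene (distinct residue positions)."""
    positions = rng.choice(np.arange(1, max(4 * n, 50)), size=n, replace=False)
    keys = []
    for pos in sorted(int(p) for p in positions):
        ref, alt = rng.choice(len(_AAS), size=2, replace=False)
        keys.append(
            VariantKey(
                gene_id=gene,
                protein_position=pos,
                ref_aa=_AAS[ref],
                alt_aa=_AAS[alt],
            )
        )
    return keys


def simulate_scores(
    n_genes: int,
    variants_per_gene: int,
    base_correlation: float = 0.5,
    seed: int = 0,
    gene_sd: float = 1.0,
    within_sd: float = 1.0,
    score_names: Sequence[str] = ("eve", "esm"),
    link_params: Optional[Dict[str, float]] = None,
    constrained_fraction: float = 0.05,
    constrained_shift: float = 5.0,
) -> Tuple[List[ScoredVariant], TruthRecord]:
    """Generate a score table with gene-level severity structure.

    ``base_correlation`` is the *total* Pearson correlation between the two
    score columns.  Scores share a per-gene offset (variance ``gene_sd``²),
    so the within-gene correlation c is derived from

        rho_total = (gene_sd² + c · within_sd²) / (gene_sd² + within_sd²)

    and must land in [-1, 1], otherwise the requested correlation is
    unattainable for the given variance split.

    A ``constrained_fraction`` of genes model the strongly constrained
    (haploinsufficient-like) class: their severity offset is shifted down
    by ``constrained_shift``, placing their variants well below the bulk —
    the separation that makes cohort score distributions bimodal.
    """
    if n_genes < 1 or variants_per_gene < 1:
        raise ParameterError("n_genes and variants_per_gene must be >= 1")
    check_correlation(base_correlation)
    if not 0.0 <= constrained_fraction < 1.0:
        raise ParameterError("constrained_fraction must be in [0, 1)")
    # offset variance includes the constrained-class shift (bimodal offsets)
    f = constrained_fraction
    tau2 = gene_sd**2 + f * (1.0 - f) * constrained_shift**2
    sw2 = within_sd**2
    c = ((tau2 + sw2) * base_correlation - tau2) / sw2
    if not -1.0 <= c <= 1.0:
        raise ParameterError(
            f"total correlation {base_correlation} unattainable with "
            f"gene_sd={gene_sd}, within_sd={within_sd}"
        )
    rng = np.random.default_rng(seed)
    cov = within_sd**2 * np.array([[1.0, c], [c, 1.0]])
    chol = np.linalg.cholesky(cov)

    truth = TruthRecord(
        link_params=dict(link_params) if link_params else {"a": 1.2, "b": 3.0}
    )
    n_constrained = int(round(constrained_fraction * n_genes))
    constrained = set(rng.choice(n_genes, size=n_constrained, replace=False).tolist())
    variants: List[ScoredVariant] = []
    for gi in range(n_genes):
        gene = _gene_name(gi)
        offset = float(rng.normal(0.0, gene_sd))
        if gi in constrained:
            offset -= constrained_shift
        truth.gene_severity[gene] = offset
        keys = _make_keys(rng, gene, variants_per_gene)
        noise = rng.standard_normal((variants_per_gene, 2)) @ chol.T
        for key, eps in zip(keys, noise):
            scores = {
                name: offset + float(e) for name, e in zip(score_names, eps)
            }
            variants.append(ScoredVariant(key=key, base_scores=scores))
    return variants, truth


def simulate_presence(
    scores: Sequence[ScoredVariant],
    truth: TruthRecord,
    seed: int = 0,
) -> List[PresenceRecord]:
    """Draw population presence flags through the true monotone link.

    Presence ~ Bernoulli(inverse-logit(g(score))) where the link is applied
    to the mean of each variant's base scores (for single-score tables this
    is the score itself).
    """
    rng = np.random.default_rng(seed)
    g = truth.link()
    x = np.array([v.mean_base_score() for v in scores])
    p = 1.0 / (1.0 + np.exp(-g(x)))
    draws = rng.random(len(scores)) < p
    return [
        PresenceRecord(key=v.key, present=bool(d)) for v, d in zip(scores, draws)
    ]


def simulate_rates(
    scores: Sequence[ScoredVariant],
    total_mu: float = 0.35,
    seed: int = 0,
    dispersion: float = 1.0,
) -> List[MutationRate]:
    """Per-variant mutation rates: log-normal weights normalised to a total.

    ``total_mu`` is Σμ over all modeled variants, so the expected background
    missense DNM count per proband is 2·total_mu (0.7 by default, the order
    observed for modeled missense in exome trio studies).
    """
    if not scores:
        raise ParameterError("empty score table")
    if total_mu <= 0:
        raise ParameterError("total_mu must be > 0")
    rng = np.random.default_rng(seed)
    w = rng.lognormal(mean=0.0, sigma=dispersion, size=len(scores))
    mu = total_mu * w / w.sum()
    return [MutationRate(key=v.key, mu=float(m)) for v, m in zip(scores, mu)]


def _variant_score(v: ScoredVariant) -> float:
    return v.popeve_score if v.popeve_score is not None else v.mean_base_score()


def simulate_cohort(
    scores: Sequence[ScoredVariant],
    rates: Sequence[MutationRate],
    n_cases: int,
    n_controls: int,
    causal_fraction: float = 0.5,
    severe_shift: float = 3.0,
    seed: int = 0,
    inherited_mean: float = 0.0,
) -> Tuple[List[CohortObservation], TruthRecord]:
    """Simulate a case/control trio cohort of de-novo mutations.

    Every patient receives background DNMs: a Poisson(2·Σμ) count of
    variants drawn with probability ∝ μ.  A ``causal_fraction`` of cases
    additionally receives one planted severe DNM: the lowest-scoring variant
    of a uniformly chosen gene among genes whose minimum score lies at least
    ``severe_shift`` standard deviations below the overall score mean.

    ``inherited_mean`` > 0 additionally gives each patient a
    Poisson(inherited_mean) count of inherited-labelled rare variants drawn
    uniformly from the variant pool, so patient-level ranking of mixed
    DNM/inherited variants can be exercised.
    """
    if not rates:
        raise ParameterError("empty rate table")
    if not 0.0 <= causal_fraction <= 1.0:
        raise ParameterError(f"causal_fraction must be in [0, 1], got {causal_fraction}")
    if severe_shift <= 0:
        raise ParameterError(f"severe_shift must be > 0, got {severe_shift}")
    rng = np.random.default_rng(seed)

    by_key = {v.key: v for v in scores}
    missing = [r.key for r in rates if r.key not in by_key]
    if missing:
        raise ParameterError(f"rates reference unscored variants, e.g. {missing[0]}")
    rate_keys = [r.key for r in rates]
    mus = np.array([r.mu for r in rates])
    lam = 2.0 * mus.sum()
    probs = mus / mus.sum()

    svals = np.array([_variant_score(v) for v in scores])
    mean_s, sd_s = float(svals.mean()), float(svals.std())
    cut = mean_s - severe_shift * sd_s

    # severe pool: per-gene minimum-score variant, genes whose min clears the cut
    gene_min: Dict[str, ScoredVariant] = {}
    for v in scores:
        g = v.key.gene_id
        if g not in gene_min or _variant_score(v) < _variant_score(gene_min[g]):
            gene_min[g] = v
    severe_pool = sorted(
        (v for v in gene_min.values() if _variant_score(v) <= cut),
        key=lambda v: v.key,
    )
    if causal_fraction > 0 and not severe_pool:
        raise ParameterError(
            f"no gene has a minimum score below mean - {severe_shift} sd; "
            "reduce severe_shift or enlarge the proteome"
        )

    all_keys = sorted(by_key)
    obs: List[CohortObservation] = []

    def background(patient: str, group: Group, taken: set) -> None:
        n = rng.poisson(lam)
        for idx in rng.choice(len(rate_keys), size=n, p=probs):
            k = rate_keys[idx]
            if k in taken:
                continue  # (patient, variant) must stay unique
            taken.add(k)
            obs.append(
                CohortObservation(
                    patient_id=patient, key=k, inheritance=Inheritance.DNM, group=group
                )
            )

    def inherited(patient: str, group: Group, taken: set) -> None:
        if inherited_mean <= 0:
            return
        n = rng.poisson(inherited_mean)
        for idx in rng.choice(len(all_keys), size=n):
            k = all_keys[idx]
            if k in taken:
                continue
            taken.add(k)
            obs.append(
                CohortObservation(
                    patient_id=patient,
                    key=k,
                    inheritance=Inheritance.INHERITED,
                    group=group,
                )
            )

    n_causal = int(round(causal_fraction * n_cases))
    planted_scores = []
    for i in range(n_cases):
        patient = f"case{i:05d}"
        taken: set = set()
        if i < n_causal:
            v = severe_pool[rng.integers(len(severe_pool))]
            taken.add(v.key)
            obs.append(
                CohortObservation(
                    patient_id=patient,
                    key=v.key,
                    inheritance=Inheritance.DNM,
                    group=Group.CASE,
                )
            )
            planted_scores.append(_variant_score(v))
        background(patient, Group.CASE, taken)
        inherited(patient, Group.CASE, taken)
    for i in range(n_controls):
        patient = f"ctrl{i:05d}"
        taken = set()
        background(patient, Group.CONTROL, taken)
        inherited(patient, Group.CONTROL, taken)

    # realised two-component mixture over cohort DNM scores
    rate_scores = np.array([_variant_score(by_key[k]) for k in rate_keys])
    bg_m = float(np.average(rate_scores, weights=probs))
    bg_v = float(np.average((rate_scores - bg_m) ** 2, weights=probs))
    if planted_scores:
        sev_m = float(np.mean(planted_scores))
        sev_v = float(np.var(planted_scores)) if len(planted_scores) > 1 else 1e-6
    else:
        sev_m, sev_v = cut, 1e-6
    exp_bg = lam * (n_cases + n_controls)
    w_sev = len(planted_scores) / (len(planted_scores) + exp_bg) if exp_bg else 1.0
    truth = TruthRecord(
        mixture_truth={
            "weights": [w_sev, 1.0 - w_sev],
            "means": [sev_m, bg_m],
            "variances": [max(sev_v, 1e-6), max(bg_v, 1e-6)],
        },
        causal_fraction=causal_fraction,
    )
    return obs, truth
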