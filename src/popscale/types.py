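"""Domain types: variants, scores, cohort observations, gene sets, graphs.

Protein coordinates are 1-based (HGVS convention, e.g. ``M31R`` is a
methionine-to-arginine substitution at residue 31).  Score orientation is
normalised at load time so that internally *more negative = more deleterious*,
matching the calibrated latent-logit scale where 0 means "no evidence against
neutrality".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from math import isfinite
from typing import Mapping, Optional

import networkx as nx

from .errors import FormatError, ParameterError, ValidationError

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_HGVS_SHORT = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True, order=True)
class VariantKey:
    """A unique missense variant: gene plus single-residue substitution."""

    gene_id: str
    protein_position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.protein_position < 1:
            raise ValidationError(
                f"protein_position must be >= 1, got {self.protein_position}"
            )
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in AMINO_ACIDS:
                raise ValidationError(f"{aa!r} is not a standard amino-acid code")
        if self.ref_aa == self.alt_aa:
            raise ValidationError(
                f"synonymous change {self.ref_aa}{self.protein_position}{self.alt_aa}"
                " is not a missense variant"
            )

    @classmethod
    def from_hgvs(cls, gene_id: str, notation: str) -> "VariantKey":
        """Parse short HGVS-p notation such as ``M31R`` or ``R192C``."""
        m = _HGVS_SHORT.match(notation.strip())
        if m is None:
            raise FormatError(f"unparsable variant notation {notation!r}")
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        return cls(gene_id=gene_id, protein_position=pos, ref_aa=ref, alt_aa=alt)

    @property
    def hgvs(self) -> str:
        return f"{self.ref_aa}{self.protein_position}{self.alt_aa}"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.gene_id}:{self.hgvs}"


@dataclass
class ScoredVariant:
    """A missense variant with one or more base-model scores.

    ``base_scores`` maps model name (e.g. ``"eve"``, ``"esm"``) to a real
    score, oriented so more negative = more deleterious.  ``popeve_score``
    is the calibrated latent-logit score, set after calibration.
    """

    key: VariantKey
    base_scores: Mapping[str, float]
    popeve_score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.base_scores:
            raise ValidationError(f"{self.key}: at least one base score required")
        for name, s in self.base_scores.items():
            if not isfinite(s):
                raise ValidationError(f"{self.key}: score {name}={s} is not finite")
        if self.popeve_score is not None and not isfinite(self.popeve_score):
            raise ValidationError(f"{self.key}: popeve_score is not finite")

    def mean_base_score(self) -> float:
        return sum(self.base_scores.values()) / len(self.base_scores)


@dataclass(frozen=True)
class PresenceRecord:
    """Whether a variant was observed at least once in the population cohort.

    Presence is deliberately boolean: allele frequency is discarded so that
    the downstream model is insensitive to population structure.
    """

    key: VariantKey
    present: bool


class Inheritance(str, Enum):
    DNM = "dnm"
    INHERITED = "inherited"
    UNKNOWN = "unknown"


class Group(str, Enum):
    CASE = "case"
    CONTROL = "control"


@dataclass(frozen=True)
class CohortObservation:
    """One (patient, variant) observation in a trio cohort."""

    patient_id: str
    key: VariantKey
    inheritance: Inheritance
    group: Group


@dataclass(frozen=True)
class MutationRate:
    """Per-haploid-genome, per-generation probability of this substitution."""

    key: VariantKey
    mu: float

    def __post_init__(self) -> None:
        if not isfinite(self.mu) or self.mu <= 0:
            raise ValidationError(f"{self.key}: mutation rate mu={self.mu} must be > 0")


@dataclass
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class InteractionGraph:
    """An undirected gene-interaction network (no self-loops)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"self-loop edges not allowed: {loops[:5]}")

    @classmethod
    def from_edges(cls, edges, nodes=()) -> "InteractionGraph":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                raise ValidationError(f"self-loop edge {u}-{v} not allowed")
            g.add_edge(u, v)
        return cls(graph=g)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def check_correlation(rho: float) -> float:
    """Validate a correlation parameter lies strictly inside (0, 1)."""
    if not (0.0 < rho < 1.0):
        raise ParameterError(f"correlation must be in (0, 1), got {rho}")
    return rho
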