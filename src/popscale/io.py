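"""TSV readers and writers for all tabular formats.

All tables are tab-separated with a header row.  Writers canonicalise: rows
sorted by variant key, floats formatted with 6 significant digits, so a
write/read/write cycle is byte-identical.  Loaders enforce the type
invariants and report offending row numbers (1-based, excluding the header).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .errors import DuplicateKeyError, FormatError, ValidationError
from .types import (
    CohortObservation,
    GeneSet,
    Group,
    Inheritance,
    InteractionGraph,
    MutationRate,
    PresenceRecord,
    ScoredVariant,
    VariantKey,
)

FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_key(gene: str, variant: str, row: int, path) -> VariantKey:
    try:
        return VariantKey.from_hgvs(gene, variant)
    except (FormatError, ValidationError) as exc:
        raise FormatError(f"{path}: row {row}: {exc}") from exc


def _check_unique(keys: Iterable, path, what: str = "key") -> None:
    seen: Dict = {}
    dups = []
    for row, k in enumerate(keys, start=1):
        if k in seen:
            dups.append((k, seen[k], row))
        else:
            seen[k] = row
    if dups:
        detail = "; ".join(f"{k} (rows {a} and {b})" for k, a, b in dups[:10])
        raise DuplicateKeyError(
            f"{path}: {len(dups)} duplicate {what}(s): {detail}",
            keys=[k for k, _, _ in dups],
        )


# ---------------------------------------------------------------------------
# score tables


def read_score_table(path, column_spec: Optional[dict] = None) -> List[ScoredVariant]:
    """Read a score table: columns ``gene``, ``variant``, one or more scores.

    ``column_spec`` may carry:

    - ``score_columns``: explicit list of score column names (default: every
      column other than gene/variant/popeve_score);
    - ``orientation``: map column name -> ``"neg_deleterious"`` (default) or
      ``"pos_deleterious"``; positive-deleterious columns are negated at load
      so that internally more negative always means more deleterious.
    """
    spec = column_spec or {}
    gene_col = spec.get("gene_column", "gene")
    var_col = spec.get("variant_column", "variant")
    df = _read_tsv(path, [gene_col, var_col])
    score_cols = spec.get("score_columns")
    if score_cols is None:
        score_cols = [
            c for c in df.columns if c not in (gene_col, var_col, "popeve_score")
        ]
    else:
        missing = [c for c in score_cols if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
    if not score_cols:
        raise FormatError(f"{path}: no score columns found")
    orientation = spec.get("orientation", {})

    out: List[ScoredVariant] = []
    keys = []
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        rec = rec._asdict()
        key = _parse_key(rec[gene_col], rec[var_col], row, path)
        scores = {}
        for c in score_cols:
            try:
                v = float(rec[c])
            except ValueError as exc:
                raise FormatError(f"{path}: row {row}: bad score {rec[c]!r} in {c}") from exc
            if orientation.get(c) == "pos_deleterious":
                v = -v
            scores[c] = v
        pop = None
        if "popeve_score" in df.columns and rec["popeve_score"] != "":
            pop = float(rec["popeve_score"])
        try:
            out.append(ScoredVariant(key=key, base_scores=scores, popeve_score=pop))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {row}: {exc}") from exc
        keys.append(key)
    _check_unique(keys, path, "variant key")
    return out


def write_score_table(variants: Sequence[ScoredVariant], path) -> None:
    variants = sorted(variants, key=lambda v: v.key)
    score_cols = sorted({c for v in variants for c in v.base_scores})
    has_pop = any(v.popeve_score is not None for v in variants)
    rows = []
    for v in variants:
        row = {"gene": v.key.gene_id, "variant": v.key.hgvs}
        for c in score_cols:
            row[c] = _fmt(v.base_scores[c]) if c in v.base_scores else ""
        if has_pop:
            row["popeve_score"] = (
                "" if v.popeve_score is None else _fmt(v.popeve_score)
            )
        rows.append(row)
    cols = ["gene", "variant", *score_cols] + (["popeve_score"] if has_pop else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# presence tables


def read_presence_table(path) -> List[PresenceRecord]:
    df = _read_tsv(path, ["gene", "variant", "present"])
    out = []
    keys = []
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        key = _parse_key(rec.gene, rec.variant, row, path)
        if rec.present not in ("0", "1"):
            raise ValidationError(
                f"{path}: row {row}: present must be 0 or 1, got {rec.present!r}"
            )
        out.append(PresenceRecord(key=key, present=rec.present == "1"))
        keys.append(key)
    _check_unique(keys, path, "variant key")
    return out


def write_presence_table(records: Sequence[PresenceRecord], path) -> None:
    records = sorted(records, key=lambda r: r.key)
    pd.DataFrame(
        [
            {"gene": r.key.gene_id, "variant": r.key.hgvs, "present": int(r.present)}
            for r in records
        ],
        columns=["gene", "variant", "present"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort tables


def read_cohort_table(path) -> List[CohortObservation]:
    df = _read_tsv(path, ["patient", "gene", "variant", "inheritance", "group"])
    out = []
    keys = []
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        key = _parse_key(rec.gene, rec.variant, row, path)
        try:
            inh = Inheritance(rec.inheritance)
        except ValueError:
            raise ValidationError(
                f"{path}: row {row}: unknown inheritance label {rec.inheritance!r}"
            ) from None
        try:
            grp = Group(rec.group)
        except ValueError:
            raise ValidationError(
                f"{path}: row {row}: unknown group label {rec.group!r}"
            ) from None
        out.append(
            CohortObservation(patient_id=rec.patient, key=key, inheritance=inh, group=grp)
        )
        keys.append((rec.patient, key))
    _check_unique(keys, path, "(patient, variant) pair")
    return out


def write_cohort_table(obs: Sequence[CohortObservation], path) -> None:
    obs = sorted(obs, key=lambda o: (o.patient_id, o.key))
    pd.DataFrame(
        [
            {
                "patient": o.patient_id,
                "gene": o.key.gene_id,
                "variant": o.key.hgvs,
                "inheritance": o.inheritance.value,
                "group": o.group.value,
            }
            for o in obs
        ],
        columns=["patient", "gene", "variant", "inheritance", "group"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mutation-rate tables


def read_rate_table(path) -> List[MutationRate]:
    df = _read_tsv(path, ["gene", "variant", "mu"])
    out = []
    keys = []
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        key = _parse_key(rec.gene, rec.variant, row, path)
        try:
            mu = float(rec.mu)
        except ValueError as exc:
            raise FormatError(f"{path}: row {row}: bad rate {rec.mu!r}") from exc
        try:
            out.append(MutationRate(key=key, mu=mu))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {row}: {exc}") from exc
        keys.append(key)
    _check_unique(keys, path, "variant key")
    return out


def write_rate_table(rates: Sequence[MutationRate], path) -> None:
    rates = sorted(rates, key=lambda r: r.key)
    pd.DataFrame(
        [
            {"gene": r.key.gene_id, "variant": r.key.hgvs, "mu": _fmt(r.mu)}
            for r in rates
        ],
        columns=["gene", "variant", "mu"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets and edge lists


def read_gene_set(path, name: Optional[str] = None) -> GeneSet:
    """One gene per line; blank lines ignored; duplicates rejected."""
    path = Path(path)
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    _check_unique(genes, path, "gene")
    return GeneSet(name=name or path.stem, genes=frozenset(genes))


def write_gene_set(gene_set: GeneSet, path) -> None:
    Path(path).write_text("\n".join(sorted(gene_set.genes)) + "\n")


def read_edge_list(path) -> InteractionGraph:
    """Two tab-separated gene columns per line (no header)."""
    edges = []
    for row, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: row {row}: expected 2 columns, got {len(parts)}")
        u, v = parts[0].strip(), parts[1].strip()
        if u == v:
            raise ValidationError(f"{path}: row {row}: self-loop edge {u}-{v}")
        edges.append((u, v))
    return InteractionGraph.from_edges(edges)


def write_edge_list(graph: InteractionGraph, path) -> None:
    lines = sorted(tuple(sorted(e)) for e in graph.graph.edges)
    Path(path).write_text("".join(f"{u}\t{v}\n" for u, v in lines))
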