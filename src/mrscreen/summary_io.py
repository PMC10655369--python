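"""Reading, validating and writing GWAS summary-statistics tables.

Defines the variant-level data model shared by every downstream stage:
one :class:`VariantAssociation` per SNP per trait, a keyed
:class:`TraitSummary` per trait, and a pairwise :class:`LDReference`.
Ingestion is strict: rows violating the variant invariants are dropped
and logged with a single reason code rather than silently repaired.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

VALID_BASES = frozenset("ACGT")

#: Canonical summary-statistics headers. A ``column_map`` passed to
#: :func:`read_summary_table` maps arbitrary source headers onto these.
CANONICAL_COLUMNS = (
    "variant_id",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
    "n",
    "n_cases",
)

MANDATORY_COLUMNS = (
    "variant_id",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "beta",
    "standard_error",
    "p_value",
    "n",
)


class SummaryIOError(Exception):
    """Configuration or validation failure while reading summary statistics."""


@dataclass(frozen=True)
class ExclusionEntry:
    """One dropped variant with the pipeline stage and a single reason code."""

    variant_id: str
    stage: str
    reason: str


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's effect record in one trait's GWAS.

    ``beta`` is the per-effect-allele estimate (log-odds for binary
    traits); ``eaf`` may be missing (None).  Positions are 1-based.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    p_value: float
    n: int
    n_cases: int | None = None

    def validation_failure(self) -> str | None:
        """Return a reason code if any invariant is violated, else None."""
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            return "invalid_allele"
        if self.effect_allele == self.other_allele:
            return "identical_alleles"
        if not (isinstance(self.se, float) or isinstance(self.se, int)) or not self.se > 0:
            return "nonpositive_se"
        if math.isnan(self.beta):
            return "missing_beta"
        if not (0.0 < self.p_value <= 1.0):
            return "invalid_p_value"
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            return "invalid_eaf"
        if self.n <= 0:
            return "nonpositive_n"
        if self.position <= 0:
            return "invalid_position"
        return None


@dataclass
class TraitSummary:
    """All validated variant records for one trait, keyed by variant id."""

    trait_id: str
    trait_label: str
    trait_type: str  # "continuous" | "binary"
    ancestry: str
    records: dict[str, VariantAssociation] = field(default_factory=dict)
    n_cases: int | None = None  # trait-level case count for binary traits
    exclusions: list[ExclusionEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise SummaryIOError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary" and self.n_cases is None:
            if not all(r.n_cases is not None for r in self.records.values()):
                raise SummaryIOError(
                    f"binary trait {self.trait_id!r} requires n_cases at the "
                    "trait level or on every record"
                )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class LDReference:
    """Symmetric pairwise r-squared lookup with a configurable default.

    Unknown pairs resolve to ``default_r2`` (0 treats them as
    independent); the diagonal is always 1.
    """

    pairs: dict[frozenset, float] = field(default_factory=dict)
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)
    default_r2: float = 0.0

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get(frozenset((a, b)), self.default_r2)

    def set_r2(self, a: str, b: str, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            raise SummaryIOError(f"r2 outside [0,1]: {value}")
        if a != b:
            self.pairs[frozenset((a, b))] = value


def _coerce_row(row: Mapping, has_n_cases: bool) -> VariantAssociation | None:
    eaf = row.get("effect_allele_frequency")
    if eaf is not None and (isinstance(eaf, float) and math.isnan(eaf)):
        eaf = None
    n_cases = row.get("n_cases") if has_n_cases else None
    if n_cases is not None and (isinstance(n_cases, float) and math.isnan(n_cases)):
        n_cases = None
    try:
        return VariantAssociation(
            variant_id=str(row["variant_id"]),
            chromosome=str(row["chromosome"]),
            position=int(row["base_pair_location"]),
            effect_allele=str(row["effect_allele"]).upper(),
            other_allele=str(row["other_allele"]).upper(),
            eaf=float(eaf) if eaf is not None else None,
            beta=float(row["beta"]),
            se=float(row["standard_error"]),
            p_value=float(row["p_value"]),
            n=int(row["n"]),
            n_cases=int(n_cases) if n_cases is not None else None,
        )
    except (TypeError, ValueError):
        return None


def read_summary_table(
    path: str | Path,
    trait_meta: Mapping[str, object],
    column_map: Mapping[str, str] | None = None,
) -> TraitSummary:
    """Read a tab-separated summary-statistics table into a TraitSummary.

    ``column_map`` maps source headers to canonical ones. Rows failing
    validation are dropped and recorded on ``TraitSummary.exclusions``
    with one reason code each; the keyed result is independent of row
    order. Raises on a missing mandatory column or zero valid rows.
    """
    path = Path(path)
    if not path.exists():
        raise SummaryIOError(f"summary table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryIOError(f"missing mandatory column(s): {', '.join(missing)}")
    if "effect_allele_frequency" not in df.columns:
        df["effect_allele_frequency"] = None
    has_n_cases = "n_cases" in df.columns

    records: dict[str, VariantAssociation] = {}
    exclusions: list[ExclusionEntry] = []
    for row in df.to_dict("records"):
        rec = _coerce_row(row, has_n_cases)
        if rec is None:
            exclusions.append(
                ExclusionEntry(str(row.get("variant_id", "?")), "ingest", "unparseable_row")
            )
            continue
        reason = rec.validation_failure()
        if reason is not None:
            exclusions.append(ExclusionEntry(rec.variant_id, "ingest", reason))
            continue
        if rec.variant_id in records:
            exclusions.append(ExclusionEntry(rec.variant_id, "ingest", "duplicate_variant_id"))
            continue
        records[rec.variant_id] = rec

    if not records:
        raise SummaryIOError(f"no valid rows in {path}")
    return TraitSummary(
        trait_id=str(trait_meta["trait_id"]),
        trait_label=str(trait_meta.get("trait_label", trait_meta["trait_id"])),
        trait_type=str(trait_meta.get("trait_type", "continuous")),
        ancestry=str(trait_meta.get("ancestry", "European")),
        records=records,
        n_cases=trait_meta.get("n_cases"),
        exclusions=exclusions,
    )


def write_summary_table(summary: TraitSummary, path: str | Path) -> None:
    """Write a TraitSummary back out in the canonical TSV dialect."""
    rows = []
    for rec in summary.records.values():
        rows.append(
            {
                "variant_id": rec.variant_id,
                "chromosome": rec.chromosome,
                "base_pair_location": rec.position,
                "effect_allele": rec.effect_allele,
                "other_allele": rec.other_allele,
                "effect_allele_frequency": rec.eaf,
                "beta": rec.beta,
                "standard_error": rec.se,
                "p_value": rec.p_value,
                "n": rec.n,
                "n_cases": rec.n_cases,
            }
        )
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_ld_matrix(path: str | Path, default_r2: float = 0.0) -> LDReference:
    """Read a long-format (id_a, id_b, r2) TSV into an LDReference."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise SummaryIOError("LD reference needs three columns: id_a, id_b, r2")
    ld = LDReference(default_r2=default_r2)
    cols = df.columns[:3]
    for a, b, r2 in df[cols].itertuples(index=False):
        ld.set_r2(str(a), str(b), float(r2))
    return ld


def write_ld_matrix(ld: LDReference, path: str | Path) -> None:
    rows = [
        {"id_a": min(pair), "id_b": max(pair), "r2": r2}
        for pair, r2 in sorted(ld.pairs.items(), key=lambda kv: (min(kv[0]), max(kv[0])))
    ]
    pd.DataFrame(rows, columns=["id_a", "id_b", "r2"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_exclusion_list(path: str | Path) -> set[str]:
    """One variant id per line; blank lines and '#' comments ignored."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_exclusion_log(entries: Iterable[ExclusionEntry], path: str | Path) -> None:
    pd.DataFrame(
        [{"variant_id": e.variant_id, "stage": e.stage, "reason": e.reason} for e in entries],
        columns=["variant_id", "stage", "reason"],
    ).to_csv(path, sep="\t", index=False)


def write_records(records, path: str | Path, config: Mapping | None = None) -> None:
    """Write AssociationRecords as TSV plus a JSON sidecar of the run config.

    Floats are written at 17 significant digits so that a re-read
    reproduces every value to well under 1e-12 relative error.
    """
    from .discovery import record_to_row, RECORD_COLUMNS  # local import: avoid cycle

    rows = [record_to_row(r) for r in records]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    sidecar = Path(str(path) + ".run.json")
    sidecar.write_text(json.dumps({"config": dict(config or {})}, indent=2, default=str))


def read_records(path: str | Path) -> pd.DataFrame:
    """Re-read an associations table written by :func:`write_records`."""
    return pd.read_csv(path, sep="\t")


__all__ = [
    "CANONICAL_COLUMNS",
    "ExclusionEntry",
    "LDReference",
    "SummaryIOError",
    "TraitSummary",
    "VariantAssociation",
    "read_exclusion_list",
    "read_ld_matrix",
    "read_records",
    "read_summary_table",
    "write_exclusion_log",
    "write_ld_matrix",
    "write_records",
    "write_summary_table",
]
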