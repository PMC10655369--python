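"""Hypergeometric over-representation analysis of significant metabolites.

For each outcome, metabolites whose primary IVW p falls below the
nominal threshold form the significant set; each annotated pathway is
tested with the exact hypergeometric upper tail
P(X ≥ k), X ~ Hypergeometric(N, K, n), where N is the shared
background size, K the pathway size within the background, n the
number of significant metabolites in the background and k the overlap.
Benjamini–Hochberg adjustment is applied across pathways within each
outcome using the same step-up implementation as the discovery screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .discovery import AssociationRecord, bh_fdr


class PathwayConfigError(Exception):
    pass


@dataclass
class PathwayAnnotation:
    """One pathway's member set against a shared background."""

    pathway_id: str
    pathway_name: str
    source: str  # e.g. KEGG-style or SMPDB-style label
    members: set[str] = field(default_factory=set)
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.background:
            raise PathwayConfigError(f"empty background for pathway {self.pathway_id}")
        if not self.members <= self.background:
            raise PathwayConfigError(
                f"members of {self.pathway_id} not contained in the background"
            )


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    source: str
    outcome_id: str
    k: int  # significant hits inside the pathway
    K: int  # pathway size
    n: int  # significant metabolites in the background
    N: int  # background size
    p: float
    q: float = float("nan")


def overrepresentation_test(
    significant: set[str], annotation: PathwayAnnotation, outcome_id: str = ""
) -> EnrichmentResult:
    """Exact upper-tail hypergeometric test of one pathway."""
    background = annotation.background
    sig = significant & background
    n = len(sig)
    big_n = len(background)
    big_k = len(annotation.members)
    k = len(sig & annotation.members)
    # P(X >= k) exactly; sf is exclusive, hence k-1 (sf(-1) = 1 covers k = 0)
    p = float(hypergeom.sf(k - 1, big_n, big_k, n))
    p = max(min(p, 1.0), 1e-300)
    return EnrichmentResult(
        pathway_id=annotation.pathway_id,
        pathway_name=annotation.pathway_name,
        source=annotation.source,
        outcome_id=outcome_id,
        k=k,
        K=big_k,
        n=n,
        N=big_n,
        p=p,
    )


def enrich_screen(
    records: list[AssociationRecord],
    annotations: list[PathwayAnnotation],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """ORA per outcome over the screen's nominally significant metabolites.

    The significant set for an outcome is every exposure with primary
    IVW p < alpha; pathways are keyed by (source, pathway_id) so a
    pathway annotated by two sources is tested once per source.  BH
    adjustment runs across pathways within each outcome.  Outcomes
    without significant metabolites yield no tests.
    """
    by_outcome: dict[str, set[str]] = {}
    for rec in records:
        if rec.primary is not None and rec.primary.p < alpha:
            by_outcome.setdefault(rec.outcome_id, set()).add(rec.exposure_id)

    # deduplicate annotations on (source, pathway_id)
    keyed: dict[tuple[str, str], PathwayAnnotation] = {}
    for ann in annotations:
        keyed.setdefault((ann.source, ann.pathway_id), ann)

    results: list[EnrichmentResult] = []
    for outcome_id, sig in sorted(by_outcome.items()):
        outcome_results = [
            overrepresentation_test(sig, ann, outcome_id)
            for ann in keyed.values()
            if ann.members  # pathways with K = 0 are skipped
        ]
        if outcome_results:
            qs = bh_fdr([r.p for r in outcome_results])
            for r, q in zip(outcome_results, qs):
                r.q = float(q)
        results.extend(outcome_results)
    return results


def read_annotation_table(path: str | Path) -> list[PathwayAnnotation]:
    """TSV with columns (source, pathway_id, pathway_name, metabolite_id).

    The background is the union of all metabolite ids in the table,
    shared across pathways.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"source", "pathway_id", "pathway_name", "metabolite_id"}
    if not needed <= set(df.columns):
        raise PathwayConfigError(f"annotation table needs columns {sorted(needed)}")
    background = set(df["metabolite_id"])
    out = []
    for (source, pid, name), grp in df.groupby(["source", "pathway_id", "pathway_name"]):
        out.append(
            PathwayAnnotation(
                pathway_id=pid,
                pathway_name=name,
                source=source,
                members=set(grp["metabolite_id"]),
                background=background,
            )
        )
    return out


def write_enrichment(results: list[EnrichmentResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "outcome_id": r.outcome_id,
                "source": r.source,
                "pathway_id": r.pathway_id,
                "pathway_name": r.pathway_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "q": r.q,
            }
            for r in results
        ],
        columns=["outcome_id", "source", "pathway_id", "pathway_name", "k", "K", "n", "N", "p", "q"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


__all__ = [
    "EnrichmentResult",
    "PathwayAnnotation",
    "PathwayConfigError",
    "enrich_screen",
    "overrepresentation_test",
    "read_annotation_table",
    "write_enrichment",
]
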