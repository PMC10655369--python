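"""Instrument selection, strength filtering and allele harmonization.

Implements the instrumental-variable rules of the screen: locus-wide
significance selection (p < 1e-5 by default), greedy LD clumping
(r² = 0.01 within ±5000 kb), the per-SNP F statistic
F = R²(N−2)/(1−R²) with an F > 10 filter, unconditional exclusion of
palindromic (A/T, C/G) variants, an optional confounder exclusion
list, and alignment of outcome effects onto the exposure's effect
allele (sign flip for swapped alleles, strand complement where needed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .summary_io import ExclusionEntry, LDReference, TraitSummary, VariantAssociation

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = {frozenset("AT"), frozenset("CG")}


class NoInstrumentsError(Exception):
    """No variant survived selection/harmonization for this pair."""


class DegenerateInstrumentError(Exception):
    """An instrument with a zero exposure effect makes the Wald ratio undefined."""


@dataclass
class InstrumentSet:
    """Harmonized per-SNP arrays for one exposure-outcome pair.

    Arrays are index-aligned over the surviving variants.  ``beta_out``
    and ``eaf_out`` are already expressed on the exposure's effect
    allele.  ``r2_snp``/``f_snp`` are the per-SNP variance explained and
    F statistic; ``r2_method`` records which definition produced each
    (``eaf`` primary, ``zscore`` fallback).
    """

    exposure_id: str
    outcome_id: str
    variant_id: np.ndarray  # dtype=object, rsID strings
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf: np.ndarray  # exposure EAF, nan when missing
    r2_snp: np.ndarray
    f_snp: np.ndarray
    n_exp: int
    r2_method: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    exclusions: list[ExclusionEntry] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return int(self.beta_exp.size)

    @property
    def r2_sum(self) -> float:
        """Set-level variance explained (sum of per-SNP R²); informational."""
        return float(np.sum(self.r2_snp))

    def subset(self, mask: np.ndarray) -> "InstrumentSet":
        return InstrumentSet(
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
            variant_id=self.variant_id[mask],
            beta_exp=self.beta_exp[mask],
            se_exp=self.se_exp[mask],
            beta_out=self.beta_out[mask],
            se_out=self.se_out[mask],
            eaf=self.eaf[mask],
            r2_snp=self.r2_snp[mask],
            f_snp=self.f_snp[mask],
            n_exp=self.n_exp,
            r2_method=self.r2_method[mask] if self.r2_method.size else self.r2_method,
            exclusions=list(self.exclusions),
        )


def select_by_significance(
    exposure: TraitSummary, p_threshold: float = 1e-5
) -> list[VariantAssociation]:
    """Records with p < threshold, ascending by p, ties broken by variant id."""
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError(f"p_threshold outside (0,1]: {p_threshold}")
    hits = [r for r in exposure.records.values() if r.p_value < p_threshold]
    hits.sort(key=lambda r: (r.p_value, r.variant_id))
    return hits


def ld_clump(
    candidates: list[VariantAssociation],
    ld: LDReference,
    r2_max: float = 0.01,
    window_kb: int = 5000,
    log: list[ExclusionEntry] | None = None,
) -> list[VariantAssociation]:
    """Greedy clumping of a p-sorted candidate list.

    Repeatedly keep the most significant remaining variant and remove
    every remaining variant on the same chromosome within ±window_kb
    whose r² with it exceeds ``r2_max``.  The window is inclusive on
    both ends (positions are 1-based).
    """
    window_bp = int(window_kb) * 1000
    remaining = list(candidates)
    kept: list[VariantAssociation] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for cand in remaining:
            if (
                cand.chromosome == index.chromosome
                and abs(cand.position - index.position) <= window_bp
                and ld.r2(index.variant_id, cand.variant_id) > r2_max
            ):
                if log is not None:
                    log.append(
                        ExclusionEntry(cand.variant_id, "clump", f"clumped_with:{index.variant_id}")
                    )
            else:
                survivors.append(cand)
        remaining = survivors
    return kept


def compute_strength(
    instruments: list[VariantAssociation], n_exp: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (R², F, method) under the standardized-exposure convention.

    R² = 2·eaf·(1−eaf)·β² when eaf is present; otherwise the z-statistic
    fallback R² = z²/(z² + N − 2) with z = β/σ.  F = R²(N−2)/(1−R²).
    """
    if n_exp <= 2:
        raise ValueError("n_exp must exceed 2 for the F statistic")
    r2 = np.empty(len(instruments))
    method = np.empty(len(instruments), dtype=object)
    for j, rec in enumerate(instruments):
        if rec.eaf is not None:
            r2[j] = 2.0 * rec.eaf * (1.0 - rec.eaf) * rec.beta**2
            method[j] = "eaf"
        else:
            z2 = (rec.beta / rec.se) ** 2
            r2[j] = z2 / (z2 + n_exp - 2)
            method[j] = "zscore"
    if np.any(r2 >= 1.0):
        bad = instruments[int(np.argmax(r2))].variant_id
        raise ValueError(f"per-SNP R² >= 1 for {bad}")
    f = r2 * (n_exp - 2) / (1.0 - r2)
    return r2, f, method


def filter_strength(
    instruments: list[VariantAssociation],
    n_exp: int,
    f_min: float = 10.0,
    log: list[ExclusionEntry] | None = None,
) -> list[VariantAssociation]:
    """Keep instruments with F > f_min; removals logged as weak_instrument."""
    r2, f, _ = compute_strength(instruments, n_exp)
    kept = []
    for rec, fj in zip(instruments, f):
        if fj > f_min:
            kept.append(rec)
        elif log is not None:
            log.append(ExclusionEntry(rec.variant_id, "strength", "weak_instrument"))
    return kept


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in PALINDROMIC_PAIRS


def _align_outcome(
    exp: VariantAssociation, out: VariantAssociation
) -> tuple[float, float | None] | None:
    """Express the outcome effect on the exposure's effect allele.

    Returns (beta_out, eaf_out) or None when alleles are irreconcilable.
    Tries direct match, swapped match (negate beta, 1−eaf), then the
    same two after complementing both outcome alleles (strand flip).
    """
    pairs = [(out.effect_allele, out.other_allele, 1.0)]
    comp = (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele], 1.0)
    if comp[:2] != pairs[0][:2]:
        pairs.append(comp)
    for ea, oa, _ in pairs:
        if ea == exp.effect_allele and oa == exp.other_allele:
            return out.beta, out.eaf
        if ea == exp.other_allele and oa == exp.effect_allele:
            return -out.beta, (1.0 - out.eaf) if out.eaf is not None else None
    return None


def harmonize_pair(
    exposure_records: list[VariantAssociation],
    outcome: TraitSummary,
    n_exp: int,
    exclusion_list: set[str] | None = None,
    exposure_id: str = "exposure",
    log: list[ExclusionEntry] | None = None,
) -> InstrumentSet:
    """Align selected exposure instruments with outcome records.

    Drops variants missing from the outcome, on the confounder
    exclusion list, palindromic, or with irreconcilable alleles; flips
    the outcome effect sign when its alleles are swapped relative to
    the exposure (complementing first on an apparent strand flip).
    Raises :class:`NoInstrumentsError` when nothing survives.
    """
    exclusion_list = exclusion_list or set()
    exclusions: list[ExclusionEntry] = []
    kept_exp: list[VariantAssociation] = []
    beta_out: list[float] = []
    se_out: list[float] = []

    for rec in exposure_records:
        if rec.variant_id in exclusion_list:
            exclusions.append(ExclusionEntry(rec.variant_id, "harmonize", "confounder_associated"))
            continue
        if _is_palindromic(rec.effect_allele, rec.other_allele):
            exclusions.append(ExclusionEntry(rec.variant_id, "harmonize", "palindromic"))
            continue
        out = outcome.records.get(rec.variant_id)
        if out is None:
            exclusions.append(ExclusionEntry(rec.variant_id, "harmonize", "missing_in_outcome"))
            continue
        aligned = _align_outcome(rec, out)
        if aligned is None:
            exclusions.append(ExclusionEntry(rec.variant_id, "harmonize", "allele_mismatch"))
            continue
        kept_exp.append(rec)
        beta_out.append(aligned[0])
        se_out.append(out.se)

    if log is not None:
        log.extend(exclusions)
    if not kept_exp:
        raise NoInstrumentsError(
            f"no instruments survive harmonization for {exposure_id} -> {outcome.trait_id}"
        )

    r2, f, method = compute_strength(kept_exp, n_exp)
    return InstrumentSet(
        exposure_id=exposure_id,
        outcome_id=outcome.trait_id,
        variant_id=np.array([r.variant_id for r in kept_exp], dtype=object),
        beta_exp=np.array([r.beta for r in kept_exp]),
        se_exp=np.array([r.se for r in kept_exp]),
        beta_out=np.array(beta_out),
        se_out=np.array(se_out),
        eaf=np.array([r.eaf if r.eaf is not None else np.nan for r in kept_exp]),
        r2_snp=r2,
        f_snp=f,
        n_exp=n_exp,
        r2_method=method,
        exclusions=exclusions,
    )


def build_instrument_set(
    exposure: TraitSummary,
    outcome: TraitSummary,
    ld: LDReference,
    p_threshold: float = 1e-5,
    clump_r2: float = 0.01,
    clump_window_kb: int = 5000,
    f_min: float = 10.0,
    exclusion_list: set[str] | None = None,
) -> InstrumentSet:
    """Full select → clump → strength-filter → harmonize pipeline."""
    log: list[ExclusionEntry] = []
    candidates = select_by_significance(exposure, p_threshold)
    if not candidates:
        raise NoInstrumentsError(f"no SNP passes p < {p_threshold} for {exposure.trait_id}")
    clumped = ld_clump(candidates, ld, clump_r2, clump_window_kb, log=log)
    strong = filter_strength(clumped, exposure.records[clumped[0].variant_id].n, f_min, log=log)
    if not strong:
        raise NoInstrumentsError(f"all instruments weak (F <= {f_min}) for {exposure.trait_id}")
    n_exp = strong[0].n
    iset = harmonize_pair(
        strong, outcome, n_exp, exclusion_list, exposure_id=exposure.trait_id, log=log
    )
    iset.exclusions = log
    return iset


__all__ = [
    "DegenerateInstrumentError",
    "InstrumentSet",
    "NoInstrumentsError",
    "build_instrument_set",
    "compute_strength",
    "filter_strength",
    "harmonize_pair",
    "ld_clump",
    "select_by_significance",
]
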