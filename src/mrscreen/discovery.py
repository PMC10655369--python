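"""Screen orchestration: pairwise runs, FDR control and robustness tiers.

Runs the exposure-by-outcome cross product in either direction through
instrument selection, harmonization, the estimator suite, MR-PRESSO
and power; applies Benjamini–Hochberg FDR within each outcome's family
of exposures (roles swapped for the reverse direction); and assigns a
robustness tier to every association:

* ``passed_all`` — FDR-significant and Egger, weighted-median and the
  MR-PRESSO-corrected estimate are all individually significant;
* ``robust``     — weighted median and MR-PRESSO both significant;
* ``potential``  — MR-PRESSO significant but the weighted median not;
* ``non_robust`` — neither sensitivity test supports the IVW signal;
* ``null``       — not FDR-significant (or no instruments).

"MR-PRESSO significant" means: the outlier-corrected estimate's p when
outliers were flagged, else a significant raw IVW together with a
non-significant global pleiotropy test.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import estimators
from .presso import presso as _run_presso
from .instruments import InstrumentSet, NoInstrumentsError, build_instrument_set
from .summary_io import LDReference, TraitSummary


@dataclass
class ScreenConfig:
    """All thresholds for one run; serialized verbatim into the sidecar."""

    iv_p_threshold: float = 1e-5
    clump_r2: float = 0.01
    clump_window_kb: int = 5000
    f_min: float = 10.0
    alpha: float = 0.05
    fdr_alpha: float = 0.05
    n_boot: int = 1000
    n_sim_presso: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.iv_p_threshold <= 1 and 0 <= self.clump_r2 <= 1):
            raise ValueError("thresholds out of range")
        if not (0 < self.alpha < 1 and 0 < self.fdr_alpha < 1):
            raise ValueError("alpha values must lie in (0,1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AssociationRecord:
    """One exposure→outcome result with FDR q and robustness tier."""

    exposure_id: str
    outcome_id: str
    direction: str  # forward | reverse
    n_snps: int
    primary: estimators.MREstimate | None
    suite: estimators.SensitivitySuite | None
    fdr_q: float = float("nan")
    tier: str = "null"
    flags: list[str] = field(default_factory=list)
    exclusions: list = field(default_factory=list)  # ExclusionEntry per dropped SNP
    seed: int = 0


TIERS = ("passed_all", "robust", "potential", "non_robust", "null")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in the input order.

    q_(i) = min_{j>=i} p_(j)·m/j, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _presso_significant(record: AssociationRecord, alpha: float) -> bool | None:
    """The tiering criterion for MR-PRESSO; None when PRESSO was omitted."""
    suite = record.suite
    if suite is None or suite.presso is None:
        return None
    pr = suite.presso
    if pr.outlier_ids:
        if pr.corrected_estimate is None:
            return None
        return pr.corrected_estimate.p < alpha
    return (record.primary is not None and record.primary.p < alpha) and (
        pr.global_p >= alpha
    )


def assign_tier(record: AssociationRecord, alpha: float = 0.05, fdr_alpha: float = 0.05) -> str:
    """Pure function of the suite's p-values, flags and thresholds."""
    if record.primary is None or math.isnan(record.fdr_q) or record.fdr_q >= fdr_alpha:
        return "null"
    suite = record.suite
    wm_sig = suite.weighted_median is not None and suite.weighted_median.p < alpha
    egger_sig = suite.egger is not None and suite.egger.p < alpha
    presso_sig = _presso_significant(record, alpha)
    if presso_sig is None:
        record.flags.append("presso_unavailable_for_tiering")
        presso_sig = False
    if suite.egger is None:
        record.flags.append("egger_unavailable_for_tiering")
    if suite.weighted_median is None:
        record.flags.append("weighted_median_unavailable_for_tiering")

    if egger_sig and wm_sig and presso_sig:
        return "passed_all"
    if wm_sig and presso_sig:
        return "robust"
    if presso_sig and not wm_sig:
        return "potential"
    return "non_robust"


def derive_pair_seed(master_seed: int, exposure_id: str, outcome_id: str, direction: str) -> int:
    """Stable per-pair seed below 2^31 so single pairs reproduce in isolation."""
    key = f"{master_seed}|{exposure_id}|{outcome_id}|{direction}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def analyse_instrument_set(
    iset: InstrumentSet, config: ScreenConfig, pair_seed: int, outcome: TraitSummary
) -> estimators.SensitivitySuite:
    """Estimator suite + PRESSO + power for a harmonized set."""
    alpha = config.alpha
    ivw_est = estimators.ivw(iset, alpha)
    suite = estimators.SensitivitySuite(ivw=ivw_est)
    suite.egger = estimators.egger(iset, alpha)
    if suite.egger is None:
        suite.flags.append("egger_omitted_insufficient_snps")
    suite.weighted_median = estimators.weighted_median(iset, config.n_boot, pair_seed, alpha)
    if suite.weighted_median is None:
        suite.flags.append("weighted_median_omitted_insufficient_snps")
    suite.presso = _run_presso(iset, config.n_sim_presso, alpha, pair_seed + 1, alpha)
    if suite.presso is None:
        suite.flags.append("too_few_snps_for_presso")
    suite.leave_one_out = estimators.leave_one_out(iset, alpha)
    if not suite.leave_one_out:
        suite.flags.append("leave_one_out_omitted_insufficient_snps")

    # power needs a binary outcome's case fraction; continuous outcomes skip it
    n_out, case_frac = _outcome_shape(outcome)
    if case_frac is not None and 0 < iset.r2_sum < 1:
        suite.power = estimators.mr_power(n_out, case_frac, iset.r2_sum, ivw_est.beta, alpha)
    return suite


def _outcome_shape(outcome: TraitSummary) -> tuple[int, float | None]:
    recs = outcome.records.values()
    n_out = max((r.n for r in recs), default=0)
    if outcome.trait_type != "binary":
        return n_out, None
    n_cases = outcome.n_cases
    if n_cases is None:
        n_cases = max((r.n_cases or 0) for r in recs)
    return n_out, (n_cases / n_out if n_out else None)


def run_pair(
    exposure: TraitSummary,
    outcome: TraitSummary,
    ld: LDReference,
    config: ScreenConfig,
    direction: str = "forward",
    exclusion_list: set[str] | None = None,
) -> AssociationRecord:
    """select → clump → strength → harmonize → estimators → presso → power."""
    pair_seed = derive_pair_seed(config.seed, exposure.trait_id, outcome.trait_id, direction)
    try:
        iset = build_instrument_set(
            exposure,
            outcome,
            ld,
            p_threshold=config.iv_p_threshold,
            clump_r2=config.clump_r2,
            clump_window_kb=config.clump_window_kb,
            f_min=config.f_min,
            exclusion_list=exclusion_list,
        )
    except NoInstrumentsError:
        return AssociationRecord(
            exposure_id=exposure.trait_id,
            outcome_id=outcome.trait_id,
            direction=direction,
            n_snps=0,
            primary=None,
            suite=None,
            tier="null",
            flags=["no_instruments"],
            seed=pair_seed,
        )
    suite = analyse_instrument_set(iset, config, pair_seed, outcome)
    return AssociationRecord(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        direction=direction,
        n_snps=iset.n_snps,
        primary=suite.ivw,
        suite=suite,
        exclusions=list(iset.exclusions),
        seed=pair_seed,
    )


def run_screen(
    exposures: list[TraitSummary],
    outcomes: list[TraitSummary],
    ld: LDReference,
    config: ScreenConfig,
    direction: str = "forward",
    exclusion_list: set[str] | None = None,
) -> list[AssociationRecord]:
    """Cross-product screen with per-family FDR and tier assignment.

    The FDR family is all exposures tested against one outcome
    (forward); the reverse direction uses the symmetric grouping, all
    outcomes tested against one exposure.
    """
    if not exposures or not outcomes:
        raise ValueError("need at least one exposure and one outcome")
    records = [
        run_pair(exp, out, ld, config, direction, exclusion_list)
        for exp in exposures
        for out in outcomes
    ]
    family_key = (lambda r: r.outcome_id) if direction == "forward" else (lambda r: r.exposure_id)
    families: dict[str, list[AssociationRecord]] = {}
    for rec in records:
        families.setdefault(family_key(rec), []).append(rec)
    for fam in families.values():
        tested = [r for r in fam if r.primary is not None]
        if tested:
            qs = bh_fdr([r.primary.p for r in tested])
            for r, q in zip(tested, qs):
                r.fdr_q = float(q)
    for rec in records:
        rec.tier = assign_tier(rec, config.alpha, config.fdr_alpha)
    return records


RECORD_COLUMNS = [
    "exposure_id",
    "outcome_id",
    "direction",
    "n_snps",
    "ivw_beta",
    "ivw_se",
    "ivw_ci_low",
    "ivw_ci_high",
    "ivw_p",
    "ivw_or",
    "ivw_or_low",
    "ivw_or_high",
    "ivw_model",
    "ivw_Q",
    "ivw_q_p",
    "ivw_i2",
    "egger_beta",
    "egger_se",
    "egger_p",
    "egger_intercept",
    "egger_intercept_se",
    "egger_intercept_p",
    "wm_beta",
    "wm_se",
    "wm_p",
    "presso_rss",
    "presso_global_p",
    "presso_n_outliers",
    "presso_outlier_ids",
    "presso_corrected_beta",
    "presso_corrected_se",
    "presso_corrected_p",
    "presso_distortion_pct",
    "presso_distortion_p",
    "power",
    "fdr_q",
    "tier",
    "flags",
    "seed",
]


def record_to_row(rec: AssociationRecord) -> dict:
    """Flatten one AssociationRecord for tabular output."""
    row = dict.fromkeys(RECORD_COLUMNS)
    row.update(
        exposure_id=rec.exposure_id,
        outcome_id=rec.outcome_id,
        direction=rec.direction,
        n_snps=rec.n_snps,
        fdr_q=rec.fdr_q,
        tier=rec.tier,
        flags=";".join(rec.flags),
        seed=rec.seed,
    )
    if rec.primary is not None:
        e = rec.primary
        row.update(
            ivw_beta=e.beta,
            ivw_se=e.se,
            ivw_ci_low=e.ci_low,
            ivw_ci_high=e.ci_high,
            ivw_p=e.p,
            ivw_or=e.odds_ratio,
            ivw_or_low=e.or_ci[0],
            ivw_or_high=e.or_ci[1],
            ivw_model=e.model,
            ivw_Q=e.Q,
            ivw_q_p=e.q_p,
            ivw_i2=e.i2,
        )
    if rec.suite is not None:
        if rec.suite.egger is not None:
            g = rec.suite.egger
            row.update(
                egger_beta=g.beta,
                egger_se=g.se,
                egger_p=g.p,
                egger_intercept=g.egger_intercept,
                egger_intercept_se=g.egger_intercept_se,
                egger_intercept_p=g.egger_intercept_p,
            )
        if rec.suite.weighted_median is not None:
            wm = rec.suite.weighted_median
            row.update(wm_beta=wm.beta, wm_se=wm.se, wm_p=wm.p)
        if rec.suite.presso is not None:
            pr = rec.suite.presso
            row.update(
                presso_rss=pr.rss_obs,
                presso_global_p=pr.global_p,
                presso_n_outliers=len(pr.outlier_ids),
                presso_outlier_ids=";".join(pr.outlier_ids),
                presso_distortion_pct=pr.distortion_coefficient,
                presso_distortion_p=pr.distortion_p,
            )
            if pr.corrected_estimate is not None:
                row.update(
                    presso_corrected_beta=pr.corrected_estimate.beta,
                    presso_corrected_se=pr.corrected_estimate.se,
                    presso_corrected_p=pr.corrected_estimate.p,
                )
        row["power"] = rec.suite.power
    return row


__all__ = [
    "AssociationRecord",
    "RECORD_COLUMNS",
    "ScreenConfig",
    "TIERS",
    "analyse_instrument_set",
    "assign_tier",
    "bh_fdr",
    "derive_pair_seed",
    "record_to_row",
    "run_pair",
    "run_screen",
]
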