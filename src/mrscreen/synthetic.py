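"""Synthetic GWAS summary statistics with the structure the screen assumes.

Generates matched exposure (continuous, variance-standardized
metabolite-style) and outcome (binary, log-odds stroke-style) summary
tables, an LD reference and pathway annotations, so every pipeline
stage is testable without consortium downloads.  The generative model:

* per-SNP true exposure effects b_j = ±sqrt(ve_j / (2 p_j (1−p_j)))
  matching a requested per-SNP variance explained ve_j on a
  standardized trait with minor-allele frequency p_j;
* observed β_Xj ~ Normal(b_j, σ_Xj), σ_Xj = 1/sqrt(2 p_j (1−p_j) N_X);
* pleiotropic effects α_j on the invalid fraction of instruments
  (none / balanced / directional / InSIDE-violating, the last
  correlating α with instrument strength);
* observed β_Yj ~ Normal(θ·b_j + α_j, σ_Yj) with the effective-sample
  log-odds calibration σ_Yj = 1/sqrt(2 p_j (1−p_j)·N_Y·K(1−K)).

Cohort-shape defaults mirror the screen's real-data scale: a 7,824
participant metabolite GWAS for the exposure and a 446,696-participant
stroke GWAS (34,217 cases) for the outcome.  All randomness flows from
the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .instruments import InstrumentSet
from .pathway import PathwayAnnotation
from .summary_io import LDReference, TraitSummary, VariantAssociation

NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
PALINDROMIC_CHOICES = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

#: Stroke-cohort shapes (sample size, cases) usable as outcome defaults.
COHORTS = {
    "any_stroke": (446_696, 40_585),
    "any_ischemic_stroke": (446_696, 34_217),
    "large_artery_stroke": (446_696, 4_373),
    "cardioembolic_stroke": (446_696, 7_193),
    "small_vessel_stroke": (446_696, 5_386),
    "lacunar_stroke": (254_959, 6_030),
    "brain_microbleed": (23_032, 2_889),
    "intracerebral_hemorrhage": (343_663, 3_749),
    "subarachnoid_hemorrhage": (343_211, 3_289),
    "transient_ischemic_attack": (360_692, 18_398),
}


class ScenarioError(Exception):
    pass


@dataclass
class SimulationScenario:
    """Full generative specification for one synthetic exposure-outcome pair."""

    n_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.45)
    n_exposure: int = 7824
    n_outcome: int = 446_696
    case_fraction: float = 34_217 / 446_696
    variance_explained: float | Sequence[float] = 0.003
    true_theta: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violating
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    outlier_spec: tuple[int, float] | None = None  # (count, displacement in outcome SEs)
    ld_blocks: list[tuple[int, float]] | None = None  # (block size, within-block r²)
    n_palindromic: int = 0
    inside_corr: float = 0.6
    effect_sign: str = "random"  # random | positive
    seed: int = 0

    def ve_array(self) -> np.ndarray:
        ve = np.broadcast_to(np.asarray(self.variance_explained, dtype=float), (self.n_snps,))
        return np.array(ve)

    def validate(self) -> None:
        ve = self.ve_array()
        if np.any(ve <= 0) or ve.sum() >= 1.0:
            raise ScenarioError("per-SNP variance explained must be positive and sum below 1")
        if not (0.0 < self.case_fraction < 1.0):
            raise ScenarioError("case_fraction must lie in (0,1)")
        if not (0.0 <= self.invalid_fraction < 1.0):
            raise ScenarioError("invalid_fraction must lie in [0,1)")
        lo, hi = self.maf_range
        if not (0.01 <= lo < hi <= 0.5):
            raise ScenarioError("maf_range must sit inside (0.01, 0.5)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violating"):
            raise ScenarioError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.n_palindromic > self.n_snps:
            raise ScenarioError("n_palindromic exceeds n_snps")


def _alleles(rng: np.random.Generator, j: int, n_palindromic: int):
    ea = np.empty(j, dtype=object)
    oa = np.empty(j, dtype=object)
    pal_idx = rng.choice(j, size=n_palindromic, replace=False) if n_palindromic else np.array([], int)
    pal_set = set(pal_idx.tolist())
    for i in range(j):
        pool = PALINDROMIC_CHOICES if i in pal_set else NON_PALINDROMIC_PAIRS
        ea[i], oa[i] = pool[rng.integers(len(pool))]
    return ea, oa


def _positions(j: int, ld_blocks: list[tuple[int, float]] | None):
    """Chromosome/position layout: LD-block members are adjacent (50 kb
    apart); everything else sits on its own 10 Mb-spaced locus."""
    chrom = np.empty(j, dtype=object)
    pos = np.empty(j, dtype=int)
    block_of = np.full(j, -1, dtype=int)
    i = 0
    locus = 0
    if ld_blocks:
        for b, (size, _) in enumerate(ld_blocks):
            for k in range(size):
                if i >= j:
                    break
                chrom[i] = str(locus % 22 + 1)
                pos[i] = 1_000_000 + (locus // 22) * 10_000_000 + k * 50_000
                block_of[i] = b
                i += 1
            locus += 1
    while i < j:
        chrom[i] = str(locus % 22 + 1)
        pos[i] = 1_000_000 + (locus // 22) * 10_000_000
        i += 1
        locus += 1
    return chrom, pos, block_of


def _pleiotropy(rng: np.random.Generator, scenario: SimulationScenario, b: np.ndarray):
    j = scenario.n_snps
    alpha = np.zeros(j)
    n_invalid = int(round(scenario.invalid_fraction * j))
    if scenario.pleiotropy_mode == "none" or n_invalid == 0:
        return alpha, np.array([], dtype=int)
    invalid = rng.choice(j, size=n_invalid, replace=False)
    mu, sd = scenario.pleiotropy_mean, scenario.pleiotropy_sd
    if scenario.pleiotropy_mode == "balanced":
        alpha[invalid] = rng.normal(0.0, sd, n_invalid)
    elif scenario.pleiotropy_mode == "directional":
        alpha[invalid] = rng.normal(mu, sd, n_invalid)
    else:  # inside_violating: α tracks instrument strength
        strength = np.abs(b[invalid])
        zs = (strength - strength.mean()) / (strength.std() or 1.0)
        rho = scenario.inside_corr
        noise = rng.normal(0.0, 1.0, n_invalid)
        alpha[invalid] = mu + sd * (rho * zs + math.sqrt(1.0 - rho**2) * noise)
    return alpha, np.sort(invalid)


def simulate_pair(
    scenario: SimulationScenario,
    exposure_id: str = "metabolite_1",
    outcome_id: str = "stroke",
) -> tuple[TraitSummary, TraitSummary, LDReference, dict]:
    """Generate one exposure-outcome pair plus LD reference and truth record."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    j = scenario.n_snps

    maf = rng.uniform(*scenario.maf_range, size=j)
    ve = scenario.ve_array()
    het = 2.0 * maf * (1.0 - maf)
    b = np.sqrt(ve / het)
    if scenario.effect_sign == "random":
        b *= rng.choice([-1.0, 1.0], size=j)

    se_x = 1.0 / np.sqrt(het * scenario.n_exposure)
    beta_x = rng.normal(b, se_x)

    alpha, invalid = _pleiotropy(rng, scenario, b)
    k_frac = scenario.case_fraction
    n_eff = scenario.n_outcome * k_frac * (1.0 - k_frac)
    se_y = 1.0 / np.sqrt(het * n_eff)
    beta_y = rng.normal(scenario.true_theta * b + alpha, se_y)

    ea, oa = _alleles(rng, j, scenario.n_palindromic)
    chrom, pos, block_of = _positions(j, scenario.ld_blocks)

    from scipy.stats import norm

    p_x = 2.0 * norm.sf(np.abs(beta_x / se_x))
    p_y = 2.0 * norm.sf(np.abs(beta_y / se_y))
    n_cases = int(round(scenario.n_outcome * k_frac))

    ids = np.array([f"rs{scenario.seed % 100_000}_{i}" for i in range(j)], dtype=object)
    exp_records = {}
    out_records = {}
    for i in range(j):
        exp_records[ids[i]] = VariantAssociation(
            variant_id=str(ids[i]), chromosome=str(chrom[i]), position=int(pos[i]),
            effect_allele=str(ea[i]), other_allele=str(oa[i]), eaf=float(maf[i]),
            beta=float(beta_x[i]), se=float(se_x[i]), p_value=float(max(p_x[i], 1e-300)),
            n=scenario.n_exposure,
        )
        out_records[ids[i]] = VariantAssociation(
            variant_id=str(ids[i]), chromosome=str(chrom[i]), position=int(pos[i]),
            effect_allele=str(ea[i]), other_allele=str(oa[i]), eaf=float(maf[i]),
            beta=float(beta_y[i]), se=float(se_y[i]), p_value=float(max(p_y[i], 1e-300)),
            n=scenario.n_outcome, n_cases=n_cases,
        )

    exposure = TraitSummary(
        trait_id=exposure_id, trait_label=exposure_id, trait_type="continuous",
        ancestry="European", records=exp_records,
    )
    outcome = TraitSummary(
        trait_id=outcome_id, trait_label=outcome_id, trait_type="binary",
        ancestry="European", records=out_records, n_cases=n_cases,
    )

    ld = LDReference()
    if scenario.ld_blocks:
        for bidx, (_, r2) in enumerate(scenario.ld_blocks):
            members = np.where(block_of == bidx)[0]
            for a in range(len(members)):
                for c in range(a + 1, len(members)):
                    ld.set_r2(str(ids[members[a]]), str(ids[members[c]]), r2)
    ld.positions = {str(ids[i]): (str(chrom[i]), int(pos[i])) for i in range(j)}

    truth = {
        "true_theta": scenario.true_theta,
        "beta_x_true": b,
        "alpha": alpha,
        "invalid_indices": invalid,
        "invalid_ids": [str(v) for v in ids[invalid]],
        "maf": maf,
        "se_x": se_x,
        "se_y": se_y,
        "variance_explained": ve,
        "seed": scenario.seed,
    }
    return exposure, outcome, ld, truth


def inject_outliers(
    outcome: TraitSummary,
    iset: InstrumentSet,
    spec: tuple[int, float],
    seed: int = 0,
) -> tuple[TraitSummary, list[str]]:
    """Displace ``count`` instrument SNPs' outcome effects by
    ``displacement`` outcome SEs; returns a modified copy and the ids."""
    count, displacement = spec
    if count >= iset.n_snps:
        raise ScenarioError("outlier count must be below the instrument count")
    if count == 0:
        return outcome, []
    rng = np.random.default_rng(seed)
    chosen = rng.choice(iset.n_snps, size=count, replace=False)
    ids = [str(iset.variant_id[i]) for i in chosen]
    new_records = dict(outcome.records)
    for vid in ids:
        rec = new_records[vid]
        new_records[vid] = replace(rec, beta=rec.beta + displacement * rec.se)
    modified = TraitSummary(
        trait_id=outcome.trait_id, trait_label=outcome.trait_label,
        trait_type=outcome.trait_type, ancestry=outcome.ancestry,
        records=new_records, n_cases=outcome.n_cases,
    )
    return modified, ids


def make_screen_fixture(
    n_exposures: int,
    n_causal: int,
    template: SimulationScenario | None = None,
    outcome_id: str = "stroke",
    pathway_size: int = 5,
    n_background_pathways: int = 4,
):
    """A multi-exposure screen sharing one outcome, with ORA ground truth.

    The first ``n_causal`` exposures carry the template's ``true_theta``
    (the rest are null), each exposure owns a disjoint SNP set merged
    into one outcome table, and the causal metabolites co-occur in one
    annotated pathway so enrichment is detectable by construction.
    """
    if n_causal > n_exposures:
        raise ScenarioError("n_causal cannot exceed n_exposures")
    template = template or SimulationScenario(true_theta=math.log(1.5))
    exposures: list[TraitSummary] = []
    merged_outcome: dict[str, VariantAssociation] = {}
    truths: dict[str, dict] = {}
    ld = LDReference()
    out_summary = None
    for e in range(n_exposures):
        theta = template.true_theta if e < n_causal else 0.0
        scen = replace(template, true_theta=theta, seed=(template.seed * 7919 + e) % 2**31)
        exp_id = f"metabolite_{e:03d}"
        exp, out, ld_e, truth = simulate_pair(scen, exposure_id=exp_id, outcome_id=outcome_id)
        # re-key variants so exposures own disjoint SNP sets
        renamed_exp, renamed_out = {}, {}
        for vid, rec in exp.records.items():
            nid = f"{vid}_e{e}"
            renamed_exp[nid] = replace(rec, variant_id=nid)
            renamed_out[nid] = replace(out.records[vid], variant_id=nid)
        exp.records = renamed_exp
        exposures.append(exp)
        merged_outcome.update(renamed_out)
        truth["invalid_ids"] = [f"{v}_e{e}" for v in truth["invalid_ids"]]
        truths[exp_id] = truth
        for pair, r2 in ld_e.pairs.items():
            a, bb = sorted(pair)
            ld.set_r2(f"{a}_e{e}", f"{bb}_e{e}", r2)
        out_summary = out
    outcome = TraitSummary(
        trait_id=outcome_id, trait_label=outcome_id, trait_type="binary",
        ancestry="European", records=merged_outcome, n_cases=out_summary.n_cases,
    )

    all_ids = [t.trait_id for t in exposures]
    causal_ids = all_ids[:n_causal]
    rng = np.random.default_rng(template.seed + 1)
    annotations = []
    if n_causal:
        members = set(causal_ids)
        extra = [m for m in all_ids if m not in members]
        while len(members) < min(pathway_size, n_exposures):
            members.add(extra.pop(0))
        annotations.append(
            PathwayAnnotation(
                pathway_id="PW_causal", pathway_name="causal cluster pathway",
                source="synthetic", members=members, background=set(all_ids),
            )
        )
    for pw in range(n_background_pathways):
        size = min(pathway_size, n_exposures)
        members = set(rng.choice(all_ids, size=size, replace=False).tolist())
        annotations.append(
            PathwayAnnotation(
                pathway_id=f"PW_rand_{pw}", pathway_name=f"background pathway {pw}",
                source="synthetic", members=members, background=set(all_ids),
            )
        )
    return exposures, outcome, ld, annotations, truths


__all__ = [
    "COHORTS",
    "ScenarioError",
    "SimulationScenario",
    "inject_outliers",
    "make_screen_fixture",
    "simulate_pair",
]
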