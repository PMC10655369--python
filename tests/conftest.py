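"""Shared fixtures and helpers: hand-built instrument sets and tiny tables."""

from __future__ import annotations

import numpy as np
import pytest

from mrscreen.instruments import InstrumentSet, harmonize_pair
from mrscreen.summary_io import TraitSummary, VariantAssociation


def make_iset(
    beta_exp,
    beta_out,
    se_out,
    se_exp=None,
    eaf=None,
    n_exp=7824,
    exposure_id="exp",
    outcome_id="out",
) -> InstrumentSet:
    """Build an InstrumentSet directly from effect arrays (tests only)."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float) * np.ones_like(beta_exp)
    se_exp = (
        np.asarray(se_exp, dtype=float) * np.ones_like(beta_exp)
        if se_exp is not None
        else np.full_like(beta_exp, 0.01)
    )
    eaf_arr = (
        np.asarray(eaf, dtype=float) * np.ones_like(beta_exp)
        if eaf is not None
        else np.full_like(beta_exp, np.nan)
    )
    j = beta_exp.size
    z2 = (beta_exp / se_exp) ** 2
    r2 = np.where(
        np.isnan(eaf_arr),
        z2 / (z2 + n_exp - 2),
        2.0 * eaf_arr * (1.0 - eaf_arr) * beta_exp**2,
    )
    f = r2 * (n_exp - 2) / (1.0 - r2)
    return InstrumentSet(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        variant_id=np.array([f"rs{i}" for i in range(j)], dtype=object),
        beta_exp=beta_exp,
        se_exp=se_exp,
        beta_out=beta_out,
        se_out=se_out,
        eaf=eaf_arr,
        r2_snp=r2,
        f_snp=f,
        n_exp=n_exp,
        r2_method=np.array(["eaf"] * j, dtype=object),
    )


def iset_from_pair(exposure: TraitSummary, outcome: TraitSummary) -> InstrumentSet:
    """Harmonize every generated SNP (no selection) — used by simulations."""
    records = list(exposure.records.values())
    return harmonize_pair(
        records, outcome, records[0].n, exposure_id=exposure.trait_id
    )


def make_variant(
    vid="rs1",
    chrom="1",
    pos=100_000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    p=1e-6,
    n=7824,
    n_cases=None,
) -> VariantAssociation:
    return VariantAssociation(
        variant_id=vid,
        chromosome=chrom,
        position=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        p_value=p,
        n=n,
        n_cases=n_cases,
    )


def make_trait(records, trait_id="trait", trait_type="continuous", n_cases=None) -> TraitSummary:
    return TraitSummary(
        trait_id=trait_id,
        trait_label=trait_id,
        trait_type=trait_type,
        ancestry="European",
        records={r.variant_id: r for r in records},
        n_cases=n_cases,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
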