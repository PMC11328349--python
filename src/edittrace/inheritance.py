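"""Family-level inheritance analysis of edited alleles.

T0 parents are matched to their transgene-free (null-segregant) T1 progeny;
each family x locus x allele signature becomes one inheritance record with
the progeny fraction carrying the allele, a 1-df chi-squared goodness-of-fit
p-value against the 75% transmission expected for a heterozygous edit in a
selfed parent, and a near-/non-Mendelian category assigned by the operational
<=20%-of-progeny cut.  Cohort summaries reproduce the study-style statistics:
per-construct editing rates, the background variation rate in plants never
exposed to a guide, T0->T1 inheritance and T1-only percentages, and the
fraction of families in which a plant with only on-target edits exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

NON_MENDELIAN_MAX_FRACTION = 0.20  # alleles in <=20% of progeny are non-Mendelian
EXPECTED_TRANSMISSION = 0.75


def percentage(numerator: int, denominator: int) -> float:
    """Plain editing-rate arithmetic: edited / assayed * 100."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator: rate undefined")
    return 100.0 * numerator / denominator


def mendelian_category(
    n_with: int,
    n_progeny: int,
    expected: float = EXPECTED_TRANSMISSION,
    alpha: float = 0.01,
) -> tuple[float, str]:
    """Chi-squared test of progeny transmission plus the categorical call.

    The p-value is a 1-df goodness-of-fit of (carriers, non-carriers) against
    (expected*n, (1-expected)*n) without continuity correction.  The category
    follows the operational cut: allele present in <=20% of progeny is
    ``non_mendelian``, otherwise ``near_mendelian``.  ``alpha`` documents the
    significance level the cut was anchored to; it does not enter the rule.
    """
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    if not 0 <= n_with <= n_progeny:
        raise ValueError("n_with must lie in [0, n_progeny]")
    exp_with = expected * n_progeny
    exp_without = (1 - expected) * n_progeny
    chi2 = (n_with - exp_with) ** 2 / exp_with + (
        (n_progeny - n_with) - exp_without
    ) ** 2 / exp_without
    p = float(stats.chi2.sf(chi2, df=1))
    category = (
        "non_mendelian"
        if n_with / n_progeny <= NON_MENDELIAN_MAX_FRACTION
        else "near_mendelian"
    )
    return p, category


def binomial_p(n_with: int, n_progeny: int, expected: float = EXPECTED_TRANSMISSION) -> float:
    """Exact two-sided binomial companion to the chi-squared test."""
    return float(stats.binomtest(n_with, n_progeny, expected).pvalue)


@dataclass
class InheritanceRecord:
    family_id: str
    locus_id: str
    signature: str
    observed_in_T0: bool
    t0_read_fraction: float  # NaN when absent in the parent
    n_progeny: int
    n_progeny_with_allele: int
    chi2_p: float
    binom_p: float
    category: str
    homozygous_parent_flag: bool = False

    @property
    def t1_fraction(self) -> float:
        return self.n_progeny_with_allele / self.n_progeny


def match_generations(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    min_progeny: int = 1,
) -> list[InheritanceRecord]:
    """Build per family x locus x signature inheritance records.

    ``calls`` is the edit-calling output table (plant_id, locus_id,
    signature, read_fraction, edited, called); ``samples`` the plant metadata
    (plant_id, generation, construct, family_id, transgene_present).  Only
    transgene-free T1 progeny count toward ``n_progeny`` (null segregants:
    their edits are inherited, not de novo); a progeny counts at a locus only
    when it has data there.  Families without genotyped progeny are skipped.
    """
    samples = samples.set_index("plant_id") if "plant_id" in samples.columns else samples
    t1_meta = samples[(samples["generation"] == "T1") & (~samples["transgene_present"])]
    calls = calls.merge(
        samples[["generation", "construct", "family_id", "transgene_present"]],
        left_on="plant_id",
        right_index=True,
    )
    t0_calls = calls[calls["generation"] == "T0"]
    t1_calls = calls[(calls["generation"] == "T1") & (~calls["transgene_present"])]

    records: list[InheritanceRecord] = []
    for family_id, fam_progeny in t1_meta.groupby("family_id"):
        progeny_ids = set(fam_progeny.index)
        if len(progeny_ids) < min_progeny:
            continue
        fam_t1 = t1_calls[t1_calls["plant_id"].isin(progeny_ids)]
        fam_t0 = t0_calls[t0_calls["family_id"] == family_id]
        if fam_t1.empty and fam_t0.empty:
            continue
        loci = set(fam_t1["locus_id"]) | set(fam_t0["locus_id"])
        for locus_id in sorted(loci):
            loc_t1 = fam_t1[fam_t1["locus_id"] == locus_id]
            loc_t0 = fam_t0[fam_t0["locus_id"] == locus_id]
            n_progeny = loc_t1["plant_id"].nunique()  # progeny with data at the locus
            if n_progeny == 0:
                continue
            parent_called = loc_t0[(loc_t0["edited"]) & (loc_t0["called"])]
            t0_fraction = dict(zip(parent_called["signature"], parent_called["read_fraction"]))
            progeny_called = loc_t1[(loc_t1["edited"]) & (loc_t1["called"])]
            signatures = set(t0_fraction) | set(progeny_called["signature"])
            for signature in sorted(signatures):
                carriers = progeny_called[progeny_called["signature"] == signature][
                    "plant_id"
                ].nunique()
                chi2_p, category = mendelian_category(carriers, n_progeny)
                records.append(
                    InheritanceRecord(
                        family_id=str(family_id),
                        locus_id=locus_id,
                        signature=signature,
                        observed_in_T0=signature in t0_fraction,
                        t0_read_fraction=t0_fraction.get(signature, float("nan")),
                        n_progeny=n_progeny,
                        n_progeny_with_allele=carriers,
                        chi2_p=chi2_p,
                        binom_p=binomial_p(carriers, n_progeny),
                        category=category,
                        homozygous_parent_flag=carriers == n_progeny and n_progeny >= 10,
                    )
                )
    return records


def inheritance_table(records: list[InheritanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family_id": [r.family_id for r in records],
            "locus_id": [r.locus_id for r in records],
            "signature": [r.signature for r in records],
            "observed_in_T0": [r.observed_in_T0 for r in records],
            "t0_read_fraction": [r.t0_read_fraction for r in records],
            "n_progeny": [r.n_progeny for r in records],
            "n_progeny_with_allele": [r.n_progeny_with_allele for r in records],
            "t1_fraction": [r.t1_fraction for r in records],
            "chi2_p": [r.chi2_p for r in records],
            "binom_p": [r.binom_p for r in records],
            "category": [r.category for r in records],
        }
    )


def summarize(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    guide_loci: pd.DataFrame,
    records: list[InheritanceRecord] | None = None,
) -> dict:
    """Cohort summary statistics.

    ``guide_loci`` maps constructs to their target loci with roles:
    columns (construct, locus_id, role) where role is ``on`` or ``off``.
    Editing rate = plants with >=1 called edited allele at the locus / plants
    with data at the locus * 100, per construct x generation x locus.
    Background rate = % of plants NOT carrying a construct's guide that have
    a called edit at that construct's target loci.  Off-target-free family %
    = families (with an edited T0 parent) in which >=1 progeny carries an
    on-target edit and no off-target edit.
    """
    samples_idx = samples.set_index("plant_id") if "plant_id" in samples.columns else samples
    merged = calls.merge(
        samples_idx[["generation", "construct", "family_id", "transgene_present"]],
        left_on="plant_id",
        right_index=True,
    )
    edited_mask = merged["edited"] & merged["called"]

    rates: dict[tuple[str, str, str], float] = {}
    for (construct, generation, locus), grp in merged.groupby(
        ["construct", "generation", "locus_id"]
    ):
        assayed = grp["plant_id"].nunique()
        edited = grp.loc[edited_mask.reindex(grp.index, fill_value=False), "plant_id"].nunique()
        rates[(construct, generation, locus)] = percentage(edited, assayed)

    background: dict[str, float] = {}
    for construct, cgrp in guide_loci.groupby("construct"):
        targets = set(cgrp["locus_id"])
        outsiders = merged[(merged["construct"] != construct) & (merged["locus_id"].isin(targets))]
        n_out = outsiders["plant_id"].nunique()
        if n_out == 0:
            continue
        n_hit = outsiders.loc[
            edited_mask.reindex(outsiders.index, fill_value=False), "plant_id"
        ].nunique()
        background[construct] = percentage(n_hit, n_out)

    summary: dict = {
        "editing_rate_percent": {
            f"{c}|{g}|{l}": v for (c, g, l), v in sorted(rates.items())
        },
        "background_rate_percent": background,
    }

    if records is not None:
        t0_alleles = [r for r in records if r.observed_in_T0]
        t1_alleles = [r for r in records if r.n_progeny_with_allele > 0]
        if t0_alleles:
            inherited = sum(1 for r in t0_alleles if r.n_progeny_with_allele > 0)
            summary["t0_inheritance_percent"] = percentage(inherited, len(t0_alleles))
        if t1_alleles:
            t1_only = sum(1 for r in t1_alleles if not r.observed_in_T0)
            summary["t1_only_percent"] = percentage(t1_only, len(t1_alleles))
        summary["category_counts"] = {
            "near_mendelian": sum(
                1 for r in records if r.n_progeny_with_allele > 0 and r.category == "near_mendelian"
            ),
            "non_mendelian": sum(
                1 for r in records if r.n_progeny_with_allele > 0 and r.category == "non_mendelian"
            ),
        }

    summary["offtarget_free_family_percent"] = _offtarget_free_families(merged, guide_loci, edited_mask)
    return summary


def _offtarget_free_families(merged: pd.DataFrame, guide_loci: pd.DataFrame, edited_mask) -> dict:
    out: dict[str, float] = {}
    for construct, cgrp in guide_loci.groupby("construct"):
        on_loci = set(cgrp.loc[cgrp["role"] == "on", "locus_id"])
        off_loci = set(cgrp.loc[cgrp["role"] == "off", "locus_id"])
        cohort = merged[merged["construct"] == construct]
        t0 = cohort[cohort["generation"] == "T0"]
        edited_parents = set(
            t0.loc[
                edited_mask.reindex(t0.index, fill_value=False)
                & t0["locus_id"].isin(on_loci | off_loci),
                "family_id",
            ]
        )
        if not edited_parents:
            continue
        t1 = cohort[(cohort["generation"] == "T1") & (~cohort["transgene_present"])]
        t1 = t1[t1["family_id"].isin(edited_parents)]
        qualifying = 0
        for family_id, fam in t1.groupby("family_id"):
            fam_edited = fam[edited_mask.reindex(fam.index, fill_value=False)]
            by_plant = fam_edited.groupby("plant_id")["locus_id"].agg(set)
            all_plants = fam["plant_id"].unique()
            for plant in all_plants:
                loci = by_plant.get(plant, set())
                if loci & on_loci and not loci & off_loci:
                    qualifying += 1
                    break
        out[construct] = percentage(qualifying, len(edited_parents))
    return out
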