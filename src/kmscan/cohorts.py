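"""Receptor-status calls from expression and cohort selection.

Molecular subtype is assigned directly from normalized array expression of
two marker probe sets: estrogen receptor alpha (ESR1, probe ``205225_at``,
cutoff 500) and HER2 (ERBB2, probe ``216836_s_at``, cutoff 4800). A sample
is called positive when its normalized intensity is strictly above the
cutoff. Progesterone receptor is not assessed (no reliable probe set on the
HG-U133A platform generation).

Analysis cohorts combine a subtype with a treatment rule. Samples lacking
relapse-free survival follow-up are always dropped; treatment rules act on
documented systemic therapy only (radiation is ignored).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "ER_PROBE",
    "ERBB2_PROBE",
    "ER_CUTOFF",
    "ERBB2_CUTOFF",
    "SUBTYPES",
    "TREATMENT_RULES",
    "CohortSpec",
    "assign_receptor_status",
    "select_cohort",
]

ER_PROBE = "205225_at"
ERBB2_PROBE = "216836_s_at"
ER_CUTOFF = 500.0
ERBB2_CUTOFF = 4800.0

SUBTYPES = ("er_pos_erbb2_neg", "basal")
TREATMENT_RULES = (
    "chemo_documented",
    "any_systemic_treatment_documented",
    "adjuvant_chemo_documented",
    "untreated_documented",
)

#: Clinical columns with controlled vocabulary {yes, no, unknown}.
CLINICAL_FLAG_COLUMNS = (
    "chemotherapy",
    "endocrine_therapy",
    "adjuvant_setting",
    "systemically_untreated",
)


@dataclass(frozen=True)
class CohortSpec:
    """A subtype plus a treatment-documentation rule."""

    subtype: str
    treatment_rule: str

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}; one of {SUBTYPES}")
        if self.treatment_rule not in TREATMENT_RULES:
            raise ValueError(
                f"unknown treatment rule {self.treatment_rule!r}; one of {TREATMENT_RULES}"
            )


def assign_receptor_status(
    matrix: ExpressionMatrix,
    er_probe: str = ER_PROBE,
    erbb2_probe: str = ERBB2_PROBE,
    er_cutoff: float = ER_CUTOFF,
    erbb2_cutoff: float = ERBB2_CUTOFF,
) -> pd.DataFrame:
    """Call ER and ERBB2 status for every sample from marker-probe intensity.

    Positive means strictly greater than the cutoff; a value exactly at the
    cutoff is called negative. Expects post-normalization intensities.

    Returns a DataFrame with columns ``sample_id``, ``er_status``,
    ``erbb2_status``, ``er_probe_value``, ``erbb2_probe_value``.
    """
    for probe in (er_probe, erbb2_probe):
        if probe not in matrix.values.index:
            raise ValueError(f"receptor probe {probe!r} not present in matrix")
    er_vals = matrix.values.loc[er_probe]
    erbb2_vals = matrix.values.loc[erbb2_probe]
    return pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "er_status": (er_vals > er_cutoff).map({True: "positive", False: "negative"}).to_numpy(),
            "erbb2_status": (erbb2_vals > erbb2_cutoff)
            .map({True: "positive", False: "negative"})
            .to_numpy(),
            "er_probe_value": er_vals.to_numpy(),
            "erbb2_probe_value": erbb2_vals.to_numpy(),
        }
    )


def _treatment_mask(clinical: pd.DataFrame, rule: str) -> pd.Series:
    chemo = clinical["chemotherapy"]
    endo = clinical["endocrine_therapy"]
    adjuvant = clinical["adjuvant_setting"]
    untreated = clinical["systemically_untreated"]
    if rule == "chemo_documented":
        return chemo == "yes"
    if rule == "any_systemic_treatment_documented":
        return (chemo == "yes") | (endo == "yes")
    if rule == "adjuvant_chemo_documented":
        return (chemo == "yes") & (adjuvant == "yes")
    if rule == "untreated_documented":
        return untreated == "yes"
    raise ValueError(f"unknown treatment rule {rule!r}")


def select_cohort(clinical: pd.DataFrame, calls: pd.DataFrame, spec: CohortSpec) -> list:
    """Return sample ids satisfying the subtype and treatment filters.

    Subtype: ``er_pos_erbb2_neg`` keeps ER-positive, ERBB2-negative samples;
    ``basal`` keeps samples negative for both receptors. Samples with missing
    survival follow-up (``rfs_months`` or ``rfs_event``) are dropped in every
    cohort; treatment documented as ``unknown`` never satisfies a rule.
    """
    call_ids = set(calls["sample_id"])
    uncovered = [s for s in clinical["sample_id"] if s not in call_ids]
    if uncovered:
        raise ValueError(f"receptor calls missing for samples: {uncovered[:5]}")
    merged = clinical.merge(calls[["sample_id", "er_status", "erbb2_status"]], on="sample_id")

    if spec.subtype == "er_pos_erbb2_neg":
        subtype_ok = (merged["er_status"] == "positive") & (merged["erbb2_status"] == "negative")
    else:  # basal
        subtype_ok = (merged["er_status"] == "negative") & (merged["erbb2_status"] == "negative")

    has_followup = merged["rfs_months"].notna() & merged["rfs_event"].notna()
    mask = subtype_ok & has_followup & _treatment_mask(merged, spec.treatment_rule)
    return merged.loc[mask, "sample_id"].tolist()
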