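"""Clinical risk-group assignment for head-and-neck cancer patients.

Oropharyngeal carcinoma (OPC) patients are stratified into low,
intermediate and high risk using the recursive-partitioning scheme based
on p16 (HPV surrogate) status, smoking and TNM stage; patients with
non-oropharyngeal primaries form a fourth group of their own, since the
p16-based scheme is prognostic only in the oropharynx.

The rule table is configuration, not code: trials that dichotomize
smoking differently (the original scheme uses a 10 pack-year cutoff,
whereas clinical metadata often records only current/former/never status)
can override ``smoker_equivalent`` or any stage set without touching the
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SITES = ("oropharynx", "hypopharynx", "supraglottic-larynx", "other")
T_STAGES = ("T1", "T2", "T3", "T4")
N_STAGES = ("N0", "N1", "N2a", "N2b", "N2c")
P16 = ("positive", "negative")
SMOKING = ("current", "former", "never")

GROUPS = ("high", "intermediate", "low", "non-OPC")


@dataclass(frozen=True)
class PatientMeta:
    """Per-patient clinical metadata used for risk stratification."""

    patient_id: str
    site: str
    t_stage: str
    n_stage: str
    p16: str
    smoking: str

    def __post_init__(self):
        for value, vocab, name in (
            (self.site, SITES, "site"),
            (self.t_stage, T_STAGES, "t_stage"),
            (self.n_stage, N_STAGES, "n_stage"),
            (self.p16, P16, "p16"),
            (self.smoking, SMOKING, "smoking"),
        ):
            if value not in vocab:
                raise ValueError(
                    f"unknown {name} {value!r} for patient {self.patient_id}; "
                    f"allowed: {vocab}"
                )


@dataclass(frozen=True)
class RiskGroup:
    label: str

    def __post_init__(self):
        if self.label not in GROUPS:
            raise ValueError(f"unknown risk group {self.label!r}; allowed: {GROUPS}")


@dataclass(frozen=True)
class RiskRules:
    """Configurable stratification rule table for OPC patients.

    ``smoker_equivalent``: smoking-status tokens mapped to the above-cutoff
    arm of the pack-year dichotomy.  ``low_nodal``: nodal stages that keep a
    p16-positive smoker in the low-risk group.  ``intermediate_t``: T stages
    placing a p16-negative non-smoker in the intermediate group (higher T
    is high risk).
    """

    opc_sites: frozenset[str] = frozenset({"oropharynx"})
    smoker_equivalent: frozenset[str] = frozenset({"current", "former"})
    low_nodal: frozenset[str] = frozenset({"N0", "N1", "N2a"})
    intermediate_t: frozenset[str] = frozenset({"T1", "T2", "T3"})

    @classmethod
    def from_dict(cls, d: dict) -> "RiskRules":
        kwargs = {k: frozenset(v) for k, v in d.items()}
        return cls(**kwargs)


DEFAULT_RULES = RiskRules()


def classify_patient(meta: PatientMeta, rules: RiskRules = DEFAULT_RULES) -> RiskGroup:
    """Assign exactly one risk group to a patient.

    Non-oropharyngeal primaries are 'non-OPC' unconditionally.  For OPC:

    * low — p16+ and (non-smoker-equivalent, or nodal stage in the low set)
    * intermediate — p16+ smoker-equivalent with advanced nodal stage, or
      p16- non-smoker-equivalent with T stage in the intermediate set
    * high — every remaining p16- patient (smoker-equivalent, or T4)
    """
    if meta.site not in rules.opc_sites:
        return RiskGroup("non-OPC")
    smoker = meta.smoking in rules.smoker_equivalent
    if meta.p16 == "positive":
        if not smoker or meta.n_stage in rules.low_nodal:
            return RiskGroup("low")
        return RiskGroup("intermediate")
    # p16-negative
    if not smoker and meta.t_stage in rules.intermediate_t:
        return RiskGroup("intermediate")
    return RiskGroup("high")
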