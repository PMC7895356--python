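"""Bundled case-study inputs and a synthetic study-table generator.

Three fixtures reproduce the bundled COVID-19 antiviral case study
end-to-end:

* :func:`scenario_tree` — the three-factor illustrative scenario: a top OR
  over forgetfulness (FORG, 0.006/day), side effects (SIDE, 0.004/day) and
  other causes (OTHER, 0.010/day) on a 10-day regimen;
* :func:`six_studies` — raw per-factor non-adherent counts from six
  oseltamivir adherence studies (S1–S6), stored as integer counts so every
  derived rate is genuinely recomputed;
* :func:`covid_tree` — the case-study tree: discontinuation (NA) as an OR
  over the five WHO adherence dimensions, with leaf rates built from the
  pooled WNARs of the six studies plus the assumed social/healthcare rate
  models (limited healthcare access 1.2e-4/day; prior-knowledge gap
  decaying 8% of its initial 1.5e-4 per elapsed day; ICT and manual
  medicine-delivery systems failing at 8.12e-5 and 5.34e-5 per day with 4 h
  and 2 h repair times; age-stratified social-support rates with an
  equal-thirds cohort mix).

The same inputs ship as package data files (``scenario.yaml``,
``covid_tree.yaml``, ``six_studies.csv``; list or export them with
``nata fixtures``) for use from the command line.

:func:`generate_synthetic_studies` draws synthetic study tables from known
per-day rates for parameter-recovery tests.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .model import (
    AgeBand,
    AgeStratifiedRate,
    ConstantRate,
    GateKind,
    LinearDecayRate,
    NafNode,
    NonAdherenceTree,
    RepairableRate,
)
from .rates import StudyRecord, read_studies_csv, wnar

__all__ = [
    "scenario_tree",
    "scenario_study",
    "six_studies",
    "covid_tree",
    "fixture_path",
    "fixture_names",
    "generate_synthetic_studies",
]

#: assumed rate models for factors not covered by the six studies
ASSUMED_RATES = {
    "HeaAcc": ConstantRate(1.2e-4),
    "PriKno": LinearDecayRate(initial_rate=1.5e-4, decay_fraction_per_day=0.08),
    "IctSys": RepairableRate(failure_rate=8.12e-5, mean_repair_time=4.0),
    "ManSys": RepairableRate(failure_rate=5.34e-5, mean_repair_time=2.0),
    "SocSup": AgeStratifiedRate(
        bands=(
            AgeBand("<25", 4.138e-4, 1 / 3),
            AgeBand("25-45", 1.379e-4, 1 / 3),
            AgeBand(">45", 2.069e-4, 1 / 3),
        )
    ),
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture data file."""
    return Path(resources.files("nata").joinpath("data", name))


def scenario_tree() -> NonAdherenceTree:
    """The three-factor illustrative tree: NA = FORG ∨ SIDE ∨ OTHER."""
    nodes = {
        "NA": NafNode(id="NA", label="Non-adherence", kind="top",
                      gate=GateKind.OR, children=("FORG", "SIDE", "OTHER")),
        "FORG": NafNode(id="FORG", label="Forgetfulness",
                        rate_model=ConstantRate(0.006)),
        "SIDE": NafNode(id="SIDE", label="Side effects",
                        rate_model=ConstantRate(0.004)),
        "OTHER": NafNode(id="OTHER", label="Other factors",
                         rate_model=ConstantRate(0.010)),
    }
    return NonAdherenceTree(nodes=nodes, top_id="NA",
                            name="three-factor scenario")


def scenario_study() -> StudyRecord:
    """The illustrative study: 20 of 100 patients non-adherent over 10 days."""
    return StudyRecord("scenario", nop=100, dom=10,
                       counts={"FORG": 6, "SIDE": 4, "OTHER": 10})


def six_studies() -> list[StudyRecord]:
    """Raw counts of the six pooled oseltamivir adherence studies."""
    return read_studies_csv(fixture_path("six_studies.csv"))


def fixture_names() -> tuple[str, ...]:
    """Names of the bundled fixture data files."""
    root = resources.files("nata").joinpath("data")
    return tuple(sorted(p.name for p in root.iterdir() if p.is_file()))


def covid_tree(studies: list[StudyRecord] | None = None) -> NonAdherenceTree:
    """The COVID-19 case-study tree with all leaf rate models populated.

    Pooled WNARs are recomputed at full precision from the study counts
    (pass ``studies`` to pool a different set); the remaining leaves use the
    assumed rate models in :data:`ASSUMED_RATES`.
    """
    if studies is None:
        studies = six_studies()
    w = {f: wnar(studies, f) for f in
         ("NoTab", "SidEff", "NoMed", "ClinImp", "Forgot", "NoSym", "Other")}

    def basic(nid: str, label: str, model) -> NafNode:
        return NafNode(id=nid, label=label, rate_model=model)

    nodes = {
        "NA": NafNode(
            id="NA", label="Non-adherence to the medication regimen",
            kind="top", gate=GateKind.OR,
            children=("SocRel", "PatRel", "ConRel", "HeaRel", "TheRel"),
        ),
        "SocRel": NafNode(
            id="SocRel", label="Social/economic-related factors",
            kind="intermediate", gate=GateKind.OR,
            children=("SocSup", "HeaAcc"),
        ),
        "PatRel": NafNode(
            id="PatRel", label="Patient-related factors",
            kind="intermediate", gate=GateKind.OR,
            children=("NoMed", "Forgot", "Other"),
        ),
        "ConRel": NafNode(
            id="ConRel", label="Condition-related factors",
            kind="intermediate", gate=GateKind.OR, children=("NoSym",),
        ),
        "HeaRel": NafNode(
            id="HeaRel", label="Healthcare-related factors",
            kind="intermediate", gate=GateKind.OR,
            children=("ClinImp", "NoTab", "DelSys", "PriKno"),
        ),
        "TheRel": NafNode(
            id="TheRel", label="Therapy-related factors",
            kind="intermediate", gate=GateKind.OR, children=("SidEff",),
        ),
        "DelSys": NafNode(
            id="DelSys", label="Medicine delivery system failure",
            kind="intermediate", gate=GateKind.AND,
            children=("IctSys", "ManSys"),
        ),
        "SocSup": basic("SocSup", "Limited social support",
                        ASSUMED_RATES["SocSup"]),
        "HeaAcc": basic("HeaAcc", "Limited healthcare access",
                        ASSUMED_RATES["HeaAcc"]),
        "NoMed": basic("NoMed", "Choice not to take medication",
                       ConstantRate(w["NoMed"])),
        "Forgot": basic("Forgot", "Forgetfulness", ConstantRate(w["Forgot"])),
        "Other": basic("Other", "Other patient-related factors",
                       ConstantRate(w["Other"])),
        "NoSym": basic("NoSym", "No symptoms", ConstantRate(w["NoSym"])),
        "ClinImp": basic("ClinImp", "Clinical improvement",
                         ConstantRate(w["ClinImp"])),
        "NoTab": basic("NoTab", "Limited tablets (2-day resupply delay)",
                       ConstantRate(w["NoTab"])),
        "SidEff": basic("SidEff", "Side effects of the medication",
                        ConstantRate(w["SidEff"])),
        "PriKno": basic("PriKno", "Lack of prior adherence knowledge",
                        ASSUMED_RATES["PriKno"]),
        "IctSys": basic("IctSys", "ICT medicine-delivery system",
                        ASSUMED_RATES["IctSys"]),
        "ManSys": basic("ManSys", "Manual medicine-delivery system",
                        ASSUMED_RATES["ManSys"]),
    }
    return NonAdherenceTree(
        nodes=nodes, top_id="NA", name="COVID-19 antiviral case study",
        description="Hypothetical 10-day out-patient antiviral regimen, "
                    "1000 participants",
    )


def generate_synthetic_studies(
    n_studies: int,
    nop_range: tuple[int, int],
    dom_range: tuple[int, int],
    true_rates: dict[str, float],
    seed: int,
) -> list[StudyRecord]:
    """Draw synthetic study tables from known per-day factor rates.

    Each study's NoP and DoM are drawn uniformly from the given inclusive
    ranges; each factor's count is Binomial(NoP, 1 − exp(−rate·DoM)),
    truncated (largest counts trimmed first) so the total never exceeds
    NoP.  Raises if the expected totals already exceed NoP at the largest
    feasible DoM (the competing-risk approximation breaks down there).
    """
    rng = np.random.default_rng(seed)
    max_p = sum(-np.expm1(-r * dom_range[1]) for r in true_rates.values())
    if max_p > 1.0:
        raise ValueError(
            f"rates too large: expected non-adherent fraction {max_p:.3f} > 1 "
            f"at DoM={dom_range[1]}"
        )
    records = []
    for i in range(n_studies):
        nop = int(rng.integers(nop_range[0], nop_range[1] + 1))
        dom = int(rng.integers(dom_range[0], dom_range[1] + 1))
        counts = {
            f: int(rng.binomial(nop, -np.expm1(-r * dom)))
            for f, r in true_rates.items()
        }
        while sum(counts.values()) > nop:  # rare: trim the largest count
            top = max(counts, key=counts.get)
            counts[top] -= 1
        records.append(StudyRecord(f"SYN{i + 1}", nop=nop, dom=dom, counts=counts))
    return records
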