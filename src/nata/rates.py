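"""Pooling multi-study non-adherence counts into per-day rates.

Each source study reports, for a cohort of ``NoP`` participants on a
``DoM``-day regimen, how many participants discontinued because of each
non-adherence factor.  From the raw counts we derive:

``NARS``
    the per-study non-adherence proportion for a factor, count / NoP;
``NAR``
    its per-day rate, NARS / DoM;
``WNAR``
    the pooled rate across studies, weighting each study's NAR by its share
    of the grand participant total: Σ_i NAR_i · NoP_i / GrandNoP, where
    GrandNoP = Σ NoP over *all* pooled studies (including studies that did
    not observe the factor — their participants still inform the weight
    base, which is what makes the pooled rates comparable across factors).

A factor absent from a study's counts is "not observed" — distinct from an
observed count of zero.  Unobserved factors contribute nothing to the WNAR
numerator but the study's NoP still enters GrandNoP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import MissingFactorError

__all__ = [
    "StudyRecord",
    "RateTable",
    "nac",
    "nars",
    "nar",
    "wnar",
    "grand_nop",
    "mean_nac_ratio",
    "build_rate_table",
    "read_studies_csv",
    "write_studies_csv",
]


@dataclass(frozen=True)
class StudyRecord:
    """One study's summary counts.

    ``counts`` maps factor id → number of participants non-adherent due to
    that factor; a missing key means the study did not observe the factor.
    """

    study_id: str
    nop: int
    dom: int
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))
        if self.nop <= 0:
            raise ValueError(f"study {self.study_id!r}: NoP must be > 0, got {self.nop}")
        if self.dom < 1:
            raise ValueError(f"study {self.study_id!r}: DoM must be >= 1, got {self.dom}")
        for factor, count in self.counts.items():
            if count < 0 or count != int(count):
                raise ValueError(
                    f"study {self.study_id!r}: count for {factor!r} must be a "
                    f"non-negative integer, got {count}"
                )
        if sum(self.counts.values()) > self.nop:
            raise ValueError(
                f"study {self.study_id!r}: factor counts sum to "
                f"{sum(self.counts.values())} > NoP = {self.nop}"
            )

    def observes(self, factor: str) -> bool:
        return factor in self.counts


def nac(record: StudyRecord) -> int:
    """Non-adherence count: total participants who discontinued, Σ factor counts."""
    return sum(record.counts.values())


def nars(record: StudyRecord, factor: str) -> float:
    """Per-study non-adherence proportion for a factor: count / NoP."""
    if not record.observes(factor):
        raise MissingFactorError(
            f"study {record.study_id!r} did not observe factor {factor!r}"
        )
    return record.counts[factor] / record.nop


def nar(record: StudyRecord, factor: str) -> float:
    """Per-study per-day non-adherence rate for a factor: NARS / DoM."""
    return nars(record, factor) / record.dom


def grand_nop(records: Sequence[StudyRecord]) -> int:
    """Grand participant total: Σ NoP over all pooled studies."""
    return sum(r.nop for r in records)


def wnar(records: Sequence[StudyRecord], factor: str) -> float:
    """NoP-weighted pooled per-day rate for a factor across studies.

    Σ_i NAR_i × NoP_i / GrandNoP over the studies observing the factor,
    with GrandNoP summing NoP over *all* records passed.
    """
    if not any(r.observes(factor) for r in records):
        raise MissingFactorError(f"no pooled study observes factor {factor!r}")
    total = grand_nop(records)
    return sum(
        nar(r, factor) * r.nop for r in records if r.observes(factor)
    ) / total


def mean_nac_ratio(records: Sequence[StudyRecord]) -> float:
    """Unweighted mean over studies of the NAC-to-NoP ratio."""
    if not records:
        raise ValueError("mean_nac_ratio requires at least one study")
    return sum(nac(r) / r.nop for r in records) / len(records)


@dataclass(frozen=True)
class RateTable:
    """Derived per-factor rates for a pooled set of studies.

    ``per_study`` maps factor → study_id → {"nars": ..., "nar": ...} for the
    studies observing the factor; ``wnar`` maps factor → pooled rate.
    """

    per_study: Mapping[str, Mapping[str, Mapping[str, float]]]
    wnar: Mapping[str, float]
    grand_nop: int

    def factors(self) -> tuple[str, ...]:
        return tuple(self.wnar)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame: one row per (factor, study) plus pooled rows."""
        rows = []
        for factor, per_study in self.per_study.items():
            for sid, vals in per_study.items():
                rows.append(
                    {"factor": factor, "study_id": sid,
                     "nars": vals["nars"], "nar": vals["nar"]}
                )
        frame = pd.DataFrame(rows)
        frame["wnar"] = frame["factor"].map(dict(self.wnar))
        return frame


def build_rate_table(records: Sequence[StudyRecord]) -> RateTable:
    """Derive NARS/NAR per study and pooled WNAR for every observed factor.

    Factors are ordered by first appearance across the study sequence.
    """
    if not records:
        raise ValueError("build_rate_table requires at least one study")
    factors: list[str] = []
    for r in records:
        for f in r.counts:
            if f not in factors:
                factors.append(f)
    per_study = {
        f: {
            r.study_id: {"nars": nars(r, f), "nar": nar(r, f)}
            for r in records
            if r.observes(f)
        }
        for f in factors
    }
    return RateTable(
        per_study=per_study,
        wnar={f: wnar(records, f) for f in factors},
        grand_nop=grand_nop(records),
    )


# --------------------------------------------------------------------------
# CSV interface (long format: study_id,NoP,DoM,factor,count)
# --------------------------------------------------------------------------


def read_studies_csv(path: str | Path) -> list[StudyRecord]:
    """Read study records from a long-format CSV.

    Columns: ``study_id,NoP,DoM,factor,count``.  One row per observed
    factor; an empty ``factor``/``count`` pair records a study with no
    observed factors.  Absent rows mean "not observed", not zero.
    """
    frame = pd.read_csv(path, dtype={"study_id": str, "factor": str})
    required = {"study_id", "NoP", "DoM", "factor", "count"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"study CSV is missing columns: {sorted(missing)}")
    records = []
    for sid, group in frame.groupby("study_id", sort=False):
        nop = group["NoP"].unique()
        dom = group["DoM"].unique()
        if len(nop) != 1 or len(dom) != 1:
            raise ValueError(f"study {sid!r} has inconsistent NoP/DoM across rows")
        # note: itertuples would shadow a column named "count"
        counts = {
            str(f): int(c)
            for f, c in zip(group["factor"], group["count"])
            if pd.notna(f) and pd.notna(c)
        }
        records.append(StudyRecord(str(sid), int(nop[0]), int(dom[0]), counts))
    return records


def write_studies_csv(records: Iterable[StudyRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        if not r.counts:
            rows.append({"study_id": r.study_id, "NoP": r.nop, "DoM": r.dom,
                         "factor": None, "count": None})
        for factor, count in r.counts.items():
            rows.append({"study_id": r.study_id, "NoP": r.nop, "DoM": r.dom,
                         "factor": factor, "count": count})
    pd.DataFrame(rows).to_csv(path, index=False)
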