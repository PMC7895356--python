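"""Seeded time-stepped Monte Carlo cohort simulator.

Simulates a cohort of patients taking a daily medication over a fixed
regimen, where each basic factor of a non-adherence tree is a competing
hazard.  Per patient and per time step, each active leaf fires with
probability ``1 − exp(−r(d)·Δt)`` (Δt in days), so the discrete-time scheme
reproduces the exponential first-event distribution exactly in the
constant-rate case and is robust to the step size.

Semantics:

* **Absorbing discontinuation** — a patient who misses a first pill is
  counted non-adherent from that day on; no further events are sampled for
  them.  The discontinuation is attributed to the basic factor that
  triggered it (ties within one step broken uniformly at random).
* **Repairable supply subsystems** — leaves with a ``repairable`` rate
  model alternate between up and down states (exponential time to failure,
  fixed repair duration) as a single shared, facility-level process per
  cohort run.  A cut set made of repairable leaves fires for a patient only
  when every member is down simultaneously at that patient's dosing time
  step, drawn uniformly at random within each day.
* **Age stratification** — each patient is assigned an age band at entry
  according to the model's cohort weights and keeps that band's hazard.
* **Decaying rates** — evaluated per whole elapsed day (day ``d`` covers
  ``[d, d+1)``).

The simulator triggers the top event through the tree's minimal cut sets,
so arbitrary AND/OR/PAND structure is supported; PAND order is ignored for
triggering (occurrence of all members suffices), matching the qualitative
reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cutsets import minimal_cut_sets
from .errors import NataError
from .model import (
    AgeStratifiedRate,
    ConstantRate,
    LinearDecayRate,
    NonAdherenceTree,
    RepairableRate,
    effective_rate,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate",
    "simulate_replicates",
    "summarize_uncertainty",
    "contributions",
    "apply_improvement",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort simulation settings.

    ``patients`` trajectories are sampled, one per simulated participant,
    stepping every ``timestep_hours`` over ``days`` days.  ``replicates``
    independent cohort runs (with per-replicate seeds spawned from ``seed``)
    are available for seed-sensitivity bands.
    """

    patients: int = 1000
    days: int = 10
    timestep_hours: float = 1.0
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.patients < 1:
            raise ValueError(f"patients must be >= 1, got {self.patients}")
        if self.days < 1:
            raise ValueError(f"days must be >= 1, got {self.days}")
        steps = 24.0 / self.timestep_hours
        if self.timestep_hours <= 0 or abs(steps - round(steps)) > 1e-9:
            raise ValueError(
                f"timestep_hours must divide 24, got {self.timestep_hours}"
            )
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")

    @property
    def steps_per_day(self) -> int:
        return round(24.0 / self.timestep_hours)


@dataclass(frozen=True)
class SimulationResult:
    """Outcome of one cohort run.

    ``nac_by_day[d]`` is the cumulative non-adherent count by the end of Day
    ``d+1``; ``p_na_by_day`` the corresponding fraction of the cohort.
    ``attributed`` maps factor id → number of discontinuations attributed to
    it; ``dimension_of`` maps each basic factor to its child-of-top grouping
    (the WHO dimension in the bundled case study).
    """

    patients: int
    days: int
    seed: int
    nac_by_day: tuple[int, ...]
    attributed: Mapping[str, int]
    dimension_of: Mapping[str, str]
    discontinuation_day: tuple[int, ...] = ()  # 1-based day per event, sorted

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributed", dict(self.attributed))
        object.__setattr__(self, "dimension_of", dict(self.dimension_of))

    @property
    def non_adherent(self) -> int:
        """Patients who missed at least one pill."""
        return self.nac_by_day[-1] if self.nac_by_day else 0

    @property
    def adherent(self) -> int:
        return self.patients - self.non_adherent

    @property
    def p_na_by_day(self) -> tuple[float, ...]:
        return tuple(c / self.patients for c in self.nac_by_day)

    @property
    def final_p_na(self) -> float:
        return self.non_adherent / self.patients


def summarize_uncertainty(result: SimulationResult) -> dict[str, float]:
    """Mean, per-patient SD and 5%/95% bounds of the final non-adherence fraction.

    The mean is the non-adherent fraction p; the SD is the per-patient
    Bernoulli standard deviation √(p(1−p)); the bounds are the normal
    approximation of the cohort mean, p ± 1.645·√(p(1−p)/n), clipped to
    [0, 1].
    """
    if result.patients == 0:
        raise ValueError("cannot summarize a run with zero patients")
    p = result.final_p_na
    sd = math.sqrt(p * (1.0 - p))
    half = 1.645 * sd / math.sqrt(result.patients)
    return {
        "mean": p,
        "sd": sd,
        "ci5": max(0.0, p - half),
        "ci95": min(1.0, p + half),
    }


def contributions(result: SimulationResult) -> dict[str, dict[str, float]]:
    """Percentage share of discontinuations attributed to each factor.

    Returns ``{"factors": {...}, "dimensions": {...}}``, both in percent and
    each summing to 100; the dimension rollup sums descendant factors into
    their child-of-top grouping.  Raises if no discontinuation occurred
    (shares are then undefined).
    """
    total = sum(result.attributed.values())
    if total == 0:
        raise NataError("no discontinuations occurred; contributions are undefined")
    factors = {f: 100.0 * c / total for f, c in result.attributed.items()}
    dims: dict[str, float] = {}
    for f, share in factors.items():
        dim = result.dimension_of.get(f, f)
        dims[dim] = dims.get(dim, 0.0) + share
    return {"factors": factors, "dimensions": dims}


def apply_improvement(
    tree: NonAdherenceTree, reductions: Mapping[str, float]
) -> NonAdherenceTree:
    """A new tree with the named leaves' rates scaled down by the given fractions.

    ``reductions`` maps basic factor id → fractional reduction in [0, 1]
    (0.2 = a 20% rate cut).  The original tree is untouched.
    """
    updates = {}
    for factor, reduction in reductions.items():
        if factor not in tree.nodes or not tree.node(factor).is_basic:
            raise KeyError(f"{factor!r} is not a basic factor of this tree")
        if not 0.0 <= reduction <= 1.0:
            raise ValueError(f"reduction for {factor!r} must be in [0, 1], got {reduction}")
        updates[factor] = tree.node(factor).rate_model.scaled(1.0 - reduction)
    return tree.with_rate_models(updates)


# --------------------------------------------------------------------------
# The simulator
# --------------------------------------------------------------------------


def _hazard_cut_sets(tree: NonAdherenceTree):
    """Split minimal cut sets into hazard-leaf and repairable-availability parts.

    Returns (cut_sets, repairable_ids) where each cut set is a pair
    (hazard_members, repairable_members).  Hazard members are cumulative
    binary occurrences; repairable members are instantaneous down states.
    """
    repairable = {
        n.id for n in tree.iter_basic() if isinstance(n.rate_model, RepairableRate)
    }
    report = minimal_cut_sets(tree)
    split = []
    for cs in report.cut_sets:
        haz = tuple(m for m in cs.members if m not in repairable)
        rep = tuple(m for m in cs.members if m in repairable)
        split.append((haz, rep))
    return split, sorted(repairable)


def simulate(tree: NonAdherenceTree, config: SimulationConfig) -> SimulationResult:
    """Run one seeded cohort simulation of a non-adherence tree.

    Fully reproducible: identical tree and config give a bit-identical
    result.  Four independent random streams are spawned from the seed —
    cohort setup (age bands, dosing times), leaf firing, supply-system
    availability and attribution tie-breaks — and the firing uniforms are
    drawn for every patient at every step whether or not they already
    discontinued.  Two runs under the same seed therefore share their
    randomness exactly, so scaling any leaf rate down can never increase
    the non-adherent count (common-random-number coupling).

    See the module docstring for the event semantics.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_setup, rng_fire, rng_system, rng_attr = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    n = config.patients
    spd = config.steps_per_day
    dt_days = config.timestep_hours / 24.0

    basic = list(tree.iter_basic())
    hazard_leaves = [b for b in basic if not isinstance(b.rate_model, RepairableRate)]
    leaf_index = {b.id: i for i, b in enumerate(hazard_leaves)}
    cut_sets, repairable_ids = _hazard_cut_sets(tree)
    rep_nodes = {rid: tree.node(rid) for rid in repairable_ids}

    # per-patient per-leaf hazard for day d; age bands drawn once per patient
    base_rates = np.zeros((n, len(hazard_leaves)))
    decaying: list[int] = []
    for j, leaf in enumerate(hazard_leaves):
        model = leaf.rate_model
        if isinstance(model, AgeStratifiedRate):
            weights = np.array([b.weight for b in model.bands])
            band_rates = np.array([b.rate for b in model.bands])
            bands = rng_setup.choice(len(band_rates), size=n, p=weights / weights.sum())
            base_rates[:, j] = band_rates[bands]
        elif isinstance(model, LinearDecayRate):
            decaying.append(j)
            base_rates[:, j] = model.initial_rate
        elif isinstance(model, ConstantRate):
            base_rates[:, j] = model.rate
        else:  # pragma: no cover - repairable filtered out above
            raise NataError(f"unexpected leaf model {model!r}")

    # shared facility-level availability trajectories
    rep_down_steps = {
        rid: max(1, round(rep_nodes[rid].rate_model.mean_repair_time
                          / config.timestep_hours))
        for rid in repairable_ids
    }
    rep_fail_p = {
        rid: -math.expm1(-rep_nodes[rid].rate_model.failure_rate * dt_days)
        for rid in repairable_ids
    }
    rep_down_left = {rid: 0 for rid in repairable_ids}

    undecided = np.ones(n, dtype=bool)  # not yet discontinued
    fired = np.zeros((n, len(hazard_leaves)), dtype=bool)
    nac_by_day = []
    attributed: dict[str, int] = {}
    dimension_of = {b.id: tree.dimension_of(b.id) for b in basic}
    disc_days: list[int] = []

    total_steps = config.days * spd
    dosing_step = rng_setup.integers(0, spd, size=(n, config.days))

    p_fire = np.empty((n, len(hazard_leaves)))
    for step in range(total_steps):
        day = step // spd
        step_of_day = step % spd

        # advance shared facility-level repairable components
        for rid in repairable_ids:
            if rep_down_left[rid] > 0:
                rep_down_left[rid] -= 1
            elif rng_system.random() < rep_fail_p[rid]:
                rep_down_left[rid] = rep_down_steps[rid]
        rep_down = {rid: rep_down_left[rid] > 0 for rid in repairable_ids}

        # uniforms are drawn for every patient regardless of status so two
        # runs under one seed share their randomness step-for-step
        p_fire[:, :] = base_rates
        for j in decaying:
            p_fire[:, j] = effective_rate(hazard_leaves[j].rate_model, day)
        np.expm1(-p_fire * dt_days, out=p_fire)
        np.negative(p_fire, out=p_fire)
        new_fire = rng_fire.random((n, len(hazard_leaves))) < p_fire
        new_fire &= ~fired
        fired |= new_fire

        # which still-undecided patients trigger the top event this step?
        at_dose = dosing_step[:, day] == step_of_day
        triggered = np.zeros(n, dtype=bool)
        candidate_mask = np.zeros((n, len(hazard_leaves)), dtype=bool)
        rep_candidates: list[str] = []
        for haz, rep in cut_sets:
            if rep and not all(rep_down[r] for r in rep):
                continue
            cols = [leaf_index[m] for m in haz]
            sat = fired[:, cols].all(axis=1) if cols else np.ones(n, dtype=bool)
            if rep:
                sat = sat & at_dose
            sat &= undecided
            if rep and sat.any():
                rep_candidates = list(rep)
            triggered |= sat
            if cols and sat.any():
                # newly fired members of a satisfied cut set can carry blame
                sel = np.ix_(np.flatnonzero(sat), cols)
                candidate_mask[sel] |= new_fire[sel]

        for patient in np.flatnonzero(triggered):
            cands = [
                hazard_leaves[j].id for j in np.flatnonzero(candidate_mask[patient, :])
            ]
            if not cands:
                # pure availability pathway: blame a down supply component
                cands = rep_candidates or repairable_ids
            choice = (
                cands[rng_attr.integers(0, len(cands))] if len(cands) > 1 else cands[0]
            )
            attributed[choice] = attributed.get(choice, 0) + 1
            disc_days.append(day + 1)
            undecided[patient] = False

        if step_of_day == spd - 1:
            nac_by_day.append(n - int(undecided.sum()))

    return SimulationResult(
        patients=n,
        days=config.days,
        seed=config.seed,
        nac_by_day=tuple(nac_by_day),
        attributed=attributed,
        dimension_of=dimension_of,
        discontinuation_day=tuple(sorted(disc_days)),
    )


def simulate_replicates(
    tree: NonAdherenceTree, config: SimulationConfig
) -> list[SimulationResult]:
    """Run ``config.replicates`` independent cohorts with spawned seeds."""
    seeds = np.random.SeedSequence(config.seed).generate_state(config.replicates)
    results = []
    for s in seeds:
        rep_config = SimulationConfig(
            patients=config.patients,
            days=config.days,
            timestep_hours=config.timestep_hours,
            seed=int(s % (2**31)),
            replicates=1,
        )
        results.append(simulate(tree, rep_config))
    return results
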