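"""Closed-form probabilistic analysis of non-adherence trees.

For a tree whose basic factors are independent with constant per-day
hazards, the top-event probability over a ``d``-day regimen has an exact
closed form:

* a factor with rate λ occurs by day ``d`` with probability ``1 − e^{−λd}``
  (the exponential CDF);
* an OR gate over independent events combines as ``1 − Π(1 − p_i)``;
* an AND gate as ``Π p_i``;
* a priority-AND gate — all events in a prescribed order — has the standard
  exponential closed form

  .. math::

     P = \\Big(\\prod_i \\lambda_i\\Big)
         \\sum_{k=0}^{n} \\frac{e^{a_k t}}{\\prod_{j \\ne k} (a_k - a_j)},

  with :math:`a_0 = 0` and :math:`a_m = -\\sum_{j \\le m} \\lambda_j` taken
  over the *reverse* occurrence order (the event required last contributes
  first to the partial sums).

Decaying and repairable leaves have no single-hazard closed form here; use
the Monte Carlo simulator for trees containing them.  Age-stratified leaves
are handled exactly as finite mixtures of exponentials.
"""

from __future__ import annotations

import math
from typing import Sequence

from .errors import CapabilityError, DegenerateRatesError
from .model import (
    AgeStratifiedRate,
    ConstantRate,
    GateKind,
    NonAdherenceTree,
)

__all__ = [
    "p_naf_exponential",
    "p_or",
    "p_and",
    "p_pand_exponential",
    "analytic_top_probability",
]


def p_naf_exponential(rate: float, d: float) -> float:
    """Probability an exponential factor with per-day rate ``rate`` occurs by day ``d``.

    ``1 − exp(−rate·d)``; ``math.expm1`` keeps precision at small rate·d.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if d < 0:
        raise ValueError(f"duration must be >= 0, got {d}")
    return -math.expm1(-rate * d)


def _check_probs(probs: Sequence[float]) -> None:
    if not probs:
        raise ValueError("need at least one probability")
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability out of [0, 1]: {p}")


def p_or(probs: Sequence[float]) -> float:
    """Probability at least one of n independent events occurs: 1 − Π(1 − p_i)."""
    _check_probs(probs)
    complement = 1.0
    for p in probs:
        complement *= 1.0 - p
    return 1.0 - complement


def p_and(probs: Sequence[float]) -> float:
    """Probability all of n independent events occur: Π p_i."""
    _check_probs(probs)
    out = 1.0
    for p in probs:
        out *= p
    return out


def p_pand_exponential(rates: Sequence[float], t: float) -> float:
    """Probability n independent exponential events all occur, in order, by time t.

    ``rates`` are per-day hazards listed in the *required occurrence order*
    (first element must occur first).  All rates must be positive with
    pairwise-distinct partial sums, else the closed form is singular and a
    :class:`DegenerateRatesError` asks for a tiny rate perturbation.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if not rates:
        raise ValueError("need at least one rate")
    if any(r <= 0 for r in rates):
        raise ValueError(f"all rates must be > 0 for the sequential closed form: {rates}")
    # partial sums run over the reverse occurrence order
    lam = list(reversed(list(rates)))
    n = len(lam)
    a = [0.0]
    for m in range(1, n + 1):
        a.append(a[-1] - lam[m - 1])
    for i in range(len(a)):
        for j in range(i + 1, len(a)):
            if math.isclose(a[i], a[j], rel_tol=0.0, abs_tol=1e-15):
                raise DegenerateRatesError(
                    f"coincident partial rate sums a_{i} == a_{j} == {a[i]}; "
                    "perturb one rate slightly to evaluate the sequential gate"
                )
    total = 0.0
    for k in range(n + 1):
        denom = 1.0
        for j in range(n + 1):
            if j != k:
                denom *= a[k] - a[j]
        total += math.exp(a[k] * t) / denom
    prod_lam = math.prod(lam)
    p = prod_lam * total
    if p < -1e-9 or p > 1 + 1e-9:
        raise ArithmeticError(
            f"sequential-gate closed form is numerically unstable here (p={p}); "
            "consider the Monte Carlo simulator"
        )
    return min(1.0, max(0.0, p))


def _leaf_probability(tree: NonAdherenceTree, node_id: str, d: float) -> float:
    model = tree.node(node_id).rate_model
    if isinstance(model, ConstantRate):
        return p_naf_exponential(model.rate, d)
    if isinstance(model, AgeStratifiedRate):
        # exact mixture of exponentials over the cohort bands
        return sum(b.weight * p_naf_exponential(b.rate, d) for b in model.bands)
    raise CapabilityError(
        f"basic node {node_id!r} has a {model.form!r} rate model; the analytic "
        "engine only handles constant (and age-stratified) hazards — use the "
        "Monte Carlo simulator for decaying or repairable leaves"
    )


def analytic_top_probability(tree: NonAdherenceTree, d: float) -> float:
    """Exact top-event probability of a constant-hazard tree over ``d`` days.

    Bottom-up evaluation: exponential CDF at the leaves, independence-based
    gate formulas above.  Exact because the tree shares no events between
    branches.  PAND gates are supported only directly over basic
    constant-rate children (the sequential closed form needs the leaf
    hazards themselves).
    """
    if d < 0:
        raise ValueError(f"duration must be >= 0, got {d}")

    def walk(node_id: str) -> float:
        node = tree.node(node_id)
        if node.is_basic:
            return _leaf_probability(tree, node_id, d)
        if node.gate is GateKind.PAND:
            child_rates = []
            for c in node.children:
                child = tree.node(c)
                if not child.is_basic or not isinstance(child.rate_model, ConstantRate):
                    raise CapabilityError(
                        f"PAND node {node_id!r} requires basic constant-rate "
                        f"children; {c!r} is not"
                    )
                child_rates.append(child.rate_model.rate)
            return p_pand_exponential(child_rates, d) if d > 0 else 0.0
        probs = [walk(c) for c in node.children]
        return p_or(probs) if node.gate is GateKind.OR else p_and(probs)

    return walk(tree.top_id)


def per_node_probabilities(tree: NonAdherenceTree, d: float) -> dict[str, float]:
    """Occurrence probability of every node of a constant-hazard tree by day ``d``."""
    out: dict[str, float] = {}

    def walk(node_id: str) -> float:
        node = tree.node(node_id)
        if node.is_basic:
            p = _leaf_probability(tree, node_id, d)
        elif node.gate is GateKind.PAND:
            p = analytic_top_probability(
                NonAdherenceTree(
                    nodes={node_id: _as_top(tree, node_id),
                           **{c: tree.node(c) for c in node.children}},
                    top_id=node_id,
                ),
                d,
            )
            for c in node.children:
                walk(c)
        else:
            probs = [walk(c) for c in node.children]
            p = p_or(probs) if node.gate is GateKind.OR else p_and(probs)
        out[node_id] = p
        return p

    walk(tree.top_id)
    return out


def _as_top(tree: NonAdherenceTree, node_id: str):
    from dataclasses import replace

    return replace(tree.node(node_id), kind="top")
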