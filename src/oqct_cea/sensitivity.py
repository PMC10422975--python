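"""Deterministic and probabilistic sensitivity analyses.

* One-way (tornado) analysis: each annotated parameter is set to the low and
  high end of its range with everything else at base case, and the
  oQCT-vs-DXA ICER is recomputed; entries are sorted by spread.
* Cost-threshold search: bisection on the oQCT unit cost for the cost at
  which the oQCT-vs-comparator ICER equals the willingness-to-pay threshold,
  or at which total discounted costs break even.
* Probabilistic sensitivity analysis (PSA): Monte Carlo sampling of all
  annotated parameters from their beta/gamma distributions
  (method-of-moments), re-running the strategy arms on each draw, with
  net-monetary-benefit acceptability and cost-effectiveness acceptability
  curves (CEAC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq


from .markov_cohort import run_cohort
from .parameters import (
    DistributionSpec,
    ModelParameters,
    ValidationError,
    get_parameter,
    set_parameter,
)
from .strategies import make_policy

__all__ = [
    "ThresholdError",
    "TornadoEntry",
    "PSAResult",
    "one_way_tornado",
    "cost_threshold",
    "sample_parameters",
    "run_psa",
    "default_wtp_grid",
]


class ThresholdError(Exception):
    """The threshold objective does not change sign over the bracket."""


@dataclass
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float
    spread: float


def _raw_icer(delta_cost: float, delta_qalys: float) -> float:
    """Signed cost-per-QALY ratio used for tornado bars (negative in the
    dominant quadrants; nan for a zero QALY difference)."""
    if delta_qalys == 0.0:
        return float("nan")
    return delta_cost / delta_qalys


def _icer_for(params: ModelParameters, strategy: str, comparator: str) -> float:
    a = run_cohort(params, make_policy(strategy, params))
    b = run_cohort(params, make_policy(comparator, params))
    return _raw_icer(a.cumulative_discounted_cost - b.cumulative_discounted_cost,
                     a.cumulative_discounted_qalys - b.cumulative_discounted_qalys)


_SUPPORT = {"beta": (0.0, 1.0)}


def one_way_tornado(
    params: ModelParameters,
    parameter_list: list[str] | None = None,
    strategy: str = "oqct",
    comparator: str = "dxa",
) -> list[TornadoEntry]:
    """One-at-a-time variation of each parameter over its range.

    Returns entries sorted descending by ICER spread; the base case is
    untouched (every variation runs on a fresh copy).
    """
    names = parameter_list if parameter_list is not None else list(params.psa)
    entries = []
    for name in names:
        spec = params.psa.get(name)
        if spec is None or spec.range_low is None or spec.range_high is None:
            raise ValidationError(f"parameter {name!r} has no range to vary")
        lo_support, hi_support = _SUPPORT.get(spec.family, (0.0, float("inf")))
        if spec.range_low < lo_support or spec.range_high > hi_support:
            raise ValidationError(
                f"range of {name!r} outside the valid support "
                f"[{lo_support}, {hi_support}]")
        icers = []
        for value in (spec.range_low, spec.range_high):
            p = params.copy()
            set_parameter(p, name, value)
            icers.append(_icer_for(p, strategy, comparator))
        spread = abs(icers[1] - icers[0])
        entries.append(TornadoEntry(name, spec.range_low, spec.range_high,
                                    icers[0], icers[1], spread))
    entries.sort(key=lambda e: (not np.isnan(e.spread), e.spread), reverse=True)
    return entries


def cost_threshold(
    params: ModelParameters,
    objective: str = "icer_equals_wtp",
    comparator: str = "dxa",
    bracket: tuple[float, float] = (0.0, 2000.0),
    tol: float = 0.5,
    wtp: float | None = None,
) -> float:
    """The oQCT unit cost at which an economic objective is met.

    ``icer_equals_wtp`` finds the cost at which the oQCT-vs-comparator ICER
    equals the willingness-to-pay threshold (via the equivalent
    net-monetary-benefit root, which is well behaved across dominance
    quadrants); ``equal_total_cost`` finds the breakeven cost at which both
    strategies' cumulative discounted costs coincide.  Bisection to ``tol``
    dollars; raises :class:`ThresholdError` (with endpoint diagnostics) if
    the objective does not change sign over ``bracket``.
    """
    if objective not in ("icer_equals_wtp", "equal_total_cost"):
        raise ValidationError(f"unknown objective {objective!r}")
    wtp = params.econ.wtp_primary if wtp is None else wtp
    comp = run_cohort(params, make_policy(comparator, params))

    def f(c: float) -> float:
        p = params.copy()
        p.oqct.unit_cost = c
        res = run_cohort(p, make_policy("oqct", p))
        dc = res.cumulative_discounted_cost - comp.cumulative_discounted_cost
        dq = res.cumulative_discounted_qalys - comp.cumulative_discounted_qalys
        if objective == "equal_total_cost":
            return dc
        return dc - wtp * dq

    fa, fb = f(bracket[0]), f(bracket[1])
    if fa == 0.0:
        return bracket[0]
    if fb == 0.0:
        return bracket[1]
    if np.sign(fa) == np.sign(fb):
        raise ThresholdError(
            f"objective {objective!r} does not change sign over "
            f"{bracket}: f({bracket[0]})={fa:.2f}, f({bracket[1]})={fb:.2f}")
    return float(brentq(f, bracket[0], bracket[1], xtol=tol))


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def _draw(spec: DistributionSpec, rng: np.random.Generator) -> float:
    if spec.family == "fixed" or spec.standard_error() == 0.0:
        return spec.mean
    a, b = spec.moment_match()
    if spec.family == "beta":
        return float(rng.beta(a, b))
    return float(rng.gamma(a, b))


def sample_parameters(
    params: ModelParameters,
    rng_seed: int | np.random.Generator,
) -> ModelParameters:
    """One Monte Carlo draw of every annotated parameter.

    Parameters are sampled independently from their annotated families via
    method-of-moments; ``fixed`` (and zero-SE) annotations stay at the mean.
    Reproducible given the seed.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    p = params.copy()
    for name in sorted(params.psa):
        set_parameter(p, name, _draw(params.psa[name], rng))
    return p


def default_wtp_grid() -> np.ndarray:
    """$0 to $250,000 in $2,500 steps (covers both printed thresholds)."""
    return np.arange(0.0, 250_000.0 + 1, 2_500.0)


@dataclass
class PSAResult:
    """Monte Carlo samples, acceptability curves and headline summary."""

    samples: pd.DataFrame     # one row per iteration
    ceac: pd.DataFrame        # one row per WTP grid point
    summary: dict
    seed: int

    @property
    def fraction_acceptable(self) -> float:
        return self.summary["fraction_acceptable_at_wtp_primary"]


def run_psa(
    params: ModelParameters,
    n_iterations: int,
    seed: int,
    wtp_grid: np.ndarray | None = None,
    strategies: tuple[str, ...] = ("no_screening", "dxa", "oqct"),
    progress: bool = False,
) -> PSAResult:
    """Probabilistic sensitivity analysis of oQCT vs DXA screening.

    Per iteration: draw one parameter set, re-run all strategy arms on the
    same draw (the cohort model is deterministic given parameters, so no
    common random numbers are needed), and record incremental outcomes.
    Acceptability uses net monetary benefit, NMB = WTP*dQALY - dCost > 0, at
    the primary threshold; the CEAC reports, per WTP grid point, the fraction
    of draws in which each strategy has the highest NMB (fractions sum to 1).
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    rng = np.random.default_rng(seed)
    wtp = params.econ.wtp_primary

    names = sorted(params.psa)
    cost = {s: np.empty(n_iterations) for s in strategies}
    qaly = {s: np.empty(n_iterations) for s in strategies}
    drawn = np.empty((n_iterations, len(names)))

    iters = range(n_iterations)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iters = tqdm(iters, desc="PSA")
        except ImportError:
            pass
    for i in iters:
        p = sample_parameters(params, rng)
        drawn[i] = [get_parameter(p, n) for n in names]
        for s in strategies:
            res = run_cohort(p, make_policy(s, p))
            cost[s][i] = res.cumulative_discounted_cost
            qaly[s][i] = res.cumulative_discounted_qalys

    dc = cost["oqct"] - cost["dxa"]
    dq = qaly["oqct"] - qaly["dxa"]
    acceptable = wtp * dq - dc > 0.0

    samples = pd.DataFrame(drawn, columns=names)
    samples.insert(0, "iteration", np.arange(n_iterations))
    samples["delta_cost"] = dc
    samples["delta_qalys"] = dq
    samples["acceptable_at_wtp"] = acceptable

    ceac_rows = []
    cost_mat = np.stack([cost[s] for s in strategies])
    qaly_mat = np.stack([qaly[s] for s in strategies])
    for w in wtp_grid:
        nmb_mat = w * qaly_mat - cost_mat
        best = np.argmax(nmb_mat, axis=0)
        row = {"wtp": w}
        for j, s in enumerate(strategies):
            row[f"p_{s}"] = float(np.mean(best == j))
        ceac_rows.append(row)
    ceac = pd.DataFrame(ceac_rows)

    summary = {
        "n_iterations": n_iterations,
        "wtp_primary": wtp,
        "fraction_acceptable_at_wtp_primary": float(np.mean(acceptable)),
        "mean_delta_cost": float(np.mean(dc)),
        "mean_delta_qalys": float(np.mean(dq)),
    }
    return PSAResult(samples=samples, ceac=ceac, summary=summary, seed=seed)
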