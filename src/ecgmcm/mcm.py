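"""Monte Carlo propagation of input PDFs through a measurement system.

The engine draws a column of samples per uncertain input, evaluates the
measurement equation row-wise, and summarises the output sample into a mean,
standard deviation, expanded uncertainty U95 = k * sd (k = 1.96 at 95%
coverage) and a symmetric-percentile coverage interval.

Per-source and per-block analysis varies only a chosen subset of inputs,
holding the rest at their nominal values.  Each input owns an independent
RNG substream spawned deterministically from the run seed, so a subset run
reuses *exactly* the sample columns the full run drew for those inputs —
budget rows and the total row are consistent by construction, and the whole
budget is reproducible from (system, m, seed) alone.

The minimum sample count for coverage probability p follows the
ceil(10^4 / (1 - p)) rule: 2x10^5 samples at p = 0.95.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .distributions import sample
from .system import MeasurementSystem

__all__ = [
    "required_samples",
    "expanded_uncertainty",
    "coverage_factor",
    "MCMResult",
    "BudgetRow",
    "UncertaintyBudget",
    "run_full",
    "run_sources",
    "budget",
    "round_mv",
    "round_pct",
]

logger = logging.getLogger(__name__)

#: Minimum sample count accepted by the propagation runs.
MIN_SAMPLES = 1000


def required_samples(p: float) -> int:
    """Minimum Monte Carlo sample count for coverage probability ``p``.

    ``ceil(10^4 / (1 - p))``: 10^5 at p=0.90, 2x10^5 at p=0.95, 10^6 at
    p=0.99.  Strictly increasing in p.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"coverage probability must be in (0, 1), got {p}")
    # round at 1e-6 first so float representation of p (0.95 -> 0.050000...044)
    # cannot push an exactly attainable count over the next integer
    return int(math.ceil(round(1e4 / (1.0 - p), 6)))


def coverage_factor(p: float = 0.95) -> float:
    """Normal coverage factor k(p); the conventional k = 1.96 at p = 0.95."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"coverage probability must be in (0, 1), got {p}")
    if abs(p - 0.95) < 1e-12:
        return 1.96
    return float(stats.norm.ppf(0.5 * (1.0 + p)))


def expanded_uncertainty(sd: float, p: float = 0.95) -> float:
    """Expanded uncertainty ``k(p) * sd`` (output units)."""
    if sd < 0:
        raise ValueError(f"standard deviation must be >= 0, got {sd}")
    return coverage_factor(p) * sd


# ---------------------------------------------------------------------------
# Rounding conventions for reports
# ---------------------------------------------------------------------------


def round_mv(x: float) -> int:
    """Report convention: voltages to the nearest integer mV, half away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def round_pct(x: float) -> float:
    """Report convention: percentages to two decimals, half away from zero."""
    return math.floor(abs(x) * 100.0 + 0.5) / 100.0 * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCMResult:
    """Summary of one Monte Carlo propagation run.

    ``U95`` is the coverage factor times the *unrounded* sample sd;
    ``U95_percent`` is relative to this run's own mean.  The
    symmetric-percentile ``coverage_interval`` at probability ``p`` is
    reported as supplementary information (for a normal output it matches
    mean +/- U95).
    """

    label: str
    samples: np.ndarray = field(repr=False)
    mean: float
    sd: float
    U95: float
    U95_percent: float
    coverage_interval: tuple[float, float]
    m: int
    seed: int
    p: float

    @classmethod
    def from_samples(
        cls, samples: np.ndarray, label: str, seed: int, p: float = 0.95
    ) -> "MCMResult":
        y = np.asarray(samples, dtype=float)
        mean = float(np.mean(y))
        sd = float(np.std(y, ddof=1)) if y.size > 1 else 0.0
        u95 = expanded_uncertainty(sd, p)
        pct = 100.0 * u95 / mean if mean != 0 else math.nan
        lo, hi = np.quantile(y, [0.5 * (1.0 - p), 0.5 * (1.0 + p)])
        return cls(
            label=label,
            samples=y,
            mean=mean,
            sd=sd,
            U95=u95,
            U95_percent=pct,
            coverage_interval=(float(lo), float(hi)),
            m=int(y.size),
            seed=int(seed),
            p=float(p),
        )

    def summary(self, unit: str = "mV") -> str:
        lo, hi = self.coverage_interval
        return (
            f"{self.label}: mean = {self.mean:.1f} {unit}, sd = {self.sd:.2f} {unit}, "
            f"U{self.p * 100:.0f} = {self.U95:.1f} {unit} ({self.U95_percent:.2f}% of mean), "
            f"{self.p * 100:.0f}% interval [{lo:.1f}, {hi:.1f}] {unit}, "
            f"m = {self.m}, seed = {self.seed}"
        )


@dataclass(frozen=True)
class BudgetRow:
    source: str
    group: str
    mean: float
    sd: float
    U95: float
    U95_percent: float
    coverage_interval: tuple[float, float]


@dataclass(frozen=True)
class UncertaintyBudget:
    """Per-source/per-block uncertainty table plus the all-sources total.

    Every row's mean coincides with the nominal output (within Monte Carlo
    error) because only the row's subset of inputs varies around unbiased
    PDFs; percentages are computed against each row's own mean.
    """

    rows: tuple[BudgetRow, ...]
    total: BudgetRow
    m: int
    seed: int
    p: float
    system_name: str = "measurement system"
    output_unit: str = "mV"

    def to_frame(self, rounded: bool = False):
        """pandas DataFrame with columns (source, group, mean_mV, sd_mV,
        U95_mV, U95_pct); ``rounded`` applies the report convention
        (integer mV, two-decimal percent)."""
        import pandas as pd

        rows = list(self.rows) + [self.total]
        rec = {
            "source": [r.source for r in rows],
            "group": [r.group for r in rows],
            "mean_mV": [round_mv(r.mean) if rounded else r.mean for r in rows],
            "sd_mV": [round_mv(r.sd) if rounded else r.sd for r in rows],
            "U95_mV": [round_mv(r.U95) if rounded else r.U95 for r in rows],
            "U95_pct": [round_pct(r.U95_percent) if rounded else r.U95_percent
                        for r in rows],
        }
        return pd.DataFrame(rec)

    def to_json_dict(self) -> dict:
        def row_dict(r: BudgetRow) -> dict:
            return {
                "source": r.source,
                "group": r.group,
                "mean": r.mean,
                "sd": r.sd,
                "U95": r.U95,
                "U95_percent": r.U95_percent,
                "coverage_interval": list(r.coverage_interval),
            }

        return {
            "system": self.system_name,
            "output_unit": self.output_unit,
            "m": self.m,
            "seed": self.seed,
            "p": self.p,
            "rows": [row_dict(r) for r in self.rows],
            "total": row_dict(self.total),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "UncertaintyBudget":
        def row(rd: dict) -> BudgetRow:
            return BudgetRow(
                source=rd["source"],
                group=rd["group"],
                mean=rd["mean"],
                sd=rd["sd"],
                U95=rd["U95"],
                U95_percent=rd["U95_percent"],
                coverage_interval=tuple(rd["coverage_interval"]),
            )

        return cls(
            rows=tuple(row(r) for r in d["rows"]),
            total=row(d["total"]),
            m=d["m"],
            seed=d["seed"],
            p=d["p"],
            system_name=d.get("system", "measurement system"),
            output_unit=d.get("output_unit", "mV"),
        )


# ---------------------------------------------------------------------------
# Propagation runs
# ---------------------------------------------------------------------------


def _column_seeds(system: MeasurementSystem, seed: int) -> dict[str, np.random.SeedSequence]:
    """One independent RNG substream per active quantity, in declaration order.

    Spawned from a single root SeedSequence so a quantity's column depends
    only on (seed, its position) — the reuse guarantee behind per-source runs.
    """
    children = np.random.SeedSequence(seed).spawn(len(system.active))
    return {q.name: child for q, child in zip(system.active, children)}


def _run(
    system: MeasurementSystem,
    vary: set[str],
    m: int | None,
    seed: int,
    p: float,
    label: str,
) -> MCMResult:
    if m is None:
        m = required_samples(p)
    if m < MIN_SAMPLES:
        raise ValueError(f"m must be >= {MIN_SAMPLES} for a meaningful summary, got {m}")
    streams = _column_seeds(system, seed)
    values: dict[str, np.ndarray | float] = {}
    for q in system.active:
        if q.name in vary:
            values[q.name] = sample(q.pdf, m, np.random.default_rng(streams[q.name]))
        else:
            values[q.name] = q.nominal
    y = np.broadcast_to(np.asarray(system.evaluate(values), dtype=float), (m,))
    return MCMResult.from_samples(y, label=label, seed=seed, p=p)


def run_full(
    system: MeasurementSystem,
    m: int | None = None,
    seed: int = 0,
    p: float = 0.95,
) -> MCMResult:
    """Propagate with every (non-frequency-only) input varying per its PDF.

    ``m`` defaults to :func:`required_samples` at ``p``.  Deterministic
    given ``seed``.
    """
    return _run(system, set(system.active_names), m, seed, p, label="All sources")


def run_sources(
    system: MeasurementSystem,
    subset: Iterable[str],
    m: int | None = None,
    seed: int = 0,
    p: float = 0.95,
    label: str | None = None,
) -> MCMResult:
    """Propagate with only ``subset`` varying; all other inputs at nominal.

    The varied columns are bit-identical to the ones :func:`run_full` draws
    at the same (m, seed), so per-source rows decompose the full run.
    """
    vary = list(dict.fromkeys(subset))
    if not vary:
        raise ValueError("subset must name at least one quantity")
    active = set(system.active_names)
    for name in vary:
        if name not in system:
            raise ValueError(f"unknown quantity {name!r}")
        if name not in active:
            raise ValueError(
                f"quantity {name!r} does not enter the static output equation "
                "(block='frequency_only')"
            )
    if label is None:
        label = "+".join(vary)
    return _run(system, set(vary), m, seed, p, label=label)


def budget(
    system: MeasurementSystem,
    grouping: Mapping[str, Sequence[str]] | None = None,
    m: int | None = None,
    seed: int = 0,
    p: float = 0.95,
) -> UncertaintyBudget:
    """Per-subset uncertainty budget plus the all-sources total row.

    ``grouping`` maps row labels to quantity-name subsets (one row per
    subset, evaluated by :func:`run_sources`); an empty mapping yields a
    budget with only the total row.  Overlapping subsets are legal but
    flagged in the log since their variances then no longer add.
    """
    if grouping is None:
        grouping = {}
    seen: dict[str, str] = {}
    for row_label, names in grouping.items():
        for n in names:
            if n in seen:
                logger.warning(
                    "budget subsets overlap: %r appears in rows %r and %r",
                    n, seen[n], row_label,
                )
            seen[n] = row_label

    if m is None:
        m = required_samples(p)

    def to_row(res: MCMResult, group: str) -> BudgetRow:
        return BudgetRow(
            source=res.label,
            group=group,
            mean=res.mean,
            sd=res.sd,
            U95=res.U95,
            U95_percent=res.U95_percent,
            coverage_interval=res.coverage_interval,
        )

    rows = []
    for row_label, names in grouping.items():
        res = run_sources(system, names, m=m, seed=seed, p=p, label=row_label)
        groups = {system[n].group for n in names}
        group = groups.pop() if len(groups) == 1 else "mixed"
        rows.append(to_row(res, group))
    total = to_row(run_full(system, m=m, seed=seed, p=p), "all")
    return UncertaintyBudget(
        rows=tuple(rows),
        total=total,
        m=m,
        seed=int(seed),
        p=float(p),
        system_name=system.name,
        output_unit=system.output_unit,
    )
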