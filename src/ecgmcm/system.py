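"""Measurement model of a two-stage ECG amplifier front-end.

The front-end is the classical three-op-amp instrumentation topology
followed by a non-inverting gain/filter stage.  With matched resistor pairs
the static transfer functions are

    v1   = (1 + 2*R1/R2) * (R5/R4) * (vin+ - vin-)        (preamplifier)
    vout = (1 + R11/R8) * v1                              (final stage)

and the RC corner frequencies of the two blocks are

    f1 = 1 / (2*pi*C1*R9)         f2 = 1 / (2*pi*C2*R11).

Baseline wander and broadband noise enter input-referred, i.e. added to the
differential input before the preamplifier gain.  The model is static: the
budgets it feeds describe amplitude uncertainty at DC/midband, so the
capacitors (and R9) shape only the corner frequencies, never ``vout``; they
are tagged ``block="frequency_only"`` and excluded from the output equation.

:class:`MeasurementSystem` generalises this: any named set of
:class:`UncertainQuantity` plus a vectorised measurement equation over the
names forms a system the Monte Carlo and analytic engines can propagate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .distributions import PDFSpec, analytic_moments, from_tolerance

__all__ = [
    "GROUPS",
    "BLOCKS",
    "UncertainQuantity",
    "MeasurementSystem",
    "ECGCircuit",
    "preamp_gain",
    "final_gain",
    "system_output",
    "cutoff_frequencies",
    "ecg_measurement_system",
    "ecg_cutoff_systems",
    "ECG_GROUPING",
    "ECG_RESISTORS",
    "ECG_PREAMP_RESISTORS",
    "ECG_FINAL_RESISTORS",
]

GROUPS = ("measurand", "measuring_system", "environment")
BLOCKS = ("input", "preamplifier", "final_stage", "frequency_only")


@dataclass(frozen=True)
class UncertainQuantity:
    """A named model input with nominal value, PDF and classification tags.

    ``group`` classifies the provenance of the uncertainty (measurand /
    measuring system / environment) for budget reporting; ``block`` places
    the quantity in the circuit.  The nominal must sit on the PDF's mean
    (to 1 part in 10^3) — budgets are reported relative to the nominal
    operating point, so a biased PDF would silently shift every row.
    """

    name: str
    group: str
    block: str
    nominal: float
    unit: str
    pdf: PDFSpec

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ValueError("quantity name must be a nonempty string")
        if self.group not in GROUPS:
            raise ValueError(
                f"{self.name}: unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.block not in BLOCKS:
            raise ValueError(
                f"{self.name}: unknown block {self.block!r}; expected one of {BLOCKS}"
            )
        mean, _ = analytic_moments(self.pdf)
        scale = max(abs(self.nominal), abs(mean))
        if scale > 0 and abs(self.nominal - mean) > 1e-3 * scale:
            raise ValueError(
                f"{self.name}: nominal {self.nominal} is not the PDF mean {mean} "
                "(tolerance 1 part in 10^3)"
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "group": self.group,
            "block": self.block,
            "nominal": self.nominal,
            "unit": self.unit,
            "pdf": self.pdf.to_dict(),
        }


class MeasurementSystem:
    """Named uncertain inputs plus a deterministic measurement equation.

    ``equation`` maps ``{name: value}`` (scalars or equal-length arrays for
    the non-``frequency_only`` quantities) to the output quantity, and must
    be vectorised numpy arithmetic.
    """

    def __init__(
        self,
        quantities: Iterable[UncertainQuantity],
        equation: Callable[[Mapping[str, np.ndarray]], np.ndarray],
        name: str = "measurement system",
        output_unit: str = "mV",
    ) -> None:
        self.quantities: list[UncertainQuantity] = list(quantities)
        names = [q.name for q in self.quantities]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate quantity names: {sorted(dupes)}")
        self._by_name = {q.name: q for q in self.quantities}
        self.equation = equation
        self.name = name
        self.output_unit = output_unit

    # -- lookups ---------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [q.name for q in self.quantities]

    @property
    def active(self) -> list[UncertainQuantity]:
        """Quantities that enter the static output equation."""
        return [q for q in self.quantities if q.block != "frequency_only"]

    @property
    def active_names(self) -> list[str]:
        return [q.name for q in self.active]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> UncertainQuantity:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown quantity {name!r} in {self.name}") from None

    # -- evaluation ------------------------------------------------------

    def evaluate(self, values: Mapping[str, np.ndarray | float]):
        missing = [n for n in self.active_names if n not in values]
        if missing:
            raise ValueError(f"missing values for quantities: {missing}")
        return self.equation(values)

    def nominal_values(self) -> dict[str, float]:
        return {q.name: q.nominal for q in self.active}

    def nominal_output(self) -> float:
        return float(self.evaluate(self.nominal_values()))

    # -- derived systems -------------------------------------------------

    def replace_pdfs(self, overrides: Mapping[str, PDFSpec]) -> "MeasurementSystem":
        """New system with the PDFs of the named quantities replaced."""
        unknown = [n for n in overrides if n not in self._by_name]
        if unknown:
            raise ValueError(f"unknown quantities in override: {unknown}")
        new = [
            replace(q, pdf=overrides[q.name]) if q.name in overrides else q
            for q in self.quantities
        ]
        return MeasurementSystem(new, self.equation, self.name, self.output_unit)

    def with_tolerance(
        self, names: Sequence[str], tol_fraction: float
    ) -> "MeasurementSystem":
        """Re-toleranced design variant.

        Rebuilds the bounded PDF of each named quantity as
        ``nominal +/- tol_fraction`` keeping its family (e.g. swapping 1%
        resistors for 0.1% parts).
        """
        overrides = {}
        for n in names:
            q = self[n]
            if q.pdf.family == "normal":
                raise ValueError(
                    f"{n}: tolerance variants apply to bounded PDFs only"
                )
            overrides[n] = from_tolerance(q.nominal, tol_fraction, q.pdf.family)
        return self.replace_pdfs(overrides)


# ---------------------------------------------------------------------------
# Transfer functions
# ---------------------------------------------------------------------------


def preamp_gain(R1, R2, R4, R5):
    """Differential gain (1 + 2*R1/R2) * (R5/R4) of the instrumentation stage.

    Any consistent resistance unit works; the gain is dimensionless.
    """
    if np.any(np.asarray(R2) <= 0) or np.any(np.asarray(R4) <= 0):
        raise ValueError("preamp_gain requires R2 > 0 and R4 > 0")
    return (1.0 + 2.0 * np.asarray(R1) / R2) * (np.asarray(R5) / R4)


def final_gain(R8, R11):
    """Non-inverting gain 1 + R11/R8 of the output stage."""
    if np.any(np.asarray(R8) <= 0):
        raise ValueError("final_gain requires R8 > 0")
    return 1.0 + np.asarray(R11) / R8


def cutoff_frequencies(R9, C1, R11, C2):
    """First-order corner frequencies (f1, f2) in Hz from SI inputs.

    ``R9``/``R11`` in ohm, ``C1``/``C2`` in farad: f1 = 1/(2*pi*C1*R9),
    f2 = 1/(2*pi*C2*R11).
    """
    for label, v in (("R9", R9), ("C1", C1), ("R11", R11), ("C2", C2)):
        if np.any(np.asarray(v) <= 0):
            raise ValueError(f"cutoff_frequencies requires {label} > 0")
    f1 = 1.0 / (2.0 * math.pi * np.asarray(C1) * R9)
    f2 = 1.0 / (2.0 * math.pi * np.asarray(C2) * R11)
    return f1, f2


@dataclass(frozen=True)
class ECGCircuit:
    """Nominal component values and input levels of the two-stage amplifier.

    Fields carry the component datasheet units: resistances in kOhm except
    ``R9`` (MOhm); ``C1`` in uF, ``C2`` in nF; all voltages in mV.
    """

    R1: float = 22.0
    R2: float = 10.0
    R4: float = 10.0
    R5: float = 47.0
    R8: float = 5.0
    R11: float = 150.0
    R9: float = 3.30
    C1: float = 1.00
    C2: float = 10.00
    vin_plus: float = 0.30
    vin_minus: float = 0.00
    baseline: float = 3.00
    noise: float = 0.00

    def __post_init__(self) -> None:
        for f in ("R1", "R2", "R4", "R5", "R8", "R11", "R9", "C1", "C2"):
            if not getattr(self, f) > 0:
                raise ValueError(f"{f} must be strictly positive")

    def preamp_gain(self) -> float:
        return float(preamp_gain(self.R1, self.R2, self.R4, self.R5))

    def final_gain(self) -> float:
        return float(final_gain(self.R8, self.R11))

    def output(self) -> float:
        """Static output voltage in mV (see :func:`system_output`)."""
        drive = self.vin_plus - self.vin_minus + self.baseline + self.noise
        return self.preamp_gain() * self.final_gain() * drive

    def cutoffs(self) -> tuple[float, float]:
        """(f1, f2) in Hz, converting the datasheet units to SI."""
        f1, f2 = cutoff_frequencies(
            self.R9 * 1e6, self.C1 * 1e-6, self.R11 * 1e3, self.C2 * 1e-9
        )
        return float(f1), float(f2)


def system_output(circuit: ECGCircuit) -> float:
    """Output voltage of the amplifier at the circuit's operating point.

    Baseline and noise are input-referred:
    ``vout = G1 * G2 * (vin+ - vin- + baseline + noise)``.
    """
    return circuit.output()


# ---------------------------------------------------------------------------
# Reference ECG system
# ---------------------------------------------------------------------------


def _ecg_equation(v: Mapping[str, np.ndarray | float]):
    g1 = preamp_gain(v["R1"], v["R2"], v["R4"], v["R5"])
    g2 = final_gain(v["R8"], v["R11"])
    drive = v["vin_plus"] - v["vin_minus"] + v["baseline"] + v["noise"]
    return g1 * g2 * drive


def _q(name, group, block, nominal, unit, pdf):
    return UncertainQuantity(name, group, block, nominal, unit, pdf)


#: Resistors of the amplifier's static signal path.
ECG_PREAMP_RESISTORS = ("R1", "R2", "R4", "R5")
ECG_FINAL_RESISTORS = ("R8", "R11")
ECG_RESISTORS = ECG_PREAMP_RESISTORS + ECG_FINAL_RESISTORS

#: Default budget rows: per-source for the voltages, per-block for the
#: amplifier stages.
ECG_GROUPING: dict[str, tuple[str, ...]] = {
    "vin": ("vin_plus", "vin_minus"),
    "Baseline": ("baseline",),
    "Preamplifier": ECG_PREAMP_RESISTORS,
    "Final stage": ECG_FINAL_RESISTORS,
    "Noise": ("noise",),
}


def ecg_measurement_system(resistor_tolerance: float = 0.01) -> MeasurementSystem:
    """The reference two-stage ECG amplifier with its assigned input PDFs.

    Voltages carry normal PDFs (vin+ 0.30 +/- 0.04 mV, vin- 0.00 +/- 0.04 mV,
    baseline 3.00 +/- 0.01 mV, noise 0.00 +/- 0.01 mV); signal-path resistors
    carry rectangular PDFs at ``resistor_tolerance`` (1% stock parts by
    default); R9/C1/C2 shape only the corner frequencies (R9 rectangular at
    1%, capacitors U-shaped at 1%) and are excluded from the static output.
    """
    tol = resistor_tolerance
    qs = [
        _q("vin_plus", "measurand", "input", 0.30, "mV", PDFSpec.normal(0.30, 0.04)),
        _q("vin_minus", "measurand", "input", 0.00, "mV", PDFSpec.normal(0.00, 0.04)),
        _q("baseline", "measurand", "input", 3.00, "mV", PDFSpec.normal(3.00, 0.01)),
        _q("R1", "measuring_system", "preamplifier", 22.0, "kOhm",
           from_tolerance(22.0, tol)),
        _q("R2", "measuring_system", "preamplifier", 10.0, "kOhm",
           from_tolerance(10.0, tol)),
        _q("R4", "measuring_system", "preamplifier", 10.0, "kOhm",
           from_tolerance(10.0, tol)),
        _q("R5", "measuring_system", "preamplifier", 47.0, "kOhm",
           from_tolerance(47.0, tol)),
        _q("R8", "measuring_system", "final_stage", 5.0, "kOhm",
           from_tolerance(5.0, tol)),
        _q("R11", "measuring_system", "final_stage", 150.0, "kOhm",
           from_tolerance(150.0, tol)),
        _q("R9", "measuring_system", "frequency_only", 3.30, "MOhm",
           from_tolerance(3.30, 0.01)),
        _q("C1", "measuring_system", "frequency_only", 1.00, "uF",
           from_tolerance(1.00, 0.01, "u_shaped")),
        _q("C2", "measuring_system", "frequency_only", 10.00, "nF",
           from_tolerance(10.00, 0.01, "u_shaped")),
        _q("noise", "environment", "input", 0.00, "mV", PDFSpec.normal(0.00, 0.01)),
    ]
    return MeasurementSystem(qs, _ecg_equation, name="ECG amplifier", output_unit="mV")


def ecg_cutoff_systems() -> tuple[MeasurementSystem, MeasurementSystem]:
    """Corner-frequency systems (f1, f2) for the two amplifier blocks.

    Separate from the voltage system because the capacitors never move the
    static output; propagating these yields corner-frequency budgets in Hz.
    """
    f1_qs = [
        _q("R9", "measuring_system", "preamplifier", 3.30, "MOhm",
           from_tolerance(3.30, 0.01)),
        _q("C1", "measuring_system", "preamplifier", 1.00, "uF",
           from_tolerance(1.00, 0.01, "u_shaped")),
    ]
    f2_qs = [
        _q("R11", "measuring_system", "final_stage", 150.0, "kOhm",
           from_tolerance(150.0, 0.01)),
        _q("C2", "measuring_system", "final_stage", 10.00, "nF",
           from_tolerance(10.00, 0.01, "u_shaped")),
    ]

    def f1_eq(v):
        return 1.0 / (2.0 * math.pi * (np.asarray(v["C1"]) * 1e-6) * (np.asarray(v["R9"]) * 1e6))

    def f2_eq(v):
        return 1.0 / (2.0 * math.pi * (np.asarray(v["C2"]) * 1e-9) * (np.asarray(v["R11"]) * 1e3))

    return (
        MeasurementSystem(f1_qs, f1_eq, name="f1 corner", output_unit="Hz"),
        MeasurementSystem(f2_qs, f2_eq, name="f2 corner", output_unit="Hz"),
    )
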