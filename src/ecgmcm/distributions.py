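"""Probability models for measurement-uncertainty sources.

Three families cover the usual metrological assignments:

* ``normal`` — quantities characterised statistically (signal levels, noise),
  parameterised by mean ``mu`` and standard deviation ``sigma``;
* ``rectangular`` — uniform on an interval ``(a, b)``, the standard choice for
  a manufacturer's tolerance where any value in the interval is equally
  credible (precision resistors);
* ``u_shaped`` — the arcsine law on ``(a, b)``, the standard choice for
  bounded quantities that dwell near their limits, e.g. reactive components
  subject to bounded periodic drift.

All three expose exact first and second moments (:func:`analytic_moments`)
so the analytic propagation engine can consume the same specs the Monte
Carlo sampler does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "FAMILIES",
    "PDFSpec",
    "sample",
    "analytic_moments",
    "from_tolerance",
]

FAMILIES = ("normal", "rectangular", "u_shaped")

#: Anything accepted by :func:`numpy.random.default_rng`.
RNGState = Union[int, np.random.Generator, np.random.SeedSequence, None]


@dataclass(frozen=True)
class PDFSpec:
    """A distribution family plus the parameters of one uncertainty source.

    Exactly the parameters of the declared family must be present:
    ``mu``/``sigma`` for ``normal``, ``a``/``b`` for the bounded families.
    All parameters are in the native units of the quantity they describe.
    """

    family: str
    mu: float | None = None
    sigma: float | None = None
    a: float | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown PDF family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.family == "normal":
            if self.mu is None or self.sigma is None:
                raise ValueError("normal PDF requires mu and sigma")
            if self.a is not None or self.b is not None:
                raise ValueError("normal PDF takes no interval bounds (a, b)")
            if not self.sigma > 0:
                raise ValueError(f"normal PDF requires sigma > 0, got {self.sigma}")
        else:
            if self.a is None or self.b is None:
                raise ValueError(f"{self.family} PDF requires bounds a and b")
            if self.mu is not None or self.sigma is not None:
                raise ValueError(f"{self.family} PDF takes no mu/sigma parameters")
            if not self.a < self.b:
                raise ValueError(
                    f"{self.family} PDF requires a < b, got a={self.a}, b={self.b}"
                )

    # -- constructors ----------------------------------------------------

    @classmethod
    def normal(cls, mu: float, sigma: float) -> "PDFSpec":
        return cls("normal", mu=float(mu), sigma=float(sigma))

    @classmethod
    def rectangular(cls, a: float, b: float) -> "PDFSpec":
        return cls("rectangular", a=float(a), b=float(b))

    @classmethod
    def u_shaped(cls, a: float, b: float) -> "PDFSpec":
        return cls("u_shaped", a=float(a), b=float(b))

    # -- convenience -----------------------------------------------------

    @property
    def mean(self) -> float:
        return analytic_moments(self)[0]

    @property
    def sd(self) -> float:
        return analytic_moments(self)[1]

    def to_dict(self) -> dict:
        d = {"family": self.family}
        for k in ("mu", "sigma", "a", "b"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PDFSpec":
        allowed = {"family", "mu", "sigma", "a", "b"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown PDF fields: {sorted(unknown)}")
        if "family" not in d:
            raise ValueError("PDF definition requires a 'family' field")
        return cls(**{k: d[k] for k in d})


def sample(spec: PDFSpec, m: int, rng_state: RNGState) -> np.ndarray:
    """Draw ``m`` independent values from ``spec``.

    The draw is a pure function of ``(spec, m, rng_state)``: passing the same
    integer seed (or an identically seeded generator) reproduces the vector
    bit for bit.  U-shaped draws use the arcsine inverse CDF
    ``x = a + (b - a) * sin^2(pi * u / 2)`` with ``u`` uniform on (0, 1).
    """
    if not isinstance(m, (int, np.integer)) or isinstance(m, bool):
        raise TypeError(f"sample count m must be an integer, got {type(m).__name__}")
    if m < 1:
        raise ValueError(f"sample count m must be >= 1, got {m}")
    rng = np.random.default_rng(rng_state)
    if spec.family == "normal":
        return rng.normal(spec.mu, spec.sigma, size=m)
    if spec.family == "rectangular":
        return rng.uniform(spec.a, spec.b, size=m)
    # u_shaped: arcsine law via inverse CDF
    u = rng.uniform(0.0, 1.0, size=m)
    return spec.a + (spec.b - spec.a) * np.sin(0.5 * np.pi * u) ** 2


def analytic_moments(spec: PDFSpec) -> tuple[float, float]:
    """Exact ``(mean, sd)`` of a spec.

    normal -> (mu, sigma); rectangular -> ((a+b)/2, (b-a)/sqrt(12));
    u_shaped (arcsine) -> ((a+b)/2, (b-a)/(2*sqrt(2))).
    """
    if spec.family == "normal":
        return float(spec.mu), float(spec.sigma)
    mid = 0.5 * (spec.a + spec.b)
    width = spec.b - spec.a
    if spec.family == "rectangular":
        return mid, width / math.sqrt(12.0)
    return mid, width / (2.0 * math.sqrt(2.0))


def from_tolerance(
    nominal: float, tol_fraction: float, family: str = "rectangular"
) -> PDFSpec:
    """Bounded PDF for a component specified as ``nominal +/- tol_fraction``.

    The interval is multiplicative on the nominal: ``a = nominal * (1 - tol)``,
    ``b = nominal * (1 + tol)``, e.g. a 22 kOhm 1% resistor maps to
    rectangular(21.78, 22.22).
    """
    if nominal == 0:
        raise ValueError("tolerance intervals need a nonzero nominal value")
    if not tol_fraction > 0:
        raise ValueError(f"tol_fraction must be > 0, got {tol_fraction}")
    if family == "normal":
        raise ValueError("tolerance intervals map to bounded PDFs, not normal")
    if family not in ("rectangular", "u_shaped"):
        raise ValueError(f"unsupported family for tolerance interval: {family!r}")
    lo = nominal * (1.0 - tol_fraction)
    hi = nominal * (1.0 + tol_fraction)
    if lo > hi:  # negative nominal flips the bounds
        lo, hi = hi, lo
    return PDFSpec(family, a=lo, b=hi)
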