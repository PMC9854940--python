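"""Declarative run configurations and report writers.

A configuration is a YAML document declaring the uncertain quantities, the
measurement equation (the built-in ``ecg`` amplifier model, or an arithmetic
expression over the quantity names), the run parameters (coverage ``p`` or
explicit sample count, seed), the budget grouping, and named design variants
(e.g. swapping tolerance classes of selected resistors).  The bundled
``ecg_amplifier.yaml`` reproduces the reference amplifier exactly.

Expression grammar: ``+ - * / **``, unary minus, parentheses, numeric
literals, quantity names, and the unary functions sin, cos, tan, exp, log,
log10, sqrt, abs.  Expressions are compiled through the Python ``ast`` with
a strict node whitelist — no attribute access, no calls beyond the table.

Reports are bit-stable: the same configuration and seed produce byte
identical CSV/JSON payloads (timestamps go to the log, not the files).
"""

from __future__ import annotations

import ast
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import yaml

from . import __version__
from .distributions import PDFSpec, from_tolerance
from .mcm import (
    UncertaintyBudget,
    budget,
    required_samples,
    round_mv,
    round_pct,
    run_full,
)
from .gum import compare_gum_mcm, gum_propagate
from .system import GROUPS, MeasurementSystem, UncertainQuantity

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "parse_config",
    "default_config_path",
    "compile_expression",
    "run_from_config",
    "render_budget",
    "parse_budget_json",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A configuration schema violation, with the offending field path."""


# ---------------------------------------------------------------------------
# Expression equations
# ---------------------------------------------------------------------------

_FUNCS: dict[str, Callable] = {
    "sin": np.sin, "cos": np.cos, "tan": np.tan,
    "exp": np.exp, "log": np.log, "log10": np.log10,
    "sqrt": np.sqrt, "abs": np.abs,
}

_BINOPS = {
    ast.Add: np.add, ast.Sub: np.subtract, ast.Mult: np.multiply,
    ast.Div: np.divide, ast.Pow: np.power,
}


def compile_expression(expr: str, names: list[str]) -> Callable[[Mapping], np.ndarray]:
    """Compile an arithmetic expression over quantity names to an equation."""
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as e:
        raise ConfigError(f"equation: cannot parse expression {expr!r}: {e}") from e
    known = set(names)

    def check(node: ast.AST) -> None:
        if isinstance(node, ast.Expression):
            check(node.body)
        elif isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
            check(node.left)
            check(node.right)
        elif isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
            check(node.operand)
        elif isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in _FUNCS:
                raise ConfigError(
                    f"equation: unknown function in {expr!r}; allowed: "
                    f"{sorted(_FUNCS)}"
                )
            if len(node.args) != 1 or node.keywords:
                raise ConfigError("equation: functions take exactly one argument")
            check(node.args[0])
        elif isinstance(node, ast.Name):
            if node.id not in known:
                raise ConfigError(
                    f"equation: unknown quantity {node.id!r} in expression"
                )
        elif isinstance(node, ast.Constant):
            if not isinstance(node.value, (int, float)):
                raise ConfigError("equation: only numeric literals allowed")
        else:
            raise ConfigError(
                f"equation: unsupported syntax ({type(node).__name__}) in {expr!r}"
            )

    check(tree)

    def evaluate(node: ast.AST, values: Mapping):
        if isinstance(node, ast.Expression):
            return evaluate(node.body, values)
        if isinstance(node, ast.BinOp):
            return _BINOPS[type(node.op)](
                evaluate(node.left, values), evaluate(node.right, values)
            )
        if isinstance(node, ast.UnaryOp):
            v = evaluate(node.operand, values)
            return -v if isinstance(node.op, ast.USub) else +v
        if isinstance(node, ast.Call):
            return _FUNCS[node.func.id](evaluate(node.args[0], values))
        if isinstance(node, ast.Name):
            return np.asarray(values[node.id])
        return node.value  # Constant

    def equation(values: Mapping):
        return evaluate(tree, values)

    equation.__doc__ = f"expression equation: {expr}"
    return equation


# ---------------------------------------------------------------------------
# Configuration parsing
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """A validated run configuration."""

    name: str
    system: MeasurementSystem
    grouping: dict[str, list[str]]
    variants: dict[str, dict[str, PDFSpec]]  # variant name -> pdf overrides
    seed: int = 0
    p: float = 0.95
    m: int | None = None  # explicit sample count; None -> required_samples(p)
    outdir: Path = Path("reports")
    formats: tuple[str, ...] = ("csv", "json")

    @property
    def samples(self) -> int:
        return self.m if self.m is not None else required_samples(self.p)

    def variant_system(self, name: str) -> MeasurementSystem:
        if name not in self.variants:
            raise ConfigError(
                f"variants.{name}: unknown variant; declared: {sorted(self.variants)}"
            )
        return self.system.replace_pdfs(self.variants[name])


def default_config_path() -> Path:
    """Path of the bundled reference amplifier configuration."""
    return Path(resources.files("ecgmcm.data") / "ecg_amplifier.yaml")


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return parse_config(raw, base_dir=path.parent)


def _require(d: dict, key: str, typ, path: str):
    if key not in d:
        raise ConfigError(f"{path}.{key}: required field missing")
    v = d[key]
    if not isinstance(v, typ):
        raise ConfigError(
            f"{path}.{key}: expected {getattr(typ, '__name__', typ)}, "
            f"got {type(v).__name__}"
        )
    return v


def parse_config(raw: dict, base_dir: Path | None = None) -> RunConfig:
    name = raw.get("name", "measurement system")
    qraw = _require(raw, "quantities", list, "config")
    quantities = []
    for i, qd in enumerate(qraw):
        path = f"config.quantities[{i}]"
        if not isinstance(qd, dict):
            raise ConfigError(f"{path}: expected a mapping")
        try:
            pdf = PDFSpec.from_dict(_require(qd, "pdf", dict, path))
            quantities.append(
                UncertainQuantity(
                    name=_require(qd, "name", str, path),
                    group=_require(qd, "group", str, path),
                    block=_require(qd, "block", str, path),
                    nominal=float(_require(qd, "nominal", (int, float), path)),
                    unit=str(qd.get("unit", "")),
                    pdf=pdf,
                )
            )
        except ValueError as e:
            raise ConfigError(f"{path}: {e}") from e
    names = [q.name for q in quantities]

    eq_name = raw.get("equation", "ecg")
    if eq_name == "ecg":
        from .system import _ecg_equation, ecg_measurement_system

        required = set(ecg_measurement_system().active_names)
        missing = sorted(required - set(names))
        if missing:
            raise ConfigError(
                f"config.quantities: the 'ecg' equation needs quantities {missing}"
            )
        equation = _ecg_equation
    else:
        if not isinstance(eq_name, str):
            raise ConfigError("config.equation: expected a string")
        equation = compile_expression(eq_name, names)

    try:
        system = MeasurementSystem(quantities, equation, name=name)
    except ValueError as e:
        raise ConfigError(f"config.quantities: {e}") from e

    grouping: dict[str, list[str]] = {}
    for label, members in (raw.get("grouping") or {}).items():
        if not isinstance(members, list):
            raise ConfigError(f"config.grouping.{label}: expected a list of names")
        for n in members:
            if n not in system:
                raise ConfigError(
                    f"config.grouping.{label}: unknown quantity {n!r}"
                )
        grouping[str(label)] = [str(n) for n in members]

    variants: dict[str, dict[str, PDFSpec]] = {}
    for vname, vraw in (raw.get("variants") or {}).items():
        path = f"config.variants.{vname}"
        if not isinstance(vraw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        overrides: dict[str, PDFSpec] = {}
        for qname, tol in (vraw.get("tolerance") or {}).items():
            if qname not in system:
                raise ConfigError(f"{path}.tolerance: unknown quantity {qname!r}")
            q = system[qname]
            if q.pdf.family == "normal":
                raise ConfigError(
                    f"{path}.tolerance.{qname}: tolerance overrides need a "
                    "bounded PDF"
                )
            try:
                overrides[qname] = from_tolerance(q.nominal, float(tol), q.pdf.family)
            except ValueError as e:
                raise ConfigError(f"{path}.tolerance.{qname}: {e}") from e
        for qname, pd_raw in (vraw.get("pdf") or {}).items():
            if qname not in system:
                raise ConfigError(f"{path}.pdf: unknown quantity {qname!r}")
            try:
                overrides[qname] = PDFSpec.from_dict(pd_raw)
            except ValueError as e:
                raise ConfigError(f"{path}.pdf.{qname}: {e}") from e
        unknown_keys = set(vraw) - {"tolerance", "pdf"}
        if unknown_keys:
            raise ConfigError(f"{path}: unknown fields {sorted(unknown_keys)}")
        if not overrides:
            raise ConfigError(f"{path}: variant declares no overrides")
        variants[str(vname)] = overrides

    p = float(raw.get("coverage", 0.95))
    if not 0.0 < p < 1.0:
        raise ConfigError(f"config.coverage: must be in (0, 1), got {p}")
    m = raw.get("samples")
    if m is not None:
        m = int(m)

    out = raw.get("output") or {}
    outdir = Path(out.get("dir", "reports"))
    if base_dir is not None and not outdir.is_absolute():
        outdir = base_dir / outdir
    formats = tuple(out.get("formats", ["csv", "json"]))
    for f in formats:
        if f not in ("csv", "json", "text"):
            raise ConfigError(f"config.output.formats: unsupported format {f!r}")

    return RunConfig(
        name=str(name),
        system=system,
        grouping=grouping,
        variants=variants,
        seed=int(raw.get("seed", 0)),
        p=p,
        m=m,
        outdir=outdir,
        formats=formats,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_GROUP_HEADINGS = {
    "measurand": "Measurand:",
    "measuring_system": "Measuring system:",
    "environment": "Environment:",
    "mixed": "Mixed:",
    "all": "",
}


def render_budget(bud: UncertaintyBudget, format: str = "text") -> str:
    """Render a budget as ``csv``, ``json`` or a grouped ``text`` table.

    The text table mirrors the budget's block structure (Measurand /
    Measuring system / Environment) and applies the report rounding
    convention: integer mV, two-decimal percent.
    """
    if format == "csv":
        return bud.to_frame(rounded=False).to_csv(index=False)
    if format == "json":
        return json.dumps(bud.to_json_dict(), indent=2, sort_keys=True)
    if format != "text":
        raise ValueError(f"unsupported format {format!r}; use csv, json or text")

    unit = bud.output_unit
    header = (
        f"{'Source':<22}{'Mean (' + unit + ')':>12}{'SD (' + unit + ')':>10}"
        f"{'U95 (' + unit + ')':>11}{'U95 (%)':>9}"
    )
    lines = [
        f"{bud.system_name} — uncertainty budget "
        f"(m = {bud.m}, p = {bud.p}, seed = {bud.seed})",
        header,
    ]

    def fmt(row, indent="  "):
        return (
            f"{indent + row.source:<22}{round_mv(row.mean):>12}"
            f"{round_mv(row.sd):>10}{round_mv(row.U95):>11}"
            f"{round_pct(row.U95_percent):>9.2f}"
        )

    order = list(GROUPS) + ["mixed"]
    groups_present = [g for g in order if any(r.group == g for r in bud.rows)]
    for g in groups_present:
        lines.append(_GROUP_HEADINGS[g])
        for r in bud.rows:
            if r.group == g:
                lines.append(fmt(r))
    lines.append(fmt(bud.total, indent=""))
    return "\n".join(lines) + "\n"


def parse_budget_json(payload: str) -> UncertaintyBudget:
    """Inverse of ``render_budget(..., 'json')``."""
    return UncertaintyBudget.from_json_dict(json.loads(payload))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _log_model_summary(label: str, system: MeasurementSystem) -> None:
    logger.info("[%s] system %r: nominal output %.4f %s",
                label, system.name, system.nominal_output(), system.output_unit)
    names = set(system.names)
    if {"R1", "R2", "R4", "R5", "R8", "R11"} <= names:
        from .system import ECGCircuit

        circ = ECGCircuit()
        logger.info(
            "[%s] gains: preamplifier %.4f, final stage %.4f; corner "
            "frequencies f1 = %.5f Hz, f2 = %.2f Hz",
            label, circ.preamp_gain(), circ.final_gain(), *circ.cutoffs(),
        )


def run_from_config(config: RunConfig, outdir: Path | None = None) -> dict[str, Path]:
    """Execute budget + analytic comparison for the base system and variants.

    Writes one budget document per declared format and one analytic
    (GUM-vs-MC) JSON per system into ``outdir``.  All documents are computed
    before anything is written, so a failure leaves no partial outputs.
    Returns ``{artifact label: path}``.
    """
    outdir = Path(outdir) if outdir is not None else config.outdir
    t_start = time.perf_counter()
    runs = [("base", config.system)] + [
        (vname, config.variant_system(vname)) for vname in config.variants
    ]

    documents: dict[str, tuple[Path, str]] = {}
    for label, system in runs:
        _log_model_summary(label, system)
        bud = budget(system, config.grouping, m=config.samples,
                     seed=config.seed, p=config.p)
        full = run_full(system, m=config.samples, seed=config.seed, p=config.p)
        gum = gum_propagate(system, p=config.p)
        comparison = compare_gum_mcm(gum, full)
        logger.info("[%s] %s", label, full.summary(system.output_unit))
        logger.info("[%s] %s", label, comparison.summary(system.output_unit))

        ext = {"csv": "csv", "json": "json", "text": "txt"}
        for f in config.formats:
            documents[f"{label}_budget_{f}"] = (
                outdir / f"{label}_budget.{ext[f]}",
                render_budget(bud, f),
            )
        gum_payload = {
            "system": system.name,
            "label": label,
            "seed": config.seed,
            "m": config.samples,
            "p": config.p,
            "software_version": __version__,
            "gum": gum.to_json_dict(),
            "comparison": comparison.to_json_dict(),
        }
        documents[f"{label}_gum"] = (
            outdir / f"{label}_gum.json",
            json.dumps(gum_payload, indent=2, sort_keys=True),
        )

    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for key, (path, text) in documents.items():
        path.write_text(text)
        written[key] = path
    logger.info(
        "wrote %d report files to %s in %.2f s (seed %d, m %d, p %s, version %s)",
        len(written), outdir, time.perf_counter() - t_start,
        config.seed, config.samples, config.p, __version__,
    )
    return written
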