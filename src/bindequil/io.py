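"""Writers (CSV, JSON, SVG) and parameter-range validation.

Output conventions: CSV is comma-separated with a header row, '.'
decimals and E-notation numbers — the same dialect the fit parser
accepts, so written curves round-trip as fit data.  JSON reports carry
both full-precision values and two-significant-figure display strings.
The SVG writer emits a standalone document with log-scaled axes, one
path per species and a set-point marker.
"""

from __future__ import annotations

import json
import logging
import math
from typing import Mapping

import numpy as np

from .curves import PROTEIN_FORMS, SweepResult, pie_fractions
from .equilibria import (
    EquilibriumState,
    ThermoContext,
    assoc_const,
    gibbs_energy,
)
from .errors import InvalidParameterError

__all__ = [
    "HARD_MIN",
    "HARD_MAX",
    "SLIDER_MIN",
    "SLIDER_MAX",
    "validate_value",
    "format_sig2",
    "sweep_to_csv",
    "state_report",
    "write_json",
    "sweep_to_svg",
]

logger = logging.getLogger("bindequil")

# Manual-entry hard validity range for all concentrations and constants.
HARD_MIN = 1e-18
HARD_MAX = 1e3
# Values outside the slider span work but may be numerically delicate.
SLIDER_MIN = 1e-9
SLIDER_MAX = 1e-1


def validate_value(name: str, value: float, allow_zero: bool = False) -> float:
    """Enforce the hard validity range; warn outside the slider range.

    Three-state policy: outside [1e-18, 1e3] is a hard error; inside the
    slider span [1e-9, 1e-1] is silently accepted; anything between is
    accepted with a logged warning.
    """
    if allow_zero and value == 0.0:
        return value
    if not (HARD_MIN <= value <= HARD_MAX):
        raise InvalidParameterError(
            f"{name} = {value!r} outside the allowed range "
            f"[{HARD_MIN:g}, {HARD_MAX:g}]"
        )
    if not (SLIDER_MIN <= value <= SLIDER_MAX):
        logger.warning(
            "%s = %g lies outside the slider range [%g, %g]; "
            "results may show numerical or graphical glitches",
            name, value, SLIDER_MIN, SLIDER_MAX,
        )
    return value


def format_sig2(x: float) -> str:
    """Two-significant-figure display string (e.g. '1.6e-08', '0.20')."""
    if x == 0:
        return "0.0"
    return f"{x:.1e}" if (abs(x) < 1e-3 or abs(x) >= 1e4) else f"{float(f'{x:.2g}'):g}"


def sweep_to_csv(result: SweepResult) -> str:
    """Render a sweep as CSV text: x column then one column per species."""
    names = list(result.series)
    lines = [",".join(["x"] + names)]
    for i, x in enumerate(result.x):
        row = [f"{x:.12e}"] + [f"{result.series[n][i]:.12e}" for n in names]
        lines.append(",".join(row))
    return "\n".join(lines) + "\n"


def state_report(
    state: EquilibriumState, ctx: ThermoContext | None = None
) -> dict:
    """JSON-ready report of one equilibrium: species concentrations,
    per-protein fractions, and K_A / ΔG for each dissociation constant."""
    ctx = ctx or ThermoContext()
    spec = state.spec
    report: dict = {
        "system": type(spec).__name__.removesuffix("Spec"),
        "parameters": {
            f: getattr(spec, f) for f in spec.__dataclass_fields__
        },
        "species": {
            name: {"value": conc, "display": format_sig2(conc)}
            for name, conc in state.species.items()
        },
        "fractions": {},
        "thermodynamics": {},
    }
    for protein in PROTEIN_FORMS[type(spec)]:
        if spec.totals[protein] > 0:
            report["fractions"][protein] = {
                name: {"value": frac, "display": format_sig2(frac)}
                for name, frac in pie_fractions(state, protein)
            }
    for name in ("K_D", "K_Dp"):
        if hasattr(spec, name):
            kd = getattr(spec, name)
            report["thermodynamics"][name] = {
                "K_D": kd,
                "K_A": assoc_const(kd),
                "delta_G_J_per_mol": gibbs_energy(kd, ctx),
                "display": {
                    "K_D": format_sig2(kd),
                    "K_A": format_sig2(assoc_const(kd)),
                    "delta_G_kJ_per_mol": format_sig2(gibbs_energy(kd, ctx) / 1e3),
                },
            }
    report["temperature_K"] = ctx.T
    return report


def write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# SVG
# ---------------------------------------------------------------------------

_PALETTE = ("#1f77b4", "#d62728", "#2ca02c", "#9467bd", "#ff7f0e")
_W, _H = 640, 420
_ML, _MR, _MT, _MB = 70, 20, 20, 50  # margins around the plot box


def _xpix(x: float, x_min: float, x_max: float) -> float:
    span = math.log10(x_max) - math.log10(x_min)
    f = (math.log10(x) - math.log10(x_min)) / span
    return _ML + f * (_W - _ML - _MR)


def sweep_to_svg(result: SweepResult) -> str:
    """Render a sweep as a standalone SVG document.

    The x axis is always logarithmic; the y axis is linear for relative
    and absolute-linear modes and logarithmic (floored at 1e-18) for the
    absolute-log mode.  One path per species plus a set-point marker.
    """
    spec = result.spec
    log_y = spec.y_mode == "absolute-log"
    floor = 1e-18

    def ytrans(v: float) -> float:
        return math.log10(max(v, floor)) if log_y else v

    ys = np.concatenate([np.asarray(s, dtype=float) for s in result.series.values()])
    ty = np.array([ytrans(v) for v in ys])
    y_lo, y_hi = float(ty.min()), float(ty.max())
    if y_hi == y_lo:
        y_hi = y_lo + 1.0
    if not log_y and spec.y_mode == "relative-linear":
        y_lo, y_hi = 0.0, 1.0

    def ypix(v: float) -> float:
        f = (ytrans(v) - y_lo) / (y_hi - y_lo)
        f = min(max(f, 0.0), 1.0)
        return _H - _MB - f * (_H - _MT - _MB)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_W}" height="{_H}" '
        f'viewBox="0 0 {_W} {_H}">',
        f'<rect x="{_ML}" y="{_MT}" width="{_W - _ML - _MR}" '
        f'height="{_H - _MT - _MB}" fill="white" stroke="black"/>',
    ]
    # decade ticks on the log x axis
    e_lo = math.ceil(math.log10(spec.x_min))
    e_hi = math.floor(math.log10(spec.x_max))
    for e in range(e_lo, e_hi + 1):
        px = _xpix(10.0**e, spec.x_min, spec.x_max)
        parts.append(
            f'<line x1="{px:.2f}" y1="{_H - _MB}" x2="{px:.2f}" '
            f'y2="{_H - _MB + 6}" stroke="black"/>'
        )
        parts.append(
            f'<text x="{px:.2f}" y="{_H - _MB + 20}" font-size="11" '
            f'text-anchor="middle">1e{e}</text>'
        )
    # y-axis end labels
    for v, anchor_y in ((y_lo, _H - _MB), (y_hi, _MT + 8)):
        label = f"{v:.3g}"
        parts.append(
            f'<text x="{_ML - 6}" y="{anchor_y}" font-size="11" '
            f'text-anchor="end">{label}</text>'
        )
    for (name, series), color in zip(result.series.items(), _PALETTE):
        pts = " ".join(
            f"{'M' if i == 0 else 'L'}{_xpix(x, spec.x_min, spec.x_max):.2f},"
            f"{ypix(v):.2f}"
            for i, (x, v) in enumerate(zip(result.x, series))
        )
        parts.append(
            f'<path d="{pts}" fill="none" stroke="{color}" stroke-width="1.5">'
            f"<title>{name}</title></path>"
        )
    # set-point marker
    if spec.x_min <= result.set_x <= spec.x_max:
        px = _xpix(result.set_x, spec.x_min, spec.x_max)
        parts.append(
            f'<line x1="{px:.2f}" y1="{_MT}" x2="{px:.2f}" y2="{_H - _MB}" '
            f'stroke="gray" stroke-dasharray="4,3"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
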