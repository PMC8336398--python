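"""One-way sensitivity analysis (tornado) on the projection.

Each named parameter is set to (1 - f) and (1 + f) times its base value
(default f = 0.25) with everything else held fixed, the full projection is
rerun, and parameters are ranked by the induced range in the output —
by default the lifetime sum of government costs in the
attacks-stop-after-10-years, no-return-to-work scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .fiscal import FiscalParameters
from .projection import (
    FiscalSummary,
    ModelInputs,
    ScenarioSpec,
    project_scenario,
    summarize,
)

__all__ = ["TornadoRow", "OWSA_PARAMETERS", "owsa", "tornado_report"]


@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    low_output: float
    high_output: float

    @property
    def range(self) -> float:
        return abs(self.high_output - self.low_output)


def _scale_attacks(spec, inputs, params, f):
    return replace(spec, attacks_per_year=spec.attacks_per_year * f), inputs, params


def _scale_duration(spec, inputs, params, f):
    if spec.attack_duration_years is None:
        raise ValueError(
            "attack duration cannot be varied in a lifelong-attack scenario"
        )
    return (
        replace(spec, attack_duration_years=spec.attack_duration_years * f),
        inputs,
        params,
    )


def _scale_chronic(spec, inputs, params, f):
    # all management categories move jointly
    return spec, replace(
        inputs, management_costs=inputs.management_costs.scaled(f)
    ), params


def _scale_attack_cost(spec, inputs, params, f):
    from .health import AttackCostLine, AttackCostTable, attack_cost_total
    from .health import default_attack_cost_table

    table = inputs.attack_costs or default_attack_cost_table()
    total = attack_cost_total(table) * f
    scaled = AttackCostTable(
        (AttackCostLine("All resources (scaled)", 1.0, 1.0, total, total),)
    )
    return spec, replace(inputs, attack_costs=scaled), params


def _scale_disability_payment(spec, inputs, params, f):
    return spec, inputs, params.with_(
        disability_annual=params.disability_annual * f
    )


#: The varied parameters: annual attack count, attack duration, chronic
#: (management) health costs, cost per hospitalized attack, and the annual
#: disability payment.
OWSA_PARAMETERS: dict[str, Callable] = {
    "annual_attacks": _scale_attacks,
    "attack_duration_years": _scale_duration,
    "chronic_health_cost": _scale_chronic,
    "cost_per_attack": _scale_attack_cost,
    "annual_disability_payment": _scale_disability_payment,
}


def owsa(
    spec: ScenarioSpec,
    inputs: ModelInputs,
    params: FiscalParameters,
    parameters: Sequence[str] | None = None,
    fraction: float = 0.25,
    output: str = "sum_government_costs",
) -> list[TornadoRow]:
    """Tornado rows, sorted by descending range (ties alphabetical)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    names = list(parameters) if parameters is not None else list(OWSA_PARAMETERS)
    unknown = [n for n in names if n not in OWSA_PARAMETERS]
    if unknown:
        raise ValueError(
            f"unknown OWSA parameter(s) {unknown}; "
            f"known: {sorted(OWSA_PARAMETERS)}"
        )
    if output not in FiscalSummary.__dataclass_fields__:
        raise ValueError(f"unknown output field {output!r}")

    def evaluate(s, i, p) -> float:
        return getattr(summarize(project_scenario(s, i, p)), output)

    rows = []
    for name in names:
        apply = OWSA_PARAMETERS[name]
        low = evaluate(*apply(spec, inputs, params, 1.0 - fraction))
        high = evaluate(*apply(spec, inputs, params, 1.0 + fraction))
        rows.append(TornadoRow(name, low, high))
    rows.sort(key=lambda r: (-r.range, r.parameter))
    return rows


def tornado_report(
    rows: Sequence[TornadoRow],
    base_output: float | None = None,
    csv_path=None,
    plot_path=None,
) -> pd.DataFrame:
    """Ranked tornado table; optionally written as CSV and horizontal bars."""
    if not rows:
        raise ValueError("no tornado rows to report")
    ordered = sorted(rows, key=lambda r: (-r.range, r.parameter))
    df = pd.DataFrame(
        {
            "parameter": [r.parameter for r in ordered],
            "low_output": [r.low_output for r in ordered],
            "high_output": [r.high_output for r in ordered],
            "range": [r.range for r in ordered],
        }
    )
    if csv_path is not None:
        df.to_csv(Path(csv_path), index=False, float_format="%.2f")
    if plot_path is not None:
        _plot_tornado(df, base_output, plot_path)
    return df


def _plot_tornado(df: pd.DataFrame, base_output, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = df.iloc[::-1]  # widest bar on top
    fig, ax = plt.subplots(figsize=(8, 0.6 * len(d) + 1.5))
    left = d[["low_output", "high_output"]].min(axis=1)
    width = (d["high_output"] - d["low_output"]).abs()
    ax.barh(d["parameter"], width, left=left, color="#4878a8")
    if base_output is not None:
        ax.axvline(base_output, color="k", lw=1)
    ax.set_xlabel("Sum of government costs (EUR, discounted)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
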