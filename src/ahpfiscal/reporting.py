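"""Result tables and the full reproducible pipeline run.

The report layer only rounds and lays out numbers already present in
:class:`FiscalSummary` / :class:`FiscalDelta` objects — it never does its
own arithmetic. Money is rounded half-up to whole euros (or cents, per the
output config); work years keep two decimals.
"""

from __future__ import annotations

import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .projection import (
    FiscalDelta,
    FiscalSummary,
    annual_chart_data,
    delta,
    net_fiscal_impact,
    project_scenario,
    summarize,
)
from .sensitivity import owsa, tornado_report

__all__ = ["round_money", "summary_table", "markdown_table", "run_all"]

log = logging.getLogger("ahpfiscal")

ROW_LABELS = {
    "disability_transfers": "Disability transfers",
    "pension_costs": "Pension costs",
    "health_costs": "Health costs",
    "sum_government_costs": "Sum of government costs",
    "lifetime_earnings": "Lifetime earnings",
    "gross_tax": "Gross tax",
    "work_years": "Work years",
}


def round_money(x: float, rounding: str = "eur") -> float:
    """Half-up rounding at euro or cent resolution (reports only)."""
    if rounding == "none":
        return float(x)
    quantum = Decimal("1") if rounding == "eur" else Decimal("0.01")
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def summary_table(
    summaries: dict[str, FiscalSummary],
    comparator: str,
    rounding: str = "eur",
) -> pd.DataFrame:
    """Seven-row results table: one column per scenario plus change columns."""
    if comparator not in summaries:
        raise KeyError(f"comparator {comparator!r} not among summaries")
    gp = summaries[comparator]
    cols: dict[str, dict] = {}
    for name, s in summaries.items():
        cols[name] = s.as_dict()
    for name, s in summaries.items():
        if name == comparator:
            continue
        d = delta(s, gp)
        cols[f"change ({name} - {comparator})"] = {
            k: v for k, v in d.as_dict().items() if k != "societal_cost"
        }
    df = pd.DataFrame(cols)
    df = df.loc[list(ROW_LABELS)]
    df.index = [ROW_LABELS[k] for k in df.index]

    def _round(row):
        if row.name == "Work years":
            return row.round(2)
        return row.map(lambda v: round_money(v, rounding))

    return df.apply(_round, axis=1)


def markdown_table(df: pd.DataFrame) -> str:
    """Render a small DataFrame as a GitHub-style markdown table."""
    headers = [""] + [str(c) for c in df.columns]
    lines = ["| " + " | ".join(headers) + " |",
             "| " + " | ".join("---" for _ in headers) + " |"]
    for idx, row in df.iterrows():
        cells = [str(idx)]
        for v in row:
            cells.append(f"{v:,.2f}" if isinstance(v, float) else str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def run_all(config: RunConfig, out_dir=None, seed: int | None = None) -> dict:
    """Project every configured scenario and write the result bundle.

    Writes the scenario/change table (CSV and/or markdown), per-age chart
    data against the comparator, the tornado CSV, and a JSON run log with
    the package version, config hash, seed and every resolved parameter.
    Deterministic given the config (the seed only enters through the
    synthetic generator).
    """
    out = Path(out_dir if out_dir is not None else config.output.directory)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        gen = config.generator.model_copy(update={"seed": seed})
        config = config.model_copy(update={"generator": gen})

    params = config.fiscal_params()
    inputs = config.model_inputs()
    specs = config.scenario_specs()
    comparator = config.comparator_name()

    log.info("projecting %d scenarios (comparator: %s)", len(specs), comparator)
    ledgers = {n: project_scenario(s, inputs, params) for n, s in specs.items()}
    summaries = {n: summarize(l) for n, l in ledgers.items()}

    table = summary_table(summaries, comparator, config.output.rounding)
    paths = {}
    if "csv" in config.output.formats:
        paths["table_csv"] = out / "fiscal_summary.csv"
        table.to_csv(paths["table_csv"])
    if "md" in config.output.formats:
        paths["table_md"] = out / "fiscal_summary.md"
        paths["table_md"].write_text(markdown_table(table))

    for name, ledger in ledgers.items():
        if name == comparator:
            continue
        chart = annual_chart_data(ledger, ledgers[comparator])
        p = out / f"chart_data_{name}.csv"
        chart.to_csv(p, float_format="%.6f")
        paths[f"chart_{name}"] = p

    impacts = {
        n: net_fiscal_impact(delta(summaries[n], summaries[comparator]))
        for n in summaries if n != comparator
    }

    tornado_path = None
    owsa_base = "a10_w" if "a10_w" in specs else None
    if owsa_base:
        rows = owsa(specs[owsa_base], inputs, params)
        tornado_path = out / "tornado.csv"
        tornado_report(
            rows,
            base_output=summaries[owsa_base].sum_government_costs,
            csv_path=tornado_path,
        )
        paths["tornado"] = tornado_path

    run_log = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.generator.seed,
        "parameters": config.model_dump(mode="json"),
        "net_fiscal_impact": {k: round_money(v, config.output.rounding)
                              for k, v in impacts.items()},
    }
    paths["run_log"] = out / "run_log.json"
    paths["run_log"].write_text(json.dumps(run_log, indent=2, sort_keys=True))
    log.info("results written to %s", out)
    return {
        "table": table,
        "summaries": summaries,
        "net_fiscal_impact": impacts,
        "paths": paths,
    }
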