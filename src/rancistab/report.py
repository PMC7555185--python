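"""Report rendering: machine-readable JSON plus human-readable tables.

Layouts mirror the standard reporting of an accelerated-oxidation study:
a per-cell OSI/CV grid, one kinetic-fit row per airflow (slope,
intercept, R^2, temperature coefficient, extrapolated 22 C shelf life,
Q10), and a correlation table with two-tier significance marks.
Printed precisions follow field convention: OSI to 1 decimal, slopes to
3, correlations to 3.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .kinetics import KineticFit

__all__ = ["render_report"]


def _fits_frame(fits: Sequence[KineticFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "airflow_L_h": f.airflow,
                "A": round(f.a, 3),
                "se_A": round(f.se_a, 3),
                "B": round(f.b, 3),
                "se_B": round(f.se_b, 3),
                "R2": round(f.r_squared, 3),
                "T_coeff_1e-2": round(f.t_coeff, 1),
                "OSI_22_h": round(f.osi_22, 0),
                "Q10": round(f.q10, 1),
            }
        )
    return pd.DataFrame(rows)


def render_report(
    fits: Sequence[KineticFit],
    summaries: pd.DataFrame | None,
    correlations: pd.DataFrame | None,
    out_dir: str | Path,
) -> dict:
    """Write ``report.json`` plus TSV and markdown tables to ``out_dir``.

    Parameters
    ----------
    fits : sequence of KineticFit
        One per airflow (may be empty).
    summaries : DataFrame or None
        Per-cell summary from :func:`rancistab.kinetics.summarize_osi`.
    correlations : DataFrame or None
        Tidy correlation table from
        :func:`rancistab.panel_stats.correlation_matrix`.
    out_dir : path
        Created if absent.

    Returns
    -------
    dict
        The JSON document that was written (full precision; the TSV/
        markdown tables are rounded to reporting precision).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    doc: dict = {
        "fits": [asdict(f) for f in fits],
        "summary": summaries.to_dict(orient="records") if summaries is not None else [],
        "correlations": (
            correlations.to_dict(orient="records") if correlations is not None else []
        ),
    }
    (out / "report.json").write_text(json.dumps(doc, indent=2, allow_nan=True) + "\n")

    md = ["# Accelerated oxidation report", ""]

    if summaries is not None and not summaries.empty:
        grid = summaries.copy()
        grid["mean_osi_h"] = grid["mean_osi_h"].round(1)
        grid["cv_pct"] = grid["cv_pct"].round(1)
        grid.to_csv(out / "summary.tsv", sep="\t", index=False)
        md += ["## OSI and CV per temperature x airflow cell", "",
               "```", grid.to_string(index=False), "```", ""]

    if fits:
        ftab = _fits_frame(fits)
        ftab.to_csv(out / "fits.tsv", sep="\t", index=False)
        md += ["## Log-linear temperature fits (log10 OSI = A*T + B)", "",
               "```", ftab.to_string(index=False), "```", ""]

    if correlations is not None and not correlations.empty:
        ctab = correlations.copy()
        ctab["r"] = ctab["r"].round(3)
        ctab.to_csv(out / "correlations.tsv", sep="\t", index=False)
        wide = ctab.assign(cell=ctab["r"].map("{:.3f}".format) + " " + ctab["mark"])
        index_cols = [c for c in ("label", "storage_months") if c in wide.columns]
        pivot = wide.pivot(index=index_cols, columns="marker", values="cell")
        md += ["## Kernel OSI vs quality markers (Pearson r, * p<0.05, ** p<0.001)",
               "", "```", pivot.to_string(), "```", ""]
    else:
        md += ["## Kernel OSI vs quality markers", "", "(no correlations)", ""]

    (out / "report.md").write_text("\n".join(md))
    return doc
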