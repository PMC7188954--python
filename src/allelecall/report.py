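"""Report assembly: xlsx workbook plus machine-readable CSV/JSON twins.

The report has four components: the genotyping results table (sample by
marker), the genotype count summary, the per-reaction QC table, and the
settings actually used for the run.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from openpyxl import Workbook

from .genotyping import summarize
from .model import AnalysisSettings, GenotypeCall, QCRecord

__all__ = ["write_report", "results_tables"]


def results_tables(calls: list[GenotypeCall], qc: list[QCRecord],
                   settings: AnalysisSettings):
    """Assemble the four report tables as DataFrames."""
    counts, wide = summarize(calls)
    wide = wide.reset_index() if not wide.empty else pd.DataFrame(columns=["sample"])
    qc_df = pd.DataFrame([rec.as_dict() for rec in qc])
    if qc_df.empty:
        qc_df = pd.DataFrame(columns=["plate", "well", "sample", "target",
                                      *QCRecord.CODE_FIELDS])
    else:
        qc_df = qc_df.sort_values(["plate", "well", "target"], ignore_index=True)
    settings_df = pd.DataFrame(
        [{"setting": k, "value": v} for k, v in settings.as_dict().items()]
    )
    return wide, counts, qc_df, settings_df


def _write_sheet(wb: Workbook, title: str, df: pd.DataFrame) -> None:
    ws = wb.create_sheet(title=title)
    ws.append(list(df.columns))
    for row in df.itertuples(index=False):
        ws.append([None if pd.isna(v) else v for v in row])


def write_report(calls: list[GenotypeCall], qc: list[QCRecord],
                 settings: AnalysisSettings, path) -> None:
    """Write the xlsx report and its CSV/JSON twins next to it.

    ``path`` names the workbook; sibling files ``<stem>_results.csv``,
    ``<stem>_genotype_counts.csv``, ``<stem>_qc.csv``, ``<stem>_settings.csv``
    and ``<stem>.json`` carry the same content for machines.
    """
    path = Path(path)
    wide, counts, qc_df, settings_df = results_tables(calls, qc, settings)

    wb = Workbook()
    wb.remove(wb.active)
    _write_sheet(wb, "Results", wide)
    _write_sheet(wb, "GenotypeCounts", counts)
    _write_sheet(wb, "QC", qc_df)
    _write_sheet(wb, "Settings", settings_df)
    path.parent.mkdir(parents=True, exist_ok=True)
    wb.save(path)

    stem = path.with_suffix("")
    wide.to_csv(f"{stem}_results.csv", index=False)
    counts.to_csv(f"{stem}_genotype_counts.csv", index=False)
    qc_df.to_csv(f"{stem}_qc.csv", index=False)
    settings_df.to_csv(f"{stem}_settings.csv", index=False)
    doc = {
        "results": wide.to_dict(orient="records"),
        "genotype_counts": counts.to_dict(orient="records"),
        "qc": qc_df.to_dict(orient="records"),
        "settings": settings.as_dict(),
    }
    Path(f"{stem}.json").write_text(json.dumps(doc, indent=1, default=str))
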