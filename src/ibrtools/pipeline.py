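"""End-to-end orchestration: inputs -> energy budget -> statistics -> IBRv2 -> report.

A run is described by a small configuration mapping (usually a YAML file):

.. code-block:: yaml

    synthetic:            # or `table: path/to/biomarker_table.csv`
      n_per_group: 20
      seed: 1
      skew: lognormal
    plates:               # optional raw microplate CSVs to process first
      - {path: plates/ache.csv, assay: AChE, kinetic: true}
    reference_group: A1
    alpha: 0.05

Outputs are plain CSVs (a tidy biomarker table, per-biomarker statistics,
a post-hoc pair table, the groups-by-biomarkers deviation matrix with the
IBRv2 score as final column, and signed deviations for radar plotting)
plus a human-readable markdown report.  Every decision-tree branch is
logged, one line per biomarker, so the statistical path is auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import assay as _assay
from . import energy as _energy
from . import ibr as _ibr
from . import stats as _stats
from . import synthetic as _synthetic

__all__ = ["ConfigurationError", "load_config", "run_pipeline", "write_biomarker_table", "read_biomarker_table"]

log = logging.getLogger("ibrtools")


class ConfigurationError(ValueError):
    """The run configuration is unusable (checked before any computation)."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a mapping")
    return cfg


def write_biomarker_table(table: pd.DataFrame, path: Path) -> None:
    """Write the tidy table plus a JSON sidecar with unit/provenance metadata."""
    table.to_csv(path, index=False, float_format="%.10g")
    sidecar = Path(str(path) + ".meta.json")
    meta = {"units": table.attrs.get("units", {}), "seed": table.attrs.get("seed")}
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_biomarker_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    sidecar = Path(str(path) + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        table.attrs["units"] = meta.get("units", {})
    return table


def _sig3(x: float) -> str:
    return "nan" if not np.isfinite(x) else f"{x:.3g}"


def _build_table(cfg: Mapping[str, Any]) -> pd.DataFrame:
    if "table" in cfg:
        table = read_biomarker_table(cfg["table"])
    elif "synthetic" in cfg:
        syn = dict(cfg["synthetic"] or {})
        design = _synthetic.default_design(
            seed=int(syn.get("seed", 0)),
            n_per_group=int(syn.get("n_per_group", 20)),
            skew=str(syn.get("skew", "lognormal")),
        )
        table = _synthetic.generate_study(design)
    else:
        raise ConfigurationError("config needs either 'table' or 'synthetic'")
    for plate_cfg in cfg.get("plates", []):
        plate = _assay.read_plate_csv(plate_cfg["path"])
        res = _assay.process_plate(plate, plate_cfg["assay"], bool(plate_cfg.get("kinetic", False)))
        table = table.set_index("animal_id")
        table[plate_cfg["assay"]] = res["value"]
        table = table.reset_index()
    return table


def run_pipeline(cfg: Mapping[str, Any], out_dir) -> dict[str, Path]:
    """Execute every stage and write the report bundle; returns output paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = cfg.get("reference_group", "A1")
    alpha = float(cfg.get("alpha", 0.05))

    table = _build_table(cfg)
    if reference not in set(table["group"].astype(str)):
        raise ConfigurationError(f"reference group {reference!r} absent from the data")

    if all(c in table.columns for c in (*_energy.RESERVE_COLUMNS, "Ec")):
        table = _energy.add_energy_columns(table)
    paths: dict[str, Path] = {}
    paths["table"] = out / "biomarker_table.csv"
    write_biomarker_table(table, paths["table"])

    biomarkers = cfg.get("biomarkers") or [
        c for c in table.columns if c not in ("animal_id", "group")
    ]
    stat_rows, posthoc_rows, skipped = [], [], []
    for b in biomarkers:
        try:
            r = _stats.compare_groups(table, b, alpha=alpha)
        except _stats.InsufficientDataError as e:
            log.warning("skip %s: %s", b, e)
            skipped.append({"biomarker": b, "reason": str(e)})
            continue
        log.info(
            "biomarker=%s branch=%s transform=%s stat=%s p=%s effect=%s",
            b, r.trail.branch, r.trail.transform_applied,
            _sig3(r.statistic), _sig3(r.p), _sig3(r.effect_size),
        )
        stat_rows.append(
            {
                "biomarker": b,
                "branch": r.trail.branch,
                "transform": r.trail.transform_applied,
                "statistic_kind": r.statistic_kind,
                "statistic": r.statistic,
                "df1": r.df1,
                "df2": r.df2 if r.df2 is not None else "",
                "n_total": r.n_total,
                "p": r.p,
                "effect_size_kind": r.effect_size_kind,
                "effect_size": r.effect_size,
                "effect_size_approx": r.effect_size_approx,
                "significant": r.significant,
                "highly_significant": r.highly_significant,
            }
        )
        ph = r.posthoc.copy()
        ph.insert(0, "biomarker", b)
        posthoc_rows.append(ph)

    stats_df = pd.DataFrame(stat_rows)
    paths["stats"] = out / "group_statistics.csv"
    stats_df.to_csv(paths["stats"], index=False, float_format="%.10g")
    paths["posthoc"] = out / "posthoc_pairs.csv"
    (pd.concat(posthoc_rows, ignore_index=True) if posthoc_rows else pd.DataFrame()).to_csv(
        paths["posthoc"], index=False, float_format="%.10g"
    )

    ibr_cfg = _ibr.IBRConfig(reference_group=reference)
    ibr_biomarkers = [b for b in biomarkers if (table[b].dropna() > 0).all()]
    result = _ibr.compute_ibr(table, biomarkers=ibr_biomarkers, config=ibr_cfg)
    abs_a = result.abs_A.copy()
    abs_a["IBRv2"] = result.scores
    paths["ibr"] = out / "ibr_deviation_matrix.csv"
    abs_a.to_csv(paths["ibr"], index_label="group", float_format="%.10g")
    paths["ibr_signed"] = out / "ibr_signed_deviations.csv"
    result.A.to_csv(paths["ibr_signed"], index_label="group", float_format="%.10g")
    try:
        paths["radar"] = out / "ibr_radar.svg"
        _ibr.plot_radar(result, paths["radar"])
    except Exception as e:  # plotting must never kill the run
        log.warning("radar plot failed: %s", e)
        paths.pop("radar", None)

    paths["report"] = out / "report.md"
    paths["report"].write_text(_render_report(stats_df, skipped, result, reference, alpha))
    return paths


def _render_report(
    stats_df: pd.DataFrame,
    skipped: list[dict],
    ibr_result: _ibr.IBRResult,
    reference: str,
    alpha: float,
) -> str:
    lines = ["# Grouped biomarker analysis report", ""]
    lines.append(f"Reference group: {reference}; alpha = {alpha}")
    lines.append("")
    lines.append("## Group comparisons")
    lines.append("")
    lines.append("| biomarker | branch | statistic | df | p | effect size |")
    lines.append("|---|---|---|---|---|---|")
    for _, r in stats_df.iterrows():
        df2 = r["df2"]
        dfs = f"({_sig3(r['df1'])}, {_sig3(float(df2))})" if df2 != "" else f"({_sig3(r['df1'])})"
        mark = "**" if r["highly_significant"] else ("*" if r["significant"] else "")
        lines.append(
            f"| {r['biomarker']} | {r['branch']} | {r['statistic_kind']} = "
            f"{_sig3(r['statistic'])} | {dfs} | {_sig3(r['p'])}{mark} | "
            f"{r['effect_size_kind']} = {_sig3(r['effect_size'])} |"
        )
    for s in skipped:
        lines.append(f"| {s['biomarker']} | skipped | — | — | — | {s['reason']} |")
    lines.append("")
    lines.append("## IBRv2 deviation matrix (absolute values)")
    lines.append("")
    header = "| group | " + " | ".join(ibr_result.biomarkers) + " | IBRv2 |"
    lines.append(header)
    lines.append("|" + "---|" * (len(ibr_result.biomarkers) + 2))
    for g in ibr_result.groups:
        cells = " | ".join(f"{abs(ibr_result.A.loc[g, b]):.3f}" for b in ibr_result.biomarkers)
        lines.append(f"| {g} | {cells} | {ibr_result.scores[g]:.2f} |")
    lines.append("")
    return "\n".join(lines) + "\n"
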