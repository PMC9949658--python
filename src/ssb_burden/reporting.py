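"""Aggregation to the published presentation and report rendering.

Results are aggregated to condition group x sex, with derived both-sex rows,
an all-condition total row, and attributable percentages
(attributable / all-cause total).  Reports render to CSV, JSON or markdown,
accompanied by a run manifest (seed, config hash, row counts).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ModelInputs, ValidationError

__all__ = [
    "BurdenResult",
    "aggregate",
    "render_report",
    "inputs_checksum",
    "run_manifest",
]

REPORT_MEASURES = ("events", "deaths", "dalys", "cost")
BOTH = "both"
ALL_GROUPS = "all"

#: presentation order of condition groups
GROUP_ORDER = [
    "owob_child",
    "owob_adult",
    "diabetes",
    "cardiac",
    "cerebrovascular",
    "ckd",
    "asthma",
    "musculoskeletal",
    "other",
    ALL_GROUPS,
]

GROUP_LABELS = {
    "owob_child": "Overweight/obesity (<18 y)",
    "owob_adult": "Overweight/obesity (adults)",
    "diabetes": "Diabetes mellitus type 2",
    "cardiac": "Cardiac conditions",
    "cerebrovascular": "Cerebrovascular conditions",
    "ckd": "Chronic kidney conditions",
    "asthma": "Asthma",
    "musculoskeletal": "Musculoskeletal conditions",
    "other": "Other conditions",
    ALL_GROUPS: "Total",
}


@dataclass
class BurdenResult:
    """Aggregated burden report: group x sex x measure rows.

    Columns: group, sex, measure, attributable, total, lo, hi, pct.  ``lo``
    and ``hi`` are 95% interval bounds on the attributable value (NaN for
    deterministic runs without uncertainty).
    """

    frame: pd.DataFrame

    COLUMNS = ["group", "sex", "measure", "attributable", "total", "lo", "hi", "pct"]

    def value(self, group: str, sex: str, measure: str) -> pd.Series:
        f = self.frame
        rows = f[(f.group == group) & (f.sex == sex) & (f.measure == measure)]
        if rows.empty:
            raise KeyError((group, sex, measure))
        return rows.iloc[0]

    def attributable(self, group: str, sex: str, measure: str) -> float:
        return float(self.value(group, sex, measure)["attributable"])

    def pct(self, group: str, sex: str, measure: str) -> float:
        return float(self.value(group, sex, measure)["pct"])

    def equals(self, other: "BurdenResult", tol: float = 1e-9) -> bool:
        a = self.frame.sort_values(["group", "sex", "measure"]).reset_index(drop=True)
        b = other.frame.sort_values(["group", "sex", "measure"]).reset_index(drop=True)
        if not (a[["group", "sex", "measure"]] == b[["group", "sex", "measure"]]).all().all():
            return False
        num = ["attributable", "total", "lo", "hi", "pct"]
        return bool(
            np.allclose(
                a[num].to_numpy(float), b[num].to_numpy(float),
                rtol=tol, atol=tol, equal_nan=True,
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "BurdenResult":
        return cls(pd.read_csv(path))


def _format_pct(pct: float) -> str:
    if not np.isfinite(pct):
        return ""
    return f"{pct:.0f}%" if pct >= 1.95 else f"{pct:.1f}%"


def aggregate(
    results: pd.DataFrame, grouping: dict[str, str] | None = None
) -> BurdenResult:
    """Aggregate attributable/total rows to group x sex with totals.

    ``results`` is a long frame with columns (group|disease), sex, measure,
    attributable, total and optional lo/hi interval bounds; per-stratum rows
    are summed.  A ``grouping`` map is required when only diseases are
    present.  Both-sex rows and an all-condition "all" row are appended and
    percentages recomputed.  Interval bounds, where present, are summed —
    a conservative approximation for derived rows.
    """
    frame = results.copy()
    if "group" not in frame.columns:
        if grouping is None:
            raise ValidationError("results carry no group column and no grouping map")
        unmapped = sorted(set(frame["disease"]) - set(grouping))
        if unmapped:
            raise ValidationError(f"diseases not mapped to a group: {unmapped}")
        frame["group"] = frame["disease"].map(grouping)

    for col in ("lo", "hi"):
        if col not in frame.columns:
            frame[col] = np.nan

    frame = frame[frame["measure"].isin(REPORT_MEASURES)]
    if frame.empty:
        frame = pd.DataFrame(
            columns=["group", "sex", "measure", "attributable", "total", "lo", "hi"]
        )

    num = ["attributable", "total", "lo", "hi"]
    by_sex = (
        frame.groupby(["group", "sex", "measure"], as_index=False)[num]
        .sum(min_count=1)
    )
    both = (
        by_sex.groupby(["group", "measure"], as_index=False)[num].sum(min_count=1)
    )
    both["sex"] = BOTH
    rows = pd.concat([by_sex, both], ignore_index=True)

    totals = rows.groupby(["sex", "measure"], as_index=False)[num].sum(min_count=1)
    totals["group"] = ALL_GROUPS
    out = pd.concat([rows, totals], ignore_index=True)
    out[num] = out[num].astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * out["attributable"].to_numpy() / out["total"].to_numpy()
    pct[~np.isfinite(pct)] = np.nan
    out["pct"] = pct

    order = {g: i for i, g in enumerate(GROUP_ORDER)}
    sex_order = {"female": 0, "male": 1, BOTH: 2}
    out = out.sort_values(
        by=["group", "sex", "measure"],
        key=lambda c: c.map(order).fillna(99) if c.name == "group"
        else (c.map(sex_order) if c.name == "sex" else c),
    ).reset_index(drop=True)
    return BurdenResult(out[BurdenResult.COLUMNS])


# ---------------------------------------------------------------------------
# rendering


def _markdown(result: BurdenResult) -> str:
    lines = [
        "| Condition | Measure | Women | Men | Both |",
        "|---|---|---|---|---|",
    ]
    f = result.frame
    groups = [g for g in GROUP_ORDER if g in set(f.group)]
    for group in groups:
        for measure in REPORT_MEASURES:
            cells = []
            for sex in ("female", "male", BOTH):
                sub = f[(f.group == group) & (f.sex == sex) & (f.measure == measure)]
                if sub.empty:
                    cells.append("")
                    continue
                r = sub.iloc[0]
                digits = 1 if measure == "cost" else 0
                cell = (
                    f"{r.attributable:,.{digits}f} / {r.total:,.{digits}f}"
                    f" ({_format_pct(r.pct)})"
                )
                if np.isfinite(r.lo) and np.isfinite(r.hi):
                    cell += f" [{r.lo:,.{digits}f}-{r.hi:,.{digits}f}]"
                cells.append(cell)
            if any(cells):
                lines.append(
                    f"| {GROUP_LABELS.get(group, group)} | {measure} | "
                    + " | ".join(cells)
                    + " |"
                )
    return "\n".join(lines) + "\n"


def render_report(
    result: BurdenResult,
    format: str,
    out_dir: str | Path,
    manifest: dict | None = None,
) -> list[Path]:
    """Write the report in ``format`` (csv | json | markdown) plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if format == "csv":
        path = out_dir / "report.csv"
        result.frame.to_csv(path, index=False)
    elif format == "json":
        path = out_dir / "report.json"
        path.write_text(
            json.dumps(result.frame.to_dict(orient="records"), indent=2, default=float)
        )
    elif format == "markdown":
        path = out_dir / "report.md"
        path.write_text(_markdown(result))
    else:
        raise ValidationError(f"unknown report format {format!r}")
    written.append(path)
    if manifest is not None:
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(mpath)
    return written


# ---------------------------------------------------------------------------
# manifest


def inputs_checksum(inputs: ModelInputs) -> str:
    """Deterministic sha256 over the canonical serialized input tables."""
    from .io import write_inputs  # local import to avoid a cycle
    import tempfile

    h = hashlib.sha256()
    with tempfile.TemporaryDirectory() as tmp:
        for path in sorted(write_inputs(inputs, tmp)):
            h.update(path.name.encode())
            h.update(path.read_bytes())
    return h.hexdigest()


def run_manifest(
    inputs: ModelInputs, seed: int | None, result: BurdenResult, **extra
) -> dict:
    return {
        "seed": seed,
        "input_checksum": inputs_checksum(inputs),
        "n_strata": len(inputs.strata),
        "n_diseases": len(inputs.diseases),
        "n_report_rows": int(len(result.frame)),
        **extra,
    }
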