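"""Readers, writers and report formatting for the pipeline's file formats.

All tabular formats are long-format UTF-8 CSV with a header row; month
indices are 1-based and contiguous.  The posterior archive is a compressed
``.npz`` of named arrays with a JSON sidecar describing the design
(column names, stored SDs, sampler settings), so a projection can be run
without re-fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .adjacency import AdjacencyStructure
from .areal import validate_panel

__all__ = [
    "read_panel",
    "write_panel",
    "read_adjacency",
    "write_adjacency",
    "write_posterior",
    "read_posterior",
    "PosteriorArchive",
    "summary_report",
]


def read_panel(path) -> pd.DataFrame:
    """Read and validate an area-month panel CSV.

    Required columns: area_id, month_index, calendar_month, observed,
    expected; any further columns are covariates.  Errors name the missing
    column, the offending row, or the missing (area, month) cell.
    """
    panel = pd.read_csv(path, float_precision="round_trip")
    for col in ("month_index", "calendar_month", "observed"):
        if col in panel.columns:
            vals = pd.to_numeric(panel[col], errors="coerce")
            bad = vals.isna() | (vals != np.floor(vals.fillna(0)))
            if bad.any():
                raise ValueError(
                    f"column '{col}' must be integer; bad value at row {int(bad.idxmax())}"
                )
            panel[col] = vals.astype(np.int64)
    validate_panel(panel)
    return panel


def write_panel(path, panel: pd.DataFrame) -> None:
    validate_panel(panel)
    panel.to_csv(path, index=False)


def _edges_from_pairs(pairs) -> AdjacencyStructure:
    ids = sorted({a for p in pairs for a in p}, key=str)
    rank = {a: i for i, a in enumerate(ids)}
    seen = set()
    edges = []
    for a, b in pairs:
        if a == b:
            raise ValueError(f"self-edge on area {a!r}")
        i, j = sorted((rank[a], rank[b]))
        if (i, j) not in seen:
            seen.add((i, j))
            edges.append((i, j))
    return AdjacencyStructure(ids, np.array(edges, dtype=np.int64))


def read_adjacency(path, format: str = "edgelist") -> AdjacencyStructure:
    """Read an adjacency file (symmetric closure applied, duplicates merged).

    ``edgelist``: one edge per line, two area ids separated by a comma or
    whitespace.  ``gal``: the GAL neighbour-list format (header line, then
    per-area id/degree lines followed by a neighbour line).
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if format == "edgelist":
        pairs = []
        for ln in lines:
            parts = [p for p in ln.replace(",", " ").split() if p]
            if parts[0].lower() in ("area_i", "area_a", "from"):  # optional header
                continue
            if len(parts) != 2:
                raise ValueError(f"malformed edge line: {ln!r}")
            pairs.append((parts[0], parts[1]))
        return _edges_from_pairs(pairs)
    if format == "gal":
        header = lines[0].split()
        # GeoDa-style headers are "0 K file var"; minimal headers are just "K"
        int(header[1] if len(header) > 1 else header[0])
        pairs = []
        i = 1
        while i < len(lines):
            area, ndeg = lines[i].split()[0], int(lines[i].split()[1])
            if ndeg > 0:
                nbrs = lines[i + 1].split()
                if len(nbrs) != ndeg:
                    raise ValueError(f"GAL degree mismatch for area {area!r}")
                pairs.extend((area, n) for n in nbrs)
                i += 2
            else:
                i += 1
        return _edges_from_pairs(pairs)
    raise ValueError(f"unknown adjacency format {format!r}")


def write_adjacency(path, adjacency: AdjacencyStructure) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in adjacency.edges:
            fh.write(f"{adjacency.area_ids[i]},{adjacency.area_ids[j]}\n")


@dataclass
class PosteriorArchive:
    """Posterior draws re-loaded from disk (enough to project and report)."""

    beta: np.ndarray
    rho: np.ndarray
    gamma: np.ndarray
    tau2: np.ndarray
    columns: list
    sd_used: dict
    meta: dict
    phi: np.ndarray | None = None
    w: np.ndarray | None = None

    def beta_draws(self, covariate: str) -> np.ndarray:
        if covariate not in self.columns:
            raise KeyError(f"unknown covariate {covariate!r}")
        return self.beta[:, self.columns.index(covariate)]


def write_posterior(path, results) -> None:
    """Save results as <path>.npz plus a JSON sidecar <path>.json."""
    path = Path(path)
    arrays = {
        "beta": results.beta,
        "rho": results.rho,
        "gamma": results.gamma,
        "tau2": results.tau2,
    }
    if results.phi is not None:
        arrays["phi"] = results.phi
    if results.w is not None:
        arrays["w"] = results.w
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    info = results.design_info
    meta = {
        "columns": list(info.columns),
        "sd_used": {k: float(v) for k, v in info.sd_used.items()},
        "acceptance": {k: float(v) for k, v in results.acceptance.items()},
        "mcmc": {
            "n_iter": results.spec.mcmc.n_iter,
            "burn_in": results.spec.mcmc.burn_in,
            "thin": results.spec.mcmc.thin,
            "seed": results.spec.mcmc.seed,
        },
        "adaptive_w": results.spec.adaptive_w,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1), encoding="utf-8")


def read_posterior(path) -> PosteriorArchive:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    return PosteriorArchive(
        beta=arrays["beta"],
        rho=arrays["rho"],
        gamma=arrays["gamma"],
        tau2=arrays["tau2"],
        phi=arrays.get("phi"),
        w=arrays.get("w"),
        columns=meta["columns"],
        sd_used=meta["sd_used"],
        meta=meta,
    )


def _fmt_int(x: float) -> str:
    return f"{int(round(x)):,}"


def summary_report(results, projection=None, mean_annual_admissions=None) -> str:
    """Markdown report: per-covariate RR table, then the projection table.

    Relative risks are printed to 3 decimal places; projected admission
    counts are comma-grouped integers.  The projection section is omitted
    when no projection is supplied.
    """
    lines = ["# Model summary", "", "| covariate | SD | RR | 95% CrI |", "|---|---|---|---|"]
    summ = results.summary()
    rr_rows = summ[summ["parameter"].isin(results.design_info.sd_used)]
    for _, row in rr_rows.iterrows():
        lines.append(
            f"| {row['parameter']} | {row['sd_used']:.3g} | {row['rr_median']:.3f} "
            f"| ({row['rr_lower_95']:.3f}, {row['rr_upper_95']:.3f}) |"
        )
    lines += ["", "| parameter | median | 95% CrI |", "|---|---|---|"]
    for name in ("rho", "gamma", "tau2"):
        row = summ[summ["parameter"] == name].iloc[0]
        lines.append(
            f"| {name} | {row['median']:.4g} | ({row['lower_95']:.4g}, {row['upper_95']:.4g}) |"
        )
    if projection is not None:
        lo, hi = projection.reductions_ci
        lines += [
            "",
            "# Projected change in admissions",
            "",
            "| reduced admissions / year | 95% CrI |",
            "|---|---|",
            f"| {_fmt_int(projection.reductions)} | ({_fmt_int(lo)}, {_fmt_int(hi)}) |",
        ]
        if mean_annual_admissions is not None:
            pct = projection.percent_of_present(mean_annual_admissions)
            lines.append(f"\nReduction equals {pct}% of present-day annual admissions.")
    return "\n".join(lines) + "\n"
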