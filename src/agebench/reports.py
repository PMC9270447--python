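"""Result export, round-trip loading, manifests and figure rendering.

All tabular artifacts are plain CSV (full-precision floats, exact float64
round trip), reports are JSON, and every export is accompanied by a manifest
listing the written files with SHA-256 checksums plus the config hash and
seed — enough to verify byte-identical reproduction of a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .aging_stats import AgingCurve, PacCurve  # noqa: E402
from .dynamics import find_error_attractors  # noqa: E402
from .engine import RESULT_COLUMNS, AgingResult, ExperimentResult  # noqa: E402
from .sampling import SamplingPlan  # noqa: E402

__all__ = ["ExportRefusedError", "export_results", "read_results", "render_report"]

# deterministic SVG output (fixed hash salt, no embedded date)
matplotlib.rcParams["svg.hashsalt"] = "agebench"

RESULTS_CSV = "results.csv"
SIDECAR_JSON = "run_info.json"
MANIFEST_JSON = "manifest.json"


class ExportRefusedError(FileExistsError):
    """Refusing to overwrite a non-empty output directory without force."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def export_results(
    result: AgingResult,
    outdir: str | Path,
    curves: dict[str, AgingCurve | PacCurve] | None = None,
    reports: dict[str, object] | None = None,
    force: bool = False,
) -> dict:
    """Write results CSV, curve CSVs, JSON reports and a checksum manifest.

    Returns the manifest dict.  Refuses an existing non-empty ``outdir``
    unless ``force`` is set.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ExportRefusedError(f"{outdir} exists and is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    written: list[Path] = []
    results_path = outdir / RESULTS_CSV
    # %.17g guarantees exact float64 round trip through the CSV
    result.to_dataframe().to_csv(results_path, index=False, float_format="%.17g")
    written.append(results_path)

    sidecar = {
        "dataset_name": result.dataset_name,
        "family": result.family,
        "plan": result.plan.to_dict(),
        "provenance": result.provenance,
        "n_degenerate": result.n_degenerate,
    }
    config_hash = hashlib.sha256(
        json.dumps(sidecar, sort_keys=True, default=_json_default).encode()
    ).hexdigest()
    sidecar["config_hash"] = config_hash
    sidecar_path = outdir / SIDECAR_JSON
    sidecar_path.write_text(json.dumps(sidecar, indent=2, default=_json_default))
    written.append(sidecar_path)

    for name, curve in (curves or {}).items():
        p = outdir / f"{name}.csv"
        curve.to_frame().to_csv(p, index=False)
        written.append(p)
    for name, report in (reports or {}).items():
        p = outdir / f"{name}.json"
        payload = report.to_dict() if hasattr(report, "to_dict") else report
        p.write_text(json.dumps(payload, indent=2, default=_json_default))
        written.append(p)

    manifest = {
        "config_hash": config_hash,
        "seed": result.plan.seed,
        "files": [{"path": p.name, "sha256": _sha256(p)} for p in sorted(written)],
    }
    (outdir / MANIFEST_JSON).write_text(json.dumps(manifest, indent=2))
    return manifest


def read_results(outdir: str | Path) -> AgingResult:
    """Reconstruct an :class:`AgingResult` from an export directory (exact fields)."""
    outdir = Path(outdir)
    df = pd.read_csv(outdir / RESULTS_CSV, float_precision="round_trip")
    info = json.loads((outdir / SIDECAR_JSON).read_text())
    plan = SamplingPlan(**info["plan"])
    results = [
        ExperimentResult(
            t0=row.t0,
            dT=row.dT,
            mse0=row.mse0,
            mse1=row.mse1,
            e_rel=row.e_rel,
            hyperparam_batch=int(row.hyperparam_batch),
            converged=bool(row.converged),
        )
        for row in df.itertuples()
    ]
    return AgingResult(
        dataset_name=info["dataset_name"],
        family=info["family"],
        plan=plan,
        results=results,
        provenance=info.get("provenance", {}),
        n_degenerate=info.get("n_degenerate", 0),
    )


def _save(fig, outdir: Path, stem: str, formats: tuple[str, ...]) -> list[Path]:
    paths = []
    for ext in formats:
        p = outdir / f"{stem}.{ext}"
        fig.savefig(p, metadata={"Date": None} if ext == "svg" else None)
        paths.append(p)
    plt.close(fig)
    return paths


def render_report(outdir: str | Path, formats: tuple[str, ...] = ("png", "svg")) -> list[Path]:
    """Render the diagnostic figures from an export directory.

    Produces (when inputs allow): the aging chart (scatter + percentile
    trends), the P_ac curve, the phase portrait, and the attractor density
    map.  Deterministic file names; SVG output is byte-stable.
    """
    outdir = Path(outdir)
    if not (outdir / RESULTS_CSV).exists():
        raise FileNotFoundError(f"missing {RESULTS_CSV} in {outdir}; export results first")
    df = pd.read_csv(outdir / RESULTS_CSV)
    written: list[Path] = []

    # aging chart: scatter of every experiment plus percentile trends
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(df["dT"], df["e_rel"], ".", ms=2, alpha=0.35, color="#888888", label="experiments")
    curve_csv = outdir / "aging_curve.csv"
    if curve_csv.exists():
        c = pd.read_csv(curve_csv)
        ax.plot(c["dt"], c["p25"], color="tab:green", label="25th pct (best case)")
        ax.plot(c["dt"], c["p50"], color="tab:blue", lw=2, label="median")
        ax.plot(c["dt"], c["p75"], color="tab:red", label="75th pct (worst case)")
    ax.set_xlabel("model age dT (days)")
    ax.set_ylabel("relative error $E_{rel}$")
    ax.set_title("Model aging chart")
    ax.legend(loc="upper left", fontsize=8)
    written += _save(fig, outdir, "aging_chart", formats)

    pac_csv = outdir / "pac_curve.csv"
    if pac_csv.exists():
        c = pd.read_csv(pac_csv)
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(c["dt"], c["p_ac"], "o-", color="tab:blue")
        ax.set_ylim(-0.02, 1.02)
        ax.set_xlabel("model age dT (days)")
        ax.set_ylabel("$P_{ac}(dT)$")
        ax.set_title("Probability of retaining an accurate model")
        written += _save(fig, outdir, "pac_curve", formats)

    phase_csv = outdir / "phase_path.csv"
    if phase_csv.exists():
        c = pd.read_csv(phase_csv)
        fig, ax = plt.subplots(figsize=(5.5, 5))
        ax.plot(c["pc1"], c["pc2"], "-", color="#aaaaaa", lw=0.8, zorder=1)
        states = c["state"] if "state" in c.columns else np.zeros(len(c))
        sc = ax.scatter(c["pc1"], c["pc2"], c=states, cmap="tab10", s=30, zorder=2)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_title("Feature-importance phase portrait")
        fig.colorbar(sc, ax=ax, label="state")
        written += _save(fig, outdir, "phase_portrait", formats)
    else:
        warnings.warn("no phase_path.csv; skipping phase portrait")

    # attractor density map recomputed from the results (deterministic)
    report = find_error_attractors((df["dT"].to_numpy(), df["e_rel"].to_numpy()))
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(df["dT"], np.log(df["e_rel"]), ".", ms=2, alpha=0.3, color="#555555")
    for mode in report.modes:
        ax.plot(mode["dT_center"], np.log(mode["e_rel_center"]), "x", color="tab:red", ms=10, mew=2)
    ax.set_xlabel("model age dT (days)")
    ax.set_ylabel("log $E_{rel}$")
    ax.set_title(f"Error attractors ({len(report.modes)} dense basins)")
    written += _save(fig, outdir, "attractor_map", formats)

    return written
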