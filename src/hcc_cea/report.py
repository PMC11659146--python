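"""Publication-style outputs: results tables, figures, and run manifests.

CSV/JSON files are the machine-checkable surface; the figures (survival
curves, tornado, incremental cost-effectiveness plane, acceptability curve)
are side effects rendered with matplotlib's Agg backend.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .cea import CEAResult
from .engine import StrategyOutcome
from .params import ParameterBundle
from .sensitivity import OWSAResult, PSAResult, ceac
from .survival import loglogistic_survival

__all__ = [
    "write_manifest",
    "write_base_case",
    "write_owsa",
    "write_psa",
    "survival_curve_frame",
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    out_dir: Path,
    command: str,
    config_path: Optional[Path],
    bundle: ParameterBundle,
    seed: Optional[int] = None,
) -> Path:
    """Write the run manifest; one per output directory, enough to re-run
    any seeded command bit-identically."""
    manifest = {
        "command": command,
        "config_path": str(config_path) if config_path else None,
        "config_sha256": _sha256(config_path) if config_path else None,
        "seed": seed,
        "settings": bundle.settings.model_dump(),
        "package_version": __version__,
        "python": platform.python_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


def survival_curve_frame(bundle: ParameterBundle, step: float = 1.0) -> pd.DataFrame:
    """Per-cycle modelled OS/PFS survival probabilities for every arm."""
    h = bundle.settings.horizon_cycles * bundle.settings.cycle_length_months
    t = np.arange(0.0, h + step, step)
    data = {"month": t}
    for arm, strat in bundle.strategies.items():
        data[f"{arm}_os"] = np.atleast_1d(loglogistic_survival(strat.os, t))
        data[f"{arm}_pfs"] = np.atleast_1d(loglogistic_survival(strat.pfs, t))
    return pd.DataFrame(data)


def write_base_case(
    out_dir: Path,
    outcomes: dict[str, StrategyOutcome],
    result: CEAResult,
    bundle: ParameterBundle,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.to_json(out_dir / "cea.json")
    result.to_frame().to_csv(out_dir / "base_case.csv")
    breakdown = {arm: out.cost_breakdown for arm, out in outcomes.items()}
    with open(out_dir / "cost_breakdown.json", "w") as fh:
        json.dump(breakdown, fh, indent=2)
    for arm, out in outcomes.items():
        out.trace.to_frame().to_csv(out_dir / f"trace_{arm}.csv", index=False)

    curves = survival_curve_frame(bundle)
    curves.to_csv(out_dir / "survival_curves.csv", index=False)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for col in curves.columns[1:]:
        style = "-" if col.endswith("_os") else "--"
        ax.plot(curves["month"], curves[col], style, label=col.replace("_", " "))
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "survival_curves.png", dpi=150)
    plt.close(fig)


def write_owsa(out_dir: Path, result: OWSAResult, top: int = 15) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.to_csv(out_dir / "owsa.csv")
    frame = result.frame.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(frame) + 1.5))
    base = result.baseline_icer
    ax.barh(frame["parameter"], frame["icer_high"] - base, left=base,
            color="#c44e52", label="high input")
    ax.barh(frame["parameter"], frame["icer_low"] - base, left=base,
            color="#4c72b0", label="low input")
    ax.axvline(base, color="k", lw=1)
    ax.set_xlabel("ICER (USD per QALY)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "tornado.png", dpi=150)
    plt.close(fig)


def write_psa(out_dir: Path, result: PSAResult) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.pairs_frame().to_csv(out_dir / "psa_pairs.csv", index=False)
    acceptability = {
        "n_draws": result.n_draws,
        "seed": result.seed,
        "n_rejected": result.n_rejected,
        "clamp_count": result.clamp_count,
        "acceptability": result.acceptability,
        "wtp_thresholds": result.wtp_thresholds,
    }
    with open(out_dir / "acceptability.json", "w") as fh:
        json.dump(acceptability, fh, indent=2)

    curve = ceac(result)
    curve.to_csv(out_dir / "ceac.csv", index=False)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.scatter(result.pairs[:, 1], result.pairs[:, 0], s=4, alpha=0.3)
    for region, wtp in result.wtp_thresholds.items():
        lim = np.array(ax.get_xlim())
        ax.plot(lim, wtp * lim, lw=1, label=f"WTP {region} ({wtp:,.0f})")
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (USD)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "ice_plane.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(curve["wtp"], curve["probability"])
    ax.axhline(0.5, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("willingness-to-pay (USD per QALY)")
    ax.set_ylabel("P(combination cost-effective)")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(out_dir / "ceac.png", dpi=150)
    plt.close(fig)
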