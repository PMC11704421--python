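"""Human-readable reports and machine-readable run summaries.

The flux-diff report supports bypass hunting during curation: when a
knockout unexpectedly stays viable, the reactions whose optimal flux
changed the most point at the compensatory route.  Individual fluxes are
not unique under alternative optima, so the report is a lead generator
for curatorial inspection, not a proof.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .fba import apply_knockout, solve_fba
from .model import GEMModel

__all__ = ["flux_diff_report", "run_summary", "write_summary"]

FLUX_DIFF_CAVEAT = (
    "fluxes from alternative optima are non-unique; treat rankings as "
    "candidate bypasses, not conclusions"
)


def flux_diff_report(model: GEMModel, genes: set[str]) -> pd.DataFrame:
    """Per-reaction optimal fluxes before/after a knockout, ranked by |delta|.

    Columns: reaction, flux_before, flux_after, abs_delta; attrs carry the
    alternative-optima caveat.
    """
    before = solve_fba(model)
    after = solve_fba(apply_knockout(model, genes))
    rows = []
    for rid in model.reactions:
        fb = before.fluxes.get(rid, 0.0)
        fa = after.fluxes.get(rid, 0.0)
        rows.append(
            {"reaction": rid, "flux_before": fb, "flux_after": fa,
             "abs_delta": abs(fa - fb)}
        )
    frame = pd.DataFrame(rows).sort_values(
        ["abs_delta", "reaction"], ascending=[False, True]
    ).reset_index(drop=True)
    frame.attrs["caveat"] = FLUX_DIFF_CAVEAT
    return frame


def run_summary(config: dict, models: dict[str, GEMModel], counts: dict) -> dict:
    """Machine-readable summary: config, model fingerprints, counts.

    Deterministic for identical inputs (no timestamps by design).
    """
    return {
        "config": config,
        "model_fingerprints": {name: m.fingerprint() for name, m in models.items()},
        "counts": counts,
    }


def write_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
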