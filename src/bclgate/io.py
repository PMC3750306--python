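"""Serialization of results: CSV for tabular output, JSON for summaries.

JSON documents embed a full echo of the resolved configuration so that any
result can be re-run bit-for-bit from its own output file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .caspase import BifurcationResult
from .config import RunConfig
from .gates import (
    GateBoundaryScan,
    GateClassification,
    MacroParameters,
    ScanResult,
)
from .protocols import Trajectory

__all__ = [
    "write_trajectory",
    "write_scan",
    "write_bifurcation_diagram",
    "write_json_result",
    "result_to_jsonable",
]


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Trajectory as CSV: time_h followed by the 11 species columns."""
    traj.to_frame().to_csv(path, index=False)


def write_scan(scan: ScanResult, path: str | Path) -> None:
    """Input-plane scan as long-format CSV: p53_killer, akt_u, bax_ss."""
    scan.to_frame().to_csv(path, index=False)


def write_bifurcation_diagram(diagram: pd.DataFrame, path: str | Path) -> None:
    """Bifurcation diagram as CSV: bax, casp_root, procasp_root, stability."""
    diagram.to_csv(path, index=False)


def result_to_jsonable(obj) -> dict:
    """Convert a result object to a plain JSON-serializable mapping."""
    if isinstance(obj, BifurcationResult):
        return {"bax_bif": obj.bax_bif, "casp_bif": obj.casp_bif}
    if isinstance(obj, MacroParameters):
        return dataclasses.asdict(obj)
    if isinstance(obj, GateClassification):
        return {
            "truth_table": {
                f"{{{c1},{c2}}}": fate.value
                for (c1, c2), fate in obj.truth_table.items()
            },
            "gate_type": obj.gate_type.value,
            "method": obj.method,
        }
    if isinstance(obj, GateBoundaryScan):
        return {
            "varied": obj.varied,
            "corner_flips": {
                f"{{{c1},{c2}}}": flip for (c1, c2), flip in obj.corner_flips.items()
            },
            "boundaries": {gt.value: v for gt, v in obj.boundaries.items()},
        }
    if isinstance(obj, dict):
        return obj
    raise TypeError(f"no JSON form defined for {type(obj).__name__}")


def write_json_result(
    obj, path: str | Path, config: RunConfig | None = None
) -> None:
    """Write a result as JSON with the resolved configuration embedded.

    Numbers are kept at full double precision; rounding is a display-layer
    concern only.
    """
    payload = {"result": result_to_jsonable(obj)}
    if config is not None:
        payload["config"] = config.to_dict()
    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")


def _default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o).__name__}")
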