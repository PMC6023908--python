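"""Deterministic report writing shared by all CLI stages.

Every JSON report embeds the software version, the seed (when one was used)
and the effective configuration; floats are serialized to six significant
digits so identical runs produce byte-identical reports.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd


def _round6(x):
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round6(v) for v in x]
    if isinstance(x, (np.floating, float)):
        x = float(x)
        if not math.isfinite(x) or x == 0.0:
            return x
        return float(f"{x:.6g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    if isinstance(x, np.ndarray):
        return _round6(x.tolist())
    return x


def write_json_report(path, payload: dict, config: dict | None = None, seed=None) -> None:
    from . import __version__

    out = {"memprobe_version": __version__}
    if seed is not None:
        out["seed"] = seed
    if config is not None:
        out["config"] = _round6(config)
    out.update(_round6(payload))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=False)
        fh.write("\n")


def write_csv(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
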