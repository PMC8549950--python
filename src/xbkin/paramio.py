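"""Parameter documents and deterministic CSV export.

Parameter sets travel as flat JSON documents with unit-suffixed keys
(e.g. ``mu_f0_per_s``, ``a_XB_MPa``); unknown keys are rejected and the
document round-trips losslessly.  Curves are written as deterministic CSV
with a fixed column order and full float precision.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Dict, Sequence, Tuple, Union

import pandas as pd

from .ratelib import (
    DM_DEFAULT_NM,
    SL0_DEFAULT_NM,
    GrowthKind,
    MomentRateParams,
    QSpec,
)

__all__ = ["load_params", "save_params", "params_to_doc", "doc_to_params",
           "write_curve", "read_curve"]

log = logging.getLogger("xbkin")

REQUIRED_KEYS = ("mu_f0_per_s", "mu_f1_per_s", "r0_per_s", "alpha", "growth",
                 "a_XB_MPa")
OPTIONAL_KEYS: Dict[str, float] = {
    "permissivity": 1.0,
    "SL0_nm": SL0_DEFAULT_NM,
    "D_M_nm": DM_DEFAULT_NM,
}


def params_to_doc(
    m: MomentRateParams,
    permissivity: float = 1.0,
    sl0_nm: float = SL0_DEFAULT_NM,
    d_m_nm: float = DM_DEFAULT_NM,
) -> dict:
    """Serialize a parameter set to the flat key/value document."""
    return {
        "mu_f0_per_s": m.mu_f0,
        "mu_f1_per_s": m.mu_f1,
        "r0_per_s": m.r0,
        "alpha": m.q.alpha,
        "growth": m.q.growth.value,
        "a_XB_MPa": m.a_xb / 1e6,
        "permissivity": permissivity,
        "SL0_nm": sl0_nm,
        "D_M_nm": d_m_nm,
    }


def doc_to_params(doc: dict) -> Tuple[MomentRateParams, dict]:
    """Validate a parameter document and build the moment-level parameters.

    Returns ``(params, context)`` where context carries permissivity, SL0
    and D_M (defaults applied and logged).  A linear-growth document with
    ``alpha >= mu_f0/mu_f1`` is accepted with a warning: its force-velocity
    curve never crosses zero, so v_max is undefined.
    """
    unknown = set(doc) - set(REQUIRED_KEYS) - set(OPTIONAL_KEYS)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    missing = [k for k in REQUIRED_KEYS if k not in doc]
    if missing:
        raise ValueError(f"missing required parameter keys: {missing}")

    context = {}
    for key, default in OPTIONAL_KEYS.items():
        if key in doc:
            context[key] = float(doc[key])
        else:
            context[key] = default
            log.info("parameter %s not given; using default %s", key, default)

    m = MomentRateParams(
        mu_f0=float(doc["mu_f0_per_s"]),
        mu_f1=float(doc["mu_f1_per_s"]),
        r0=float(doc["r0_per_s"]),
        q=QSpec(alpha=float(doc["alpha"]), growth=GrowthKind(doc["growth"])),
        a_xb=float(doc["a_XB_MPa"]) * 1e6,
    )
    if m.q.growth is not GrowthKind.SUBLINEAR and m.q.alpha >= m.ratio:
        warnings.warn(
            "alpha >= mu_f0/mu_f1 with linear growth: v_max undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    return m, context


def load_params(path: Union[str, Path]) -> Tuple[MomentRateParams, dict]:
    """Read and validate a JSON parameter document."""
    with open(path) as fh:
        doc = json.load(fh)
    return doc_to_params(doc)


def save_params(path: Union[str, Path], m: MomentRateParams, **context) -> None:
    doc = params_to_doc(m, **context)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_curve(
    path: Union[str, Path], curve: pd.DataFrame, columns: Sequence[str]
) -> None:
    """Write a curve as deterministic CSV: fixed column order, full float
    precision, header row.  Missing columns raise; extras are dropped."""
    missing = [c for c in columns if c not in curve.columns]
    if missing:
        raise ValueError(f"curve is missing columns {missing}")
    curve.loc[:, list(columns)].to_csv(
        path, index=False, float_format="%.17g", lineterminator="\n"
    )


def read_curve(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
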