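"""CSV/JSON interchange for cohort tables, with schema validation.

Column dictionary (units): see docs/data_dictionary.md.  Baseline CSV: one
row per subject; visits CSV: long format, one row per eGFR measurement.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import PREDICTORS
from .errors import IntegrityError, SchemaError

logger = logging.getLogger(__name__)

REQUIRED_BASELINE_COLUMNS = ("subject_id", "country", "uacr") + tuple(
    p for p in PREDICTORS if p != "log2_uacr"
)
REQUIRED_VISIT_COLUMNS = ("subject_id", "country", "time_years", "egfr")


def write_cohort_csv(
    baselines: pd.DataFrame, visits: pd.DataFrame, baseline_path, visits_path
) -> None:
    baselines.to_csv(baseline_path, index=False)
    visits.to_csv(visits_path, index=False)


def read_cohort_csv(baseline_path, visits_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and validate baseline and visit tables.

    Raises :class:`SchemaError` naming any missing column and
    :class:`IntegrityError` on duplicate (subject, time) visits.  Baseline
    rows with non-positive UACR are rejected (log2 undefined) with the count
    logged; ``log2_uacr`` and ``baseline_egfr`` are derived when absent.
    """
    baselines = pd.read_csv(baseline_path)
    visits = pd.read_csv(visits_path)

    miss_b = [c for c in REQUIRED_BASELINE_COLUMNS if c not in baselines.columns]
    if miss_b:
        raise SchemaError(f"baseline table missing columns: {miss_b}")
    miss_v = [c for c in REQUIRED_VISIT_COLUMNS if c not in visits.columns]
    if miss_v:
        raise SchemaError(f"visit table missing columns: {miss_v}")

    dup = visits.duplicated(subset=["subject_id", "time_years"])
    if dup.any():
        rows = visits.loc[dup, ["subject_id", "time_years"]].head(3).to_dict("records")
        raise IntegrityError(f"duplicate (subject, time) visits, e.g. {rows}")

    bad_uacr = ~(baselines["uacr"] > 0) | ~np.isfinite(baselines["uacr"])
    if bad_uacr.any():
        logger.warning(
            "rejected %d baseline rows with non-positive UACR (log2 undefined)",
            int(bad_uacr.sum()),
        )
        baselines = baselines.loc[~bad_uacr].reset_index(drop=True)
        visits = visits[visits["subject_id"].isin(baselines["subject_id"])].reset_index(
            drop=True
        )

    if "log2_uacr" not in baselines.columns:
        baselines = baselines.assign(log2_uacr=np.log2(baselines["uacr"]))
    if "baseline_egfr" not in baselines.columns:
        base = visits.loc[visits["time_years"] == 0.0].set_index("subject_id")["egfr"]
        baselines = baselines.assign(
            baseline_egfr=base.reindex(baselines["subject_id"]).to_numpy()
        )
    return baselines, visits


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def config_hash(payload: dict) -> str:
    """Stable hash of a JSON-serializable configuration."""
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
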