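"""Reading and writing observed-trial summary tables.

An observed two-stage drop-the-loser trial is exchanged as a small table
with one row per arm and columns

    arm_id, stage1_estimate, stage1_se, stage2_estimate, stage2_se

where the stage-2 columns are blank for every arm except the one carried
forward.  CSV and JSON (list-of-records) are both supported.  Arm ids are
1-based in files; indices inside :class:`~dtlshrink.trial_model.TrialOutcome`
are 0-based.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .trial_model import TrialDesign, TrialOutcome, select_best

__all__ = ["read_trial", "write_trial", "TRIAL_COLUMNS"]

TRIAL_COLUMNS = (
    "arm_id",
    "stage1_estimate",
    "stage1_se",
    "stage2_estimate",
    "stage2_se",
)


class TrialFormatError(ValueError):
    """Raised when a trial table violates the schema."""


def _load_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise TrialFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_trial(
    path: str | Path, small_k_fix: bool = False
) -> tuple[TrialOutcome, TrialDesign]:
    """Parse an observed trial table into an outcome and its design.

    Validates that exactly one arm carries stage-2 data.  If that arm is
    not the stage-1 maximum (selection made on other grounds), the trial is
    accepted with a warning — but the bias corrections assume max-selection
    and their guarantees are void.  The runner-up is then the best arm by
    stage-1 estimate other than the continued one.
    """
    df = _load_frame(path).sort_values("arm_id").reset_index(drop=True)
    k = len(df)
    if k < 2:
        raise TrialFormatError("a trial needs at least 2 arms")
    x = df["stage1_estimate"].to_numpy(dtype=float)
    se1 = df["stage1_se"].to_numpy(dtype=float)
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(se1)):
        raise TrialFormatError("stage-1 estimates and SEs must all be present")
    if not np.allclose(se1, se1[0], rtol=1e-12, atol=0.0):
        raise TrialFormatError(
            "the model assumes a common stage-1 SE across arms; got "
            f"{sorted(set(se1))}"
        )

    y = pd.to_numeric(df["stage2_estimate"], errors="coerce").to_numpy(dtype=float)
    se2 = pd.to_numeric(df["stage2_se"], errors="coerce").to_numpy(dtype=float)
    has_y = np.isfinite(y)
    if has_y.sum() != 1:
        raise TrialFormatError(
            f"exactly one arm must carry a stage-2 estimate; found {has_y.sum()}"
        )
    s = int(np.flatnonzero(has_y)[0])
    if not np.isfinite(se2[s]):
        raise TrialFormatError("the continued arm must carry a stage-2 SE")

    s_max, r_max = select_best(x)
    if s != s_max:
        warnings.warn(
            "the continued arm is not the stage-1 maximum; estimators assume "
            "max-selection, so bias-correction guarantees are void",
            UserWarning,
            stacklevel=2,
        )
        rest = np.delete(x, s)
        r = int(np.argmax(rest))
        if r >= s:
            r += 1
    else:
        r = r_max

    design = TrialDesign(
        k=k, sigma1=float(se1[0]), sigma2=float(se2[s]), small_k_fix=small_k_fix
    )
    outcome = TrialOutcome(x=x, s=s, r=r, y_s=float(y[s]))
    return outcome, design


def write_trial(
    outcome: TrialOutcome, design: TrialDesign, path: str | Path
) -> None:
    """Write an outcome back to the observed-trial CSV/JSON schema."""
    k = design.k
    rows = pd.DataFrame(
        {
            "arm_id": np.arange(1, k + 1),
            "stage1_estimate": outcome.x,
            "stage1_se": np.full(k, design.sigma1),
            "stage2_estimate": np.full(k, np.nan),
            "stage2_se": np.full(k, np.nan),
        }
    )
    rows.loc[outcome.s, "stage2_estimate"] = outcome.y_s
    rows.loc[outcome.s, "stage2_se"] = design.sigma2
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = rows.where(pd.notna(rows), None).to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    else:
        rows.to_csv(path, index=False)
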