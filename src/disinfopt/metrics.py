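"""Model performance criteria: R², RMSE, and mean bias error.

Conventions: errors are predicted − observed, so a negative MBE means the
model under-predicts contamination on average.  R² is 1 − SSE/SST about
the observed mean and may be negative for models worse than the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["r_squared", "rmse", "mbe", "EvaluationReport", "evaluate"]


def _pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size != p.size:
        raise ValueError(f"length mismatch: {o.size} observed vs {p.size} predicted")
    if o.size == 0:
        raise ValueError("empty input")
    return o, p


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 − SSE/SST."""
    o, p = _pair(observed, predicted)
    if o.size < 2:
        raise ValueError("R^2 needs at least 2 points")
    sst = float(((o - o.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    sse = float(((o - p) ** 2).sum())
    return 1.0 - sse / sst


def rmse(observed, predicted) -> float:
    """Root mean square error."""
    o, p = _pair(observed, predicted)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def mbe(observed, predicted) -> float:
    """Mean bias error, mean(predicted − observed)."""
    o, p = _pair(observed, predicted)
    return float(np.mean(p - o))


@dataclass(frozen=True)
class EvaluationReport:
    """R², RMSE and MBE of a prediction set, with its size and label."""

    r2: float
    rmse: float
    mbe: float
    n: int
    set_label: str = ""

    def to_dict(self) -> dict:
        return {"set": self.set_label, "n": self.n, "r2": self.r2,
                "rmse": self.rmse, "mbe": self.mbe}


def evaluate(observed, predicted, set_label: str = "") -> EvaluationReport:
    o, p = _pair(observed, predicted)
    return EvaluationReport(
        r2=r_squared(o, p), rmse=rmse(o, p), mbe=mbe(o, p),
        n=int(o.size), set_label=set_label,
    )
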