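"""Disinfection experiment data: treatments, summaries, replicate reconstruction.

The experimental unit is a *treatment* — a point in protocol space
(NaOCl % v/v, H2O2 %, immersion minutes).  Each treatment was run in
``n_reps`` replicates of ``seeds_per_rep`` seeds, so a replicate's
contamination percentage is discretized to multiples of
``100 / seeds_per_rep`` (20 % for 5 seeds).  Published summaries report
mean ± SE over replicates; because the outcome lattice is so coarse, the
per-replicate values can usually be recovered exactly from the printed
(mean, SE) pair by exhaustive search — that inversion is
:func:`reconstruct_replicates`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Treatment",
    "TreatmentSummary",
    "ReplicateObservation",
    "ExperimentTable",
    "NoSolutionError",
    "AmbiguousReconstructionError",
    "load_table1",
    "reconstruct_replicates",
    "expand_to_replicates",
    "split_train_test",
    "read_experiment_csv",
    "write_experiment_csv",
]

CSV_COLUMNS = ["naocl", "h2o2", "time", "mean", "se"]


class NoSolutionError(ValueError):
    """No replicate multiset reproduces the printed mean/SE pair."""


class AmbiguousReconstructionError(ValueError):
    """More than one replicate multiset reproduces the printed mean/SE pair."""

    def __init__(self, message: str, candidates: list[tuple[float, ...]]):
        super().__init__(message)
        self.candidates = candidates


@dataclass(frozen=True, order=True)
class Treatment:
    """A disinfection protocol: concentrations and immersion time."""

    naocl: float  # sodium hypochlorite, % v/v
    h2o2: float  # hydrogen peroxide, %
    time: float  # immersion time, minutes

    def __post_init__(self) -> None:
        for name in ("naocl", "h2o2", "time"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.naocl, self.h2o2, self.time], dtype=float)


@dataclass(frozen=True)
class TreatmentSummary:
    """Published per-treatment summary: mean ± SE contamination over replicates."""

    treatment: Treatment
    mean_contamination: float  # %, printed to 1 decimal
    se_contamination: float  # %, printed to 2 decimals
    n_reps: int = 3
    seeds_per_rep: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_contamination <= 100.0:
            raise ValueError(f"mean out of [0, 100]: {self.mean_contamination}")
        if self.se_contamination < 0:
            raise ValueError(f"negative SE: {self.se_contamination}")


@dataclass(frozen=True)
class ReplicateObservation:
    """One replicate's contamination %, a multiple of 100/seeds_per_rep."""

    treatment: Treatment
    contamination: float


@dataclass
class ExperimentTable:
    """Ordered collection of treatment summaries with unique treatments."""

    summaries: list[TreatmentSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for s in self.summaries:
            if s.treatment in seen:
                raise ValueError(f"duplicate treatment: {s.treatment}")
            seen.add(s.treatment)

    def __len__(self) -> int:
        return len(self.summaries)

    def __iter__(self):
        return iter(self.summaries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s.treatment.naocl, s.treatment.h2o2, s.treatment.time,
             s.mean_contamination, s.se_contamination)
            for s in self.summaries
        ]
        return pd.DataFrame(rows, columns=CSV_COLUMNS, dtype=float)


# Disinfection experiment: 19 treatments over NaOCl (% v/v), H2O2 (%),
# immersion time (min); contamination % mean +/- SE over 3 replicates of
# 5 seeds each.  Also shipped as data/table1.csv.
_TABLE1_ROWS: tuple[tuple[float, float, float, float, float], ...] = (
    (0, 0, 0, 100.0, 0.00),
    (0, 10, 5, 86.7, 6.67),
    (0, 10, 10, 86.7, 6.67),
    (0, 10, 20, 86.7, 6.67),
    (0, 20, 5, 86.7, 6.67),
    (0, 20, 10, 86.7, 6.67),
    (0, 20, 20, 73.3, 6.67),
    (0, 30, 5, 86.7, 6.67),
    (0, 30, 10, 80.0, 11.55),
    (0, 30, 20, 73.3, 6.67),
    (5, 0, 5, 53.3, 17.64),
    (5, 0, 10, 26.7, 6.67),
    (5, 0, 15, 0.0, 0.00),
    (10, 0, 5, 6.7, 6.67),
    (10, 0, 10, 0.0, 0.00),
    (10, 0, 15, 0.0, 0.00),
    (15, 0, 5, 6.7, 6.67),
    (15, 0, 10, 0.0, 0.00),
    (15, 0, 15, 0.0, 0.00),
)


def load_table1() -> ExperimentTable:
    """The packaged cannabis-seed disinfection experiment (19 treatments)."""
    return ExperimentTable(
        [
            TreatmentSummary(Treatment(n, h, t), m, se)
            for n, h, t, m, se in _TABLE1_ROWS
        ]
    )


def packaged_csv_path() -> Path:
    """Path to the packaged CSV copy of the experiment table."""
    return Path(str(resources.files("disinfopt").joinpath("data/table1.csv")))


def _mean_se(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if len(arr) < 2:
        return mean, 0.0
    # SE convention throughout: sample SD (n-1 divisor) / sqrt(n)
    se = float(arr.std(ddof=1) / np.sqrt(len(arr)))
    return mean, se


def replicate_mean_se(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error (sample SD / sqrt(n)) of replicate values."""
    return _mean_se(values)


def reconstruct_replicates(
    summary: TreatmentSummary,
    mean_tol: float = 0.05,
    se_tol: float = 0.005,
) -> list[ReplicateObservation]:
    """Invert a printed mean ± SE into the unique per-replicate multiset.

    Enumerates every multiset of ``n_reps`` values from the contamination
    lattice {0, 100/seeds, ..., 100} and keeps those whose recomputed mean
    and SE fall within half a printed ULP (1 decimal for the mean, 2 for
    the SE) of the published pair.

    Raises
    ------
    NoSolutionError
        If no multiset matches.
    AmbiguousReconstructionError
        If more than one matches; the candidates are attached to the error.
    """
    step = 100.0 / summary.seeds_per_rep
    levels = [step * k for k in range(summary.seeds_per_rep + 1)]
    matches: list[tuple[float, ...]] = []
    for combo in itertools.combinations_with_replacement(levels, summary.n_reps):
        mean, se = _mean_se(combo)
        if (
            abs(mean - summary.mean_contamination) <= mean_tol
            and abs(se - summary.se_contamination) <= se_tol
        ):
            matches.append(combo)
    label = (
        f"({summary.treatment.naocl}, {summary.treatment.h2o2}, "
        f"{summary.treatment.time})"
    )
    if not matches:
        raise NoSolutionError(
            f"no replicate multiset reproduces mean={summary.mean_contamination}"
            f" SE={summary.se_contamination} for treatment {label}"
        )
    if len(matches) > 1:
        raise AmbiguousReconstructionError(
            f"{len(matches)} multisets reproduce mean={summary.mean_contamination}"
            f" SE={summary.se_contamination} for treatment {label}: {matches}",
            matches,
        )
    return [ReplicateObservation(summary.treatment, v) for v in matches[0]]


def expand_to_replicates(table: ExperimentTable) -> list[ReplicateObservation]:
    """Reconstruct every summary's replicates; n_rows × n_reps observations."""
    out: list[ReplicateObservation] = []
    for summary in table:
        try:
            out.extend(reconstruct_replicates(summary))
        except (NoSolutionError, AmbiguousReconstructionError) as exc:
            raise type(exc)(
                f"reconstruction failed for treatment "
                f"({summary.treatment.naocl}, {summary.treatment.h2o2}, "
                f"{summary.treatment.time}): {exc}"
            ) from exc
    return out


def observations_to_arrays(
    observations: Iterable[ReplicateObservation],
) -> tuple[np.ndarray, np.ndarray]:
    """(n, 3) treatment matrix and (n,) contamination vector."""
    obs = list(observations)
    X = np.array([o.treatment.as_array() for o in obs], dtype=float)
    y = np.array([o.contamination for o in obs], dtype=float)
    return X, y


def split_train_test(
    observations: Sequence[ReplicateObservation],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[ReplicateObservation], list[ReplicateObservation]]:
    """Seeded, treatment-stratified partition into train and test sets.

    The split is exhaustive and disjoint.  Stratification guarantees at
    least one replicate of every treatment stays in training (so the model
    never extrapolates to a wholly unseen protocol); if the requested
    fraction cannot be honored under that constraint, the test set is
    simply smaller.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    obs = list(observations)
    if len(obs) < 2:
        raise ValueError("need at least 2 observations to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(obs))
    n_test_target = int(round(test_fraction * len(obs)))
    remaining_per_treatment: dict[Treatment, int] = {}
    for o in obs:
        remaining_per_treatment[o.treatment] = (
            remaining_per_treatment.get(o.treatment, 0) + 1
        )
    # with one observation per treatment, stratification is vacuous and
    # would empty the test set; fall back to a plain random split
    stratify = any(c > 1 for c in remaining_per_treatment.values())
    test_idx: set[int] = set()
    for i in order:
        if len(test_idx) >= n_test_target:
            break
        t = obs[i].treatment
        if not stratify or remaining_per_treatment[t] > 1:  # keep >= 1 in train
            test_idx.add(int(i))
            remaining_per_treatment[t] -= 1
    train = [o for i, o in enumerate(obs) if i not in test_idx]
    test = [o for i, o in enumerate(obs) if i in test_idx]
    return train, test


def read_experiment_csv(path: str | Path) -> ExperimentTable:
    """Read a naocl,h2o2,time,mean,se CSV into an :class:`ExperimentTable`."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in CSV_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad or coerced.isna().any():
            rows = bad or df.index[coerced.isna()].tolist()
            raise ValueError(f"{path}: non-numeric cell(s) in column {col!r}, row(s) {rows}")
        df[col] = coerced
    summaries = []
    for idx, row in df.iterrows():
        try:
            summaries.append(
                TreatmentSummary(
                    Treatment(row["naocl"], row["h2o2"], row["time"]),
                    float(row["mean"]),
                    float(row["se"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: invalid row {idx}: {exc}") from exc
    try:
        return ExperimentTable(summaries)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_experiment_csv(table: ExperimentTable, path: str | Path) -> None:
    """Write an :class:`ExperimentTable` to CSV (round-trips with read)."""
    table.to_frame().to_csv(path, index=False)
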