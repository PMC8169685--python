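"""Linear-model normalization of VMR traces.

Raw displacement traces carry three nuisance components on top of the
stimulus-evoked signal: each larva's own baseline locomotor level, a
per-well light-intensity effect, and a batch (biological-replicate) effect.
These are removed with an ordinary-least-squares decomposition fitted on the
dark-acclimation baseline window only, so that post-offset treatment effects
cannot leak into the correction:

    baseline_sec ~ intercept + batch + well_position        (OLS, per second)
    larva residual = larva's baseline mean - OLS prediction

The predicted baseline of a larva (intercept + batch coefficient + well
coefficient + larva residual) equals its own baseline-window mean, so the
subtraction removes batch shifts, well-position gradients and idiosyncratic
activity in one step.  A single global offset, chosen as the smallest value
that keeps every normalized second non-negative on the training traces, is
then added because displacement is a non-negative quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import MappingError, WindowRangeError
from .plate_io import PlateTrace

__all__ = ["NormalizationModel", "fit_normalization", "apply_normalization"]


@dataclass
class NormalizationModel:
    """Fitted baseline decomposition plus the non-negativity offset.

    Batch and well coefficients use treatment (reference-level) coding: the
    first level in sorted order is the reference with coefficient 0, so with
    no planted effects all reported coefficients are near zero.
    """

    intercept: float
    batch_effects: dict[str, float]
    well_effects: dict[str, float]
    larva_baseline: dict[tuple[str, str], float]  # residual deviation per larva
    offset: float
    baseline_window: tuple[int, int]  # [start, end) in t_sec bins
    rank_deficient: bool = False
    info: dict = field(default_factory=dict)

    def predicted_baseline(self, plate: str, well: str, batch: str) -> float:
        key = (str(plate), str(well))
        if key not in self.larva_baseline:
            raise MappingError(f"larva {key} was not seen during fitting")
        if str(batch) not in self.batch_effects:
            raise MappingError(f"batch {batch!r} was not seen during fitting")
        well_label = str(well)
        if well_label not in self.well_effects:
            raise MappingError(f"well position {well_label!r} was not seen during fitting")
        return (
            self.intercept
            + self.batch_effects[str(batch)]
            + self.well_effects[well_label]
            + self.larva_baseline[key]
        )

    def to_text(self, path: str | Path) -> Path:
        """Serialize as a plain-text key/value file."""
        path = Path(path)
        lines = [
            f"intercept\t{self.intercept!r}",
            f"offset\t{self.offset!r}",
            f"baseline_window\t{self.baseline_window[0]}\t{self.baseline_window[1]}",
            f"rank_deficient\t{int(self.rank_deficient)}",
        ]
        for b, v in sorted(self.batch_effects.items()):
            lines.append(f"batch\t{b}\t{v!r}")
        for w, v in sorted(self.well_effects.items()):
            lines.append(f"well\t{w}\t{v!r}")
        for (p, w), v in sorted(self.larva_baseline.items()):
            lines.append(f"larva\t{p}\t{w}\t{v!r}")
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_text(cls, path: str | Path) -> "NormalizationModel":
        intercept = offset = 0.0
        window = (0, 0)
        rank_deficient = False
        batches: dict[str, float] = {}
        wells: dict[str, float] = {}
        larvae: dict[tuple[str, str], float] = {}
        for line in Path(path).read_text().splitlines():
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "intercept":
                intercept = float(parts[1])
            elif parts[0] == "offset":
                offset = float(parts[1])
            elif parts[0] == "baseline_window":
                window = (int(parts[1]), int(parts[2]))
            elif parts[0] == "rank_deficient":
                rank_deficient = bool(int(parts[1]))
            elif parts[0] == "batch":
                batches[parts[1]] = float(parts[2])
            elif parts[0] == "well":
                wells[parts[1]] = float(parts[2])
            elif parts[0] == "larva":
                larvae[(parts[1], parts[2])] = float(parts[3])
        return cls(intercept, batches, wells, larvae, offset, window, rank_deficient)


def _larva_table(trace: PlateTrace, window: tuple[int, int]) -> pd.DataFrame:
    df = trace.records
    sub = df[(df["t_sec"] >= window[0]) & (df["t_sec"] < window[1])]
    if not len(sub):
        raise WindowRangeError("baseline window selects no records")
    agg = (
        sub.groupby(["plate", "well"], observed=True)
        .agg(
            ybar=("displacement_cm", "mean"),
            batch=("batch", "first"),
        )
        .reset_index()
    )
    return agg


def fit_normalization(
    trace: PlateTrace,
    baseline_window: tuple[int, int] | None = None,
) -> NormalizationModel:
    """Fit the baseline decomposition on the dark-acclimation window.

    ``baseline_window`` is a half-open ``[start, end)`` range of ``t_sec``
    bins; it defaults to the full initial dark segment and must end at or
    before the light-on event so that no stimulus-evoked activity enters the
    fit.  The model is fitted on controls and treated wells jointly.
    """
    light_on = trace.protocol.light_on
    if baseline_window is None:
        baseline_window = (0, light_on)
    start, end = baseline_window
    if not (0 <= start < end <= light_on):
        raise WindowRangeError(
            f"baseline window {baseline_window} must lie within the dark "
            f"acclimation segment [0, {light_on})"
        )

    larvae = _larva_table(trace, baseline_window)
    batch_levels = sorted(map(str, larvae["batch"].unique()))
    well_levels = sorted(map(str, larvae["well"].unique()))
    b_idx = {b: i for i, b in enumerate(batch_levels)}
    w_idx = {w: i for i, w in enumerate(well_levels)}

    n = len(larvae)
    n_b, n_w = len(batch_levels) - 1, len(well_levels) - 1
    X = np.zeros((n, 1 + n_b + n_w))
    X[:, 0] = 1.0
    for i, (batch, well) in enumerate(zip(larvae["batch"].astype(str), larvae["well"].astype(str))):
        bi, wi = b_idx[batch], w_idx[well]
        if bi > 0:
            X[i, bi] = 1.0
        if wi > 0:
            X[i, n_b + wi] = 1.0
    y = larvae["ybar"].to_numpy(float)

    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rank_deficient = rank < X.shape[1]
    if rank_deficient:
        warnings.warn(
            "rank-deficient normalization design (aliased batch/well levels); "
            "using the minimum-norm least-squares solution",
            stacklevel=2,
        )

    intercept = float(beta[0])
    batch_effects = {batch_levels[0]: 0.0}
    for b in batch_levels[1:]:
        batch_effects[b] = float(beta[b_idx[b]])
    well_effects = {well_levels[0]: 0.0}
    for w in well_levels[1:]:
        well_effects[w] = float(beta[n_b + w_idx[w]])

    fitted = X @ beta
    resid = y - fitted
    larva_baseline = {
        (str(p), str(w)): float(r)
        for p, w, r in zip(larvae["plate"], larvae["well"], resid)
    }

    model = NormalizationModel(
        intercept=intercept,
        batch_effects=batch_effects,
        well_effects=well_effects,
        larva_baseline=larva_baseline,
        offset=0.0,
        baseline_window=(start, end),
        rank_deficient=rank_deficient,
    )
    adjusted = _adjusted_values(trace, model)
    model.offset = float(max(0.0, -adjusted.min())) if adjusted.size else 0.0
    return model


def _adjusted_values(trace: PlateTrace, model: NormalizationModel) -> np.ndarray:
    df = trace.records
    meta = (
        df.groupby(["plate", "well"], observed=True)["batch"]
        .first()
        .reset_index()
    )
    meta["_pred"] = [
        model.predicted_baseline(p, w, b)
        for p, w, b in zip(meta["plate"], meta["well"], meta["batch"])
    ]
    merged = df[["plate", "well"]].merge(
        meta[["plate", "well", "_pred"]], on=["plate", "well"], how="left"
    )
    pred = merged["_pred"].to_numpy(float)
    return df["displacement_cm"].to_numpy(float) - pred


def apply_normalization(trace: PlateTrace, model: NormalizationModel) -> PlateTrace:
    """Subtract the predicted baseline and add the non-negativity offset.

    ``normalized = raw - (intercept + batch + well + larva residual) + offset``.
    On the traces the model was fitted to, the minimum normalized value is
    exactly zero when the offset is binding.  Factor levels or larvae the
    model has never seen raise :class:`~vmrscreen.exceptions.MappingError`.
    """
    adjusted = _adjusted_values(trace, model) + model.offset
    return trace.with_displacement(adjusted)
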