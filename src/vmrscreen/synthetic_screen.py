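"""Synthetic VMR plates, screens and dose-response readouts.

The generative model for a larva's per-second displacement is

    d(w, t) = max(0, b_w + u_batch + v_well + A_w * exp(-(k-1)/tau_w) * 1[k >= 1] + eps_wt)

where ``k = t - t_off`` is the 1-based post-light-offset second, ``b_w`` is
the larva's dark baseline level, ``u_batch`` an additive batch (biological
replicate) effect, ``v_well`` an additive per-well light-intensity effect
proportional to the plate column, ``A_w`` the startle amplitude of a
responding larva and ``eps`` Gaussian measurement noise.  Dead (toxic-well)
larvae emit near-zero displacement throughout.

Default genotype parameters are calibrated so that the grand mean
displacement in the first second after light offset is 0.281 cm for
wild-type larvae and 0.127 cm for the Q344X rhodopsin-truncation model,
the group means observed for those genotypes under a 0.01 lx scotopic
light-off stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve, logistic_response
from .exceptions import DesignError, DomainError, ProtocolError
from .plate_io import (
    SCOTOPIC_PROTOCOL,
    PlateTrace,
    StimulusProtocol,
    TRACE_COLUMNS,
    well_name,
)

__all__ = [
    "GenotypeParams",
    "WT_PARAMS",
    "Q344X_PARAMS",
    "DrugEffect",
    "DrugSpec",
    "ScreenDesign",
    "ScreenSim",
    "simulate_plate",
    "simulate_screen",
    "simulate_dose_response",
    "redox_library",
]


@dataclass(frozen=True)
class GenotypeParams:
    """Generative parameters for one genotype.

    ``startle_amplitude`` is the mean displacement added in the first second
    after light offset (cm); the burst then decays exponentially with time
    constant ``startle_tau`` (s).  ``baseline_rate`` is the mean dark
    locomotor level (cm/s) and ``baseline_dispersion`` the between-larvae SD
    of that level.  ``response_probability`` is the fraction of larvae that
    startle at all; ``noise_scale`` is the per-second measurement noise SD.
    """

    baseline_rate: float = 0.08
    baseline_dispersion: float = 0.02
    startle_amplitude: float = 0.201
    startle_tau: float = 3.0
    response_probability: float = 1.0
    noise_scale: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "baseline_rate",
            "baseline_dispersion",
            "startle_amplitude",
            "startle_tau",
            "noise_scale",
        ):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if not (0 <= self.response_probability <= 1):
            raise DomainError("response_probability must lie in [0, 1]")


#: Wild-type defaults: baseline 0.08 + startle 0.201 = 0.281 cm at offset+1 s.
WT_PARAMS = GenotypeParams(startle_amplitude=0.201)

#: Q344X defaults: baseline 0.08 + startle 0.047 = 0.127 cm at offset+1 s.
Q344X_PARAMS = GenotypeParams(startle_amplitude=0.047)


@dataclass(frozen=True)
class DrugEffect:
    """Multiplicative modifiers a treatment applies to the startle burst.

    ``tau_multiplier > 1`` prolongs the burst (a sustained light-off VMR);
    ``lethality`` is the per-larva probability of death, which silences the
    well entirely.
    """

    amplitude_multiplier: float = 1.0
    tau_multiplier: float = 1.0
    toxic: bool = False
    lethality: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_multiplier < 0 or self.tau_multiplier < 0:
            raise DomainError("effect multipliers must be non-negative")
        if not (0 <= self.lethality <= 1):
            raise DomainError("lethality must lie in [0, 1]")


#: Sustained-response effect size used for planted hits: a burst 1.5x larger
#: that decays 4x more slowly, mirroring a drug that prolongs the light-off VMR.
HIT_EFFECT = DrugEffect(amplitude_multiplier=1.5, tau_multiplier=4.0)


@dataclass(frozen=True)
class DrugSpec:
    name: str
    effect: DrugEffect = field(default_factory=DrugEffect)
    is_hit: bool = False


@dataclass(frozen=True)
class ScreenDesign:
    """Layout of a two-replicate drug screen with shared vehicle controls."""

    seed: int
    n_drugs: int = 84
    replicates_per_drug: int = 2
    larvae_per_replicate: int = 24
    control_replicates: int = 9
    control_group_size: int = 48
    batch_effect_scale: float = 0.03
    well_intensity_scale: float = 0.002
    vehicle_treatment: str = "DMSO"

    def __post_init__(self) -> None:
        for name in (
            "replicates_per_drug",
            "larvae_per_replicate",
            "control_replicates",
            "control_group_size",
        ):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be positive")
        if self.n_drugs < 0:
            raise DesignError("n_drugs must be >= 0")
        if self.batch_effect_scale < 0 or self.well_intensity_scale < 0:
            raise DesignError("effect scales must be non-negative")


def _assign_wells(n: int, plate_prefix: str) -> tuple[list[str], list[str], np.ndarray]:
    """Cycle larvae through A1..H12, opening a new plate every 96 wells."""
    plates, wells, cols = [], [], np.empty(n, dtype=np.int64)
    for i in range(n):
        row, col = divmod(i % 96, 12)
        plates.append(f"{plate_prefix}_p{i // 96 + 1:02d}")
        wells.append(well_name(row, col + 1))
        cols[i] = col + 1
    return plates, wells, cols


def _render_records(
    layout: pd.DataFrame,
    protocol: StimulusProtocol,
    rng: np.random.Generator,
    noise_scale: float,
) -> pd.DataFrame:
    """Vectorized rendering of per-second displacement for a larva layout.

    ``layout`` must carry one row per larva with columns ``plate, batch,
    well, genotype, treatment, dose_uM, level, amplitude, tau, dead`` where
    ``level = baseline + batch effect + well-intensity effect``.
    """
    t_off = protocol.light_off  # raises ProtocolError when absent
    total = protocol.total_duration_s
    n = len(layout)
    level = layout["level"].to_numpy(float)[:, None]
    d = np.broadcast_to(level, (n, total)).copy()

    # startle burst: bins t_off .. total-1 are post-offset seconds 1 .. total-t_off
    k = np.arange(1, total - t_off + 1, dtype=float)
    tau = layout["tau"].to_numpy(float)[:, None]
    amp = layout["amplitude"].to_numpy(float)[:, None]
    with np.errstate(divide="ignore"):
        decay = np.exp(-np.where(tau > 0, (k[None, :] - 1.0) / tau, np.inf))
    decay[:, 0] = 1.0  # first post-offset second carries the full amplitude
    d[:, t_off:] += amp * decay

    d += rng.normal(0.0, noise_scale, size=(n, total))
    np.maximum(d, 0.0, out=d)

    dead = layout["dead"].to_numpy(bool)
    if dead.any():
        # immobile larvae: residual tracking jitter only
        d[dead] = rng.uniform(0.0, 0.001, size=(int(dead.sum()), total))

    t_sec = np.tile(np.arange(total, dtype=np.int64), n)
    rec = {
        "plate": pd.Categorical(np.repeat(layout["plate"].to_numpy(), total)),
        "batch": pd.Categorical(np.repeat(layout["batch"].to_numpy(), total)),
        "well": pd.Categorical(np.repeat(layout["well"].to_numpy(), total)),
        "genotype": pd.Categorical(np.repeat(layout["genotype"].to_numpy(), total)),
        "treatment": pd.Categorical(np.repeat(layout["treatment"].to_numpy(), total)),
        "dose_uM": np.repeat(layout["dose_uM"].to_numpy(float), total),
        "t_sec": t_sec,
        "displacement_cm": d.ravel(),
    }
    return pd.DataFrame(rec, columns=list(TRACE_COLUMNS))


def _draw_larvae(
    rng: np.random.Generator,
    n: int,
    params: GenotypeParams,
    effect: DrugEffect,
) -> dict[str, np.ndarray]:
    base = rng.normal(params.baseline_rate, params.baseline_dispersion, n)
    responder = rng.random(n) < params.response_probability
    dead = rng.random(n) < effect.lethality
    amp = np.where(responder, params.startle_amplitude * effect.amplitude_multiplier, 0.0)
    tau = np.full(n, params.startle_tau * effect.tau_multiplier)
    return {"base": base, "amplitude": amp, "tau": tau, "dead": dead}


def simulate_plate(
    genotype_params: GenotypeParams,
    protocol: StimulusProtocol = SCOTOPIC_PROTOCOL,
    n_batches: int = 18,
    larvae_per_batch: int = 48,
    *,
    genotype: str = "WT",
    treatment: str = "DMSO",
    dose_um: float = 0.0,
    drug_effect: DrugEffect | None = None,
    batch_effect_scale: float = 0.03,
    well_intensity_scale: float = 0.002,
    batch_prefix: str = "b",
    seed: int,
) -> PlateTrace:
    """Simulate one treatment arm across ``n_batches`` biological replicates.

    Identical seeds produce identical traces.  Batch effects are drawn once
    per batch from ``N(0, batch_effect_scale)``; the per-well intensity
    effect is ``well_intensity_scale * (column - 6.5)``, a linear proxy for
    lamp inhomogeneity across the plate.
    """
    protocol.light_off  # validate up front -> ProtocolError
    effect = drug_effect or DrugEffect()
    rng = np.random.default_rng(seed)
    n = n_batches * larvae_per_batch
    batch_ids = [f"{batch_prefix}{i + 1:02d}" for i in range(n_batches)]
    batch_shift = rng.normal(0.0, batch_effect_scale, n_batches)

    rows = []
    for bi, batch in enumerate(batch_ids):
        plates, wells, cols = _assign_wells(larvae_per_batch, f"{batch}")
        draws = _draw_larvae(rng, larvae_per_batch, genotype_params, effect)
        rows.append(
            pd.DataFrame(
                {
                    "plate": plates,
                    "batch": batch,
                    "well": wells,
                    "genotype": genotype,
                    "treatment": treatment,
                    "dose_uM": float(dose_um),
                    "level": draws["base"]
                    + batch_shift[bi]
                    + well_intensity_scale * (cols - 6.5),
                    "amplitude": draws["amplitude"],
                    "tau": draws["tau"],
                    "dead": draws["dead"],
                }
            )
        )
    layout = pd.concat(rows, ignore_index=True)
    records = _render_records(layout, protocol, rng, genotype_params.noise_scale)
    return PlateTrace(protocol, records)


def redox_library(
    n_drugs: int = 84,
    n_toxic: int = 16,
    hit_index: int | None = 41,
    hit_effect: DrugEffect = HIT_EFFECT,
) -> tuple[DrugSpec, ...]:
    """A drug library shaped like a small redox screening collection:
    ``n_toxic`` lethal compounds, one planted sustained-response hit, and
    inert compounds for the remainder.  Assignment is deterministic.
    """
    if n_drugs < 0:
        raise DesignError("n_drugs must be >= 0")
    if n_toxic > n_drugs:
        raise DesignError(f"cannot plant {n_toxic} toxic drugs among {n_drugs}")
    if hit_index is not None and not (0 <= hit_index < n_drugs):
        raise DesignError(f"hit_index {hit_index} outside the library")
    specs: list[DrugSpec] = []
    toxic_budget = n_toxic
    for i in range(n_drugs):
        name = f"drug_{i + 1:03d}"
        if hit_index is not None and i == hit_index:
            specs.append(DrugSpec(name, hit_effect, is_hit=True))
        elif toxic_budget > 0:
            specs.append(
                DrugSpec(name, DrugEffect(toxic=True, lethality=1.0))
            )
            toxic_budget -= 1
        else:
            specs.append(DrugSpec(name))
    if toxic_budget > 0:
        raise DesignError("could not place all toxic drugs")
    return tuple(specs)


@dataclass
class ScreenSim:
    """A simulated screen: the combined trace plus the ground-truth table."""

    trace: PlateTrace
    truth: pd.DataFrame
    design: ScreenDesign


def simulate_screen(
    design: ScreenDesign,
    library: Sequence[DrugSpec],
    protocol: StimulusProtocol = SCOTOPIC_PROTOCOL,
    genotype_params: GenotypeParams = Q344X_PARAMS,
    *,
    genotype: str = "Q344X",
    dose_um: float = 10.0,
) -> ScreenSim:
    """Simulate every replicate of a drug screen plus vehicle controls.

    Vehicle (DMSO, dose 0) larvae are generated in every batch with an
    identity :class:`DrugEffect`.  Replicates of a drug land in different
    batches.  The returned truth table records toxicity/hit labels and the
    planted effect parameters for downstream validation.
    """
    protocol.light_off
    if len({s.name for s in library}) != len(library):
        raise DesignError("duplicate drug names in library")
    rng = np.random.default_rng(design.seed)
    n_b = design.control_replicates
    batch_ids = [f"b{i + 1:02d}" for i in range(n_b)]
    batch_shift = rng.normal(0.0, design.batch_effect_scale, n_b)
    shift = max(1, n_b // 2)

    # per-batch well cursors so wells/plates stay unique within a batch
    cursors = {b: 0 for b in batch_ids}

    def take_wells(batch: str, count: int):
        start = cursors[batch]
        cursors[batch] = start + count
        plates, wells, cols = [], [], np.empty(count, dtype=np.int64)
        for j, i in enumerate(range(start, start + count)):
            row, col = divmod(i % 96, 12)
            plates.append(f"{batch}_p{i // 96 + 1:02d}")
            wells.append(well_name(row, col + 1))
            cols[j] = col + 1
        return plates, wells, cols

    layouts = []

    def add_group(batch_i: int, count: int, treatment: str, dose: float, effect: DrugEffect):
        batch = batch_ids[batch_i]
        plates, wells, cols = take_wells(batch, count)
        draws = _draw_larvae(rng, count, genotype_params, effect)
        layouts.append(
            pd.DataFrame(
                {
                    "plate": plates,
                    "batch": batch,
                    "well": wells,
                    "genotype": genotype,
                    "treatment": treatment,
                    "dose_uM": float(dose),
                    "level": draws["base"]
                    + batch_shift[batch_i]
                    + design.well_intensity_scale * (cols - 6.5),
                    "amplitude": draws["amplitude"],
                    "tau": draws["tau"],
                    "dead": draws["dead"],
                }
            )
        )

    for bi in range(n_b):
        add_group(bi, design.control_group_size, design.vehicle_treatment, 0.0, DrugEffect())
    for di, spec in enumerate(library):
        for r in range(design.replicates_per_drug):
            add_group(
                (di + r * shift) % n_b,
                design.larvae_per_replicate,
                spec.name,
                dose_um,
                spec.effect,
            )

    layout = pd.concat(layouts, ignore_index=True)
    records = _render_records(layout, protocol, rng, genotype_params.noise_scale)
    truth = pd.DataFrame(
        {
            "drug": [s.name for s in library],
            "is_toxic": [s.effect.toxic for s in library],
            "is_hit": [s.is_hit for s in library],
            "amplitude_multiplier": [s.effect.amplitude_multiplier for s in library],
            "tau_multiplier": [s.effect.tau_multiplier for s in library],
            "lethality": [s.effect.lethality for s in library],
        }
    )
    return ScreenSim(PlateTrace(protocol, records), truth, design)


def simulate_dose_response(
    curve: DoseResponseCurve,
    doses_m: Sequence[float],
    noise_sd: float,
    *,
    n_wells: int = 4,
    seed: int,
    experiment: str = "E1",
) -> pd.DataFrame:
    """Simulate a normalized-scale luminescence table on a dose grid.

    Each dose gets ``n_wells`` readings equal to the logistic response plus
    Gaussian noise; output is deterministic per seed.
    """
    doses = np.asarray(doses_m, float)
    if np.any(doses <= 0):
        raise DomainError("doses must be positive molar concentrations")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    dose_rep = np.repeat(doses, n_wells)
    resp = logistic_response(
        dose_rep, curve.bottom, curve.top, curve.pxc50, curve.hill, curve.orientation
    )
    resp = resp + rng.normal(0.0, noise_sd, resp.shape)
    return pd.DataFrame(
        {
            "experiment": experiment,
            "dose_M": dose_rep,
            "well": np.tile(np.arange(1, n_wells + 1), doses.size),
            "luminescence": resp,
        }
    )
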