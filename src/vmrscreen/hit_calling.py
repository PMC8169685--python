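"""The drug-screening funnel: toxicity, replicate consistency, significance.

A screened compound becomes a hit in a given post-offset window when

1. it is not toxic (at most half of its larvae classified dead/immobile),
2. its two biological replicates are consistent - the high-dimensional
   two-sample test between the replicate window matrices returns p > 0.9,
   i.e. the replicates are far more similar than a typical null draw, and
3. the drug-treated VMR differs significantly from the vehicle (DMSO)
   control - Hotelling's T-squared p < 0.05, by default required of each
   replicate separately.

Both cutoffs are strict inequalities; a consistency p-value of exactly 0.9
fails.  The funnel summary mirrors the screening table layout: starting
drugs, non-toxic drugs, consistent drugs per window, and consistent+
significant drugs (hits) per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DesignError, DomainError, InsufficientSampleError
from .mv_tests import TestResult, hd_two_sample_test, hotelling_t2
from .normalization import apply_normalization, fit_normalization
from .plate_io import PlateTrace, WindowMatrix, extract_window

__all__ = [
    "ScreenConfig",
    "WindowCall",
    "HitRecord",
    "ScreenSummary",
    "ScreenResult",
    "consistency_pass",
    "flag_toxic",
    "replicate_consistency",
    "drug_vs_control",
    "run_screen",
    "summarize_screen",
]

Window = tuple[int, int]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and modes of the hit-calling pipeline."""

    seed: int
    windows: tuple[Window, ...] = ((1, 1), (1, 30))
    consistency_threshold: float = 0.9
    alpha: float = 0.05
    movement_threshold_frac: float = 0.05
    toxic_fraction: float = 0.5
    n_boot: int = 1000
    comparison: str = "per_replicate"  # or "pooled"
    normalize: bool = True
    vehicle_treatment: str = "DMSO"

    def __post_init__(self) -> None:
        for name in ("consistency_threshold", "alpha", "toxic_fraction"):
            if not (0 < getattr(self, name) < 1):
                raise DomainError(f"{name} must lie in (0, 1)")
        if not self.windows:
            raise DesignError("at least one analysis window is required")
        if self.comparison not in ("per_replicate", "pooled"):
            raise DomainError("comparison must be 'per_replicate' or 'pooled'")


def consistency_pass(p_value: float, threshold: float = 0.9) -> bool:
    """Strict similarity rule: replicates pass only when p > threshold."""
    return p_value > threshold


@dataclass
class WindowCall:
    window: Window
    consistency_p: float | None
    consistency_pass: bool
    control_p: float | None
    significant: bool
    hit: bool
    control_p_per_replicate: tuple[float, ...] = ()


@dataclass
class HitRecord:
    drug: str
    toxic: bool
    dead_fraction: float
    calls: dict[Window, WindowCall] = field(default_factory=dict)


@dataclass
class ScreenSummary:
    """Funnel counts per window, in screening-table shape."""

    n_starting: int
    n_non_toxic: int
    n_consistent: dict[Window, int]
    n_hits: dict[Window, int]
    hit_drugs: dict[Window, tuple[str, ...]]

    def to_dict(self) -> dict:
        return {
            "starting_drugs": self.n_starting,
            "non_toxic_drugs": self.n_non_toxic,
            "windows": {
                f"{w[0]}-{w[1]}s": {
                    "consistent": self.n_consistent[w],
                    "consistent_and_significant": self.n_hits[w],
                    "hits": list(self.hit_drugs[w]),
                }
                for w in self.n_consistent
            },
        }


@dataclass
class ScreenResult:
    records: list[HitRecord]
    summary: ScreenSummary
    table: pd.DataFrame


def _larva_totals(records: pd.DataFrame) -> pd.Series:
    return records.groupby(["plate", "well"], observed=True)["displacement_cm"].sum()


def flag_toxic(
    drug_records: pd.DataFrame,
    healthy_median: float,
    movement_threshold_frac: float = 0.05,
    toxic_fraction: float = 0.5,
) -> tuple[bool, dict]:
    """Flag a drug as toxic from the raw traces of its pooled replicates.

    A larva counts as dead/immobile when its total recorded displacement is
    below ``movement_threshold_frac`` of the healthy-control median total;
    the drug is toxic when the dead fraction exceeds ``toxic_fraction``.
    """
    if not len(drug_records):
        raise InsufficientSampleError("empty trace for toxicity flagging")
    if healthy_median <= 0:
        raise DomainError("healthy-control median total must be positive")
    totals = _larva_totals(drug_records)
    dead = totals < movement_threshold_frac * healthy_median
    dead_fraction = float(dead.mean())
    return dead_fraction > toxic_fraction, {
        "dead_fraction": dead_fraction,
        "n_larvae": int(totals.size),
        "threshold_cm": float(movement_threshold_frac * healthy_median),
    }


@dataclass
class ConsistencyResult:
    p_value: float
    passed: bool
    test: TestResult


def replicate_consistency(
    rep1: WindowMatrix,
    rep2: WindowMatrix,
    n_boot: int = 1000,
    *,
    seed: int,
    threshold: float = 0.9,
) -> ConsistencyResult:
    """Similarity of two biological replicates over the same window.

    Runs the high-dimensional two-sample test between the replicate
    matrices; a large p-value indicates similarity and the pair passes when
    ``p > threshold`` (strictly).
    """
    if (rep1.start_offset, rep1.end_offset, rep1.event) != (
        rep2.start_offset,
        rep2.end_offset,
        rep2.event,
    ):
        raise DesignError("replicate windows must share the same window spec")
    res = hd_two_sample_test(rep1, rep2, n_boot=n_boot, seed=seed)
    return ConsistencyResult(res.p_value, consistency_pass(res.p_value, threshold), res)


@dataclass
class SignificanceResult:
    p_value: float
    passed: bool
    test: TestResult


def drug_vs_control(
    drug: WindowMatrix, vehicle: WindowMatrix, alpha: float = 0.05
) -> SignificanceResult:
    """Hotelling's T-squared comparison of a drug group against vehicle."""
    res = hotelling_t2(drug, vehicle)
    return SignificanceResult(res.p_value, res.p_value < alpha, res)


def _flat_rows(rec: HitRecord) -> list[dict]:
    rows = []
    for window, call in rec.calls.items():
        rows.append(
            {
                "drug": rec.drug,
                "window": f"{window[0]}-{window[1]}s",
                "toxic": rec.toxic,
                "dead_fraction": rec.dead_fraction,
                "consistency_p": call.consistency_p,
                "consistency_pass": call.consistency_pass,
                "control_p": call.control_p,
                "significant": call.significant,
                "hit": call.hit,
            }
        )
    if not rec.calls:
        rows.append(
            {
                "drug": rec.drug,
                "window": None,
                "toxic": rec.toxic,
                "dead_fraction": rec.dead_fraction,
                "consistency_p": None,
                "consistency_pass": False,
                "control_p": None,
                "significant": False,
                "hit": False,
            }
        )
    return rows


def run_screen(trace: PlateTrace, config: ScreenConfig) -> ScreenResult:
    """Run the full funnel on a screen trace.

    Pipeline per drug: baseline normalization (fitted jointly on the whole
    screen), window extraction, toxicity flagging on the raw traces,
    replicate consistency, and Hotelling comparison against the pooled
    vehicle control.  Deterministic given ``config.seed``.
    """
    df = trace.records
    vehicle_name = config.vehicle_treatment
    treatments = sorted(map(str, df["treatment"].unique()))
    drugs = [t for t in treatments if t != vehicle_name]
    if vehicle_name not in treatments:
        if drugs:
            raise DesignError(f"no vehicle ({vehicle_name}) wells in the screen")
        return ScreenResult([], summarize_screen([], config.windows), pd.DataFrame())
    # vehicle must cover every batch that hosts drug wells
    drug_batches = set(df.loc[df["treatment"] != vehicle_name, "batch"].astype(str))
    veh_batches = set(df.loc[df["treatment"] == vehicle_name, "batch"].astype(str))
    missing = drug_batches - veh_batches
    if missing:
        raise DesignError(
            f"vehicle controls missing from batch(es): {', '.join(sorted(missing))}"
        )

    analysed = trace
    if config.normalize:
        model = fit_normalization(trace)
        analysed = apply_normalization(trace, model)

    healthy_median = float(
        _larva_totals(df[df["treatment"] == vehicle_name]).median()
    )

    vehicle_windows = {
        w: extract_window(
            analysed,
            {"treatment": vehicle_name},
            start_offset=w[0],
            end_offset=w[1],
            label=vehicle_name,
        )
        for w in config.windows
    }

    children = np.random.SeedSequence(config.seed).spawn(max(len(drugs), 1) * len(config.windows))
    seed_iter = iter(children)
    records: list[HitRecord] = []
    for drug in drugs:
        sub_raw = df[df["treatment"] == drug]
        toxic, diag = flag_toxic(
            sub_raw,
            healthy_median,
            config.movement_threshold_frac,
            config.toxic_fraction,
        )
        rec = HitRecord(drug=drug, toxic=toxic, dead_fraction=diag["dead_fraction"])
        rep_batches = sorted(map(str, sub_raw["batch"].unique()))
        for window in config.windows:
            child = next(seed_iter)
            if toxic:
                rec.calls[window] = WindowCall(
                    window, None, False, None, False, False
                )
                continue
            if len(rep_batches) != 2:
                raise DesignError(
                    f"drug {drug!r} has {len(rep_batches)} replicates; the "
                    "consistency criterion requires exactly 2"
                )
            reps = [
                extract_window(
                    analysed,
                    {"treatment": drug, "batch": b},
                    start_offset=window[0],
                    end_offset=window[1],
                    label=f"{drug}:{b}",
                )
                for b in rep_batches
            ]
            cons_seed = int(child.generate_state(1, np.uint32)[0] % (2**31))
            cons = replicate_consistency(
                reps[0],
                reps[1],
                n_boot=config.n_boot,
                seed=cons_seed,
                threshold=config.consistency_threshold,
            )
            if config.comparison == "per_replicate":
                sigs = [
                    drug_vs_control(r, vehicle_windows[window], config.alpha)
                    for r in reps
                ]
                significant = all(s.passed for s in sigs)
                control_p = max(s.p_value for s in sigs)
                per_rep = tuple(s.p_value for s in sigs)
            else:
                pooled = extract_window(
                    analysed,
                    {"treatment": drug},
                    start_offset=window[0],
                    end_offset=window[1],
                    label=drug,
                )
                sig = drug_vs_control(pooled, vehicle_windows[window], config.alpha)
                significant = sig.passed
                control_p = sig.p_value
                per_rep = (sig.p_value,)
            rec.calls[window] = WindowCall(
                window=window,
                consistency_p=cons.p_value,
                consistency_pass=cons.passed,
                control_p=control_p,
                significant=significant,
                hit=cons.passed and significant,
                control_p_per_replicate=per_rep,
            )
        records.append(rec)

    summary = summarize_screen(records, config.windows)
    table = pd.DataFrame([row for rec in records for row in _flat_rows(rec)])
    return ScreenResult(records, summary, table)


def summarize_screen(
    records: list[HitRecord], windows: tuple[Window, ...] | None = None
) -> ScreenSummary:
    """Collapse per-drug records into the monotone funnel counts.

    Counts are invariant to record order; hit lists are sorted.
    """
    if windows is None:
        windows = tuple(
            sorted({w for rec in records for w in rec.calls})
        )
    n_starting = len(records)
    non_toxic = [r for r in records if not r.toxic]
    n_consistent = {}
    n_hits = {}
    hit_drugs = {}
    for w in windows:
        cons = [r for r in non_toxic if w in r.calls and r.calls[w].consistency_pass]
        hits = [r for r in cons if r.calls[w].hit]
        n_consistent[w] = len(cons)
        n_hits[w] = len(hits)
        hit_drugs[w] = tuple(sorted(r.drug for r in hits))
    return ScreenSummary(
        n_starting=n_starting,
        n_non_toxic=len(non_toxic),
        n_consistent=n_consistent,
        n_hits=n_hits,
        hit_drugs=hit_drugs,
    )
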