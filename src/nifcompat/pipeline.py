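"""Per-carrier compatibility calls, cohort summaries and the
distance-activity regression.

A carrier is screened against two thresholds derived from the behaviour
of carriers known to support nitrogen fixation: a mean edge-to-edge
cofactor distance of at most 10 Å over the top docking poses, and a
computed tunneling rate of at least 10⁶ s⁻¹. A carrier passing both is
called compatible, one failing both incompatible, and disagreement is
called marginal (typically a short-distance carrier with a weak driving
force or vice versa).

For carriers whose two clusters have distinct midpoint potentials, the
higher (less negative) potential is used for the rate. The rate is
evaluated at the mean distance; per-model rates are also retained since
some carriers are bimodal across docking poses.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import SaltBridge, nearest_ligand_cofactor
from .structure_io import DockedComplexModel
from .tunneling import (
    DEFAULT_ACCEPTOR_POTENTIAL_MV,
    DEFAULT_PARAMS,
    TunnelingParams,
    driving_force,
    log10_tunneling_rate,
)

__all__ = [
    "CarrierRecord",
    "CompatibilityCall",
    "DistanceActivityFit",
    "ROLE_CLASSES",
    "DISTANCE_THRESHOLD_A",
    "RATE_THRESHOLD_LOG10",
    "read_carrier_table",
    "evaluate_carrier",
    "classify_cohort",
    "fit_distance_activity",
    "render_report",
    "report_to_json",
    "calls_to_table",
]

logger = logging.getLogger(__name__)

ROLE_CLASSES = ("nif", "non_nif_bacterial", "plant")

#: Mean cofactor distance at or below which carriers supporting nitrogen
#: fixation cluster, Å.
DISTANCE_THRESHOLD_A = 10.0

#: Slowest tunneling rate computed for a carrier that supports nitrogen
#: fixation, log10 s⁻¹.
RATE_THRESHOLD_LOG10 = 6.0


@dataclass
class CarrierRecord:
    """Identity and redox properties of one electron carrier."""

    carrier_id: str
    organism: str
    role_class: str
    potentials_mV: tuple[float, ...]
    activity: float | None = None

    def __post_init__(self) -> None:
        if self.role_class not in ROLE_CLASSES:
            raise ValueError(f"unknown role_class {self.role_class!r}")
        if not self.potentials_mV:
            raise ValueError("at least one midpoint potential is required")

    @property
    def effective_potential_mV(self) -> float:
        """Higher (less negative) of the cluster potentials."""
        return max(self.potentials_mV)


@dataclass
class CompatibilityCall:
    """Aggregate distance/rate screen result for one carrier."""

    carrier_id: str
    per_model_R: list[float]
    mean_R: float
    effective_potential_mV: float
    log10_rate_at_mean_R: float
    distance_pass: bool
    rate_pass: bool
    verdict: str  # compatible | marginal | incompatible
    per_model_log10_rate: list[float] = field(default_factory=list)
    ligand_cofactor_kind: str = ""


@dataclass
class DistanceActivityFit:
    """OLS fit of relative nitrogenase activity on mean cofactor distance."""

    n: int
    slope: float
    intercept: float
    r_squared: float


def read_carrier_table(source) -> list[CarrierRecord]:
    """Read carrier metadata from TSV.

    Expected columns: carrier_id, organism, role_class, potential_mv_1,
    potential_mv_2 (blank allowed), activity (blank allowed).
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        pots = [float(row.potential_mv_1)]
        p2 = getattr(row, "potential_mv_2", None)
        if p2 is not None and not (isinstance(p2, float) and math.isnan(p2)):
            pots.append(float(p2))
        act = getattr(row, "activity", None)
        if act is not None and isinstance(act, float) and math.isnan(act):
            act = None
        records.append(
            CarrierRecord(
                carrier_id=str(row.carrier_id),
                organism=str(row.organism),
                role_class=str(row.role_class),
                potentials_mV=tuple(pots),
                activity=None if act is None else float(act),
            )
        )
    return records


def evaluate_carrier(
    models: list[DockedComplexModel],
    record: CarrierRecord,
    params: TunnelingParams = DEFAULT_PARAMS,
    acceptor_potential_mv: float = DEFAULT_ACCEPTOR_POTENTIAL_MV,
    distance_threshold: float = DISTANCE_THRESHOLD_A,
    rate_threshold_log10: float = RATE_THRESHOLD_LOG10,
) -> CompatibilityCall:
    """Screen one carrier across its docking poses.

    Per-pose R comes from the nearest ligand cofactor; the rate is
    evaluated at the arithmetic mean R using the carrier's effective
    potential. Poses without a ligand cofactor are skipped with a warning.
    """
    if not models:
        raise ValueError("at least one docked model is required")
    per_R: list[float] = []
    kinds: list[str] = []
    for m in models:
        if not m.ligand_cofactors:
            logger.warning(
                "model %d of %s has no ligand cofactor; skipped", m.model_index, record.carrier_id
            )
            continue
        cof, meas = nearest_ligand_cofactor(m)
        per_R.append(meas.R)
        kinds.append(cof.kind)
    if not per_R:
        raise ValueError(f"no usable docking model for {record.carrier_id}")

    mean_r = float(np.mean(per_R))
    dg = driving_force(record.effective_potential_mV, acceptor_potential_mv)
    log10_rate = log10_tunneling_rate(mean_r, dg, params).log10_rate
    per_rates = [log10_tunneling_rate(r, dg, params).log10_rate for r in per_R]
    distance_pass = mean_r <= distance_threshold
    rate_pass = log10_rate >= rate_threshold_log10
    if distance_pass and rate_pass:
        verdict = "compatible"
    elif not distance_pass and not rate_pass:
        verdict = "incompatible"
    else:
        verdict = "marginal"
    return CompatibilityCall(
        carrier_id=record.carrier_id,
        per_model_R=per_R,
        mean_R=mean_r,
        effective_potential_mV=record.effective_potential_mV,
        log10_rate_at_mean_R=log10_rate,
        distance_pass=distance_pass,
        rate_pass=rate_pass,
        verdict=verdict,
        per_model_log10_rate=per_rates,
        ligand_cofactor_kind=kinds[0] if kinds else "",
    )


def _quartiles(values: list[float]) -> dict[str, float]:
    arr = np.asarray(values, float)
    return {
        "median": float(np.median(arr)),
        "q25": float(np.percentile(arr, 25)),
        "q75": float(np.percentile(arr, 75)),
    }


def classify_cohort(
    calls: list[CompatibilityCall], records: list[CarrierRecord]
) -> dict[str, dict]:
    """Per-role verdict counts and distance/rate box-summary statistics."""
    roles = {r.carrier_id: r.role_class for r in records}
    summary: dict[str, dict] = {}
    for call in calls:
        role = roles[call.carrier_id]
        entry = summary.setdefault(
            role,
            {"n": 0, "verdicts": {"compatible": 0, "marginal": 0, "incompatible": 0},
             "_R": [], "_rate": []},
        )
        entry["n"] += 1
        entry["verdicts"][call.verdict] += 1
        entry["_R"].append(call.mean_R)
        entry["_rate"].append(call.log10_rate_at_mean_R)
    for role, entry in summary.items():
        entry["distance"] = _quartiles(entry.pop("_R"))
        entry["log10_rate"] = _quartiles(entry.pop("_rate"))
        entry["rate_pass_fraction"] = (
            sum(1 for c in calls if roles[c.carrier_id] == role and c.rate_pass) / entry["n"]
        )
    return summary


def fit_distance_activity(pairs: list[tuple[float, float]]) -> DistanceActivityFit:
    """Ordinary least squares of activity on mean cofactor distance.

    r² = 1 − SS_res/SS_tot. Constant activity yields r² = 0; a constant
    predictor is rejected as degenerate.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (distance, activity) pairs")
    x = np.asarray([p[0] for p in pairs], float)
    y = np.asarray([p[1] for p in pairs], float)
    if np.any(y < 0):
        raise ValueError("activities must be non-negative")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: zero variance in distance")
    if np.ptp(y) == 0:
        return DistanceActivityFit(n=len(pairs), slope=0.0, intercept=float(y[0]), r_squared=0.0)
    res = stats.linregress(x, y)
    return DistanceActivityFit(
        n=len(pairs),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def render_report(
    calls: list[CompatibilityCall],
    fit: DistanceActivityFit | None = None,
    bridges: dict[str, list[SaltBridge]] | None = None,
) -> dict:
    """Machine-readable screen report with deterministic field order."""
    carriers = []
    for call in sorted(calls, key=lambda c: c.carrier_id):
        entry = {
            "carrier_id": call.carrier_id,
            "per_model_R": [round(r, 3) for r in call.per_model_R],
            "mean_R": round(call.mean_R, 3),
            "effective_potential_mV": call.effective_potential_mV,
            "log10_rate_at_mean_R": round(call.log10_rate_at_mean_R, 3),
            "per_model_log10_rate": [round(r, 3) for r in call.per_model_log10_rate],
            "ligand_cofactor_kind": call.ligand_cofactor_kind,
            "distance_pass": call.distance_pass,
            "rate_pass": call.rate_pass,
            "verdict": call.verdict,
        }
        if bridges is not None:
            blist = bridges.get(call.carrier_id, [])
            entry["n_salt_bridges"] = len(blist)
            entry["hotspot_touches"] = sorted(
                {f"{_one(b.fe_protein_residue[2])}{b.fe_protein_residue[1]}" for b in blist}
            )
        carriers.append(entry)
    report = {"n_carriers": len(carriers), "carriers": carriers}
    if fit is not None:
        report["distance_activity_fit"] = {
            "n": fit.n,
            "slope": round(fit.slope, 4),
            "intercept": round(fit.intercept, 4),
            "r_squared": round(fit.r_squared, 4),
        }
    return report


def _one(resname: str) -> str:
    return {"ARG": "R", "LYS": "K", "ASP": "D", "GLU": "E"}.get(resname, "?")


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization of a report."""
    return json.dumps(report, indent=2, sort_keys=False)


def calls_to_table(calls: list[CompatibilityCall]) -> pd.DataFrame:
    """Compatibility calls as a flat DataFrame (TSV-friendly)."""
    return pd.DataFrame(
        [
            {
                "carrier_id": c.carrier_id,
                "mean_R": round(c.mean_R, 3),
                "effective_potential_mV": c.effective_potential_mV,
                "log10_rate": round(c.log10_rate_at_mean_R, 3),
                "distance_pass": c.distance_pass,
                "rate_pass": c.rate_pass,
                "verdict": c.verdict,
            }
            for c in sorted(calls, key=lambda c: c.carrier_id)
        ]
    )
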