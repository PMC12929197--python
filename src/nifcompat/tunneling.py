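"""Empirical electron-tunneling rate ruler for interprotein transfer.

The rate of single-step electron tunneling between two protein-bound
redox cofactors is estimated from the edge-to-edge distance R (Å) and the
driving force ΔG⁰ (eV) with the Moser–Dutton empirical ruler. With
reorganization energy λ (eV) and intervening-medium packing density ρ:

    exergonic  (ΔG⁰ ≤ 0):
        log10 k = 13.0 − (1.2 − 0.8ρ)(R − 3.6) − 3.1(ΔG⁰ + λ)²/λ
    endergonic (ΔG⁰ > 0):
        log10 k = 13.0 − (1.2 − 0.8ρ)(R − 3.6) − 3.1(−ΔG⁰ + λ)²/λ − ΔG⁰/0.06

The two branches agree at ΔG⁰ = 0 and differ by the Boltzmann penalty
ΔG⁰/0.06 eV per decade for uphill transfer. 13.0 is log10 of the rate at
van-der-Waals contact (3.6 Å) for activationless transfer (ΔG⁰ = −λ);
the distance attenuation is (1.2 − 0.8ρ) decades per Å (0.592 at the
default ρ = 0.76). Defaults λ = 0.65 eV and ρ = 0.76 are the generic
intraprotein medium values.

Driving force follows ΔG⁰(eV) = (E_donor − E_acceptor)/1000 with midpoint
potentials in mV, so transfer to a higher-potential acceptor is downhill
(ΔG⁰ < 0). The Fe-protein acceptor potential defaults to −415 mV (the
reported ADP-bound range spans −415 to −470 mV).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TunnelingParams",
    "TunnelingResult",
    "RateGrid",
    "DEFAULT_ACCEPTOR_POTENTIAL_MV",
    "DEFAULT_PARAMS",
    "driving_force",
    "log10_tunneling_rate",
    "build_rate_grid",
    "max_distance_for_rate",
    "required_potential_for_rate",
    "grid_to_frame",
    "plot_rate_grid",
]

#: Midpoint potential assumed for the ADP-bound Fe protein, mV vs SHE.
DEFAULT_ACCEPTOR_POTENTIAL_MV = -415.0


@dataclass(frozen=True)
class TunnelingParams:
    """Constants of the empirical tunneling rate law."""

    lambda_reorg: float = 0.65  # reorganization energy, eV
    rho: float = 0.76  # packing density of the intervening medium, 0..1
    intercept: float = 13.0  # log10 rate at contact, activationless
    slope_a: float = 1.2  # distance-attenuation constants, decades/Å
    slope_b: float = 0.8
    contact_distance: float = 3.6  # van der Waals contact, Å
    franck_condon_coeff: float = 3.1  # quadratic ΔG-dependence coefficient
    thermal_factor: float = 0.06  # uphill penalty, eV per decade

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.lambda_reorg <= 0:
            raise ValueError("lambda_reorg must be positive")

    @property
    def distance_slope(self) -> float:
        """Decades of rate lost per Å of edge-to-edge distance."""
        return self.slope_a - self.slope_b * self.rho


DEFAULT_PARAMS = TunnelingParams()


@dataclass
class TunnelingResult:
    """One rate evaluation: driving force, distance, branch and rate."""

    delta_g: float
    R: float
    regime: str  # "exergonic" | "endergonic"
    log10_rate: float

    @property
    def rate(self) -> float:
        """k_et in s⁻¹."""
        return 10.0 ** self.log10_rate


@dataclass
class RateGrid:
    """log10 rates over a donor-potential × distance grid."""

    potentials: np.ndarray  # donor midpoint potentials, mV
    distances: np.ndarray  # edge-to-edge distances, Å
    acceptor_potential: float  # mV
    log10_rates: np.ndarray  # shape (len(potentials), len(distances))
    params: TunnelingParams = field(default_factory=TunnelingParams)


def driving_force(donor_potential_mv: float, acceptor_potential_mv: float) -> float:
    """ΔG⁰ in eV for one-electron transfer between two midpoint potentials.

    Negative when the acceptor potential is higher than the donor's
    (downhill, exergonic); positive when uphill.
    """
    if not (math.isfinite(donor_potential_mv) and math.isfinite(acceptor_potential_mv)):
        raise ValueError("potentials must be finite")
    return (donor_potential_mv - acceptor_potential_mv) / 1000.0


def log10_tunneling_rate(
    R: float, delta_g: float, params: TunnelingParams = DEFAULT_PARAMS
) -> TunnelingResult:
    """Evaluate the empirical ruler at distance R (Å) and ΔG⁰ (eV)."""
    if not (math.isfinite(R) and math.isfinite(delta_g)):
        raise ValueError("R and delta_g must be finite")
    if R < params.contact_distance:
        warnings.warn(
            f"R = {R:.2f} Å is below van-der-Waals contact "
            f"({params.contact_distance} Å); the ruler extrapolates",
            stacklevel=2,
        )
    lam = params.lambda_reorg
    base = params.intercept - params.distance_slope * (R - params.contact_distance)
    if delta_g <= 0:
        log10_k = base - params.franck_condon_coeff * (delta_g + lam) ** 2 / lam
        regime = "exergonic"
    else:
        log10_k = (
            base
            - params.franck_condon_coeff * (-delta_g + lam) ** 2 / lam
            - delta_g / params.thermal_factor
        )
        regime = "endergonic"
    return TunnelingResult(delta_g=delta_g, R=R, regime=regime, log10_rate=log10_k)


def default_potential_grid() -> np.ndarray:
    """Donor potentials −1000 … −200 mV in 25 mV increments (33 values)."""
    return np.arange(-1000.0, -199.0, 25.0)


def default_distance_grid() -> np.ndarray:
    """Distances 4 … 20 Å in 1 Å increments (17 values)."""
    return np.arange(4.0, 21.0, 1.0)


def build_rate_grid(
    acceptor_potential_mv: float = DEFAULT_ACCEPTOR_POTENTIAL_MV,
    params: TunnelingParams = DEFAULT_PARAMS,
    potentials: np.ndarray | None = None,
    distances: np.ndarray | None = None,
) -> RateGrid:
    """Sweep the rate law over the donor-potential × distance grid.

    Each cell equals a standalone :func:`log10_tunneling_rate` evaluation;
    rows are monotone non-increasing in distance.
    """
    pots = default_potential_grid() if potentials is None else np.asarray(potentials, float)
    dists = default_distance_grid() if distances is None else np.asarray(distances, float)
    rates = np.empty((pots.size, dists.size))
    for i, p in enumerate(pots):
        dg = driving_force(float(p), acceptor_potential_mv)
        for j, r in enumerate(dists):
            rates[i, j] = log10_tunneling_rate(float(r), dg, params).log10_rate
    return RateGrid(
        potentials=pots,
        distances=dists,
        acceptor_potential=acceptor_potential_mv,
        log10_rates=rates,
        params=params,
    )


def max_distance_for_rate(
    donor_potential_mv: float,
    acceptor_potential_mv: float,
    threshold_log10: float,
    params: TunnelingParams = DEFAULT_PARAMS,
    distance_grid: np.ndarray | None = None,
) -> float | None:
    """Largest grid distance whose log10 rate meets the threshold.

    Operates on the discrete 1 Å screening grid (not continuous
    root-finding). Returns None if no grid point qualifies.
    """
    dists = default_distance_grid() if distance_grid is None else np.asarray(distance_grid, float)
    if dists.size == 0:
        raise ValueError("empty distance grid")
    dg = driving_force(donor_potential_mv, acceptor_potential_mv)
    ok = [float(r) for r in dists if log10_tunneling_rate(float(r), dg, params).log10_rate >= threshold_log10]
    return max(ok) if ok else None


def required_potential_for_rate(
    distance: float,
    acceptor_potential_mv: float,
    threshold_log10: float,
    params: TunnelingParams = DEFAULT_PARAMS,
    potential_grid: np.ndarray | None = None,
) -> float | None:
    """Highest (least negative) grid donor potential meeting the threshold.

    Returns None if the threshold is unattainable at this distance on the
    25 mV screening grid.
    """
    pots = default_potential_grid() if potential_grid is None else np.asarray(potential_grid, float)
    if pots.size == 0:
        raise ValueError("empty potential grid")
    ok = [
        float(p)
        for p in pots
        if log10_tunneling_rate(
            distance, driving_force(float(p), acceptor_potential_mv), params
        ).log10_rate
        >= threshold_log10
    ]
    return max(ok) if ok else None


def grid_to_frame(grid: RateGrid):
    """RateGrid as a labeled DataFrame (potentials as rows, Å as columns)."""
    import pandas as pd

    return pd.DataFrame(
        grid.log10_rates,
        index=pd.Index([f"{p:.0f}" for p in grid.potentials], name="potential_mV"),
        columns=[f"{d:.0f}" for d in grid.distances],
    )


def plot_rate_grid(grid: RateGrid, threshold_log10: float = 6.0, ax=None):
    """Family of log10-rate vs potential curves, one line per distance."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    cmap = plt.get_cmap("Blues")
    n = grid.distances.size
    for j, d in enumerate(grid.distances):
        ax.plot(
            grid.potentials,
            grid.log10_rates[:, j],
            color=cmap(0.3 + 0.7 * j / max(n - 1, 1)),
            lw=1.2,
            label=f"{d:.0f} Å" if j in (0, n - 1) else None,
        )
    ax.axhline(threshold_log10, ls="--", color="k", lw=0.8)
    ax.set_xlabel("donor midpoint potential (mV)")
    ax.set_ylabel(r"$\log_{10}\,k_{et}$ (s$^{-1}$)")
    ax.legend(frameon=False, fontsize=8)
    return ax
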