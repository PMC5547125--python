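"""Unit conversions between LJ / theory units and physical DNA scales.

The coarse-grained chain maps onto double-stranded DNA as follows: one
bead of diameter sigma = 2 nm and mass ~3744 amu stands for ~6 base
pairs, chosen so that the model persistence length (25 beads for bending
rigidity kappa_b = 30 at kT = 1.2) matches the 150 bp persistence length
of dsDNA.  At room temperature (295 K) the LJ energy is
epsilon = kB*T/1.2 ~ 3.39e-21 J, which makes the LJ time unit
sigma*sqrt(m/epsilon) ~ 85.6 ps.

The voltage mapping assumes twelve unit charges per bead with an
effective charge of 0.094 e each and a force scale of 2.0 pN per LJ force
unit; it is approximate — see ``force_to_voltage``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KB",
    "AMU",
    "ELEMENTARY_CHARGE",
    "UnitMap",
    "persistence_length_lj",
    "lj_time_scale",
    "bp_per_bead",
    "force_to_voltage",
    "map_experiment",
]

KB = 1.380649e-23           # J/K
AMU = 1.66053906660e-27     # kg
ELEMENTARY_CHARGE = 1.602176634e-19  # C


@dataclass(frozen=True)
class UnitMap:
    """Physical values of the LJ units plus DNA coarse-graining constants."""

    sigma_phys: float = 2.0e-9        # m
    mass_phys: float = 3744.0         # amu
    temperature_phys: float = 295.0   # K
    kBT_lj: float = 1.2               # dimensionless temperature
    epsilon_phys: float | None = None  # J; derived from T if omitted
    effective_charge_per_unit: float = 0.094  # elementary charges
    unit_charges_per_bead: float = 12.0
    force_scale: float = 2.0e-12      # N per LJ force unit (2.0 pN)
    dna_persistence_bp: float = 150.0
    model_persistence_beads: float = 25.0

    def __post_init__(self) -> None:
        for name in ("sigma_phys", "mass_phys", "temperature_phys", "kBT_lj",
                     "effective_charge_per_unit", "unit_charges_per_bead",
                     "force_scale", "dna_persistence_bp",
                     "model_persistence_beads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.epsilon_phys is None:
            object.__setattr__(self, "epsilon_phys",
                               KB * self.temperature_phys / self.kBT_lj)
        else:
            consistent = KB * self.temperature_phys / self.kBT_lj
            if abs(self.epsilon_phys - consistent) > 5e-3 * consistent:
                raise ValueError(
                    "epsilon_phys inconsistent with kB*T/kBT_lj beyond 0.5%")


def persistence_length_lj(bend_kappa: float, kBT: float) -> float:
    """Dimensionless persistence length ``lp = kappa_b / kBT`` (3D)."""
    if kBT <= 0:
        raise ValueError("kBT must be > 0")
    if bend_kappa < 0:
        raise ValueError("bending rigidity must be >= 0")
    return bend_kappa / kBT


def lj_time_scale(unit_map: UnitMap) -> float:
    """Seconds per LJ time unit, ``sigma * sqrt(m / epsilon)``."""
    m_kg = unit_map.mass_phys * AMU
    return unit_map.sigma_phys * np.sqrt(m_kg / unit_map.epsilon_phys)


def bp_per_bead(unit_map: UnitMap) -> float:
    """Base pairs represented by one bead (persistence-length matching)."""
    return unit_map.dna_persistence_bp / unit_map.model_persistence_beads


def force_to_voltage(unit_map: UnitMap, f_lj: float) -> tuple[float, bool]:
    """Approximate pore voltage (mV) equivalent to an LJ driving force.

    ``V = f * force_scale * sigma / (charges_per_bead * q_eff * e)``.
    Returns ``(millivolts, approximate_flag)``: with the default constants
    f = 10 maps to ~221 mV whereas the conventional correspondence quoted
    for nanopore experiments rounds this to 200 mV; the ~10% gap is
    inherent to the printed constants and deliberately not tuned away.
    """
    if f_lj < 0:
        raise ValueError("driving force must be >= 0")
    charge = (unit_map.unit_charges_per_bead
              * unit_map.effective_charge_per_unit * ELEMENTARY_CHARGE)
    volts = f_lj * unit_map.force_scale * unit_map.sigma_phys / charge
    return volts * 1e3, True


def map_experiment(table, unit_map: UnitMap, theory) -> dict:
    """Compare experimental (length_bp, dwell_time) data with the theory.

    ``table`` is a DataFrame-like with columns ``length_bp`` and
    ``dwell_time_s``; ``theory`` is a ``ScalingResult`` whose grid covers
    the experimental lengths in beads (``N0 = length_bp / bp_per_bead``).
    A single multiplicative time factor is fitted in log space, and
    log-log slopes of both series are reported.  Records with non-positive
    length or time are rejected individually and reported.

    Returns a dict with keys ``table`` (DataFrame: n0_beads, t_exp,
    t_theory_scaled), ``time_factor``, ``slope_experiment``,
    ``slope_theory``, ``rejected`` (count).
    """
    import pandas as pd

    df = pd.DataFrame(table)
    required = {"length_bp", "dwell_time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"experiment table must have columns {sorted(required)}")
    ok = (df["length_bp"] > 0) & (df["dwell_time_s"] > 0)
    rejected = int((~ok).sum())
    df = df[ok].copy()
    if len(df) < 3:
        raise ValueError("need at least 3 valid experimental records")

    beads = df["length_bp"].to_numpy(float) / bp_per_bead(unit_map)
    t_exp = df["dwell_time_s"].to_numpy(float)

    grid = np.asarray(theory.n0_grid, float)
    tau = np.asarray(theory.tau, float)
    if beads.min() < grid.min() or beads.max() > grid.max():
        raise ValueError("theory scan does not cover the experimental lengths")
    tau_at = np.exp(np.interp(np.log(beads), np.log(grid), np.log(tau)))

    log_factor = float(np.mean(np.log(t_exp) - np.log(tau_at)))
    factor = float(np.exp(log_factor))
    slope_exp = float(np.polyfit(np.log(beads), np.log(t_exp), 1)[0])
    slope_th = float(np.polyfit(np.log(beads), np.log(tau_at), 1)[0])

    out = pd.DataFrame({
        "length_bp": df["length_bp"].to_numpy(float),
        "n0_beads": beads,
        "t_exp": t_exp,
        "t_theory_scaled": tau_at * factor,
    })
    return {"table": out, "time_factor": factor,
            "slope_experiment": slope_exp, "slope_theory": slope_th,
            "rejected": rejected}
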