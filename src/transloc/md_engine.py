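"""Langevin bead-spring MD of nanopore translocation.

A coarse-grained polymer of ``N0`` beads (WCA excluded volume, FENE
bonds, discrete bending rigidity ``kappa_b``) is driven through a
nanopore — 16 static beads of diameter sigma on a circle of diameter
3 sigma in a repulsive 9-3 wall at x = 0 — by a constant force ``f``
acting on beads inside the pore.  Dynamics are Langevin at temperature
``kBT`` with solvent friction ``eta`` per bead, integrated with BAOAB.

Default parameters are the reference set: epsilon = sigma = m = 1,
k = 30, R0 = 1.5 sigma, kappa_b = 30, eta = 0.7, kBT = 1.2,
f in {5, 10, 20}; the persistence length is then kappa_b/kBT = 25 and
one bead corresponds to roughly 6 bp of dsDNA.

Translocation protocol: the chain is grown on the cis side from a
discrete worm-like-chain sampler with its head bead held at the pore
center by a stiff harmonic tether, relaxed with the drive off, then at
t = 0 the tether is released and the drive switched on.  If the chain
retracts entirely to the cis side the attempt is restarted from a fresh
equilibrium configuration (no reflective boundaries).  The translocation
time is the moment the last bead reaches the trans side; per-bead waiting
times come from last-passage filtering of the trans-side bead count, so
recrossings are not double counted.

Measurement helpers: free-chain equilibrium end-to-end statistics (for
validating the chain-statistics interpolation formula) and ensemble
waiting-time inversion of the trans-side friction.  Note on units: the
theory measures length in *segments*; the discrete chain's natural
segment is its mean bond length b0 ~ 0.961 sigma (FENE + WCA minimum),
so dimensionless comparisons divide MD distances by b0 and count a chain
of N beads as N - 1 segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from . import _md_kernels as _k
from .chain_model import ChainGeometryParams, end_to_end_distance
from .iftp_solver import cis_front_profile
from .trans_friction import FrictionTrace, extract_from_waiting_times

__all__ = [
    "MDConfig",
    "TranslocationRun",
    "equilibrium_bond_length",
    "build_pore",
    "sample_wlc_configuration",
    "forces",
    "equilibrium_end_to_end",
    "run_translocation",
    "run_ensemble",
    "measure_trans_friction",
    "calibrate_pore_friction",
    "write_xyz",
]


@dataclass(frozen=True)
class MDConfig:
    """Simulation parameters (LJ units); defaults are the reference set."""

    epsilon: float = 1.0
    sigma: float = 1.0
    mass: float = 1.0
    fene_k: float = 30.0
    fene_r0: float = 1.5
    bend_kappa: float = 30.0
    solvent_friction: float = 0.7
    kBT: float = 1.2
    drive_force: float = 20.0
    n_beads: int = 64
    dt: float = 0.005
    n_pore_beads: int = 16
    pore_circle_diameter: float = 3.0
    pore_thickness: float = 1.0
    tether_stiffness: float = 200.0
    equilibration_steps: int = 100_000
    max_steps: int = 2_000_000
    max_restarts: int = 50
    escape_x: float = -2.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.fene_r0 <= self.sigma / 1.5:
            raise ValueError("need dt > 0 and a sensible FENE range")
        if self.n_beads < 2:
            raise ValueError("need at least 2 beads")

    @property
    def lumen_radius(self) -> float:
        """Radial extent of the wall opening (pore-bead circle radius)."""
        return self.pore_circle_diameter * self.sigma / 2.0

    @property
    def persistence_length(self) -> float:
        return self.bend_kappa / self.kBT

    @property
    def time_unit(self) -> float:
        """Theory time unit eta sigma^2 / kBT, in LJ time."""
        return self.solvent_friction * self.sigma**2 / self.kBT

    @property
    def dimensionless_force(self) -> float:
        """Drive in theory units, f sigma / kBT."""
        return self.drive_force * self.sigma / self.kBT


@dataclass
class TranslocationRun:
    """Outcome of one translocation attempt (LJ units)."""

    tau: float
    waiting_times: np.ndarray
    restarted: int
    seed: int
    success: bool
    first_passage_waits: np.ndarray | None = None
    #: trans-side maximum x-reach when each bead first arrived
    trans_extent: np.ndarray | None = None


def equilibrium_bond_length(config: MDConfig) -> float:
    """Bond length minimizing FENE + WCA (~0.961 sigma for defaults)."""
    eps, sig, k, r0 = (config.epsilon, config.sigma, config.fene_k,
                       config.fene_r0)

    def u(r):
        wca = 0.0
        if r < 2 ** (1 / 6) * sig:
            s6 = (sig / r) ** 6
            wca = 4 * eps * (s6 * s6 - s6) + eps
        return wca - 0.5 * k * r0**2 * math.log(1 - (r / r0) ** 2)

    res = minimize_scalar(u, bounds=(0.5 * sig, 0.99 * r0), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


def build_pore(config: MDConfig) -> np.ndarray:
    """Static pore beads: a circle of diameter 3 sigma in the x=0 plane."""
    k = np.arange(config.n_pore_beads)
    phi = 2.0 * np.pi * k / config.n_pore_beads
    r = config.pore_circle_diameter * config.sigma / 2.0
    return np.column_stack([np.zeros_like(phi), r * np.cos(phi),
                            r * np.sin(phi)])


def sample_wlc_configuration(config: MDConfig, n: int,
                             rng: np.random.Generator,
                             start=(0.0, 0.0, 0.0),
                             direction=(-1.0, 0.0, 0.0)) -> np.ndarray:
    """Draw a discrete worm-like-chain configuration.

    Bond angles follow the exact Boltzmann weight of the bending
    potential, exp(kappa_b cos(theta) / kBT) sin(theta); azimuths are
    uniform.  Hard overlaps (non-bonded beads closer than 0.85 sigma)
    are rejected step-wise so the subsequent MD relaxation starts from a
    finite-energy state; for stiff chains this almost never triggers.
    """
    b0 = equilibrium_bond_length(config)
    kappa = config.bend_kappa / config.kBT
    min_d2 = (0.9 * config.sigma) ** 2
    for _ in range(100):  # whole-chain attempts
        pos = np.empty((n, 3))
        pos[0] = start
        t = np.asarray(direction, float)
        t = t / np.linalg.norm(t)
        ok = True
        for i in range(1, n):
            for _try in range(60):
                if kappa > 1e-12:
                    u = rng.random()
                    # inverse CDF of p(c) ~ exp(kappa c) on [-1, 1]
                    cos_t = 1.0 + np.log(u + (1.0 - u)
                                         * np.exp(-2.0 * kappa)) / kappa
                else:
                    cos_t = 2.0 * rng.random() - 1.0
                sin_t = math.sqrt(max(0.0, 1.0 - cos_t**2))
                phi = 2.0 * np.pi * rng.random()
                # local frame around current tangent
                a = (np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9
                     else np.array([1.0, 0.0, 0.0]))
                e1 = np.cross(t, a)
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(t, e1)
                t_new = cos_t * t + sin_t * (math.cos(phi) * e1
                                             + math.sin(phi) * e2)
                t_new /= np.linalg.norm(t_new)
                cand = pos[i - 1] + b0 * t_new
                if i < 2 or np.min(np.sum((pos[:i - 1] - cand) ** 2,
                                          axis=1)) > min_d2:
                    t = t_new
                    pos[i] = cand
                    break
            else:
                ok = False
                break
        if ok:
            return pos
    raise RuntimeError("could not sample a non-overlapping configuration")


def forces(positions: np.ndarray, config: MDConfig, *, wall: bool = False,
           pore: np.ndarray | None = None, drive: float = 0.0,
           tether_stiffness: float = 0.0) -> np.ndarray:
    """Total force on each bead for a given configuration.

    Raises ``RuntimeError`` naming the bond if a FENE spring is at or
    beyond its maximum extension (the signature of a too-large time step).
    """
    pos = np.ascontiguousarray(positions, dtype=float)
    pore_arr = pore if pore is not None else np.zeros((0, 3))
    out = np.zeros_like(pos)
    status = _k.forces(pos, pore_arr, config.epsilon, config.sigma,
                       config.fene_k, config.fene_r0, config.bend_kappa,
                       wall, config.lumen_radius, drive,
                       config.pore_thickness / 2.0, tether_stiffness, out)
    if status > 0:
        raise RuntimeError(f"FENE bond {status - 1} at maximum extension")
    if status < 0:
        raise RuntimeError("non-finite force encountered")
    return out


def _draw_velocities(config: MDConfig, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(config.kBT / config.mass), size=(n, 3))


def _subseed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def equilibrium_end_to_end(config: MDConfig, n: int, n_samples: int = 8,
                           seed: int = 0, burn_steps: int = 40_000,
                           sample_steps: int = 150_000,
                           sample_every: int = 500) -> dict:
    """Free-chain mean-squared end-to-end distance with replica stderr.

    Runs ``n_samples`` independent replicas (fresh worm-like-chain initial
    conditions), discards ``burn_steps`` and time-averages R_ee^2 over the
    rest.  No wall, pore or drive.  Returns a dict with keys ``r2_mean``,
    ``r_rms``, ``r_rms_stderr``, ``kinetic_per_bead``, ``bond_length``,
    ``n_segments``.
    """
    rng = np.random.default_rng(seed)
    pore = np.zeros((0, 3))
    reps = []
    kes = []
    for _ in range(n_samples):
        pos = sample_wlc_configuration(config, n, rng)
        vel = _draw_velocities(config, n, rng)
        total = burn_steps + sample_steps
        buf = np.zeros((total // sample_every + 2, 2))
        status, written = _k.baoab_run(
            pos, vel, pore, total, config.dt,
            config.epsilon, config.sigma, config.fene_k, config.fene_r0,
            config.bend_kappa, config.solvent_friction, config.kBT,
            config.mass, False, config.lumen_radius, 0.0,
            config.pore_thickness / 2.0, 0.0, _subseed(rng),
            sample_every, buf)
        if status != 0:
            raise RuntimeError(f"free-chain run failed with status {status}")
        skip = burn_steps // sample_every
        reps.append(buf[skip:written, 0].mean())
        kes.append(buf[skip:written, 1].mean())
    reps = np.asarray(reps)
    r2 = float(reps.mean())
    r_rms = math.sqrt(r2)
    # delta method: std(r) ~ std(r2) / (2 r)
    stderr = float(reps.std(ddof=1) / math.sqrt(len(reps)) / (2 * r_rms))
    return {
        "r2_mean": r2,
        "r_rms": r_rms,
        "r_rms_stderr": stderr,
        "kinetic_per_bead": float(np.mean(kes)),
        "bond_length": equilibrium_bond_length(config),
        "n_segments": n - 1,
    }


def run_translocation(config: MDConfig, seed: int = 0) -> TranslocationRun:
    """One full translocation: build, equilibrate, drive, (re)start.

    Deterministic given ``seed``.  Raises ``RuntimeError`` when the
    restart budget is exhausted (e.g. drive too weak to beat entropic
    recoil) and ``TimeoutError`` when the step budget is.
    """
    rng = np.random.default_rng(seed)
    pore = build_pore(config)
    n = config.n_beads
    restarts = 0
    while restarts <= config.max_restarts:
        # fresh cis-side configuration, head bead at the pore center;
        # reject drawings with beads inside the wall's repulsive range
        # (|x| < 3^{1/6} sigma outside the lumen) or on the trans side
        for _ in range(500):
            pos = sample_wlc_configuration(config, n, rng)
            x, rho = pos[1:, 0], np.hypot(pos[1:, 1], pos[1:, 2])
            cis = np.all(x < -0.2 * config.sigma)
            clear = np.all((rho < 0.9 * config.lumen_radius)
                           | (x < -1.2 * config.sigma))
            dp = np.linalg.norm(pos[:, None, :] - pore[None, :, :], axis=-1)
            if cis and clear and dp.min() > 0.95 * config.sigma:
                break
        else:
            raise RuntimeError("could not draw a cis-side configuration")
        vel = _draw_velocities(config, n, rng)
        buf = np.zeros((1, 2))
        status, _ = _k.baoab_run(
            pos, vel, pore, config.equilibration_steps, config.dt,
            config.epsilon, config.sigma, config.fene_k, config.fene_r0,
            config.bend_kappa, config.solvent_friction, config.kBT,
            config.mass, True, config.lumen_radius, 0.0,
            config.pore_thickness / 2.0, config.tether_stiffness,
            _subseed(rng), 0, buf)
        if status != 0:
            raise RuntimeError(f"equilibration failed with status {status}")

        last_below = np.zeros(n + 1)
        first_above = np.zeros(n + 1)
        trans_extent = np.zeros(n + 1)
        outcome, status, t_final = _k.translocate_run(
            pos, vel, pore, config.max_steps, config.dt, config.epsilon,
            config.sigma, config.fene_k, config.fene_r0, config.bend_kappa,
            config.solvent_friction, config.kBT, config.mass,
            config.lumen_radius, config.drive_force,
            config.pore_thickness / 2.0, _subseed(rng), config.escape_x,
            last_below, first_above, trans_extent)
        if status != 0:
            raise RuntimeError(f"translocation failed with status {status}")
        if outcome == 1:
            # w(k) = T_k - T_{k-1} with T_k the last time fewer than k
            # beads were on the trans side (T_0 = 0, drive-on moment)
            waits = np.diff(np.concatenate([[0.0], last_below[1:]]))
            waits[-1] += t_final - last_below[n]
            fp = np.diff(first_above)
            return TranslocationRun(tau=t_final, waiting_times=waits,
                                    restarted=restarts, seed=seed,
                                    success=True, first_passage_waits=fp,
                                    trans_extent=trans_extent[1:].copy())
        if outcome == 2:
            restarts += 1
            continue
        raise TimeoutError("translocation exceeded the step budget")
    raise RuntimeError(
        f"chain escaped to the cis side {restarts} times; drive too weak")


def run_ensemble(config: MDConfig, n_runs: int,
                 seed: int = 0) -> list[TranslocationRun]:
    """Independent translocation runs with per-run seeds derived from seed."""
    rng = np.random.default_rng(seed)
    return [run_translocation(config, seed=_subseed(rng))
            for _ in range(n_runs)]


def _mean_waiting_times(runs) -> tuple[np.ndarray, np.ndarray]:
    w = np.stack([r.waiting_times for r in runs])
    return w.mean(axis=0), w.std(axis=0, ddof=1) / math.sqrt(len(runs))


def calibrate_pore_friction(w_dimless: np.ndarray, front: np.ndarray,
                            f_dimless: float, s_window=(2, 8)) -> float:
    """Effective pore friction from the small-s waiting times.

    In the growth regime the inverted quantity ``f w(s) - R(s)`` equals
    eta_p + eta_TS(s) with eta_TS vanishing linearly as s -> 0, so the
    intercept of a linear fit over an early-s window estimates eta_p.
    The first bead is excluded: it starts inside the pore and its waiting
    time carries no drag information.
    """
    lo, hi = s_window
    s = np.arange(1, len(w_dimless) + 1, dtype=float)
    m = (s >= lo) & (s <= hi)
    y = f_dimless * w_dimless[m] - front[m]
    coef = np.polyfit(s[m], y, 1)
    return float(max(coef[1], 0.0))


def calibrate_pore_friction_flexible(config: MDConfig, n_runs: int = 16,
                                     seed: int = 0,
                                     s_band: tuple[int, int] = (8, 56),
                                     flexible_lp: float | None = None) -> float:
    """Pore friction from a fully flexible control ensemble.

    For a fully flexible chain the trans-side drag is absorbable into the
    pore term, so ``f w(s) - R(s)`` averaged over interior beads
    estimates eta_p directly.  A kappa_b = 0 copy of ``config`` is
    translocated ``n_runs`` times; the front profile R(s) uses the
    effective persistence length of the flexible bead-spring chain, by
    default inferred by matching the measured free-chain end-to-end
    distance to the interpolation formula (~0.8 segments: excluded
    volume between bond neighbours stiffens the walk slightly).

    This is the default calibration route: the head bead starts inside
    the pore, so its own waiting time carries no drag signal, and the
    first few beads carry a flux-establishment transient that poisons
    intercept-style estimates.
    """
    flex = MDConfig(**{**config.__dict__, "bend_kappa": 0.0})
    rng = np.random.default_rng(seed)
    if flexible_lp is None:
        from scipy.optimize import brentq

        eq = equilibrium_end_to_end(flex, flex.n_beads, n_samples=8,
                                    seed=_subseed(rng), burn_steps=40_000,
                                    sample_steps=80_000)
        target = eq["r_rms"] / eq["bond_length"]
        n_seg = float(flex.n_beads - 1)

        def gap(lp):
            return (end_to_end_distance(
                ChainGeometryParams(persistence_length=lp), n_seg) - target)

        flexible_lp = brentq(gap, 0.1, 10.0)
    runs = run_ensemble(flex, n_runs, seed=_subseed(rng))
    w_lj, _ = _mean_waiting_times(runs)
    w = w_lj / flex.time_unit
    chain = ChainGeometryParams(persistence_length=flexible_lp)
    n_seg = float(flex.n_beads - 1)
    s_mid = np.arange(1, flex.n_beads + 1, dtype=float) - 0.5
    front = cis_front_profile(chain, n_seg, np.minimum(s_mid, n_seg))
    lo, hi = s_band
    y = flex.dimensionless_force * w[lo - 1:hi] - front[lo - 1:hi]
    return float(y.mean())


def measure_trans_friction(runs, config: MDConfig,
                           chain: ChainGeometryParams | None = None,
                           pore_friction: float | None = None,
                           smooth_window: int = 5
                           ) -> tuple[FrictionTrace, float]:
    """Invert ensemble waiting times into a trans-side friction trace.

    Waiting times are ensemble averaged, converted to theory units, and
    inverted with the friction-independent tension-front profile R(s) of
    the IFTP solution: eta_TS(s) = f w(s) - R(s) - eta_p.  When
    ``pore_friction`` is None it is calibrated from the small-s intercept
    (see :func:`calibrate_pore_friction`).  Returns (trace, eta_p); with
    fewer than 10 runs the trace is flagged ``low_confidence``.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for a friction trace")
    chain = chain or ChainGeometryParams(
        persistence_length=config.persistence_length)
    n = config.n_beads
    w_lj, w_err = _mean_waiting_times(runs)
    w_dimless = w_lj / config.time_unit
    w_err_dimless = w_err / config.time_unit
    f_dimless = config.dimensionless_force
    # theory counts N-1 segments for an N-bead chain
    n_seg = float(n - 1)
    s_mid = np.arange(1, n + 1, dtype=float) - 0.5
    front = cis_front_profile(chain, n_seg, np.minimum(s_mid, n_seg))
    if pore_friction is None:
        pore_friction = calibrate_pore_friction(w_dimless, front, f_dimless)
    trace = extract_from_waiting_times(
        w_dimless, front, pore_friction, f_dimless,
        smooth_window=smooth_window)
    trace = FrictionTrace(
        s_values=trace.s_values, eta_values=trace.eta_values,
        uncertainty=f_dimless * w_err_dimless,
        provenance="md_extracted", clipped_points=trace.clipped_points,
        low_confidence=len(runs) < 10)
    return trace, float(pore_friction)


def write_xyz(path, positions: np.ndarray, *, time: float = 0.0,
              translocated: int = 0, append: bool = False) -> None:
    """Write/append one frame in XYZ format (comment carries t and s)."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{len(positions)}\n")
        fh.write(f"t={time:.6f} s={translocated}\n")
        for x, y, z in positions:
            fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")
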