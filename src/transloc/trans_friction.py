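"""Trans-side friction of a translocating semi-flexible chain.

The chain portion already threaded to the *trans* side drags against the
solvent.  For a stiff chain this drag is a non-monotonic function of the
number of translocated beads ``s``, with three regimes:

I.   growth — the emerging segment is straight and aligned with the drive,
     so the friction grows with its x-extension, ``eta = c1 * R_x(s)``;
II.  plateau — the segment buckles and the friction saturates at
     ``eta_sat`` (reference MD value ~10.63 for N0=64, kappa_b=30, f=20);
III. decay — buckling relaxes the drag, which decays exponentially with
     scale ``lam`` toward an asymptote ``eta_inf`` (~5.5 in the same setup).

The piecewise model is continuous at both breakpoints; in the default
``linear_in_s`` mode ``R_x(s) = s``, which also reproduces the rigid-rod
special case ``eta_TS(s) = s`` used by the closed-form rod translocation
time.  ``chain_model_rx`` mode instead uses the equilibrium end-to-end
distance of the trans segment.

This module also inverts ensemble-averaged waiting times into a friction
trace (``eta_TS(s) = f*w(s) - R(s) - eta_p``) and fits the piecewise model
to such traces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import brentq, least_squares

from .chain_model import ChainGeometryParams, end_to_end_distance

__all__ = [
    "TransFrictionModel",
    "FrictionTrace",
    "FrictionFit",
    "evaluate",
    "extract_from_waiting_times",
    "fit",
    "zero_friction",
    "rod_friction",
    "reference_friction",
    "load_calibration",
    "save_calibration",
]


@dataclass(frozen=True)
class TransFrictionModel:
    """Continuous three-regime trans-side friction eta_TS(s).

    ``growth_end`` (s1) is not stored: continuity at the growth/plateau
    junction fixes it to ``eta_sat / c1`` in ``linear_in_s`` mode (or the
    root of ``c1 * R_x(s1) = eta_sat`` in ``chain_model_rx`` mode).
    """

    growth_coefficient: float  # c1, friction per unit trans extension
    saturation_value: float    # eta_sat, regime-II plateau
    asymptote: float           # eta_inf, s -> N0 limit
    plateau_end: float         # s2, start of the exponential decay
    decay_scale: float         # lam, beads
    extension_mode: str = "linear_in_s"

    def __post_init__(self) -> None:
        if not (self.saturation_value >= self.asymptote > 0):
            raise ValueError("require eta_sat >= eta_inf > 0")
        if self.growth_coefficient <= 0 or self.decay_scale <= 0:
            raise ValueError("c1 and decay scale must be > 0")
        if self.extension_mode not in ("linear_in_s", "chain_model_rx"):
            raise ValueError(f"unknown extension_mode {self.extension_mode!r}")

    def growth_end(self, chain: ChainGeometryParams | None = None) -> float:
        """Breakpoint s1 where the growth branch meets the plateau."""
        target = self.saturation_value / self.growth_coefficient
        if self.extension_mode == "linear_in_s":
            s1 = target
        else:
            if chain is None:
                raise ValueError("chain params required in chain_model_rx mode")
            # R_x is monotone in s, R_x(s) <= s, so the root is >= target.
            hi = 2.0 * target
            while end_to_end_distance(chain, hi) < target:
                hi *= 2.0
            s1 = brentq(
                lambda s: end_to_end_distance(chain, s) - target, 1e-12, hi
            )
        return min(s1, self.plateau_end)


@dataclass(frozen=True)
class FrictionTrace:
    """Friction vs translocated beads, from MD or from a model."""

    s_values: np.ndarray
    eta_values: np.ndarray
    uncertainty: np.ndarray | None = None
    provenance: str = "model_evaluated"  # or "md_extracted"
    clipped_points: int = 0  # negatives clipped to 0 during extraction
    low_confidence: bool = False  # extraction from too small an ensemble

    def __post_init__(self) -> None:
        s = np.asarray(self.s_values, float)
        e = np.asarray(self.eta_values, float)
        if s.shape != e.shape:
            raise ValueError("s and eta grids differ in shape")
        if np.any(np.diff(s) <= 0):
            raise ValueError("s_values must be strictly increasing")
        if not np.all(np.isfinite(e)) or np.any(e < 0):
            raise ValueError("eta values must be finite and >= 0")


@dataclass(frozen=True)
class FrictionFit:
    """Fit result: the model plus residual diagnostics."""

    model: TransFrictionModel
    residual_rms: float
    converged: bool
    message: str = ""


def evaluate(model: TransFrictionModel, s,
             chain: ChainGeometryParams | None = None):
    """Evaluate eta_TS at translocated-bead count ``s`` (scalar or array)."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("translocated bead count s must be >= 0")
    s1 = model.growth_end(chain)
    s2 = model.plateau_end
    if model.extension_mode == "linear_in_s":
        rx = s
    else:
        rx = np.where(s > 0, end_to_end_distance(chain, np.maximum(s, 1e-12)), 0.0)
    # clip the decay argument so the unselected np.where branch stays finite
    decay_arg = np.clip((s - s2) / model.decay_scale, 0.0, 700.0)
    eta = np.where(
        s <= s1,
        model.growth_coefficient * rx,
        np.where(
            s <= s2,
            model.saturation_value,
            model.asymptote
            + (model.saturation_value - model.asymptote) * np.exp(-decay_arg),
        ),
    )
    return eta if eta.ndim else float(eta)


def extract_from_waiting_times(waiting, cis_front, pore_friction: float,
                               drive: float, smooth_window: int = 0,
                               s_values=None) -> FrictionTrace:
    """Invert waiting times into a trans-side friction trace.

    In the deterministic strong-stretching theory the waiting time of bead
    ``s`` is ``w(s) = Gamma(s)/f = (R(s) + eta_p + eta_TS(s))/f``, so

        eta_TS(s) = f * w(s) - R(s) - eta_p.

    Parameters are all dimensionless (theory units).  ``waiting`` and
    ``cis_front`` must share a grid; ``s_values`` defaults to 1..len(w).
    Negative inverted values are clipped to zero and counted.  An optional
    centered moving average of odd width ``smooth_window`` is applied to the
    waiting times first.
    """
    w = np.asarray(waiting, dtype=float)
    r = np.asarray(cis_front, dtype=float)
    if w.shape != r.shape:
        raise ValueError("waiting-time and cis-front grids differ in shape")
    if np.any(w <= 0):
        raise ValueError("waiting times must be positive")
    if smooth_window > 1:
        if smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        w = np.convolve(np.pad(w, pad, mode="edge"), kernel, mode="valid")
    eta = drive * w - r - pore_friction
    if np.all(eta < 0):
        raise ValueError(
            "all inverted friction values negative: pore-friction "
            "calibration inconsistent with the waiting times"
        )
    clipped = int(np.sum(eta < -1e-9))  # ignore pure rounding residue
    eta = np.clip(eta, 0.0, None)
    if s_values is None:
        s_values = np.arange(1, len(w) + 1, dtype=float)
    return FrictionTrace(
        s_values=np.asarray(s_values, float),
        eta_values=eta,
        provenance="md_extracted",
        clipped_points=clipped,
    )


def _model_curve(theta, s):
    c1, eta_sat, eta_inf, s2, lam = theta
    s1 = min(eta_sat / c1, s2)
    return np.where(
        s <= s1,
        c1 * s,
        np.where(s <= s2, eta_sat,
                 eta_inf + (eta_sat - eta_inf) * np.exp(-(s - s2) / lam)),
    )


def fit(trace: FrictionTrace, n0: float,
        fix_saturation: float | None = None,
        fix_asymptote: float | None = None,
        trim: int = 2) -> FrictionFit:
    """Least-squares fit of the three-regime model to a friction trace.

    ``trim`` points are dropped at each end (pore entry/exit artifacts in MD
    traces).  ``fix_saturation`` / ``fix_asymptote`` pin eta_sat / eta_inf
    instead of fitting them.  The fit is flagged non-converged when the
    optimizer fails or the recovered breakpoints are degenerate
    (``s1 >= s2`` or ``s2`` outside the data range — e.g. a monotone trace
    with no plateau).
    """
    s = np.asarray(trace.s_values, float)
    eta = np.asarray(trace.eta_values, float)
    if trim > 0 and len(s) > 2 * trim + 5:
        s, eta = s[trim:-trim], eta[trim:-trim]
    if len(s) < 10:
        raise ValueError("need at least 10 points spanning the three regimes")

    # data-driven initial guess
    eta_sat0 = fix_saturation if fix_saturation is not None else float(np.max(eta))
    eta_inf0 = fix_asymptote if fix_asymptote is not None else float(
        max(np.mean(eta[-3:]), 1e-3))
    head = slice(0, max(3, len(s) // 8))
    c10 = max(float(np.polyfit(s[head], eta[head], 1)[0]), 1e-3)
    near_sat = s[eta >= 0.95 * eta_sat0]
    s20 = float(near_sat[-1]) if len(near_sat) else float(0.6 * n0)
    lam0 = max(n0 / 8.0, 1.0)

    free = {"c1": c10, "eta_sat": eta_sat0, "eta_inf": eta_inf0,
            "s2": s20, "lam": lam0}
    fixed = {}
    if fix_saturation is not None:
        fixed["eta_sat"] = free.pop("eta_sat")
    if fix_asymptote is not None:
        fixed["eta_inf"] = free.pop("eta_inf")
    names = list(free)

    def theta_full(p):
        d = {**dict(zip(names, p)), **fixed}
        return (d["c1"], d["eta_sat"], d["eta_inf"], d["s2"], d["lam"])

    def resid(p):
        return _model_curve(theta_full(p), s) - eta

    lower = {"c1": 1e-6, "eta_sat": 1e-6, "eta_inf": 1e-6, "s2": float(s[0]),
             "lam": 1e-3}
    upper = {"c1": np.inf, "eta_sat": np.inf, "eta_inf": np.inf,
             "s2": float(2 * n0), "lam": 10.0 * n0}
    res = least_squares(
        resid, [free[k] for k in names],
        bounds=([lower[k] for k in names], [upper[k] for k in names]),
        x_scale="jac", ftol=1e-14, xtol=1e-14, gtol=1e-14,
    )
    c1, eta_sat, eta_inf, s2, lam = theta_full(res.x)
    eta_inf = min(eta_inf, eta_sat)
    try:
        model = TransFrictionModel(
            growth_coefficient=c1, saturation_value=eta_sat,
            asymptote=eta_inf, plateau_end=s2, decay_scale=lam)
    except ValueError as exc:
        return FrictionFit(
            model=TransFrictionModel(1.0, max(eta_sat, 1e-6),
                                     min(eta_inf, eta_sat), s2, lam),
            residual_rms=float(np.sqrt(np.mean(res.fun**2))),
            converged=False, message=str(exc))
    s1 = model.growth_end()
    degenerate = not (s1 < s2 < n0)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return FrictionFit(model=model, residual_rms=rms,
                       converged=bool(res.success) and not degenerate,
                       message="degenerate breakpoints" if degenerate else res.message)


def zero_friction() -> TransFrictionModel:
    """Vanishing trans-side friction (fully flexible chain limit)."""
    return TransFrictionModel(growth_coefficient=1e-12, saturation_value=1e-9,
                              asymptote=1e-9, plateau_end=np.inf,
                              decay_scale=1.0)


def rod_friction(n0: float) -> TransFrictionModel:
    """Rigid-rod special case eta_TS(s) = s for s in [0, N0]."""
    return TransFrictionModel(growth_coefficient=1.0, saturation_value=float(n0),
                              asymptote=float(n0), plateau_end=float(n0),
                              decay_scale=1.0)


def save_calibration(model: TransFrictionModel, path, *, n0: float,
                     kappa_b: float, f: float, provenance: str) -> None:
    payload = {
        "c1": model.growth_coefficient,
        "eta_sat": model.saturation_value,
        "eta_inf": model.asymptote,
        "s2": model.plateau_end,
        "lambda": model.decay_scale,
        "extension_mode": model.extension_mode,
        "n0": n0, "kappa_b": kappa_b, "f": f,
        "provenance": provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_calibration(source) -> tuple[TransFrictionModel, dict]:
    """Load a calibration JSON; returns (model, metadata)."""
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    model = TransFrictionModel(
        growth_coefficient=payload["c1"],
        saturation_value=payload["eta_sat"],
        asymptote=payload["eta_inf"],
        plateau_end=payload["s2"],
        decay_scale=payload["lambda"],
        extension_mode=payload.get("extension_mode", "linear_in_s"),
    )
    meta = {k: payload[k] for k in ("n0", "kappa_b", "f", "provenance")
            if k in payload}
    return model, meta


def reference_friction() -> TransFrictionModel:
    """Shipped calibration for the reference case N0=64, kappa_b=30, f=20."""
    ref = resources.files("transloc.data").joinpath("reference_friction.json")
    with ref.open() as fh:
        model, _ = load_calibration(fh)
    return model
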