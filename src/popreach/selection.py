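"""Target selection: color saliency, recurrent color competition, selection
history, and the location field that the movement system reads.

The selection stage has three coupled pieces:

* A **color saliency** stage that assigns each of the four color units a
  feed-forward drive: high for the odd (target) color, low for the distractor
  color, baseline for absent colors.  Because each unit's input is its
  saliency, integration speed rises with saliency.

* A **color competition** layer: a rectified recurrent network (Grossberg
  style) over the four color units with self-excitation ``b`` and global
  inhibition ``d``,

      tau * du_i/dt = -u_i + b*f(u_i) - d*sum_{j!=i} f(u_j) + s_i + bias_i,

  with ``f`` half-wave rectification and additive Gaussian noise.  A color
  "wins" when its rectified activation crosses ``winner_threshold``; the
  dynamics keep running afterwards, which is what lets late history biases
  leak into an ongoing movement.

* A **selection history** store holding the previous trial's target and
  distractor colors.  Five model variants turn the store into a bias on the
  color units: facilitation only (M1), inhibition only (M2), both at once
  (M3a), facilitation then inhibition (M3b), or inhibition then facilitation
  (M3c).  The timed variants switch at a fixed fraction of the calibrated
  display-onset-to-movement-onset interval.

The color units gate Gaussian feature maps multiplicatively into a 2D
dynamic neural field over the display plane (local excitation, global
inhibition); the field's peak is the current best guess of the target
location and is what the movement stage tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .design import (
    COLOR_POOL,
    Display,
    corner_position,
)

# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SaliencyConfig:
    """Feed-forward color drive.  The odd color is the most salient item in
    the display; the (triple) distractor color is weakly salient; absent
    colors get the baseline."""

    target: float = 1.0
    distractor: float = 0.4
    absent: float = 0.0


@dataclass(frozen=True)
class CompetitionParams:
    """Recurrent color-competition parameters.

    ``noise_sd`` is the standard deviation of the additive noise per unit
    per sqrt(ms); the per-step increment is scaled by sqrt(dt) so that the
    stochastic dynamics are insensitive to the integration step.
    """

    b: float = 0.9            # self-excitation gain
    d: float = 0.8            # global (mutual) inhibition gain
    tau: float = 200.0        # time constant, ms
    noise_sd: float = 0.002   # per-sqrt(ms) additive noise SD
    dt: float = 2.0           # Euler step, ms
    winner_threshold: float = 1.0
    t_max: float = 1500.0     # trial cap, ms

    def __post_init__(self) -> None:
        if min(self.b, self.d, self.tau, self.dt) <= 0:
            raise ValueError("b, d, tau, dt must be positive")
        if self.winner_threshold <= 0:
            raise ValueError("winner_threshold must exceed the resting level")


@dataclass(frozen=True)
class FieldParams:
    """2D location-field parameters (Amari-style: local excitation via a
    Gaussian kernel, global inhibition, negative resting level)."""

    x_range: tuple[float, float] = (-10.0, 10.0)
    y_range: tuple[float, float] = (10.0, 30.0)
    grid_step: float = 0.625          # cm
    tau: float = 60.0                 # ms
    h: float = -0.1                   # resting level
    input_gain: float = 1.2
    item_sigma: float = 1.3           # cm, feature-map bump width
    exc_gain: float = 0.3
    exc_sigma: float = 1.8            # cm
    inh_gain: float = 0.004           # global inhibition per unit summed output
    peak_threshold: float = 0.2       # field output declaring a peak


@dataclass(frozen=True)
class HistoryModelSpec:
    """One of the five inter-trial selection-history mechanisms.

    ``switch_fraction`` applies to the timed variants only: M3b runs
    facilitation before the switch and inhibition after; M3c the reverse.
    The switch time is ``switch_fraction * onset_interval`` where
    ``onset_interval`` is the calibrated display-to-movement-onset time.
    """

    variant: str = "M3c"
    fac_gain: float = 0.30
    inh_gain: float = 0.60
    switch_fraction: float = 0.65

    VARIANTS = ("M1", "M2", "M3a", "M3b", "M3c")

    def __post_init__(self) -> None:
        if self.variant not in self.VARIANTS:
            raise ValueError(f"unknown history variant {self.variant!r}")
        if self.fac_gain < 0 or self.inh_gain < 0:
            raise ValueError("gains must be nonnegative")
        if not (0.0 < self.switch_fraction <= 1.0):
            raise ValueError("switch_fraction must lie in (0, 1]")
        # Single-mechanism variants force the other gain to zero.
        if self.variant == "M1" and self.inh_gain != 0.0:
            object.__setattr__(self, "inh_gain", 0.0)
        if self.variant == "M2" and self.fac_gain != 0.0:
            object.__setattr__(self, "fac_gain", 0.0)

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return {
            "M1": ("fac_gain",),
            "M2": ("inh_gain",),
            "M3a": ("fac_gain", "inh_gain"),
            "M3b": ("fac_gain", "inh_gain", "switch_fraction"),
            "M3c": ("fac_gain", "inh_gain", "switch_fraction"),
        }[self.variant]


@dataclass
class HistoryStore:
    """One-trial memory of the previous target and distractor colors."""

    prev_target: Optional[str] = None
    prev_distractor: Optional[str] = None

    @property
    def empty(self) -> bool:
        return self.prev_target is None and self.prev_distractor is None


def update_history(store: HistoryStore, display: Display) -> HistoryStore:
    """Overwrite the store with the completed trial's true display roles."""
    return HistoryStore(display.target_color, display.distractor_color)


# --------------------------------------------------------------------------
# Saliency and history bias
# --------------------------------------------------------------------------


def compute_saliency(
    display: Display, config: SaliencyConfig = SaliencyConfig()
) -> dict[str, float]:
    """Assign each color unit its feed-forward drive for this display."""
    s = {c: config.absent for c in COLOR_POOL}
    s[display.distractor_color] = config.distractor
    s[display.target_color] = config.target
    return s


def history_bias(
    store: HistoryStore,
    spec: HistoryModelSpec,
    t: float,
    onset_interval: float,
) -> dict[str, float]:
    """Bias on the color units contributed by the previous trial at time
    ``t`` (ms since display onset).

    Facilitation adds ``fac_gain`` to the previous target's unit; inhibition
    subtracts ``inh_gain`` from the previous distractor's unit.  Which of
    the two applies at ``t`` depends on the variant.
    """
    if onset_interval <= 0:
        raise ValueError("onset_interval must be positive")
    bias = {c: 0.0 for c in COLOR_POOL}
    if store.empty:
        return bias
    t_switch = spec.switch_fraction * onset_interval
    if spec.variant == "M1":
        fac, inh = True, False
    elif spec.variant == "M2":
        fac, inh = False, True
    elif spec.variant == "M3a":
        fac, inh = True, True
    elif spec.variant == "M3b":
        fac, inh = (t < t_switch), (t >= t_switch)
    else:  # M3c
        fac, inh = (t >= t_switch), (t < t_switch)
    if fac and store.prev_target is not None:
        bias[store.prev_target] += spec.fac_gain
    if inh and store.prev_distractor is not None:
        bias[store.prev_distractor] -= spec.inh_gain
    return bias


# --------------------------------------------------------------------------
# Color competition
# --------------------------------------------------------------------------


@dataclass
class ColorCompetitionState:
    u: np.ndarray                    # activation per color, COLOR_POOL order
    t: float = 0.0                   # elapsed ms
    winner: Optional[str] = None
    winner_time: Optional[float] = None

    @classmethod
    def resting(cls) -> "ColorCompetitionState":
        return cls(u=np.zeros(len(COLOR_POOL)))


def _rect(u: np.ndarray) -> np.ndarray:
    return np.maximum(u, 0.0)


def step_color_competition(
    state: ColorCompetitionState,
    saliency: np.ndarray,
    bias: np.ndarray,
    params: CompetitionParams,
    rng: Optional[np.random.Generator] = None,
) -> ColorCompetitionState:
    """One Euler step of the rectified recurrent competition.

    ``saliency`` and ``bias`` are arrays in ``COLOR_POOL`` order.  The
    winner is declared at the first threshold crossing of the rectified
    output; ties within a step go to the larger activation, then to the
    fixed color order.
    """
    f = _rect(state.u)
    total = f.sum()
    du = (-state.u + params.b * f - params.d * (total - f)
          + saliency + bias) * (params.dt / params.tau)
    u = state.u + du
    if params.noise_sd > 0.0 and rng is not None:
        u = u + rng.normal(
            0.0, params.noise_sd * np.sqrt(params.dt), size=u.shape
        )
    t = state.t + params.dt
    winner, wtime = state.winner, state.winner_time
    if winner is None:
        out = _rect(u)
        crossed = np.flatnonzero(out >= params.winner_threshold)
        if crossed.size:
            # larger activation wins; argmax breaks exact ties by color order
            best = crossed[np.argmax(u[crossed])]
            winner = COLOR_POOL[best]
            wtime = t
    return ColorCompetitionState(u=u, t=t, winner=winner, winner_time=wtime)


def run_color_competition(
    display: Display,
    store: HistoryStore,
    spec: HistoryModelSpec,
    params: CompetitionParams,
    rng: Optional[np.random.Generator] = None,
    onset_interval: float = 300.0,
    saliency_config: SaliencyConfig = SaliencyConfig(),
) -> list[ColorCompetitionState]:
    """Run the color competition alone until a winner or ``t_max``.

    Returns the full state trace (the initial resting state included).  A
    run that reaches ``t_max`` without a winner leaves ``winner`` as None
    in the final state; callers treat that as an unresolved trial rather
    than an error.
    """
    sal = saliency_array(compute_saliency(display, saliency_config))
    state = ColorCompetitionState.resting()
    trace = [state]
    n_steps = int(round(params.t_max / params.dt))
    for _ in range(n_steps):
        bias = bias_array(history_bias(store, spec, state.t, onset_interval))
        state = step_color_competition(state, sal, bias, params, rng)
        trace.append(state)
        if state.winner is not None:
            break
    return trace


def saliency_array(s: dict[str, float]) -> np.ndarray:
    return np.array([s[c] for c in COLOR_POOL])


def bias_array(b: dict[str, float]) -> np.ndarray:
    return np.array([b[c] for c in COLOR_POOL])


def trace_to_array(trace: list[ColorCompetitionState]) -> np.ndarray:
    """(n_steps, 1+4) array of t and the four activations, for CSV export."""
    return np.array([[st.t, *st.u] for st in trace])


# --------------------------------------------------------------------------
# Location field
# --------------------------------------------------------------------------


@dataclass
class LocationField:
    a: np.ndarray                    # activation, shape (ny, nx)
    params: FieldParams
    xs: np.ndarray
    ys: np.ndarray

    @classmethod
    def resting(cls, params: FieldParams) -> "LocationField":
        xs = np.arange(params.x_range[0], params.x_range[1] + 1e-9,
                       params.grid_step)
        ys = np.arange(params.y_range[0], params.y_range[1] + 1e-9,
                       params.grid_step)
        a = np.full((ys.size, xs.size), params.h)
        return cls(a=a, params=params, xs=xs, ys=ys)

    @property
    def max_output(self) -> float:
        return float(max(self.a.max(), 0.0))

    def peak(self) -> Optional[tuple[float, float]]:
        """(x, y) of the field maximum, or None below the peak threshold."""
        if self.a.max() < self.params.peak_threshold:
            return None
        iy, ix = np.unravel_index(np.argmax(self.a), self.a.shape)
        return (float(self.xs[ix]), float(self.ys[iy]))

    def readout(self) -> Optional[tuple[float, float]]:
        """Population-vector readout: the activation-weighted centroid of
        the rectified field output, or None if the field is silent.  Unlike
        :meth:`peak` this is a graded quantity — while several locations are
        still active the readout lies between them, which is what lets
        unresolved competition bend an ongoing movement."""
        out = _rect(self.a)
        total = out.sum()
        if total <= 0.0 or self.a.max() < self.params.peak_threshold:
            return None
        w = out / total
        x = float((w.sum(axis=0) * self.xs).sum())
        y = float((w.sum(axis=1) * self.ys).sum())
        return (x, y)


def _gauss_conv_matrix(n: int, sigma_px: float, truncate: float = 4.0
                       ) -> np.ndarray:
    """Dense 1D Gaussian-convolution matrix (zero boundary, kernel
    truncated at ``truncate`` sigmas and normalized), so that smoothing a
    field is two small matrix products instead of a filter call."""
    radius = int(truncate * sigma_px + 0.5)
    offsets = np.arange(-radius, radius + 1)
    w = np.exp(-0.5 * (offsets / sigma_px) ** 2)
    w /= w.sum()
    K = np.zeros((n, n))
    for o, wi in zip(offsets, w):
        K += wi * np.eye(n, k=o)
    return K


_CONV_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def conv_matrices(params: FieldParams) -> tuple[np.ndarray, np.ndarray]:
    """(Ky, Kx) Gaussian smoothing matrices for a field's grid."""
    key = (params.x_range, params.y_range, params.grid_step, params.exc_sigma)
    if key not in _CONV_CACHE:
        fld = LocationField.resting(params)
        sig = params.exc_sigma / params.grid_step
        _CONV_CACHE[key] = (
            _gauss_conv_matrix(fld.ys.size, sig),
            _gauss_conv_matrix(fld.xs.size, sig),
        )
    return _CONV_CACHE[key]


def feature_maps(display: Display, params: FieldParams) -> np.ndarray:
    """Gaussian feature maps per color, shape (4, ny, nx) in COLOR_POOL
    order.  The target color's map has one bump at the target corner; the
    distractor color's map has bumps at the three remaining corners; absent
    colors map to zero."""
    xs = np.arange(params.x_range[0], params.x_range[1] + 1e-9,
                   params.grid_step)
    ys = np.arange(params.y_range[0], params.y_range[1] + 1e-9,
                   params.grid_step)
    gx, gy = np.meshgrid(xs, ys)
    maps = np.zeros((len(COLOR_POOL), ys.size, xs.size))
    color_corners = {c: [] for c in COLOR_POOL}
    color_corners[display.target_color].append(display.target_corner)
    color_corners[display.distractor_color].extend(display.distractor_corners)
    for ci, color in enumerate(COLOR_POOL):
        for corner in color_corners[color]:
            px, py = corner_position(corner)
            maps[ci] += np.exp(
                -((gx - px) ** 2 + (gy - py) ** 2)
                / (2.0 * params.item_sigma ** 2)
            )
    return maps


def gate_and_step_location_field(
    fld: LocationField,
    maps: np.ndarray,
    color_output: np.ndarray,
    dt: float,
) -> LocationField:
    """One field step with multiplicative gating of the feature maps by the
    rectified color-unit outputs.

    Input to the field is ``sum_c f(u_c) * map_c``; absent colors therefore
    contribute exactly zero, and early in the competition (near-equal
    activations) all four item locations receive input.
    """
    p = fld.params
    inp = p.input_gain * np.tensordot(_rect(color_output), maps, axes=(0, 0))
    out = _rect(fld.a)
    Ky, Kx = conv_matrices(p)
    exc = p.exc_gain * (Ky @ out @ Kx)
    inh = p.inh_gain * out.sum()
    da = (-fld.a + p.h + inp + exc - inh) * (dt / p.tau)
    return replace(fld, a=fld.a + da)
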