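"""Deterministic mean-field models of the host birth-death process.

Two layers:

* a two-type system for the densities of carrier (``x_plus``) and
  non-carrier (``x_minus``) females, assuming a 1:1 sex ratio, with
  vertical transmission probabilities (alpha, beta) and horizontal uptake
  at per-capita rate ``e0``;
* a six-type system with explicit male classes carrying a Y-linked
  transmission-modifier allele (``y`` types suppress male transmission,
  ``z`` types allow it).

Plus the closed-form boundary equilibria, invasion rates and thresholds,
outcome classification from an invasion initial condition, and (w, e0)
phase-diagram scans.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ODEParams",
    "ODEState2",
    "ODEState6",
    "RegionLabel",
    "PhaseDiagram",
    "rhs_two_type",
    "equilibrium_I",
    "equilibrium_II",
    "invasion_rate_at_I",
    "thresholds",
    "integrate",
    "classify_outcome",
    "phase_scan",
    "rhs_six_type",
    "modifier_trajectory",
]

_MODE_AB = {"biparental": (1.0, 1.0), "maternal": (1.0, 0.0),
            "paternal": (0.0, 1.0)}


@dataclass(frozen=True)
class ODEParams:
    """Rate constants for the deterministic systems.

    ``nu`` converts densities to counts (x = n / nu); with ``nu = 1`` the
    state variables are female counts and ``2 d' nu (x+ + x-)`` equals
    ``d'`` times the total host count.
    """

    b0: float = 4.0
    d0: float = 1.0
    dprime: float = 0.001
    nu: float = 1.0
    e0: float = 0.0
    alpha: float = 1.0
    beta: float = 1.0
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        for name in ("b0", "d0", "dprime", "e0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.w <= 0:
            raise ValueError("w must be positive")

    def with_mode(self, mode: str) -> "ODEParams":
        a, b = _MODE_AB[mode]
        return replace(self, alpha=a, beta=b)


@dataclass(frozen=True)
class ODEState2:
    x_plus: float
    x_minus: float

    @property
    def total(self) -> float:
        return self.x_plus + self.x_minus

    def as_array(self) -> np.ndarray:
        return np.array([self.x_plus, self.x_minus])


@dataclass(frozen=True)
class ODEState6:
    x_plus: float
    x_minus: float
    y_plus: float
    y_minus: float
    z_plus: float
    z_minus: float

    @property
    def N(self) -> float:
        return (self.x_plus + self.x_minus + self.y_plus + self.y_minus
                + self.z_plus + self.z_minus)

    def as_array(self) -> np.ndarray:
        return np.array([self.x_plus, self.x_minus, self.y_plus,
                         self.y_minus, self.z_plus, self.z_minus])


@dataclass(frozen=True)
class RegionLabel:
    """Long-run outcome of an invasion: one of loss / fixation / bimorphic /
    host_extinction / unresolved, with the terminal densities."""

    label: str
    terminal_state: tuple

    _VALID = ("loss", "fixation", "bimorphic", "host_extinction", "unresolved")

    def __post_init__(self) -> None:
        if self.label not in self._VALID:
            raise ValueError(f"invalid label {self.label!r}")


@dataclass
class PhaseDiagram:
    w_grid: np.ndarray
    e0_grid: np.ndarray
    labels: np.ndarray  # object array of shape (len(e0_grid), len(w_grid))
    mode: str
    params: ODEParams = field(default_factory=ODEParams)

    def __post_init__(self) -> None:
        if self.labels.shape != (len(self.e0_grid), len(self.w_grid)):
            raise ValueError("label matrix shape does not match grids")

    def label_row(self, e0: float) -> list[str]:
        i = int(np.argmin(np.abs(self.e0_grid - e0)))
        return [lab for lab in self.labels[i]]

    def boundary_cells(self) -> list[tuple[int, int]]:
        """Grid cells whose label differs from a right/upper neighbour."""
        cells = []
        for i in range(self.labels.shape[0]):
            for j in range(self.labels.shape[1]):
                if (j + 1 < self.labels.shape[1]
                        and self.labels[i, j] != self.labels[i, j + 1]):
                    cells.append((i, j))
                elif (i + 1 < self.labels.shape[0]
                        and self.labels[i, j] != self.labels[i + 1, j]):
                    cells.append((i, j))
        return cells


def _rhs2(t, s, p: ODEParams):
    xp = max(s[0], 0.0)
    xm = max(s[1], 0.0)
    tot = xp + xm
    if tot <= 0.0:
        return [0.0, 0.0]
    a, b, w = p.alpha, p.beta, p.w
    dd = p.d0 + 2.0 * p.dprime * p.nu * tot
    birth_p = (p.b0 / 2.0) * (xp * xp * (a + b - a * b)
                              + (a + b) * xm * xp) / tot
    birth_m = (p.b0 / 2.0) * (xm * xm + (2.0 - a - b) * xm * xp
                              + (1.0 - a) * (1.0 - b) * xp * xp) / tot
    dxp = birth_p - xp * dd / w + p.e0 * xm
    dxm = birth_m - xm * dd - p.e0 * xm
    return [dxp, dxm]


def rhs_two_type(state: ODEState2, params: ODEParams) -> tuple[float, float]:
    """Time derivatives (dx+/dt, dx-/dt) of the two-type system."""
    d = _rhs2(0.0, state.as_array(), params)
    return (d[0], d[1])


def equilibrium_I(params: ODEParams) -> ODEState2:
    """Symbiont-free boundary equilibrium (0, (b0/2 - d0) / (2 d' nu))."""
    if params.e0 != 0:
        raise ValueError("equilibrium I requires e0 = 0 "
                         "(symbiont-free state is not invariant otherwise)")
    xm = (params.b0 / 2.0 - params.d0) / (2.0 * params.dprime * params.nu)
    if xm < 0:
        raise ValueError("b0/2 <= d0: host population is not viable")
    return ODEState2(0.0, xm)


def equilibrium_II(params: ODEParams) -> ODEState2:
    """All-carrier boundary equilibrium ((w b0/2 - d0) / (2 d' nu), 0)."""
    if params.e0 != 0:
        raise ValueError("equilibrium II is defined at e0 = 0")
    xp = (params.w * params.b0 / 2.0 - params.d0) / (2.0 * params.dprime * params.nu)
    if xp < 0:
        raise ValueError("w b0/2 <= d0: carrier population is not viable")
    return ODEState2(xp, 0.0)


def invasion_rate_at_I(params: ODEParams, mode: str | None = None) -> float:
    """Initial per-capita growth rate of carriers at equilibrium I.

    Equals (b0/2)((alpha + beta) - 1/w); for the presets this is
    b0 (1 - 1/(2w)) (biparental) and (b0/2)(1 - 1/w) (maternal).
    """
    if params.e0 != 0:
        raise ValueError("invasion rate at I is defined at e0 = 0")
    p = params.with_mode(mode) if mode is not None else params
    return (p.b0 / 2.0) * ((p.alpha + p.beta) - 1.0 / p.w)


def thresholds(params: ODEParams) -> tuple[float, float, float]:
    """(w0 biparental, w0 maternal, w1) = (1/2, 1, 2 d0 / b0).

    w0 is the invasion threshold at equilibrium I; w1 is the host-extinction
    threshold at which the all-carrier equilibrium density reaches zero.
    """
    if params.b0 == 0:
        raise ValueError("b0 = 0: thresholds undefined")
    return (0.5, 1.0, 2.0 * params.d0 / params.b0)


def integrate(rhs, initial_state, params: ODEParams, t_span,
              t_eval=None, rtol: float = 1e-8, atol: float = 1e-10):
    """Adaptive integration of one of the model right-hand sides.

    ``rhs`` is either :func:`rhs_two_type` or :func:`rhs_six_type` (the
    state-based signatures); the corresponding state object supplies the
    initial condition.  Returns the scipy solution object with small
    negative excursions (within ``atol``) clamped to zero.
    """
    if rhs is rhs_two_type:
        fun = _rhs2
    elif rhs is rhs_six_type:
        fun = _rhs6
    else:
        fun = rhs
    y0 = (initial_state.as_array()
          if hasattr(initial_state, "as_array") else np.asarray(initial_state, float))
    if np.any(y0 < 0):
        raise ValueError("initial densities must be nonnegative")
    sol = solve_ivp(fun, t_span, y0, args=(params,), method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    neg = sol.y < 0
    if np.any(sol.y < -100 * atol):
        raise RuntimeError("solver produced densities below -100*atol")
    sol.y[neg] = 0.0
    return sol


def classify_outcome(params: ODEParams, mode: str | None = None,
                     init_frac: float = 0.01, eps: float = 1e-6,
                     extinction_threshold: float = 0.5,
                     conv_tol: float = 1e-7, t_cap: float = 1e4,
                     rtol: float = 1e-8, atol: float = 1e-10) -> RegionLabel:
    """Classify the fate of an invading symbiont in the two-type system.

    Integrates from equilibrium I perturbed by a small carrier density
    (``init_frac`` of the resident density) until the state stops changing
    (|d state/dt| per unit time below ``conv_tol``) or ``t_cap``.

    Labels: ``host_extinction`` once the total host count (both sexes)
    falls below ``extinction_threshold`` hosts -- collapse below one
    individual is extinction even when the approach to zero density is
    only algebraic in time; at convergence, ``fixation`` if the
    non-carrier share x-/total is below ``eps``, ``loss`` if the carrier
    share is below ``eps`` (only reachable at e0 = 0), otherwise
    ``bimorphic``.  Non-convergence within ``t_cap`` yields
    ``unresolved``.
    """
    p = params.with_mode(mode) if mode is not None else params
    xm_hat = (p.b0 / 2.0 - p.d0) / (2.0 * p.dprime * p.nu)
    if xm_hat <= 0:
        raise ValueError("host population not viable without the symbiont")
    y = np.array([init_frac * xm_hat, xm_hat])
    t = 0.0
    chunk = 10.0
    while t < t_cap:
        chunk = min(chunk, t_cap - t)
        sol = solve_ivp(_rhs2, (t, t + chunk), y, args=(p,), method="LSODA",
                        rtol=rtol, atol=atol)
        if not sol.success:
            return RegionLabel("unresolved", tuple(y))
        y_new = np.maximum(sol.y[:, -1], 0.0)
        rate = np.abs(y_new - y).max() / chunk
        t += chunk
        y = y_new
        total = 2.0 * p.nu * y.sum()  # both sexes, in host counts
        if total < extinction_threshold:
            return RegionLabel("host_extinction", tuple(y))
        d = np.abs(_rhs2(t, y, p)).max()
        if rate < conv_tol and d < max(conv_tol, 1e-6 * max(1.0, y.max())):
            xp, xm = y
            if xm < eps * (xp + xm):
                return RegionLabel("fixation", tuple(y))
            if xp < eps * (xp + xm) and p.e0 == 0:
                return RegionLabel("loss", tuple(y))
            return RegionLabel("bimorphic", tuple(y))
        chunk = min(chunk * 2.0, 200.0)
    return RegionLabel("unresolved", tuple(y))


def phase_scan(w_values, e0_values, mode: str, params: ODEParams | None = None,
               refine: bool = False, refine_step: float = 0.001,
               **classify_kwargs) -> PhaseDiagram:
    """Classify every (w, e0) grid point for one transmission mode.

    With ``refine=True``, w-boundaries between differing labels are located
    by bisection down to ``refine_step`` and stored on the returned
    diagram as ``diagram.refined_boundaries`` (a list of
    ``(e0, w_lo, w_hi, label_lo, label_hi)`` tuples).
    """
    base = (params or ODEParams()).with_mode(mode)
    w_values = np.asarray(w_values, float)
    e0_values = np.asarray(e0_values, float)
    if np.any(np.diff(w_values) <= 0) or (len(e0_values) > 1
                                          and np.any(np.diff(e0_values) <= 0)):
        raise ValueError("grid vectors must be strictly increasing")
    labels = np.empty((len(e0_values), len(w_values)), dtype=object)
    for i, e0 in enumerate(e0_values):
        for j, w in enumerate(w_values):
            pr = replace(base, e0=float(e0), w=float(w))
            labels[i, j] = classify_outcome(pr, **classify_kwargs).label
    diagram = PhaseDiagram(w_values, e0_values, labels, mode, base)
    if refine:
        diagram.refined_boundaries = _refine_w_boundaries(
            diagram, base, refine_step, **classify_kwargs)
    return diagram


def _refine_w_boundaries(diagram: PhaseDiagram, base: ODEParams,
                         step: float, **classify_kwargs):
    out = []
    for i, e0 in enumerate(diagram.e0_grid):
        row = diagram.labels[i]
        for j in range(len(row) - 1):
            if row[j] == row[j + 1]:
                continue
            lo, hi = float(diagram.w_grid[j]), float(diagram.w_grid[j + 1])
            lab_lo, lab_hi = row[j], row[j + 1]
            while hi - lo > step:
                mid = 0.5 * (lo + hi)
                lab = classify_outcome(
                    replace(base, e0=float(e0), w=mid), **classify_kwargs).label
                if lab == lab_lo:
                    lo = mid
                else:
                    hi = mid
                    lab_hi = lab
            out.append((float(e0), lo, hi, lab_lo, lab_hi))
    return out


def _rhs6(t, s, p: ODEParams):
    xp, xm, yp, ym, zp, zm = (max(v, 0.0) for v in s)
    F = xp + xm
    M = yp + ym + zp + zm
    if F <= 0.0 or M <= 0.0:
        return [0.0] * 6
    N = F + M
    w, e0, hb = p.w, p.e0, p.b0 / 2.0
    dd = p.d0 + p.dprime * p.nu * N
    dxp = hb * (xp * M + xm * zp) / M - xp * dd / w + e0 * xm
    dxm = hb * (xm * ym + xm * yp + xm * zm) / M - xm * dd - e0 * xm
    dyp = hb * (xp * yp + xp * ym) / F - yp * dd / w + e0 * ym
    dym = hb * (xm * ym + xm * yp) / F - ym * dd - e0 * ym
    dzp = hb * (xp * zp + xp * zm + xm * zp) / F - zp * dd / w + e0 * zm
    dzm = hb * (xm * zm) / F - zm * dd - e0 * zm
    return [dxp, dxm, dyp, dym, dzp, dzm]


def rhs_six_type(state: ODEState6, params: ODEParams) -> tuple:
    """Time derivatives of the six-type (sex x carriage x male allele) system.

    Females are x types; males carrying the transmission-suppressing allele
    are y types (their matings follow the maternal rule), males carrying the
    transmission-permitting allele are z types (biparental rule).  Horizontal
    uptake at rate e0 acts on every non-carrier class; carrier death rates
    are divided by w.
    """
    F = state.x_plus + state.x_minus
    M = state.y_plus + state.y_minus + state.z_plus + state.z_minus
    if F <= 0.0 or M <= 0.0:
        raise ValueError("six-type derivatives need positive female and male "
                         "totals (mating fractions undefined)")
    return tuple(_rhs6(0.0, state.as_array(), params))


def modifier_trajectory(params: ODEParams, init: ODEState6, t_span,
                        t_eval=None, rtol: float = 1e-8, atol: float = 1e-10):
    """Integrate the six-type system and derive frequency series.

    Returns a dict with keys ``t``, the six density series (``x_plus`` ...),
    and derived series ``carrier_freq`` (carriers / total),
    ``m_minus_freq`` (y males / all males) and ``D``, the male-class
    disequilibrium p1 p4 - p2 p3 with classes (y-, y+, z-, z+).
    """
    if t_eval is None:
        t_eval = np.linspace(t_span[0], t_span[1], 201)
    sol = integrate(rhs_six_type, init, params, t_span, t_eval=t_eval,
                    rtol=rtol, atol=atol)
    xp, xm, yp, ym, zp, zm = sol.y
    males = yp + ym + zp + zm
    total = xp + xm + males
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = ym / males
        p2 = yp / males
        p3 = zm / males
        p4 = zp / males
        out = {
            "t": sol.t,
            "x_plus": xp, "x_minus": xm,
            "y_plus": yp, "y_minus": ym,
            "z_plus": zp, "z_minus": zm,
            "carrier_freq": (xp + yp + zp) / total,
            "m_minus_freq": (yp + ym) / males,
            "D": p1 * p4 - p2 * p3,
        }
    return out
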