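"""Multi-exponential spectral fits of rotational correlation functions.

A correlation function C(t) is represented as a sum of exponentials over
a fixed, logarithmically equidistant timescale grid,

    C_fit(t) = sum_i alpha_i exp(-t / tau_i),      alpha_i >= 0,

with the weights obtained by non-negative least squares (NNLS). The grid
fineness acts as the implicit regularizer: no penalty beyond
non-negativity is applied. Two named presets cover the common cases —
"NH" (N = 100 timescales, 1 ps … 100 ns) for peptide backbone amides and
"CH" (N = 500, 1 fs … 1 us) for detergent C-H bonds with substantial
sub-picosecond dynamics.

From the fit follow, analytically,

    J(omega)  = 2 sum_i alpha_i tau_i / (1 + omega^2 tau_i^2)   (spectral density)
    tau_eff   = integral C_fit dt = sum_i alpha_i tau_i = J(0)/2

A small weight occasionally lands on the slowest grid timescale when the
correlation function has not fully decayed to zero within the available
lags; :func:`filter_artificial_slow` zeroes such weights (default
threshold 1%) and records the removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize

from .correlation import CorrelationFunction

__all__ = [
    "TimescaleGrid",
    "ExponentialFit",
    "build_grid",
    "fit_exponentials",
    "filter_artificial_slow",
    "spectral_density",
    "effective_correlation_time",
    "write_fit_table",
    "read_fit_table",
    "GRID_PRESETS",
]

#: Named grids: (n, tau_min_ps, tau_max_ps).
GRID_PRESETS: dict[str, tuple[int, float, float]] = {
    "NH": (100, 1.0, 1.0e5),        # 1 ps .. 100 ns
    "CH": (500, 1.0e-3, 1.0e6),     # 1 fs .. 1 us
}


@dataclass(frozen=True)
class TimescaleGrid:
    """Log-equidistant timescale grid, tau in ps."""

    taus: np.ndarray

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        object.__setattr__(self, "taus", taus)
        if taus.ndim != 1 or taus.size < 2:
            raise ValueError("grid needs at least two timescales")
        if np.any(taus <= 0) or np.any(np.diff(taus) <= 0):
            raise ValueError("timescales must be positive and strictly increasing")
        ratios = taus[1:] / taus[:-1]
        if np.max(np.abs(ratios / ratios[0] - 1.0)) > 1e-9:
            raise ValueError("grid must be log-equidistant")

    @property
    def n(self) -> int:
        return int(self.taus.size)

    @property
    def tau_min(self) -> float:
        return float(self.taus[0])

    @property
    def tau_max(self) -> float:
        return float(self.taus[-1])

    def __eq__(self, other) -> bool:
        return (isinstance(other, TimescaleGrid)
                and self.taus.shape == other.taus.shape
                and bool(np.all(self.taus == other.taus)))


def build_grid(n: int | None = None, tau_min: float | None = None,
               tau_max: float | None = None, preset: str | None = None) -> TimescaleGrid:
    """Build a log-equidistant grid, either explicitly or from a preset.

    ``build_grid(preset="NH")`` gives 100 timescales from 1 ps to 100 ns
    (ratio 10^(5/99)); ``preset="CH"`` gives 500 from 1 fs to 1 us.
    """
    if preset is not None:
        try:
            n, tau_min, tau_max = GRID_PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; available: {sorted(GRID_PRESETS)}") from None
    if n is None or tau_min is None or tau_max is None:
        raise ValueError("provide n, tau_min and tau_max, or a preset name")
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < tau_min < tau_max:
        raise ValueError("require 0 < tau_min < tau_max")
    return TimescaleGrid(np.geomspace(tau_min, tau_max, int(n)))


@dataclass
class ExponentialFit:
    """NNLS weights on a timescale grid for one site's correlation function.

    ``residual`` is the RMS misfit over the fitted lag points. ``flags``
    marks weights zeroed by the artificial-slow-timescale filter.
    """

    site_label: str
    grid: TimescaleGrid
    weights: np.ndarray
    residual: float
    flags: np.ndarray = field(default=None)  # bool per grid point

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.grid.n,):
            raise ValueError("one weight per grid timescale required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if self.flags is None:
            self.flags = np.zeros(self.grid.n, dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool)

    def reconstruct(self, times: np.ndarray) -> np.ndarray:
        """Evaluate C_fit at the given times (ps)."""
        t = np.asarray(times, dtype=float)
        return np.exp(-t[..., None] / self.grid.taus) @ self.weights

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


def fit_exponentials(cf: CorrelationFunction, grid: TimescaleGrid) -> ExponentialFit:
    """Fit non-negative exponential weights to a correlation function.

    Solves ``min || C(t_k) - sum_i alpha_i exp(-t_k/tau_i) ||_2`` over
    ``alpha_i >= 0`` with every lag point weighted equally. The solution is
    deterministic; near-degenerate neighbouring grid points may trade
    weight between solvers, but the reconstructed curve and J(omega) are
    solver-independent.
    """
    t = cf.lags
    c = cf.values
    if t.size < 10:
        raise ValueError("need at least 10 lag points to fit")
    if not np.all(np.isfinite(c)):
        raise ValueError("correlation values contain non-finite entries")
    if np.all(c == 0):
        raise ValueError("correlation values are all zero")
    A = np.exp(-t[:, None] / grid.taus)
    weights, rnorm = scipy.optimize.nnls(A, c)
    residual = float(rnorm / np.sqrt(t.size))
    return ExponentialFit(cf.site_label, grid, weights, residual)


def filter_artificial_slow(fit: ExponentialFit, weight_threshold: float = 0.01,
                           n_slowest: int = 1) -> ExponentialFit:
    """Zero a small weight sitting on the slowest grid timescale(s).

    Such weights arise when the correlation function has not equilibrated
    to its zero plateau within the fitted lag range; below
    ``weight_threshold`` (default 1%) they are treated as artifacts and
    removed (flagged, not renormalized). A slow weight exceeding the
    threshold is left untouched with a warning — it may be real dynamics
    or a sign the simulation is too short.

    ``n_slowest`` extends the filter to the k slowest grid points.
    """
    if not 0.0 <= weight_threshold <= 1.0:
        raise ValueError("weight_threshold must be in [0, 1]")
    weights = fit.weights.copy()
    flags = fit.flags.copy()
    touched = False
    for i in range(fit.grid.n - 1, fit.grid.n - 1 - n_slowest, -1):
        w = weights[i]
        if w == 0.0:
            continue
        if w < weight_threshold:
            weights[i] = 0.0
            flags[i] = True
            touched = True
        else:
            warnings.warn(
                f"site {fit.site_label!r}: weight {w:.3g} on slow timescale "
                f"{fit.grid.taus[i]:.3g} ps exceeds the artifact threshold "
                f"{weight_threshold:g}; keeping it", stacklevel=2)
    if not touched and np.array_equal(flags, fit.flags):
        return fit
    return replace(fit, weights=weights, flags=flags)


def spectral_density(fit: ExponentialFit, omega: float | np.ndarray):
    """Spectral density J(omega) of the fitted correlation function.

    ``omega`` in rad/ps; the result carries units of ps (so J(0) = 2 tau_eff).
    Normalization follows C(0) = 1: J here is five times the conventional
    Lipari-Szabo spectral density, which the relaxation module accounts for.
    """
    omega = np.asarray(omega, dtype=float)
    taus = fit.grid.taus
    J = 2.0 * np.sum(fit.weights * taus / (1.0 + (omega[..., None] * taus) ** 2), axis=-1)
    return float(J) if J.ndim == 0 else J


def effective_correlation_time(fit: ExponentialFit) -> float:
    """tau_eff = integral of C_fit over [0, inf) = sum_i alpha_i tau_i, in ps.

    Evaluated as J(0)/2 so the consistency chain tau_eff = J(0)/2 holds
    to the last bit.
    """
    return float(spectral_density(fit, 0.0) / 2.0)


def write_fit_table(fits: list[ExponentialFit], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# spinscape exponential-fit table\n")
        fh.write("# columns: tau_ps\tweight\tfiltered\n")
        for fit in fits:
            fh.write(f"# site {fit.site_label}\n")
            fh.write(f"# residual {fit.residual:.9g}\n")
            for tau, w, fl in zip(fit.grid.taus, fit.weights, fit.flags):
                fh.write(f"{tau:.9g}\t{w:.9g}\t{int(fl)}\n")


def read_fit_table(path) -> list[ExponentialFit]:
    fits: list[ExponentialFit] = []
    label = None
    residual = 0.0
    rows: list[tuple[float, float, int]] = []

    def flush():
        nonlocal rows
        if label is not None and rows:
            arr = np.asarray(rows)
            # snap the 9-digit printed taus back onto the exact grid
            taus = np.geomspace(arr[0, 0], arr[-1, 0], arr.shape[0])
            if not np.allclose(taus, arr[:, 0], rtol=1e-6):
                raise ValueError(f"{path}: site {label!r} timescales are not "
                                 "log-equidistant")
            fits.append(ExponentialFit(label, TimescaleGrid(taus),
                                       arr[:, 1], residual, arr[:, 2].astype(bool)))
        rows = []

    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("site "):
                    flush()
                    label = body[5:].strip()
                elif body.startswith("residual "):
                    residual = float(body[9:])
                continue
            parts = line.split()
            rows.append((float(parts[0]), float(parts[1]), int(parts[2])))
    flush()
    return fits
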