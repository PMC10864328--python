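"""Second-order Legendre (P2) rotational autocorrelation functions.

For a unit bond vector u(t) the rotational correlation function is

    C(t) = < P2( u(t') . u(t'+t) ) >_{t'} ,   P2(x) = (3 x^2 - 1) / 2,

averaged over every available time origin t'. The implementation expands
P2 of the dot product into autocorrelations of the six independent
component products u_a u_b and evaluates them with FFTs, which is exact
(it matches a direct double loop to rounding error) and O(n log n).

Lag times run from 0 up to a fraction of the total trajectory length —
by default 1/100 for a single-molecule site and 1/20 when averaging a
group of equivalent sites across many molecules, where the extra
statistics justify longer lags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len, rfft, irfft

from .trajectory_io import VectorTrajectory

__all__ = [
    "CorrelationFunction",
    "p2_autocorrelation",
    "average_correlations",
    "write_correlation_table",
    "read_correlation_table",
    "DEFAULT_SINGLE_LAG_FRACTION",
    "DEFAULT_GROUP_LAG_FRACTION",
]

DEFAULT_SINGLE_LAG_FRACTION = 1.0 / 100.0
DEFAULT_GROUP_LAG_FRACTION = 1.0 / 20.0


@dataclass
class CorrelationFunction:
    """P2 autocorrelation of one site (or averaged group of sites)."""

    site_label: str
    lags: np.ndarray      # ps, starting at 0, uniformly spaced
    values: np.ndarray    # dimensionless, values[0] == 1 for unit input
    n_frames_used: int
    max_lag_fraction: float

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape or self.lags.ndim != 1:
            raise ValueError("lags and values must be matching 1-D arrays")
        if self.lags[0] != 0.0:
            raise ValueError("lags must start at 0")

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])


def _autocorr_fft(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Unnormalized autocorrelation sums  ac[k] = sum_t x[t] x[t+k]."""
    n = x.size
    nfft = next_fast_len(2 * n)
    f = rfft(x, nfft)
    return irfft(f * np.conj(f), nfft)[:n_lags]


def _p2_site(u: np.ndarray, n_lags: int) -> np.ndarray:
    """P2 autocorrelation of one site from component-product autocorrelations.

    (u.v)^2 = sum_{a,b} u_a u_b v_a v_b, so the lag average of the squared
    dot product is a weighted sum of six scalar autocorrelations.
    """
    n = u.shape[0]
    acc = np.zeros(n_lags)
    for a in range(3):
        for b in range(a, 3):
            s = u[:, a] * u[:, b]
            w = 1.0 if a == b else 2.0
            acc += w * _autocorr_fft(s, n_lags)
    counts = n - np.arange(n_lags)
    return 1.5 * acc / counts - 0.5


def p2_autocorrelation(
    vt: VectorTrajectory,
    max_lag_fraction: float | None = None,
    group_average: dict[str, list[str]] | None = None,
) -> list[CorrelationFunction]:
    """Compute P2 rotational autocorrelation functions for every site/group.

    Parameters
    ----------
    vt:
        Input unit-vector trajectory (>= 2 frames, uniform dt).
    max_lag_fraction:
        Longest lag as a fraction of the total trajectory length. Defaults
        to 1/100 per single site and 1/20 for multi-site groups.
    group_average:
        Optional mapping ``{group_label: [site_label, ...]}``. The group's
        correlation function is the arithmetic mean of its members'
        functions (chemically equivalent sites, e.g. the same SDS carbon
        in every molecule).

    Returns one :class:`CorrelationFunction` per site (or per group, in
    mapping order) with lags 0, dt, 2 dt, ...
    """
    if vt.n_frames < 2:
        raise ValueError("need at least 2 frames")
    frac = max_lag_fraction
    if frac is None:
        frac = DEFAULT_GROUP_LAG_FRACTION if group_average else DEFAULT_SINGLE_LAG_FRACTION
    if not 0.0 < frac <= 1.0:
        raise ValueError("max_lag_fraction must be in (0, 1]")

    total = (vt.n_frames - 1) * vt.dt
    n_lags = int(np.floor(frac * total / vt.dt)) + 1
    n_lags = min(n_lags, vt.n_frames)
    if n_lags < 10:
        warnings.warn(
            f"max_lag_fraction={frac:g} yields only {n_lags} lags; "
            "statistics will be poor", stacklevel=2)
    lags = vt.dt * np.arange(n_lags)

    per_site = {}
    results = []

    def site_cf(label: str) -> np.ndarray:
        if label not in per_site:
            per_site[label] = _p2_site(vt.site(label), n_lags)
        return per_site[label]

    if group_average:
        for gname, members in group_average.items():
            if not members:
                raise ValueError(f"group {gname!r} is empty")
            vals = np.mean([site_cf(m) for m in members], axis=0)
            results.append(CorrelationFunction(gname, lags, vals, vt.n_frames, frac))
    else:
        for label in vt.site_labels:
            results.append(
                CorrelationFunction(label, lags, site_cf(label), vt.n_frames, frac))

    coarse = [cf.site_label for cf in results
              if cf.values.size > 1 and cf.values[1] < 0.95]
    if coarse:
        warnings.warn(
            "C(dt) < 0.95 for site(s) "
            f"{coarse}: the trajectory saving frequency may be too coarse to "
            "resolve the fastest motions", stacklevel=2)
    return results


def average_correlations(cfs: list[CorrelationFunction],
                         label: str | None = None) -> CorrelationFunction:
    """Average correlation functions from replicate simulations.

    All inputs must share the same lag axis. Whether replicas are averaged
    before fitting or fitted individually is the caller's choice.
    """
    if not cfs:
        raise ValueError("no correlation functions to average")
    lags = cfs[0].lags
    for cf in cfs[1:]:
        if cf.lags.shape != lags.shape or not np.allclose(cf.lags, lags, rtol=0, atol=1e-9):
            raise ValueError("correlation functions have mismatched lag axes")
    vals = np.mean([cf.values for cf in cfs], axis=0)
    return CorrelationFunction(
        label or f"avg({','.join(cf.site_label for cf in cfs)})",
        lags, vals, cfs[0].n_frames_used, cfs[0].max_lag_fraction)


def write_correlation_table(cfs: list[CorrelationFunction], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# spinscape correlation table\n")
        fh.write("# columns: lag_ps\tvalue\n")
        for cf in cfs:
            fh.write(f"# site {cf.site_label}\n")
            for lag, val in zip(cf.lags, cf.values):
                fh.write(f"{lag:.9g}\t{val:.9g}\n")


def read_correlation_table(path) -> list[CorrelationFunction]:
    labels: list[str] = []
    blocks: list[list[tuple[float, float]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("site "):
                    labels.append(body[5:].strip())
                    blocks.append([])
                continue
            if not blocks:
                raise ValueError(f"{path}:{lineno}: data before any site header")
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            blocks[-1].append((float(parts[0]), float(parts[1])))
    out = []
    for label, rows in zip(labels, blocks):
        arr = np.asarray(rows)
        out.append(CorrelationFunction(label, arr[:, 0], arr[:, 1],
                                       n_frames_used=0, max_lag_fraction=float("nan")))
    return out
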